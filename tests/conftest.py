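from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from dimorph import (
    SimulationConfig,
    build_profiles,
    call_sde_all,
    generate_dataset,
    join_and_validate,
)


def make_dataset(rows: dict[str, dict[str, list[float]]], replicate_noise: float = 0.0):
    """Build a tiny validated dataset from per-probeset, per-tissue
    (male values, female values) specs.

    ``rows`` maps probeset id -> tissue -> (m_values, f_values); every
    probeset must cover the same tissues with the same group sizes.
    """
    first = next(iter(rows.values()))
    tissues = list(first)
    sample_ids, animal, tcol, scol = [], [], [], []
    for tissue in tissues:
        m_vals, f_vals = first[tissue]
        for sex, vals in (("M", m_vals), ("F", f_vals)):
            for k in range(len(vals)):
                sample_ids.append(f"{tissue}_{sex}{k + 1}")
                animal.append(f"{sex}{k + 1}")
                tcol.append(tissue)
                scol.append(sex)
    data = {}
    for pid, spec in rows.items():
        vals = []
        for tissue in tissues:
            m_vals, f_vals = spec[tissue]
            vals.extend(list(m_vals) + list(f_vals))
        data[pid] = vals
    matrix = pd.DataFrame(data, index=sample_ids).T
    matrix.index.name = "probeset_id"
    annotation = pd.DataFrame(
        {"sample_id": sample_ids, "animal_id": animal, "tissue": tcol, "sex": scol}
    )
    return join_and_validate(matrix, annotation)


@pytest.fixture(scope="session")
def demo_sim():
    """One moderate default-shaped simulation shared across tests."""
    cfg = SimulationConfig(n_probesets=2500, seed=11)
    matrix, annotation, truth = generate_dataset(cfg)
    dataset = join_and_validate(matrix, annotation)
    stats = call_sde_all(dataset)
    profiles = build_profiles(stats)
    return SimpleNamespace(
        cfg=cfg,
        matrix=matrix,
        annotation=annotation,
        truth=truth,
        dataset=dataset,
        stats=stats,
        profiles=profiles,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
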