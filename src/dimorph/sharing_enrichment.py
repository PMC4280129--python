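"""Pairwise sharing of SDE probesets between tissues and its enrichment
over chance.

The sharing universe is the set of probesets SDE in at least two
tissues (ubiquitous-SDE probesets excluded by default — they would
dominate every pair). With n_X the number of such probesets SDE in
tissue X and T the pair-weighted total

    T = sum over probesets of C(k, 2),  k = number of SDE tissues,

the chance expectation for a pair (A, B) is

    expected = frac_A * frac_B * T,   frac_X = n_X / T,

i.e. expected = n_A * n_B / T, and enrichment = observed / expected.
A probeset SDE in 2 tissues contributes 1 pair, in 3 tissues 3 pairs,
in 4 tissues 6 pairs.

`enrichment_null_mc` provides a Monte-Carlo oracle for this chance
model: by default each of the T pair slots hits pair (A, B) with
probability frac_A * frac_B, which reproduces the expectation formula
exactly; a set-resampling null (each probeset redraws its tissue set
with inclusion weights proportional to frac) is available for
comparison but is not mean-one under the formula above.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from dimorph.cross_tissue import CrossTissueProfiles

__all__ = [
    "shared_counts",
    "total_probeset_pairs",
    "enrichment_table",
    "excess_from_enrichment",
    "enrichment_null_mc",
    "NullDistribution",
]


def _sharing_universe(
    profiles: CrossTissueProfiles, exclude: Iterable[str]
) -> pd.DataFrame:
    """Boolean probeset x tissue SDE matrix of the sharing universe."""
    exclude = set(exclude)
    keep = (profiles.n_sde >= 2) & ~profiles.probesets.isin(sorted(exclude))
    return profiles.sde.loc[keep]


def shared_counts(
    profiles: CrossTissueProfiles, exclude: Iterable[str] = ()
) -> pd.DataFrame:
    """Symmetric tissue x tissue table of shared SDE probesets.

    Entry (A, B) counts probesets SDE in both A and B regardless of
    bias direction; the diagonal holds each tissue's count of
    multi-tissue SDE probesets (the sharing universe's per-tissue
    totals).
    """
    s = _sharing_universe(profiles, exclude).to_numpy(dtype=np.int64)
    counts = s.T @ s
    tissues = profiles.tissues
    return pd.DataFrame(counts, index=tissues, columns=tissues)


def total_probeset_pairs(
    profiles: CrossTissueProfiles, exclude: Iterable[str] = ()
) -> int:
    """Pair-weighted size of the sharing universe: sum of C(k, 2)."""
    k = _sharing_universe(profiles, exclude).sum(axis=1).to_numpy()
    return int((k * (k - 1) // 2).sum())


def excess_from_enrichment(observed: float, enrichment: float) -> float:
    """Probesets shared beyond chance: observed - observed/enrichment.

    Algebraically observed - expected, but computable from a reported
    (observed, enrichment) pair alone.
    """
    if enrichment == 0:
        raise ValueError("enrichment must be nonzero")
    return observed - observed / enrichment


def enrichment_table(
    profiles: CrossTissueProfiles, exclude: Iterable[str] = ()
) -> pd.DataFrame:
    """PairSharingRecord table over all unordered tissue pairs.

    Columns: tissue_a, tissue_b, observed, frac_a, frac_b, total_pairs,
    expected, enrichment, excess. Enrichment is NaN (undefined) when
    expected is 0; a warning is issued if that happens with nonzero
    observed sharing. Records are symmetric in (A, B); each unordered
    pair appears once, in tissue order.
    """
    counts = shared_counts(profiles, exclude)
    total = total_probeset_pairs(profiles, exclude)
    tissues = list(counts.index)
    diag = pd.Series(np.diag(counts.to_numpy()), index=tissues, dtype=float)
    frac = diag / total if total > 0 else diag * np.nan
    rows = []
    for a, b in itertools.combinations(tissues, 2):
        observed = int(counts.loc[a, b])
        expected = frac[a] * frac[b] * total if total > 0 else 0.0
        if expected > 0:
            enrichment = observed / expected
        else:
            enrichment = np.nan
            if observed > 0:
                warnings.warn(
                    f"pair ({a}, {b}): observed sharing {observed} but expected 0; "
                    "enrichment undefined"
                )
        rows.append(
            {
                "tissue_a": a,
                "tissue_b": b,
                "observed": observed,
                "frac_a": frac[a],
                "frac_b": frac[b],
                "total_pairs": total,
                "expected": expected,
                "enrichment": enrichment,
                "excess": observed - expected,
            }
        )
    return pd.DataFrame(rows)


def render_table2_matrix(
    profiles: CrossTissueProfiles, exclude: Iterable[str] = (), decimals: int = 1
) -> pd.DataFrame:
    """Square rendering: shared counts above the diagonal, per-tissue
    multi-tissue SDE totals on it, enrichment (1 decimal) below."""
    counts = shared_counts(profiles, exclude)
    table = enrichment_table(profiles, exclude)
    tissues = list(counts.index)
    out = pd.DataFrame("", index=tissues, columns=tissues, dtype=object)
    for t in tissues:
        out.loc[t, t] = str(int(counts.loc[t, t]))
    pos = {t: i for i, t in enumerate(tissues)}
    for rec in table.itertuples():
        i, j = pos[rec.tissue_a], pos[rec.tissue_b]
        hi, lo = (rec.tissue_a, rec.tissue_b) if i < j else (rec.tissue_b, rec.tissue_a)
        out.loc[hi, lo] = str(int(rec.observed))
        if np.isfinite(rec.enrichment):
            out.loc[lo, hi] = f"{rec.enrichment:.{decimals}f}"
    return out


@dataclass
class NullDistribution:
    """Per-pair Monte-Carlo null of shared counts.

    mean/q025/q975 are tissue-pair indexed Series of the simulated
    shared-count distribution; mean_enrichment averages simulated
    count/expected over replicates and pairs with positive expectation.
    """

    mean: pd.Series
    q025: pd.Series
    q975: pd.Series
    mean_enrichment: float
    se_enrichment: float
    n_reps: int
    method: str


def enrichment_null_mc(
    profiles: CrossTissueProfiles,
    n_reps: int,
    seed: int,
    exclude: Iterable[str] = (),
    method: str = "pair_slots",
) -> NullDistribution:
    """Monte-Carlo null distribution of per-pair shared counts.

    method="pair_slots" (default): each replicate draws, for every
    unordered tissue pair, a Binomial(T, frac_a*frac_b) shared count —
    the generative reading of the chance formula, mean-one by
    construction. method="resample_sets": each replicate reassigns
    every universe probeset's k SDE tissues by weighted sampling
    without replacement (weights proportional to frac) and recounts
    sharing.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method not in ("pair_slots", "resample_sets"):
        raise ValueError("method must be 'pair_slots' or 'resample_sets'")
    rng = np.random.default_rng(seed)
    universe = _sharing_universe(profiles, exclude)
    tissues = profiles.tissues
    n_t = len(tissues)
    k = universe.sum(axis=1).to_numpy()
    total = int((k * (k - 1) // 2).sum())
    if total == 0:
        raise ValueError("sharing universe is empty (no multi-tissue SDE probesets)")
    n_x = universe.sum(axis=0).to_numpy(dtype=float)
    frac = n_x / total
    pairs = list(itertools.combinations(range(n_t), 2))
    pair_index = pd.MultiIndex.from_tuples(
        [(tissues[i], tissues[j]) for i, j in pairs], names=["tissue_a", "tissue_b"]
    )
    p_pair = np.array([frac[i] * frac[j] for i, j in pairs])
    expected = p_pair * total

    if method == "pair_slots":
        sims = rng.binomial(total, np.clip(p_pair, 0, 1), size=(n_reps, len(pairs)))
    else:
        weights = n_x / n_x.sum()
        sims = np.empty((n_reps, len(pairs)), dtype=np.int64)
        ks = k[k >= 2]
        for r in range(n_reps):
            member = np.zeros((len(ks), n_t), dtype=bool)
            for row, kk in enumerate(ks):
                chosen = rng.choice(n_t, size=int(kk), replace=False, p=weights)
                member[row, chosen] = True
            cnt = member.T @ member
            sims[r] = [cnt[i, j] for i, j in pairs]

    ok = expected > 0
    ratios = sims[:, ok] / expected[ok]
    mean_enr = float(ratios.mean())
    se_enr = float(ratios.mean(axis=1).std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.nan
    return NullDistribution(
        mean=pd.Series(sims.mean(axis=0), index=pair_index),
        q025=pd.Series(np.quantile(sims, 0.025, axis=0), index=pair_index),
        q975=pd.Series(np.quantile(sims, 0.975, axis=0), index=pair_index),
        mean_enrichment=mean_enr,
        se_enrichment=se_enr,
        n_reps=n_reps,
        method=method,
    )
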