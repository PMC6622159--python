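"""Scoring ranked couplings against contact maps.

The headline metric is the positive predictive value (PPV) of the top
k ranked coupling pairs: the fraction of them that are contacts under a
chosen definition, conventionally at k = floor(L/2).  Average precision
summarises the whole ranking (the recall-weighted mean of precision)
and is less sensitive to the number of true contacts, which matters
when comparing contact definitions that classify different counts.
Per-protein PPVs under two definitions are compared with a paired
Wilcoxon signed-rank test and summarised as the median percent increase.

Short-range pairs (chain separation below ``min_sep``) are excluded from
the ranking before taking the top k, matching the restriction applied to
contacts, so numerator and denominator refer to the same pair universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import wilcoxon

from .contact_geometry import ContactMap
from .coupling_scores import RankedPairs

__all__ = [
    "EvalResult",
    "PairedComparison",
    "ppv_top_k",
    "average_precision",
    "paired_comparison",
    "benchmark_statistics",
]


@dataclass(frozen=True)
class EvalResult:
    ppv: float
    k: int
    n_true: int
    average_precision: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.ppv <= 1.0):
            raise ValueError("ppv must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class PairedComparison:
    ppvs_a: tuple[float, ...]
    ppvs_b: tuple[float, ...]
    median_ratio: float
    percent_increase: float
    statistic: float
    p_value: float


def _check_compatible(rp: RankedPairs, cm: ContactMap) -> None:
    if rp.L != cm.L:
        raise ValueError(f"ranking is for L={rp.L} but contact map has L={cm.L}")
    if rp.min_sep != cm.min_sep:
        raise ValueError(
            f"ranking min_sep={rp.min_sep} differs from contact map min_sep={cm.min_sep}"
        )


def ppv_top_k(rp: RankedPairs, cm: ContactMap, k: int | None = None) -> EvalResult:
    """PPV of the top k ranked pairs; k defaults to floor(L/2)."""
    _check_compatible(rp, cm)
    if k is None:
        k = rp.L // 2
    top = rp.top(k)
    hits = sum(1 for p in top if p in cm.pairs)
    return EvalResult(ppv=hits / k, k=k, n_true=len(cm.pairs))


def average_precision(rp: RankedPairs, cm: ContactMap) -> float:
    """AP = sum_k (R_k - R_{k-1}) P_k over the full deterministic ranking."""
    _check_compatible(rp, cm)
    n_true = len(cm.pairs)
    if n_true == 0:
        raise ValueError("empty contact map")
    labels = np.fromiter(
        ((i, j) in cm.pairs for i, j, _ in rp.pairs), dtype=bool, count=len(rp)
    )
    tp = np.cumsum(labels)
    precision = tp / np.arange(1, len(rp) + 1)
    # recall increments are 1/n_true exactly at the true-contact ranks
    return float(precision[labels].sum() / n_true)


def paired_comparison(ppvs_a, ppvs_b) -> PairedComparison:
    """Wilcoxon signed-rank comparison of paired per-protein PPVs.

    The effect size is the median of elementwise ratios b/a, reported as
    a percent increase of b over a.  Uses the exact signed-rank null for
    fewer than 25 pairs (when no differences are zero) and the normal
    approximation otherwise.
    """
    a = np.asarray(ppvs_a, dtype=float)
    b = np.asarray(ppvs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.any(a == 0):
        raise ValueError("zero PPV in the reference method; ratios undefined")
    d = b - a
    if np.all(d == 0):
        # degenerate test: no evidence either way, but the effect size
        # (median ratio 1, a 0% increase) is still well defined
        import warnings

        warnings.warn("all paired differences are zero; signed-rank test is degenerate")
        res_stat, res_p = 0.0, 1.0
    else:
        method = "exact" if (a.size < 25 and not np.any(d == 0)) else "approx"
        res = wilcoxon(b, a, alternative="two-sided", method=method)
        res_stat, res_p = float(res.statistic), float(res.pvalue)
    med = float(np.median(b / a))
    return PairedComparison(
        ppvs_a=tuple(a.tolist()),
        ppvs_b=tuple(b.tolist()),
        median_ratio=med,
        percent_increase=(med - 1.0) * 100.0,
        statistic=res_stat,
        p_value=res_p,
    )


def benchmark_statistics(pdb_paths, chains=None, min_sep: int = 12, cutoff: float = 8.0) -> dict:
    """Dataset-level medians over a collection of structures.

    For each structure: the Spearman correlation between CA and
    side-chain-center distances, the count-matched CA/SC-center and
    CB/SC-center contact overlaps, and the all-eligible-pairs fraction of
    both-toward side-chain orientations.  Returns the medians across
    structures, the summary used for benchmark sets of solved proteins.
    """
    from .contact_geometry import (
        ReferenceMethod,
        contacts_fixed,
        contacts_matched,
        distance_correlation,
        distance_matrix,
        eligible_pairs,
    )
    from .orientation import OrientationType, orientation_summary
    from .structure_io import load_structure

    pdb_paths = list(pdb_paths)
    if not pdb_paths:
        raise ValueError("no structures given")
    if chains is None:
        chains = [None] * len(pdb_paths)
    rhos, ov_ca_sc, ov_cb_sc, toward = [], [], [], []
    for path, chain in zip(pdb_paths, chains):
        s = load_structure(path, chain=chain, map_nonstandard=True)
        dm_ca = distance_matrix(s, ReferenceMethod.CA)
        dm_cb = distance_matrix(s, ReferenceMethod.CB)
        dm_sc = distance_matrix(s, ReferenceMethod.SC_CENTER)
        cm_ca = contacts_fixed(dm_ca, cutoff, min_sep)
        n = len(cm_ca.pairs)
        from .contact_geometry import overlap_fraction
        cm_sc = contacts_matched(dm_sc, n, min_sep).contact_map
        cm_cb = contacts_matched(dm_cb, n, min_sep).contact_map
        rhos.append(distance_correlation(dm_ca, dm_sc, min_sep))
        ov_ca_sc.append(overlap_fraction(cm_ca, cm_sc))
        ov_cb_sc.append(overlap_fraction(cm_cb, cm_sc))
        summ = orientation_summary(s, eligible_pairs(s.L, min_sep))
        toward.append(summ.fractions[OrientationType.BOTH_TOWARD])
    return {
        "n_structures": len(pdb_paths),
        "median_spearman_ca_sc": float(np.median(rhos)),
        "median_overlap_ca_sc": float(np.median(ov_ca_sc)),
        "median_overlap_cb_sc": float(np.median(ov_cb_sc)),
        "median_both_toward_all_pairs": float(np.median(toward)),
    }
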