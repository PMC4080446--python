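"""Moderated two-sample statistic with permutation FDR (SAM-style).

For gene *i* with case mean x̄_c, control mean x̄_n and pooled standard error
s_i, the moderated statistic is

    d_i = (x̄_c − x̄_n) / (s_i + s0)

where s0 ≥ 0 is a small "fudge" constant that stabilises the variance of d
across the range of s_i. s0 is chosen as the percentile of the s_i
distribution that minimises the coefficient of variation of the median
absolute deviation of d across s_i-quantile bins — the classic SAM recipe.

False-discovery rates come from group-label permutations: for the symmetric
cutoff |d| ≥ c, the estimated FDR is the median permutation count of
|d*| ≥ c divided by the observed count, and per-gene q-values are made
monotone nonincreasing in |d| by a step-down pass.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd

from .types import CASE, CONTROL, GeneProfileMatrix

logger = logging.getLogger(__name__)

HYPO_THRESHOLD = 0.2
HYPER_THRESHOLD = 0.8


def classify_level(mean_beta: float) -> str:
    """Hypo-/mid-/hypermethylated by mean beta (boundaries inclusive)."""
    if mean_beta <= HYPO_THRESHOLD:
        return "hypo"
    if mean_beta >= HYPER_THRESHOLD:
        return "hyper"
    return "mid"


def collapse_probes(
    probe_matrix: GeneProfileMatrix, probe_to_gene: dict[str, str]
) -> GeneProfileMatrix:
    """Average multi-probe rows into one row per gene, per sample.

    Probes with no mapping are dropped (logged).
    """
    mapped = probe_matrix.values.index.map(probe_to_gene.get)
    unmapped = probe_matrix.values.index[mapped.isna()]
    if len(unmapped):
        logger.info("collapse_probes: dropped %d unmapped probes", len(unmapped))
    keep = ~mapped.isna()
    values = probe_matrix.values.loc[keep].groupby(mapped[keep]).mean()
    values.index.name = probe_matrix.values.index.name
    return GeneProfileMatrix(values, probe_matrix.groups)


def _group_arrays(matrix: GeneProfileMatrix) -> tuple[np.ndarray, np.ndarray]:
    return matrix.group_values(CASE), matrix.group_values(CONTROL)


def _pooled_se(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Two-sample pooled standard error of the mean difference, per row."""
    n1, n2 = case.shape[1], control.shape[1]
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((control - control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / (n1 + n2 - 2)
    return np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))


def pooled_se(matrix: GeneProfileMatrix) -> pd.Series:
    case, control = _group_arrays(matrix)
    return pd.Series(_pooled_se(case, control), index=matrix.genes, name="s")


def _d_stat(case: np.ndarray, control: np.ndarray, s0: float) -> np.ndarray:
    s = _pooled_se(case, control)
    if s0 == 0 and np.any(s == 0):
        raise ValueError("zero-variance gene with s0=0: d is undefined")
    return (case.mean(axis=1) - control.mean(axis=1)) / (s + s0)


def sam_d(matrix: GeneProfileMatrix, s0: float) -> pd.Series:
    """Moderated d statistic per gene; s0=0 gives the ordinary t statistic."""
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    case, control = _group_arrays(matrix)
    return pd.Series(_d_stat(case, control, s0), index=matrix.genes, name="d")


def estimate_s0(matrix: GeneProfileMatrix, n_bins: int = 25) -> float:
    """Percentile-search fudge factor minimising the CV of d's spread.

    Candidate s0 values are the 0,5,...,100 percentiles of the s_i
    distribution; genes are binned by s_i quantile and the coefficient of
    variation of the per-bin median absolute deviation of d is minimised.
    Falls back to median(s) when the search is degenerate.
    """
    case, control = _group_arrays(matrix)
    s = _pooled_se(case, control)
    diff = case.mean(axis=1) - control.mean(axis=1)
    if np.allclose(s, s[0]):
        return float(np.median(s))
    n_bins = min(n_bins, max(2, len(s) // 10))
    # quantile bins of s
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = None, math.inf
    for s0 in candidates:
        d = diff / (s + s0)
        mads = np.array(
            [np.median(np.abs(d[b] - np.median(d[b]))) for b in bins]
        )
        mean_mad = mads.mean()
        if mean_mad == 0:
            continue
        cv = mads.std() / mean_mad
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    if best_s0 is None:
        best_s0 = float(np.median(s))
    return best_s0


def _distinct_case_assignments(
    n_samples: int, n_case: int, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Sample distinct case-column index sets, or enumerate all if few."""
    total = math.comb(n_samples, n_case)
    if total <= n_perm:
        if total < n_perm:
            logger.info(
                "sam_fdr: only %d distinct permutations exist (requested %d); "
                "using all", total, n_perm,
            )
        return [np.array(c) for c in combinations(range(n_samples), n_case)]
    seen: set[tuple[int, ...]] = set()
    out: list[np.ndarray] = []
    while len(out) < n_perm:
        pick = tuple(sorted(rng.choice(n_samples, size=n_case, replace=False)))
        if pick in seen:
            continue
        seen.add(pick)
        out.append(np.array(pick))
    return out


def sam_fdr(
    matrix: GeneProfileMatrix,
    n_perm: int = 200,
    fdr_cutoff: float = 0.05,
    rng_seed: int = 0,
    s0: float | None = None,
) -> pd.DataFrame:
    """Permutation q-values for the moderated d statistic.

    Returns a DataFrame indexed by gene with columns ``d``, ``q``,
    ``mean_control``, ``mean_case``, ``class_control``, ``class_case`` and
    ``called`` (q < ``fdr_cutoff``).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    rng = np.random.default_rng(rng_seed)
    if s0 is None:
        s0 = estimate_s0(matrix)

    all_values = matrix.values.to_numpy(float)
    is_case = (matrix.groups == CASE).to_numpy()
    n_case = int(is_case.sum())
    n_samples = all_values.shape[1]

    case, control = _group_arrays(matrix)
    d = _d_stat(case, control, s0)
    abs_d = np.abs(d)

    assignments = _distinct_case_assignments(n_samples, n_case, n_perm, rng)

    # observed count of |d| >= |d_i| for each gene
    sorted_abs = np.sort(abs_d)
    n_genes = len(abs_d)
    obs_count = n_genes - np.searchsorted(sorted_abs, abs_d, side="left")

    # per-permutation counts of |d*| >= |d_i|
    perm_counts = np.empty((len(assignments), n_genes))
    for j, case_cols in enumerate(assignments):
        mask = np.zeros(n_samples, dtype=bool)
        mask[case_cols] = True
        d_perm = _d_stat(all_values[:, mask], all_values[:, ~mask], s0)
        sp = np.sort(np.abs(d_perm))
        perm_counts[j] = n_genes - np.searchsorted(sp, abs_d, side="left")
    median_false = np.median(perm_counts, axis=0)

    q_raw = np.clip(median_false / np.maximum(obs_count, 1), 0.0, 1.0)

    # step-down: q must be nonincreasing in |d|
    order = np.argsort(-abs_d, kind="stable")  # descending |d|
    q_sorted = q_raw[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_raw)
    q[order] = q_sorted

    mean_control = matrix.group_means(CONTROL)
    mean_case = matrix.group_means(CASE)
    result = pd.DataFrame(
        {
            "d": d,
            "q": q,
            "mean_control": mean_control,
            "mean_case": mean_case,
            "class_control": mean_control.map(classify_level),
            "class_case": mean_case.map(classify_level),
        },
        index=matrix.genes,
    )
    result["called"] = result["q"] < fdr_cutoff
    result.attrs["s0"] = s0
    result.attrs["n_perm"] = len(assignments)
    return result
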