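"""SAM-style two-class differential expression with permutation q-values.

The statistic for feature *i* is the moderated t-like score

    d_i = (mean_tumor - mean_normal) / (s_i + s0)

with the pooled scatter

    s_i = sqrt{ (1/n1 + 1/n2) * [SS_normal + SS_tumor] / (n1 + n2 - 2) }

computed on log2-scale values. The exchangeability constant s0 either is the
median of the s_i ("median_s") or is picked from the s-percentile grid
{0, 5, ..., 100} (plus literal 0) by minimizing the coefficient of variation
of the d_i across s-quantile bins ("percentile_search", the Tusher-style
recipe).

False discovery rates come from group-label permutations: with each observed
|d_i| as a cutoff, the number of permuted scores exceeding the cutoff is
aggregated over permutations (median by default, matching samr's "median
number of falsely called genes") and divided by the observed count, then
clipped to [0, 1] and monotonized so q never increases with |d|. When the
number of distinct label assignments C(n, n_tumor) is at most the permutation
cap, all assignments are enumerated and the estimate is exact and
deterministic; otherwise assignments are sampled with the configured seed.

Fold changes are mean(tumor)/mean(normal) on the *linear* scale; selection
takes a feature when q <= q_threshold and max(fc, 1/fc) >= fc_threshold,
calling the direction from fc vs 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .io import NORMAL, TUMOR, ExpressionMatrix, GroupLabels, UsageError

LOG2_EPSILON = 1.0  # pseudo-count before log2 for linear (count-like) input


@dataclass(frozen=True)
class SamConfig:
    s0_strategy: str = "percentile_search"  # or "median_s"
    n_permutations: int = 1000
    q_threshold: float = 1e-6
    fc_threshold: float = 2.5
    seed: int = 0
    null_aggregate: str = "median"  # or "mean"

    def __post_init__(self) -> None:
        if self.s0_strategy not in ("median_s", "percentile_search"):
            raise UsageError(f"unknown s0_strategy {self.s0_strategy!r}")
        if self.n_permutations < 1:
            raise UsageError("n_permutations must be >= 1")
        if not 0.0 <= self.q_threshold <= 1.0:
            raise UsageError("q_threshold must lie in [0, 1]")
        if self.fc_threshold < 1.0:
            raise UsageError("fc_threshold must be >= 1")
        if self.null_aggregate not in ("median", "mean"):
            raise UsageError(f"unknown null_aggregate {self.null_aggregate!r}")


def _log2_values(matrix: ExpressionMatrix) -> pd.DataFrame:
    if matrix.scale_hint == "log2":
        return matrix.values
    return np.log2(matrix.values + LOG2_EPSILON)


def _group_masks(matrix: ExpressionMatrix, labels: GroupLabels) -> tuple[np.ndarray, np.ndarray]:
    labels.validate_against(matrix)
    cols = matrix.sample_ids
    normal = np.array([labels.mapping.get(s) == NORMAL for s in cols])
    tumor = np.array([labels.mapping.get(s) == TUMOR for s in cols])
    return normal, tumor


def _d_and_s(X: np.ndarray, F: np.ndarray, assign: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized d and s for many tumor-assignment vectors.

    X: features x samples with NaN replaced by 0, F: finite mask,
    assign: n_assign x samples boolean tumor indicator.
    Returns (d, s), each features x n_assign; NaN where a group has <2
    observed values for the feature.
    """
    A = assign.T.astype(float)  # samples x n_assign
    B = (~assign).T.astype(float)
    n1 = F @ B  # normal counts, features x n_assign
    n2 = F @ A
    with np.errstate(invalid="ignore", divide="ignore"):
        sum1, sum2 = X @ B, X @ A
        sq1, sq2 = (X * X) @ B, (X * X) @ A
        m1, m2 = sum1 / n1, sum2 / n2
        ss = (sq1 - n1 * m1 * m1) + (sq2 - n2 * m2 * m2)
        ss = np.maximum(ss, 0.0)  # guard tiny negative rounding
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2.0))
        d = (m2 - m1) / (s + s0)
    bad = (n1 < 2) | (n2 < 2)
    d[bad] = np.nan
    s[bad] = np.nan
    return d, s


def sam_d_statistics(matrix: ExpressionMatrix, labels: GroupLabels, s0: float) -> pd.DataFrame:
    """Per-feature SAM d and pooled scatter s on log2 values.

    Features with fewer than two observed values in either group get NaN and
    are excluded downstream.
    """
    if s0 < 0:
        raise UsageError("s0 must be >= 0")
    normal, tumor = _group_masks(matrix, labels)
    log2 = _log2_values(matrix).to_numpy()
    F = np.isfinite(log2)
    X = np.where(F, log2, 0.0)
    relevant = normal | tumor
    d, s = _d_and_s(X[:, relevant], F[:, relevant], tumor[relevant][None, :], s0)
    return pd.DataFrame({"d": d[:, 0], "s": s[:, 0]}, index=matrix.values.index)


def choose_s0(
    s_values: np.ndarray | pd.Series,
    strategy: str = "percentile_search",
    numerators: np.ndarray | pd.Series | None = None,
) -> float:
    """Pick the exchangeability constant s0.

    ``median_s`` returns the median scatter. ``percentile_search`` needs the
    per-feature numerators r_i = mean difference (so that d_i = r_i/(s_i+s0))
    and returns the grid candidate minimizing the coefficient of variation of
    a robust spread of d across s-quantile bins; for constant s all candidates
    tie and the smallest (0) is returned.
    """
    s = np.asarray(s_values, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise UsageError("no finite scatter values")
    if np.all(s == 0):
        return 0.0
    if strategy == "median_s":
        return float(np.median(s))
    if strategy != "percentile_search":
        raise UsageError(f"unknown strategy {strategy!r}")
    if numerators is None:
        raise UsageError("percentile_search requires the per-feature numerators")
    r = np.asarray(numerators, dtype=float)
    keep = np.isfinite(r) & np.isfinite(np.asarray(s_values, dtype=float))
    r = r[keep]
    s = np.asarray(s_values, dtype=float)[keep]
    order = np.argsort(s, kind="mergesort")
    r, s = r[order], s[order]
    n_bins = min(10, max(1, s.size // 5))
    bins = np.array_split(np.arange(s.size), n_bins)
    candidates = np.unique(np.concatenate(([0.0], np.percentile(s, np.arange(0, 101, 5)))))
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = r / (s + s0)
        spreads = np.array([
            1.4826 * np.median(np.abs(d[idx] - np.median(d[idx]))) for idx in bins
        ])
        mean = spreads.mean()
        cv = np.inf if mean == 0 else spreads.std() / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def evaluate_cv(s_values, numerators, s0: float) -> float:
    """Coefficient of variation of the binned d spread at a given s0 (diagnostic)."""
    s = np.asarray(s_values, dtype=float)
    r = np.asarray(numerators, dtype=float)
    keep = np.isfinite(s) & np.isfinite(r)
    r, s = r[keep], s[keep]
    order = np.argsort(s, kind="mergesort")
    r, s = r[order], s[order]
    n_bins = min(10, max(1, s.size // 5))
    bins = np.array_split(np.arange(s.size), n_bins)
    d = r / (s + s0)
    spreads = np.array([
        1.4826 * np.median(np.abs(d[idx] - np.median(d[idx]))) for idx in bins
    ])
    mean = spreads.mean()
    return np.inf if mean == 0 else float(spreads.std() / mean)


def _assignments(n_samples: int, n_tumor: int, config: SamConfig) -> tuple[np.ndarray, bool]:
    """Tumor-assignment indicator matrix: exhaustive if feasible, else sampled."""
    total = comb(n_samples, n_tumor)
    if total <= config.n_permutations:
        assign = np.zeros((total, n_samples), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n_samples), n_tumor)):
            assign[i, list(idx)] = True
        return assign, True
    rng = np.random.default_rng(config.seed)
    assign = np.zeros((config.n_permutations, n_samples), dtype=bool)
    for i in range(config.n_permutations):
        assign[i, rng.choice(n_samples, size=n_tumor, replace=False)] = True
    return assign, False


def permutation_q_values(
    matrix: ExpressionMatrix, labels: GroupLabels, config: SamConfig
) -> pd.Series:
    """Permutation FDR estimate per feature (see module docstring)."""
    normal, tumor = _group_masks(matrix, labels)
    relevant = normal | tumor
    log2 = _log2_values(matrix).to_numpy()[:, relevant]
    F = np.isfinite(log2)
    X = np.where(F, log2, 0.0)
    obs_assign = tumor[relevant][None, :]

    d_obs, s_obs = _d_and_s(X, F, obs_assign, s0=0.0)
    r_obs = d_obs[:, 0] * s_obs[:, 0]  # numerator back-computed at s0=0
    if config.s0_strategy == "median_s":
        s0 = choose_s0(s_obs[:, 0], "median_s")
    else:
        s0 = choose_s0(s_obs[:, 0], "percentile_search", numerators=r_obs)
    d_obs, _ = _d_and_s(X, F, obs_assign, s0=s0)
    d_obs = d_obs[:, 0]

    n_samples = int(relevant.sum())
    n_tumor = int(tumor[relevant].sum())
    assign, _exact = _assignments(n_samples, n_tumor, config)
    d_null, _ = _d_and_s(X, F, assign, s0=s0)

    valid = np.isfinite(d_obs)
    abs_obs = np.abs(d_obs[valid])
    sorted_obs = np.sort(abs_obs)
    # observed count of scores >= each threshold (inclusive)
    obs_count = abs_obs.size - np.searchsorted(sorted_obs, abs_obs, side="left")

    abs_null = np.abs(d_null[valid])  # features x n_assign
    null_counts = np.empty((assign.shape[0], abs_obs.size))
    for p in range(assign.shape[0]):
        col = np.sort(abs_null[:, p][np.isfinite(abs_null[:, p])])
        null_counts[p] = col.size - np.searchsorted(col, abs_obs, side="left")
    if config.null_aggregate == "median":
        expected_false = np.median(null_counts, axis=0)
    else:
        expected_false = null_counts.mean(axis=0)

    q = np.clip(expected_false / obs_count, 0.0, 1.0)
    # monotonize: q must not increase with |d|
    order = np.argsort(-abs_obs, kind="mergesort")
    q_sorted = np.maximum.accumulate(q[order])
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted
    out = np.full(d_obs.shape, np.nan)
    out[valid] = q_mono
    return pd.Series(out, index=matrix.values.index, name="q")


def fold_changes(matrix: ExpressionMatrix, labels: GroupLabels) -> pd.Series:
    """Linear-scale mean(tumor)/mean(normal) per feature; NaN when undefined."""
    normal, tumor = _group_masks(matrix, labels)
    values = matrix.values
    if matrix.scale_hint == "log2":
        values = np.power(2.0, values)
    arr = values.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_n = np.nanmean(np.where(normal[None, :], arr, np.nan), axis=1)
        mean_t = np.nanmean(np.where(tumor[None, :], arr, np.nan), axis=1)
        fc = mean_t / mean_n
    fc[~(mean_n > 0)] = np.nan
    return pd.Series(fc, index=matrix.values.index, name="fc")


def de_table(matrix: ExpressionMatrix, labels: GroupLabels, config: SamConfig) -> pd.DataFrame:
    """Full per-feature table: d, s, q, fc and the selection direction call."""
    stats = sam_d_statistics(matrix, labels, s0=0.0)
    r = stats["d"] * stats["s"]
    if config.s0_strategy == "median_s":
        s0 = choose_s0(stats["s"], "median_s")
    else:
        s0 = choose_s0(stats["s"], "percentile_search", numerators=r)
    stats = sam_d_statistics(matrix, labels, s0=s0)
    table = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "d": stats["d"].to_numpy(),
        "s": stats["s"].to_numpy(),
        "q": permutation_q_values(matrix, labels, config).to_numpy(),
        "fc": fold_changes(matrix, labels).to_numpy(),
    }).set_index("feature_id", drop=False)
    up, down = select_differential(table, config)
    direction = np.where(
        table["feature_id"].isin(sorted(up)), "up",
        np.where(table["feature_id"].isin(sorted(down)), "down", "ns"),
    )
    table["direction"] = direction
    return table


def select_differential(
    de_results: pd.DataFrame, config: SamConfig
) -> tuple[set[str], set[str]]:
    """Apply the q and two-sided fold-change thresholds; split by direction."""
    q = de_results["q"].to_numpy(dtype=float)
    fc = de_results["fc"].to_numpy(dtype=float)
    ids = de_results["feature_id"] if "feature_id" in de_results else de_results.index
    ids = np.asarray(ids, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.maximum(fc, 1.0 / fc)
    ok = np.isfinite(q) & np.isfinite(fc) & (q <= config.q_threshold) & (ratio >= config.fc_threshold)
    up = set(ids[ok & (fc > 1.0)])
    down = set(ids[ok & (fc < 1.0)])
    return up, down
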