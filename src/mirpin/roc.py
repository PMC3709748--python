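"""Marker evaluation: rank-statistic AUC with the Hanley-McNeil standard error.

The AUC is the Mann-Whitney probability estimate

    A = [#{pos > neg} + 0.5 * #{ties}] / (n_pos * n_neg)

computed from average ranks. Its standard error uses the Hanley-McNeil
closed form with Q1 = A/(2-A) and Q2 = 2A^2/(1+A):

    se = sqrt{[A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)}

and significance against the chance line A = 0.5 is a one-sided normal
z-test. ``se_mode="observed"`` uses the SE at the observed A;
``se_mode="null"`` uses the SE evaluated at A = 0.5.

The positive class is tumor and scores are used as-is — a marker that drops
in tumors simply shows A < 0.5 (the source study reports such values rather
than flipping); pass ``flip=True`` to negate scores explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NORMAL, TUMOR, ExpressionMatrix, GroupLabels, UsageError


@dataclass(frozen=True)
class RocResult:
    mirna_id: str
    auc: float
    se: float
    z: float
    p: float
    n_pos: int
    n_neg: int
    orientation: str = "as_is"  # or "flipped"
    degenerate_se: bool = False


def auc_mann_whitney(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Rank-based AUC with 0.5 credit for ties."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise UsageError("both score groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: pos.size].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form SE of the AUC; zero at the degenerate extremes A in {0, 1}."""
    if not 0.0 <= auc <= 1.0:
        raise UsageError(f"AUC must lie in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise UsageError("group sizes must be >= 1")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auc_p_value(
    auc: float, n_pos: int, n_neg: int, se_mode: str = "observed"
) -> tuple[float, float]:
    """One-sided z-test of A against 0.5; returns (z, p)."""
    if se_mode not in ("observed", "null"):
        raise UsageError(f"se_mode must be 'observed' or 'null', got {se_mode!r}")
    se = hanley_mcneil_se(auc if se_mode == "observed" else 0.5, n_pos, n_neg)
    if auc == 0.5:
        return 0.0, 0.5
    if se == 0.0:
        return math.copysign(math.inf, auc - 0.5), 0.0 if auc > 0.5 else 1.0
    z = (auc - 0.5) / se
    return float(z), float(stats.norm.sf(z))


def evaluate_marker(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    mirna_id: str = "",
    *,
    se_mode: str = "observed",
    flip: bool = False,
) -> RocResult:
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if flip:
        pos, neg = -pos, -neg
    a = auc_mann_whitney(pos, neg)
    se = hanley_mcneil_se(a, pos.size, neg.size)
    z, p = auc_p_value(a, pos.size, neg.size, se_mode=se_mode)
    return RocResult(
        mirna_id=mirna_id, auc=a, se=se, z=z, p=p,
        n_pos=pos.size, n_neg=neg.size,
        orientation="flipped" if flip else "as_is",
        degenerate_se=(se == 0.0 and a != 0.5),
    )


def roc_table(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    features: Iterable[str] | None = None,
    *,
    se_mode: str = "observed",
    flip: bool = False,
) -> pd.DataFrame:
    """Evaluate each requested feature as a tumor-vs-normal marker."""
    labels.validate_against(matrix)
    pos_ids = [s for s in matrix.sample_ids if labels.mapping.get(s) == TUMOR]
    neg_ids = [s for s in matrix.sample_ids if labels.mapping.get(s) == NORMAL]
    if features is None:
        features = matrix.feature_ids
    rows = []
    for fid in features:
        if fid not in matrix.values.index:
            raise UsageError(f"feature {fid!r} not in matrix")
        row = matrix.values.loc[fid]
        pos = row[pos_ids].dropna().to_numpy()
        neg = row[neg_ids].dropna().to_numpy()
        res = evaluate_marker(pos, neg, fid, se_mode=se_mode, flip=flip)
        rows.append({
            "feature_id": fid, "auc": res.auc, "se": res.se, "z": res.z,
            "p": res.p, "n_pos": res.n_pos, "n_neg": res.n_neg,
        })
    return pd.DataFrame(rows, columns=["feature_id", "auc", "se", "z", "p",
                                       "n_pos", "n_neg"])
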