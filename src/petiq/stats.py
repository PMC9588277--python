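"""Statistical comparison of reconstruction conditions.

The comparison layer used for repeated phantom measurements: the Friedman
rank test across conditions (balanced repeated measures), Dunn's post-hoc
pairwise test on the Friedman mean ranks, Tukey's HSD applied pointwise to
MTF curves pooled over frequency, and paired t-tests for FWHM values.
Alpha defaults to 0.05 everywhere and is echoed in the findings tables.

Panels are plain DataFrames: one row per replicate, one column per
condition.  With only three replicate scans — a realistic phantom study —
the chi-square approximation to the Friedman statistic is coarse; an
exact-permutation p-value is available via ``permutation=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

__all__ = [
    "FriedmanResult",
    "friedman_test",
    "dunn_posthoc",
    "curve_difference_test",
    "paired_t",
]

_MIN_P = np.finfo(float).tiny


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    mean_ranks: pd.Series  # per condition
    n_replicates: int


def _check_panel(panel: pd.DataFrame, min_conditions: int = 3) -> pd.DataFrame:
    panel = pd.DataFrame(panel)
    if panel.isna().any().any():
        raise AnalysisError("unbalanced panel: missing values present")
    if panel.shape[1] < min_conditions:
        raise AnalysisError(
            f"need at least {min_conditions} conditions, have {panel.shape[1]}"
        )
    if panel.shape[0] < 2:
        raise AnalysisError("need at least 2 replicates")
    return panel


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Within-replicate ranks, average ranks on ties."""
    return np.apply_along_axis(sps.rankdata, 1, values)


def friedman_test(panel: pd.DataFrame, permutation: bool = False) -> FriedmanResult:
    """Friedman chi-square test across the panel's condition columns.

    With ``permutation=True`` the p-value is computed by exhaustive
    permutation of condition labels within replicates (feasible for the
    small designs this is meant for) instead of the chi-square
    approximation; the statistic is unchanged.
    """
    panel = _check_panel(panel)
    values = panel.to_numpy(dtype=float)
    ranks = _rank_rows(values)
    mean_ranks = pd.Series(ranks.mean(axis=0), index=panel.columns)
    if np.all(values == values[:, :1]):
        # every replicate fully tied: no rank variation at all
        return FriedmanResult(0.0, 1.0, mean_ranks, panel.shape[0])
    stat, p = sps.friedmanchisquare(*values.T)
    if permutation:
        n, k = values.shape
        perms = list(permutations(range(k)))
        if len(perms) ** n > 2_000_000:
            raise AnalysisError("design too large for exhaustive permutation")
        count = 0
        total = 0
        idx = np.zeros(n, dtype=int)
        # iterate the cartesian product of row permutations
        while True:
            permuted = np.vstack([values[i, list(perms[idx[i]])] for i in range(n)])
            s = sps.friedmanchisquare(*permuted.T)[0]
            count += s >= stat - 1e-12
            total += 1
            j = 0
            while j < n:
                idx[j] += 1
                if idx[j] < len(perms):
                    break
                idx[j] = 0
                j += 1
            else:
                break
        p = count / total
    return FriedmanResult(float(stat), float(p), mean_ranks, panel.shape[0])


def dunn_posthoc(panel: pd.DataFrame, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on Friedman mean ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt(k (k+1) / (6 n)), two-sided p-values,
    multiplicity-adjusted by ``adjust`` in {"none", "bonferroni", "holm"}.
    Ties are handled by average ranks within replicates.
    """
    panel = _check_panel(panel, min_conditions=2)
    values = panel.to_numpy(dtype=float)
    n, k = values.shape
    mean_ranks = _rank_rows(values).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i, j in combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((panel.columns[i], panel.columns[j], z, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["condition_a", "condition_b", "z", "p_raw"])
    out["p_adj"] = _adjust(out["p_raw"].to_numpy(), adjust)
    return out


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise AnalysisError(f"unknown adjustment {method!r}")


def curve_difference_test(curves: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey's HSD across conditions, pooling all frequency points.

    ``curves`` maps condition label -> 1-D curve (or 2-D replicates x points,
    flattened).  Every curve sample is treated as an independent observation,
    mirroring a pointwise comparison "across all points in frequency space";
    within-curve correlation of adjacent frequencies is deliberately not
    modeled.
    """
    if len(curves) < 2:
        raise AnalysisError("need at least two conditions")
    labels = list(curves)
    samples = [np.asarray(curves[lab], dtype=float).ravel() for lab in labels]
    if len({s.size for s in samples}) != 1:
        raise AnalysisError("curves must share one frequency grid")
    res = sps.tukey_hsd(*samples)
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        rows.append((labels[i], labels[j],
                     float(np.mean(samples[i]) - np.mean(samples[j])),
                     float(res.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["condition_a", "condition_b",
                                       "mean_difference", "p_adj"])


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t-test on two matched condition vectors.

    A constant nonzero difference with zero variance is reported as
    (+/-inf, tiny) rather than NaN so downstream significance flags stay
    well-defined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AnalysisError("paired t needs two equal-length vectors")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), _MIN_P
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)
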