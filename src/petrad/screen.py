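"""Univariate association of radiomic features with nodal status.

Each feature is tested with a two-sided Wilcoxon rank-sum (Mann-Whitney)
test, scored with the rank-based AUC (oriented so AUC >= 0.5), and given a
Youden-optimal cut-off.  The screen applies a raw p <= 0.01 filter with no
multiplicity correction (the published protocol); a Benjamini-Hochberg
column is attached for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .framework import EvaluationReport, confusion, univariate_classifier
from .io import Cohort


def rank_test(values_pos, values_neg) -> float:
    """Two-sided Mann-Whitney p-value: exact enumeration when the pooled
    sample is <= 20 with no ties, otherwise the tie-corrected normal
    approximation with continuity correction."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([pos, neg])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        pos, neg, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def auc(values_pos, values_neg) -> tuple[float, str]:
    """Rank AUC with ties counted 1/2, oriented so the returned AUC >= 0.5.

    Returns (auc, direction) where direction is 'positive-high' when high
    feature values indicate the positive class, else 'positive-low'.
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    raw = u / (len(pos) * len(neg))
    if raw >= 0.5:
        return float(raw), "positive-high"
    return float(1.0 - raw), "positive-low"


def youden_cutoff(values_pos, values_neg, direction: str) -> float:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent sorted unique pooled values;
    ties are broken toward the higher-sensitivity cut-off, then toward the
    smaller threshold.
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    uniq = np.unique(np.concatenate([pos, neg]))
    if len(uniq) == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for c in candidates:
        sens = float(np.mean(univariate_classifier(pos, c, direction)))
        spec = float(np.mean(1 - univariate_classifier(neg, c, direction)))
        key = (sens + spec - 1.0, sens, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return float(best[1])


@dataclass
class UnivariateResult:
    feature_name: str
    p_value: float
    auc: float
    direction: str
    optimal_cutoff: float
    constant: bool = False


def _pos_neg(cohort: Cohort, feature_name: str) -> tuple[np.ndarray, np.ndarray]:
    vals = cohort.feature_values(feature_name)
    y = cohort.ln_histology
    return vals[y == 1], vals[y == 0]


def screen_feature(cohort: Cohort, feature_name: str) -> UnivariateResult:
    pos, neg = _pos_neg(cohort, feature_name)
    if np.ptp(np.concatenate([pos, neg])) == 0:
        warnings.warn(f"feature {feature_name!r} is constant", stacklevel=2)
        return UnivariateResult(feature_name, 1.0, 0.5, "positive-high",
                                float(pos[0]), constant=True)
    p = rank_test(pos, neg)
    a, direction = auc(pos, neg)
    cut = youden_cutoff(pos, neg, direction)
    return UnivariateResult(feature_name, p, a, direction, cut)


def screen_all(cohort: Cohort) -> list[UnivariateResult]:
    """One result per feature, sorted by p-value (feature-name tiebreak)."""
    results = [screen_feature(cohort, name) for name in cohort.feature_names]
    return sorted(results, key=lambda r: (r.p_value, r.feature_name))


def loo_cutoff_assessment(cohort: Cohort, feature_name: str) -> EvaluationReport:
    """Leave-one-out assessment of the single-feature cut-off rule: for each
    patient the direction and Youden cut-off are fitted on the other n - 1
    patients and the held-out patient is classified."""
    vals = cohort.feature_values(feature_name)
    y = cohort.ln_histology
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("each class needs >= 2 members for leave-one-out fitting")
    preds = np.zeros(len(y), dtype=int)
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        pos, neg = vals[keep & (y == 1)], vals[keep & (y == 0)]
        _, direction = auc(pos, neg)
        cut = youden_cutoff(pos, neg, direction)
        preds[i] = univariate_classifier(vals[i], cut, direction)[0]
    return confusion(preds, y)


class UnivariateScreen:
    """Model-style wrapper: ``UnivariateScreen(cohort).fit()`` returns a
    results object with the ranked table and a text summary."""

    def __init__(self, cohort: Cohort):
        self.cohort = cohort

    def fit(self) -> "UnivariateScreenResults":
        return UnivariateScreenResults(self.cohort, screen_all(self.cohort))


class UnivariateScreenResults:
    def __init__(self, cohort: Cohort, results: list[UnivariateResult]):
        self.cohort = cohort
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "feature": r.feature_name,
                    "p_value": r.p_value,
                    "auc": r.auc,
                    "direction": r.direction,
                    "optimal_cutoff": r.optimal_cutoff,
                    "constant": r.constant,
                }
                for r in self.results
            ]
        )
        # information-only multiplicity correction; the selection rule itself
        # uses the raw p <= 0.01 screen
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        bh = np.empty_like(p)
        m = len(p)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, p[i] * m / (rank_idx + 1))
            bh[i] = prev
        df["p_bh"] = bh
        return df

    def significant(self, p_threshold: float = 0.01) -> list[UnivariateResult]:
        return [r for r in self.results if r.p_value <= p_threshold and not r.constant]

    def summary(self, top: int = 12) -> str:
        lines = [
            f"Univariate screen: {len(self.results)} features, "
            f"{len(self.significant())} with p <= 0.01",
            f"{'feature':<20}{'p':>12}{'AUC':>8}  direction      cutoff",
        ]
        for r in self.results[:top]:
            lines.append(
                f"{r.feature_name:<20}{r.p_value:>12.3e}{r.auc:>8.3f}  "
                f"{r.direction:<13} {r.optimal_cutoff:.4g}"
            )
        return "\n".join(lines)
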