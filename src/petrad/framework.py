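"""Evaluation metrics and the unified visual + radiomic prognostic rule.

A patient is called nodal-positive by the unified framework when either the
clinician's visual PET reading or the radiomic model calls them positive
(logical OR).  Sensitivity/specificity are reported as integer percent with
half-up rounding only at reporting time, never inside computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Cohort


def percent(x: float) -> int:
    """Half-up rounding to integer percent (e.g. 69/70 -> 99)."""
    return int(np.floor(100.0 * x + 0.5))


def gmean(sensitivity: float, specificity: float) -> float:
    return float(np.sqrt(sensitivity * specificity))


@dataclass
class EvaluationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    predictions: np.ndarray | None = field(default=None, compare=False)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def gmean(self) -> float:
        return gmean(self.sensitivity, self.specificity)

    @property
    def sensitivity_pct(self) -> int:
        return percent(self.sensitivity)

    @property
    def specificity_pct(self) -> int:
        return percent(self.specificity)

    def summary(self) -> str:
        return (
            f"TP {self.tp}  TN {self.tn}  FP {self.fp}  FN {self.fn}  "
            f"sensitivity {self.sensitivity_pct}%  specificity {self.specificity_pct}%  "
            f"gmean {self.gmean:.4f}"
        )


def confusion(predictions, truth) -> EvaluationReport:
    """Confusion counts and derived rates for aligned binary vectors."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {y.shape} truth")
    return EvaluationReport(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        predictions=pred,
    )


def unified_predict(visual, radiomic) -> np.ndarray:
    """OR-combination: positive if either reading calls positive."""
    v = np.asarray(visual, dtype=int)
    r = np.asarray(radiomic, dtype=int)
    return (v | r).astype(int)


def univariate_classifier(values, cutoff: float, direction: str) -> np.ndarray:
    """Threshold rule: for 'positive-low' features positive iff value < cutoff
    (strict), symmetrically value > cutoff for 'positive-high'."""
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    if direction == "positive-low":
        return (vals < cutoff).astype(int)
    if direction == "positive-high":
        return (vals > cutoff).astype(int)
    raise ValueError(f"unknown direction {direction!r}")


def scanner_robustness(cohort: Cohort, feature_name: str) -> float:
    """Kruskal-Wallis p-value of the feature across scanner groups."""
    frame = cohort.feature_frame()
    scanners = np.asarray(cohort.scanner_ids)
    groups = [
        frame.loc[scanners == s, feature_name].to_numpy(dtype=float)
        for s in sorted(set(scanners))
    ]
    if len(groups) < 2:
        raise ValueError("need at least 2 scanner groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every scanner group needs at least 2 patients")
    return float(stats.kruskal(*groups).pvalue)


def evaluate_pipeline(
    cohort: Cohort,
    mode: str,
    feature_name: str = "GLSZM_ZP",
    cutoff: float | None = None,
    direction: str | None = None,
    ensemble=None,
    loo: bool = False,
) -> EvaluationReport:
    """Score one prediction mode against histology.

    Modes: 'visual' (the clinician's labels); 'univariate' (feature cutoff
    rule, either a fixed cutoff/direction or leave-one-out refitting with
    ``loo=True``); 'multivariate' (a trained ensemble); and their OR
    combinations 'unified-univariate' / 'unified-multivariate'.
    """
    truth = cohort.ln_histology
    if mode == "visual":
        return confusion(cohort.visual_detection, truth)

    if mode in ("univariate", "unified-univariate"):
        if loo:
            from .screen import loo_cutoff_assessment

            radiomic = loo_cutoff_assessment(cohort, feature_name).predictions
        else:
            if cutoff is None or direction is None:
                raise ValueError("univariate mode needs cutoff and direction (or loo=True)")
            radiomic = univariate_classifier(
                cohort.feature_values(feature_name), cutoff, direction
            )
    elif mode in ("multivariate", "unified-multivariate"):
        if ensemble is None:
            raise ValueError("multivariate mode needs a trained ensemble")
        radiomic = ensemble.classify(cohort.feature_frame())
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if mode.startswith("unified"):
        radiomic = unified_predict(cohort.visual_detection, radiomic)
    return confusion(radiomic, truth)
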