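"""Multivariate modelling: correlation-gated feature reduction, stepwise
neural-network model selection, leave-one-out assessment and the final
200-member ensemble.

The protocol mirrors the published one: features surviving the univariate
p <= 0.01 screen enter a greedy redundancy filter (admit a feature only if
|Spearman rho| < 0.85 against everything already kept); candidate networks
(one hidden layer, 2-5 neurons) are compared by the mean gmean index over
leave-one-out sessions with stratified 72/13-proportioned train/validation
splits and a four-fold positive-case loss weight; the selected architecture
is finally trained as an ensemble whose averaged output is thresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .framework import EvaluationReport, confusion
from .io import Cohort
from .nn import TrainedNetwork, n_parameters, train_network_raw
from .screen import UnivariateResult

#: reference split of an 85-patient training pool into 72 train / 13 validation
SPLIT_TRAIN_N, SPLIT_VAL_N = 72, 13


@dataclass
class ReductionConfig:
    p_threshold: float = 0.01
    rho_threshold: float = 0.85

    def __post_init__(self) -> None:
        for name in ("p_threshold", "rho_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1], got {v}")


def spearman(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson correlation of mid-ranks).
    A constant input is undefined; returns 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("Spearman correlation undefined for a constant vector; returning 0",
                      stacklevel=2)
        return 0.0
    return float(stats.spearmanr(x, y).statistic)


def reduce_features(
    univariate: list[UnivariateResult],
    cohort: Cohort,
    config: ReductionConfig | None = None,
) -> list[str]:
    """Greedy redundancy-gated selection.

    Seeds with the smallest-p (largest-AUC tiebreak) feature, then walks the
    remaining features in increasing p order, admitting one only if its
    p-value passes the screen and its |Spearman rho| against every
    already-selected feature stays below the threshold.
    """
    config = config or ReductionConfig()
    ranked = sorted(
        (r for r in univariate if not r.constant),
        key=lambda r: (r.p_value, -r.auc, r.feature_name),
    )
    ranked = [r for r in ranked if r.p_value <= config.p_threshold]
    if not ranked:
        warnings.warn("no feature passes the univariate p-threshold", stacklevel=2)
        return []
    frame = cohort.feature_frame()
    selected = [ranked[0].feature_name]
    for r in ranked[1:]:
        x = frame[r.feature_name].to_numpy(dtype=float)
        if all(
            abs(spearman(x, frame[s].to_numpy(dtype=float))) < config.rho_threshold
            for s in selected
        ):
            selected.append(r.feature_name)
    return selected


# ---------------------------------------------------------------------------
# Splits


def split_sizes(n_pool: int) -> tuple[int, int]:
    """Scale the reference 72/13 subdivision to a pool of ``n_pool`` patients."""
    val_n = max(1, int(round(n_pool * SPLIT_VAL_N / (SPLIT_TRAIN_N + SPLIT_VAL_N))))
    return n_pool - val_n, val_n


def make_split(
    cohort_or_labels, train_n: int, val_n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split of a patient pool into train/validation index
    arrays; the validation positive count is round(val_n * prevalence),
    adjusted so both parts contain both classes.  Reproducible from ``seed``.
    """
    if isinstance(cohort_or_labels, Cohort):
        y = cohort_or_labels.ln_histology
    else:
        y = np.asarray(cohort_or_labels, dtype=int)
    n = len(y)
    if train_n + val_n != n:
        raise ValueError(f"train_n + val_n = {train_n + val_n} != pool size {n}")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == n:
        raise ValueError("both classes must be present in the pool")
    val_pos = int(round(val_n * n_pos / n))
    val_pos = min(max(val_pos, 1), n_pos - 1)  # both parts keep both classes
    val_neg = val_n - val_pos
    n_neg = n - n_pos
    if not 1 <= val_neg <= n_neg - 1:
        raise ValueError("a class is too small to appear in both parts")
    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(np.where(y == 1)[0])
    neg_idx = rng.permutation(np.where(y == 0)[0])
    val_idx = np.sort(np.concatenate([pos_idx[:val_pos], neg_idx[:val_neg]]))
    train_idx = np.sort(np.concatenate([pos_idx[val_pos:], neg_idx[val_neg:]]))
    return train_idx, val_idx


# ---------------------------------------------------------------------------
# Model spec / training


@dataclass
class ModelSpec:
    input_features: tuple[str, ...]
    hidden_neurons: int = 3
    positive_weight: float = 4.0
    output_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_features = tuple(self.input_features)
        if not self.input_features:
            raise ValueError("need at least one input feature")
        if self.hidden_neurons < 1:
            raise ValueError("need at least one hidden neuron")

    @property
    def n_parameters(self) -> int:
        return n_parameters(len(self.input_features), self.hidden_neurons)


def _design(cohort: Cohort, features) -> tuple[np.ndarray, np.ndarray]:
    frame = cohort.feature_frame()
    X = frame[list(features)].to_numpy(dtype=float)
    return X, cohort.ln_histology


def train_network(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    spec: ModelSpec,
    seed: int,
) -> TrainedNetwork:
    return train_network_raw(
        X[train_idx], y[train_idx], X[val_idx], y[val_idx],
        n_hidden=spec.hidden_neurons,
        positive_weight=spec.positive_weight,
        seed=seed,
    )


@dataclass
class LOOAssessment:
    sensitivity: np.ndarray  # per session
    specificity: np.ndarray
    gmean: np.ndarray

    @property
    def mean_gmean(self) -> float:
        return float(self.gmean.mean())

    def summary(self) -> str:
        return (
            f"sensitivity {self.sensitivity.mean():.3f} +/- {self.sensitivity.std():.3f}  "
            f"specificity {self.specificity.mean():.3f} +/- {self.specificity.std():.3f}  "
            f"gmean {self.mean_gmean:.3f} +/- {self.gmean.std():.3f}"
        )


def loo_gmean(
    cohort: Cohort, spec: ModelSpec, n_sessions: int = 20, seed: int = 0
) -> LOOAssessment:
    """Leave-one-out sessions: each held-out patient is predicted by a network
    trained on a stratified 72/13-proportioned split of the remaining pool;
    per-session confusion gives sensitivity/specificity/gmean."""
    X, y = _design(cohort, spec.input_features)
    n = len(y)
    ss = np.random.SeedSequence([seed, spec.seed])
    session_seeds = ss.generate_state(n_sessions * n * 2).reshape(n_sessions, n, 2) % (2**31)
    sens, specf, gm = [], [], []
    for s in range(n_sessions):
        preds = np.zeros(n, dtype=int)
        for i in range(n):
            pool = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            train_n, val_n = split_sizes(n - 1)
            tr, va = make_split(y[pool], train_n, val_n, int(session_seeds[s, i, 0]))
            net = train_network(X, y, pool[tr], pool[va], spec, int(session_seeds[s, i, 1]))
            preds[i] = int(net.predict(X[i : i + 1])[0] >= spec.output_threshold)
        rep = confusion(preds, y)
        sens.append(rep.sensitivity)
        specf.append(rep.specificity)
        gm.append(rep.gmean)
    return LOOAssessment(np.array(sens), np.array(specf), np.array(gm))


def select_model(
    cohort: Cohort,
    candidate_features: list[str],
    hidden_options: tuple[int, ...] = (2, 3, 4, 5),
    n_sessions: int = 20,
    seed: int = 0,
) -> ModelSpec:
    """Stepwise backward selection over input features x hidden sizes, scored
    by mean gmean on leave-one-out sessions; stops when no single-feature
    removal strictly improves the score.  Ties prefer fewer inputs, then
    fewer neurons, then lexicographically smaller feature sets."""
    if not candidate_features:
        raise ValueError("need at least one candidate feature")
    cache: dict[tuple, float] = {}

    def score(features: tuple[str, ...], h: int) -> float:
        key = (features, h)
        if key not in cache:
            spec = ModelSpec(features, h)
            cache[key] = loo_gmean(cohort, spec, n_sessions=n_sessions, seed=seed).mean_gmean
        return cache[key]

    def pick(configs):
        """Best (score, fewer inputs, fewer neurons, lexicographic) config."""
        return max(
            configs,
            key=lambda fh: (score(*fh), -len(fh[0]), -fh[1], tuple(-ord(c) for c in ",".join(fh[0]))),
        )

    full = tuple(sorted(candidate_features))
    current, best_h = pick([(full, h) for h in hidden_options])
    best_score = score(current, best_h)

    while len(current) > 1:
        trials = [
            (tuple(f for f in current if f != drop), h)
            for drop in current
            for h in hidden_options
        ]
        cand_feats, cand_h = pick(trials)
        cand_score = score(cand_feats, cand_h)
        if cand_score > best_score:
            current, best_h, best_score = cand_feats, cand_h, cand_score
        else:
            break
    return ModelSpec(current, best_h)


@dataclass
class TrainedEnsemble:
    """N independently trained members; the model output is the mean of the
    member outputs, classified at ``spec.output_threshold``."""

    members: list[TrainedNetwork]
    spec: ModelSpec

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.spec.input_features)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.mean([m.predict(X) for m in self.members], axis=0)

    def classify(self, X) -> np.ndarray:
        return (self.predict(X) >= self.spec.output_threshold).astype(int)


def train_final_ensemble(
    cohort: Cohort, spec: ModelSpec, n_runs: int = 200, seed: int = 0
) -> TrainedEnsemble:
    """Train ``n_runs`` members on the whole cohort, each with a fresh seeded
    stratified train/validation subdivision (72/13-proportioned)."""
    X, y = _design(cohort, spec.input_features)
    run_seeds = np.random.SeedSequence([seed, spec.seed, 1]).generate_state(n_runs * 2)
    run_seeds = run_seeds.reshape(n_runs, 2) % (2**31)
    train_n, val_n = split_sizes(len(y))
    members = []
    for r in range(n_runs):
        tr, va = make_split(y, train_n, val_n, int(run_seeds[r, 0]))
        members.append(train_network(X, y, tr, va, spec, int(run_seeds[r, 1])))
    return TrainedEnsemble(members, spec)


# ---------------------------------------------------------------------------
# Model-object facade


class NodalModel:
    """Radiomic nodal-metastasis model over a feature-extracted cohort.

    ``NodalModel(cohort, features).fit()`` trains the averaged ensemble and
    returns a results object; with ``features=None`` the inputs are chosen by
    the univariate screen + reduction + stepwise selection pipeline.
    """

    def __init__(
        self,
        cohort: Cohort,
        input_features: list[str] | None = None,
        hidden_neurons: int | None = 3,
        positive_weight: float = 4.0,
    ):
        self.cohort = cohort
        self.input_features = input_features
        self.hidden_neurons = hidden_neurons
        self.positive_weight = positive_weight

    def fit(
        self,
        n_runs: int = 200,
        n_sessions: int = 20,
        hidden_options: tuple[int, ...] = (2, 3, 4, 5),
        seed: int = 0,
    ) -> "NodalModelResults":
        features = self.input_features
        if features is None:
            from .screen import UnivariateScreen

            screen = UnivariateScreen(self.cohort).fit()
            features = reduce_features(screen.results, self.cohort)
            if not features:
                raise ValueError("no feature passes the univariate screen")
        if self.hidden_neurons is None:
            spec = select_model(
                self.cohort, list(features), hidden_options, n_sessions=n_sessions, seed=seed
            )
        else:
            spec = ModelSpec(tuple(features), self.hidden_neurons, self.positive_weight)
        ensemble = train_final_ensemble(self.cohort, spec, n_runs=n_runs, seed=seed)
        return NodalModelResults(self, spec, ensemble)


class NodalModelResults:
    def __init__(self, model: NodalModel, spec: ModelSpec, ensemble: TrainedEnsemble):
        self.model = model
        self.spec = spec
        self.ensemble = ensemble

    def predict(self, cohort: Cohort | pd.DataFrame) -> np.ndarray:
        frame = cohort.feature_frame() if isinstance(cohort, Cohort) else cohort
        return self.ensemble.predict(frame)

    def evaluate(self, cohort: Cohort, unified: bool = False) -> EvaluationReport:
        pred = self.ensemble.classify(cohort.feature_frame())
        if unified:
            pred = (pred | cohort.visual_detection).astype(int)
        return confusion(pred, cohort.ln_histology)

    def summary(self) -> str:
        rep = self.evaluate(self.model.cohort)
        return (
            f"Ensemble of {len(self.ensemble.members)} networks, "
            f"inputs {list(self.spec.input_features)}, "
            f"{self.spec.hidden_neurons} hidden neurons "
            f"({self.spec.n_parameters} parameters)\n"
            f"Training-cohort confusion: {rep.summary()}"
        )
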