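"""Per-participant linear-SVM percept decoding with cross-condition
generalization.

For each participant and frequency separation, linear support vector
machines (C = 1) are trained to classify integrated vs segregated
neutral-condition epochs from the 150 standardized time-point features of
each 600 ms epoch. Class imbalance is removed by random subsampling of the
larger class; five-fold stratified cross-validation is repeated 100 times,
giving 500 fold-evaluations whose mean percent correct is the participant's
accuracy. Feature weights are converted to activation patterns (training
covariance times weight vector, the Haufe transformation), which zeroes
noise features that carry weight only for noise cancellation. The 500
trained models then classify all non-neutral epochs regardless of report,
and the accuracy-adjusted expected-difference test compares the classified
intention effect with what accurate reports would predict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from .behavior import BehavioralStats, paired_t_with_d
from .univariate import task_contrasts

LABEL_INTEGRATED = 0
LABEL_SEGREGATED = 1


@dataclass
class DecoderEnsemble:
    """A participant x delta_f ensemble of fold-trained linear classifiers.

    Weight vectors live in the standardized feature space of their training
    fold; ``scaler_mean``/``scaler_std`` map raw epochs into it. The sign
    convention is fixed so a positive decision value means segregated, hence
    a positive (corrected) weight marks a time point where a more positive
    response favors segregated classification.
    """

    weights: np.ndarray  # (n_models, n_features)
    biases: np.ndarray  # (n_models,)
    scaler_mean: np.ndarray  # (n_models, n_features)
    scaler_std: np.ndarray  # (n_models, n_features)
    cv_accuracy: float  # percent correct over all fold-evaluations
    corrected_weights: np.ndarray  # (n_features,) mean activation pattern
    folds: int = 5
    repeats: int = 100
    C: float = 1.0

    @property
    def n_models(self) -> int:
        return int(self.weights.shape[0])


def haufe_pattern(X: np.ndarray, w: np.ndarray, shrinkage: float | str = 0.0) -> np.ndarray:
    """Activation pattern for a linear decoder: cov(X) @ w.

    With zero shrinkage this equals, up to a constant, the per-feature
    covariance between feature values and decision values. ``shrinkage``
    may be a float in [0, 1] (convex combination with a scaled identity) or
    "lw" for the Ledoit-Wolf estimate, which guarantees invertibility-grade
    conditioning on small subsamples.
    """
    if shrinkage == "lw":
        cov, _ = ledoit_wolf(X)
    else:
        cov = np.cov(X, rowvar=False, ddof=1)
        if shrinkage:
            mu = np.trace(cov) / cov.shape[0]
            cov = (1.0 - shrinkage) * cov + shrinkage * mu * np.eye(cov.shape[0])
    return cov @ w


def train_decoders(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    repeats: int = 100,
    C: float = 1.0,
    rng: np.random.Generator | None = None,
    compute_patterns: bool = True,
    shrinkage: float | str = "lw",
    solver: str = "liblinear",
) -> DecoderEnsemble:
    """Train the balanced subsampled linear-SVM ensemble for one
    participant and frequency separation.

    Per repeat, the larger class is subsampled without replacement to the
    smaller class's count and split into stratified folds; features are
    standardized with training-fold statistics only, which are stored and
    reused at test time and for non-neutral epochs.

    ``solver`` selects the linear-SVM implementation: "liblinear"
    (squared-hinge primal solver; fast enough for hundreds of epochs per
    class and 500 fold-evaluations) or "libsvm" (the classical hinge-loss
    dual solver) — their hyperplanes agree closely on standardized epochs
    and either can serve as a cross-check of the other.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    rng = np.random.default_rng(rng)
    idx_int = np.flatnonzero(y == LABEL_INTEGRATED)
    idx_seg = np.flatnonzero(y == LABEL_SEGREGATED)
    if len(idx_int) == 0 or len(idx_seg) == 0:
        raise ValueError("both classes must be present")
    n_per_class = min(len(idx_int), len(idx_seg))
    if n_per_class < folds:
        raise ValueError(
            f"smallest class has {n_per_class} epochs; need at least {folds}"
        )
    n_models = folds * repeats
    n_feat = X.shape[1]
    weights = np.empty((n_models, n_feat))
    biases = np.empty(n_models)
    scaler_mean = np.empty((n_models, n_feat))
    scaler_std = np.empty((n_models, n_feat))
    patterns = np.zeros(n_feat)
    correct = np.empty(n_models)
    m = 0
    for _ in range(repeats):
        sub = np.concatenate(
            [
                rng.choice(idx_int, n_per_class, replace=False),
                rng.choice(idx_seg, n_per_class, replace=False),
            ]
        )
        Xs, ys = X[sub], y[sub]
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train_idx, test_idx in skf.split(Xs, ys):
            mu = Xs[train_idx].mean(axis=0)
            sd = Xs[train_idx].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr = (Xs[train_idx] - mu) / sd
            Xte = (Xs[test_idx] - mu) / sd
            if solver == "libsvm":
                clf = SVC(kernel="linear", C=C)
            elif solver == "liblinear":
                clf = LinearSVC(C=C, dual=False)
            else:
                raise ValueError(f"unknown solver {solver!r}")
            clf.fit(Xtr, ys[train_idx])
            # sklearn orders classes [0, 1]; decision > 0 predicts class 1
            # (segregated), matching the package-wide sign convention.
            w = clf.coef_[0]
            weights[m] = w
            biases[m] = clf.intercept_[0]
            scaler_mean[m] = mu
            scaler_std[m] = sd
            correct[m] = 100.0 * np.mean(clf.predict(Xte) == ys[test_idx])
            if compute_patterns:
                patterns += haufe_pattern(Xtr, w, shrinkage)
            m += 1
    return DecoderEnsemble(
        weights=weights,
        biases=biases,
        scaler_mean=scaler_mean,
        scaler_std=scaler_std,
        cv_accuracy=float(correct.mean()),
        corrected_weights=patterns / n_models if compute_patterns else patterns,
        folds=folds,
        repeats=repeats,
        C=C,
    )


def haufe_correct(ensemble: DecoderEnsemble) -> np.ndarray:
    """The ensemble's mean activation pattern (computed during training)."""
    return ensemble.corrected_weights


def normalize_pattern(pattern: np.ndarray) -> np.ndarray:
    """Unit-Euclidean-norm scaling applied per participant before group
    averaging of activation patterns."""
    norm = np.linalg.norm(pattern)
    return pattern / norm if norm > 0 else pattern


def classify_nonneutral(ensemble: DecoderEnsemble, X: np.ndarray) -> float:
    """Percent of epochs classified as segregated, averaged over all models.

    Each model standardizes the epochs with its stored training-fold
    parameters before applying its hyperplane.
    """
    X = np.asarray(X, float)
    if X.shape[1] != ensemble.weights.shape[1]:
        raise ValueError(
            f"epochs have {X.shape[1]} features, ensemble expects "
            f"{ensemble.weights.shape[1]}"
        )
    # decision_m(x) = w_m . ((x - mu_m) / sd_m) + b_m for every model at once
    scaled_w = ensemble.weights / ensemble.scaler_std  # (M, F)
    offsets = ensemble.biases - np.sum(
        scaled_w * ensemble.scaler_mean, axis=1
    )  # (M,)
    decisions = X @ scaled_w.T + offsets[None, :]  # (n_epochs, M)
    return float(100.0 * np.mean(decisions > 0))


def adjusted_expected_difference(
    report_pct: dict,
    classified_pct: dict,
    accuracy: dict,
) -> tuple[np.ndarray, np.ndarray, BehavioralStats]:
    """Accuracy-adjusted expected-vs-observed intention-effect comparison.

    ``report_pct[(participant, delta_f, condition)]`` is the reported
    percent segregation, ``classified_pct`` the percent of epochs classified
    as segregated, and ``accuracy[(participant, delta_f)]`` the neutral CV
    accuracy. Reported percentages are scaled by (accuracy - 50)/50 — a
    chance classifier carries no signal, a perfect one reproduces reports —
    and the attempt-segregation-minus-integration difference of these
    adjusted reports (averaged over frequency separations) is compared with
    the observed classified difference by a paired t test.
    """
    participants = sorted({k[0] for k in classified_pct})
    dfs = sorted({k[1] for k in classified_pct})
    expected, observed = [], []
    for part in participants:
        exp_terms, obs_terms = [], []
        for df in dfs:
            gain = (accuracy[(part, df)] - 50.0) / 50.0

            def adj(cond: str) -> float:
                return report_pct[(part, df, cond)] * gain

            exp_terms.append(
                0.5 * (adj("attend_high") + adj("attend_low"))
                - adj("attempt_integration")
            )
            obs_terms.append(
                0.5 * (
                    classified_pct[(part, df, "attend_high")]
                    + classified_pct[(part, df, "attend_low")]
                )
                - classified_pct[(part, df, "attempt_integration")]
            )
        expected.append(np.mean(exp_terms))
        observed.append(np.mean(obs_terms))
    expected_arr = np.asarray(expected)
    observed_arr = np.asarray(observed)
    return expected_arr, observed_arr, paired_t_with_d(observed_arr, expected_arr)


def decode_task_contrasts(classified_pct: dict) -> dict:
    """The four intention contrasts on classified percentages, frequency
    separations equally weighted, each tested with a paired t."""
    participants = sorted({k[0] for k in classified_pct})
    dfs = sorted({k[1] for k in classified_pct})
    cols = {}
    for cond in ("attend_high", "attend_low", "attempt_integration"):
        cols[cond] = np.array(
            [
                np.mean([classified_pct[(part, df, cond)] for df in dfs])
                for part in participants
            ]
        )
    return task_contrasts(
        cols["attend_high"], cols["attend_low"], cols["attempt_integration"]
    )
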