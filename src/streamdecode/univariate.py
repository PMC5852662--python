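"""Percept-conditional evoked averaging and group-level univariate tests.

The percept signature is assessed on neutral-condition epochs: per
participant, epochs are averaged within each frequency separation x percept
cell, the two frequency separations are given equal weight, and the group
segregated-minus-integrated difference is tested point-by-point with a
cluster-based permutation test (within-participant sign flips of the
difference wave, max-cluster-mass null). Window statistics, the four
intention-task contrasts, and the report-weighted expected-vs-observed
response-bias test operate on the same evoked means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

from .behavior import BehavioralStats, INTEGRATED, SEGREGATED, paired_t_with_d
from .epoching import EpochSet

WINDOW_DEFAULT = (0.216, 0.288)

#: The four intention contrasts as weights over
#: (attend_high, attend_low, attempt_integration).
TASK_CONTRASTS = {
    "mean_seg_minus_int": (0.5, 0.5, -1.0),
    "attend_high_minus_int": (1.0, 0.0, -1.0),
    "attend_low_minus_int": (0.0, 1.0, -1.0),
    "attend_high_minus_low": (1.0, -1.0, 0.0),
}


# ---------------------------------------------------------------------------
# Evoked means


def percept_evoked_means(epochs: EpochSet) -> dict:
    """Neutral-condition cell means per (delta_f, percept), plus
    delta_f-collapsed percept means with the two separations equally
    weighted regardless of cell sizes."""
    sel = epochs.retained & (epochs.condition == "neutral")
    dfs = sorted(np.unique(epochs.delta_f[sel]))
    cells: dict = {}
    for df, percept in product(dfs, (INTEGRATED, SEGREGATED)):
        mask = sel & (epochs.delta_f == df) & (epochs.labels == percept)
        if not np.any(mask):
            raise ValueError(f"empty neutral cell (delta_f={df}, percept={percept})")
        cells[(float(df), percept)] = epochs.data[mask].mean(axis=0)
    for percept in (INTEGRATED, SEGREGATED):
        cells[percept] = np.mean([cells[(float(df), percept)] for df in dfs], axis=0)
    return cells


def instruction_evoked_means(epochs: EpochSet) -> dict:
    """Non-neutral condition means per (delta_f, instruction), irrespective
    of reported percept, plus delta_f-collapsed instruction means."""
    cells: dict = {}
    conditions = [c for c in np.unique(epochs.condition) if c not in ("neutral", "")]
    dfs = sorted(np.unique(epochs.delta_f[epochs.retained]))
    for df, cond in product(dfs, conditions):
        mask = (
            epochs.retained & (epochs.delta_f == df) & (epochs.condition == cond)
        )
        if not np.any(mask):
            raise ValueError(f"empty cell (delta_f={df}, condition={cond})")
        cells[(float(df), cond)] = epochs.data[mask].mean(axis=0)
    for cond in conditions:
        cells[cond] = np.mean([cells[(float(df), cond)] for df in dfs], axis=0)
    return cells


# ---------------------------------------------------------------------------
# Cluster-based permutation test


@dataclass
class ClusterTestResult:
    t_series: np.ndarray
    critical_t: float
    clusters: list  # (start, end_exclusive, mass) tuples, all suprathreshold runs
    max_cluster_mass: float
    null_masses: np.ndarray
    p: float
    cluster_ps: list = field(default_factory=list)

    def significant_clusters(self, alpha: float = 0.05) -> list:
        return [
            c for c, p in zip(self.clusters, self.cluster_ps) if p <= alpha
        ]


def _t_series(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / (sd / np.sqrt(n))


def _clusters_from_t(t_series: np.ndarray, critical_t: float) -> list:
    """Maximal runs of same-sign suprathreshold t values with their masses."""
    clusters = []
    for sign in (1.0, -1.0):
        above = sign * t_series > critical_t
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(above))
        for s, e in zip(starts, ends):
            clusters.append((int(s), int(e), float(t_series[s:e].sum())))
    return sorted(clusters, key=lambda c: c[0])


def _max_masses(diffs_t: np.ndarray, critical_t: float) -> np.ndarray:
    """Max |cluster mass| for each row of a (B, T) array of t series."""
    out = np.zeros(diffs_t.shape[0])
    for b in range(diffs_t.shape[0]):
        clusters = _clusters_from_t(diffs_t[b], critical_t)
        if clusters:
            out[b] = max(abs(c[2]) for c in clusters)
    return out


def _sign_flip_t(diff: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t series for each sign assignment; vectorized over assignments.

    Sign flips leave per-participant squared values unchanged, so only the
    mean needs recomputation per assignment.
    """
    n = diff.shape[0]
    means = signs @ diff / n
    msq = (diff**2).sum(axis=0) / n
    var = (msq - means**2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return means / np.sqrt(var / n)


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Cluster-based permutation test of cond_a vs cond_b evoked means.

    Pointwise paired t values are thresholded at the two-sided critical t
    for ``alpha``; contiguous same-sign suprathreshold runs form clusters
    scored by mass (sum of t). The null permutes condition labels within
    participant, i.e. randomly sign-flips each participant's difference
    wave, and records the maximum |cluster mass| per permutation. The
    reported p is the proportion of null masses at or above the observed
    maximum, counting the observed statistic itself.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition arrays must share (participants, time) shape")
    n = cond_a.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    diff = cond_a - cond_b
    critical_t = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    t_obs = _t_series(diff)
    clusters = _clusters_from_t(t_obs, critical_t)
    max_mass = max((abs(c[2]) for c in clusters), default=0.0)

    if exhaustive:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(rng)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_t = _sign_flip_t(diff, signs)
    null_masses = _max_masses(null_t, critical_t)

    def mass_p(mass: float) -> float:
        if exhaustive:
            return float(np.mean(null_masses >= mass - 1e-12))
        return float((1 + np.sum(null_masses >= mass - 1e-12)) / (len(null_masses) + 1))

    p = mass_p(max_mass) if clusters else 1.0
    cluster_ps = [mass_p(abs(c[2])) for c in clusters]
    return ClusterTestResult(
        t_series=t_obs,
        critical_t=critical_t,
        clusters=clusters,
        max_cluster_mass=float(max_mass),
        null_masses=null_masses,
        p=p,
        cluster_ps=cluster_ps,
    )


# ---------------------------------------------------------------------------
# Window statistics and task contrasts


def window_samples(
    n_samples: int, sample_rate: float, window: tuple[float, float] = WINDOW_DEFAULT
) -> np.ndarray:
    """Indices of samples whose latency lies inside the window, inclusive at
    both bounds on the sampling grid."""
    t = np.arange(n_samples) / sample_rate
    lo, hi = window
    if lo < 0 or hi > (n_samples - 1) / sample_rate + 1e-12:
        raise ValueError("window lies outside the epoch")
    return np.flatnonzero((t >= lo - 1e-12) & (t <= hi + 1e-12))


def window_mean(
    means: np.ndarray, sample_rate: float, window: tuple[float, float] = WINDOW_DEFAULT
) -> np.ndarray:
    idx = window_samples(means.shape[-1], sample_rate, window)
    return means[..., idx].mean(axis=-1)


def window_effect(
    means_seg: np.ndarray,
    means_int: np.ndarray,
    sample_rate: float,
    window: tuple[float, float] = WINDOW_DEFAULT,
) -> tuple[np.ndarray, BehavioralStats]:
    """Per-participant segregated-minus-integrated window means and the
    paired test against zero."""
    diffs = window_mean(means_seg, sample_rate, window) - window_mean(
        means_int, sample_rate, window
    )
    stats_out = paired_t_with_d(
        window_mean(means_seg, sample_rate, window),
        window_mean(means_int, sample_rate, window),
    )
    return diffs, stats_out


def task_contrasts(
    attend_high: np.ndarray, attend_low: np.ndarray, attempt_integration: np.ndarray
) -> dict[str, tuple[np.ndarray, BehavioralStats]]:
    """The four intention contrasts on per-participant values, each tested
    with a paired t against zero."""
    arrays = {
        "attend_high": np.asarray(attend_high, float),
        "attend_low": np.asarray(attend_low, float),
        "attempt_integration": np.asarray(attempt_integration, float),
    }
    out = {}
    for name, (wh, wl, wi) in TASK_CONTRASTS.items():
        values = (
            wh * arrays["attend_high"]
            + wl * arrays["attend_low"]
            + wi * arrays["attempt_integration"]
        )
        out[name] = (values, paired_t_with_d(values))
    return out


def expected_nonneutral_response(
    neutral_window: dict,
    observed_window: dict,
    p_seg: dict,
) -> tuple[np.ndarray, np.ndarray, BehavioralStats]:
    """Report-weighted expected-vs-observed test of response bias.

    ``neutral_window[(participant, delta_f, percept)]`` are neutral window
    means, ``observed_window[(participant, delta_f, condition)]`` the
    non-neutral window means, and ``p_seg[(participant, delta_f,
    condition)]`` the proportion of reported segregation. The expected
    response in a non-neutral condition mixes the neutral percept means by
    the reported proportions; the attempt-segregation-minus-integration
    contrast is formed for both expected and observed values (frequency
    separations equally weighted) and compared with a paired t test. If
    reports are accurate and the neutral signature generalizes, expected
    and observed agree.
    """
    participants = sorted({k[0] for k in observed_window})
    dfs = sorted({k[1] for k in observed_window})
    seg_conditions = ("attend_high", "attend_low")
    expected, observed = [], []
    for part in participants:
        exp_terms, obs_terms = [], []
        for df in dfs:
            m_int = neutral_window[(part, df, INTEGRATED)]
            m_seg = neutral_window[(part, df, SEGREGATED)]

            def mix(cond: str) -> float:
                p = p_seg[(part, df, cond)]
                return p * m_seg + (1.0 - p) * m_int

            exp_contrast = (
                0.5 * (mix("attend_high") + mix("attend_low"))
                - mix("attempt_integration")
            )
            obs_contrast = 0.5 * (
                observed_window[(part, df, seg_conditions[0])]
                + observed_window[(part, df, seg_conditions[1])]
            ) - observed_window[(part, df, "attempt_integration")]
            exp_terms.append(exp_contrast)
            obs_terms.append(obs_contrast)
        expected.append(np.mean(exp_terms))
        observed.append(np.mean(obs_terms))
    expected_arr = np.asarray(expected)
    observed_arr = np.asarray(observed)
    return expected_arr, observed_arr, paired_t_with_d(observed_arr, expected_arr)
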