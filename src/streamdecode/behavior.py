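"""Behavioral analysis of percept report streams.

A listener continuously reports hearing the triplet sequence as *integrated*
(one stream) or *segregated* (two streams). This module segments a press
stream into perceptual phases, computes percent-segregation and
phase-duration summaries on transformed scales (logit for percentages, log
for durations), and provides the repeated-measures tests used on those
summaries: one-way repeated-measures ANOVA with Huynh-Feldt df adjustment,
paired t tests with Cohen's d and noncentral-t confidence intervals, and
within-participant (Cousineau-Morey) condition CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import optimize, stats

INTEGRATED = "integrated"
SEGREGATED = "segregated"
PERCEPTS = (INTEGRATED, SEGREGATED)

INITIAL_INTEGRATED = "initial_integrated"
SUBSEQUENT_INTEGRATED = "subsequent_integrated"
PHASE_CLASSES = (INITIAL_INTEGRATED, SUBSEQUENT_INTEGRATED, SEGREGATED)

CONDITIONS = ("neutral", "attempt_integration", "attend_high", "attend_low")


@dataclass
class ReportStream:
    """Timestamped percept button presses for one sequence."""

    presses: list[tuple[float, str]]
    condition: str
    delta_f: float
    sequence_duration: float

    def __post_init__(self) -> None:
        times = [t for t, _ in self.presses]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("press times must be strictly increasing")
        if any(t < 0 or t > self.sequence_duration for t in times):
            raise ValueError("press times must lie within the sequence")
        percepts = [p for _, p in self.presses]
        if any(p not in PERCEPTS for p in percepts):
            raise ValueError(f"percepts must be one of {PERCEPTS}")
        if any(p1 == p2 for p1, p2 in zip(percepts, percepts[1:])):
            raise ValueError("consecutive presses must alternate percepts")

    @property
    def press_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.presses], dtype=float)


@dataclass
class Phase:
    phase_class: str
    onset: float
    duration: float
    completed: bool

    @property
    def percept(self) -> str:
        return SEGREGATED if self.phase_class == SEGREGATED else INTEGRATED


@dataclass
class PhaseTable:
    """Perceptual phases tiling the reported part of one sequence."""

    phases: list[Phase]
    condition: str = "neutral"
    delta_f: float = 6.0
    participant: str = ""

    def durations(self, phase_class: str, completed_only: bool = True) -> np.ndarray:
        return np.array(
            [
                p.duration
                for p in self.phases
                if p.phase_class == phase_class and (p.completed or not completed_only)
            ]
        )


@dataclass
class BehavioralStats:
    """Container for the statistics the pipeline reports.

    ``d`` is mean(diff)/sd(diff) (often written d_z); ``d_av`` standardizes
    the mean difference by the pooled SD of the two conditions, which is the
    smaller quantity conventionally reported for strongly correlated
    repeated measures.
    """

    t: float | None = None
    df: float | None = None
    p: float | None = None
    d: float | None = None
    d_ci: tuple[float, float] | None = None
    d_av: float | None = None
    F: float | None = None
    df_num: float | None = None
    df_den: float | None = None
    df_num_adj: float | None = None
    df_den_adj: float | None = None
    epsilon_hf: float | None = None
    eta_sq_p: float | None = None
    eta_sq_p_ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Phase segmentation and sequence-level summaries


def segment_phases(reports: ReportStream) -> PhaseTable:
    """Segment an alternating press stream into perceptual phases.

    Phase k spans press k to press k+1; the final phase is truncated at the
    sequence end and flagged incomplete. The first phase is classed
    ``initial_integrated`` iff its percept is integrated; later integrated
    phases are ``subsequent_integrated``.
    """
    phases: list[Phase] = []
    presses = reports.presses
    for k, (time, percept) in enumerate(presses):
        end = (
            presses[k + 1][0] if k + 1 < len(presses) else reports.sequence_duration
        )
        completed = k + 1 < len(presses)
        if percept == INTEGRATED:
            cls = INITIAL_INTEGRATED if k == 0 else SUBSEQUENT_INTEGRATED
        else:
            cls = SEGREGATED
        phases.append(Phase(cls, time, end - time, completed))
    return PhaseTable(
        phases=phases,
        condition=reports.condition,
        delta_f=reports.delta_f,
    )


def sequence_meets_criteria(table: PhaseTable) -> bool:
    """Sequence qualifies iff the first phase is integrated and at least two
    completed phases follow it."""
    if not table.phases:
        return False
    if table.phases[0].phase_class != INITIAL_INTEGRATED:
        return False
    n_completed_subsequent = sum(1 for p in table.phases[1:] if p.completed)
    return n_completed_subsequent >= 2


def percent_segregation(reports: ReportStream) -> float:
    """Percent of reported time spent segregated.

    The denominator runs from the first press to the sequence end; the
    unreported interval before the first press carries no percept.
    """
    if not reports.presses:
        raise ValueError("percent segregation undefined without any press")
    table = segment_phases(reports)
    seg = sum(p.duration for p in table.phases if p.percept == SEGREGATED)
    total = reports.sequence_duration - reports.presses[0][0]
    return 100.0 * seg / total


# ---------------------------------------------------------------------------
# Transformed-scale means


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (100.0 - p))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(-x))


def transformed_condition_means(
    values: np.ndarray, transform: str, strict: bool = True
) -> float:
    """Mean on the transformed scale, back-transformed for reporting.

    ``logit`` for percentages in (0, 100), ``log`` for durations. In strict
    mode exact 0/100% values raise; lenient mode is handled by the caller
    via an empirical-logit correction before calling.
    """
    values = np.asarray(values, dtype=float)
    if transform == "log":
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive values")
        return float(np.exp(np.mean(np.log(values))))
    if transform == "logit":
        if np.any((values <= 0) | (values >= 100)):
            if strict:
                raise ValueError(
                    "logit transform requires values strictly inside (0, 100); "
                    "exclude 0/100% conditions or use a lenient correction"
                )
            n = len(values)
            values = np.clip(values, 100.0 / (2 * n + 2), 100.0 * (2 * n + 1) / (2 * n + 2))
        return float(_inv_logit(np.mean(_logit(values))))
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# Repeated-measures statistics


def _rm_anova_F(wide: np.ndarray) -> float:
    """One-way repeated-measures F by direct sum-of-squares decomposition."""
    n, k = wide.shape
    grand = wide.mean()
    ss_cond = n * np.sum((wide.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((wide.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((wide - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    if ss_err <= 0:
        return np.inf if ss_cond > 0 else 0.0
    return float((ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1))))


def rm_anova_hf(
    wide: pd.DataFrame, n_boot: int = 2000, rng: np.random.Generator | None = None
) -> BehavioralStats:
    """One-way repeated-measures ANOVA with Huynh-Feldt df adjustment.

    ``wide`` is participants x factor levels, complete and balanced. The p
    value is computed at the Huynh-Feldt adjusted degrees of freedom;
    uncorrected dfs are reported alongside. Partial eta squared gets a
    percentile-bootstrap CI over participants.
    """
    if wide.isna().any().any():
        raise ValueError("rm_anova_hf requires a complete table (no missing cells)")
    arr = wide.to_numpy(dtype=float)
    n, k = arr.shape
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="level", value_name="y"
    )
    aov = pg.rm_anova(
        data=long, dv="y", within="level", subject="subject", effsize="np2"
    )
    F = float(aov.loc[0, "F"])
    np2 = float(aov.loc[0, "np2"])
    with np.errstate(invalid="ignore", divide="ignore"):
        eps = 1.0 if k == 2 else float(np.squeeze(pg.epsilon(wide, correction="hf")))
    eps = 1.0 if not np.isfinite(eps) else min(eps, 1.0)
    df_num, df_den = float(k - 1), float((n - 1) * (k - 1))
    p = float(stats.f.sf(F, df_num * eps, df_den * eps))

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(rng)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Fb = _rm_anova_F(arr[idx])
            boots[b] = Fb * df_num / (Fb * df_num + df_den)
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))

    return BehavioralStats(
        F=F,
        df_num=df_num,
        df_den=df_den,
        df_num_adj=df_num * eps,
        df_den_adj=df_den * eps,
        epsilon_hf=eps,
        p=p,
        eta_sq_p=np2,
        eta_sq_p_ci=ci,
    )


def _d_ci_noncentral_t(t_obs: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """CI for d_z by inverting the noncentral-t distribution.

    ``nct.cdf(t_obs, df, nc)`` is monotonically decreasing in the
    noncentrality ``nc``; NaNs from extreme tail evaluations are replaced by
    their limiting values so the bracketing search stays well defined.
    """
    df = n - 1
    alpha = 1.0 - level
    scale = np.sqrt(n)

    def cdf(nc: float) -> float:
        val = stats.nct.cdf(t_obs, df, nc)
        if np.isnan(val):
            return 0.0 if nc > t_obs else 1.0
        return float(val)

    def invert(target: float) -> float:
        f = lambda nc: cdf(nc) - target
        span = abs(t_obs) + 2.0
        lo, hi = t_obs - span, t_obs + span
        for _ in range(60):
            if f(lo) > 0 > f(hi):
                break
            lo -= span
            hi += span
            span *= 1.5
        else:  # pragma: no cover
            return np.nan
        return optimize.brentq(f, lo, hi)

    return (invert(1.0 - alpha / 2) / scale, invert(alpha / 2) / scale)


def paired_t_with_d(x: np.ndarray, y: np.ndarray | None = None) -> BehavioralStats:
    """Paired t test with Cohen's d (d_z and averaged-variance d_av) and a
    noncentral-t CI for d_z. ``y=None`` tests ``x`` against zero."""
    x = np.asarray(x, dtype=float)
    diff = x if y is None else x - np.asarray(y, dtype=float)
    n = diff.shape[0]
    if n < 2:
        raise ValueError("need at least two paired observations")
    sd = diff.std(ddof=1)
    if sd == 0:
        t_obs = np.inf if diff.mean() > 0 else (-np.inf if diff.mean() < 0 else 0.0)
        return BehavioralStats(
            t=float(t_obs),
            df=float(n - 1),
            p=0.0 if t_obs != 0 else 1.0,
            d=float(np.sign(diff.mean()) * np.inf) if t_obs != 0 else 0.0,
            extra={"zero_variance": True},
        )
    t_obs = diff.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t_obs), n - 1)
    d = diff.mean() / sd
    if y is None:
        d_av = d
    else:
        y_arr = np.asarray(y, dtype=float)
        pooled = np.sqrt((x.std(ddof=1) ** 2 + y_arr.std(ddof=1) ** 2) / 2)
        d_av = diff.mean() / pooled if pooled > 0 else np.inf * np.sign(diff.mean())
    return BehavioralStats(
        t=float(t_obs),
        df=float(n - 1),
        p=float(p),
        d=float(d),
        d_ci=_d_ci_noncentral_t(float(t_obs), n),
        d_av=float(d_av),
    )


def within_participant_ci(
    wide: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Within-participant condition CIs: Cousineau centering with the Morey
    small-sample correction sqrt(k/(k-1)) applied to the deviations."""
    arr = wide.to_numpy(dtype=float)
    n, k = arr.shape
    centered = arr - arr.mean(axis=1, keepdims=True) + arr.mean()
    corrected = (centered - centered.mean(axis=0)) * np.sqrt(k / (k - 1)) + centered.mean(
        axis=0
    )
    sem = corrected.std(axis=0, ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, n - 1) * sem
    means = arr.mean(axis=0)
    return pd.DataFrame(
        {"mean": means, "ci_low": means - half, "ci_high": means + half},
        index=wide.columns,
    )
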