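"""Synthetic cohorts of bistable auditory-streaming sessions.

The generator emulates the study conditions end to end: sequences of 250
HLH- triplets (100 ms tones, 50 ms intra-triplet gaps, 200 ms between
triplets, hence a 600 ms triplet period), frequency separations of 4 or 6
semitones, four instruction conditions (neutral, attempt integration,
attend high, attend low), alternating percept phases with log-normally
distributed durations and a longer initial integrated phase, and continuous
auditory-cortex source waveforms in which each triplet evokes tone-locked
deflections plus, during reported segregation, an added positivity confined
to 216-288 ms after triplet onset. Between-participant template variability
(latency and amplitude jitter, occasional global sign flips) produces
realistic group-level effect sizes, including individuals whose percept
signature is opposite in sign to the group mean.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import (
    CONDITIONS,
    INTEGRATED,
    SEGREGATED,
    Phase,
    PhaseTable,
    ReportStream,
)
from .io import ContinuousRecording, write_events, write_recording

TRIPLET_PERIOD = 0.600
TONE_DURATION = 0.100
TONE_OFFSETS = (0.000, 0.150, 0.300)
DELTA_FS = (4.0, 6.0)
H_FREQ_DEFAULT = 1017.0

#: Per-block instruction schedule: two neutral, one attempt integration,
#: one attend high, one attend low.
BLOCK_CONDITIONS = (
    "neutral",
    "neutral",
    "attempt_integration",
    "attend_high",
    "attend_low",
)


# ---------------------------------------------------------------------------
# Stimulus construction


@dataclass
class StimulusTimeline:
    """Triplet and tone onset times and frequencies for one sequence."""

    sequence_id: str
    n_triplets: int
    triplet_onsets: np.ndarray
    tone_onsets: np.ndarray  # (n_triplets, 3)
    tone_freqs: tuple[float, float, float]  # H, L, H
    delta_f: float
    sample_rate: float = 1000.0

    @property
    def duration(self) -> float:
        return self.n_triplets * TRIPLET_PERIOD


def semitone_shift(freq: float, semitones: float) -> float:
    return freq * 2.0 ** (semitones / 12.0)


def build_stimulus_timeline(
    n_triplets: int,
    h_freq: float = H_FREQ_DEFAULT,
    delta_f: float = 6.0,
    sequence_id: str = "seq",
    sample_rate: float = 1000.0,
) -> StimulusTimeline:
    """Construct the temporal skeleton of one HLH- sequence.

    The L tone sits ``delta_f`` semitones below the H tone; tones within a
    triplet start at +0, +150 and +300 ms, and triplets repeat every 600 ms.
    """
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    if h_freq <= 0:
        raise ValueError("h_freq must be positive")
    if delta_f <= 0:
        raise ValueError("delta_f must be positive")
    triplet_onsets = np.arange(n_triplets) * TRIPLET_PERIOD
    tone_onsets = triplet_onsets[:, None] + np.asarray(TONE_OFFSETS)[None, :]
    l_freq = semitone_shift(h_freq, -delta_f)
    return StimulusTimeline(
        sequence_id=sequence_id,
        n_triplets=n_triplets,
        triplet_onsets=triplet_onsets,
        tone_onsets=tone_onsets,
        tone_freqs=(h_freq, l_freq, h_freq),
        delta_f=delta_f,
        sample_rate=sample_rate,
    )


def timeline_events(timeline: StimulusTimeline, condition: str = "neutral") -> pd.DataFrame:
    """Flatten a timeline into tone rows of an events table."""
    rows = []
    for i in range(timeline.n_triplets):
        for j in range(3):
            rows.append(
                {
                    "onset": timeline.tone_onsets[i, j],
                    "duration": TONE_DURATION,
                    "event_type": "tone",
                    "value": f"{timeline.tone_freqs[j]:.3f}",
                    "condition": condition,
                    "delta_f": timeline.delta_f,
                }
            )
    return pd.DataFrame(rows)


def build_filler_timeline(rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Inter-sequence filler: a timing tone, a run of 33 random-frequency
    tones (log-uniform 200-2000 Hz) to disrupt memory of the previous
    sequence, and a final warning tone, embedded in long silences. Total
    duration just under 40 s."""
    rng = np.random.default_rng(rng)
    rows = []
    t = 5.005
    rows.append((t, TONE_DURATION, "tone", "250.000"))
    t += TONE_DURATION + 1.900
    for _ in range(33):
        freq = float(np.exp(rng.uniform(np.log(200.0), np.log(2000.0))))
        rows.append((t, TONE_DURATION, "tone", f"{freq:.3f}"))
        t += TONE_DURATION + 0.050
    t += -0.050 + 22.945  # no gap after the last random tone
    rows.append((t, TONE_DURATION, "tone", "250.000"))
    t += TONE_DURATION + 5.000
    table = pd.DataFrame(rows, columns=["onset", "duration", "event_type", "value"])
    table["condition"] = "filler"
    table["delta_f"] = 0.0
    table.attrs["total_duration"] = t
    return table


# ---------------------------------------------------------------------------
# Percept phase simulation


@dataclass
class PerceptParams:
    """Log-normal phase-duration model.

    ``mu_log_*`` are log-seconds for the neutral condition at the midpoint
    between the two frequency separations. Instruction and frequency
    separation act multiplicatively on phase durations: a condition's
    intention multiplier lengthens phases of the instructed percept and
    shortens the other percept's phases by the same factor, and the larger
    frequency separation does the same in favor of segregation.
    """

    mu_log_initial_integrated: float = float(np.log(12.0))
    mu_log_integrated: float = float(np.log(6.8))
    mu_log_segregated: float = float(np.log(6.8))
    sigma_log: float = 0.55
    intention_multipliers: dict = field(
        default_factory=lambda: {
            "neutral": 1.0,
            "attempt_integration": 1.54,
            "attend_high": 1.54,
            "attend_low": 1.54,
        }
    )
    delta_f_multiplier: float = 1.25
    between_participant_sd: float = 0.30
    first_report_latency: float = 2.0
    first_integrated_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_log < 0 or self.between_participant_sd < 0:
            raise ValueError("sigmas must be non-negative")
        if any(m <= 0 for m in self.intention_multipliers.values()):
            raise ValueError("intention multipliers must be positive")
        if self.delta_f_multiplier <= 0:
            raise ValueError("delta_f multiplier must be positive")

    def seg_bias(self, condition: str, delta_f: float) -> float:
        """Net log-scale shift favoring segregated (+) over integrated (-)."""
        m = self.intention_multipliers[condition]
        if condition == "attempt_integration":
            bias = -np.log(m)
        elif condition in ("attend_high", "attend_low"):
            bias = np.log(m)
        else:
            bias = 0.0
        df_bias = np.log(self.delta_f_multiplier)
        bias += df_bias if delta_f >= 5.0 else -df_bias
        return float(bias)


def simulate_phase_sequence(
    params: PerceptParams,
    condition: str,
    delta_f: float,
    duration: float,
    rng: np.random.Generator,
    participant_offset: float = 0.0,
) -> tuple[PhaseTable, ReportStream]:
    """Simulate alternating percept phases and the matching press stream.

    The first report occurs ``first_report_latency`` seconds after sequence
    start; a press marks each subsequent phase onset; the final phase is
    truncated at the sequence end and flagged incomplete.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    bias = params.seg_bias(condition, delta_f) + participant_offset
    mus = {
        "initial_integrated": params.mu_log_initial_integrated - bias,
        "subsequent_integrated": params.mu_log_integrated - bias,
        SEGREGATED: params.mu_log_segregated + bias,
    }
    t = params.first_report_latency
    first_integrated = rng.random() < params.first_integrated_prob
    percept = INTEGRATED if first_integrated else SEGREGATED
    phases: list[Phase] = []
    presses: list[tuple[float, str]] = []
    first = True
    while t < duration:
        presses.append((t, percept))
        if percept == INTEGRATED:
            cls = "initial_integrated" if first else "subsequent_integrated"
        else:
            cls = SEGREGATED
        d = float(np.exp(rng.normal(mus[cls], params.sigma_log)))
        end = t + d
        completed = end < duration
        phases.append(Phase(cls, t, min(end, duration) - t, completed))
        t = end
        percept = SEGREGATED if percept == INTEGRATED else INTEGRATED
        first = False
    table = PhaseTable(phases=phases, condition=condition, delta_f=delta_f)
    reports = ReportStream(
        presses=presses,
        condition=condition,
        delta_f=delta_f,
        sequence_duration=duration,
    )
    return table, reports


def reports_to_events(reports: ReportStream) -> pd.DataFrame:
    rows = [
        {
            "onset": t,
            "duration": 0.0,
            "event_type": "press",
            "value": percept,
            "condition": reports.condition,
            "delta_f": reports.delta_f,
        }
        for t, percept in reports.presses
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Neural synthesis


@dataclass
class NeuralParams:
    """Evoked-response and noise model for the source waveform.

    Each tone evokes a gamma-shaped deflection peaking ``kernel_peak_latency``
    seconds after tone onset; during reported segregation a raised-cosine
    positivity spanning ``segregation_window`` is added to every triplet.
    Noise is Gaussian with power spectrum ~ 1/f^exponent plus a white floor,
    band-limited to the analysis band. Participant templates apply latency
    and amplitude jitter and, with ``sign_flip_probability``, a global
    polarity flip of the source waveform.
    """

    kernel_peak_latency: float = 0.055
    kernel_shape: float = 3.0  # gamma shape parameter; peak at shape*scale
    kernel_amplitudes: tuple[float, float, float] = (3.2, 2.7, 3.0)
    segregation_window: tuple[float, float] = (0.216, 0.288)
    segregation_effect_amplitude: float = 0.32
    template_latency_jitter: float = 0.008
    template_amplitude_jitter: float = 0.35
    sign_flip_probability: float = 0.15
    noise_spectrum_exponent: float = 1.0
    noise_white_fraction: float = 0.5
    noise_sd: float = 1.0
    noise_band: tuple[float, float] = (0.278, 30.0)

    def __post_init__(self) -> None:
        lo, hi = self.segregation_window
        if not (0.0 <= lo < hi < TRIPLET_PERIOD):
            raise ValueError("segregation window must lie within [0, 0.6) s")
        if not 0.0 <= self.sign_flip_probability <= 1.0:
            raise ValueError("sign_flip_probability must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ParticipantTemplate:
    """Per-participant variation applied to the canonical evoked response."""

    amplitude_scale: float = 1.0
    latency_shifts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sign: int = 1


def draw_participant_template(
    neural: NeuralParams, rng: np.random.Generator
) -> ParticipantTemplate:
    amp = float(np.exp(rng.normal(0.0, neural.template_amplitude_jitter)))
    shifts = tuple(rng.normal(0.0, neural.template_latency_jitter, size=3))
    sign = -1 if rng.random() < neural.sign_flip_probability else 1
    return ParticipantTemplate(amplitude_scale=amp, latency_shifts=shifts, sign=sign)


def _gamma_bump(t: np.ndarray, peak: float, shape: float) -> np.ndarray:
    """Unit-peak gamma-shaped deflection; peak at ``peak`` seconds."""
    scale = peak / shape
    x = np.where(t > 0, t / scale, 0.0)
    with np.errstate(invalid="ignore"):
        y = (x / shape) ** shape * np.exp(shape - x)
    return np.where(t > 0, y, 0.0)


def evoked_kernel(
    t: np.ndarray,
    neural: NeuralParams,
    template: ParticipantTemplate | None = None,
) -> np.ndarray:
    """Canonical single-triplet evoked response evaluated at times ``t``
    (seconds from triplet onset)."""
    template = template or ParticipantTemplate()
    out = np.zeros_like(t, dtype=float)
    for offset, amp, shift in zip(
        TONE_OFFSETS, neural.kernel_amplitudes, template.latency_shifts
    ):
        out += amp * _gamma_bump(
            t - offset - shift, neural.kernel_peak_latency, neural.kernel_shape
        )
    return template.sign * template.amplitude_scale * out


def segregation_bump(
    t: np.ndarray,
    neural: NeuralParams,
    template: ParticipantTemplate | None = None,
) -> np.ndarray:
    """Raised-cosine positivity confined to the segregation window."""
    template = template or ParticipantTemplate()
    lo, hi = neural.segregation_window
    inside = (t >= lo) & (t <= hi)
    out = np.zeros_like(t, dtype=float)
    out[inside] = 0.5 * (1.0 - np.cos(2 * np.pi * (t[inside] - lo) / (hi - lo)))
    return (
        template.sign
        * template.amplitude_scale
        * neural.segregation_effect_amplitude
        * out
    )


def band_noise(
    n_samples: int,
    sample_rate: float,
    neural: NeuralParams,
    rng: np.random.Generator,
    size: int | tuple = (),
) -> np.ndarray:
    """Gaussian noise with PSD ~ 1/f^exponent plus a white floor, restricted
    to the analysis band, scaled to ``noise_sd`` standard deviation."""
    if neural.noise_sd == 0:
        shape = (size,) if isinstance(size, int) else tuple(size)
        return np.zeros(shape + (n_samples,))
    shape = (size,) if isinstance(size, int) else tuple(size)
    white = rng.standard_normal(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    f_safe = np.maximum(freqs, 1.0 / max(n_samples / sample_rate, 1.0))
    gain = np.sqrt(
        f_safe ** (-neural.noise_spectrum_exponent) + neural.noise_white_fraction
    )
    lo, hi = neural.noise_band
    gain = np.where((freqs >= lo) & (freqs <= hi), gain, 0.0)
    spec = np.fft.rfft(white, axis=-1) * gain
    shaped = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(shaped**2)) or 1.0
    return shaped * (neural.noise_sd / rms)


def _governing_percepts(
    triplet_onsets: np.ndarray, phases: PhaseTable
) -> np.ndarray:
    """Percept governing each triplet: the phase containing its onset; onsets
    before the first report count as integrated."""
    percepts = np.array([INTEGRATED] * len(triplet_onsets), dtype=object)
    for phase in phases.phases:
        inside = (triplet_onsets >= phase.onset) & (
            triplet_onsets < phase.onset + phase.duration
        )
        percepts[inside] = phase.percept
    return percepts


def synthesize_recording(
    timeline: StimulusTimeline,
    phases: PhaseTable,
    neural: NeuralParams,
    template: ParticipantTemplate,
    rng: np.random.Generator,
) -> ContinuousRecording:
    """Continuous source waveform for one sequence at the timeline's rate.

    Each triplet contributes the participant's evoked kernel; triplets whose
    onset falls in a segregated phase additionally carry the segregation
    positivity. Band-limited 1/f-plus-white noise is added throughout.
    """
    last_phase_end = max(
        (p.onset + p.duration for p in phases.phases), default=timeline.duration
    )
    if last_phase_end - timeline.duration > 1e-9:
        raise ValueError(
            "phase table extends beyond the stimulus timeline "
            f"({last_phase_end:.3f} s > {timeline.duration:.3f} s)"
        )
    fs = timeline.sample_rate
    n_samples = int(round(timeline.duration * fs))
    n_epoch = int(round(TRIPLET_PERIOD * fs))
    t_epoch = np.arange(n_epoch) / fs
    kernel = evoked_kernel(t_epoch, neural, template)
    effect = segregation_bump(t_epoch, neural, template)
    data = np.zeros(n_samples)
    percepts = _governing_percepts(timeline.triplet_onsets, phases)
    for onset, percept in zip(timeline.triplet_onsets, percepts):
        i0 = int(round(onset * fs))
        seg = data[i0 : i0 + n_epoch]
        contrib = kernel if percept == INTEGRATED else kernel + effect
        seg += contrib[: len(seg)]
    data += band_noise(n_samples, fs, neural, rng)
    return ContinuousRecording(
        data=data,
        sample_rate=fs,
        meta={
            "sequence_id": timeline.sequence_id,
            "condition": phases.condition,
            "delta_f": timeline.delta_f,
        },
    )


# ---------------------------------------------------------------------------
# Fast epoch-level generation (post-preprocessing domain)


@lru_cache(maxsize=4)
def _analysis_lowpass_kernel(sample_rate: float) -> np.ndarray:
    from .preprocessing import LOWPASS_30, design_windowed_sinc

    return design_windowed_sinc(LOWPASS_30, sample_rate)


def analysis_waveforms(
    neural: NeuralParams,
    template: ParticipantTemplate,
    sample_rate: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel and segregation-effect waveforms as they appear after the
    preprocessing chain: low-passed at 30 Hz and with the period mean
    removed (the high-pass rejects the DC of the periodic evoked signal)."""
    from .preprocessing import filter_signal

    n_epoch = int(round(TRIPLET_PERIOD * sample_rate))
    t = np.arange(n_epoch) / sample_rate
    lp = _analysis_lowpass_kernel(sample_rate)
    kernel = filter_signal(evoked_kernel(t, neural, template), lp)
    effect = filter_signal(segregation_bump(t, neural, template), lp)
    return kernel - kernel.mean(), effect - effect.mean()


def simulate_labeled_epochs(
    n_integrated: int,
    n_segregated: int,
    neural: NeuralParams,
    template: ParticipantTemplate,
    rng: np.random.Generator,
    sample_rate: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw triplet-locked epochs directly at the analysis sampling rate.

    Matches the distribution of epochs obtained by synthesizing a continuous
    recording and preprocessing it (evoked waveforms band-limited to the
    analysis band, noise in-band), except that epoch noise is drawn
    independently per epoch. Returns ``(X_integrated, X_segregated)`` with
    0.6 s of samples per row.
    """
    n_epoch = int(round(TRIPLET_PERIOD * sample_rate))
    kernel, effect = analysis_waveforms(neural, template, sample_rate)
    noise = band_noise(
        n_epoch, sample_rate, neural, rng, size=n_integrated + n_segregated
    )
    X_int = kernel[None, :] + noise[:n_integrated]
    X_seg = (kernel + effect)[None, :] + noise[n_integrated:]
    return X_int, X_seg


def simulate_cohort_condition_means(
    n_participants: int,
    n_epochs_per_cell: int,
    neural: NeuralParams,
    rng: np.random.Generator,
    sample_rate: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant integrated and segregated evoked means (the inputs to
    the group cluster test), drawn from the generator's epoch model."""
    n_epoch = int(round(TRIPLET_PERIOD * sample_rate))
    means_int = np.empty((n_participants, n_epoch))
    means_seg = np.empty((n_participants, n_epoch))
    for p in range(n_participants):
        template = draw_participant_template(neural, rng)
        X_int, X_seg = simulate_labeled_epochs(
            n_epochs_per_cell, n_epochs_per_cell, neural, template, rng, sample_rate
        )
        means_int[p] = X_int.mean(axis=0)
        means_seg[p] = X_seg.mean(axis=0)
    return means_int, means_seg


def simulate_null_condition_means(
    n_participants: int,
    n_epochs_per_cell: int,
    neural: NeuralParams,
    rng: np.random.Generator,
    sample_rate: float = 250.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two condition means per participant drawn from identical
    distributions (the segregation effect removed): the null for
    false-positive-rate calibration of the cluster test."""
    null = replace(neural, segregation_effect_amplitude=0.0)
    return simulate_cohort_condition_means(
        n_participants, n_epochs_per_cell, null, rng, sample_rate
    )


def simulate_participant_epochs(
    participant_id: str,
    rng: np.random.Generator,
    percept: PerceptParams,
    neural: NeuralParams,
    n_blocks: int = 4,
    n_triplets: int = 250,
    guard: float = 1.5,
    neural_intention_attenuation: float = 1.0,
    sample_rate: float = 250.0,
):
    """One participant's full session as labeled analysis-ready epochs.

    A fast equivalent of synthesize-preprocess-epoch: phase sequences and
    the press-guard mask are simulated exactly as in the full path, but
    epoch waveforms are drawn directly in the analysis band. Returns
    ``(EpochSet, report_pct)`` where ``report_pct[(delta_f, condition)]``
    is the reported percent segregation pooled over that cell's sequences.

    ``neural_intention_attenuation`` models a biased reporter: reports (and
    hence epoch labels, guard masking and behavioral percentages) always
    follow the fully intention-modulated phase process, but the *neural*
    percept follows a process whose intention multipliers are raised to
    this exponent. At 1.0 reports are accurate by construction; at 0.0 the
    intention conditions change reports without changing perception.
    """
    from . import epoching as ep
    from .behavior import percent_segregation

    duration = n_triplets * TRIPLET_PERIOD
    template = draw_participant_template(neural, rng)
    offset = float(rng.normal(0.0, percept.between_participant_sd))
    kernel, effect = analysis_waveforms(neural, template, sample_rate)
    n_samp = kernel.shape[0]
    alpha = neural_intention_attenuation
    truth_percept = (
        percept
        if alpha == 1.0
        else replace(
            percept,
            intention_multipliers={
                c: m**alpha for c, m in percept.intention_multipliers.items()
            },
        )
    )
    schedule = _block_schedule(rng, n_blocks)
    sets = []
    pct_cells: dict[tuple[float, str], list[float]] = {}
    for b, block in enumerate(schedule):
        for s, (condition, delta_f) in enumerate(block):
            table, reports = simulate_phase_sequence(
                percept, condition, delta_f, duration, rng, participant_offset=offset
            )
            if alpha == 1.0 or condition == "neutral":
                truth_table = table
            else:
                truth_table, _ = simulate_phase_sequence(
                    truth_percept,
                    condition,
                    delta_f,
                    duration,
                    rng,
                    participant_offset=offset,
                )
            onsets = np.arange(n_triplets) * TRIPLET_PERIOD
            percepts = _governing_percepts(onsets, truth_table)
            noise = band_noise(n_samp, sample_rate, neural, rng, size=n_triplets)
            data = noise + kernel[None, :]
            data[percepts == SEGREGATED] += effect[None, :]
            es = ep.EpochSet(
                data=data,
                onsets=onsets,
                sample_rate=sample_rate,
                delta_f=np.full(n_triplets, delta_f),
                condition=np.array([condition] * n_triplets, dtype=object),
                sequence_id=np.array(
                    [f"{participant_id}_b{b:02d}_s{s:02d}"] * n_triplets, dtype=object
                ),
                participant_id=participant_id,
            )
            es.retained = ep.apply_exclusion(es, reports, guard=guard)
            es.labels = ep.label_epochs(es, reports)
            sets.append(es)
            pct_cells.setdefault((delta_f, condition), []).append(
                percent_segregation(reports)
            )
    epochs = ep.concatenate_epochs(sets)
    report_pct = {k: float(np.mean(v)) for k, v in pct_cells.items()}
    return epochs, report_pct


def simulate_cohort_epochs(
    n_participants: int,
    percept: PerceptParams,
    neural: NeuralParams,
    seed: int | np.random.SeedSequence = 0,
    n_blocks: int = 4,
    n_triplets: int = 250,
    guard: float = 1.5,
    neural_intention_attenuation: float = 1.0,
    sample_rate: float = 250.0,
):
    """Epoch sets and report percentages for a whole cohort (fast path).

    Returns ``(epoch_sets, report_pct)`` in the shapes the analysis stages
    consume: a dict participant -> EpochSet and a dict keyed by
    (participant, delta_f, condition) holding reported percent segregation.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    epoch_sets: dict[str, object] = {}
    report_pct: dict[tuple, float] = {}
    for p, child in enumerate(ss.spawn(n_participants)):
        pid = f"p{p:02d}"
        epochs, pct = simulate_participant_epochs(
            pid,
            np.random.default_rng(child),
            percept,
            neural,
            n_blocks=n_blocks,
            n_triplets=n_triplets,
            guard=guard,
            neural_intention_attenuation=neural_intention_attenuation,
            sample_rate=sample_rate,
        )
        epoch_sets[pid] = epochs
        for (df, cond), v in pct.items():
            report_pct[(pid, df, cond)] = v
    return epoch_sets, report_pct


# ---------------------------------------------------------------------------
# Cohort generation


def _block_schedule(
    rng: np.random.Generator, n_blocks: int
) -> list[list[tuple[str, float]]]:
    """Instruction/delta-f schedule: per block two non-consecutive neutral
    sequences plus one of each intention condition; delta f alternates from
    sequence to sequence; every condition x delta f cell occurs at least
    once across the session (guaranteed by rejection sampling)."""
    for _ in range(1000):
        blocks = []
        for b in range(n_blocks):
            while True:
                order = list(BLOCK_CONDITIONS)
                rng.shuffle(order)
                neutral_pos = [i for i, c in enumerate(order) if c == "neutral"]
                if neutral_pos[1] - neutral_pos[0] > 1:
                    break
            start = DELTA_FS[b % 2]
            dfs = [
                DELTA_FS[(DELTA_FS.index(start) + i) % 2] for i in range(len(order))
            ]
            blocks.append(list(zip(order, dfs)))
        cells = set(itertools.chain.from_iterable(blocks))
        # full condition x delta-f coverage needs at least two blocks
        wanted = len(CONDITIONS) * len(DELTA_FS) if n_blocks >= 2 else 0
        if len(cells) >= wanted:
            return blocks
    raise RuntimeError("could not build a balanced schedule")  # pragma: no cover


def generate_participant(
    participant_id: str,
    seed_seq: np.random.SeedSequence,
    percept: PerceptParams,
    neural: NeuralParams,
    n_blocks: int = 4,
    n_triplets: int = 250,
    h_freq: float = H_FREQ_DEFAULT,
    synthesize: bool = True,
) -> dict:
    """Simulate one participant's full session in memory.

    Returns a dict with the participant template, per-sequence timelines,
    phase tables, report streams and (optionally) recordings.
    """
    rng = np.random.default_rng(seed_seq)
    template = draw_participant_template(neural, rng)
    offset = float(rng.normal(0.0, percept.between_participant_sd))
    schedule = _block_schedule(rng, n_blocks)
    sequences = []
    for b, block in enumerate(schedule):
        for s, (condition, delta_f) in enumerate(block):
            seq_id = f"{participant_id}_b{b:02d}_s{s:02d}"
            timeline = build_stimulus_timeline(
                n_triplets, h_freq=h_freq, delta_f=delta_f, sequence_id=seq_id
            )
            table, reports = simulate_phase_sequence(
                percept,
                condition,
                delta_f,
                timeline.duration,
                rng,
                participant_offset=offset,
            )
            rec = (
                synthesize_recording(timeline, table, neural, template, rng)
                if synthesize
                else None
            )
            sequences.append(
                {
                    "sequence_id": seq_id,
                    "block": b,
                    "condition": condition,
                    "delta_f": delta_f,
                    "timeline": timeline,
                    "phases": table,
                    "reports": reports,
                    "recording": rec,
                }
            )
    return {
        "participant_id": participant_id,
        "template": template,
        "behavior_offset": offset,
        "sequences": sequences,
    }


def generate_cohort(
    out_dir: str | Path,
    n_participants: int,
    percept: PerceptParams | None = None,
    neural: NeuralParams | None = None,
    seed: int = 0,
    n_blocks: int = 4,
    n_triplets: int = 250,
    h_freq: float = H_FREQ_DEFAULT,
    synthesize: bool = True,
    overwrite: bool = False,
) -> Path:
    """Write a simulated cohort to disk: per participant, one events table
    and one recording (float32 + JSON sidecar) per sequence, plus a cohort
    manifest. Deterministic given ``seed``."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    percept = percept or PerceptParams()
    neural = neural or NeuralParams()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass overwrite=True to replace"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    seed_seqs = np.random.SeedSequence(seed).spawn(n_participants)
    manifest = {"seed": seed, "n_participants": n_participants, "participants": []}
    for p, seed_seq in enumerate(seed_seqs):
        pid = f"p{p:02d}"
        data = generate_participant(
            pid,
            seed_seq,
            percept,
            neural,
            n_blocks=n_blocks,
            n_triplets=n_triplets,
            h_freq=h_freq,
            synthesize=synthesize,
        )
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        for seq in data["sequences"]:
            events = pd.concat(
                [
                    timeline_events(seq["timeline"], seq["condition"]),
                    reports_to_events(seq["reports"]),
                ]
            ).sort_values("onset", kind="stable")
            stem = pdir / seq["sequence_id"]
            write_events(f"{stem}_events.tsv", events)
            if seq["recording"] is not None:
                seq["recording"].meta["seed"] = seed
                write_recording(f"{stem}_rec", seq["recording"])
        manifest["participants"].append(
            {"participant_id": pid, "n_sequences": len(data["sequences"])}
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
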