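"""FIR windowed-sinc band filtering and downsampling.

The analysis band is 0.278-30 Hz: a low-pass at 30 Hz (6 dB cutoff,
6.667 Hz transition band) and a high-pass at 0.278 Hz (6 dB cutoff,
0.556 Hz transition band), both linear-phase Hamming-windowed sinc filters
applied zero-phase, followed by decimation to 250 Hz. The high-pass period
(1/0.278 Hz = 3.6 s) matches the shortest possible interval between
retained epochs carrying different percept reports, so slow drift cannot
masquerade as a percept difference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import ContinuousRecording

#: Hamming-window kernel-length factor: transition width ~ 3.3 / N_taps
#: in normalized frequency.
_HAMMING_TBW_FACTOR = 3.3


@dataclass
class FilterSpec:
    kind: str  # "lowpass" | "highpass"
    cutoff_6db: float
    transition_bw: float
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError("kind must be 'lowpass' or 'highpass'")
        if self.cutoff_6db <= 0 or self.transition_bw <= 0:
            raise ValueError("cutoff and transition bandwidth must be positive")
        if self.kind == "highpass" and self.cutoff_6db - self.transition_bw / 2 < 0:
            raise ValueError("highpass transition band extends below 0 Hz")


LOWPASS_30 = FilterSpec("lowpass", 30.0, 6.667)
HIGHPASS_0278 = FilterSpec("highpass", 0.278, 0.556)


def design_windowed_sinc(spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Linear-phase windowed-sinc kernel with the -6 dB point at the cutoff.

    Kernel length is ceil(3.3 / normalized transition bandwidth), rounded up
    to odd so the kernel is symmetric about an integer group delay.
    """
    nyquist = sample_rate / 2.0
    if spec.cutoff_6db >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_6db} Hz must be below Nyquist ({nyquist} Hz)"
        )
    numtaps = int(np.ceil(_HAMMING_TBW_FACTOR * sample_rate / spec.transition_bw))
    if numtaps % 2 == 0:
        numtaps += 1
    kernel = signal.firwin(
        numtaps,
        spec.cutoff_6db,
        window=spec.window,
        pass_zero=(spec.kind == "lowpass"),
        fs=sample_rate,
    )
    # pin the DC gain exactly (1 for lowpass, 0 for highpass); the residual
    # being spread over all taps leaves the passband response unchanged to
    # within ~1e-6
    if spec.kind == "lowpass":
        kernel = kernel / kernel.sum()
    else:
        kernel = kernel - kernel.sum() / numtaps
    return kernel


def filter_signal(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-phase application of a symmetric FIR kernel.

    The signal is reflect-padded by half the kernel length on each side
    before convolution, so the output has the input's length and no onset
    transient from an implicit zero boundary.
    """
    data = np.asarray(data, dtype=float)
    if kernel.shape[0] > data.shape[-1]:
        raise ValueError(
            f"kernel ({kernel.shape[0]} taps) longer than signal "
            f"({data.shape[-1]} samples)"
        )
    half = kernel.shape[0] // 2
    padded = np.concatenate(
        [data[..., 1 : half + 1][..., ::-1], data, data[..., -half - 1 : -1][..., ::-1]],
        axis=-1,
    )
    return signal.fftconvolve(padded, kernel, mode="valid")


def filter_recording(rec: ContinuousRecording, spec: FilterSpec) -> ContinuousRecording:
    kernel = design_windowed_sinc(spec, rec.sample_rate)
    return replace(rec, data=filter_signal(rec.data, kernel))


def resample(rec: ContinuousRecording, target_rate: float) -> ContinuousRecording:
    """Downsample by integer decimation; anti-alias filtering must have been
    applied beforehand (the 30 Hz low-pass suffices for 250 Hz)."""
    if target_rate > rec.sample_rate:
        raise ValueError("upsampling is not supported")
    if target_rate == rec.sample_rate:
        return rec
    ratio = rec.sample_rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} Hz must integer-divide {rec.sample_rate} Hz"
        )
    return replace(rec, data=rec.data[..., ::factor], sample_rate=target_rate)


def preprocess_recording(
    rec: ContinuousRecording,
    lowpass: FilterSpec = LOWPASS_30,
    highpass: FilterSpec = HIGHPASS_0278,
    target_rate: float = 250.0,
) -> ContinuousRecording:
    """Low-pass, high-pass, then decimate: the standard chain applied to
    every continuous recording before epoching."""
    out = filter_recording(rec, lowpass)
    out = filter_recording(out, highpass)
    return resample(out, target_rate)
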