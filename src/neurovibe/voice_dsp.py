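"""Voice signal chain.

Short-time energy segmentation, a one-sided STFT with exact overlap-add
inversion, per-frequency spectral gating against an estimated noise floor,
a Mel filterbank, and MFCC extraction.

Framing convention: frames are half-open sample intervals [t*S, t*S + N) with
0-based indices, so a signal of length L yields floor((L - N)/S) + 1 frames.
The same convention is shared by the energy series and the spectrogram, which
keeps voice-activity intervals and time-frequency columns aligned.

MFCCs follow the log-Mel/DCT construction

    M_m(t) = sum_f h_m(f) * P(f, t)
    MFCC_n(t) = sum_{m=1..M} log(max(M_m(t), eps)) * cos[pi*n/M * (m - 1/2)]

for n = 1..n_coeffs; the DC cepstral term (n = 0) is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .pipeline_io import VoiceRecording


def _frame_count(length: int, frame: int, hop: int) -> int:
    if frame > length:
        raise ValueError(f"frame length {frame} exceeds signal length {length}")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    return (length - frame) // hop + 1


@dataclass
class EnergySeries:
    values: np.ndarray      # E(t) per frame, >= 0
    frame: int              # window length N in samples
    hop: int                # shift S in samples


@dataclass
class SpectroMatrix:
    values: np.ndarray      # complex, (N//2 + 1, T)
    window: np.ndarray
    frame: int
    hop: int
    rate: int

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.values) ** 2


@dataclass
class MelBank:
    weights: np.ndarray     # (M, n_bins), non-negative
    centers_hz: np.ndarray

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


@dataclass
class MFCCMatrix:
    values: np.ndarray      # (n_coeffs, T); coefficient n = row n-1


def short_time_energy(rec: VoiceRecording | np.ndarray, frame: int, hop: int,
                      ) -> EnergySeries:
    """E(t) = sum of squared samples over window t (length N, shift S)."""
    x = rec.samples if isinstance(rec, VoiceRecording) else np.asarray(rec, float)
    n_frames = _frame_count(len(x), frame, hop)
    sq = x ** 2
    energy = np.array([sq[t * hop: t * hop + frame].sum() for t in range(n_frames)])
    return EnergySeries(energy, frame, hop)


def segment_speech(energy: EnergySeries, rel_threshold: float,
                   min_frames: int = 1) -> list[tuple[int, int]]:
    """Half-open frame-index intervals where E >= rel_threshold * max(E).

    Runs shorter than ``min_frames`` are dropped.  All-zero energy yields an
    empty list (pure silence, not an error).
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    e = energy.values
    peak = e.max() if len(e) else 0.0
    if peak <= 0:
        return []
    active = e >= rel_threshold * peak
    intervals = []
    start = None
    for t, flag in enumerate(active):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            if t - start >= min_frames:
                intervals.append((start, t))
            start = None
    if start is not None and len(active) - start >= min_frames:
        intervals.append((start, len(active)))
    return intervals


def _make_window(name: str | np.ndarray, frame: int) -> np.ndarray:
    if isinstance(name, np.ndarray):
        if len(name) != frame:
            raise ValueError("window length must equal the frame length")
        return name.astype(float)
    return get_window(name, frame, fftbins=True)


def stft(rec: VoiceRecording | np.ndarray, frame: int, hop: int,
         window: str | np.ndarray = "hann", rate: int | None = None,
         ) -> SpectroMatrix:
    """One-sided STFT over half-open frames; (N//2 + 1) x T complex matrix."""
    if isinstance(rec, VoiceRecording):
        x, sr = rec.samples, rec.rate
    else:
        x, sr = np.asarray(rec, float), int(rate or 0)
    w = _make_window(window, frame)
    n_frames = _frame_count(len(x), frame, hop)
    frames = np.stack([x[t * hop: t * hop + frame] for t in range(n_frames)])
    X = np.fft.rfft(frames * w, axis=1).T
    return SpectroMatrix(X, w, frame, hop, sr)


def istft(spec: SpectroMatrix) -> np.ndarray:
    """Weighted overlap-add inversion; exact on the covered sample range.

    Raises if the squared-window coverage vanishes anywhere inside the
    reconstructed span (window/hop combination that cannot be inverted).
    """
    frames = np.fft.irfft(spec.values.T, n=spec.frame, axis=1)
    n_frames = frames.shape[0]
    length = (n_frames - 1) * spec.hop + spec.frame
    num = np.zeros(length)
    den = np.zeros(length)
    w = spec.window
    for t in range(n_frames):
        sl = slice(t * spec.hop, t * spec.hop + spec.frame)
        num[sl] += frames[t] * w
        den[sl] += w ** 2
    cutoff = 1e-3 * den.max()
    interior = slice(spec.frame, max(length - spec.frame, spec.frame))
    if np.any(den[interior] < cutoff):
        raise ValueError("window/hop combination is not invertible "
                         "(zero squared-window coverage)")
    covered = den >= cutoff      # edge samples with negligible coverage -> 0
    out = np.zeros(length)
    out[covered] = num[covered] / den[covered]
    return out


def estimate_gate_threshold(spec: SpectroMatrix, noise_percentile: float,
                            ) -> np.ndarray:
    """Per-frequency noise floor Th(f): the given percentile of |X(f, .)|
    across frames (lower-interpolation convention)."""
    if not 0 < noise_percentile < 100:
        raise ValueError("noise_percentile must be in (0, 100)")
    return np.percentile(spec.magnitudes, noise_percentile, axis=1,
                         method="lower")


def spectral_gate(spec: SpectroMatrix, threshold: float | np.ndarray,
                  ) -> SpectroMatrix:
    """Zero the cells with |X(f,t)| < Th; survivors keep their phase.

    ``threshold`` may be a scalar or a per-frequency vector.
    """
    th = np.asarray(threshold, dtype=float)
    if th.ndim == 1:
        th = th[:, None]
    elif th.ndim != 0:
        raise ValueError("threshold must be a scalar or per-frequency vector")
    if np.any(th < 0):
        raise ValueError("threshold must be >= 0")
    gated = np.where(spec.magnitudes >= th, spec.values, 0.0)
    return SpectroMatrix(gated, spec.window, spec.frame, spec.hop, spec.rate)


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(frame: int, rate: int, n_filters: int,
                   f_low: float = 0.0, f_high: float | None = None) -> MelBank:
    """M triangular filters, peak-normalized to 1, with centers equally
    spaced on the Mel scale between f_low and f_high."""
    if n_filters < 2:
        raise ValueError("need at least 2 Mel filters")
    f_high = rate / 2 if f_high is None else f_high
    if not 0 <= f_low < f_high <= rate / 2:
        raise ValueError("need 0 <= f_low < f_high <= rate/2")
    n_bins = frame // 2 + 1
    bin_hz = np.arange(n_bins) * rate / frame
    edges = mel_to_hz(np.linspace(hz_to_mel(f_low), hz_to_mel(f_high),
                                  n_filters + 2))
    weights = np.zeros((n_filters, n_bins))
    for m in range(n_filters):
        lo, center, hi = edges[m], edges[m + 1], edges[m + 2]
        rising = (bin_hz - lo) / max(center - lo, 1e-12)
        falling = (hi - bin_hz) / max(hi - center, 1e-12)
        weights[m] = np.clip(np.minimum(rising, falling), 0.0, 1.0)
    if np.any(weights.sum(axis=1) <= 0):
        raise ValueError(
            f"{n_filters} filters are too many for {n_bins} frequency bins")
    weights /= weights.max(axis=1, keepdims=True)   # peak-normalize each filter

    return MelBank(weights, edges[1:-1])


def mfcc(power: np.ndarray, bank: MelBank, n_coeffs: int,
         log_floor: float = 1e-10) -> MFCCMatrix:
    """MFCC_n(t) for n = 1..n_coeffs from a one-sided power spectrogram."""
    if n_coeffs > bank.n_filters:
        raise ValueError("n_coeffs must be <= number of Mel filters")
    P = np.atleast_2d(np.asarray(power, dtype=float))
    mel_power = bank.weights @ P                       # (M, T)
    log_mel = np.log(np.maximum(mel_power, log_floor))
    M = bank.n_filters
    n = np.arange(1, n_coeffs + 1)[:, None]
    m = np.arange(1, M + 1)[None, :]
    dct = np.cos(np.pi * n / M * (m - 0.5))            # (n_coeffs, M)
    return MFCCMatrix(dct @ log_mel)


def denoise(rec: VoiceRecording, frame: int, hop: int,
            window: str = "hann", noise_percentile: float = 20.0,
            ) -> tuple[VoiceRecording, SpectroMatrix]:
    """Spectral-gate a recording against its per-frequency noise floor.

    Returns the reconstructed time-domain recording (trimmed to the covered
    sample range) together with the gated spectrogram.
    """
    spec = stft(rec, frame, hop, window)
    th = estimate_gate_threshold(spec, noise_percentile)
    gated = spectral_gate(spec, th)
    cleaned = istft(gated)
    return (VoiceRecording(cleaned, rec.rate, rec.label, rec.subject_id),
            gated)
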