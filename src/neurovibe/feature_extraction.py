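"""Per-subject feature vectors for the two modalities.

The behavioral block V_behavior holds population moments of each subject's
series (mean, variance, skewness) plus constrained-DTW distances to one
class-medoid template per class.  The voice block V_voice holds pitch,
jitter, shimmer and HNR from glottal-cycle analysis of the denoised
waveform, plus four moment statistics (mean, variance, skewness, excess
kurtosis) of each MFCC coefficient across frames: 4 + 4 * n_coeffs entries.

The warping distance used throughout is a weighted DTW with an off-diagonal
skip penalty:

    D(i,j) = w(i,j)*|a_i - b_j| + min{ D(i-1,j) + alpha*p,
                                       D(i,j-1) + alpha*p,
                                       D(i-1,j-1) },

so every insertion or deletion step costs an extra alpha*p while the diagonal
is free; with w = 1 and p = 0 this reduces to classical DTW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline_io import VoiceRecording
from . import voice_dsp


class UnvoicedSignalError(ValueError):
    """Raised when no stable voiced periodicity can be found in a signal."""


# ---------------------------------------------------------------------------
# series statistics
# ---------------------------------------------------------------------------

@dataclass
class SeriesStats:
    mean: float
    variance: float
    skewness: float
    length: int


def series_stats(series) -> SeriesStats:
    """Population (1/N) mean, variance and skewness; skewness is defined 0
    for a constant series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    if var > 0:
        skew = ((x - mu) ** 3).mean() / var ** 1.5
    else:
        skew = 0.0
    return SeriesStats(float(mu), float(var), float(skew), x.size)


# ---------------------------------------------------------------------------
# constrained DTW
# ---------------------------------------------------------------------------

@dataclass
class IDTWResult:
    distance: float
    cost: np.ndarray                  # cumulative cost matrix, (N, M)
    path: list                        # 0-based (i, j) pairs, (0,0) .. (N-1,M-1)
    alpha: float
    skip_penalty: float


def idtw(a, b, w: float | np.ndarray = 1.0, alpha: float = 1.0,
         p: float = 0.0) -> IDTWResult:
    """Weighted DTW distance with per-step skip penalty alpha*p on the two
    off-diagonal moves.  Backtracking prefers diagonal, then vertical, so the
    returned optimal path is deterministic under ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be nonempty")
    if alpha < 0 or p < 0:
        raise ValueError("alpha and p must be >= 0")
    n, m = a.size, b.size
    W = np.asarray(w, dtype=float)
    if W.ndim == 0:
        W = np.full((n, m), float(W))
    elif W.shape != (n, m):
        raise ValueError(f"weight matrix shape {W.shape} != ({n}, {m})")
    local = W * np.abs(a[:, None] - b[None, :])
    skip = alpha * p
    D = np.empty((n, m))
    D[0, 0] = local[0, 0]
    for j in range(1, m):
        D[0, j] = local[0, j] + D[0, j - 1] + skip
    for i in range(1, n):
        D[i, 0] = local[i, 0] + D[i - 1, 0] + skip
        for j in range(1, m):
            D[i, j] = local[i, j] + min(D[i - 1, j] + skip,
                                        D[i, j - 1] + skip,
                                        D[i - 1, j - 1])
    # backtrack; tie preference: diagonal, vertical, horizontal
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            options = (D[i - 1, j - 1], D[i - 1, j] + skip, D[i, j - 1] + skip)
            best = min(options)
            if options[0] == best:
                i, j = i - 1, j - 1
            elif options[1] == best:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return IDTWResult(float(D[n - 1, m - 1]), D, path, alpha, p)


def gaussian_band_weights(n: int, m: int, band: float = 2.0) -> np.ndarray:
    """Optional weighting emphasizing near-diagonal alignments: weight grows
    away from the (rescaled) diagonal, discouraging large warps."""
    i = np.arange(n)[:, None] / max(n - 1, 1)
    j = np.arange(m)[None, :] / max(m - 1, 1)
    return 1.0 + (1.0 - np.exp(-((i - j) * max(n, m) / band) ** 2 / 2.0))


def default_skip_penalty(a, b, scale: float = 0.1) -> float:
    """Scale-aware default p: a fraction of the mean absolute series level."""
    level = np.mean(np.abs(np.concatenate([np.ravel(a), np.ravel(b)])))
    return float(scale * level)


def idtw_medoid(series_list: list, alpha: float = 1.0, p: float = 0.0) -> int:
    """Index of the series minimizing the summed IDTW distance to the others
    (ties to the lowest index)."""
    if not series_list:
        raise ValueError("no series given")
    k = len(series_list)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = idtw(series_list[i], series_list[j], 1.0, alpha, p).distance
            dist[i, j] = dist[j, i] = d
    return int(np.argmin(dist.sum(axis=1)))


def idtw_reference_features(series, templates: dict, alpha: float = 1.0,
                            p: float = 0.0) -> dict:
    """IDTW distance from a subject's series to each class-medoid template."""
    if not templates:
        raise ValueError("at least one template required")
    out = {}
    for name, template in templates.items():
        template = np.asarray(template, dtype=float)
        if template.size == 0:
            raise ValueError(f"template {name!r} is empty")
        out[f"idtw_{name}"] = idtw(series, template, 1.0, alpha, p).distance
    return out


# ---------------------------------------------------------------------------
# glottal-cycle analysis
# ---------------------------------------------------------------------------

@dataclass
class GlottalCycles:
    periods: np.ndarray       # T_i in seconds, > 0
    amplitudes: np.ndarray    # per-cycle peak amplitude A_i
    marks: np.ndarray         # sub-sample cycle-start positions (samples)

    @property
    def n_cycles(self) -> int:
        return len(self.periods)


def _autocorr(x: np.ndarray) -> np.ndarray:
    n = len(x)
    size = 1 << (2 * n - 1).bit_length()
    spectrum = np.fft.rfft(x, size)
    return np.fft.irfft(spectrum * np.conj(spectrum), size)[:n]


def _parabolic_refine(y: np.ndarray, k: int) -> float:
    """Sub-sample peak position around index k by parabola through 3 points."""
    return _parabolic_vertex(y, k)[0]


def _parabolic_vertex(y: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-sample peak (position, value) around index k."""
    if k <= 0 or k >= len(y) - 1:
        return float(k), float(y[k])
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    if denom == 0:
        return float(k), float(y[k])
    offset = 0.5 * (y[k - 1] - y[k + 1]) / denom
    value = y[k] - 0.25 * (y[k - 1] - y[k + 1]) * offset
    return k + offset, float(value)


def _dominant_lag(x: np.ndarray, rate: int, f0_min: float, f0_max: float,
                  ) -> tuple[float, float]:
    """Best normalized-autocorrelation lag in the pitch range and its value.

    The raw lagged product sum is normalized by the energies of the two
    overlapping segments (not by r(0) alone), which removes the shrinking
    overlap bias of the plain estimator; the peak value is refined to
    sub-sample precision by parabolic interpolation.
    """
    n = len(x)
    r = _autocorr(x)
    if r[0] <= 0:
        raise UnvoicedSignalError("silent signal")
    lag_lo = max(2, int(rate / f0_max))
    lag_hi = min(n - 2, int(math.ceil(rate / f0_min)))
    if lag_hi <= lag_lo:
        raise UnvoicedSignalError("signal too short for the pitch range")
    csum = np.concatenate([[0.0], np.cumsum(x ** 2)])
    lags = np.arange(lag_lo, lag_hi + 1)
    head = csum[n - lags] - csum[0]        # energy of x[0 : n-tau]
    tail = csum[n] - csum[lags]            # energy of x[tau : n]
    norm = np.sqrt(np.maximum(head * tail, 1e-300))
    rho_all = r[lag_lo:lag_hi + 1] / norm
    # octave guard: a perfectly periodic signal scores equally at every
    # multiple of the fundamental lag, so take the smallest near-maximal lag
    near = np.flatnonzero(rho_all >= rho_all.max() - 0.02)
    k = int(near[0])
    _, rho = _parabolic_vertex(rho_all, k)
    lag = _parabolic_refine(r, lag_lo + k)
    return lag, float(min(rho, 1.0))


def estimate_glottal_cycles(samples, rate: int, f0_min: float = 50.0,
                            f0_max: float = 500.0,
                            voicing_threshold: float = 0.3) -> GlottalCycles:
    """Locate glottal cycle marks by autocorrelation-guided peak picking.

    The dominant autocorrelation lag in the pitch search range fixes an
    expected period; successive waveform peaks are then picked inside a
    +-35% window around each expected mark and refined to sub-sample
    precision.  Periods are the spacings of successive marks; amplitudes are
    per-cycle peak magnitudes.  Signals whose normalized autocorrelation peak
    falls below the voicing threshold raise :class:`UnvoicedSignalError`.
    """
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    if len(x) < 4 or np.max(np.abs(x)) <= 0:
        raise UnvoicedSignalError("silent or too-short signal")
    lag, rho = _dominant_lag(x, rate, f0_min, f0_max)
    if rho < voicing_threshold:
        raise UnvoicedSignalError(
            f"normalized autocorrelation peak {rho:.3f} below "
            f"voicing threshold {voicing_threshold}")
    period = lag
    half_band = 0.35 * period
    # anchor at the strongest peak, then walk both directions
    anchor = int(np.argmax(x))
    marks = [_parabolic_refine(x, anchor)]
    pos = marks[0]
    while pos + period + half_band < len(x):
        lo = int(round(pos + period - half_band))
        hi = int(round(pos + period + half_band)) + 1
        k = lo + int(np.argmax(x[lo:hi]))
        pos = _parabolic_refine(x, k)
        marks.append(pos)
    pos = marks[0]
    while pos - period - half_band >= 0:
        lo = int(round(pos - period - half_band))
        hi = int(round(pos - period + half_band)) + 1
        k = lo + int(np.argmax(x[lo:hi]))
        pos = _parabolic_refine(x, k)
        marks.insert(0, pos)
    marks = np.asarray(marks)
    if len(marks) < 2:
        raise UnvoicedSignalError("fewer than two cycle marks found")
    periods = np.diff(marks) / rate
    if np.any(periods <= 0):
        raise UnvoicedSignalError("non-increasing cycle marks")
    # cycle amplitude = interpolated peak magnitude at the cycle's own mark
    # (a window max would blend in the neighbouring cycle's peak)
    amplitudes = np.empty(len(periods))
    for i in range(len(periods)):
        center = int(round(marks[i]))
        lo = max(center - 2, 0)
        hi = min(center + 3, len(x))
        k = lo + int(np.argmax(np.abs(x[lo:hi])))
        amplitudes[i] = abs(_parabolic_vertex(np.abs(x), k)[1])
    return GlottalCycles(periods, amplitudes, marks)


def pitch(cycles: GlottalCycles) -> float:
    """Fundamental frequency f0 = 1 / mean cycle period (Hz)."""
    if cycles.n_cycles < 1:
        raise ValueError("no cycles")
    return float(1.0 / cycles.periods.mean())


def jitter(cycles: GlottalCycles) -> float:
    """Mean relative cycle-to-cycle period variation,
    (1/(N-1)) * sum |T_i - T_{i+1}| / T_i."""
    T = cycles.periods
    if len(T) < 2:
        raise ValueError("jitter needs at least 2 cycles")
    if np.any(T == 0):
        raise ValueError("zero cycle period")
    return float(np.mean(np.abs(T[:-1] - T[1:]) / T[:-1]))


def shimmer(cycles: GlottalCycles) -> float:
    """Mean relative cycle-to-cycle amplitude variation on A_i."""
    A = cycles.amplitudes
    if len(A) < 2:
        raise ValueError("shimmer needs at least 2 cycles")
    if np.any(A == 0):
        raise ValueError("zero cycle amplitude")
    return float(np.mean(np.abs(A[:-1] - A[1:]) / A[:-1]))


def hnr(samples, rate: int, f0_min: float = 50.0, f0_max: float = 500.0,
        cap_db: float = 60.0) -> float:
    """Harmonics-to-noise ratio, 10*log10(P_harmonic / P_noise) in dB.

    The harmonic/noise power split comes from the normalized autocorrelation
    peak rho at the pitch lag: P_h / P_n = rho / (1 - rho).  Capped at
    +-cap_db.
    """
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    if len(x) < 4 or np.max(np.abs(x)) <= 0:
        raise UnvoicedSignalError("silent or too-short signal")
    _, rho = _dominant_lag(x, rate, f0_min, f0_max)
    if rho <= 0:
        return -cap_db
    if rho >= 1:
        return cap_db
    value = 10.0 * math.log10(rho / (1.0 - rho))
    return float(np.clip(value, -cap_db, cap_db))


def hnr_from_powers(p_harmonic: float, p_noise: float,
                    cap_db: float = 60.0) -> float:
    """HNR in dB directly from harmonic and noise powers."""
    if p_harmonic <= 0:
        return -cap_db
    if p_noise <= 0:
        return cap_db
    return float(np.clip(10.0 * math.log10(p_harmonic / p_noise),
                         -cap_db, cap_db))


# ---------------------------------------------------------------------------
# MFCC moment statistics
# ---------------------------------------------------------------------------

def mfcc_stats(matrix: voice_dsp.MFCCMatrix | np.ndarray,
               literal_moments: bool = False) -> pd.DataFrame:
    """Per-coefficient mean, variance, skewness and excess kurtosis across
    frames.

    Skewness and kurtosis are standardized central moments m3/m2^(3/2) and
    m4/m2^2 - 3 (both 0 when the variance is 0).  With
    ``literal_moments`` the alternative non-standardized expressions
    (1/T) * sum (M[f,t] - mu_f / sigma_f^2)^3  and  ...^4 - 3 are evaluated
    instead; they are provided for comparison only and are neither
    dimensionless nor bounded.
    """
    M = matrix.values if isinstance(matrix, voice_dsp.MFCCMatrix) else \
        np.atleast_2d(np.asarray(matrix, dtype=float))
    if M.size == 0:
        raise ValueError("empty MFCC matrix")
    mu = M.mean(axis=1)
    var = ((M - mu[:, None]) ** 2).mean(axis=1)
    if literal_moments:
        with np.errstate(divide="ignore", invalid="ignore"):
            centered = M - (mu / var)[:, None]
        skew = np.where(var > 0, (centered ** 3).mean(axis=1), 0.0)
        kurt = np.where(var > 0, (centered ** 4).mean(axis=1) - 3.0, 0.0)
    else:
        m3 = ((M - mu[:, None]) ** 3).mean(axis=1)
        m4 = ((M - mu[:, None]) ** 4).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(var > 0, m3 / var ** 1.5, 0.0)
            kurt = np.where(var > 0, m4 / var ** 2 - 3.0, 0.0)
    return pd.DataFrame({"mean": mu, "var": var, "skew": skew, "kurt": kurt},
                        index=np.arange(1, M.shape[0] + 1))


# ---------------------------------------------------------------------------
# vector assembly
# ---------------------------------------------------------------------------

VOICE_QUALITY_NAMES = ("pitch", "jitter", "shimmer", "hnr")


def voice_quality(rec: VoiceRecording, f0_min: float = 50.0,
                  f0_max: float = 500.0, voicing_threshold: float = 0.3,
                  ) -> dict:
    """Pitch, jitter, shimmer and HNR of one recording; NaN when unvoiced."""
    try:
        cycles = estimate_glottal_cycles(rec.samples, rec.rate, f0_min,
                                         f0_max, voicing_threshold)
        return {"pitch": pitch(cycles), "jitter": jitter(cycles),
                "shimmer": shimmer(cycles),
                "hnr": hnr(rec.samples, rec.rate, f0_min, f0_max)}
    except (UnvoicedSignalError, ValueError):
        return {name: float("nan") for name in VOICE_QUALITY_NAMES}


def extract_voice_vector(rec: VoiceRecording, config) -> pd.Series:
    """The full per-recording voice block: acoustic quality measures on the
    denoised waveform plus MFCC moment statistics of the gated spectrogram."""
    cleaned, gated = voice_dsp.denoise(
        rec, config.frame, config.hop, config.window,
        config.gate_noise_percentile)
    quality = voice_quality(cleaned, config.f0_min, config.f0_max,
                            config.voicing_threshold)
    bank = voice_dsp.mel_filterbank(config.frame, rec.rate,
                                    config.mel_filters, config.mel_f_low,
                                    min(config.mel_f_high, rec.rate / 2))
    coeffs = voice_dsp.mfcc(gated.power, bank, config.mfcc_n_coeffs,
                            config.log_floor)
    stats = mfcc_stats(coeffs, config.literal_moments)
    values = dict(quality)
    for idx, row in stats.iterrows():
        for stat in ("mean", "var", "skew", "kurt"):
            values[f"mfcc{idx:02d}_{stat}"] = row[stat]
    return pd.Series(values)


def extract_behavior_vector(series, templates: dict, alpha: float = 1.0,
                            p: float = 0.0) -> pd.Series:
    """The behavioral block: series moments plus IDTW template distances."""
    stats = series_stats(series)
    values = {"beh_mean": stats.mean, "beh_var": stats.variance,
              "beh_skew": stats.skewness}
    values.update(idtw_reference_features(series, templates, alpha, p))
    return pd.Series(values)


def impute_unvoiced(voice_df: pd.DataFrame, medians: pd.Series | None = None,
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing voice-quality values (unvoiced recordings) with training
    medians; returns the filled table and the medians used."""
    if medians is None:
        medians = voice_df.median(axis=0, skipna=True)
    return voice_df.fillna(medians), medians


def assemble_vectors(behavior_rows: list[pd.Series] | pd.DataFrame,
                     voice_rows: list[pd.Series] | pd.DataFrame,
                     voice_medians: pd.Series | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Stack per-subject feature rows into the two named, ordered blocks.

    Returns (V_behavior, V_voice, medians): column order follows the first
    row and is stable across runs; missing voice-quality entries (unvoiced
    recordings) are imputed with ``voice_medians`` (computed from the given
    rows when not supplied, i.e. at training time).
    """
    v_behavior = (behavior_rows if isinstance(behavior_rows, pd.DataFrame)
                  else pd.DataFrame(behavior_rows)).reset_index(drop=True)
    v_voice = (voice_rows if isinstance(voice_rows, pd.DataFrame)
               else pd.DataFrame(voice_rows)).reset_index(drop=True)
    if len(v_behavior) != len(v_voice):
        raise ValueError("behavior and voice row counts differ")
    v_voice, medians = impute_unvoiced(v_voice, voice_medians)
    return v_behavior, v_voice, medians
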