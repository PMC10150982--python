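"""Audio -> segmented syllable spectrograms -> low-dimensional latents.

The built-in feature path mirrors a standard bioacoustics preparation:
amplitude-threshold segmentation of the waveform, a 128 x 128 log-magnitude
mel spectrogram per segment (clipped to a tuned floor/ceiling and rescaled to
[0, 1], symmetrically zero-padded in time), and within-syllable PCA truncated
at the effective dimensionality — the smallest component count explaining
more than 99% of variance (typically 6-8 for juvenile syllables).  Externally
computed encoder latents (e.g. a 32-d VAE posterior mean) enter through the
same :class:`SyllableDataset` contract, in which case PCA only determines the
effective dimensionality and truncation.

STFT parameters (512-sample Hann window, 128-sample hop at 44.1 kHz, so 128
frames cover ~0.38 s) are package defaults, all overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import stft

__all__ = [
    "SpectrogramImage",
    "SyllableDataset",
    "segment_sounds",
    "make_spectrogram",
    "fit_pca_features",
    "mel_filterbank",
    "mel_frequencies",
    "read_wav",
    "write_wav",
]

N_MELS = 128
N_FRAMES = 128
DEFAULT_NPERSEG = 512
DEFAULT_HOP = 128


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_frequencies(n_mels: int = N_MELS, fmin: float = 0.0, fmax: float = 22050.0) -> np.ndarray:
    """Center frequencies (Hz) of ``n_mels`` mel-spaced triangular filters."""
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    return edges[1:-1]


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int = N_MELS,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    if fmax is None:
        fmax = sample_rate / 2.0
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_fft // 2 + 1)
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    fb = np.zeros((n_mels, fft_freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_sounds(
    waveform: np.ndarray,
    sample_rate: int,
    amplitude_threshold: float = 0.05,
    min_gap: float = 0.02,
    min_duration: float = 0.02,
    envelope_window: float = 0.005,
) -> list[tuple[int, int]]:
    """Amplitude-threshold segmentation into half-open sample intervals.

    The RMS envelope over a 5 ms window is thresholded; supra-threshold runs
    separated by gaps shorter than ``min_gap`` seconds are merged, and runs
    shorter than ``min_duration`` seconds are dropped.  Intervals are
    0-based, half-open, sorted and non-overlapping.
    """
    if amplitude_threshold <= 0:
        raise ValueError("amplitude_threshold must be positive")
    x = np.asarray(waveform, dtype=float)
    if x.size == 0:
        return []
    win = max(1, int(round(envelope_window * sample_rate)))
    kernel = np.ones(win) / win
    env = np.sqrt(np.convolve(x * x, kernel, mode="same"))
    above = env >= amplitude_threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # half-open ends
    merged: list[list[int]] = []
    gap_samples = int(round(min_gap * sample_rate))
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < gap_samples:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    min_samples = int(round(min_duration * sample_rate))
    return [(s, e) for s, e in merged if e - s >= min_samples]


# ---------------------------------------------------------------------------
# spectrograms
# ---------------------------------------------------------------------------

@dataclass
class SpectrogramImage:
    """128 (mel) x 128 (time) log-magnitude image, values in [0, 1]."""

    values: np.ndarray
    floor: float
    ceiling: float
    segment: tuple[int, int]
    n_valid_frames: int

    def __post_init__(self):
        if self.values.shape != (N_MELS, N_FRAMES):
            raise ValueError(f"spectrogram must be {N_MELS}x{N_FRAMES}, got {self.values.shape}")


def make_spectrogram(
    waveform: np.ndarray,
    sample_rate: int,
    floor: float = -9.0,
    ceiling: float = 2.0,
    segment: tuple[int, int] | None = None,
    nperseg: int = DEFAULT_NPERSEG,
    hop: int = DEFAULT_HOP,
) -> SpectrogramImage:
    """Log-magnitude mel spectrogram of one segment, clipped and rescaled.

    The segment must fit in ``N_FRAMES`` STFT frames at the configured hop
    (~0.38 s at the defaults); shorter segments are symmetrically zero-padded
    in time to 128 frames.
    """
    if floor >= ceiling:
        raise ValueError("floor must be below ceiling")
    x = np.asarray(waveform, dtype=float)
    if segment is not None:
        x = x[segment[0] : segment[1]]
    else:
        segment = (0, x.size)
    _, _, z = stft(x, fs=sample_rate, nperseg=nperseg, noverlap=nperseg - hop,
                   window="hann", boundary=None, padded=True)
    mag = np.abs(z)
    n_frames = mag.shape[1]
    if n_frames > N_FRAMES:
        max_dur = ((N_FRAMES - 1) * hop + nperseg) / sample_rate
        raise ValueError(
            f"segment spans {n_frames} STFT frames > {N_FRAMES}; maximum duration "
            f"at hop={hop} is {max_dur:.3f} s"
        )
    fb = mel_filterbank(sample_rate, nperseg)
    logmel = np.log(fb @ mag + 1e-12)
    img = (np.clip(logmel, floor, ceiling) - floor) / (ceiling - floor)
    pad_total = N_FRAMES - n_frames
    left = pad_total // 2
    out = np.zeros((N_MELS, N_FRAMES))
    out[:, left : left + n_frames] = img
    return SpectrogramImage(values=out, floor=floor, ceiling=ceiling,
                            segment=tuple(segment), n_valid_frames=n_frames)


# ---------------------------------------------------------------------------
# PCA features
# ---------------------------------------------------------------------------

@dataclass
class SyllableDataset:
    """One syllable's renditions with their truncated PCA representation."""

    renditions: pd.DataFrame  # carries z1..zk projections (+ any metadata cols)
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (k, D), orthonormal rows
    k: int
    variance_explained: float
    warnings: list[str] = field(default_factory=list)

    def project(self, flat: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(flat) - self.pca_mean) @ self.pca_components.T

    def reconstruct(self, latents: np.ndarray) -> np.ndarray:
        return np.atleast_2d(latents) @ self.pca_components + self.pca_mean


def fit_pca_features(
    features: np.ndarray,
    variance_threshold: float = 0.99,
    metadata: pd.DataFrame | None = None,
    latent_prefix: str = "z",
) -> SyllableDataset:
    """Within-syllable PCA truncated at the effective dimensionality.

    ``features`` is (n, D): flattened spectrogram images or external encoder
    latents.  k is the smallest component count whose cumulative explained
    variance exceeds ``variance_threshold``; if the data's rank is reached
    first, k falls back to the rank with a recorded warning.  The returned
    table carries each rendition's k-dim projection as ``z1..zk`` alongside
    any ``metadata`` columns.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(features, dtype=float)
    n, dim = x.shape
    n_max = min(n - 1 if n > 1 else 1, dim)
    pca = PCA(n_components=n_max, svd_solver="full")
    pca.fit(x)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    warnings_: list[str] = []
    above = np.flatnonzero(cum > variance_threshold)
    k = int(above[0]) + 1 if above.size else n_max
    rank = int(np.sum(pca.explained_variance_ > 1e-10 * max(pca.explained_variance_[0], 1e-300)))
    rank = max(rank, 1)
    if k > rank:
        warnings_.append(
            f"variance threshold {variance_threshold} only reached via zero-variance "
            f"components; k reduced to numerical rank {rank}"
        )
        k = rank
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} renditions, got {n}")
    components = pca.components_[:k]
    proj = (x - pca.mean_) @ components.T
    table = metadata.reset_index(drop=True).copy() if metadata is not None else pd.DataFrame(index=range(n))
    for i in range(k):
        table[f"{latent_prefix}{i + 1}"] = proj[:, i]
    return SyllableDataset(
        renditions=table, pca_mean=pca.mean_.copy(), pca_components=components.copy(),
        k=k, variance_explained=float(cum[k - 1]), warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path: str) -> tuple[np.ndarray, int]:
    """Read a WAV file to a float waveform in [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data.astype(float) / np.iinfo(data.dtype).max
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - info.max / 2) / (info.max / 2)
    else:
        data = data.astype(float)
    return data, int(sr)


def write_wav(path: str, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a float waveform as 16-bit PCM."""
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (x * 32767).astype(np.int16))
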