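"""Acoustic feature extraction: spectrogram, Mel-spectrogram, MFCCs, fusion.

A standardised 10 s / 16 kHz clip is framed with a 400-sample Hann window
hopped by 200 samples under centred framing, giving 801 frames.  The
magnitude spectrogram (201 x 801) is pooled through 128 triangular filters
uniformly spaced on the Mel scale over 0-8000 Hz; MFCCs are the first 20
orthonormal type-II DCT coefficients of the decibel-scaled Mel spectrum.
The fused model input stacks the 128 Mel rows on top of the 20 MFCC rows:
a 148 x 801 matrix, each block optionally standardised to zero mean / unit
variance over all of its elements.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.fft import dct

from .preprocess import AudioClip

SAMPLE_RATE = 16_000
WINDOW = 400
HOP = 200
N_MELS = 128
N_MFCC = 20
FMIN, FMAX = 0.0, 8_000.0
DB_FLOOR = -80.0

N_FREQ_BINS = WINDOW // 2 + 1  # 201
N_FRAMES_10S = 10 * SAMPLE_RATE // HOP + 1  # 801


@dataclasses.dataclass
class SpectrogramMatrix:
    values: np.ndarray  # (201, 801) magnitudes
    window_size: int = WINDOW
    hop: int = HOP


@dataclasses.dataclass
class MelSpectrogram:
    values: np.ndarray  # (128, n_frames)
    in_decibels: bool = False


@dataclasses.dataclass
class MFCCMatrix:
    values: np.ndarray  # (20, n_frames)
    n_orders: int = N_MFCC


@dataclasses.dataclass
class FeatureMatrix:
    """Fused input: rows 0-127 Mel (dB), rows 128-147 MFCC."""

    values: np.ndarray  # (148, 801)
    normalized: bool
    mel_rows: int = N_MELS
    mfcc_rows: int = N_MFCC


def hz_to_mel(f):
    """Mel scale: f_mel = 2595 * log10(1 + f / 700)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    m = np.asarray(m, dtype=float)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def stft_magnitude(clip: AudioClip, expected_len: int | None = 10 * SAMPLE_RATE
                   ) -> SpectrogramMatrix:
    """Centred-framing magnitude STFT (Hann window 400, hop 200).

    For a standardised 10 s clip the result is 201 x 801.
    """
    x = np.asarray(clip.samples, dtype=float)
    if expected_len is not None and len(x) != expected_len:
        raise ValueError(f"expected {expected_len} samples, got {len(x)}")
    pad = WINDOW // 2
    xp = np.pad(x, (pad, pad))
    n_frames = 1 + (len(xp) - WINDOW) // HOP
    frames = np.lib.stride_tricks.sliding_window_view(xp, WINDOW)[::HOP]
    frames = frames[:n_frames]
    win = np.hanning(WINDOW + 1)[:-1]  # periodic Hann
    mag = np.abs(np.fft.rfft(frames * win, axis=1))
    return SpectrogramMatrix(values=mag.T.copy())


def mel_filterbank(n_mels: int = N_MELS, n_fft: int = WINDOW,
                   sr: int = SAMPLE_RATE,
                   fmin: float = FMIN, fmax: float = FMAX) -> np.ndarray:
    """Triangular filters uniformly spaced in Mel, area-normalised.

    Returns an (n_mels, n_fft//2 + 1) non-negative weight matrix.
    """
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
        fb[m] *= 2.0 / (hi - lo)  # area (Slaney-style) normalisation
    return fb


def mel_spectrogram(spec: SpectrogramMatrix) -> MelSpectrogram:
    """Apply the 128-filter Mel bank to the power spectrogram."""
    fb = mel_filterbank()
    power = spec.values**2
    return MelSpectrogram(values=fb @ power, in_decibels=False)


def to_decibels(mel: MelSpectrogram) -> MelSpectrogram:
    """10*log10(power / max power), floored at -80 dB."""
    if mel.in_decibels:
        return mel
    p = mel.values
    ref = p.max()
    if ref <= 0:
        return MelSpectrogram(np.full_like(p, DB_FLOOR), in_decibels=True)
    db = 10.0 * np.log10(np.maximum(p, 1e-30) / ref)
    return MelSpectrogram(np.maximum(db, DB_FLOOR), in_decibels=True)


def mfcc(mel_db: MelSpectrogram, n_orders: int = N_MFCC) -> MFCCMatrix:
    """First ``n_orders`` orthonormal type-II DCT coefficients per frame."""
    if not mel_db.in_decibels:
        raise ValueError("MFCCs are computed on the decibel-scaled Mel "
                         "spectrogram; call to_decibels first")
    coeffs = dct(mel_db.values, type=2, axis=0, norm="ortho")[:n_orders]
    return MFCCMatrix(values=coeffs, n_orders=n_orders)


def normalize_feature(m: np.ndarray) -> np.ndarray:
    """(m - mean(m)) / std(m) over all elements (population std)."""
    m = np.asarray(m, dtype=float)
    sd = m.std()
    if sd == 0:
        raise ValueError("cannot normalize a constant matrix")
    return (m - m.mean()) / sd


def fuse(mel_db: MelSpectrogram, mf: MFCCMatrix,
         normalize: bool = True) -> FeatureMatrix:
    """Stack Mel rows atop MFCC rows; optionally standardise each block
    independently before concatenation."""
    a, b = mel_db.values, mf.values
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"column mismatch: {a.shape[1]} vs {b.shape[1]} frames")
    if normalize:
        a = normalize_feature(a)
        b = normalize_feature(b)
    return FeatureMatrix(values=np.vstack([a, b]), normalized=normalize,
                         mel_rows=a.shape[0], mfcc_rows=b.shape[0])


def featurize(clip: AudioClip, normalize: bool = True,
              n_mfcc: int = N_MFCC) -> FeatureMatrix:
    """Full chain: STFT -> Mel -> dB -> MFCC -> fuse (148 x 801)."""
    spec = stft_magnitude(clip)
    mel = mel_spectrogram(spec)
    mel_db = to_decibels(mel)
    mf = mfcc(mel_db, n_orders=n_mfcc)
    return fuse(mel_db, mf, normalize=normalize)


def waveform_features(clip: AudioClip, frame: int = HOP) -> np.ndarray:
    """Raw-waveform baseline input: non-overlapping 200-sample frames of a
    standardised clip, shaped (frame, n_steps) = (200, 800) so the time axis
    matches the spectral features' layout (features x steps)."""
    x = np.asarray(clip.samples, dtype=float)
    n_steps = len(x) // frame
    return x[: n_steps * frame].reshape(n_steps, frame).T.copy()
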