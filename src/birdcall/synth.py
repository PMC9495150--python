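"""Synthetic bird-call corpus generation.

Each species is modelled as a harmonic chirp "voice": syllables are linear
frequency sweeps (50-500 ms) built from a fundamental plus weaker harmonics,
shaped by a Hann amplitude envelope, separated by species-typical silent
gaps, and optionally buried in white Gaussian noise at a chosen level below
the syllable peak.  Species fundamentals occupy disjoint frequency bands so
the resulting classification task is solvable by construction, which is what
makes model-training tests on this corpus meaningful.

All audio is mono 16-bit PCM WAV at 16 kHz.  Corpora are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

SAMPLE_RATE = 16_000
NYQUIST = SAMPLE_RATE // 2
#: lowest admissible fundamental: safely above the 150 Hz high-pass stopband
F0_FLOOR = 200.0
#: highest admissible partial (keep everything below Nyquist with margin)
F_CEIL = 7_900.0
#: minimum separation between species' band centres, Hz
MIN_CENTER_SEP = 200.0

SYLLABLE_DUR_BOUNDS = (0.05, 0.5)
DEFAULT_CLIP_DUR_RANGE = (6.0, 14.0)


@dataclasses.dataclass(frozen=True)
class SpeciesSpec:
    """Acoustic parameters of one synthetic species."""

    species_id: str
    f0_range: tuple[float, float]            # Hz, fundamental band
    n_harmonics: int
    syllable_dur_range: tuple[float, float]  # s, within [0.05, 0.5]
    inter_syllable_gap_range: tuple[float, float]  # s
    chirp_slope: float                       # Hz/s frequency sweep
    amplitude_jitter: float                  # relative fraction

    def __post_init__(self):
        lo, hi = self.f0_range
        if not lo < hi:
            raise ValueError("f0 range must satisfy low < high")
        if lo < F0_FLOOR:
            raise ValueError(f"fundamental below {F0_FLOOR} Hz floor")
        if hi * self.n_harmonics >= NYQUIST:
            raise ValueError("highest harmonic exceeds Nyquist")
        dlo, dhi = self.syllable_dur_range
        if dlo < SYLLABLE_DUR_BOUNDS[0] or dhi > SYLLABLE_DUR_BOUNDS[1]:
            raise ValueError("syllable durations must lie in [0.05, 0.5] s")
        if self.n_harmonics < 1:
            raise ValueError("need at least the fundamental")


@dataclasses.dataclass
class DatasetManifest:
    """Index of a generated corpus: one row per written WAV."""

    records: pd.DataFrame  # columns: wav_path, species_id, duration_s
    seed: int
    n_species: int

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path)
        return DatasetManifest(
            records=df, seed=-1, n_species=df["species_id"].nunique()
        )


def make_species_specs(n_species: int, seed: int) -> list[SpeciesSpec]:
    """Draw ``n_species`` mutually discriminable species voices.

    Band centres are evenly spaced between 500 Hz and 6500 Hz (at least
    200 Hz apart) with a small seeded jitter, so fundamentals never overlap.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    lo_center, hi_center = 500.0, 6_500.0
    if n_species > 1:
        sep = (hi_center - lo_center) / (n_species - 1)
    if n_species > int((hi_center - lo_center) / MIN_CENTER_SEP) + 1:
        raise ValueError(
            f"cannot place {n_species} species bands >= {MIN_CENTER_SEP} Hz "
            f"apart below Nyquist"
        )
    rng = np.random.default_rng(seed)
    centers = np.linspace(lo_center, hi_center, n_species)
    # jitter must neither break the minimum separation nor push the lowest
    # band near the high-pass stopband
    jitter_amp = min(max(0.0, (sep - MIN_CENTER_SEP) / 2.0) * 0.5, 150.0)
    centers = centers + rng.uniform(-jitter_amp, jitter_amp, size=n_species)
    specs = []
    for i, c in enumerate(centers):
        half_bw = rng.uniform(40.0, min(90.0, MIN_CENTER_SEP / 2 - 5))
        f0 = (max(F0_FLOOR, c - half_bw), c + half_bw)
        n_harm = int(min(3, F_CEIL // f0[1]))
        n_harm = max(1, n_harm)
        dur_lo = rng.uniform(0.06, 0.15)
        dur_hi = dur_lo + rng.uniform(0.05, 0.2)
        gap_lo = rng.uniform(0.1, 0.3)
        gap_hi = gap_lo + rng.uniform(0.1, 0.4)
        specs.append(
            SpeciesSpec(
                species_id=f"species_{i:03d}",
                f0_range=(float(f0[0]), float(f0[1])),
                n_harmonics=n_harm,
                syllable_dur_range=(float(dur_lo), float(min(dur_hi, 0.5))),
                inter_syllable_gap_range=(float(gap_lo), float(gap_hi)),
                chirp_slope=float(rng.uniform(-1500.0, 1500.0)),
                amplitude_jitter=float(rng.uniform(0.05, 0.2)),
            )
        )
    return specs


def _render_syllable(
    spec: SpeciesSpec, dur: float, rng: np.random.Generator
) -> np.ndarray:
    """One Hann-enveloped harmonic linear chirp."""
    n = max(int(round(dur * SAMPLE_RATE)), 2)
    t = np.arange(n) / SAMPLE_RATE
    f_start = rng.uniform(*spec.f0_range)
    # keep the sweep inside the band
    f_end = np.clip(f_start + spec.chirp_slope * dur, *spec.f0_range)
    inst_freq = f_start + (f_end - f_start) * t / dur
    phase = 2 * np.pi * np.cumsum(inst_freq) / SAMPLE_RATE
    sig = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        sig += np.sin(k * phase + rng.uniform(0, 2 * np.pi)) / k
    env = np.hanning(n)
    amp = 1.0 + rng.uniform(-spec.amplitude_jitter, spec.amplitude_jitter)
    return amp * env * sig


def synthesize_annotated(
    spec: SpeciesSpec, duration_s: float, noise_db: float, seed: int
):
    """Render a call and return ``(clip, events)`` where ``events`` is the
    ground-truth list of syllable ``(start_s, end_s)`` pairs."""
    from .preprocess import AudioClip  # local import to avoid a cycle

    if duration_s <= 0.05:
        raise ValueError("duration must exceed 0.05 s")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration_s * SAMPLE_RATE))
    samples = np.zeros(n_total)
    events: list[tuple[float, float]] = []
    t_cursor = rng.uniform(*spec.inter_syllable_gap_range) * 0.5
    while True:
        dur = rng.uniform(*spec.syllable_dur_range)
        start = int(round(t_cursor * SAMPLE_RATE))
        end = start + int(round(dur * SAMPLE_RATE))
        if end >= n_total:
            break
        syl = _render_syllable(spec, dur, rng)
        samples[start : start + len(syl)] += syl
        events.append((start / SAMPLE_RATE, (start + len(syl)) / SAMPLE_RATE))
        t_cursor += dur + rng.uniform(*spec.inter_syllable_gap_range)
    if not events:  # clip shorter than one gap+syllable: force one syllable
        dur = min(spec.syllable_dur_range[0], duration_s - 0.01)
        syl = _render_syllable(spec, dur, rng)
        samples[: len(syl)] += syl
        events.append((0.0, len(syl) / SAMPLE_RATE))
    peak = np.abs(samples).max()
    samples *= 0.9 / peak  # headroom against int16 clipping
    if np.isfinite(noise_db):
        # noise_db is the noise PEAK level relative to the syllable peak;
        # a Gaussian's observed peak is ~4 sigma, so sigma = peak/4.
        sigma = 0.9 * 10.0 ** (noise_db / 20.0) / 4.0
        samples = samples + rng.normal(0.0, sigma, size=n_total)
        samples = np.clip(samples, -1.0, 1.0)
    return AudioClip(samples=samples, sample_rate=SAMPLE_RATE), events


def synthesize_call(
    spec: SpeciesSpec, duration_s: float, noise_db: float, seed: int
):
    """Render one call clip (see :func:`synthesize_annotated`)."""
    clip, _ = synthesize_annotated(spec, duration_s, noise_db, seed)
    return clip


def build_dataset(
    specs: list[SpeciesSpec],
    clips_per_species: int,
    out_dir: str | Path,
    seed: int,
    noise_db: float = -25.0,
    clip_dur_range: tuple[float, float] = DEFAULT_CLIP_DUR_RANGE,
) -> DatasetManifest:
    """Write a labelled WAV corpus and its CSV manifest.

    Clip durations are drawn uniformly from ``clip_dur_range`` (default
    6-14 s) so downstream standardisation exercises both the padding and
    the cropping path.
    """
    if clips_per_species < 2:
        raise ValueError("need >= 2 clips per species for a stratified split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        for j in range(clips_per_species):
            dur = float(rng.uniform(*clip_dur_range))
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clip = synthesize_call(spec, dur, noise_db, clip_seed)
            path = out_dir / f"{spec.species_id}_{j:04d}.wav"
            write_wav(path, clip.samples)
            rows.append(
                {"wav_path": str(path), "species_id": spec.species_id,
                 "duration_s": dur}
            )
    manifest = DatasetManifest(
        records=pd.DataFrame(rows), seed=seed, n_species=len(specs)
    )
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def write_wav(path: str | Path, samples: np.ndarray) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM mono at 16 kHz."""
    pcm = np.round(np.clip(samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(str(path), SAMPLE_RATE, pcm)
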