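"""Ground-truth developmental latent datasets (and toy audio) for testing.

The generator emulates the statistical structure the downstream analyses
assume in a juvenile zebra finch recording corpus: each syllable type is a
cluster in a k-dimensional latent feature space whose mean drifts smoothly
across development (~60-95 days post hatch) and whose rendition-to-rendition
Gaussian variation has higher entropy in the morning than in the evening,
declining linearly within each day and slowly across development.  Birds sing
only inside a lights-on window; by default the cluster mean advances only
while the bird is singing ("song-time" progress), so there is no overnight
change in the mean — the configuration under which any overnight quantile
effects must come from variability, not mean regression.

Entropy is controlled by isotropic scaling of a per-syllable eigenvalue
spectrum whose geometric mean is one, so the *allocation* of variance across
latent directions (eigenvalue ratios, slowly rotating eigenbasis) and the
*entropy* (overall magnitude) are independently controllable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm

from .devmodel import GaussianSnapshot

__all__ = [
    "GroundTruthParams",
    "generate_dataset",
    "true_mean_at",
    "true_covariance_at",
    "true_entropy_at",
    "TrueGaussianModel",
    "synth_syllable_audio",
    "write_dataset",
    "read_dataset",
    "LATENT_PREFIX",
]

LATENT_PREFIX = "z"
_ENTROPY_CONST = 0.5 * (1.0 + np.log(2.0 * np.pi))  # per-dimension entropy of N(0,1)


@dataclass(frozen=True)
class GroundTruthParams:
    """Parameters of the synthetic developmental corpus.

    Defaults correspond to the study conditions this package targets:
    5 birds x 13 syllables, 60-95 dph, a 14 h lights-on window, ~200
    renditions per syllable per day, entropy declining ~1 nat over each day
    and slowly across development.
    """

    n_birds: int = 5
    syllables_per_bird: int = 13
    k: int = 6
    age_range: tuple[float, float] = (60.0, 95.0)
    day_window: tuple[float, float] = (7.0, 21.0)  # lights on/off, hours
    total_displacement: float = 5.0  # latent units traversed over age_range
    mean_progress: str = "song_time"  # "song_time" (no overnight advance) | "continuous"
    entropy_base: float = 8.5  # nats, at age_range[0], lights-on
    entropy_day_amplitude: float = 1.0  # nats of linear within-day decline
    entropy_dev_slope: float = -0.033  # nats per dph across development
    eigen_decay: float = 0.7  # geometric decay of eigenvalue spectrum
    rotation_deg_per_day: float = 1.0  # eigenbasis rotation rate
    renditions_per_day: int = 200
    center_scale: float = 10.0  # SD of syllable cluster centers
    seed: int = 0

    @property
    def n_days(self) -> int:
        return int(np.ceil(self.age_range[1])) - int(self.age_range[0])

    @property
    def days(self) -> np.ndarray:
        return np.arange(int(self.age_range[0]), int(np.ceil(self.age_range[1])))

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        on, off = self.day_window
        if not on < off:
            raise ValueError(f"lights_on must precede lights_off, got {self.day_window}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError(f"empty age_range {self.age_range}")
        if not 0 < self.eigen_decay <= 1:
            raise ValueError("eigen_decay must be in (0, 1]")
        if self.renditions_per_day < 1:
            raise ValueError("renditions_per_day must be positive")
        # entropy at the most contracted corner must keep eigenvalues away
        # from underflow; isotropic exp scaling is positive but can vanish
        # numerically if the schedule is absurd.
        for age in (self.age_range[0], self.age_range[1]):
            for tod in self.day_window:
                lam = _eigenvalues_at(self, age, tod)
                if lam.min() < 1e-12:
                    raise ValueError(
                        "implied covariance numerically non-positive-definite "
                        f"(min eigenvalue {lam.min():.3g}) for every syllable at "
                        f"age={age} dph, time_of_day={tod} h; raise entropy_base "
                        "or shrink the entropy schedule amplitudes"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["day_window"] = list(self.day_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthParams":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        d["day_window"] = tuple(d["day_window"])
        return cls(**d)


# ---------------------------------------------------------------------------
# deterministic per-syllable structure
# ---------------------------------------------------------------------------

def _syllable_rng(params: GroundTruthParams, bird: int, syl: int, stream: int) -> np.random.Generator:
    # counter-based substreams: any (bird, syllable) subset regenerates
    # identically regardless of which other subsets were drawn
    return np.random.default_rng([params.seed, bird, syl, stream])


def _syllable_structure(params: GroundTruthParams, bird: int, syl: int):
    """(center, unit drift direction, eigen ratios, base eigenbasis, rotation generator)."""
    rng = _syllable_rng(params, bird, syl, 0)
    k = params.k
    center = rng.normal(0.0, params.center_scale, size=k)
    u = rng.normal(size=k)
    u /= np.linalg.norm(u)
    ratios = params.eigen_decay ** np.arange(k, dtype=float)
    ratios /= np.exp(np.mean(np.log(ratios)))  # geometric mean 1 -> det decoupled
    q0, _ = np.linalg.qr(rng.normal(size=(k, k)))
    a = rng.normal(size=(k, k))
    a = a - a.T
    ev = np.abs(np.linalg.eigvals(a).imag).max()
    if ev > 0:
        a = a / ev  # unit angular speed
    gen = a * np.deg2rad(params.rotation_deg_per_day)
    return center, u, ratios, q0, gen


def _day_fraction(params: GroundTruthParams, tod: np.ndarray | float) -> np.ndarray:
    on, off = params.day_window
    return np.clip((np.asarray(tod, dtype=float) - on) / (off - on), 0.0, 1.0)


def _progress(params: GroundTruthParams, age: np.ndarray | float, tod: np.ndarray | float) -> np.ndarray:
    a0, a1 = params.age_range
    age = np.asarray(age, dtype=float)
    if params.mean_progress == "continuous":
        return np.clip((age - a0) / (a1 - a0), 0.0, 1.0)
    if params.mean_progress != "song_time":
        raise ValueError(f"unknown mean_progress {params.mean_progress!r}")
    day = np.floor(age)
    s = (day - int(a0)) + _day_fraction(params, tod)
    return np.clip(s / params.n_days, 0.0, 1.0)


def _entropy_at(params: GroundTruthParams, age, tod) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    return (
        params.entropy_base
        + params.entropy_dev_slope * (age - params.age_range[0])
        - params.entropy_day_amplitude * _day_fraction(params, tod)
    )


def _eigenvalues_at(params: GroundTruthParams, age, tod) -> np.ndarray:
    h = _entropy_at(params, age, tod)
    log_det = 2.0 * (h - params.k * _ENTROPY_CONST)
    c = np.exp(log_det / params.k)
    ratios = params.eigen_decay ** np.arange(params.k, dtype=float)
    ratios /= np.exp(np.mean(np.log(ratios)))
    return np.atleast_1d(c)[..., None] * ratios


def _check_range(params: GroundTruthParams, age: float, tod: float) -> None:
    a0, a1 = params.age_range
    on, off = params.day_window
    if not (a0 <= age < np.ceil(a1)) or not (on <= tod <= off):
        raise ValueError(
            f"query (age={age}, tod={tod}) outside generated range "
            f"age [{a0}, {np.ceil(a1)}), time-of-day [{on}, {off}]"
        )


def true_mean_at(params: GroundTruthParams, bird: int, syl: int, age: float, tod: float) -> np.ndarray:
    """Generating mean mu*(age, tod) of syllable (bird, syl)."""
    _check_range(params, age, tod)
    center, u, _, _, _ = _syllable_structure(params, bird, syl)
    return center + u * params.total_displacement * _progress(params, age, tod)


def true_covariance_at(params: GroundTruthParams, bird: int, syl: int, age: float, tod: float) -> np.ndarray:
    """Generating covariance Sigma*(age, tod) of syllable (bird, syl)."""
    _check_range(params, age, tod)
    _, _, ratios, q0, gen = _syllable_structure(params, bird, syl)
    lam = _eigenvalues_at(params, age, tod).ravel()
    q = q0 @ expm(gen * (age - params.age_range[0]))
    return (q * lam) @ q.T


def true_entropy_at(params: GroundTruthParams, age: float, tod: float) -> float:
    """Differential entropy (nats) of the generating Gaussian at (age, tod).

    The eigenvalue spectrum is normalized to geometric mean one, so entropy is
    shared across syllables and equals the schedule value exactly.
    """
    _check_range(params, age, tod)
    return float(_entropy_at(params, age, tod))


class TrueGaussianModel:
    """The generator itself viewed as a distribution model of one syllable.

    Exposes the same ``k`` / ``snapshot(age, tod)`` surface as a trained
    density network, so every downstream stage (entropy trajectories,
    clamping, simulation) can be exercised against exact ground truth.
    """

    def __init__(self, params: GroundTruthParams, bird: int = 0, syl: int = 0):
        params.validate()
        self.params = params
        self.bird = bird
        self.syl = syl
        self.k = params.k

    def snapshot(self, age_dph: float, time_of_day_h: float) -> GaussianSnapshot:
        mu = true_mean_at(self.params, self.bird, self.syl, age_dph, time_of_day_h)
        sigma = true_covariance_at(self.params, self.bird, self.syl, age_dph, time_of_day_h)
        return GaussianSnapshot.from_covariance(mu, sigma)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(params: GroundTruthParams) -> pd.DataFrame:
    """Draw the full synthetic corpus as a flat rendition table.

    Returns a DataFrame with columns ``bird_id, syllable_id, age_dph,
    time_of_day_h, day_index, z1..zk``, one row per rendition.  Deterministic
    given ``params.seed``; each (bird, syllable) block is drawn from its own
    counter-derived substream.
    """
    params.validate()
    on, off = params.day_window
    frames = []
    for bird in range(params.n_birds):
        for syl in range(params.syllables_per_bird):
            rng = _syllable_rng(params, bird, syl, 1)
            _, _, ratios, q0, gen = _syllable_structure(params, bird, syl)
            rows_tod, rows_day = [], []
            for day in params.days:
                tod = np.sort(rng.uniform(on, off, size=params.renditions_per_day))
                rows_tod.append(tod)
                rows_day.append(np.full(tod.size, day, dtype=int))
            tod = np.concatenate(rows_tod)
            day_idx = np.concatenate(rows_day)
            age = day_idx + tod / 24.0
            lam = _eigenvalues_at(params, age, tod)  # (n, k)
            # eigenbasis rotates slowly with age; evaluate per day (rotation
            # rate ~1 deg/day makes sub-day rotation negligible) for speed
            mu = _mean_block(params, bird, syl, age, tod)
            eps = rng.standard_normal((age.size, params.k))
            z = np.empty_like(eps)
            for day in params.days:
                m = day_idx == day
                q = q0 @ expm(gen * (day + 0.5 - params.age_range[0]))
                z[m] = mu[m] + (np.sqrt(lam[m]) * eps[m]) @ q.T
            frames.append(
                pd.DataFrame(
                    {
                        "bird_id": f"bird{bird:02d}",
                        "syllable_id": f"b{bird:02d}_s{syl:02d}",
                        "age_dph": age,
                        "time_of_day_h": tod,
                        "day_index": day_idx,
                        **{f"{LATENT_PREFIX}{i + 1}": z[:, i] for i in range(params.k)},
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _mean_block(params, bird, syl, age, tod):
    center, u, _, _, _ = _syllable_structure(params, bird, syl)
    p = _progress(params, age, tod)
    return center[None, :] + np.outer(p * params.total_displacement, u)


def latent_columns(df: pd.DataFrame) -> list[str]:
    """The z1..zk columns of a rendition table, in dimension order."""
    cols = [c for c in df.columns if c.startswith(LATENT_PREFIX) and c[len(LATENT_PREFIX):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(LATENT_PREFIX):]))


# ---------------------------------------------------------------------------
# toy audio
# ---------------------------------------------------------------------------

def synth_syllable_audio(
    params: GroundTruthParams,
    syllable_id: int,
    age: float,
    seed: int,
    sample_rate: int = 44100,
    f0: float | None = None,
    amplitude: float = 0.3,
    n_harmonics: int = 5,
    pad_s: float = 0.05,
) -> tuple[np.ndarray, int]:
    """A short harmonic-stack syllable embedded in silence.

    Fundamental frequency and duration vary smoothly with ``age``; the peak
    amplitude equals ``amplitude`` (default 0.3, well above the segmentation
    threshold defaults in :mod:`songdev.features`).  ``amplitude = 0``
    produces pure silence.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng([seed, syllable_id])
    dur = min(0.12 + 0.002 * (age - params.age_range[0]), 0.28)
    if f0 is None:
        f0 = 1200.0 + 40.0 * syllable_id + 8.0 * (age - params.age_range[0])
    n = int(round(dur * sample_rate))
    t = np.arange(n) / sample_rate
    wave = np.zeros(n)
    if amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
        for h in range(1, n_harmonics + 1):
            wave += 0.5 ** (h - 1) * np.sin(2 * np.pi * h * f0 * t + phases[h - 1])
        ramp = int(0.005 * sample_rate)
        env = np.ones(n)
        env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[n - ramp:] = env[:ramp][::-1]
        wave *= env
        wave *= amplitude / np.abs(wave).max()
    pad = np.zeros(int(pad_s * sample_rate))
    return np.concatenate([pad, wave, pad]), sample_rate


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dataset(df: pd.DataFrame, path: str, params: GroundTruthParams | None = None) -> None:
    """Write the rendition table as CSV (plus a parquet twin when pyarrow is
    available) and the generating parameters as a YAML sidecar."""
    path = str(path)
    if not path.endswith(".csv"):
        raise ValueError("dataset path must end in .csv")
    df.to_csv(path, index=False)
    try:
        df.to_parquet(path[:-4] + ".parquet")
    except ImportError:  # pragma: no cover - pyarrow optional
        pass
    if params is not None:
        with open(path[:-4] + ".yaml", "w") as fh:
            yaml.safe_dump({"ground_truth": params.to_dict()}, fh)


def read_dataset(path: str) -> tuple[pd.DataFrame, GroundTruthParams | None]:
    import os

    df = pd.read_csv(path)
    side = str(path)[:-4] + ".yaml"
    params = None
    if os.path.exists(side):
        with open(side) as fh:
            d = yaml.safe_load(fh)
        if d and "ground_truth" in d:
            params = GroundTruthParams.from_dict(d["ground_truth"])
    return df, params
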