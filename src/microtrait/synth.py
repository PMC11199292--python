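"""Synthetic resting-state EEG and cohorts with known ground truth.

The generator emulates the study conditions downstream code is built for:
64-channel eyes-closed EEG at 512 Hz whose scalp topography at every instant
is one of K=4 fixed zero-mean maps, driven by a sign-flipping oscillatory
carrier (alpha-band, amplitude-modulated), with state run lengths drawn from a
gamma law (population mean 80 ms, between-subject SD 15 ms, i.e. the centre of
the 40-120 ms range typical of resting microstates). On the trait side, a
cohort table plants an aggression score that depends linearly on microstate
stability with a gender-specific standardized slope (defaults -0.47 for men,
-0.14 for women), mapped onto 12 Likert items in 1..6.

State transitions are aligned by default to zero crossings of the carrier
(moments of minimal field power), which is where topographic switches are
observed in real recordings; pass ``snap_to_carrier=False`` for transitions at
arbitrary phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .maps import canonical_maps, gfp, zero_mean
from .montage import SensorMontage, make_montage
from .preprocess import EEGRecording, EpochSet

__all__ = [
    "FixedRunLength",
    "GammaRunLength",
    "make_prototype_maps",
    "simulate_state_sequence",
    "simulate_eeg",
    "inject_spikes",
    "SubjectSimulation",
    "simulate_recording",
    "CohortSimConfig",
    "simulate_trait_table",
    "trait_analysis_table",
    "simulate_cohort",
    "LazyCohort",
]


# --------------------------------------------------------------------------
# run-length laws
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedRunLength:
    """Degenerate law: every run lasts exactly `n_samples` samples."""

    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("run length must be >= 1 sample")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.n_samples, dtype=int)

    @property
    def mean_samples(self) -> float:
        return float(self.n_samples)


@dataclass(frozen=True)
class GammaRunLength:
    """Gamma run-length law in samples, discretized by rounding to >= 1.

    Parameterized by mean and SD; ``shape = (mean/sd)**2``,
    ``scale = sd**2/mean``.
    """

    mean_samples: float
    sd_samples: float

    def __post_init__(self) -> None:
        if self.mean_samples <= 0 or self.sd_samples <= 0:
            raise ValueError("mean and SD must be positive")

    @classmethod
    def from_ms(cls, mean_ms: float, sd_ms: float, sfreq: float) -> "GammaRunLength":
        return cls(mean_ms * sfreq / 1000.0, sd_ms * sfreq / 1000.0)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        shape = (self.mean_samples / self.sd_samples) ** 2
        scale = self.sd_samples**2 / self.mean_samples
        draws = rng.gamma(shape, scale, size)
        return np.maximum(1, np.rint(draws)).astype(int)


# --------------------------------------------------------------------------
# maps and state sequences
# --------------------------------------------------------------------------


def make_prototype_maps(
    montage: SensorMontage, K: int = 4, seed: int = 0
) -> np.ndarray:
    """`K` zero-mean unit-norm generator maps on `montage`.

    The first four are the canonical dipolar topographies A-D; any further
    maps are random zero-mean fields orthogonalized against the earlier ones.
    All pairs satisfy polarity-invariant |corr| <= 0.7.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    base = canonical_maps(montage)
    if K <= 4:
        return base[:K].copy()
    rng = np.random.default_rng(seed)
    maps = [m for m in base]
    C = montage.n_channels
    while len(maps) < K:
        v = zero_mean(rng.normal(size=C))
        for m in maps:
            v -= (v @ m) * m
        n = np.linalg.norm(v)
        if n < 1e-8:
            raise ValueError(f"montage cannot support {K} distinct maps")
        maps.append(v / n)
    return np.stack(maps)


def simulate_state_sequence(
    duration_law,
    n_samples: int,
    K: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    snap_period: float | None = None,
) -> np.ndarray:
    """Semi-Markov label vector: i.i.d. run lengths, no self-transitions.

    Each run's label is uniform over the other ``K - 1`` states. With
    `snap_period` (in samples) run boundaries are moved to the nearest
    multiple of that period — used to place switches at carrier zero
    crossings; runs collapsed to zero length disappear (adjacent equal labels
    then merge).
    """
    if K < 2:
        raise ValueError("need K >= 2 states for non-self transitions")
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if n_samples == 0:
        return np.empty(0, dtype=int)
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths: list[int] = []
    total = 0
    while total < n_samples:
        batch = duration_law.sample(rng, 64)
        if np.any(batch < 1):
            raise ValueError("duration law produced a non-positive run length")
        lengths.extend(int(x) for x in batch)
        total += int(batch.sum())
    n_runs = next(i for i in range(1, len(lengths) + 1) if sum(lengths[:i]) >= n_samples)
    lengths = lengths[:n_runs]
    labs = np.empty(n_runs, dtype=int)
    labs[0] = rng.integers(K)
    for i in range(1, n_runs):
        step = rng.integers(1, K)
        labs[i] = (labs[i - 1] + step) % K
    ends = np.cumsum(lengths)
    if snap_period is not None:
        if snap_period <= 0:
            raise ValueError("snap_period must be positive")
        ends = np.rint(np.rint(ends / snap_period) * snap_period).astype(int)
    out = np.empty(n_samples, dtype=int)
    prev = 0
    for lab, end in zip(labs, ends):
        end = min(int(end), n_samples)
        if end > prev:
            out[prev:end] = lab
        prev = max(prev, end)
        if prev >= n_samples:
            break
    if prev < n_samples:
        out[prev:] = labs[-1]
    return out


def _carrier(
    n_samples: int,
    sfreq: float,
    oscillation_hz: float,
    am_hz: float,
    am_depth: float,
    am_phase: float,
) -> np.ndarray:
    t = np.arange(n_samples) / sfreq
    env = 1.0 + am_depth * np.sin(2 * np.pi * am_hz * t + am_phase)
    return np.sin(2 * np.pi * oscillation_hz * t) * env


def simulate_eeg(
    maps: np.ndarray,
    labels: np.ndarray,
    snr: float | None = 5.0,
    oscillation_hz: float = 10.0,
    sfreq: float = 512.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    am_hz: float = 2.0,
    am_depth: float = 0.5,
    amplitude_uv: float = 15.0,
    channel_labels: tuple[str, ...] | None = None,
    return_parts: bool = False,
):
    """Render a label sequence into continuous EEG.

    Sample ``t`` equals ``maps[labels[t]] * a(t)`` plus spatially white
    Gaussian noise, where ``a(t)`` is an amplitude-modulated sinusoid at
    `oscillation_hz` (so the field polarity flips within each state). Maps
    are rescaled to unit GFP, then the whole signal to `amplitude_uv` GFP
    peak-scale; the noise SD is set so RMS(signal)/RMS(noise) equals `snr`
    (``snr=None`` disables noise).
    """
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if maps.ndim != 2:
        raise ValueError("maps must be (K, n_channels)")
    K, C = maps.shape
    if np.max(np.abs(maps.mean(axis=1))) > 1e-6 * max(np.abs(maps).max(), 1e-30):
        raise ValueError("generator maps must be zero-mean across channels")
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError("labels index outside the map set")
    if channel_labels is not None and len(channel_labels) != C:
        raise ValueError("channel label count must match map channel count")
    if snr is not None and not math.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    scaled = maps / np.maximum(gfp(maps, axis=1)[:, None], 1e-30)
    n = labels.size
    a = _carrier(n, sfreq, oscillation_hz, am_hz, am_depth, am_phase=rng.uniform(0, 2 * np.pi))
    sig = scaled[labels].T * a[None, :] * amplitude_uv
    rms_sig = float(np.sqrt(np.mean(sig**2))) if n else 0.0
    if snr is None or math.isinf(snr) or rms_sig == 0.0:
        noise = np.zeros_like(sig)
    else:
        noise = rng.normal(0.0, rms_sig / snr, size=sig.shape)
    data = sig + noise
    if channel_labels is None:
        channel_labels = tuple(f"CH{i + 1:02d}" for i in range(C))
    rec = EEGRecording(
        data=data,
        sfreq=sfreq,
        labels=channel_labels,
        annotations=[(0.0, n / sfreq, "eyes_closed")],
    )
    if return_parts:
        return rec, {"signal": sig, "noise": noise, "carrier": a}
    return rec


def inject_spikes(
    epochs: EpochSet,
    n_spiked: int,
    amplitude_uv: float = 150.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Add one `amplitude_uv` spike to `n_spiked` randomly chosen epochs.

    Returns the modified epoch set and the ground-truth spiked indices; used
    to test the amplitude rejection rule.
    """
    if n_spiked > epochs.n_epochs:
        raise ValueError("cannot spike more epochs than exist")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.choice(epochs.n_epochs, size=n_spiked, replace=False)
    data = epochs.epochs.copy()
    for e in idx:
        ch = rng.integers(data.shape[1])
        t = rng.integers(data.shape[2])
        data[e, ch, t] += amplitude_uv * (1 if rng.integers(2) else -1)
    out = EpochSet(
        epochs=data,
        sfreq=epochs.sfreq,
        epoch_length=epochs.epoch_length,
        labels=epochs.labels,
        reference=epochs.reference,
        provenance=dict(epochs.provenance),
    )
    return out, np.sort(idx)


# --------------------------------------------------------------------------
# subject-level recordings
# --------------------------------------------------------------------------


@dataclass
class SubjectSimulation:
    """One synthetic subject: the recording plus everything planted in it."""

    subject_id: str
    recording: EEGRecording
    state_labels: np.ndarray
    maps: np.ndarray
    duration_mean_ms: float  # the subject's latent run-length mean
    realized_mean_duration_ms: float  # mean run length actually rendered

    @staticmethod
    def realized_duration(labels: np.ndarray, sfreq: float) -> float:
        runs = run_lengths(labels)
        return float(np.mean(runs)) * 1000.0 / sfreq


def run_lengths(labels: np.ndarray) -> np.ndarray:
    """Lengths of maximal constant runs in a label vector."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.empty(0, dtype=int)
    change = np.flatnonzero(np.diff(labels) != 0)
    bounds = np.concatenate([[-1], change, [labels.size - 1]])
    return np.diff(bounds).astype(int)


def simulate_recording(
    montage: SensorMontage,
    duration_mean_ms: float = 80.0,
    duration_sd_ms: float = 15.0,
    record_seconds: float = 120.0,
    K: int = 4,
    snr: float | None = 5.0,
    oscillation_hz: float = 10.0,
    sfreq: float = 512.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    maps: np.ndarray | None = None,
    snap_to_carrier: bool = True,
    subject_id: str = "sub-01",
) -> SubjectSimulation:
    """Simulate one subject's eyes-closed resting recording."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if maps is None:
        maps = make_prototype_maps(montage, K)
    law = GammaRunLength.from_ms(duration_mean_ms, duration_sd_ms, sfreq)
    n = int(round(record_seconds * sfreq))
    snap = sfreq / (2.0 * oscillation_hz) if snap_to_carrier else None
    labels = simulate_state_sequence(law, n, K, rng=rng, snap_period=snap)
    rec = simulate_eeg(
        maps,
        labels,
        snr=snr,
        oscillation_hz=oscillation_hz,
        sfreq=sfreq,
        rng=rng,
        channel_labels=montage.labels,
    )
    return SubjectSimulation(
        subject_id=subject_id,
        recording=rec,
        state_labels=labels,
        maps=maps,
        duration_mean_ms=duration_mean_ms,
        realized_mean_duration_ms=SubjectSimulation.realized_duration(labels, sfreq),
    )


# --------------------------------------------------------------------------
# cohorts with planted trait effects
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimConfig:
    """Ground-truth parameters of a synthetic cohort.

    Defaults reproduce the study conditions: N = 101 (58 women, 43 men),
    120 s of eyes-closed 64-channel EEG per subject at 512 Hz, four states
    with population-mean duration 80 ms (between-subject SD 15 ms), SNR 5,
    and standardized aggression-on-duration slopes of -0.47 in men and
    -0.14 in women. ``noise_sd_trait=None`` sets the trait residual SD per
    gender to ``sqrt(1 - beta**2)`` so the planted beta *is* the
    within-gender standardized slope.
    """

    seed: int
    n_subjects: int = 101
    K: int = 4
    n_channels: int = 64
    duration_mean_population: float = 80.0
    duration_sd_population: float = 15.0
    duration_sd_within: float = 15.0
    duration_sd_type: float | None = None  # table-only per-type jitter
    snr: float = 5.0
    oscillation_hz: float = 10.0
    sfreq: float = 512.0
    record_seconds: float = 120.0
    snap_to_carrier: bool = True
    beta_male: float = -0.47
    beta_female: float = -0.14
    noise_sd_trait: float | None = None
    prop_female: float = 58.0 / 101.0
    aq_mean: float = 3.5
    aq_sd: float = 0.8
    true_maps: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.duration_mean_population <= 0:
            raise ValueError("population mean duration must be positive")
        if abs(self.beta_male) > 1 or abs(self.beta_female) > 1:
            raise ValueError("standardized slopes must satisfy |beta| <= 1")
        if not (1.0 <= self.aq_mean <= 6.0):
            raise ValueError("aq_mean must map into the 1..6 AQ range")
        if not (0.0 <= self.prop_female <= 1.0):
            raise ValueError("prop_female must be in [0, 1]")

    @property
    def sd_type(self) -> float:
        # Default chosen so the type-consistency ICC of durations is 0.75.
        if self.duration_sd_type is not None:
            return self.duration_sd_type
        return self.duration_sd_population / math.sqrt(3.0)


def _aq_items(target: float, rng: np.random.Generator, n_items: int = 12) -> np.ndarray:
    """12 integer responses in 1..6 whose mean is within 1/(2*12) of `target`."""
    target = float(np.clip(target, 1.0, 6.0))
    total = int(np.clip(round(target * n_items), n_items, 6 * n_items))
    base = total // n_items
    rem = total - base * n_items
    items = np.array([base + 1] * rem + [base] * (n_items - rem), dtype=int)
    rng.shuffle(items)
    for _ in range(2 * n_items):  # mean-preserving jitter within scale bounds
        i, j = rng.integers(n_items), rng.integers(n_items)
        if i != j and items[i] < 6 and items[j] > 1:
            items[i] += 1
            items[j] -= 1
    return items


def _genders(config: CohortSimConfig, rng: np.random.Generator) -> np.ndarray:
    n_female = int(round(config.n_subjects * config.prop_female))
    g = np.array(["female"] * n_female + ["male"] * (config.n_subjects - n_female))
    rng.shuffle(g)
    return g


def _trait_scores(
    config: CohortSimConfig,
    genders: np.ndarray,
    z_duration: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    betas = np.where(genders == "male", config.beta_male, config.beta_female)
    if config.noise_sd_trait is None:
        resid_sd = np.sqrt(np.maximum(0.0, 1.0 - betas**2))
    else:
        resid_sd = np.full(genders.size, config.noise_sd_trait)
    y = betas * z_duration + rng.normal(0.0, 1.0, genders.size) * resid_sd
    target = np.clip(config.aq_mean + config.aq_sd * y, 1.0, 6.0)
    return y, target


def simulate_trait_table(
    config: CohortSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort table with planted gender-specific duration-aggression slopes.

    No EEG is rendered: per-type durations are the subject's latent mean plus
    type jitter (SD chosen so the planted type-consistency ICC is 0.75), and
    per-type occurrences follow the semi-Markov identity
    ``occurrence = coverage * 1000 / duration`` with coverage 1/4.

    Returns ``(subject_table, ground_truth)``: the subject table carries
    gender, the 12 AQ items and the stability metrics; the ground truth
    carries the planted latents.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    genders = _genders(config, rng)
    latent = rng.normal(config.duration_mean_population, config.duration_sd_population, n)
    latent = np.clip(latent, 20.0, None)
    types = ("A", "B", "C", "D")
    per_type = latent[:, None] + rng.normal(0.0, config.sd_type, (n, len(types)))
    per_type = np.clip(per_type, 10.0, None)
    mean_dur = per_type.mean(axis=1)
    sd_mean = math.sqrt(
        config.duration_sd_population**2 + config.sd_type**2 / len(types)
    )
    z = (mean_dur - config.duration_mean_population) / sd_mean
    y, target = _trait_scores(config, genders, z, rng)
    items = np.stack([_aq_items(t, rng) for t in target])
    occ = 250.0 / per_type  # coverage 1/4 each
    rows = {
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "gender": genders,
    }
    for j in range(12):
        rows[f"aq_item_{j + 1:02d}"] = items[:, j]
    for k, t in enumerate(types):
        rows[f"duration_{t}_ms"] = per_type[:, k]
    for k, t in enumerate(types):
        rows[f"occurrence_{t}_hz"] = occ[:, k]
    rows["mean_duration_ms"] = mean_dur
    rows["mean_occurrence_hz"] = occ.mean(axis=1)
    subject_table = pd.DataFrame(rows)
    ground_truth = pd.DataFrame(
        {
            "subject_id": rows["subject_id"],
            "gender": genders,
            "true_latent_duration_ms": latent,
            "true_mean_duration_ms": mean_dur,
            "planted_beta": np.where(genders == "male", config.beta_male, config.beta_female),
            "trait_z_score": y,
            "aq_target": target,
        }
    )
    return subject_table, ground_truth


def trait_analysis_table(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Score the AQ items and return the analysis-ready subject table."""
    from .traitstats import score_aq

    out = subject_table.copy()
    item_cols = [f"aq_item_{j + 1:02d}" for j in range(12)]
    scores = out[item_cols].apply(
        lambda r: pd.Series(score_aq(r.to_numpy()).as_dict()), axis=1
    )
    return pd.concat([out, scores], axis=1)


class LazyCohort:
    """Sequence of :class:`SubjectSimulation`, rendered on demand.

    Rendering a full cohort of two-minute 64-channel recordings eagerly would
    hold gigabytes in memory; each subject is instead generated (bit-)
    deterministically from its own spawned seed when indexed.
    """

    def __init__(self, config: CohortSimConfig, latents: np.ndarray, montage: SensorMontage):
        self._config = config
        self._latents = latents
        self.montage = montage
        self._maps = (
            np.asarray(config.true_maps, dtype=float)
            if config.true_maps is not None
            else make_prototype_maps(montage, config.K)
        )
        self._seeds = np.random.SeedSequence(config.seed).spawn(len(latents))

    @property
    def maps(self) -> np.ndarray:
        return self._maps

    def __len__(self) -> int:
        return len(self._latents)

    def __getitem__(self, i: int) -> SubjectSimulation:
        if not 0 <= i < len(self):
            raise IndexError(i)
        cfg = self._config
        rng = np.random.default_rng(self._seeds[i])
        return simulate_recording(
            self.montage,
            duration_mean_ms=float(self._latents[i]),
            duration_sd_ms=cfg.duration_sd_within,
            record_seconds=cfg.record_seconds,
            K=cfg.K,
            snr=cfg.snr,
            oscillation_hz=cfg.oscillation_hz,
            sfreq=cfg.sfreq,
            rng=rng,
            maps=self._maps,
            snap_to_carrier=cfg.snap_to_carrier,
            subject_id=f"sub-{i + 1:03d}",
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[LazyCohort, pd.DataFrame, pd.DataFrame]:
    """Full cohort: EEG recordings, subject table, and ground truth.

    Gender, latent mean duration and AQ responses are fixed first; the
    recordings then render each subject's latent run-length law into EEG,
    lazily. Aggression is planted on the z-score of the latent duration
    (population mean/SD), i.e. on the quantity the segmentation pipeline
    estimates. The subject table carries only identifiers, gender and the
    12 AQ items — the stability metrics are what the pipeline must produce.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    genders = _genders(config, rng)
    latent = rng.normal(config.duration_mean_population, config.duration_sd_population, n)
    latent = np.clip(latent, 20.0, None)
    z = (latent - config.duration_mean_population) / config.duration_sd_population
    y, target = _trait_scores(config, genders, z, rng)
    items = np.stack([_aq_items(t, rng) for t in target])
    rows = {
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "gender": genders,
    }
    for j in range(12):
        rows[f"aq_item_{j + 1:02d}"] = items[:, j]
    subject_table = pd.DataFrame(rows)
    ground_truth = pd.DataFrame(
        {
            "subject_id": rows["subject_id"],
            "gender": genders,
            "true_latent_duration_ms": latent,
            "planted_beta": np.where(genders == "male", config.beta_male, config.beta_female),
            "trait_z_score": y,
            "aq_target": target,
        }
    )
    montage = make_montage(config.n_channels)
    cohort = LazyCohort(config, latent, montage)
    return cohort, subject_table, ground_truth
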