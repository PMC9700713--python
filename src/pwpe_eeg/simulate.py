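"""Synthetic study generator: oddball sequences, cohort table, trial-locked EEG.

Emulates the study conditions of a duration-deviant auditory oddball
recording: ~1830 tones at 500 ms ISI, 90% standards / 10% deviants, a
32-channel modified 10-20 cap sampled at 500 Hz, and a cohort of healthy
controls (HC) plus clinical high-risk (CHR) individuals carrying SIPS
symptom scores. Planted effects tie trial-wise EEG amplitude linearly to
z-scored HGF regressors inside a chosen channel set and latency window,
so every downstream stage (preprocessing, first-level GLM, group
inference, ANCOVA) is testable against known ground truth.

The noise model is AR(1) in time with Gaussian spatial correlation
across channels plus stereotyped blink transients on the EOG channel —
enough structure to exercise smoothing, artifact rejection and cluster
inference, with no claim to match real EEG spectra.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._exceptions import AlignmentError, ConfigurationError
from .containers import ChannelInfo, EpochSet, ToneSequence, make_cap32
from .hgf import TrajectorySet

__all__ = ["ParadigmSpec", "CohortSpec", "EffectSpec", "NoiseSpec",
           "gen_tone_sequence", "gen_block_sequence", "gen_cohort",
           "gen_subject_eeg", "subject_scales"]

#: blink leakage factors from the vertical EOG onto frontal electrodes
_BLINK_LEAK = {"Fp1": 0.4, "Fp2": 0.4, "F7": 0.15, "F3": 0.15, "Fz": 0.15,
               "F4": 0.15, "F8": 0.15}


@dataclass
class ParadigmSpec:
    """Oddball paradigm layout (defaults mirror the emulated study)."""

    n_trials: int = 1830
    p_deviant: float = 0.10
    isi_ms: float = 500.0
    srate: float = 500.0
    epoch_window: tuple[float, float] = (-100.0, 400.0)
    channels: ChannelInfo = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_deviant <= 1.0:
            raise ConfigurationError("p_deviant must lie in [0, 1]")
        if self.srate <= 0:
            raise ConfigurationError("srate must be > 0")
        lo, hi = self.epoch_window
        if not (lo < 0.0 < hi):
            raise ConfigurationError("epoch window must straddle stimulus onset")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.channels is None:
            self.channels = make_cap32()

    @property
    def times(self) -> np.ndarray:
        """Epoch sample times in ms (inclusive of both window edges)."""
        step = 1000.0 / self.srate
        lo, hi = self.epoch_window
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


@dataclass
class CohortSpec:
    """Simulated cohort composition and SIPS score distributions."""

    n_hc: int = 23
    n_chr: int = 31
    sips_positive: tuple[float, float] = (10.5, 3.6)
    sips_negative: tuple[float, float] = (12.8, 4.9)
    sips_disorganised: tuple[float, float] = (5.6, 3.2)
    sips_general: tuple[float, float] = (9.6, 4.0)
    age_hc: tuple[float, float] = (21.5, 2.8)
    age_chr: tuple[float, float] = (20.7, 2.4)
    #: amplitude multiplier slope per SD of SIPS positive (CHR subjects)
    effect_link: float = 0.5

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_chr < 1:
            raise ConfigurationError("cohort counts must be >= 1")
        for name in ("sips_positive", "sips_negative", "sips_disorganised",
                     "sips_general"):
            if getattr(self, name)[1] < 0:
                raise ConfigurationError(f"{name} sd must be >= 0")


@dataclass
class EffectSpec:
    """A planted linear effect: amplitude (uV) per unit of z-scored regressor."""

    regressor: str = "epsilon2"
    channels: tuple[str, ...] = ("F3", "Fz", "F4", "FC1", "FC2", "Cz")
    window: tuple[float, float] = (100.0, 228.0)
    amplitude: float = 5.0


@dataclass
class NoiseSpec:
    """Additive noise: AR(1) in time, Gaussian-kernel correlation in space."""

    trial_sd: float = 10.0        # uV, stationary sd per channel/sample
    ar1: float = 0.95             # temporal autocorrelation at 500 Hz
    spatial_scale: float = 40.0   # mm correlation length across channels
    blink_rate: float = 0.05      # probability of a blink per trial
    blink_amplitude: float = 300.0  # uV on the vertical EOG channel
    drift_sd: float = 2.0         # uV slow per-trial baseline drift

    def __post_init__(self) -> None:
        if self.trial_sd <= 0:
            raise ConfigurationError("trial_sd must be > 0")
        if not 0.0 <= self.ar1 < 1.0:
            raise ConfigurationError("ar1 must lie in [0, 1)")


def gen_tone_sequence(spec: ParadigmSpec, seed: int,
                      min_gap: int | None = None) -> ToneSequence:
    """Draw a pseudorandom standard/deviant sequence.

    Placement is i.i.d. Bernoulli(p_deviant) by default; ``min_gap``
    optionally enforces at least that many standards between deviants
    (deviants violating the gap are re-flipped to standards).
    """
    rng = np.random.default_rng(seed)
    u = (rng.random(spec.n_trials) < spec.p_deviant).astype(np.int8)
    if min_gap:
        last = -min_gap - 1
        for k in range(u.size):
            if u[k] == 1:
                if k - last <= min_gap:
                    u[k] = 0
                else:
                    last = k
    return ToneSequence(u, isi_ms=spec.isi_ms,
                        meta={"p_deviant": spec.p_deviant, "seed": seed,
                              "min_gap": min_gap})


def gen_block_sequence(rates: list[float], block_len: int,
                       seed: int) -> ToneSequence:
    """Deviant sequence with block-switching deviant rates (for volatility tests)."""
    rng = np.random.default_rng(seed)
    parts = [(rng.random(block_len) < p).astype(np.int8) for p in rates]
    return ToneSequence(np.concatenate(parts),
                        meta={"rates": list(rates), "block_len": block_len})


def gen_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """One row per subject: id, group, age, sex, SIPS subscale totals.

    HC rows carry demographics only; CHR rows additionally carry SIPS
    totals drawn from the configured Gaussians and clipped at zero.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(spec.n_hc):
        rows.append({"subject": f"hc{i + 1:02d}", "group": "HC",
                     "age": rng.normal(*spec.age_hc),
                     "sex": "F" if rng.random() < 13 / 23 else "M"})
    for i in range(spec.n_chr):
        row = {"subject": f"chr{i + 1:02d}", "group": "CHR",
               "age": rng.normal(*spec.age_chr),
               "sex": "F" if rng.random() < 10 / 31 else "M"}
        for name in ("sips_positive", "sips_negative", "sips_disorganised",
                     "sips_general"):
            mean, sd = getattr(spec, name)
            row[name] = max(0.0, rng.normal(mean, sd))
        rows.append(row)
    return pd.DataFrame(rows)


def subject_scales(cohort: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    """Per-subject effect multipliers: 1 for HC, SIPS-linked for CHR.

    CHR scale = 1 + effect_link * (sips_positive - mean) / sd, using the
    population mean/sd from the spec so the link slope is exact.
    """
    mean, sd = spec.sips_positive
    scales = np.ones(len(cohort))
    chr_mask = (cohort["group"] == "CHR").to_numpy()
    if sd > 0:
        z = (cohort.loc[chr_mask, "sips_positive"].to_numpy() - mean) / sd
        scales[chr_mask] = 1.0 + spec.effect_link * z
    return scales


def _spatial_chol(channels: ChannelInfo, scale: float) -> np.ndarray:
    d = np.linalg.norm(channels.pos[:, None, :] - channels.pos[None, :, :],
                       axis=-1)
    cov = np.exp(-0.5 * (d / max(scale, 1e-9)) ** 2)
    cov += 1e-6 * np.eye(channels.n)
    return np.linalg.cholesky(cov)


def gen_subject_eeg(sequence: ToneSequence, trajectories: TrajectorySet,
                    effects: list[EffectSpec], noise: NoiseSpec,
                    subject_scale: float = 1.0, seed: int = 0,
                    paradigm: ParadigmSpec | None = None) -> EpochSet:
    """Simulate one subject's epoched EEG with planted regressor effects.

    amplitude(trial, channel, t) = drift + sum_effects[A * scale * z(reg)]
    + AR(1) spatially correlated noise (+ blink transients on/near EOG).
    Fully deterministic given ``seed``.
    """
    paradigm = paradigm or ParadigmSpec(n_trials=len(sequence))
    if len(trajectories) != len(sequence):
        raise AlignmentError(
            f"trajectories ({len(trajectories)}) not aligned with tone "
            f"sequence ({len(sequence)})")
    rng = np.random.default_rng(seed)
    ch = paradigm.channels
    times = paradigm.times
    n_tr, n_ch, n_s = len(sequence), ch.n, times.size

    # spatially correlated AR(1) noise, stationary sd = trial_sd
    white = rng.standard_normal((n_tr, n_s, n_ch)) @ _spatial_chol(
        ch, noise.spatial_scale).T
    white = np.swapaxes(white, 1, 2)  # (trials, channels, samples)
    innov_sd = np.sqrt(1.0 - noise.ar1 ** 2)
    data = noise.trial_sd * lfilter([innov_sd], [1.0, -noise.ar1], white, axis=2)

    # slow per-trial drift (common across channels)
    if noise.drift_sd > 0:
        offs = rng.normal(0.0, noise.drift_sd, n_tr)
        slope = rng.normal(0.0, noise.drift_sd, n_tr)
        ramp = (times - times[0]) / (times[-1] - times[0])
        data += (offs[:, None] + slope[:, None] * ramp[None, :])[:, None, :]

    # planted regressor-locked effects (boxcar in the window/channels)
    for eff in effects:
        x = trajectories.regressor(eff.regressor)
        sd = x.std()
        if sd == 0:
            raise ConfigurationError(
                f"regressor {eff.regressor!r} has zero variance; cannot plant")
        z = (x - x.mean()) / sd
        t_mask = (times >= eff.window[0]) & (times <= eff.window[1])
        if not t_mask.any():
            raise ConfigurationError(
                f"effect window {eff.window} outside epoch window")
        idx = [ch.index(c) for c in eff.channels]
        bump = eff.amplitude * subject_scale * z
        data[np.ix_(np.arange(n_tr), idx, np.flatnonzero(t_mask))] += \
            bump[:, None, None]

    # blink transients: Gaussian bump on VEOG with frontal leakage
    blink_trials: list[int] = []
    eog_idx = np.flatnonzero(ch.eog)
    if noise.blink_rate > 0 and eog_idx.size:
        hit = rng.random(n_tr) < noise.blink_rate
        centers = rng.uniform(times[0] + 50, times[-1] - 50, n_tr)
        width = 40.0  # ms
        for t in np.flatnonzero(hit):
            shape = np.exp(-0.5 * ((times - centers[t]) / width) ** 2)
            for j in eog_idx:
                data[t, j] += noise.blink_amplitude * shape
            for name, leak in _BLINK_LEAK.items():
                if name in ch.names:
                    data[t, ch.index(name)] += \
                        leak * noise.blink_amplitude * shape
            blink_trials.append(int(t))

    return EpochSet(data=data, times=times, srate=paradigm.srate,
                    tones=sequence.u.copy(), channels=ch.copy(),
                    meta={"blink_trials": ",".join(map(str, blink_trials)),
                          "n_blinks": len(blink_trials),
                          "subject_scale": subject_scale, "seed": seed})
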