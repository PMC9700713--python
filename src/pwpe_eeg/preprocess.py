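"""EEG preprocessing: bandpass, blink handling, epoching, artifact rejection.

Implements the fixed rule set of the emulated study: zero-phase 0.5-30 Hz
Butterworth filtering, rejection of trials overlapping blink excursions
on the vertical EOG, epoching to -100..400 ms with -100..0 ms baseline
correction, absolute 100 uV amplitude rejection, and flagging +
interpolation of channels artefactual in more than 20% of trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from ._exceptions import ConfigurationError, PwpeError
from .containers import ChannelInfo, EpochSet

__all__ = ["ContinuousRecording", "bandpass", "detect_blinks",
           "epoch_and_baseline", "reject_amplitude",
           "flag_and_interpolate_channels", "read_raw", "from_mne_raw",
           "preprocess_epochs"]


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG (uV) with stimulus events."""

    data: np.ndarray                  # (n_channels, n_samples)
    srate: float
    events: list[tuple[int, int]]     # (sample index, tone label)
    channels: ChannelInfo
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.srate <= 0:
            raise ConfigurationError("srate must be > 0")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise ConfigurationError(f"event sample {s} outside record")


def bandpass(rec: ContinuousRecording, low: float = 0.5, high: float = 30.0,
             order: int = 4) -> ContinuousRecording:
    """Zero-phase (forward-backward) Butterworth bandpass per channel."""
    nyq = rec.srate / 2.0
    if not 0.0 < low < high < nyq:
        raise ConfigurationError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz")
    sos = butter(order, [low, high], btype="bandpass", fs=rec.srate,
                 output="sos")
    out = sosfiltfilt(sos, rec.data, axis=1)
    return ContinuousRecording(out, rec.srate, list(rec.events),
                               rec.channels.copy(), dict(rec.meta))


def detect_blinks(rec: ContinuousRecording, eog_threshold: float = 250.0,
                  pad_ms: float = 100.0) -> list[tuple[int, int]]:
    """Supra-threshold excursions on the vertical EOG, padded and merged.

    Returns half-open sample intervals ``(start, stop)``.
    """
    eog_idx = np.flatnonzero(rec.channels.eog)
    if eog_idx.size == 0:
        raise ConfigurationError("no EOG-role channel in the recording")
    sig = np.abs(rec.data[eog_idx[0]])
    above = sig > eog_threshold
    if not above.any():
        return []
    pad = int(round(pad_ms / 1000.0 * rec.srate))
    edges = np.flatnonzero(np.diff(np.r_[0, above.view(np.int8), 0]))
    starts, stops = edges[::2], edges[1::2]
    intervals = []
    for a, b in zip(starts, stops):
        a, b = max(0, a - pad), min(sig.size, b + pad)
        if intervals and a <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
        else:
            intervals.append((int(a), int(b)))
    return intervals


def epoch_and_baseline(rec: ContinuousRecording,
                       window: tuple[float, float] = (-100.0, 400.0),
                       baseline: tuple[float, float] = (-100.0, 0.0),
                       blink_intervals: list[tuple[int, int]] | None = None,
                       ) -> EpochSet:
    """Cut epochs around events and subtract the pre-stimulus baseline mean.

    Trials overlapping a blink interval are marked rejected (reason
    'blink'); events too close to the record edge are dropped and
    counted in ``meta['n_dropped_edge']``.
    """
    if not (window[0] <= baseline[0] < baseline[1] <= window[1]):
        raise ConfigurationError("baseline must lie inside the epoch window")
    step = 1000.0 / rec.srate
    off_lo = int(round(window[0] / step))
    off_hi = int(round(window[1] / step))
    times = step * np.arange(off_lo, off_hi + 1)
    n_total = rec.data.shape[1]
    blink_intervals = blink_intervals or []

    epochs, tones, reasons = [], [], []
    n_edge = 0
    for sample, label in rec.events:
        a, b = sample + off_lo, sample + off_hi + 1
        if a < 0 or b > n_total:
            n_edge += 1
            continue
        epochs.append(rec.data[:, a:b])
        tones.append(label)
        blink = any(a < stop and start < b for start, stop in blink_intervals)
        reasons.append("blink" if blink else "none")
    if not epochs:
        raise PwpeError("no epochs could be cut from the recording")
    data = np.stack(epochs)
    base_mask = (times >= baseline[0]) & (times <= baseline[1])
    data -= data[:, :, base_mask].mean(axis=2, keepdims=True)
    reasons = np.asarray(reasons, dtype=object)
    return EpochSet(data=data, times=times, srate=rec.srate,
                    tones=np.asarray(tones), channels=rec.channels.copy(),
                    kept=reasons == "none", rejection_reason=reasons,
                    meta={"n_dropped_edge": n_edge,
                          "n_events": len(rec.events)})


def _artefact_matrix(epochs: EpochSet, threshold: float) -> np.ndarray:
    """(trial, channel) True where |amplitude| exceeds threshold anywhere."""
    return np.abs(epochs.data).max(axis=2) > threshold


def reject_amplitude(epochs: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Reject trials whose non-bad scalp channels exceed |threshold| uV.

    Blink-rejected trials stay blink-rejected. Per-channel artefact
    fractions (over non-blink trials) are stored for the channel rule.
    """
    out = epochs.copy()
    art = _artefact_matrix(out, threshold)
    scalp = out.channels.scalp & ~out.channels.bad
    candidate = out.rejection_reason != "blink"
    bad_trial = art[:, scalp].any(axis=1) & candidate
    out.rejection_reason = np.where(bad_trial, "amplitude",
                                    out.rejection_reason).astype(object)
    out.kept = out.rejection_reason == "none"
    denom = max(int(candidate.sum()), 1)
    out.meta = dict(out.meta)
    out.meta["amplitude_threshold"] = threshold
    out.meta["artefact_fraction"] = art[candidate].sum(axis=0) / denom
    return out


def flag_and_interpolate_channels(epochs: EpochSet,
                                  max_fraction: float = 0.20,
                                  threshold: float | None = None) -> EpochSet:
    """Flag channels artefactual in > max_fraction of trials; interpolate them.

    Flagged channels are replaced by inverse-distance-weighted averages
    of the good scalp channels and excluded from the trial-rejection
    rule, which is then re-applied (trials rejected only because of a
    now-bad channel are recovered).
    """
    if "artefact_fraction" not in epochs.meta:
        epochs = reject_amplitude(epochs, threshold or 100.0)
    frac = np.asarray(epochs.meta["artefact_fraction"], float)
    out = epochs.copy()
    newly_bad = (frac > max_fraction) & out.channels.scalp & ~out.channels.bad
    if not newly_bad.any():
        return out
    out.channels.bad = out.channels.bad | newly_bad
    good = out.channels.scalp & ~out.channels.bad
    if good.sum() < 4:
        raise PwpeError(
            f"only {int(good.sum())} good scalp channels remain (< 4)")
    pos = out.channels.pos
    for j in np.flatnonzero(newly_bad):
        d = np.linalg.norm(pos[good] - pos[j], axis=1)
        w = 1.0 / np.maximum(d, 1e-6) ** 2
        w /= w.sum()
        out.data[:, j, :] = np.einsum("g,tgs->ts", w, out.data[:, good, :])
    # re-run the amplitude rule without the flagged channels
    thr = float(out.meta.get("amplitude_threshold", threshold or 100.0))
    candidate = out.rejection_reason != "blink"
    out.rejection_reason = np.where(candidate, "none",
                                    out.rejection_reason).astype(object)
    out.kept = out.rejection_reason == "none"
    return reject_amplitude(out, thr)


def preprocess_epochs(epochs: EpochSet, amplitude_threshold: float = 100.0,
                      eog_threshold: float = 250.0,
                      max_channel_fraction: float = 0.20) -> EpochSet:
    """Epoch-level cleaning for already-epoched (e.g. synthetic) data.

    Trials whose EOG channel exceeds ``eog_threshold`` anywhere in the
    epoch are blink-rejected; then the amplitude and bad-channel rules
    are applied.
    """
    out = epochs.copy()
    eog_idx = np.flatnonzero(out.channels.eog)
    if eog_idx.size:
        blink = np.abs(out.data[:, eog_idx[0], :]).max(axis=1) > eog_threshold
        out.rejection_reason = np.where(blink, "blink",
                                        out.rejection_reason).astype(object)
        out.kept = out.rejection_reason == "none"
    out = reject_amplitude(out, amplitude_threshold)
    return flag_and_interpolate_channels(out, max_channel_fraction)


def rejection_log(epochs: EpochSet, path: str | Path | None = None
                  ) -> pd.DataFrame:
    df = pd.DataFrame({"trial": np.arange(epochs.n_trials),
                       "tone": epochs.tones, "kept": epochs.kept,
                       "reason": epochs.rejection_reason})
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


# -- readers for the study's continuous formats -------------------------

def from_mne_raw(raw, stim_labels: dict[int, int] | None = None,
                 eog_names: tuple[str, ...] = ("VEOG", "EOG", "vEOG"),
                 ) -> ContinuousRecording:
    """Wrap an mne Raw object (BrainVision/EDF/...) as a ContinuousRecording.

    Amplitudes are converted from volts to microvolts; events are taken
    from annotations when present. Channel 2D positions fall back to the
    standard 10-20 projection for recognised names.
    """
    import mne

    from .containers import _standard_1020_2d
    data = raw.get_data() * 1e6
    names = list(raw.ch_names)
    std = _standard_1020_2d()
    pos = np.array([std.get(n, (0.0, 0.0)) for n in names])
    role = np.asarray(["eog" if n in eog_names else "scalp" for n in names],
                      dtype=object)
    events = []
    try:
        ev, ev_id = mne.events_from_annotations(raw, verbose="error")
        label_of = stim_labels or {v: (1 if "dev" in k.lower() else 0)
                                   for k, v in ev_id.items()}
        events = [(int(s), int(label_of.get(code, 0))) for s, _, code in ev]
    except Exception:
        pass
    ch = ChannelInfo(names, pos, role, np.zeros(len(names), bool))
    return ContinuousRecording(data, float(raw.info["sfreq"]), events, ch)


def read_raw(path: str | Path, **kwargs) -> ContinuousRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) file into a ContinuousRecording."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ConfigurationError(f"unsupported raw format: {path.suffix}")
    return from_mne_raw(raw, **kwargs)
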