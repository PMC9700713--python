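"""Core data containers: tone sequences, channel montage, epoched EEG.

All amplitudes are in microvolts, times in milliseconds, electrode
positions in millimetres on a 2D azimuthal-equidistant scalp projection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError

#: 32-electrode actiCAP layout (modified International 10-20 system).
CAP_32 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 FC5 FC1 FC2 FC6 T7 C3 Cz C4 T8 TP9 CP5 CP1 "
    "CP2 CP6 TP10 P7 P3 Pz P4 P8 PO9 O1 Oz O2 PO10"
).split()

HEAD_RADIUS_MM = 90.0

REJECTION_REASONS = ("none", "blink", "amplitude")


@lru_cache(maxsize=1)
def _standard_1020_2d() -> dict[str, tuple[float, float]]:
    """2D positions (mm) for the standard 10-20 montage.

    3D electrode positions come from MNE's built-in template montage and
    are flattened with an azimuthal-equidistant projection about the
    vertex, scaled so the equatorial ring sits at ``HEAD_RADIUS_MM``.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    ch_pos = montage.get_positions()["ch_pos"]
    out = {}
    for name, xyz in ch_pos.items():
        x, y, z = xyz
        r = float(np.linalg.norm(xyz))
        if r == 0:
            out[name] = (0.0, 0.0)
            continue
        theta = float(np.arccos(np.clip(z / r, -1.0, 1.0)))  # angle from vertex
        rho = HEAD_RADIUS_MM * theta / (np.pi / 2.0)
        horiz = float(np.hypot(x, y))
        if horiz < 1e-12:
            out[name] = (0.0, 0.0)
        else:
            out[name] = (rho * x / horiz, rho * y / horiz)
    return out


@dataclass
class ChannelInfo:
    """Channel names, 2D scalp positions (mm) and roles.

    ``role`` is ``"scalp"`` or ``"eog"``; ``bad`` flags channels excluded
    from trial rejection and interpolated for sensor statistics.
    """

    names: list[str]
    pos: np.ndarray          # (n, 2) mm
    role: np.ndarray         # (n,) str
    bad: np.ndarray          # (n,) bool

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("channel names must be unique")
        self.pos = np.asarray(self.pos, dtype=float)
        self.role = np.asarray(self.role, dtype=object)
        self.bad = np.asarray(self.bad, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def scalp(self) -> np.ndarray:
        return np.asarray([r == "scalp" for r in self.role])

    @property
    def eog(self) -> np.ndarray:
        return np.asarray([r == "eog" for r in self.role])

    def index(self, name: str) -> int:
        return self.names.index(name)

    def copy(self) -> "ChannelInfo":
        return ChannelInfo(list(self.names), self.pos.copy(),
                           self.role.copy(), self.bad.copy())


def make_cap32(include_eog: bool = True) -> ChannelInfo:
    """Channel info for the 32-electrode cap, plus a vertical EOG channel."""
    pos2d = _standard_1020_2d()
    names = list(CAP_32)
    pos = [pos2d[n] for n in names]
    role = ["scalp"] * len(names)
    if include_eog:
        names.append("VEOG")
        pos.append((25.0, 100.0))  # above the right eye, outside the cap hull
        role.append("eog")
    return ChannelInfo(names, np.asarray(pos, float), np.asarray(role, object),
                       np.zeros(len(names), bool))


@dataclass
class ToneSequence:
    """Binary oddball input: 0 = standard (50 ms), 1 = deviant (100 ms)."""

    u: np.ndarray
    isi_ms: float = 500.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.int8)
        if self.u.ndim != 1:
            raise ConfigurationError("tone sequence must be 1-D")
        if not np.isin(self.u, (0, 1)).all():
            raise ConfigurationError("tones must be binary (0/1)")

    def __len__(self) -> int:
        return self.u.size

    @property
    def deviant_fraction(self) -> float:
        return float(self.u.mean())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"trial": np.arange(len(self)), "u": self.u}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, isi_ms: float = 500.0) -> "ToneSequence":
        df = pd.read_csv(path, sep="\t")
        return cls(df["u"].to_numpy(), isi_ms=isi_ms)


@dataclass
class EpochSet:
    """Trials x channels x samples EEG with rejection bookkeeping."""

    data: np.ndarray                # (n_trials, n_channels, n_samples) uV
    times: np.ndarray               # (n_samples,) ms relative to onset
    srate: float
    tones: np.ndarray               # (n_trials,) 0/1
    channels: ChannelInfo
    kept: np.ndarray = None         # (n_trials,) bool
    rejection_reason: np.ndarray = None  # (n_trials,) str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.tones = np.asarray(self.tones, dtype=np.int8)
        n = self.data.shape[0]
        if self.kept is None:
            self.kept = np.ones(n, bool)
        if self.rejection_reason is None:
            self.rejection_reason = np.asarray(["none"] * n, dtype=object)
        self.kept = np.asarray(self.kept, bool)
        self.rejection_reason = np.asarray(self.rejection_reason, dtype=object)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), self.srate,
                        self.tones.copy(), self.channels.copy(),
                        self.kept.copy(), self.rejection_reason.copy(),
                        dict(self.meta))

    def rejection_counts(self) -> dict[str, int]:
        out = {r: 0 for r in REJECTION_REASONS}
        for r in self.rejection_reason:
            out[r] = out.get(r, 0) + 1
        return out

    # -- HDF5 round trip (track_times disabled for byte-stable files) ----
    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            for key, arr in (("data", self.data), ("times", self.times),
                             ("tones", self.tones), ("kept", self.kept),
                             ("pos", self.channels.pos),
                             ("bad", self.channels.bad)):
                f.create_dataset(key, data=arr, track_times=False)
            str_dt = h5py.string_dtype()
            f.create_dataset("reason", data=self.rejection_reason.astype("S"),
                             track_times=False)
            f.create_dataset("names", dtype=str_dt, track_times=False,
                             data=[str(n) for n in self.channels.names])
            f.create_dataset("role", dtype=str_dt, track_times=False,
                             data=[str(r) for r in self.channels.role])
            f.attrs["srate"] = self.srate
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str)):
                    f.attrs[f"meta_{k}"] = v

    @classmethod
    def load_h5(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            names = [n.decode() if isinstance(n, bytes) else n
                     for n in f["names"][()]]
            role = np.asarray([r.decode() if isinstance(r, bytes) else r
                               for r in f["role"][()]], dtype=object)
            ch = ChannelInfo(names, f["pos"][()], role, f["bad"][()])
            reason = np.asarray([r.decode() for r in f["reason"][()]],
                                dtype=object)
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
            return cls(f["data"][()], f["times"][()], float(f.attrs["srate"]),
                       f["tones"][()], ch, f["kept"][()], reason, meta)
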