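"""Multi-channel fluorescence trace container and text/TIFF IO.

A :class:`Trace` holds uniformly sampled fluorescence channels from a
line-scan recording (ROI-averaged, one value per line) together with the
sampling interval and the role of each channel (ATP sensor, Ca indicator,
or an ATP-insensitive reference used for ratiometric correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

VALID_ROLES = frozenset({"sensor", "reference", "calcium"})

# canonical channel names whose role is inferred when none is given
DEFAULT_ROLE_NAMES = {
    "atp": "sensor", "sensor": "sensor",
    "ca": "calcium", "calcium": "calcium",
    "ref": "reference", "reference": "reference",
}


@dataclass
class Trace:
    """Uniformly sampled multi-channel fluorescence time series.

    Parameters
    ----------
    values : ndarray, shape (n_channels, n_samples)
        Fluorescence in arbitrary units (or F/F0 after normalization).
    dt_ms : float
        Sampling interval in milliseconds.
    channels : tuple of str
        Channel names, one per row of ``values``.
    roles : dict
        Maps channel name to one of ``{"sensor", "reference", "calcium"}``.
    extent_um : float, optional
        Spatial extent of the scanned line covered by the ROI, in µm.
    """

    values: np.ndarray
    dt_ms: float
    channels: tuple
    roles: dict = field(default_factory=dict)
    extent_um: float | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        self.channels = tuple(self.channels)
        if self.values.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[0]} channel rows but "
                f"{len(self.channels)} channel names"
            )
        for name, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"unknown role {role!r} for channel {name!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms / 1000.0

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def by_role(self, role: str) -> np.ndarray:
        for name, r in self.roles.items():
            if r == role:
                return self.channel(name)
        raise KeyError(f"no channel with role {role!r}")

    def has_role(self, role: str) -> bool:
        return role in self.roles.values()

    # ------------------------------------------------------------------ IO
    def to_csv(self, path) -> None:
        """Write the trace as tidy CSV with columns time_s, channel, value."""
        frames = []
        t = self.time_s
        for i, name in enumerate(self.channels):
            frames.append(
                pd.DataFrame(
                    {"time_s": t, "channel": name, "value": self.values[i]}
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dt_ms: float | None = None, roles=None) -> "Trace":
        df = pd.read_csv(path)
        names = list(dict.fromkeys(df["channel"]))
        rows, n = [], None
        for name in names:
            sub = df[df["channel"] == name].sort_values("time_s")
            if n is None:
                n = len(sub)
                if dt_ms is None:
                    ts = sub["time_s"].to_numpy()
                    if len(ts) < 2:
                        raise ValueError("cannot infer dt from a single sample")
                    dt_ms = float(np.median(np.diff(ts)) * 1000.0)
            elif len(sub) != n:
                raise ValueError("channels have unequal lengths")
            rows.append(sub["value"].to_numpy())
        if roles is None:
            roles = {n: DEFAULT_ROLE_NAMES[n.lower()]
                     for n in names if n.lower() in DEFAULT_ROLE_NAMES}
        return cls(np.vstack(rows), dt_ms, tuple(names), roles)

    def to_tiff(self, directory, prefix: str = "trace") -> list:
        """Write one single-page 32-bit TIFF per channel (1 x T raster)."""
        from pathlib import Path

        paths = []
        for i, name in enumerate(self.channels):
            p = Path(directory) / f"{prefix}_{name}.tif"
            tifffile.imwrite(p, self.values[i][None, :].astype(np.float32))
            paths.append(p)
        return paths

    @classmethod
    def from_tiff(cls, paths, channels, dt_ms: float, roles=None) -> "Trace":
        rows = [np.asarray(tifffile.imread(p), dtype=float).ravel() for p in paths]
        return cls(np.vstack(rows), dt_ms, tuple(channels), roles or {})
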