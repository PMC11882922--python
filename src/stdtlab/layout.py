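"""64-channel extended 10-20 layout with 2-D scalp projection.

Channel names and idealized 3-D positions come from the standard biosemi-64
montage; 2-D coordinates are an azimuthal-equidistant projection of the
positions onto the unit disk (vertex at the origin, radius proportional to
the polar angle from the vertex, normalized so the outermost electrode sits
at radius 1). vEOG/hEOG are carried as extra non-scalp channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["ChannelLayout", "biosemi64_layout"]


@dataclass(frozen=True)
class ChannelLayout:
    names: tuple[str, ...]
    pos2d: np.ndarray  # (n_scalp, 2), unit-disk coordinates
    eog_names: tuple[str, ...] = ("vEOG", "hEOG")

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if self.pos2d.shape != (len(self.names), 2):
            raise ValueError("pos2d must be (n_scalp, 2)")

    @property
    def n_scalp(self) -> int:
        return len(self.names)

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.names + self.eog_names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def distances_to(self, name: str) -> np.ndarray:
        """Euclidean 2-D layout distance of every scalp channel to ``name``."""
        ref = self.pos2d[self.index(name)]
        return np.linalg.norm(self.pos2d - ref, axis=1)


@lru_cache(maxsize=1)
def biosemi64_layout() -> ChannelLayout:
    """Build the default 64-channel layout (cached; montage load is not free)."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    names = tuple(montage.ch_names)
    xyz = np.array([pos[n] for n in names])
    xyz = xyz - xyz.mean(axis=0) * np.array([1.0, 1.0, 0.0])  # recentre in the axial plane
    r = np.linalg.norm(xyz, axis=1)
    theta = np.arccos(np.clip(xyz[:, 2] / r, -1, 1))  # polar angle from vertex
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    rad = theta / theta.max()
    pos2d = np.column_stack([rad * np.cos(phi), rad * np.sin(phi)])
    # rotate so +y is anterior (mne: +x right, +y anterior already) — keep as is
    layout = ChannelLayout(names=names, pos2d=pos2d)
    required = {"CP4", "C6", "FC2", "FC1", "FCz", "Cz", "C2", "CPz"}
    missing = required - set(names)
    if missing:  # pragma: no cover - guards against montage changes
        raise RuntimeError(f"montage lacks required channels: {missing}")
    return layout
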