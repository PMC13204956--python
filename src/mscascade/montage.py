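"""The 19-channel international 10–20 montage used throughout the package.

Positions are 2D projections of the scalp (x: left < 0 < right, y:
posterior < 0 < anterior) on the unit circle, sufficient for building
dipolar microstate prototypes and for topographic plotting.  They are
bundled as a plain-text table so the montage is inspectable and
replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["Montage", "standard_1020_19"]


@dataclass(frozen=True)
class Montage:
    """Ordered electrode names with 2D projected positions."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), columns x, y

    def __post_init__(self) -> None:
        if len(self.names) != self.positions.shape[0]:
            raise ValueError("names and positions disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names: list[str]) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(tuple(names), self.positions[idx])


def standard_1020_19() -> Montage:
    """Load the bundled 19-channel 10–20 montage table."""
    ref = resources.files("mscascade.data").joinpath("montage_1020_19.tsv")
    names: list[str] = []
    xy: list[list[float]] = []
    with ref.open("r") as fh:
        header = fh.readline().split()
        assert header == ["name", "x", "y"]
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            names.append(parts[0])
            xy.append([float(parts[1]), float(parts[2])])
    return Montage(tuple(names), np.asarray(xy, dtype=float))
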