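"""Electrode layouts and montage (channel-set) definitions.

The package ships a 64-channel 10/20 layout with electrode positions on the
unit sphere (head radius normalized to 1), which is the geometry the
spherical-spline surface Laplacian operates on.  Users can supply their own
layout as a whitespace-delimited text file of ``label x y z`` rows.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "MontageSpec",
    "MONTAGES",
    "montage_spec",
    "read_layout",
    "default_layout",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class ElectrodeLayout:
    """Channel labels with unit-sphere positions.

    Parameters
    ----------
    labels : list of str
        Unique 10/20-style channel names.
    positions : (n_channels, 3) ndarray
        Cartesian positions with unit norm (x: right, y: anterior,
        z: superior).
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(labels), 3):
            raise ValueError(
                f"positions must be ({len(labels)}, 3), got {pos.shape}"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-5):
            raise ValueError("electrode positions must lie on the unit sphere")
        # snap to exact unit norm (tolerance for file round-trips)
        pos = pos / norms[:, None]
        if np.any(np.abs(np.linalg.norm(pos, axis=1) - 1.0) > _UNIT_TOL):
            raise ValueError("could not normalize electrode positions")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, labels) -> np.ndarray:
        """Row indices of the given labels, in the given order."""
        lut = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in lut]
        if missing:
            raise KeyError(f"channels not in layout: {missing}")
        return np.array([lut[l] for l in labels], dtype=int)

    def subset(self, labels) -> "ElectrodeLayout":
        idx = self.index(labels)
        return ElectrodeLayout(tuple(labels), self.positions[idx])


@dataclass(frozen=True)
class MontageSpec:
    """A named channel subset used for the channel-count experiments."""

    name: str
    members: tuple[str, ...]


#: The nine-channel motor set the channel-reduction analysis singles out.
SET9 = ("C3", "C4", "Cz", "F3", "F4", "P3", "P4", "T7", "T8")

#: Sensorimotor grid around C3/C4 (three fronto-central/central/centro-parietal
#: rows, midline excluded), 18 channels.
SET18 = (
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CP2", "CP4", "CP6",
)

SET12 = ("F3", "Fz", "F4", "FC3", "FC4", "C3", "Cz", "C4", "CP3", "CP4", "P3", "P4")

SET6 = ("FC3", "FC4", "C3", "C4", "CP3", "CP4")

#: C3 plus its four-electrode neighbourhood: the minimal set from which a
#: single Laplacian-referenced C3 channel can be derived.
LAPLACIAN_C3 = ("C3", "FC3", "C5", "C1", "CP3")

MONTAGES: dict[str, tuple[str, ...] | None] = {
    "all64": None,  # resolved against the layout at hand
    "set18": SET18,
    "set12": SET12,
    "set9": SET9,
    "set6": SET6,
    "laplacianC3": LAPLACIAN_C3,
}


def montage_spec(name: str, layout: ElectrodeLayout | None = None) -> MontageSpec:
    """Resolve a montage name to its member channels.

    ``all64`` keeps every channel of *layout* (required for that name only).
    """
    if name not in MONTAGES:
        raise ValueError(
            f"unknown montage {name!r}; valid names: {sorted(MONTAGES)}"
        )
    members = MONTAGES[name]
    if members is None:
        if layout is None:
            raise ValueError("montage 'all64' needs a layout to enumerate channels")
        members = tuple(layout.labels)
    return MontageSpec(name, tuple(members))


def read_layout(path) -> ElectrodeLayout:
    """Read a whitespace-delimited ``label x y z`` layout file."""
    labels: list[str] = []
    rows: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed layout line: {raw!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if not labels:
        raise ValueError(f"no electrodes found in layout file {path}")
    return ElectrodeLayout(tuple(labels), np.array(rows))


def default_layout() -> ElectrodeLayout:
    """The packaged 64-channel 10/20 layout (unit-sphere positions)."""
    ref = importlib.resources.files("erdmonitor.data") / "layout_1020_64.txt"
    with importlib.resources.as_file(ref) as path:
        return read_layout(path)
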