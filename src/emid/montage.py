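"""Topology-preserving 2D electrode arrangement.

EEG caps place electrodes on a roughly regular lattice over the scalp.  To
let convolutional models exploit the spatial neighbourhood structure of the
channels, each time sample is re-arranged into a sparse 10x9 matrix whose
cells correspond to scalp positions; cells without an electrode are held at
exactly zero.  The packaged default grid covers the 61 frontal/central/
parietal/temporal electrodes of the high-density motor-execution cap used
throughout this package (10-10-style labels such as ``FCC1`` or ``CCP3``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Montage",
    "MontageError",
    "build_montage",
    "default_placement",
    "frame_samples",
    "load_montage",
]

GRID_ROWS = 10
GRID_COLS = 9


class MontageError(ValueError):
    """Raised for unknown, duplicate or missing channel labels."""


def _normalize(label: str) -> str:
    return label.strip().lower()


def default_placement() -> dict[str, tuple[int, int]]:
    """Return the packaged 61-electrode grid placement (label -> (row, col))."""
    text = resources.files("emid.data").joinpath("standard_grid.json").read_text()
    doc = json.loads(text)
    return {lab: (int(r), int(c)) for lab, (r, c) in doc["placement"].items()}


@dataclass(frozen=True)
class Montage:
    """Assignment of channel labels to cells of a ``grid_rows`` x ``grid_cols`` grid.

    ``placement`` maps each label to a 0-based (row, col); row 0 is the most
    anterior (frontal) row, column 0 the leftmost.  Rows/cols occupied by no
    label stay at zero in every frame the montage produces.
    """

    placement: Mapping[str, tuple[int, int]]
    grid_rows: int = GRID_ROWS
    grid_cols: int = GRID_COLS
    _index: dict[str, tuple[int, int]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen_cells: set[tuple[int, int]] = set()
        index: dict[str, tuple[int, int]] = {}
        for label, (row, col) in self.placement.items():
            if not (0 <= row < self.grid_rows and 0 <= col < self.grid_cols):
                raise MontageError(f"cell {(row, col)} for {label!r} outside grid")
            if (row, col) in seen_cells:
                raise MontageError(f"cell {(row, col)} assigned twice")
            key = _normalize(label)
            if key in index:
                raise MontageError(f"duplicate channel label {label!r}")
            seen_cells.add((row, col))
            index[key] = (int(row), int(col))
        object.__setattr__(self, "_index", index)

    @property
    def labels(self) -> list[str]:
        return list(self.placement)

    @property
    def n_placed(self) -> int:
        return len(self.placement)

    @property
    def n_empty(self) -> int:
        return self.grid_rows * self.grid_cols - self.n_placed

    def cell(self, label: str) -> tuple[int, int]:
        try:
            return self._index[_normalize(label)]
        except KeyError:
            raise MontageError(f"unknown channel label {label!r}") from None

    def mask(self) -> np.ndarray:
        """Boolean grid, True at placed cells."""
        m = np.zeros((self.grid_rows, self.grid_cols), dtype=bool)
        for row, col in self.placement.values():
            m[row, col] = True
        return m

    def coordinates(self, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) index arrays for ``labels``, in the given order."""
        cells = [self.cell(lab) for lab in labels]
        rows = np.array([r for r, _ in cells], dtype=np.intp)
        cols = np.array([c for _, c in cells], dtype=np.intp)
        return rows, cols

    def frames(self, signal: np.ndarray, labels: Sequence[str]) -> np.ndarray:
        """Tensorize a (channels, samples) signal into (samples, rows, cols).

        ``labels`` gives the channel order of ``signal`` and must cover the
        montage's labels exactly (case-insensitive).  Unplaced cells are 0.
        """
        signal = np.asarray(signal)
        if signal.ndim != 2 or signal.shape[0] != len(labels):
            raise MontageError(
                f"signal shape {signal.shape} does not match {len(labels)} labels"
            )
        keys = {_normalize(lab) for lab in labels}
        missing = set(self._index) - keys
        extra = keys - set(self._index)
        if missing or extra:
            raise MontageError(
                f"channel set mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
            )
        rows, cols = self.coordinates(labels)
        out = np.zeros((signal.shape[1], self.grid_rows, self.grid_cols), signal.dtype)
        out[:, rows, cols] = signal.T
        return out

    def to_json(self, path: str | Path) -> None:
        doc = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "placement": {lab: list(cell) for lab, cell in self.placement.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def load_montage(path: str | Path) -> Montage:
    """Load a montage from a JSON mapping file (editable alternative caps)."""
    doc = json.loads(Path(path).read_text())
    placement = {lab: (int(r), int(c)) for lab, (r, c) in doc["placement"].items()}
    return Montage(placement, int(doc["grid_rows"]), int(doc["grid_cols"]))


def build_montage(channel_labels: Iterable[str]) -> Montage:
    """Build the default-grid montage restricted to ``channel_labels``.

    Every label must occupy a cell of the packaged grid; recordings whose
    channel names cannot be mapped (e.g. missing-name headers) are rejected
    rather than guessed at.
    """
    labels = list(channel_labels)
    if not labels:
        raise MontageError("channel label list is empty")
    canonical = {_normalize(lab): (lab, cell) for lab, cell in default_placement().items()}
    placement: dict[str, tuple[int, int]] = {}
    seen: set[str] = set()
    for label in labels:
        key = _normalize(label)
        if key in seen:
            raise MontageError(f"duplicate channel label {label!r}")
        seen.add(key)
        if key not in canonical:
            raise MontageError(f"unknown channel label {label!r}: no cell in the standard grid")
        name, cell = canonical[key]
        placement[name] = cell
    return Montage(placement)


def frame_samples(sample_per_channel: Mapping[str, float], montage: Montage) -> np.ndarray:
    """Arrange one multichannel sample into its 2D grid frame.

    The sample map must cover exactly the montage's channels; all unplaced
    cells of the returned (rows, cols) matrix are exactly 0.
    """
    labels = list(sample_per_channel)
    values = np.array([sample_per_channel[lab] for lab in labels], dtype=float)
    return montage.frames(values[:, None], labels)[0]
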