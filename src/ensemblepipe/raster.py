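"""Binary raster plots: the core data container and its file formats.

A raster plot ``R`` is a binary matrix of shape ``[N neurons x F frames]``.
Row ``i`` is the activity vector of neuron ``i`` (when was it active);
column ``t`` is the population vector at frame ``t`` (who was active).
The acquisition frame rate (frames per second) travels with the matrix as
metadata because every time-based quantity downstream (firing rates,
recurrence times) needs it.

Two plain-text formats are supported:

* ``matrix`` -- one row per neuron, 0/1 cells separated by whitespace or
  commas (auto-detected).
* ``events`` -- a header ``#N=<int> #F=<int> #fps=<float>`` followed by
  ``neuron<TAB>frame`` records, 0-based. Duplicate records collapse.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = ["Raster", "RasterFormatError", "load_raster", "save_raster", "subraster"]


class RasterFormatError(ValueError):
    """Raised when a raster file violates the binary-matrix contract."""


@dataclass(frozen=True)
class Raster:
    """A validated binary activity raster with acquisition metadata.

    Parameters
    ----------
    matrix:
        ``(n_neurons, n_frames)`` array of 0/1 values (stored as ``uint8``).
    fps:
        Acquisition rate in frames per second; must be positive.
    neuron_ids:
        Optional stable labels, one per neuron. Defaults to ``0..N-1``.
    """

    matrix: np.ndarray
    fps: float
    neuron_ids: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        if mat.ndim != 2 or mat.shape[0] < 1 or mat.shape[1] < 1:
            raise RasterFormatError(
                f"raster matrix must be 2-D with N>=1, F>=1; got shape {mat.shape}"
            )
        bad = ~np.isin(mat, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise RasterFormatError(
                f"non-binary value {mat[i, j]!r} at neuron {i}, frame {j}"
            )
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise ValueError(f"fps must be a positive real, got {self.fps}")
        object.__setattr__(self, "matrix", mat.astype(np.uint8))
        ids = self.neuron_ids
        if ids is None:
            ids = tuple(range(mat.shape[0]))
        else:
            ids = tuple(ids)
            if len(ids) != mat.shape[0]:
                raise ValueError(
                    f"{len(ids)} neuron_ids for {mat.shape[0]} neurons"
                )
        object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_neurons(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps

    @property
    def n_events(self) -> int:
        """Total number of active (neuron, frame) entries."""
        return int(self.matrix.sum())

    def activity_vector(self, neuron: int) -> np.ndarray:
        """Row ``neuron`` of the raster (the neuron's activity over time)."""
        return self.matrix[neuron]

    def population_vector(self, frame: int) -> np.ndarray:
        """Column ``frame`` of the raster (who was active at that frame)."""
        return self.matrix[:, frame]

    def events(self) -> np.ndarray:
        """``(n_events, 2)`` array of (neuron, frame) active entries."""
        return np.argwhere(self.matrix == 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Raster):
            return NotImplemented
        return (
            self.fps == other.fps
            and self.neuron_ids == other.neuron_ids
            and np.array_equal(self.matrix, other.matrix)
        )


def _parse_matrix_text(text: str) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.replace(",", " ").split()
        row = []
        for col, cell in enumerate(cells):
            if cell == "0":
                row.append(0)
            elif cell == "1":
                row.append(1)
            else:
                raise RasterFormatError(
                    f"non-binary cell {cell!r} at line {lineno}, column {col}"
                )
        rows.append(row)
    if not rows:
        raise RasterFormatError("empty raster file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise RasterFormatError(f"ragged rows: widths {sorted(widths)}")
    return np.array(rows, dtype=np.uint8)


def _parse_events_text(text: str) -> tuple[np.ndarray, Optional[float]]:
    n = f = None
    fps = None
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line.replace("#", " ").replace(",", " ").split():
                if "=" in token:
                    key, _, val = token.partition("=")
                    key = key.strip().upper()
                    if key == "N":
                        n = int(val)
                    elif key == "F":
                        f = int(val)
                    elif key == "FPS":
                        fps = float(val)
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise RasterFormatError(
                f"expected 'neuron<TAB>frame' at line {lineno}, got {line!r}"
            )
        records.append((int(parts[0]), int(parts[1])))
    if n is None or f is None:
        raise RasterFormatError("events file missing '#N=<int> #F=<int>' header")
    mat = np.zeros((n, f), dtype=np.uint8)
    for neuron, frame in records:
        if not (0 <= neuron < n and 0 <= frame < f):
            raise RasterFormatError(
                f"event ({neuron}, {frame}) out of declared bounds N={n}, F={f}"
            )
        mat[neuron, frame] = 1  # duplicates collapse
    return mat, fps


def load_raster(
    path: Union[str, os.PathLike],
    format: str = "matrix",
    fps: Optional[float] = None,
) -> Raster:
    """Load a binary raster from a delimited-matrix or events file.

    ``fps`` is required for matrix files (the matrix carries no rate); for
    events files it overrides the header value when given.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise RasterFormatError(f"empty file: {path}")
    if format == "matrix":
        if fps is None:
            raise ValueError("fps is required when loading a matrix file")
        return Raster(_parse_matrix_text(text), fps=fps)
    if format == "events":
        mat, header_fps = _parse_events_text(text)
        fps = fps if fps is not None else header_fps
        if fps is None:
            raise ValueError("fps missing from both header and arguments")
        return Raster(mat, fps=fps)
    raise ValueError(f"unknown raster format {format!r}")


def save_raster(raster: Raster, path: Union[str, os.PathLike], format: str = "matrix") -> None:
    """Write ``raster`` so that :func:`load_raster` reproduces it bit-exactly."""
    if format == "matrix":
        buf = io.StringIO()
        for row in raster.matrix:
            buf.write(" ".join("1" if v else "0" for v in row))
            buf.write("\n")
        payload = buf.getvalue()
    elif format == "events":
        lines = [f"#N={raster.n_neurons} #F={raster.n_frames} #fps={raster.fps!r}"]
        for neuron, frame in raster.events():
            lines.append(f"{neuron}\t{frame}")
        payload = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown raster format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(payload)


def subraster(raster: Raster, neuron_subset: Sequence[int]) -> Raster:
    """Restrict the raster to a subset of neurons, preserving order and fps.

    The frame axis is untouched: a subraster is the set of activity vectors
    of one neuronal ensemble, still aligned to the original recording.
    """
    idx = list(neuron_subset)
    if len(idx) == 0:
        raise ValueError("neuron_subset must be non-empty")
    for i in idx:
        if not (0 <= int(i) < raster.n_neurons):
            raise IndexError(
                f"neuron index {i} out of range for {raster.n_neurons} neurons"
            )
    idx = np.asarray(idx, dtype=int)
    return Raster(
        raster.matrix[idx],
        fps=raster.fps,
        neuron_ids=tuple(raster.neuron_ids[i] for i in idx),
    )
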