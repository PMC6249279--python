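"""Point-set container shared by all metrics and simulators.

A localization nanoscopy image is a set of points in ``R^n`` (n = 2 for
lateral imaging, 3 with an axial or time coordinate, 4 with both), with
coordinates in nanometres.  Points need not be distinct: frame-by-frame
localization produces many estimates per emitter, and repeats are legal
inputs to every metric in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["PointSet"]


@dataclass(frozen=True)
class PointSet:
    """Ordered collection of n-dimensional points (nm).

    Parameters
    ----------
    coords : ndarray, shape (n_points, dim)
        One point per row.  Any array-like accepted; stored as float64.
    labels : sequence, optional
        Per-point identifiers (e.g. frame numbers).  Carried through
        subsetting, never used by the metrics themselves.
    """

    coords: np.ndarray
    labels: tuple | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim == 1:  # a single point, or a 1D point list
            arr = arr.reshape(-1, 1)
        if arr.ndim != 2:
            raise ValueError(f"coords must be 2D (n_points, dim); got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("coords contain non-finite values")
        object.__setattr__(self, "coords", arr)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != arr.shape[0]:
                raise ValueError(
                    f"{len(labels)} labels for {arr.shape[0]} points"
                )
            object.__setattr__(self, "labels", labels)

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.coords[i]

    def __iter__(self) -> Iterable[np.ndarray]:
        return iter(self.coords)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    # -- helpers -------------------------------------------------------
    @classmethod
    def from_points(cls, points: Sequence[Sequence[float]], labels=None) -> "PointSet":
        return cls(np.asarray(points, dtype=float), labels)

    def subset(self, idx) -> "PointSet":
        """New PointSet keeping the rows in ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        labels = tuple(self.labels[i] for i in idx) if self.labels is not None else None
        return PointSet(self.coords[idx], labels)

    def remove(self, idx) -> "PointSet":
        """New PointSet with the rows in ``idx`` dropped."""
        keep = np.setdiff1d(np.arange(len(self)), np.asarray(idx, dtype=int))
        return self.subset(keep)


def _check_pair(a: PointSet, b: PointSet) -> None:
    """Shared precondition for two-set operations."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")
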