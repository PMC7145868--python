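"""Periodic-boundary geometry for orthorhombic boxes.

All lengths in nm. Only rectangular boxes are supported; analyses in this
package are defined on flat membrane patches, for which the minimum-image
convention reduces to per-axis wrapping.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .frames import Frame, Selection

__all__ = [
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_positions",
    "center_of_mass",
    "unwrap_group",
]


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3,):
        raise ValueError("box must be a 3-vector of orthorhombic edge lengths")
    if not np.all(box > 0):
        raise ValueError(f"box edges must be positive, got {box}")
    return box


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Minimum-image displacement ``b - a`` under an orthorhombic box.

    Accepts single vectors or broadcastable arrays of shape ``(..., 3)``.
    """
    box = _check_box(np.asarray(box))
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: Sequence[float]) -> float | np.ndarray:
    """Euclidean distance between ``a`` and ``b`` under minimum image (nm)."""
    d = minimum_image_displacement(a, b, box)
    out = np.sqrt(np.sum(d * d, axis=-1))
    return float(out) if out.ndim == 0 else out


def wrap_positions(positions: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Wrap coordinates into the primary cell ``[0, box)`` per axis."""
    box = _check_box(np.asarray(box))
    return np.mod(positions, box)


def center_of_mass(
    frame: Frame,
    sel: Selection,
    masses: Mapping[str, float] | np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted mean position of a selection (nm).

    With ``masses=None`` all particles get unit mass (the CG-bead default),
    so the result is the geometric centroid. ``masses`` may be a mapping
    from particle name to mass or an explicit per-member array in selection
    order. The group is assumed whole (unwrapped); callers crossing the
    periodic boundary must unwrap first (see :func:`unwrap_group`).
    """
    rows = sel.rows(frame)
    pos = frame.positions[rows]
    if masses is None:
        w = np.ones(len(rows))
    elif isinstance(masses, Mapping):
        w = np.array([masses.get(str(frame.names[r]), 1.0) for r in rows], dtype=float)
    else:
        w = np.asarray(masses, dtype=float)
        if w.shape != (len(rows),):
            raise ValueError(f"masses has shape {w.shape}, expected ({len(rows)},)")
    total = w.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    return (pos * w[:, None]).sum(axis=0) / total


def unwrap_group(positions: np.ndarray, box: Sequence[float]) -> np.ndarray:
    """Make a particle group whole across periodic boundaries.

    Every particle is shifted by integer box vectors so it lies within half
    a box of the first particle. Valid for groups smaller than half the box
    in every direction (true for any single protein or lipid here).
    """
    box = _check_box(np.asarray(box))
    ref = positions[0]
    return ref + minimum_image_displacement(ref, positions, box)
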