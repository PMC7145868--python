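"""Core domain types: particles, frames, selections and lipid topology.

A :class:`Frame` stores one snapshot of a coarse-grained (or atomistic)
system as structure-of-arrays: per-particle identifiers plus an ``(N, 3)``
position array in nanometres and an orthorhombic box. Trajectories are plain
sequences of frames with a stable particle order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence

import numpy as np

__all__ = [
    "Particle",
    "Frame",
    "Selection",
    "LipidTopologyMap",
    "parse_selection_expr",
]


@dataclass(frozen=True)
class Particle:
    """A single labeled particle (CG bead or atom). Positions in nm."""

    index: int
    name: str
    residue_name: str
    residue_id: int
    chain_or_molecule_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"particle {self.index}: non-finite position {pos}")
        object.__setattr__(self, "position", pos)


class Frame:
    """One snapshot: labeled particles, orthorhombic box (nm) and time (ps).

    Parameters
    ----------
    indices, names, residue_names, residue_ids, chains
        Per-particle identifier arrays, all of length ``N``. Indices must be
        unique within the frame (1-based ids as in GRO files).
    positions
        ``(N, 3)`` array of coordinates in nm.
    box
        Orthorhombic box edge lengths ``(lx, ly, lz)`` in nm, all > 0.
    time
        Frame time in ps.
    """

    __slots__ = ("indices", "names", "residue_names", "residue_ids", "chains",
                 "positions", "box", "time", "_row_of")

    def __init__(
        self,
        indices: Sequence[int],
        names: Sequence[str],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        chains: Sequence[str],
        positions: np.ndarray,
        box: Sequence[float],
        time: float = 0.0,
    ) -> None:
        self.indices = np.asarray(indices, dtype=np.int64)
        self.names = np.asarray(names, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=np.int64)
        self.chains = np.asarray(chains, dtype=object)
        self.positions = np.asarray(positions, dtype=float)
        self.box = np.asarray(box, dtype=float)
        self.time = float(time)
        n = len(self.indices)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match {n} particles"
            )
        for arr, label in ((self.names, "names"), (self.residue_names, "residue_names"),
                           (self.residue_ids, "residue_ids"), (self.chains, "chains")):
            if len(arr) != n:
                raise ValueError(f"{label} has length {len(arr)}, expected {n}")
        if not np.all(np.isfinite(self.positions)):
            bad = int(np.where(~np.isfinite(self.positions).all(axis=1))[0][0])
            raise ValueError(f"particle row {bad}: non-finite position")
        if self.box.shape != (3,):
            raise ValueError("box must be a 3-vector of edge lengths")
        if not np.all(self.box > 0):
            raise ValueError(f"box edges must be positive, got {self.box}")
        if len(np.unique(self.indices)) != n:
            raise ValueError("particle indices must be unique within a frame")
        self._row_of: Dict[int, int] | None = None

    @classmethod
    def from_particles(
        cls, particles: Iterable[Particle], box: Sequence[float], time: float = 0.0
    ) -> "Frame":
        plist = list(particles)
        return cls(
            indices=[p.index for p in plist],
            names=[p.name for p in plist],
            residue_names=[p.residue_name for p in plist],
            residue_ids=[p.residue_id for p in plist],
            chains=[p.chain_or_molecule_id for p in plist],
            positions=np.array([p.position for p in plist], dtype=float).reshape(-1, 3),
            box=box,
            time=time,
        )

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def n_particles(self) -> int:
        return len(self.indices)

    @property
    def particles(self) -> List[Particle]:
        return [
            Particle(int(self.indices[i]), str(self.names[i]), str(self.residue_names[i]),
                     int(self.residue_ids[i]), str(self.chains[i]), self.positions[i].copy())
            for i in range(len(self))
        ]

    def rows_for(self, particle_indices: Sequence[int]) -> np.ndarray:
        """Rows of the position array holding the given particle ids."""
        if self._row_of is None:
            self._row_of = {int(ix): row for row, ix in enumerate(self.indices)}
        try:
            return np.array([self._row_of[int(i)] for i in particle_indices], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"particle index {exc.args[0]} not present in frame") from None

    def with_positions(self, positions: np.ndarray, time: float | None = None) -> "Frame":
        """New frame sharing labels but with replaced coordinates (and time)."""
        return Frame(self.indices, self.names, self.residue_names, self.residue_ids,
                     self.chains, positions, self.box,
                     self.time if time is None else time)


@dataclass
class Selection:
    """A named group of particle ids (1-based, as in common MD index files)."""

    name: str
    member_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.member_indices, dtype=np.int64))
        if idx.size == 0:
            raise ValueError(f"selection {self.name!r} is empty")
        self.member_indices = idx

    def __len__(self) -> int:
        return len(self.member_indices)

    def rows(self, frame: Frame) -> np.ndarray:
        return frame.rows_for(self.member_indices)


_RESID_RANGE = re.compile(r"^(\d+)(?:-(\d+))?$")


def parse_selection_expr(expr: str, frame: Frame, name: str = "selection") -> Selection:
    """Build a selection from a small residue/name mini-language.

    Supported clauses, joined with ``and``:

    - ``resid 69-75,127-133`` — residue-id ranges (inclusive) or single ids
    - ``resname POPE,POPG`` — residue names
    - ``name BB,PO4`` — particle names

    Examples
    --------
    >>> sel = parse_selection_expr("resid 69-75,127-133", frame)
    """
    mask = np.ones(len(frame), dtype=bool)
    clauses = [c.strip() for c in expr.split(" and ")]
    for clause in clauses:
        parts = clause.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"cannot parse selection clause {clause!r}")
        key, arg = parts[0].lower(), parts[1]
        items = [a.strip() for a in arg.split(",") if a.strip()]
        if key == "resid":
            sub = np.zeros(len(frame), dtype=bool)
            for item in items:
                m = _RESID_RANGE.match(item)
                if not m:
                    raise ValueError(f"bad resid range {item!r} in {expr!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                sub |= (frame.residue_ids >= lo) & (frame.residue_ids <= hi)
            mask &= sub
        elif key == "resname":
            mask &= np.isin(frame.residue_names.astype(str), items)
        elif key == "name":
            mask &= np.isin(frame.names.astype(str), items)
        else:
            raise ValueError(f"unknown selection keyword {key!r} in {expr!r}")
    if not mask.any():
        raise ValueError(f"selection {expr!r} matches no particles")
    return Selection(name=name, member_indices=frame.indices[mask])


class LipidTopologyMap:
    """Maps lipid residue names to lipid types and their headgroup beads.

    Parameters
    ----------
    lipid_types
        ``residue_name -> lipid_type`` (e.g. ``{"POPE": "POPE", "CDL2": "CL"}``).
    headgroup_beads
        ``lipid_type -> list of headgroup bead names`` (phosphatidyl and
        glycerol beads for contact analysis).
    phosphate_beads
        ``lipid_type -> list of phosphate bead names`` (leaflet/surface
        analysis). A multi-phosphate lipid (cardiolipin) lists both beads but
        is always counted as one molecule.
    """

    def __init__(
        self,
        lipid_types: Mapping[str, str],
        headgroup_beads: Mapping[str, Sequence[str]],
        phosphate_beads: Mapping[str, Sequence[str]],
    ) -> None:
        self.lipid_types = dict(lipid_types)
        self.headgroup_beads = {k: list(v) for k, v in headgroup_beads.items()}
        self.phosphate_beads = {k: list(v) for k, v in phosphate_beads.items()}
        for t in set(self.lipid_types.values()):
            if t not in self.headgroup_beads:
                raise ValueError(f"lipid type {t!r} has no headgroup beads defined")
            if t not in self.phosphate_beads:
                raise ValueError(f"lipid type {t!r} has no phosphate beads defined")

    @property
    def types(self) -> List[str]:
        return sorted(set(self.lipid_types.values()))

    def lipid_type_of(self, residue_name: str) -> str | None:
        return self.lipid_types.get(residue_name)

    def lipid_rows(self, frame: Frame) -> Dict[tuple, np.ndarray]:
        """Group frame rows by lipid molecule.

        Returns ``{(residue_id, lipid_type): rows}`` for every residue whose
        name maps to a lipid type. Each molecule appears exactly once.
        """
        out: Dict[tuple, list] = {}
        resnames = frame.residue_names.astype(str)
        for row in range(len(frame)):
            t = self.lipid_types.get(resnames[row])
            if t is None:
                continue
            out.setdefault((int(frame.residue_ids[row]), t), []).append(row)
        return {k: np.asarray(v, dtype=np.intp) for k, v in out.items()}

    def census(self, frame: Frame) -> Dict[str, int]:
        """Whole-system lipid count per type (molecules, not beads)."""
        counts: Dict[str, int] = {t: 0 for t in self.types}
        for (_rid, t) in self.lipid_rows(frame):
            counts[t] += 1
        return counts


def iter_frames(trajectory: Iterable[Frame]) -> Iterator[Frame]:
    """Normalise a trajectory argument (list, generator) into an iterator."""
    return iter(trajectory)
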