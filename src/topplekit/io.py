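"""Readers and writers for the dialects the pipeline consumes and emits.

Supported formats
-----------------
- GRO fixed-column coordinate files (nm; box on the last line).
- PDB coordinate files (Å on disk, converted to nm; box from ``CRYST1``).
- A plain whitespace-table trajectory dialect (see README for the grammar):
  ``FRAME <time_ps> <bx> <by> <bz>`` separator records followed by one
  ``x y z`` row per particle in template order.
- GROMACS-style index files: ``[ group ]`` headers with 1-based particle ids.
- Umbrella-window sample files: a metadata header comment carrying the
  restraint centre and force constant, then ``time_ps coordinate_nm`` rows;
  a TSV manifest lists the windows of a set.

All readers raise :class:`ParseError` with a file name and line number on
malformed input; a missing box is an explicit error, never a silent default.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterator, List, Sequence

import numpy as np

from .frames import Frame, Selection

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_index_file",
    "write_index_file",
    "read_window_file",
    "write_window_file",
    "read_window_manifest",
    "write_window_manifest",
]


class ParseError(ValueError):
    """Malformed record in an input file; message carries file and line."""

    def __init__(self, path: str, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------------------
# GRO


def _read_gro(path: str) -> Frame:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError(path, len(lines), "GRO file needs title, count, atoms and box lines")
    try:
        natoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(path, 2, f"cannot parse atom count from {lines[1]!r}") from None
    if len(lines) < natoms + 3:
        raise ParseError(path, len(lines), f"expected {natoms} atom lines plus a box line")
    indices, names, resnames, resids, positions = [], [], [], [], []
    for i in range(natoms):
        ln = lines[2 + i]
        lineno = 3 + i
        if len(ln) < 44:
            raise ParseError(path, lineno, f"truncated GRO atom record ({len(ln)} chars)")
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            indices.append(int(ln[15:20]))
            positions.append((float(ln[20:28]), float(ln[28:36]), float(ln[36:44])))
        except ValueError as exc:
            raise ParseError(path, lineno, f"malformed fixed-column field: {exc}") from None
    box_line = lines[2 + natoms].split()
    if len(box_line) < 3:
        raise ParseError(path, 3 + natoms, "missing or incomplete box line")
    try:
        box = [float(v) for v in box_line[:3]]
    except ValueError:
        raise ParseError(path, 3 + natoms, f"cannot parse box from {lines[2 + natoms]!r}") from None
    if len(box_line) > 3 and any(abs(float(v)) > 1e-9 for v in box_line[3:9]):
        raise ParseError(path, 3 + natoms, "triclinic boxes are not supported (off-diagonal box elements)")
    # GRO atom indices wrap at 100000; re-index if duplicates arise
    if len(set(indices)) != natoms:
        indices = list(range(1, natoms + 1))
    return Frame(indices, names, resnames, resids, [""] * natoms,
                 np.asarray(positions), box)


def _write_gro(frame: Frame, path: str, title: str = "written by topplekit") -> None:
    with open(path, "w") as fh:
        fh.write(f"{title}\n{len(frame):5d}\n")
        for i in range(len(frame)):
            fh.write(
                f"{int(frame.residue_ids[i]) % 100000:5d}{str(frame.residue_names[i])[:5]:<5s}"
                f"{str(frame.names[i])[:5]:>5s}{int(frame.indices[i]) % 100000:5d}"
                f"{frame.positions[i, 0]:8.3f}{frame.positions[i, 1]:8.3f}{frame.positions[i, 2]:8.3f}\n"
            )
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB (Å on disk; nm in memory)


def _read_pdb(path: str) -> Frame:
    indices, names, resnames, resids, chains, positions = [], [], [], [], [], []
    box = None
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            rec = ln[:6]
            if rec == "CRYST1":
                try:
                    box = [float(ln[6:15]) / 10.0, float(ln[15:24]) / 10.0, float(ln[24:33]) / 10.0]
                    angles = [float(ln[33:40]), float(ln[40:47]), float(ln[47:54])]
                except ValueError:
                    raise ParseError(path, lineno, "malformed CRYST1 record") from None
                if any(abs(a - 90.0) > 1e-6 for a in angles):
                    raise ParseError(path, lineno, "triclinic boxes are not supported (CRYST1 angles != 90)")
            elif rec in ("ATOM  ", "HETATM"):
                if len(ln.rstrip("\n")) < 54:
                    raise ParseError(path, lineno, "truncated ATOM/HETATM record")
                try:
                    indices.append(int(ln[6:11]))
                    names.append(ln[12:16].strip())
                    resnames.append(ln[17:21].strip())
                    chains.append(ln[21].strip())
                    resids.append(int(ln[22:26]))
                    positions.append((float(ln[30:38]) / 10.0, float(ln[38:46]) / 10.0,
                                      float(ln[46:54]) / 10.0))
                except ValueError as exc:
                    raise ParseError(path, lineno, f"malformed fixed-column field: {exc}") from None
    if not indices:
        raise ParseError(path, 0, "no ATOM/HETATM records found")
    if box is None:
        raise ParseError(path, 0, "no CRYST1 record: box dimensions are required")
    if len(set(indices)) != len(indices):
        indices = list(range(1, len(indices) + 1))
    return Frame(indices, names, resnames, resids, chains, np.asarray(positions), box)


def _write_pdb(frame: Frame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"CRYST1{frame.box[0] * 10:9.3f}{frame.box[1] * 10:9.3f}{frame.box[2] * 10:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for i in range(len(frame)):
            name = str(frame.names[i])[:4]
            chain = (str(frame.chains[i]) or " ")[:1]
            fh.write(
                f"ATOM  {int(frame.indices[i]) % 100000:5d} {name:<4s} "
                f"{str(frame.residue_names[i])[:4]:<4s}{chain}{int(frame.residue_ids[i]) % 10000:4d}    "
                f"{frame.positions[i, 0] * 10:8.3f}{frame.positions[i, 1] * 10:8.3f}"
                f"{frame.positions[i, 2] * 10:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
            )
        fh.write("END\n")


def read_structure(path: str, dialect: str | None = None) -> Frame:
    """Read a single-frame coordinate file (GRO or PDB) into a :class:`Frame`.

    Positions are returned in nm regardless of dialect; PDB Å are converted
    on read. The dialect defaults to the file extension.
    """
    if dialect is None:
        dialect = os.path.splitext(path)[1].lstrip(".").lower()
    if dialect == "gro":
        return _read_gro(path)
    if dialect == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unknown structure dialect {dialect!r} (expected 'gro' or 'pdb')")


def write_structure(frame: Frame, path: str, dialect: str | None = None) -> None:
    """Write a :class:`Frame` as GRO or PDB (dialect from extension by default)."""
    if dialect is None:
        dialect = os.path.splitext(path)[1].lstrip(".").lower()
    if dialect == "gro":
        _write_gro(frame, path)
    elif dialect == "pdb":
        _write_pdb(frame, path)
    else:
        raise ValueError(f"unknown structure dialect {dialect!r} (expected 'gro' or 'pdb')")


# ---------------------------------------------------------------------------
# Whitespace-table trajectory dialect


def read_trajectory(path: str, template: Frame) -> Iterator[Frame]:
    """Lazily read the whitespace-table trajectory dialect.

    Each frame is a ``FRAME <time_ps> <bx> <by> <bz>`` record followed by one
    ``x y z`` row (nm) per particle in the template's particle order. Lines
    starting with ``#`` are comments. Yields frames carrying the template's
    labels. An empty file yields nothing (with a logged warning).
    """
    n = len(template)
    frame_idx = -1
    with open(path) as fh:
        time = None
        box = None
        rows: List[tuple] = []
        start_line = 0
        any_frame = False

        def finish(lineno: int) -> Frame:
            if len(rows) != n:
                raise ParseError(path, lineno,
                                 f"frame {frame_idx}: expected {n} particle rows, got {len(rows)}")
            return template.with_positions(np.asarray(rows, dtype=float), time=time)

        for lineno, ln in enumerate(fh, start=1):
            s = ln.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("FRAME"):
                if frame_idx >= 0:
                    yield finish(lineno)
                    any_frame = True
                parts = s.split()
                if len(parts) != 5:
                    raise ParseError(path, lineno, "FRAME record needs time and 3 box lengths")
                try:
                    time = float(parts[1])
                    box = [float(v) for v in parts[2:5]]
                except ValueError:
                    raise ParseError(path, lineno, f"malformed FRAME record {s!r}") from None
                template = template.with_positions(template.positions)
                template.box = np.asarray(box, dtype=float)
                frame_idx += 1
                rows = []
                start_line = lineno
            else:
                if frame_idx < 0:
                    raise ParseError(path, lineno, "particle row before first FRAME record")
                vals = s.split()
                if len(vals) != 3:
                    raise ParseError(path, lineno, f"expected 3 coordinates, got {len(vals)}")
                try:
                    rows.append((float(vals[0]), float(vals[1]), float(vals[2])))
                except ValueError:
                    raise ParseError(path, lineno, f"malformed coordinate row {s!r}") from None
                if len(rows) > n:
                    raise ParseError(path, lineno, f"frame {frame_idx}: expected {n} particle rows")
        if frame_idx >= 0:
            yield finish(start_line + len(rows) + 1)
            any_frame = True
        if not any_frame:
            logger.warning("trajectory file %s contains no frames", path)


def write_trajectory(frames: Sequence[Frame], path: str) -> None:
    """Write frames in the whitespace-table trajectory dialect."""
    with open(path, "w") as fh:
        fh.write("# topplekit trajectory table: FRAME time_ps box_x box_y box_z; rows x y z in nm\n")
        for fr in frames:
            fh.write(f"FRAME {fr.time:.6g} {fr.box[0]:.6f} {fr.box[1]:.6f} {fr.box[2]:.6f}\n")
            np.savetxt(fh, fr.positions, fmt="%.6f")


# ---------------------------------------------------------------------------
# Index files (named groups of 1-based particle ids)


def read_index_file(path: str) -> Dict[str, Selection]:
    """Read a ``[ group ]`` index file into named selections."""
    groups: Dict[str, List[int]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            s = ln.split(";")[0].strip()
            if not s:
                continue
            if s.startswith("[") and s.endswith("]"):
                current = s[1:-1].strip()
                groups.setdefault(current, [])
            else:
                if current is None:
                    raise ParseError(path, lineno, "indices before any [ group ] header")
                try:
                    groups[current].extend(int(v) for v in s.split())
                except ValueError:
                    raise ParseError(path, lineno, f"non-integer index in {s!r}") from None
    out: Dict[str, Selection] = {}
    for gname, idx in groups.items():
        if not idx:
            raise ParseError(path, 0, f"group {gname!r} is empty")
        out[gname] = Selection(name=gname, member_indices=np.asarray(idx, dtype=np.int64))
    if not out:
        raise ParseError(path, 0, "no groups found")
    return out


def write_index_file(selections: Sequence[Selection], path: str) -> None:
    with open(path, "w") as fh:
        for sel in selections:
            fh.write(f"[ {sel.name} ]\n")
            idx = sel.member_indices
            for start in range(0, len(idx), 15):
                fh.write(" ".join(str(int(v)) for v in idx[start:start + 15]) + "\n")


# ---------------------------------------------------------------------------
# Umbrella window files


def write_window_file(path: str, center: float, force_constant: float,
                      samples: np.ndarray, times: np.ndarray | None = None) -> None:
    """Write one umbrella window: header comment + ``time_ps coordinate_nm`` rows."""
    samples = np.asarray(samples, dtype=float)
    if times is None:
        times = np.arange(len(samples), dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# center_nm= {center:.6g} force_constant_kj_mol_nm2= {force_constant:.6g}\n")
        fh.write("# time_ps coordinate_nm\n")
        np.savetxt(fh, np.column_stack([times, samples]), fmt="%.6f")


def read_window_file(path: str):
    """Read one umbrella-window sample file.

    Returns ``(center, force_constant, times, samples)``. The restraint
    parameters come from the ``# center_nm= ... force_constant_kj_mol_nm2=``
    header; their absence is an error.
    """
    center = force_constant = None
    times: List[float] = []
    samples: List[float] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            s = ln.strip()
            if not s:
                continue
            if s.startswith("#"):
                toks = s[1:].split()
                for i, tok in enumerate(toks):
                    if tok.startswith("center_nm=") or tok == "center_nm=":
                        val = tok.split("=", 1)[1] or toks[i + 1]
                        center = float(val)
                    if tok.startswith("force_constant_kj_mol_nm2=") or tok == "force_constant_kj_mol_nm2=":
                        val = tok.split("=", 1)[1] or toks[i + 1]
                        force_constant = float(val)
                continue
            vals = s.split()
            if len(vals) != 2:
                raise ParseError(path, lineno, f"expected 'time coordinate', got {s!r}")
            try:
                times.append(float(vals[0]))
                samples.append(float(vals[1]))
            except ValueError:
                raise ParseError(path, lineno, f"malformed sample row {s!r}") from None
    if center is None or force_constant is None:
        raise ParseError(path, 0, "window file lacks center_nm=/force_constant_kj_mol_nm2= header")
    if not samples:
        raise ParseError(path, 0, "window file contains no samples")
    return center, force_constant, np.asarray(times), np.asarray(samples)


def write_window_manifest(path: str, window_paths: Sequence[str], temperature: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K\t{temperature:.6g}\n")
        fh.write("# window_file\n")
        for p in window_paths:
            fh.write(f"{p}\n")


def read_window_manifest(path: str):
    """Read a window manifest; returns ``(temperature, absolute window paths)``."""
    base = os.path.dirname(os.path.abspath(path))
    temperature = None
    paths: List[str] = []
    with open(path) as fh:
        for ln in fh:
            s = ln.strip()
            if not s:
                continue
            if s.startswith("#"):
                toks = s[1:].split()
                if toks and toks[0] == "temperature_K" and len(toks) > 1:
                    temperature = float(toks[1])
                continue
            paths.append(s if os.path.isabs(s) else os.path.join(base, s))
    if temperature is None:
        raise ParseError(path, 0, "manifest lacks '# temperature_K <value>' header")
    if not paths:
        raise ParseError(path, 0, "manifest lists no window files")
    return temperature, paths


# ---------------------------------------------------------------------------
# Lipid topology map TSV


def write_topology_tsv(topo, path: str) -> None:
    """Write a lipid topology map as TSV: residue_name, lipid_type,
    headgroup beads (comma-separated), phosphate beads."""
    with open(path, "w") as fh:
        fh.write("# residue_name\tlipid_type\theadgroup_beads\tphosphate_beads\n")
        for resname, ltype in sorted(topo.lipid_types.items()):
            fh.write(f"{resname}\t{ltype}\t{','.join(topo.headgroup_beads[ltype])}\t"
                     f"{','.join(topo.phosphate_beads[ltype])}\n")


def read_topology_tsv(path: str):
    """Read a lipid topology map TSV written by :func:`write_topology_tsv`."""
    from .frames import LipidTopologyMap

    lipid_types, head, phos = {}, {}, {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            s = ln.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) != 4:
                raise ParseError(path, lineno, f"expected 4 tab-separated fields, got {len(parts)}")
            resname, ltype, hbeads, pbeads = parts
            lipid_types[resname] = ltype
            head[ltype] = hbeads.split(",")
            phos[ltype] = pbeads.split(",")
    if not lipid_types:
        raise ParseError(path, 0, "topology map is empty")
    return LipidTopologyMap(lipid_types, head, phos)
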