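"""Lipid-protein interaction fingerprints.

A contact exists when any particle of a protein residue lies within a
cutoff (default 0.7 nm, minimum image) of any headgroup bead (phosphatidyl
or glycerol CG beads) of a lipid molecule. From per-frame contacts the
module derives the annular-shell census, the depletion-enrichment (D-E)
index per lipid type,

    D-E(L) = ratio(L)_shell / ratio(L)_bulk,

per-residue contact occupancies for binding-site mapping, and 2-D headgroup
density maps. Shell membership is molecule-level: a cardiolipin contacting
through both of its phosphates is one shell lipid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .frames import Frame, LipidTopologyMap, Selection
from .membrane import GridMap

logger = logging.getLogger(__name__)

__all__ = [
    "ShellCensus",
    "DEResult",
    "ResidueContactProfile",
    "lipid_contacts",
    "shell_census",
    "de_index",
    "residue_contact_profile",
    "headgroup_density_map",
    "DepletionEnrichmentAnalyzer",
    "group_binding_sites",
]


@dataclass
class ShellCensus:
    """Per-frame annular-shell lipid counts and the whole-system composition."""

    frame_counts: List[Dict[str, int]]  # one dict per frame: lipid_type -> shell count
    bulk_counts: Dict[str, int]
    cutoff: float

    @property
    def n_frames(self) -> int:
        return len(self.frame_counts)


@dataclass
class DEResult:
    lipid_type: str
    de_index: float
    n_frames: int
    per_frame_values: List[float] = field(default_factory=list)

    @property
    def se(self) -> float:
        """Standard error of the frame-mean shell ratio, on the D-E scale."""
        if len(self.per_frame_values) < 2:
            return float("nan")
        return float(np.std(self.per_frame_values, ddof=1) / np.sqrt(len(self.per_frame_values)))


@dataclass
class ResidueContactProfile:
    """Fraction of frames in which each residue touches each lipid type."""

    occupancy: Dict[Tuple[int, str], float]  # (residue_id, lipid_type) -> [0, 1]
    cutoff: float
    n_frames: int
    # per frame, per lipid molecule: the set of residues co-contacting it
    co_contacts: List[Dict[tuple, Set[int]]] = field(default_factory=list)


def _headgroup_rows(frame: Frame, topo: LipidTopologyMap):
    """Rows of headgroup beads with their (residue_id, lipid_type) labels."""
    names = frame.names.astype(str)
    rows: List[int] = []
    labels: List[tuple] = []
    for (rid, ltype), lrows in topo.lipid_rows(frame).items():
        hnames = set(topo.headgroup_beads[ltype])
        for r in lrows:
            if names[r] in hnames:
                rows.append(r)
                labels.append((rid, ltype))
    return np.asarray(rows, dtype=np.intp), labels


def lipid_contacts(frame: Frame, protein_sel: Selection, topo: LipidTopologyMap,
                   cutoff: float = 0.7) -> Set[Tuple[int, int, str]]:
    """Residue-lipid contact pairs in one frame.

    Returns a set of ``(residue_id, lipid_molecule_id, lipid_type)``; a pair
    is present iff any particle of the protein residue is within ``cutoff``
    nm (minimum image) of any headgroup bead of that lipid molecule. The
    search uses a periodic cell-list index (kd-tree); results are exactly
    those of the all-pairs computation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    hg_rows, hg_labels = _headgroup_rows(frame, topo)
    if len(hg_rows) == 0:
        raise ValueError(
            f"no headgroup beads resolvable from topology map (beads: {topo.headgroup_beads})"
        )
    prot_rows = protein_sel.rows(frame)
    box = frame.box
    ppos = np.mod(frame.positions[prot_rows], box)
    hpos = np.mod(frame.positions[hg_rows], box)
    tree_p = cKDTree(ppos, boxsize=box)
    tree_h = cKDTree(hpos, boxsize=box)
    pairs = tree_p.query_ball_tree(tree_h, r=cutoff)
    prot_resids = frame.residue_ids[prot_rows]
    out: Set[Tuple[int, int, str]] = set()
    for ip, hits in enumerate(pairs):
        rid = int(prot_resids[ip])
        for ih in hits:
            lip_rid, ltype = hg_labels[ih]
            out.add((rid, lip_rid, ltype))
    return out


def shell_census(frames: Iterable[Frame], protein_sel: Selection,
                 topo: LipidTopologyMap, cutoff: float = 0.7) -> ShellCensus:
    """Count shell lipids per type per frame (molecule-level membership).

    A lipid is in the annular shell iff it has at least one contact with any
    protein residue. The bulk composition is the whole-system per-type
    molecule census (taken from the first frame; lipid identities are stable
    along a trajectory).
    """
    frame_counts: List[Dict[str, int]] = []
    bulk: Dict[str, int] | None = None
    for fr in frames:
        if bulk is None:
            bulk = topo.census(fr)
        contacts = lipid_contacts(fr, protein_sel, topo, cutoff=cutoff)
        shell_lipids = {(lip, ltype) for (_r, lip, ltype) in contacts}
        counts: Dict[str, int] = {t: 0 for t in topo.types}
        for (_lip, ltype) in shell_lipids:
            counts[ltype] += 1
        frame_counts.append(counts)
    if bulk is None:
        raise ValueError("need at least one frame")
    return ShellCensus(frame_counts=frame_counts, bulk_counts=bulk, cutoff=cutoff)


class DepletionEnrichmentAnalyzer(BaseEstimator):
    """Depletion-enrichment fingerprint of lipid types around a protein.

    For each lipid type L, the D-E index is the ratio of L's share of the
    annular shell (all lipids with a headgroup bead within ``cutoff`` nm of
    the protein) to L's share of the whole system. 1 means neutral mixing,
    >1 enrichment, <1 depletion.

    Parameters
    ----------
    cutoff : float
        Contact cutoff in nm (default 0.7).
    estimator : {"perframe", "pooled"}
        "perframe" (default) averages the per-frame shell ratios and then
        divides by the bulk ratio; "pooled" pools shell counts over frames
        first. The pooled variant satisfies the weighted identity
        sum_L bulk_ratio(L) * D-E(L) = 1 exactly.

    Attributes
    ----------
    census_ : ShellCensus
    results_ : list of DEResult
    de_ : dict lipid_type -> D-E index
    """

    def __init__(self, cutoff: float = 0.7, estimator: str = "perframe") -> None:
        self.cutoff = cutoff
        self.estimator = estimator

    def fit(self, frames: Iterable[Frame], protein_sel: Selection,
            topo: LipidTopologyMap) -> "DepletionEnrichmentAnalyzer":
        if self.estimator not in ("perframe", "pooled"):
            raise ValueError(f"estimator must be 'perframe' or 'pooled', got {self.estimator!r}")
        census = shell_census(frames, protein_sel, topo, cutoff=self.cutoff)
        self.census_ = census
        self.results_ = de_index(census, estimator=self.estimator)
        self.de_ = {r.lipid_type: r.de_index for r in self.results_}
        return self


def de_index(census: ShellCensus, estimator: str = "perframe") -> List[DEResult]:
    """Depletion-enrichment index per lipid type from a shell census.

    Frames with an empty shell are skipped (a logged count); a type absent
    from the bulk is an error, as its bulk ratio is undefined.
    """
    n_bulk_total = sum(census.bulk_counts.values())
    if n_bulk_total == 0:
        raise ValueError("bulk census is empty")
    types = sorted(census.bulk_counts)
    occupied = [fc for fc in census.frame_counts if sum(fc.values()) > 0]
    n_skipped = len(census.frame_counts) - len(occupied)
    if n_skipped:
        logger.info("de_index: skipped %d frames with empty shells", n_skipped)
    if not occupied:
        raise ValueError("all frames have empty annular shells; cannot form shell ratios")
    results: List[DEResult] = []
    for t in types:
        bulk_ratio = census.bulk_counts[t] / n_bulk_total
        if bulk_ratio == 0:
            raise ValueError(f"lipid type {t!r} absent from the bulk; D-E undefined")
        per_frame = [fc.get(t, 0) / sum(fc.values()) / bulk_ratio for fc in occupied]
        if estimator == "perframe":
            de = float(np.mean(per_frame))
        else:
            pooled_shell = sum(fc.get(t, 0) for fc in occupied)
            pooled_total = sum(sum(fc.values()) for fc in occupied)
            de = (pooled_shell / pooled_total) / bulk_ratio
        results.append(DEResult(lipid_type=t, de_index=de, n_frames=len(occupied),
                                per_frame_values=per_frame))
    return results


def residue_contact_profile(frames: Iterable[Frame], protein_sel: Selection,
                            topo: LipidTopologyMap,
                            cutoff: float = 0.7) -> ResidueContactProfile:
    """Per-residue, per-lipid-type contact occupancy over a trajectory.

    Occupancy is the fraction of frames in which the residue touches at
    least one lipid of the type. Also records, per frame and per lipid
    molecule, the set of residues simultaneously in contact with that one
    lipid (the raw material for binding-site grouping).
    """
    hit_frames: Dict[Tuple[int, str], int] = {}
    co: List[Dict[tuple, Set[int]]] = []
    n_frames = 0
    for fr in frames:
        n_frames += 1
        contacts = lipid_contacts(fr, protein_sel, topo, cutoff=cutoff)
        seen: Set[Tuple[int, str]] = set()
        frame_co: Dict[tuple, Set[int]] = {}
        for (rid, lip, ltype) in contacts:
            seen.add((rid, ltype))
            frame_co.setdefault((lip, ltype), set()).add(rid)
        for key in seen:
            hit_frames[key] = hit_frames.get(key, 0) + 1
        co.append(frame_co)
    if n_frames == 0:
        raise ValueError("need at least one frame")
    occ = {k: v / n_frames for k, v in hit_frames.items()}
    return ResidueContactProfile(occupancy=occ, cutoff=cutoff, n_frames=n_frames,
                                 co_contacts=co)


def group_binding_sites(profile: ResidueContactProfile, lipid_type: str,
                        min_shared_fraction: float = 0.2) -> List[Set[int]]:
    """Group residues into binding sites by single-linkage co-contact.

    Two residues join the same site when they are simultaneously in contact
    with one individual lipid of ``lipid_type`` in at least
    ``min_shared_fraction`` of the frames. This is a toolkit convention for
    turning co-contact statistics into discrete sites.
    """
    pair_counts: Dict[Tuple[int, int], int] = {}
    for frame_co in profile.co_contacts:
        for (lip, ltype), residues in frame_co.items():
            if ltype != lipid_type:
                continue
            rs = sorted(residues)
            for i in range(len(rs)):
                for j in range(i + 1, len(rs)):
                    pair_counts[(rs[i], rs[j])] = pair_counts.get((rs[i], rs[j]), 0) + 1
    threshold = min_shared_fraction * profile.n_frames
    parent: Dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), c in pair_counts.items():
        if c >= threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    sites: Dict[int, Set[int]] = {}
    for r in parent:
        sites.setdefault(find(r), set()).add(r)
    return sorted((s for s in sites.values() if len(s) > 1), key=lambda s: (-len(s), min(s)))


def headgroup_density_map(frames: Iterable[Frame], topo: LipidTopologyMap,
                          lipid_type: str, x_edges: np.ndarray, y_edges: np.ndarray,
                          protein_sel: Selection | None = None) -> GridMap:
    """2-D headgroup-bead density of one lipid type (counts / nm^2 / frame).

    Positions are taken in protein-centred coordinates when ``protein_sel``
    is given (the protein centroid is moved to the box centre, lateral
    wrap applied).
    """
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    hist = np.zeros((nx, ny))
    n_frames = 0
    n_beads = 0
    for fr in frames:
        n_frames += 1
        work = fr
        if protein_sel is not None:
            rows = protein_sel.rows(fr)
            shift = np.zeros(3)
            shift[:2] = fr.positions[rows, :2].mean(axis=0) - fr.box[:2] / 2.0
            work = fr.with_positions(np.mod(fr.positions - shift, fr.box))
        hg_rows, hg_labels = _headgroup_rows(work, topo)
        sel = [r for r, (_rid, t) in zip(hg_rows, hg_labels) if t == lipid_type]
        n_beads += len(sel)
        if sel:
            xy = work.positions[np.asarray(sel, dtype=np.intp), :2]
            h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[x_edges, y_edges])
            hist += h
    if n_frames == 0:
        raise ValueError("need at least one frame")
    if n_beads == 0:
        logger.warning("no headgroup beads of type %r found; density map is all zero", lipid_type)
    cell_area = np.outer(np.diff(x_edges), np.diff(y_edges))
    vals = hist / cell_area / n_frames
    mask = np.zeros_like(vals, dtype=bool)
    return GridMap(x_edges, y_edges, vals, n_frames, mask, units="nm^-2 frame^-1")
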