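"""Leaflet assignment, polynomial surface fits, thickness and curvature maps.

The bilayer around a membrane protein is described per leaflet by a smooth
surface z(x, y) fitted to phosphate-bead positions. Thickness is the
difference of the two leaflet surfaces; local mean curvature follows the
Monge-patch formula from the analytic derivatives of the fit.

Two fitting strategies are provided:

``global``
    One bivariate polynomial of total degree <= 4 per leaflet over the whole
    analysis patch (the per-leaflet :class:`SurfaceFit`). Appropriate when
    the deformation is representable by a single quartic over the patch.
``local``
    A moving-window quartic fit around every grid cell (k-nearest phosphate
    beads, periodic in x/y), evaluated at the cell centre. This resolves
    localized deformations (e.g. a thinning dimple a few nm wide) inside a
    large bilayer patch that no single quartic can represent, at the cost of
    a smoothing length set by the neighbour count.

Maps are computed per frame and averaged cell-wise over frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .frames import Frame, LipidTopologyMap, Selection
logger = logging.getLogger(__name__)

__all__ = [
    "LeafletAssignment",
    "SurfaceFit",
    "GridMap",
    "assign_leaflets",
    "fit_leaflet_surface",
    "thickness_map",
    "mean_curvature_map",
    "protein_footprint",
    "MembraneMapper",
]


def _monomial_exponents(degree: int) -> List[Tuple[int, int]]:
    return [(i, j) for i in range(degree + 1) for j in range(degree + 1) if i + j <= degree]


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels and the phosphate midplane."""

    labels: Dict[tuple, str]  # (residue_id, lipid_type) -> upper|lower|excluded
    midplane_z: float

    def lipids(self, leaflet: str) -> List[tuple]:
        return [k for k, v in self.labels.items() if v == leaflet]


@dataclass
class SurfaceFit:
    """Bivariate polynomial surface z(x, y) for one leaflet (nm).

    Coefficients are over the full total-degree basis, in the order given
    by ``exponents``; coordinates are taken relative to ``origin`` for
    numerical conditioning.
    """

    leaflet: str
    coefficients: np.ndarray
    degree: int
    origin: Tuple[float, float]
    fit_rms: float
    domain: Tuple[Tuple[float, float], Tuple[float, float]]
    exponents: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exponents:
            self.exponents = _monomial_exponents(self.degree)
        if len(self.coefficients) != len(self.exponents):
            raise ValueError("coefficient count does not match polynomial basis size")

    def _rel(self, x, y):
        return np.asarray(x, dtype=float) - self.origin[0], np.asarray(y, dtype=float) - self.origin[1]

    def evaluate(self, x, y) -> np.ndarray:
        u, v = self._rel(x, y)
        z = np.zeros(np.broadcast(u, v).shape)
        for c, (i, j) in zip(self.coefficients, self.exponents):
            z = z + c * u**i * v**j
        return z

    def derivative(self, x, y, dx: int = 0, dy: int = 0) -> np.ndarray:
        """Analytic partial derivative d^(dx+dy) z / dx^dx dy^dy."""
        u, v = self._rel(x, y)
        out = np.zeros(np.broadcast(u, v).shape)
        for c, (i, j) in zip(self.coefficients, self.exponents):
            if i < dx or j < dy:
                continue
            fac = 1.0
            for k in range(dx):
                fac *= i - k
            for k in range(dy):
                fac *= j - k
            out = out + c * fac * u ** (i - dx) * v ** (j - dy)
        return out

    def mean_curvature(self, x, y) -> np.ndarray:
        """Monge-patch mean curvature H(x, y) in nm^-1.

        H = [(1+z_y^2) z_xx - 2 z_x z_y z_xy + (1+z_x^2) z_yy]
            / [2 (1+z_x^2+z_y^2)^(3/2)]

        Positive for a bowl opening toward +z (e.g. z = 0.05 (x^2+y^2)
        gives H = 0.1 at the origin); adding a constant to the surface
        leaves H unchanged and reflecting it through z = 0 flips the sign.
        """
        zx = self.derivative(x, y, 1, 0)
        zy = self.derivative(x, y, 0, 1)
        zxx = self.derivative(x, y, 2, 0)
        zyy = self.derivative(x, y, 0, 2)
        zxy = self.derivative(x, y, 1, 1)
        num = (1 + zy**2) * zxx - 2 * zx * zy * zxy + (1 + zx**2) * zyy
        den = 2.0 * (1 + zx**2 + zy**2) ** 1.5
        return num / den


@dataclass
class GridMap:
    """A frame-averaged 2-D field on a rectangular grid.

    ``values[i, j]`` belongs to the cell between ``x_edges[i], x_edges[i+1]``
    and ``y_edges[j], y_edges[j+1]``. Cells under the protein footprint are
    flagged in ``protein_footprint_mask`` and carry NaN, never zero.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    n_frames_averaged: int
    protein_footprint_mask: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        nx, ny = len(self.x_edges) - 1, len(self.y_edges) - 1
        if self.values.shape != (nx, ny):
            raise ValueError(f"values shape {self.values.shape} does not match grid ({nx}, {ny})")
        if self.protein_footprint_mask.shape != (nx, ny):
            raise ValueError("mask shape does not match grid")

    @property
    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return cx, cy


def assign_leaflets(frame: Frame, topo: LipidTopologyMap,
                    dead_zone: float = 0.5) -> LeafletAssignment:
    """Assign each phosphate-bearing lipid to the upper or lower leaflet.

    A lipid's z is the mean over its phosphate beads (cardiolipin's two
    phosphates are averaged); the midplane is the mean of these per-lipid
    values, so every molecule counts once and a multi-phosphate species
    cannot skew the split. Lipids within ``dead_zone`` nm of the midplane
    are labelled ``excluded``.
    """
    lipid_rows = topo.lipid_rows(frame)
    names = frame.names.astype(str)
    z_all: List[float] = []
    lipid_z: Dict[tuple, float] = {}
    for (rid, ltype), rows in lipid_rows.items():
        pnames = set(topo.phosphate_beads[ltype])
        prows = [r for r in rows if names[r] in pnames]
        if not prows:
            continue
        zs = frame.positions[prows, 2]
        z_all.extend(zs.tolist())
        lipid_z[(rid, ltype)] = float(zs.mean())
    if not z_all:
        raise ValueError(
            "no phosphate beads matched the topology map "
            f"(phosphate bead names: {topo.phosphate_beads})"
        )
    if len(lipid_z) < 2:
        raise ValueError("need at least 2 phosphate-bearing lipids to define leaflets")
    midplane = float(np.mean(list(lipid_z.values())))
    labels: Dict[tuple, str] = {}
    for key, z in lipid_z.items():
        dz = z - midplane
        if abs(dz) < dead_zone:
            labels[key] = "excluded"
        else:
            labels[key] = "upper" if dz > 0 else "lower"
    return LeafletAssignment(labels=labels, midplane_z=midplane)


def fit_leaflet_surface(points: np.ndarray, degree: int = 4,
                        leaflet: str = "upper") -> SurfaceFit:
    """Least-squares bivariate polynomial fit z(x, y) to phosphate positions.

    ``points`` is ``(N, 3)`` with N at least the basis size (15 at degree 4).
    Points are expected pre-unwrapped (and typically protein-centred). The
    fit is over the full total-degree monomial basis; a rank-deficient
    design (e.g. collinear points) is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array of x, y, z")
    exps = _monomial_exponents(degree)
    nb = len(exps)
    if len(pts) < nb:
        raise ValueError(
            f"need at least {nb} points for a degree-{degree} surface fit, got {len(pts)}"
        )
    x0, y0 = pts[:, 0].mean(), pts[:, 1].mean()
    u = pts[:, 0] - x0
    v = pts[:, 1] - y0
    A = np.stack([u**i * v**j for i, j in exps], axis=1)
    coef, _res, rank, _sv = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    if rank < nb:
        raise ValueError(
            f"rank-deficient surface fit (rank {rank} < {nb}); "
            "points may be collinear — use a larger patch"
        )
    resid = A @ coef - pts[:, 2]
    rms = float(np.sqrt(np.mean(resid**2)))
    domain = ((float(pts[:, 0].min()), float(pts[:, 0].max())),
              (float(pts[:, 1].min()), float(pts[:, 1].max())))
    return SurfaceFit(leaflet=leaflet, coefficients=coef, degree=degree,
                      origin=(float(x0), float(y0)), fit_rms=rms, domain=domain,
                      exponents=exps)


def _check_domain(fit: SurfaceFit, x_edges: np.ndarray, y_edges: np.ndarray,
                  tol: float = 1e-9) -> None:
    (xmin, xmax), (ymin, ymax) = fit.domain
    if x_edges[0] < xmin - tol or x_edges[-1] > xmax + tol \
            or y_edges[0] < ymin - tol or y_edges[-1] > ymax + tol:
        raise ValueError(
            f"grid [{x_edges[0]}, {x_edges[-1]}] x [{y_edges[0]}, {y_edges[-1]}] "
            f"extends outside the {fit.leaflet} fit domain {fit.domain}"
        )


def thickness_map(upper: SurfaceFit, lower: SurfaceFit,
                  x_edges: np.ndarray, y_edges: np.ndarray) -> GridMap:
    """Bilayer thickness z_upper - z_lower (nm) at grid cell centres."""
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    _check_domain(upper, x_edges, y_edges)
    _check_domain(lower, x_edges, y_edges)
    cx = 0.5 * (x_edges[:-1] + x_edges[1:])
    cy = 0.5 * (y_edges[:-1] + y_edges[1:])
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    vals = upper.evaluate(X, Y) - lower.evaluate(X, Y)
    if np.any(vals < 0):
        logger.warning("thickness map has %d negative cells (upper surface below lower)",
                       int((vals < 0).sum()))
    mask = np.zeros_like(vals, dtype=bool)
    return GridMap(x_edges, y_edges, vals, 1, mask, units="nm")


def mean_curvature_map(fit: SurfaceFit, x_edges: np.ndarray,
                       y_edges: np.ndarray) -> GridMap:
    """Mean curvature H (nm^-1) of a fitted leaflet surface on a grid."""
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    _check_domain(fit, x_edges, y_edges)
    cx = 0.5 * (x_edges[:-1] + x_edges[1:])
    cy = 0.5 * (y_edges[:-1] + y_edges[1:])
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    vals = fit.mean_curvature(X, Y)
    mask = np.zeros_like(vals, dtype=bool)
    return GridMap(x_edges, y_edges, vals, 1, mask, units="nm^-1")


def protein_footprint(frame: Frame, protein_sel: Selection | None,
                      x_edges: np.ndarray, y_edges: np.ndarray,
                      pad: float = 0.3) -> np.ndarray:
    """Boolean grid of cells whose centre lies within ``pad`` nm (x/y,
    minimum image) of any protein particle projection."""
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    mask = np.zeros((nx, ny), dtype=bool)
    if protein_sel is None:
        return mask
    rows = protein_sel.rows(frame)
    if len(rows) == 0:
        return mask
    box_xy = frame.box[:2]
    pxy = np.mod(frame.positions[rows, :2], box_xy)
    cx = 0.5 * (x_edges[:-1] + x_edges[1:])
    cy = 0.5 * (y_edges[:-1] + y_edges[1:])
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    centers = np.mod(np.column_stack([X.ravel(), Y.ravel()]), box_xy)
    tree = cKDTree(pxy, boxsize=box_xy)
    hits = tree.query_ball_point(centers, r=pad)
    flat = np.array([len(h) > 0 for h in hits], dtype=bool)
    return flat.reshape(nx, ny)


def _local_quartic_eval(points_xy: np.ndarray, z: np.ndarray, centers: np.ndarray,
                        box_xy: np.ndarray, degree: int, k: int):
    """Moving-window polynomial fit around each centre (periodic k-NN).

    Returns ``(value, zx, zy, zxx, zyy, zxy)`` arrays evaluated at the
    centres, from a batched normal-equation solve.
    """
    exps = _monomial_exponents(degree)
    nb = len(exps)
    n = len(points_xy)
    if n < nb:
        raise ValueError(f"need at least {nb} phosphate points for degree-{degree} local fits, got {n}")
    k = min(k, n)
    if k < nb:
        raise ValueError(f"local neighbourhood size {k} is below the basis size {nb}")
    pts = np.mod(points_xy, box_xy)
    tree = cKDTree(pts, boxsize=box_xy)
    _d, idx = tree.query(np.mod(centers, box_xy), k=k)
    # minimum-image offsets of each neighbour from its centre
    d = pts[idx] - np.mod(centers, box_xy)[:, None, :]
    d -= box_xy * np.round(d / box_xy)
    u, v = d[..., 0], d[..., 1]
    A = np.stack([u**i * v**j for i, j in exps], axis=-1)  # (nc, k, nb)
    zn = z[idx]
    G = np.einsum("nki,nkj->nij", A, A)
    b = np.einsum("nki,nk->ni", A, zn)
    G += 1e-12 * np.eye(nb)
    coef = np.linalg.solve(G, b[..., None])[..., 0]  # (nc, nb)

    def pick(i, j, fac=1.0):
        try:
            col = exps.index((i, j))
        except ValueError:
            return np.zeros(len(centers))
        return fac * coef[:, col]

    # at the window centre (u, v) = (0, 0): only low-order terms survive
    return (pick(0, 0), pick(1, 0), pick(0, 1),
            pick(2, 0, 2.0), pick(0, 2, 2.0), pick(1, 1, 1.0))


class MembraneMapper(BaseEstimator):
    """Frame-averaged bilayer thickness and mean-curvature maps.

    For each frame, phosphate beads are split into leaflets about the
    phosphate midplane, a degree-``degree`` polynomial surface is fitted per
    leaflet (globally over the patch, or locally around every grid cell),
    and thickness/curvature are evaluated at cell centres; maps are averaged
    cell-wise over frames. Cells under the protein footprint are masked and
    reported as NaN.

    Parameters
    ----------
    grid_spacing : float
        Grid cell edge, nm (default 0.2).
    mode : {"local", "global"}
        Surface-fit strategy (see module docstring). Local is the default;
        it handles deformations narrower than the analysis patch.
    n_local : int
        Neighbours per moving-window fit in local mode (default 60,
        an effective smoothing radius of a few nm at CG lipid densities).
    degree : int
        Polynomial total degree (default 4).
    dead_zone : float
        Half-width of the midplane exclusion zone, nm (default 0.5).
    footprint_pad : float
        Protein footprint padding, nm (default 0.3).
    center_on_protein : bool
        Re-centre each frame laterally on the protein centroid before
        fitting (default True when a protein selection is given).

    Attributes
    ----------
    thickness_ : GridMap (nm)
    curvature_upper_, curvature_lower_ : GridMap (nm^-1)
    x_edges_, y_edges_ : ndarray
    n_frames_ : int
    """

    def __init__(self, grid_spacing: float = 0.2, mode: str = "local",
                 n_local: int = 60, degree: int = 4, dead_zone: float = 0.5,
                 footprint_pad: float = 0.3, center_on_protein: bool = True) -> None:
        self.grid_spacing = grid_spacing
        self.mode = mode
        self.n_local = n_local
        self.degree = degree
        self.dead_zone = dead_zone
        self.footprint_pad = footprint_pad
        self.center_on_protein = center_on_protein

    def _leaflet_points(self, frame: Frame, topo: LipidTopologyMap):
        assign = assign_leaflets(frame, topo, dead_zone=self.dead_zone)
        names = frame.names.astype(str)
        lipid_rows = topo.lipid_rows(frame)
        pts = {"upper": [], "lower": []}
        for key, rows in lipid_rows.items():
            label = assign.labels.get(key)
            if label not in pts:
                continue
            pnames = set(topo.phosphate_beads[key[1]])
            for r in rows:
                if names[r] in pnames:
                    pts[label].append(frame.positions[r])
        return {k: np.asarray(v).reshape(-1, 3) for k, v in pts.items()}, assign

    def fit(self, frames: Iterable[Frame], topo: LipidTopologyMap,
            protein_sel: Selection | None = None) -> "MembraneMapper":
        if self.mode not in ("local", "global"):
            raise ValueError(f"mode must be 'local' or 'global', got {self.mode!r}")
        frames = list(frames)
        if not frames:
            raise ValueError("need at least one frame")
        box = frames[0].box
        nx = max(1, int(round(box[0] / self.grid_spacing)))
        ny = max(1, int(round(box[1] / self.grid_spacing)))
        x_edges = np.linspace(0.0, box[0], nx + 1)
        y_edges = np.linspace(0.0, box[1], ny + 1)
        cx = 0.5 * (x_edges[:-1] + x_edges[1:])
        cy = 0.5 * (y_edges[:-1] + y_edges[1:])
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        centers = np.column_stack([X.ravel(), Y.ravel()])

        thick_sum = np.zeros((nx, ny))
        curvU_sum = np.zeros((nx, ny))
        curvL_sum = np.zeros((nx, ny))
        counts = np.zeros((nx, ny), dtype=int)
        mask_union = np.zeros((nx, ny), dtype=bool)

        for fr in frames:
            work = fr
            if protein_sel is not None and self.center_on_protein:
                rows = protein_sel.rows(fr)
                shift = np.zeros(3)
                shift[:2] = fr.positions[rows, :2].mean(axis=0) - fr.box[:2] / 2.0
                work = fr.with_positions(np.mod(fr.positions - shift, fr.box))
            pts, _assign = self._leaflet_points(work, topo)
            fmask = protein_footprint(work, protein_sel, x_edges, y_edges,
                                      pad=self.footprint_pad)
            if fmask.all():
                raise ValueError("protein footprint covers the whole grid; nothing to fit")
            mask_union |= fmask
            if protein_sel is not None:
                prow = protein_sel.rows(work)
                pxy = work.positions[prow, :2]
                for leaf in ("upper", "lower"):
                    p = pts[leaf]
                    if len(p) == 0:
                        continue
                    d = p[:, None, :2] - pxy[None, :, :]
                    d -= work.box[:2] * np.round(d / work.box[:2])
                    near = (np.sqrt((d**2).sum(-1)) < self.footprint_pad).any(axis=1)
                    pts[leaf] = p[~near]
            vals = {}
            for leaf in ("upper", "lower"):
                p = pts[leaf]
                if self.mode == "local":
                    z0, _zx, _zy, zxx, zyy, zxy = _local_quartic_eval(
                        p[:, :2], p[:, 2], centers, work.box[:2], self.degree, self.n_local)
                    zx, zy = _zx, _zy
                    num = (1 + zy**2) * zxx - 2 * zx * zy * zxy + (1 + zx**2) * zyy
                    H = num / (2.0 * (1 + zx**2 + zy**2) ** 1.5)
                    vals[leaf] = (z0.reshape(nx, ny), H.reshape(nx, ny))
                else:
                    sf = fit_leaflet_surface(p, degree=self.degree, leaflet=leaf)
                    vals[leaf] = (sf.evaluate(X, Y), sf.mean_curvature(X, Y))
            th = vals["upper"][0] - vals["lower"][0]
            if np.any(th[~fmask] < 0):
                logger.warning("frame t=%.1f: negative thickness cells", fr.time)
            ok = ~fmask
            thick_sum[ok] += th[ok]
            curvU_sum[ok] += vals["upper"][1][ok]
            curvL_sum[ok] += vals["lower"][1][ok]
            counts[ok] += 1

        def averaged(total: np.ndarray, units: str) -> GridMap:
            out = np.full((nx, ny), np.nan)
            has = counts > 0
            out[has] = total[has] / counts[has]
            out[mask_union] = np.nan
            return GridMap(x_edges, y_edges, out, len(frames), mask_union.copy(), units=units)

        self.x_edges_ = x_edges
        self.y_edges_ = y_edges
        self.n_frames_ = len(frames)
        self.thickness_ = averaged(thick_sum, "nm")
        self.curvature_upper_ = averaged(curvU_sum, "nm^-1")
        self.curvature_lower_ = averaged(curvL_sum, "nm^-1")
        return self
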