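"""Synthetic-trajectory generators with known ground truth.

Every analysis stage in this package has a generator here whose output it
should recover: coarse-grained bilayer patches with a prescribed mid-surface
and thickness field, helical protein bead clouds with a prescribed tilt,
tilt time series with two-state Markov or noisy-constant dynamics, lipid
placements with prescribed annular-shell enrichment, and umbrella windows
Boltzmann-sampled from a closed-form potential. Generators are pure
functions of their spec plus a seed (bitwise-reproducible); per-frame
randomness uses deterministically spawned sub-streams.

The lipid geometry is deliberately minimal (phosphate + glycerol headgroup
beads and two tail beads per lipid): enough to exercise leaflet, surface
and contact logic, with no pretence of emulating real lipid conformations
or energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .frames import Frame, LipidTopologyMap, Selection
from .free_energy import KB_KJ_MOL_K, UmbrellaWindow, WindowSet
from .orientation import TiltSeries

__all__ = [
    "BilayerSpec",
    "TiltDynamicsSpec",
    "PotentialSpec",
    "make_bilayer_trajectory",
    "make_protein_beads",
    "make_tilt_trajectory",
    "make_enriched_shell_frames",
    "make_umbrella_samples",
    "default_topology",
]

# Composition of the bacterial model membrane the study conditions use
DEFAULT_COMPOSITION = {"POPE": 0.70, "POPG": 0.25, "CL": 0.05}


def default_topology(types: Sequence[str] = ("POPE", "POPG", "CL")) -> LipidTopologyMap:
    """Topology map for the minimal synthetic lipids.

    Single-phosphate lipids carry one PO4 bead; cardiolipin (CL) carries
    two (PO41, PO42) but is one molecule. GL0 is the glycerol headgroup
    bead; headgroups are the phosphatidyl plus glycerol beads.
    """
    lipid_types = {t: t for t in types}
    head, phos = {}, {}
    for t in types:
        if t == "CL":
            phos[t] = ["PO41", "PO42"]
            head[t] = ["PO41", "PO42", "GL0"]
        else:
            phos[t] = ["PO4"]
            head[t] = ["PO4", "GL0"]
    return LipidTopologyMap(lipid_types, head, phos)


@dataclass
class BilayerSpec:
    """A planar or locally deformed CG bilayer patch.

    ``mid_surface`` and ``thickness_field`` are callables (x, y) -> nm
    evaluated on protein-free, box-centred coordinates; phosphate beads sit
    at mid +- thickness/2 with Gaussian z-noise. Defaults mirror the
    bacterial model membrane (POPE:POPG:CL 70:25:5, ~0.63 nm^2 per lipid,
    4 nm bulk thickness).
    """

    box: Tuple[float, float, float] = (25.0, 25.0, 10.0)
    n_lipids_per_leaflet: int = 1000
    composition: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    mid_surface: Callable = None
    thickness_field: Callable = None
    phosphate_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition fractions must sum to 1, got {total}")
        if self.mid_surface is None:
            self.mid_surface = lambda x, y: np.zeros_like(np.asarray(x, dtype=float)) + self.box[2] / 2.0
        if self.thickness_field is None:
            self.thickness_field = lambda x, y: np.full_like(np.asarray(x, dtype=float), 4.0)


def gaussian_dimple_thickness(bulk: float = 4.0, depth: float = 0.4,
                              sigma: float = 2.0,
                              center: Tuple[float, float] = (0.0, 0.0)) -> Callable:
    """Thickness field bulk - depth * exp(-r^2 / (2 sigma^2)) around a centre.

    With the defaults this emulates a bilayer thinning from a 4.0 nm bulk
    to 3.6 nm at a protein docking site.
    """

    def f(x, y):
        r2 = (np.asarray(x, dtype=float) - center[0]) ** 2 + (np.asarray(y, dtype=float) - center[1]) ** 2
        return bulk - depth * np.exp(-r2 / (2.0 * sigma**2))

    return f


def make_bilayer_trajectory(spec: BilayerSpec, n_frames: int,
                            topo: LipidTopologyMap | None = None):
    """Generate a bilayer trajectory with prescribed surface fields.

    Lipids occupy a jittered lattice per leaflet; each frame re-draws a
    small lateral jitter and the phosphate z-noise from a per-frame
    sub-stream of the seed. Every lipid gets its phosphate bead(s), a
    glycerol headgroup bead 0.3 nm below the phosphate (toward the
    midplane) and two tail beads; cardiolipin gets two phosphates 0.3 nm
    apart. Returns ``(frames, topo)``.
    """
    lx, ly, lz = spec.box
    n = spec.n_lipids_per_leaflet
    n_side = int(np.ceil(np.sqrt(n)))
    if n_side * n_side < n:
        raise ValueError("lattice cannot hold the requested lipid count")
    spacing = min(lx, ly) / n_side
    types = sorted(spec.composition)
    if topo is None:
        topo = default_topology(types)

    ss = np.random.SeedSequence(spec.seed)
    root = np.random.default_rng(ss)
    # fixed per-lipid home sites and types (stable along the trajectory)
    home: Dict[str, np.ndarray] = {}
    type_of: Dict[str, np.ndarray] = {}
    for leaf in ("upper", "lower"):
        gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
        sites = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)[:n]
        sites = (sites + 0.5) * spacing
        sites += root.uniform(-0.3 * spacing, 0.3 * spacing, size=sites.shape)
        home[leaf] = np.mod(sites, [lx, ly])
        probs = [spec.composition[t] for t in types]
        type_of[leaf] = root.choice(len(types), size=n, p=probs)

    child_seeds = ss.spawn(n_frames)
    frames: List[Frame] = []
    for fi in range(n_frames):
        rng = np.random.default_rng(child_seeds[fi])
        indices, names, resnames, resids, chains, positions = [], [], [], [], [], []
        pid = 1
        rid = 1
        for leaf, sign in (("upper", 1.0), ("lower", -1.0)):
            xy = home[leaf] + rng.normal(0.0, 0.2, size=home[leaf].shape)
            xy = np.mod(xy, [lx, ly])
            # fields are defined on box-centred coordinates
            xc = xy[:, 0] - lx / 2.0
            yc = xy[:, 1] - ly / 2.0
            mid = spec.mid_surface(xc, yc)
            thick = spec.thickness_field(xc, yc)
            if np.any(thick <= 0):
                raise ValueError("thickness_field must be positive over the box")
            z_surf = mid + sign * thick / 2.0
            noise = rng.normal(0.0, spec.phosphate_noise_sd, size=n)
            for li in range(n):
                t = types[type_of[leaf][li]]
                zp = z_surf[li] + noise[li]
                x0, y0 = xy[li]
                phos = topo.phosphate_beads[t]
                for pi, pname in enumerate(phos):
                    indices.append(pid); names.append(pname); resnames.append(t)
                    resids.append(rid); chains.append("")
                    positions.append((np.mod(x0 + 0.3 * pi, lx), y0, zp))
                    pid += 1
                indices.append(pid); names.append("GL0"); resnames.append(t)
                resids.append(rid); chains.append("")
                positions.append((x0, y0, zp - sign * 0.3))
                pid += 1
                for ti, tname in enumerate(("C1A", "C2A")):
                    indices.append(pid); names.append(tname); resnames.append(t)
                    resids.append(rid); chains.append("")
                    positions.append((x0, y0, zp - sign * (0.8 + 0.5 * ti)))
                    pid += 1
                rid += 1
        frames.append(Frame(indices, names, resnames, resids, chains,
                            np.asarray(positions), spec.box, time=fi * 1000.0))
    return frames, topo


def make_protein_beads(tilt: float, n_beads: int = 22, helix_pitch: float = 0.54,
                       anchor: Sequence[float] = (0.0, 0.0, 0.0),
                       radius: float = 0.23, residue_start: int = 1,
                       box: Sequence[float] = (100.0, 100.0, 100.0)):
    """Helical bead cloud whose principal axis makes ``tilt`` deg with +z.

    An ideal alpha-helical backbone (3.6 beads per turn, rise
    ``helix_pitch``/3.6 per bead) is built with residue ids increasing
    bottom to top and rotated so that the principal axis of the finite bead
    cloud — not the nominal helix axis, which a discrete helix's phase-
    height coupling tilts by a fraction of a degree — makes exactly
    ``tilt`` degrees with +z. Returns ``(Frame, Selection)`` for the helix.
    """
    if not 0.0 <= tilt <= 180.0:
        raise ValueError("tilt must be in [0, 180] degrees")
    if n_beads < 4:
        raise ValueError("need at least 4 beads for a meaningful helix")
    k = np.arange(n_beads)
    rise = helix_pitch / 3.6
    theta = 2.0 * np.pi * k / 3.6
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * k])
    pts -= pts.mean(axis=0)
    # principal axis of the canonical cloud, oriented toward increasing k
    _evals, evecs = np.linalg.eigh(pts.T @ pts)
    a0 = evecs[:, -1]
    if np.dot(a0, pts[-1] - pts[0]) < 0:
        a0 = -a0
    target = np.array([np.sin(np.radians(tilt)), 0.0, np.cos(np.radians(tilt))])
    v = np.cross(a0, target)
    c = float(np.dot(a0, target))
    if c < -1.0 + 1e-8:
        # near-antipodal: rotate 180 deg about any axis perpendicular to a0
        perp = np.cross(a0, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a0, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        rot = 2.0 * np.outer(perp, perp) - np.eye(3)
    elif np.linalg.norm(v) < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    pts = pts @ rot.T + np.asarray(anchor, dtype=float)
    resids = residue_start + k
    frame = Frame(indices=1 + k, names=["BB"] * n_beads, residue_names=["HEL"] * n_beads,
                  residue_ids=resids, chains=["P"] * n_beads, positions=pts, box=box)
    sel = Selection(name="helix5", member_indices=frame.indices)
    return frame, sel


@dataclass
class TiltDynamicsSpec:
    """Prescribed tilt-angle dynamics for one replica.

    ``two_state_markov`` alternates between a toppled-band mean and a
    canonical mean with exponential dwell times set by ``transition_rates``
    (toppled->canonical, canonical->toppled, per ps); ``constant_noisy``
    adds Gaussian noise around ``mean_angles[0]``.
    """

    model: str = "two_state_markov"
    mean_angles: Tuple[float, float] = (90.0, 30.0)  # (toppled, canonical)
    angle_noise_sd: float = 5.0
    transition_rates: Tuple[float, float] = (1e-4, 1e-4)
    n_frames: int = 1000
    dt: float = 100.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("constant_noisy", "two_state_markov"):
            raise ValueError(f"unknown tilt model {self.model!r}")
        if any(r < 0 for r in self.transition_rates):
            raise ValueError("transition rates must be non-negative")
        for a in np.atleast_1d(self.mean_angles):
            if not 0 <= a <= 180:
                raise ValueError("mean angles must be in [0, 180]")

    @property
    def stationary_toppled_probability(self) -> float:
        k_tc, k_ct = self.transition_rates
        if k_tc + k_ct == 0:
            return 1.0
        return k_ct / (k_tc + k_ct)


def make_tilt_trajectory(spec: TiltDynamicsSpec, replica_id: str = "replica") -> TiltSeries:
    """Simulate one tilt-angle time series from the prescribed dynamics."""
    rng = np.random.default_rng(spec.seed)
    times = spec.dt * (1.0 + np.arange(spec.n_frames))
    if spec.model == "constant_noisy":
        mean = np.atleast_1d(spec.mean_angles)[0]
        angles = mean + rng.normal(0.0, spec.angle_noise_sd, size=spec.n_frames)
    else:
        k_tc, k_ct = spec.transition_rates
        p_leave = {0: 1.0 - np.exp(-k_tc * spec.dt), 1: 1.0 - np.exp(-k_ct * spec.dt)}
        # start from the stationary distribution
        state = 0 if rng.random() < spec.stationary_toppled_probability else 1
        states = np.empty(spec.n_frames, dtype=int)
        for i in range(spec.n_frames):
            states[i] = state
            if rng.random() < p_leave[state]:
                state = 1 - state
        means = np.asarray(spec.mean_angles)[states]
        angles = means + rng.normal(0.0, spec.angle_noise_sd, size=spec.n_frames)
    return TiltSeries(replica_id=replica_id, times=times,
                      angles=np.clip(angles, 0.0, 180.0))


def make_enriched_shell_frames(bulk_composition: Dict[str, float],
                               shell_composition: Dict[str, float],
                               n_shell: int = 25, n_bulk: int = 975,
                               n_frames: int = 200, seed: int = 0,
                               cutoff: float = 0.7,
                               box: Tuple[float, float, float] = (14.0, 14.0, 14.0)):
    """Frames with a prescribed annular-shell lipid composition.

    A four-bead dummy protein sits at the box centre among
    ``n_shell + n_bulk`` single-bead lipids whose types are fixed once with
    exact whole-system counts matching ``bulk_composition`` (lipid
    identities are stable along a trajectory, as in any MD output). Each
    frame, a multinomial draw from ``shell_composition`` decides how many
    molecules of each type sit inside the protein's contact shell; those
    molecules are moved within the cutoff, everything else to the far
    field (separation from the shell guaranteed to exceed the cutoff).
    Enrichment thus arises from molecules exchanging between shell and
    bulk, and the frames round-trip losslessly through the coordinate-only
    trajectory dialect. Returns ``(frames, topo, protein_selection)``.
    """
    for comp, lab in ((bulk_composition, "bulk"), (shell_composition, "shell")):
        if abs(sum(comp.values()) - 1.0) > 1e-6:
            raise ValueError(f"{lab} composition must sum to 1")
    if n_shell < 0 or n_bulk <= 0:
        raise ValueError("need n_bulk > 0 and n_shell >= 0")
    types = sorted(set(bulk_composition) | set(shell_composition))
    topo = LipidTopologyMap({t: t for t in types},
                            {t: ["HD0"] for t in types},
                            {t: ["HD0"] for t in types})
    box = np.asarray(box, dtype=float)
    center = box / 2.0
    prot_offsets = 0.15 * np.array([[1, 1, 1], [-1, -1, 1], [1, -1, -1], [-1, 1, -1]])
    prot_pos = center + prot_offsets
    r_far_min = 2.0 * cutoff + 0.3  # guaranteed separation from the shell
    if r_far_min > min(box) / 2.0 - 0.5:
        raise ValueError("box too small to host a bulk population outside the shell")

    # fixed molecule types: exact counts by largest remainder
    n_lip = n_shell + n_bulk
    fracs = np.array([bulk_composition.get(t, 0.0) for t in types])
    counts = np.floor(fracs * n_lip).astype(int)
    rem = fracs * n_lip - counts
    for i in np.argsort(-rem)[: n_lip - counts.sum()]:
        counts[i] += 1
    lipid_types: List[str] = []
    for t, c in zip(types, counts):
        lipid_types.extend([t] * int(c))
    rows_of_type = {t: np.array([i for i, lt in enumerate(lipid_types) if lt == t])
                    for t in types}
    shell_probs = np.array([shell_composition.get(t, 0.0) for t in types])

    ss = np.random.SeedSequence(seed)
    frames: List[Frame] = []
    names = ["P1", "P2", "P3", "P4"] + ["HD0"] * n_lip
    resnames = ["PRT"] * 4 + lipid_types
    resids = list(range(1, 5 + n_lip))
    chains = ["A"] * 4 + [""] * n_lip
    for fi, child in enumerate(ss.spawn(n_frames)):
        rng = np.random.default_rng(child)
        want = rng.multinomial(n_shell, shell_probs)
        shell_idx: List[int] = []
        for ti, t in enumerate(types):
            avail = rows_of_type[t]
            take = min(int(want[ti]), len(avail))
            if take < want[ti]:
                raise ValueError(
                    f"not enough {t} molecules ({len(avail)}) for the requested shell draw"
                )
            shell_idx.extend(rng.choice(avail, size=take, replace=False).tolist())
        shell_set = set(shell_idx)
        lipid_pos = np.empty((n_lip, 3))
        for li in shell_idx:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = rng.uniform(0.35, cutoff - 0.05)
            lipid_pos[li] = prot_pos[rng.integers(4)] + r * u
        far = [li for li in range(n_lip) if li not in shell_set]
        n_placed = 0
        while n_placed < len(far):
            cand = rng.uniform(0.0, box, size=(4 * (len(far) - n_placed), 3))
            keep = cand[np.linalg.norm(cand - center, axis=1) > r_far_min]
            keep = keep[: len(far) - n_placed]
            lipid_pos[far[n_placed:n_placed + len(keep)]] = keep
            n_placed += len(keep)
        positions = np.vstack([prot_pos, lipid_pos])
        frames.append(Frame(np.arange(1, 5 + n_lip), names, resnames, resids, chains,
                            positions, box, time=fi * 1000.0))
    protein_sel = Selection(name="protein", member_indices=np.arange(1, 5))
    return frames, topo, protein_sel


@dataclass
class PotentialSpec:
    """Umbrella windows Boltzmann-sampled from a closed-form potential.

    Defaults follow the published umbrella design: 51 windows spaced
    0.1 nm apart with K = 2500 kJ mol^-1 nm^-2 at 303 K.
    """

    potential: Callable = None  # U(x) in kJ/mol
    domain: Tuple[float, float] = (-2.6, 2.6)
    centers: Sequence[float] = None
    force_constant: float = 2500.0
    n_samples_per_window: int = 10_000
    temperature: float = 303.0
    seed: int = 0
    grid_resolution: float = 1e-3

    def __post_init__(self) -> None:
        if self.potential is None:
            self.potential = lambda x: 0.5 * 100.0 * np.asarray(x, dtype=float) ** 2
        if self.centers is None:
            self.centers = -2.5 + 0.1 * np.arange(51)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.domain[1] <= self.domain[0]:
            raise ValueError("domain must be an increasing interval")
        if np.any(self.centers < self.domain[0]) or np.any(self.centers > self.domain[1]):
            raise ValueError("window centers must lie inside the domain")


def harmonic_potential(k: float = 100.0) -> Callable:
    return lambda x: 0.5 * k * np.asarray(x, dtype=float) ** 2


def double_well_potential(barrier: float = 10.0) -> Callable:
    """U(x) = barrier * (x^2 - 1)^2: minima at +-1, barrier at x = 0."""
    return lambda x: barrier * (np.asarray(x, dtype=float) ** 2 - 1.0) ** 2


def make_umbrella_samples(spec: PotentialSpec) -> WindowSet:
    """Draw independent Boltzmann samples for each umbrella window.

    Sampling is exact inverse-CDF on a fine grid (resolution
    ``grid_resolution`` nm): samples are independent draws from the biased
    density proportional to exp(-[U(x) + K/2 (x - c)^2] / kT), so WHAM
    error theory applies cleanly.
    """
    kT = KB_KJ_MOL_K * spec.temperature
    x = np.arange(spec.domain[0], spec.domain[1] + spec.grid_resolution / 2,
                  spec.grid_resolution)
    U = np.asarray(spec.potential(x), dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("potential must be finite on the domain")
    ss = np.random.SeedSequence(spec.seed)
    windows: List[UmbrellaWindow] = []
    for c, child in zip(spec.centers, ss.spawn(len(spec.centers))):
        rng = np.random.default_rng(child)
        e = U + 0.5 * spec.force_constant * (x - c) ** 2
        logw = -(e - e.min()) / kT
        w = np.exp(logw)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
        if cdf[-1] <= 0:
            raise ValueError(f"window at {c}: biased density is numerically zero everywhere")
        cdf /= cdf[-1]
        u = rng.random(spec.n_samples_per_window)
        samples = np.interp(u, cdf, x)
        windows.append(UmbrellaWindow(center=float(c), force_constant=spec.force_constant,
                                      samples=samples,
                                      times=np.arange(len(samples), dtype=float)))
    return WindowSet(windows=windows, temperature=spec.temperature)
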