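"""Umbrella-sampling free-energy estimation along a 1-D reaction coordinate.

The reaction coordinate is the distance between the centres of mass of two
groups (EcfT and the bottom of the S-component in the original system).
Windows are biased by harmonic restraints U_i(x) = K/2 (x - c_i)^2; the
unbiased profile is recovered by the weighted histogram analysis method
(WHAM): on a grid of bins x_j with pooled counts H_j, window sample counts
N_i and biases b_ij = exp(-beta U_i(x_j)), solve self-consistently

    p_j = H_j / sum_i N_i exp(beta f_i) b_ij,
    exp(-beta f_i) = sum_j b_ij p_j,

then F_j = -kT ln p_j anchored at the profile minimum. The solver runs a
quasi-Newton minimisation of the equivalent convex likelihood to get close,
then successive substitution down to the requested fixed-point tolerance
(same fixed point either way). Error bars come from a moving-block
bootstrap over each window's sample series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .frames import Frame, Selection
from .geometry import center_of_mass, minimum_image_distance

logger = logging.getLogger(__name__)

__all__ = [
    "KB_KJ_MOL_K",
    "UmbrellaWindow",
    "WindowSet",
    "PMFProfile",
    "reaction_coordinate",
    "validate_windows",
    "WhamEstimator",
    "wham",
    "bootstrap_pmf",
]

KB_KJ_MOL_K = 0.0083144621  # Boltzmann constant, kJ mol^-1 K^-1


@dataclass
class UmbrellaWindow:
    """One umbrella window: restraint parameters and biased samples (nm)."""

    center: float
    force_constant: float  # kJ mol^-1 nm^-2
    samples: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if self.samples.size == 0:
            raise ValueError(f"window at {self.center}: no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"window at {self.center}: non-finite samples")

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(x) - self.center) ** 2


@dataclass
class WindowSet:
    """An ordered set of umbrella windows at one temperature."""

    windows: List[UmbrellaWindow]
    temperature: float  # K

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("window set is empty")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        centers = np.array([w.center for w in self.windows])
        if np.any(np.diff(centers) <= 0):
            raise ValueError("window centers must be strictly increasing")

    @property
    def kT(self) -> float:
        return KB_KJ_MOL_K * self.temperature

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class PMFProfile:
    """Anchored free-energy profile with bootstrap errors (kJ mol^-1)."""

    bin_centers: np.ndarray
    free_energy: np.ndarray  # NaN for unoccupied bins
    errors: np.ndarray
    reference: int  # bin index where F = 0
    window_offsets: np.ndarray  # f_i, kJ mol^-1 (gauge: f_0 = 0)


def reaction_coordinate(frame: Frame, ecf_t_sel: Selection, s_bottom_sel: Selection,
                        masses: Mapping[str, float] | None = None) -> float:
    """COM-COM distance (nm) between two groups, minimum image on the
    COM difference. Groups must be whole (unwrap first if split)."""
    com_a = center_of_mass(frame, ecf_t_sel, masses)
    com_b = center_of_mass(frame, s_bottom_sel, masses)
    return float(minimum_image_distance(com_a, com_b, frame.box))


# ---------------------------------------------------------------------------
# WHAM internals


def _make_bins(ws: WindowSet, bin_width: float):
    lo = min(w.samples.min() for w in ws.windows)
    hi = max(w.samples.max() for w in ws.windows)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def validate_windows(ws: WindowSet, bin_width: float = 0.02) -> List[Dict]:
    """Sanity-check umbrella windows before WHAM.

    Reports per-window sample count, mean deviation from the restraint
    centre and sample SD, plus the number of histogram bins each adjacent
    pair shares. Raises if any adjacent pair shares zero occupied bins
    (WHAM cannot connect the windows across such a gap).
    """
    edges, _ = _make_bins(ws, bin_width)
    occupied = [np.histogram(w.samples, bins=edges)[0] > 0 for w in ws.windows]
    report: List[Dict] = []
    for i, w in enumerate(ws.windows):
        entry = {
            "center": w.center,
            "n_samples": int(w.samples.size),
            "mean_minus_center": float(w.samples.mean() - w.center),
            "sample_sd": float(w.samples.std(ddof=0)),
            "overlap_next": None,
        }
        if i + 1 < len(ws.windows):
            shared = int(np.sum(occupied[i] & occupied[i + 1]))
            entry["overlap_next"] = shared
            if shared == 0:
                raise ValueError(
                    f"windows {i} (center {w.center}) and {i + 1} "
                    f"(center {ws.windows[i + 1].center}) share no occupied bins; "
                    "the sampled ranges do not overlap"
                )
        report.append(entry)
    if len(ws.windows) == 1:
        logger.warning("single umbrella window: the PMF shape is restraint-dominated")
    return report


def _wham_solve(H: np.ndarray, logN: np.ndarray, logB: np.ndarray, kT: float,
                tol: float, max_iter: int, g0: np.ndarray | None = None,
                method: str = "hybrid"):
    """Solve the WHAM equations for log window weights g_i = beta f_i.

    Returns (g, log_p, n_iter) with g gauge-fixed to g[0] = 0 and log_p the
    normalised unbiased log-probabilities over occupied bins.
    """
    occ = H > 0
    logH = np.log(H[occ])
    lB = logB[:, occ]  # (n_win, n_occ)
    n_win = len(logN)
    g = np.zeros(n_win) if g0 is None else g0.astype(float).copy()

    def log_p_of(g):
        logD = logsumexp(logN[:, None] + g[:, None] + lB, axis=0)
        lp = logH - logD
        return lp - logsumexp(lp)

    if method not in ("hybrid", "iterative"):
        raise ValueError(f"method must be 'hybrid' or 'iterative', got {method!r}")

    if method == "hybrid":
        # convex negative log-likelihood in g (gauge direction is flat)
        def obj(g):
            M = logN[:, None] + g[:, None] + lB
            logD = logsumexp(M, axis=0)
            val = float(np.sum(H[occ] * logD) - np.sum(np.exp(logN) * g))
            W = np.exp(M - logD)  # (n_win, n_occ)
            grad = W @ H[occ] - np.exp(logN)
            return val, grad

        res = minimize(obj, g, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
        g = res.x

    # successive substitution to the stated fixed-point tolerance
    beta_tol = tol / kT
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lp = log_p_of(g)
        g_new = -logsumexp(lB + lp[None, :], axis=1)
        g_new -= g_new[0]
        delta = np.max(np.abs(g_new - (g - g[0])))
        g = g_new
        if delta < beta_tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max |delta f| = {delta * kT:.3g} kJ/mol)"
        )
    if n_iter == max_iter and delta >= beta_tol:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max |delta f| = {delta * kT:.3g} kJ/mol)"
        )
    return g, log_p_of(g), n_iter


def _profile_from_logp(log_p: np.ndarray, occ: np.ndarray, centers: np.ndarray,
                       kT: float, anchor: str, radial_correction: bool):
    F = np.full(len(centers), np.nan)
    F[occ] = -kT * log_p
    if radial_correction:
        F[occ] = F[occ] - 2.0 * kT * np.log(centers[occ])
    finite = np.where(np.isfinite(F))[0]
    if anchor == "min":
        ref = int(finite[np.argmin(F[finite])])
    elif anchor == "left":
        ref = int(finite[0])
    elif anchor == "right":
        ref = int(finite[-1])
    else:
        raise ValueError(f"anchor must be 'min', 'left' or 'right', got {anchor!r}")
    F -= F[ref]
    return F, ref


class WhamEstimator(BaseEstimator):
    """WHAM estimator for a 1-D potential of mean force.

    Parameters
    ----------
    bin_width : float
        Histogram bin width, nm (default 0.02).
    tol : float
        Fixed-point tolerance on the window free energies, kJ/mol (1e-7).
    max_iter : int
        Iteration cap for the successive-substitution stage (default 1e6).
    method : {"hybrid", "iterative"}
        "hybrid" (default) warm-starts with a quasi-Newton minimisation of
        the equivalent convex likelihood; both converge to the same fixed
        point at ``tol``.
    anchor : {"min", "left", "right"}
        Where the free energy is set to zero (default: profile minimum).
    radial_correction : bool
        Apply the -2 kT ln(x) Jacobian correction for a distance coordinate
        (off by default).
    n_boot : int
        Moving-block bootstrap replicates for error bars (0 disables).
    block : int or "auto"
        Bootstrap block length; "auto" uses the integrated autocorrelation
        time of each window (minimum 1).
    seed : int or None
        Seed for the bootstrap resampling (fixed seed => identical errors).

    Attributes
    ----------
    bin_centers_, free_energy_, errors_ : ndarray
    reference_ : int
    window_offsets_ : ndarray (f_i in kJ/mol, f_0 = 0)
    n_iter_ : int
    profile_ : PMFProfile
    """

    def __init__(self, bin_width: float = 0.02, tol: float = 1e-7,
                 max_iter: int = 1_000_000, method: str = "hybrid",
                 anchor: str = "min", radial_correction: bool = False,
                 n_boot: int = 0, block="auto", seed: int | None = None) -> None:
        self.bin_width = bin_width
        self.tol = tol
        self.max_iter = max_iter
        self.method = method
        self.anchor = anchor
        self.radial_correction = radial_correction
        self.n_boot = n_boot
        self.block = block
        self.seed = seed

    def _setup(self, ws: WindowSet):
        edges, centers = _make_bins(ws, self.bin_width)
        logN = np.log(np.array([w.samples.size for w in ws.windows], dtype=float))
        biases = np.stack([w.bias(centers) for w in ws.windows])  # (n_win, n_bins)
        logB = -biases / ws.kT
        return edges, centers, logN, logB

    def fit(self, ws: WindowSet) -> "WhamEstimator":
        validate_windows(ws, bin_width=self.bin_width)
        edges, centers, logN, logB = self._setup(ws)
        H = np.zeros(len(centers))
        for w in ws.windows:
            H += np.histogram(w.samples, bins=edges)[0]
        g, log_p, n_iter = _wham_solve(H, logN, logB, ws.kT, self.tol,
                                       self.max_iter, method=self.method)
        occ = H > 0
        F, ref = _profile_from_logp(log_p, occ, centers, ws.kT,
                                    self.anchor, self.radial_correction)
        errors = np.full(len(centers), np.nan)
        if self.n_boot:
            errors = self._bootstrap(ws, edges, centers, logN, logB, g)
        self.bin_centers_ = centers
        self.free_energy_ = F
        self.errors_ = errors
        self.reference_ = ref
        self.window_offsets_ = g * ws.kT
        self.n_iter_ = n_iter
        self.profile_ = PMFProfile(centers, F, errors, ref, g * ws.kT)
        return self

    # -- bootstrap ---------------------------------------------------------

    @staticmethod
    def _block_length(samples: np.ndarray) -> int:
        """Block length from the integrated autocorrelation time.

        tau = 1 + 2 sum rho_k, summed until the first non-positive
        autocorrelation (initial-positive-sequence truncation); white noise
        gives tau ~ 1.
        """
        x = samples - samples.mean()
        n = len(x)
        if n < 4 or np.allclose(x, 0):
            return 1
        acov = np.correlate(x, x, mode="full")[n - 1:] / n
        if acov[0] <= 0:
            return 1
        rho = acov / acov[0]
        tau = 1.0
        for k in range(1, min(n // 2, 1000)):
            if rho[k] <= 0:
                break
            tau += 2.0 * rho[k]
        return max(1, int(np.ceil(tau)))

    def _bootstrap(self, ws: WindowSet, edges, centers, logN, logB,
                   g_full: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        blocks = []
        for w in ws.windows:
            b = self._block_length(w.samples) if self.block == "auto" else int(self.block)
            blocks.append(min(max(1, b), len(w.samples)))
        occ_template = None
        profiles = []
        n_failed = 0
        for _rep in range(self.n_boot):
            H = np.zeros(len(centers))
            for w, b in zip(ws.windows, blocks):
                n = len(w.samples)
                n_blocks = int(np.ceil(n / b))
                starts = rng.integers(0, n - b + 1, size=n_blocks)
                idx = (starts[:, None] + np.arange(b)[None, :]).ravel()[:n]
                H += np.histogram(w.samples[idx], bins=edges)[0]
            try:
                _g, log_p, _it = _wham_solve(H, logN, logB, ws.kT, self.tol,
                                             self.max_iter, g0=g_full,
                                             method=self.method)
            except RuntimeError:
                n_failed += 1
                continue
            occ = H > 0
            F, _ref = _profile_from_logp(log_p, occ, centers, ws.kT,
                                         self.anchor, self.radial_correction)
            profiles.append(F)
            occ_template = occ if occ_template is None else occ_template
        if n_failed > 0.1 * self.n_boot:
            raise RuntimeError(
                f"{n_failed}/{self.n_boot} bootstrap replicates failed to converge"
            )
        if n_failed:
            logger.warning("dropped %d non-convergent bootstrap replicates", n_failed)
        P = np.array(profiles)
        n_ok = np.sum(np.isfinite(P), axis=0)
        sd = np.full(P.shape[1], np.nan)
        # bins present in fewer than half the replicates carry no error bar
        enough = n_ok >= max(2, len(profiles) // 2)
        with np.errstate(invalid="ignore"):
            sd[enough] = np.nanstd(P[:, enough], axis=0, ddof=1)
        return sd


def wham(ws: WindowSet, bin_width: float = 0.02, tol: float = 1e-7,
         max_iter: int = 1_000_000, **kwargs) -> PMFProfile:
    """Estimate the PMF from a window set (thin wrapper over WhamEstimator)."""
    est = WhamEstimator(bin_width=bin_width, tol=tol, max_iter=max_iter, **kwargs)
    return est.fit(ws).profile_


def bootstrap_pmf(ws: WindowSet, wham_params: Mapping | None = None,
                  n_boot: int = 200, block="auto", seed: int = 0) -> np.ndarray:
    """Per-bin bootstrap SD of the anchored PMF (moving-block resampling)."""
    params = dict(wham_params or {})
    est = WhamEstimator(n_boot=n_boot, block=block, seed=seed, **params)
    return est.fit(ws).errors_
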