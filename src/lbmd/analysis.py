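"""Observables: distributions, thickness, RDF, diffusion, shape, transport.

Trajectories are plain arrays of shape (n_frames, n_beads, 3) in Å
(unwrapped where diffusion is measured), with a frame spacing in ns
supplied by the caller.  Estimators are invariant under rigid
translations and box wrapping of their input, and every nontrivial
one is validated against an independent oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import periodogram
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)


# ======================================================================
# shape: gyration tensor
# ======================================================================
@dataclass
class GyrationResult:
    """Ordered eigenvalues λ1 ≥ λ2 ≥ λ3 (Å²) and eigenvectors of a
    mass-weighted gyration tensor snapshot."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    degenerate: bool = False

    @property
    def rg2(self) -> float:
        return float(np.sum(self.eigenvalues))


def gyration_tensor(positions: np.ndarray, masses: np.ndarray = None,
                    degeneracy_rtol: float = 1e-6) -> GyrationResult:
    """Eigen-decomposition of the second-moment tensor about the CoM."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        raise ValueError("gyration tensor needs at least 2 particles")
    m = np.ones(len(positions)) if masses is None else np.asarray(masses, dtype=float)
    com = np.average(positions, axis=0, weights=m)
    d = positions - com
    S = (m[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / m.sum()
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(vals[0], 1e-300)
    degen = bool(np.min(np.abs(np.diff(vals))) < degeneracy_rtol * scale)
    if degen:
        log.warning("near-degenerate gyration eigenvalues: eigenvectors unstable")
    return GyrationResult(vals, vecs, degen)


def gyration_dynamics(trajectory: np.ndarray, masses: np.ndarray = None,
                      tracked_bead: Optional[int] = None):
    """Per-frame gyration eigenvalues and z-projections.

    Returns a dict of time series: eigenvalues (T, 3), the absolute
    z-projection |Λ⁽³⁾·ẑ| of the smallest-eigenvalue axis, and, if a
    tracked bead index is given, |v̂·ẑ| for the vector from that bead
    to the instantaneous centre of mass.  For degenerate frames the
    reported projection is that of the degenerate subspace.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    T = len(trajectory)
    eigs = np.empty((T, 3))
    proj3 = np.empty(T)
    projv = np.empty(T) if tracked_bead is not None else None
    zhat = np.array([0.0, 0.0, 1.0])
    for t in range(T):
        res = gyration_tensor(trajectory[t], masses)
        eigs[t] = res.eigenvalues
        if res.degenerate:
            # subspace projection of ẑ onto the two degenerate minor axes
            sub = res.eigenvectors[:, 1:]
            proj3[t] = float(np.linalg.norm(sub.T @ zhat))
        else:
            proj3[t] = abs(float(res.eigenvectors[:, 2] @ zhat))
        if tracked_bead is not None:
            m = np.ones(trajectory.shape[1]) if masses is None else masses
            com = np.average(trajectory[t], axis=0, weights=m)
            v = trajectory[t, tracked_bead] - com
            projv[t] = abs(v[2] / np.linalg.norm(v))
    out = {"eigenvalues": eigs, "proj_axis3": proj3}
    if projv is not None:
        out["proj_tracked"] = projv
    return out


def oscillation_period(series: np.ndarray, dt: float,
                       significance: float = 5.0) -> Optional[float]:
    """Dominant period (same time unit as ``dt``) via the spectral peak
    of the detrended series; None (with a log diagnostic) if no peak
    stands out above ``significance`` × the median spectral power."""
    series = np.asarray(series, dtype=float)
    x = series - np.polyval(np.polyfit(np.arange(len(series)), series, 1),
                            np.arange(len(series)))
    freqs, power = periodogram(x, fs=1.0 / dt)
    freqs, power = freqs[1:], power[1:]
    peak = int(np.argmax(power))
    med = np.median(power)
    if med > 0 and power[peak] < significance * med:
        log.info("no significant spectral peak (peak/median = %.2f)",
                 power[peak] / med)
        return None
    return float(1.0 / freqs[peak])


# ======================================================================
# structure: distributions, thickness, rdf
# ======================================================================
def _normalized_hist(values, bins):
    hist, edges = np.histogram(values, bins=bins, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, hist


def bonded_distributions(trajectory: np.ndarray, topology, box,
                         bond_bin: float = 0.02, angle_bin: float = 1.0,
                         charges: np.ndarray = None,
                         charge_rmax: float = 12.0
                         ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Probability densities of bond lengths, angles, and charged-bead
    distances, grouped by unique term type.

    Each histogram is a normalized density (unit integral).  With
    per-bead ``charges``, distances between all charged bead pairs
    (within ``charge_rmax``, minimum-image) are histogrammed per
    type pair as well.  Needs a reasonably long trajectory (≥ 1000
    frames recommended) for smooth densities.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    box = np.asarray(box, dtype=float)
    if trajectory.ndim == 2:
        trajectory = trajectory[None]
    if len(trajectory) < 1000:
        log.warning("only %d frames: distributions will be noisy", len(trajectory))
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    def mic(d):
        return d - box * np.round(d / box)

    by_type: Dict[str, list] = {}
    for t in topology.bonds:
        key = f"bond_{topology.type_names[t.i]}-{topology.type_names[t.j]}"
        by_type.setdefault(key, []).append((t.i, t.j))
    for key, pairs in by_type.items():
        idx = np.array(pairs)
        d = mic(trajectory[:, idx[:, 0]] - trajectory[:, idx[:, 1]])
        r = np.linalg.norm(d, axis=-1).ravel()
        bins = np.arange(max(r.min() - 0.2, 0.0), r.max() + 0.2, bond_bin)
        out[key] = _normalized_hist(r, bins)

    by_type = {}
    for t in topology.angles:
        key = (f"angle_{topology.type_names[t.i]}-"
               f"{topology.type_names[t.j]}-{topology.type_names[t.k]}")
        by_type.setdefault(key, []).append((t.i, t.j, t.k))
    for key, triples in by_type.items():
        idx = np.array(triples)
        a = mic(trajectory[:, idx[:, 0]] - trajectory[:, idx[:, 1]])
        b = mic(trajectory[:, idx[:, 2]] - trajectory[:, idx[:, 1]])
        cos = np.sum(a * b, axis=-1) / (np.linalg.norm(a, axis=-1)
                                        * np.linalg.norm(b, axis=-1))
        th = np.degrees(np.arccos(np.clip(cos, -1, 1))).ravel()
        out[key] = _normalized_hist(th, np.arange(0, 180 + angle_bin, angle_bin))

    if charges is not None:
        charged = np.flatnonzero(np.asarray(charges) != 0.0)
        if len(charged) == 0:
            raise ValueError("no charged beads in selection")
        ii, jj = np.triu_indices(len(charged), k=1)
        pi, pj = charged[ii], charged[jj]
        names = np.array(topology.type_names)
        pair_key = np.array(["-".join(sorted((a, b)))
                             for a, b in zip(names[pi], names[pj])])
        d = mic(trajectory[:, pi] - trajectory[:, pj])
        r = np.linalg.norm(d, axis=-1)
        for key in np.unique(pair_key):
            vals = r[:, pair_key == key].ravel()
            vals = vals[vals <= charge_rmax]
            if len(vals):
                bins = np.arange(0.0, charge_rmax + bond_bin, 5 * bond_bin)
                out[f"charged_{key}"] = _normalized_hist(vals, bins)
    return out


def membrane_thickness(positions: np.ndarray, phosphate_mask,
                       fit_normal: bool = False) -> float:
    """Phosphate-plane to phosphate-plane distance of a planar membrane.

    Leaflets are assigned by the sign of the (normal-projected)
    coordinate relative to the membrane mid-plane; with ``fit_normal``
    the normal comes from the smallest principal axis of the phosphate
    cloud (for tilted membranes) instead of ẑ.
    """
    p = np.asarray(positions, dtype=float)[np.asarray(phosphate_mask)]
    if fit_normal:
        c = p - p.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        normal = vt[2]
    else:
        normal = np.array([0.0, 0.0, 1.0])
    proj = p @ normal
    mid = np.median(proj)
    upper, lower = proj[proj > mid], proj[proj <= mid]
    t = float(abs(upper.mean() - lower.mean()))
    if t < 5.0:
        raise ValueError("leaflet assignment ambiguous (separation < 5 Å)")
    return t


def rdf(frames: np.ndarray, box, selection=None, r_max: float = 15.0,
        bins: int = 75) -> Tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r), PBC-aware, normalized by
    ideal-gas shell counts."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    box = np.asarray(box, dtype=float)
    if np.any(box < 2 * r_max):
        raise ValueError("box must be at least 2·r_max in each dimension")
    edges = np.linspace(0.0, r_max, bins + 1)
    counts = np.zeros(bins)
    sel = slice(None) if selection is None else np.asarray(selection)
    n_frames = len(frames)
    n = None
    for fr in frames:
        pos = fr[sel]
        n = len(pos)
        wrapped = np.mod(pos, box)
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs) == 0:
            continue
        d = wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]]
        d -= box * np.round(d / box)
        counts += np.histogram(np.linalg.norm(d, axis=1), bins=edges)[0]
    vol = float(np.prod(box))
    rho = n / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = 0.5 * n * rho * shell * n_frames
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, counts / ideal


# ======================================================================
# diffusion
# ======================================================================
@dataclass
class DiffusionFit:
    """Per-system lateral diffusion estimate with block statistics."""

    D: float  # Å²/ns
    stderr: float
    block_values: np.ndarray
    block_len: float = 100.0  # ns
    fit_window: Tuple[float, float] = (20.0, 40.0)  # ns
    linear: bool = True


def msd2d(positions: np.ndarray, dt: float, max_lag: Optional[int] = None):
    """In-plane (xy) MSD vs lag time, averaged over origins and particles."""
    xy = np.asarray(positions, dtype=float)[..., :2]
    T = len(xy)
    max_lag = max_lag or T - 1
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    for li, lag in enumerate(lags):
        d = xy[lag:] - xy[:-lag]
        msd[li] = np.mean(np.sum(d**2, axis=-1))
    return lags * dt, msd


def msd2d_block(positions: np.ndarray, dt: float, block_len: float = 100.0,
                fit_window: Tuple[float, float] = (20.0, 40.0),
                leaflet_masks: Optional[Sequence[np.ndarray]] = None,
                exponent_tol: float = 0.3) -> DiffusionFit:
    """Block-averaged lateral diffusion coefficient.

    The (unwrapped) trajectory is divided into independent blocks of
    ``block_len`` (ns); in each block D comes from a linear fit of the
    2D MSD inside ``fit_window``, D = slope/4, and the reported value
    is the block mean with its standard error.  Per-leaflet
    centre-of-mass drift is removed frame by frame when leaflet masks
    are given.  Anomalous transport in the window (log-log MSD slope
    far from 1, e.g. ballistic motion) is flagged with
    ``linear=False`` and a warning.
    """
    pos = np.asarray(positions, dtype=float).copy()
    if fit_window[1] > block_len:
        raise ValueError("fit window exceeds block length")
    if leaflet_masks is not None:
        for mask in leaflet_masks:
            com = pos[:, mask, :].mean(axis=1, keepdims=True)
            pos[:, mask, :] -= com - com[0]
    frames_per_block = int(round(block_len / dt))
    n_blocks = len(pos) // frames_per_block
    if n_blocks < 2:
        raise ValueError("trajectory shorter than 2 blocks")
    lo, hi = (int(round(fit_window[0] / dt)), int(round(fit_window[1] / dt)))
    Ds, exps = [], []
    for b in range(n_blocks):
        chunk = pos[b * frames_per_block:(b + 1) * frames_per_block]
        t, msd = msd2d(chunk, dt, max_lag=hi)
        tw, mw = t[lo - 1:hi], msd[lo - 1:hi]
        slope, _ = np.polyfit(tw, mw, 1)
        Ds.append(slope / 4.0)
        if np.all(mw > 0):
            exps.append(np.polyfit(np.log(tw), np.log(mw), 1)[0])
        else:
            exps.append(1.0 if np.allclose(mw, 0) else np.nan)
    Ds = np.array(Ds)
    alpha = float(np.nanmedian(exps))
    linear = bool(abs(alpha - 1.0) <= exponent_tol)
    if not linear:
        log.warning("MSD exponent %.2f deviates from diffusive: D unreliable",
                    alpha)
    stderr = float(Ds.std(ddof=1) / np.sqrt(len(Ds))) if len(Ds) > 1 else float("nan")
    if len(Ds) < 3:
        log.warning("fewer than 3 blocks: standard error unreliable")
    return DiffusionFit(float(Ds.mean()), stderr, Ds, block_len, fit_window, linear)


# ----- finite-size models ---------------------------------------------
ERG_PER_K = 1.380649e-16  # Boltzmann constant, erg/K
CM = 1e-8  # Å → cm


def periodic_sd_diffusion(L: float, eta_m: float, eta_f: float = 0.01,
                          b: float = 2.87e5, H: float = 240.0,
                          lipid_radius: float = 5.0,
                          temperature: float = 310.0) -> float:
    """Truncated-sum periodic membrane-hydrodynamics model of D(L).

    A tracer in a periodic membrane patch of lateral size L (Å)
    embedded in bulk fluid with transverse repeat distance H feels the
    in-plane mobility summed over the nonzero box wavevectors k:

        D = k_B T / (2 L²) Σ_k  ½ [Λs(k) + Λa(k)],
        Λs = 1 / (η_m k² + 2 η_f k coth(kH/2)),
        Λa = 1 / (η_m k² + 2 η_f k coth(kH/2) + 4 b),

    with membrane surface viscosity η_m (P·cm), bulk viscosity η_f
    (P), intermonolayer friction b (P/cm) damping the
    leaflet-antisymmetric modes, and the sum truncated at the inverse
    lipid size k_max = π/R.  D grows logarithmically with L, the
    finite-size signature of membrane hydrodynamics under PBC.
    Returns D in Å²/ns.
    """
    L_cm = L * CM
    H_cm = H * CM
    kmax = np.pi / (lipid_radius * CM)
    dk = 2.0 * np.pi / L_cm
    nmax = int(kmax / dk) + 1
    n = np.arange(-nmax, nmax + 1)
    kx, ky = np.meshgrid(n * dk, n * dk, indexing="ij")
    k = np.sqrt(kx**2 + ky**2)
    mask = (k > 0) & (k <= kmax)
    k = k[mask]
    bulk = 2.0 * eta_f * k / np.tanh(0.5 * k * H_cm)
    lam_s = 1.0 / (eta_m * k**2 + bulk)
    lam_a = 1.0 / (eta_m * k**2 + bulk + 4.0 * b)
    mob = 0.5 * np.sum(0.5 * (lam_s + lam_a)) / L_cm**2  # s/g
    D_cm2_s = ERG_PER_K * temperature * mob
    return D_cm2_s / CM**2 * 1e-9  # Å²/ns


def diffusion_size_fit(L: np.ndarray, D: np.ndarray, model: str = "loglinear",
                       errors: Optional[np.ndarray] = None, **model_kwargs):
    """Fit D(L) across box sizes.

    ``loglinear`` fits D = a + c·ln L (the asymptotic form of the
    periodic hydrodynamic model) by weighted least squares and returns
    (a, c).  ``periodic_sd`` fits the truncated-sum model with free
    membrane surface viscosity η_m (bulk viscosity and interleaflet
    friction held fixed at the supplied values).
    """
    L = np.asarray(L, dtype=float)
    D = np.asarray(D, dtype=float)
    if len(L) < 3:
        raise ValueError("need at least 3 box sizes")
    order = np.argsort(L)
    if errors is not None:
        err = np.asarray(errors, dtype=float)[order]
        drop = np.diff(D[order])
        if np.any(drop < -2 * np.hypot(err[1:], err[:-1])):
            log.warning("D(L) non-monotone beyond error bars")
    w = None if errors is None else 1.0 / np.asarray(errors, dtype=float)
    if model == "loglinear":
        X = np.column_stack([np.ones_like(L), np.log(L)])
        if w is not None:
            X = X * w[:, None]
            y = D * w
        else:
            y = D
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return {"a": float(coef[0]), "c": float(coef[1])}
    if model == "periodic_sd":
        fixed = dict(model_kwargs)
        eta0 = fixed.pop("eta_m0", 5e-8)

        def resid(p):
            pred = np.array([periodic_sd_diffusion(l, p[0], **fixed) for l in L])
            r = pred - D
            return r if w is None else r * w

        sol = least_squares(resid, x0=[eta0], bounds=([1e-12], [1e-3]))
        return {"eta_m": float(sol.x[0])}
    raise ValueError(f"unknown model {model!r}")


# ======================================================================
# transport: adsorption, localisation, release
# ======================================================================
def min_surface_distance(trajectory: np.ndarray, probe_mask, membrane_mask,
                         box, bead_radius: float = 2.35,
                         contact_threshold: float = 5.0,
                         dt: float = None, sustain: float = 1.0):
    """Minimal distance of a probe's CoM to the membrane surface beads.

    Per frame: min over surface beads of |probe CoM − bead| − bead
    radius, minimum-image.  If ``dt`` (ns/frame) is given, also
    returns the adsorption time: the first crossing below the contact
    threshold sustained for at least ``sustain`` ns (None if never).
    """
    trajectory = np.asarray(trajectory, dtype=float)
    box = np.asarray(box, dtype=float)
    probe_mask = np.asarray(probe_mask)
    membrane_mask = np.asarray(membrane_mask)
    series = np.empty(len(trajectory))
    for t, fr in enumerate(trajectory):
        com = fr[probe_mask].mean(axis=0)
        d = fr[membrane_mask] - com
        d -= box * np.round(d / box)
        series[t] = np.min(np.linalg.norm(d, axis=1)) - bead_radius
    if dt is None:
        return series
    need = max(1, int(round(sustain / dt)))
    below = series < contact_threshold
    run = 0
    for t, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= need:
            return series, (t - need + 1) * dt
    return series, None


def radial_localisation(trajectory: np.ndarray, selections: Dict[str, np.ndarray],
                        centre, r_max: float = None, bins: int = 60,
                        mol_index: np.ndarray = None):
    """Shell-volume-corrected densities of cargo CoM distances from the
    vesicle centre, one per species selection.

    Returns {name: (r, ρ(r))} with ∫ ρ 4πr² dr = 1, so uniformly
    distributed cargo gives a flat ρ(r).
    """
    trajectory = np.asarray(trajectory, dtype=float)
    centre = np.asarray(centre, dtype=float)
    out = {}
    for name, sel in selections.items():
        sel = np.asarray(sel)
        if mol_index is not None:
            mols = np.unique(mol_index[sel])
            coms = np.stack([
                trajectory[:, sel[mol_index[sel] == m]].mean(axis=1) for m in mols
            ], axis=1)
        else:
            coms = trajectory[:, sel]
        r = np.linalg.norm(coms - centre, axis=-1).ravel()
        rmax = r_max or (r.max() * 1.05 + 1e-9)
        edges = np.linspace(0, rmax, bins + 1)
        hist, _ = np.histogram(r, bins=edges)
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        dens = hist / (shell * len(r))
        centers = 0.5 * (edges[1:] + edges[:-1])
        out[name] = (centers, dens)
    return out


def release_trace(trajectory: np.ndarray, substrate_indices: List[np.ndarray],
                  centre, outer_radius: float, dt: float,
                  margin: float = 10.0, sustain: float = 1.0):
    """Per-substrate distance-to-vesicle-centre traces and release times.

    A substrate is released at the first frame its CoM exceeds
    (outer radius + margin) and stays outside for ``sustain`` ns (or
    until the trajectory ends).
    """
    trajectory = np.asarray(trajectory, dtype=float)
    centre = np.asarray(centre, dtype=float)
    need = max(1, int(round(sustain / dt)))
    traces, times = [], []
    for sel in substrate_indices:
        com = trajectory[:, np.asarray(sel)].mean(axis=1)
        r = np.linalg.norm(com - centre, axis=1)
        traces.append(r)
        outside = r > outer_radius + margin
        release = None
        run = 0
        for t, flag in enumerate(outside):
            run = run + 1 if flag else 0
            if run >= need:
                release = (t - run + 1) * dt
                break
        else:
            if run > 0 and outside[-1]:
                release = (len(outside) - run) * dt
        times.append(release)
    return np.array(traces), times
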