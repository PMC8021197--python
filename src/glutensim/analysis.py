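"""Observables: contacts, mobility, shape, rheology, entanglements, cavities.

Everything here consumes the protocol's :class:`~glutensim.protocol.Snapshot`
and time-series records (or plain arrays) and returns plain numbers, so
the functions are equally usable on simulation output and on constructed
test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import units
from .forcefield import KIND_STATIC

# ---------------------------------------------------------------------------
# unwrapping helpers (X/Y are periodic; chains must be made whole first)


def unwrap_chain(positions: np.ndarray, box) -> np.ndarray:
    """Rebuild a chain as a continuous curve by walking min-image bonds."""
    steps = box.min_image(np.diff(positions, axis=0))
    out = np.empty_like(positions)
    out[0] = positions[0]
    out[1:] = positions[0] + np.cumsum(steps, axis=0)
    return out


def unwrap_trajectory(frames: np.ndarray, box) -> np.ndarray:
    """Make per-bead trajectories continuous in time across the X/Y wrap."""
    frames = np.asarray(frames, dtype=float)
    steps = box.min_image(np.diff(frames, axis=0))
    out = np.empty_like(frames)
    out[0] = frames[0]
    out[1:] = frames[0] + np.cumsum(steps, axis=0)
    return out


# ---------------------------------------------------------------------------
# contact bookkeeping


def _active_contact_mask(snap, f_cut: float = 1.5) -> np.ndarray:
    """A contact is 'made' if it is switching on or fully on.

    Static pairs never switch off, so they count only while the beads
    are within the same r < f_cut * sigma criterion that governs the
    dynamic contacts.
    """
    made = snap.contact_lambdas > 0.0
    static = snap.contact_kinds == KIND_STATIC
    if np.any(static):
        pairs = snap.contact_pairs[static]
        d = snap.box.min_image(snap.positions[pairs[:, 1]] - snap.positions[pairs[:, 0]])
        r = np.linalg.norm(d, axis=1)
        made[static] &= r < f_cut * snap.contact_sigmas[static]
    return made


def coordination_number(snap, n_residues: int) -> float:
    """Mean number of contacts per residue: z = 2 * n_contacts / N."""
    return 2.0 * float(np.sum(_active_contact_mask(snap))) / n_residues


def interchain_contacts(snap, chain_ids: np.ndarray) -> int:
    """Number of active contacts whose beads belong to different chains."""
    m = _active_contact_mask(snap)
    p = snap.contact_pairs[m]
    return int(np.sum(chain_ids[p[:, 0]] != chain_ids[p[:, 1]]))


def disulfide_count(snap) -> int:
    from .forcefield import KIND_DISULFIDE
    return int(np.sum((snap.contact_kinds == KIND_DISULFIDE)
                      & (snap.contact_lambdas > 0.0)))


# ---------------------------------------------------------------------------
# mobility and shape


def rmsf(frames: np.ndarray, box=None, remove_drift: bool = True,
         ) -> tuple[np.ndarray, float]:
    """Root-mean-square fluctuation about each bead's time-mean position.

    ``frames`` is (T, N, 3) with T >= 2.  With ``remove_drift`` the
    per-frame centre of mass is subtracted first, so a rigid translation
    of the whole system contributes nothing.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need at least two frames")
    if box is not None:
        frames = unwrap_trajectory(frames, box)
    if remove_drift:
        frames = frames - frames.mean(axis=1, keepdims=True)
    mean = frames.mean(axis=0)
    dev2 = np.sum((frames - mean) ** 2, axis=2)
    per_residue = np.sqrt(dev2.mean(axis=0))
    return per_residue, float(per_residue.mean())


@dataclass(frozen=True)
class ShapeSummary:
    """Sorted radii of inertia and the distortion parameter.

    ``w`` = (R2 - Rbar) / Rbar with Rbar = (R1 + R3)/2: 0 for an ideal
    sphere, 1 for an ideal rod, negative for oblate shapes.
    """

    R1: float
    R2: float
    R3: float

    @property
    def w(self) -> float:
        rbar = 0.5 * (self.R1 + self.R3)
        return (self.R2 - rbar) / rbar


def distortion(points: np.ndarray) -> ShapeSummary:
    """Shape of one chain from the eigenvalues of its inertia tensor."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least three beads")
    r = points - points.mean(axis=0)
    r2 = np.einsum("ij,ij->i", r, r)
    inertia = np.sum(r2) * np.eye(3) - r.T @ r
    lam = np.sort(np.linalg.eigvalsh(inertia))
    lam = np.maximum(lam, 0.0)
    radii = np.sqrt(lam / len(points))
    return ShapeSummary(*radii)


def mean_distortion(snap, topology) -> float:
    """Distortion parameter averaged over all chains of a snapshot."""
    vals = []
    for sl in topology.chain_slices():
        pts = unwrap_chain(snap.positions[sl], snap.box)
        vals.append(distortion(pts).w)
    return float(np.mean(vals))


def end_to_end_distances(snap, topology) -> np.ndarray:
    out = []
    for sl in topology.chain_slices():
        pts = unwrap_chain(snap.positions[sl], snap.box)
        out.append(float(np.linalg.norm(pts[-1] - pts[0])))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# pull-curve characteristics


def fmax(series: np.ndarray, n_points: int = 5, min_separation: int = 1,
         ) -> tuple[float, float]:
    """Characteristic maximum force: mean and SD of the n largest samples.

    Samples are taken from the window-averaged series with a minimum
    index separation so that a single spike is not counted n times.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < n_points:
        raise ValueError(f"series shorter than {n_points} points")
    order = np.argsort(series)[::-1]
    chosen: list[int] = []
    for idx in order:
        if all(abs(idx - c) >= min_separation for c in chosen):
            chosen.append(int(idx))
        if len(chosen) == n_points:
            break
    if len(chosen) < n_points:
        raise ValueError("min_separation too large for series length")
    vals = series[chosen]
    return float(vals.mean()), float(vals.std())


def weighted_fmax(values_and_ses: list[tuple[float, float]]) -> tuple[float, float]:
    """Combine per-seed F_max values, weights proportional to 1/SE^2."""
    v = np.asarray([x[0] for x in values_and_ses], dtype=float)
    se = np.asarray([x[1] for x in values_and_ses], dtype=float)
    if np.any(se <= 0):
        return float(v.mean()), 0.0
    w = 1.0 / se ** 2
    mean = float(np.sum(w * v) / np.sum(w))
    return mean, float(np.sqrt(1.0 / np.sum(w)))


def wmax(work_series: np.ndarray) -> float:
    """Maximum of the running work; a plateau after rupture is the maximum."""
    return float(np.max(np.asarray(work_series, dtype=float)))


# ---------------------------------------------------------------------------
# dynamic shear modulus


@dataclass
class RheologyFit:
    """Result of fitting F(t) = F0 cos(wt + delta) against the strain drive.

    ``Gp``/``Gpp`` are the storage and loss moduli (phi0/gamma0) cos/sin
    delta in MPa; ``phi0`` is the stress amplitude in MPa.
    """

    F0_nN: float
    delta: float
    gamma0: float
    phi0_MPa: float
    Gp_MPa: float
    Gpp_MPa: float
    low_signal: bool = False

    @property
    def tan_delta(self) -> float:
        if abs(self.Gp_MPa) <= 1e-12 * abs(self.Gpp_MPa):
            return np.inf   # purely viscous response
        return self.Gpp_MPa / self.Gp_MPa


def _amp_phase(t: np.ndarray, y: np.ndarray, omega: float) -> tuple[float, float]:
    """Least-squares amplitude and phase of y ~ R cos(omega t + psi)."""
    basis = np.stack([np.cos(omega * t), np.sin(omega * t), np.ones_like(t)], axis=1)
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    a, b = coef[0], coef[1]
    return float(np.hypot(a, b)), float(-np.arctan2(b, a))


def fit_dynamic_modulus(t: np.ndarray, strain_offset: np.ndarray,
                        force: np.ndarray, surface_area: float, s0: float,
                        amplitude: float, omega: float,
                        discard_periods: float = 1.0) -> RheologyFit:
    """Fit the oscillatory response and evaluate G' and G''.

    ``strain_offset`` is the wall displacement series (nm) and ``force``
    the matching wall-force series in eps/nm; the first
    ``discard_periods`` drive periods are dropped as transient.  The
    moduli follow from the stress/strain amplitudes, gamma0 = A/s0 and
    phi0 = F0/S, with the phase difference delta folded into [0, pi).
    """
    t = np.asarray(t, dtype=float)
    period = 2.0 * np.pi / omega
    keep = t - t[0] >= discard_periods * period
    if (t[keep][-1] - t[keep][0]) < period:
        raise ValueError("need at least one full period after the discard window")
    tt, st, ft = t[keep], np.asarray(strain_offset)[keep], np.asarray(force)[keep]
    _, psi_strain = _amp_phase(tt, st, omega)
    f0, psi_force = _amp_phase(tt, ft, omega)
    delta = float(np.mod(psi_force - psi_strain, np.pi))
    gamma0 = amplitude / s0
    f0_nN = float(units.force_to_nN(f0))
    phi0_MPa = float(units.stress_nN_per_nm2_to_MPa(f0_nN / surface_area))
    ratio = phi0_MPa / gamma0
    fit = RheologyFit(F0_nN=f0_nN, delta=delta, gamma0=gamma0,
                      phi0_MPa=phi0_MPa,
                      Gp_MPa=float(ratio * np.cos(delta)),
                      Gpp_MPa=float(ratio * np.sin(delta)))
    if f0 <= 0 or not np.isfinite(f0):
        fit.low_signal = True
    return fit


def fit_from_result(result, discard_periods: float = 1.0) -> RheologyFit:
    """Run the modulus fit on a :class:`ProtocolResult` oscillation record."""
    osc = result.oscillation
    if osc is None:
        raise ValueError("run had no oscillation stage")
    if result.mode == "shear":
        strain, force = osc["shear"], osc["fx"]
    else:
        strain, force = osc["s"] - result.s0, osc["fz"]
    return fit_dynamic_modulus(osc["t"], strain, force, result.surface_area,
                               result.s0, osc["A"], osc["omega"],
                               discard_periods=discard_periods)


# ---------------------------------------------------------------------------
# entanglements (primitive-path contraction with non-crossing constraint)


@dataclass
class EntanglementResult:
    l_k: int
    per_chain: list[int]
    paths: list[np.ndarray]
    converged: bool


def _segment_triangle_hits(p: np.ndarray, q: np.ndarray, tri: tuple) -> np.ndarray:
    """Möller-Trumbore: which segments p[k]->q[k] pierce triangle (a,b,c)."""
    a, b, c = tri
    e1, e2 = b - a, c - a
    d = q - p
    h = np.cross(d, e2)
    det = np.einsum("j,kj->k", e1, h)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = p - a
    u = np.einsum("kj,kj->k", s, h) * inv
    qv = np.cross(s, e1)
    v = np.einsum("kj,kj->k", d, qv) * inv
    tpar = np.einsum("j,kj->k", e2, qv) * inv
    eps = 1e-9
    return (ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
            & (tpar >= -eps) & (tpar <= 1 + eps))


def primitive_paths(chains: list[np.ndarray], max_sweeps: int = 1000,
                    step: float = 0.5, tol: float = 1e-3,
                    prune_tol: float = 0.01, prune_every: int = 5,
                    ) -> tuple[list[np.ndarray], bool]:
    """Contract each chain toward a straight line, ends fixed, no crossings.

    Iterative geometric minimization: every interior vertex moves a
    fraction ``step`` toward the midpoint of its neighbours unless the
    two triangles swept by the move would be pierced by any other path
    segment (segments adjacent to the vertex on its own path are exempt).
    Returns the contracted paths and a convergence flag.
    """
    paths = [np.array(c, dtype=float) for c in chains]
    converged = False

    def total_length() -> float:
        return float(sum(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))
                         for p in paths))

    def prune() -> None:
        # delete interior vertices lying within prune_tol of the chord of
        # their neighbours: straightened stretches collapse to single
        # segments (the path geometry changes by less than prune_tol)
        for ci, path in enumerate(paths):
            while len(path) > 2:
                chord = path[2:] - path[:-2]
                cl = np.linalg.norm(chord, axis=1)
                rel = path[1:-1] - path[:-2]
                tpar = np.einsum("ij,ij->i", rel, chord) / np.maximum(cl, 1e-12) ** 2
                foot = path[:-2] + np.clip(tpar, 0, 1)[:, None] * chord
                dev = np.linalg.norm(path[1:-1] - foot, axis=1)
                drop = np.flatnonzero(dev < prune_tol) + 1
                if not len(drop):
                    break
                # never remove two adjacent vertices in one pass
                keep_alt = drop[np.r_[True, np.diff(drop) > 1]]
                mask = np.ones(len(path), dtype=bool)
                mask[keep_alt] = False
                path = path[mask]
            paths[ci] = path

    length = total_length()
    for sweep in range(max_sweeps):
        if prune_tol > 0 and sweep and sweep % prune_every == 0:
            prune()
        moved = 0.0
        seg_p, seg_q, seg_chain, seg_idx, offs = [], [], [], [], []
        off = 0
        for ci, path in enumerate(paths):
            seg_p.append(path[:-1])
            seg_q.append(path[1:])
            seg_chain.append(np.full(len(path) - 1, ci))
            seg_idx.append(np.arange(len(path) - 1))
            offs.append(off)
            off += len(path) - 1
        P = np.concatenate(seg_p)
        Q = np.concatenate(seg_q)
        SC = np.concatenate(seg_chain)
        SI = np.concatenate(seg_idx)
        # prefilter: only segments near a vertex can pierce its small swept
        # triangles, so query a tree of segment midpoints once per sweep
        mids = 0.5 * (P + Q)
        seg_len = np.linalg.norm(Q - P, axis=1)
        reach = 0.5 * float(seg_len.max(initial=0.0))
        tree = cKDTree(mids)
        for ci, path in enumerate(paths):
            if len(path) < 3:
                continue
            span = np.linalg.norm(path[2:] - path[:-2], axis=1)
            # margin absorbs vertex motion during the sweep (tree is stale)
            radius = reach + 0.75 * float(span.max(initial=0.0)) + 1.0
            near_lists = tree.query_ball_point(path[1:-1], radius)
            base = offs[ci]
            crowded = np.zeros(len(path), dtype=bool)
            cands: dict[int, np.ndarray] = {}
            for v in range(1, len(path) - 1):
                cand = np.asarray(near_lists[v - 1], dtype=np.intp)
                keep = ~((SC[cand] == ci) & (SI[cand] >= v - 2)
                         & (SI[cand] <= v + 1))
                cand = cand[keep]
                if len(cand):
                    crowded[v] = True
                    cands[v] = cand
            # vertices with no obstacle in reach relax toward their
            # neighbour midpoints in vectorized red-black passes
            interior = np.arange(1, len(path) - 1)
            for parity in (1, 0):
                sel = interior[(interior % 2 == parity) & ~crowded[interior]]
                if len(sel):
                    target = 0.5 * (path[sel - 1] + path[sel + 1])
                    delta = step * (target - path[sel])
                    moved += float(np.sum(np.linalg.norm(delta, axis=1)))
                    path[sel] += delta
            P[base: base + len(path) - 1] = path[:-1]
            Q[base: base + len(path) - 1] = path[1:]
            # crowded vertices move one at a time with crossing checks
            for v in np.flatnonzero(crowded):
                mid = 0.5 * (path[v - 1] + path[v + 1])
                new = path[v] + step * (mid - path[v])
                if np.allclose(new, path[v], atol=1e-12):
                    continue
                cand = cands[v]
                blocked = False
                for tri in ((path[v - 1], path[v], new),
                            (path[v + 1], path[v], new)):
                    if np.linalg.norm(np.cross(tri[1] - tri[0],
                                               tri[2] - tri[0])) < 1e-14:
                        continue
                    if np.any(_segment_triangle_hits(P[cand], Q[cand], tri)):
                        blocked = True
                        break
                if not blocked:
                    moved += float(np.linalg.norm(new - path[v]))
                    path[v] = new
                if v < len(path) - 1:
                    P[base + v] = path[v]
                Q[base + v - 1] = path[v]
            # refresh this chain's segment block after the fast passes
            P[base: base + len(path) - 1] = path[:-1]
            Q[base: base + len(path) - 1] = path[1:]
        new_length = total_length()
        # converged when vertices stop moving, or when the paths are as
        # short as the obstacles allow (sliding along an obstacle keeps
        # `moved` finite while the length no longer drops)
        if moved < tol or length - new_length < 1e-5 * max(length, 1.0):
            converged = True
            break
        length = new_length
    return paths, converged


def _point_to_segments_dist(pt: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    d = q - p
    denom = np.einsum("kj,kj->k", d, d)
    num = np.einsum("kj,kj->k", d, pt[None, :] - p)
    tpar = np.clip(np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0),
                   0.0, 1.0)
    closest = p + tpar[:, None] * d
    return float(np.min(np.linalg.norm(closest - pt, axis=1)))


def entanglement_count(chains: list[np.ndarray], angle_deg: float = 10.0,
                       contact_dist: float = 0.5, **pp_kwargs) -> EntanglementResult:
    """Count interchain entanglements from contracted primitive paths.

    A kink is a contiguous run of interior vertices whose turning angle
    exceeds ``angle_deg`` and which lie within ``contact_dist`` (twice
    the bead radius) of another chain's contracted path.  Straight
    parallel chains give zero; a chain hooked through another gives one
    per wrap.  Self-entanglements (knots) are not counted because the
    proximity test only looks at *other* chains.
    """
    paths, converged = primitive_paths(chains, **pp_kwargs)
    per_chain = []
    for ci, path in enumerate(paths):
        flags = np.zeros(len(path), dtype=bool)
        if len(path) > 2:
            u = path[1:-1] - path[:-2]
            v = path[2:] - path[1:-1]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            good = (nu > 1e-12) & (nv > 1e-12)
            cosang = np.ones(len(u))
            cosang[good] = np.einsum("ij,ij->i", u[good], v[good]) / (nu[good] * nv[good])
            turning = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            cand = np.flatnonzero(turning > angle_deg) + 1
            others_p = [p[:-1] for k, p in enumerate(paths) if k != ci]
            others_q = [p[1:] for k, p in enumerate(paths) if k != ci]
            if others_p:
                P = np.concatenate(others_p)
                Q = np.concatenate(others_q)
                for idx in cand:
                    if _point_to_segments_dist(path[idx], P, Q) < contact_dist:
                        flags[idx] = True
        # contiguous flagged runs count once
        runs = int(np.sum(flags[1:] & ~flags[:-1])) + int(flags[0])
        per_chain.append(runs)
    return EntanglementResult(l_k=int(np.sum(per_chain)), per_chain=per_chain,
                              paths=paths, converged=converged)


# ---------------------------------------------------------------------------
# cavities (grid + probe, flood fill from the box faces)


@dataclass
class CavityResult:
    n_cavities: int
    max_volume: float
    total_cavity_volume: float
    occupied_volume: float
    exterior_volume: float
    box_volume: float
    volumes: np.ndarray


def cavity_volumes(positions: np.ndarray, box, grid: float = 0.1,
                   probe: float = 0.38,
                   min_volume: float | None = None) -> CavityResult:
    """Classify the box into occupied / exterior / cavities on a grid.

    A cell is occupied when its centre lies within the probe radius of
    any bead (the probe cannot be centred there); free cells connected
    (6-neighbourhood) to any box face are exterior; the remaining free
    components are cavities.  Beads are replicated across the X/Y
    periodic boundary so the contour is wrap-consistent.  Cell volumes
    are chosen so occupied + exterior + cavities equals the box volume
    exactly.

    Interior pockets smaller than ``min_volume`` (default: the volume of
    the probe sphere itself) cannot physically host the probe - they are
    corner/discretization artifacts and are reported as part of the
    exterior-plus-occupied remainder, not as cavities.
    """
    if grid > probe:
        raise ValueError("grid spacing must not exceed the probe radius")
    if min_volume is None:
        min_volume = 4.0 / 3.0 * np.pi * probe ** 3
    L = np.array([box.Lx, box.Ly, box.s])
    shape = np.maximum(np.round(L / grid).astype(int), 1)
    cell = L / shape
    cell_volume = float(np.prod(cell))
    axes = [(np.arange(n) + 0.5) * c for n, c in zip(shape, cell)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    pts = [positions]
    for dim, ext in ((0, box.Lx), (1, box.Ly)):
        lo = positions[:, dim] < probe
        hi = positions[:, dim] > ext - probe
        for m, shift in ((lo, ext), (hi, -ext)):
            if np.any(m):
                img = positions[m].copy()
                img[:, dim] += shift
                pts.append(img)
    tree = cKDTree(np.concatenate(pts))
    dist, _ = tree.query(centers, k=1)
    occupied = (dist < probe).reshape(tuple(shape))

    free = ~occupied
    labels, nlab = ndimage.label(free)
    face_labels = set()
    for axis in range(3):
        face_labels |= set(np.unique(np.take(labels, 0, axis=axis)))
        face_labels |= set(np.unique(np.take(labels, -1, axis=axis)))
    face_labels.discard(0)
    counts = np.bincount(labels.ravel(), minlength=nlab + 1)
    cav_volumes = [counts[lab] * cell_volume for lab in range(1, nlab + 1)
                   if lab not in face_labels
                   and counts[lab] * cell_volume >= min_volume]
    cav_volumes = np.sort(cav_volumes)[::-1] if cav_volumes else np.empty(0)
    occ_vol = float(np.sum(occupied)) * cell_volume
    cav_vol = float(np.sum(cav_volumes))
    return CavityResult(
        n_cavities=len(cav_volumes),
        max_volume=float(cav_volumes[0]) if len(cav_volumes) else 0.0,
        total_cavity_volume=cav_vol,
        occupied_volume=occ_vol,
        exterior_volume=float(np.prod(shape)) * cell_volume - occ_vol - cav_vol,
        box_volume=float(np.prod(shape)) * cell_volume,
        volumes=cav_volumes)


# ---------------------------------------------------------------------------
# kneading-effect ratios


def oscillation_effect_ratios(after: dict[str, tuple[float, float]],
                              baseline: dict[str, tuple[float, float]],
                              ) -> dict[str, tuple[float, float]]:
    """Ratios observable_after_oscillation / observable_without, with
    uncertainties propagated in quadrature on the relative errors."""
    out = {}
    for key, (va, ea) in after.items():
        vb, eb = baseline[key]
        if vb == 0:
            raise ZeroDivisionError(f"baseline {key} is zero")
        r = va / vb
        err = abs(r) * np.sqrt((ea / va) ** 2 + (eb / vb) ** 2) \
            if va != 0 else abs(eb / vb)
        out[key] = (float(r), float(err))
    return out


# ---------------------------------------------------------------------------
# run-level summary


def summarize_run(result, topology, n_entanglement_snaps: int = 5,
                  pull_fmax_points: int = 5) -> dict:
    """All headline observables of one protocol run, in metric units."""
    snaps = result.analysis_snapshots
    n = topology.n_residues
    z_vals = [coordination_number(s, n) for s in snaps]
    ni_vals = [interchain_contacts(s, topology.chain_ids) for s in snaps]
    w_vals = [mean_distortion(s, topology) for s in snaps]
    ss_vals = [disulfide_count(s) for s in snaps]
    frames = np.stack([s.positions for s in snaps])
    _, rmsf_mean = rmsf(frames, box=snaps[-1].box)

    pick = np.linspace(0, len(snaps) - 1, min(n_entanglement_snaps, len(snaps)),
                       dtype=int)
    lk_vals = []
    for k in pick:
        chains = [unwrap_chain(snaps[k].positions[sl], snaps[k].box)
                  for sl in topology.chain_slices()]
        lk_vals.append(entanglement_count(chains).l_k)

    f_nN = result.pull.force_nN()
    fm, fsd = fmax(f_nN, n_points=min(pull_fmax_points, len(f_nN)))
    out = {
        "z": (float(np.mean(z_vals)), float(np.std(z_vals))),
        "n_inter": (float(np.mean(ni_vals)), float(np.std(ni_vals))),
        "w": (float(np.mean(w_vals)), float(np.std(w_vals))),
        "rmsf_nm": (rmsf_mean, 0.0),
        "l_k": (float(np.mean(lk_vals)), float(np.std(lk_vals))),
        "F_max_nN": (fm, fsd),
        "W_max_nN_nm": (wmax(result.pull.work_nN_nm()), 0.0),
        "disulfides": (float(np.mean(ss_vals)), float(np.std(ss_vals))),
        "end_to_end_nm": (float(np.mean(end_to_end_distances(snaps[-1], topology))), 0.0),
    }
    return out
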