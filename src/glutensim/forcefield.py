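"""Potentials and the dynamic contact machinery.

One bead per residue.  Bonded beads interact through a stiff harmonic
spring; chain stiffness comes from tabulated bond-angle and dihedral
potentials with glycine and proline treated as special classes.  All
non-bonded pairs feel a truncated-and-shifted repulsive Lennard-Jones
core (excluded volume).  On top of that, *dynamic contacts* — the model's
stand-in for hydrogen bonds and sidechain packing — are born and die
during the run based on the instantaneous backbone geometry:

* every interior bead carries a local frame (binormal ``h`` pointing
  along a possible backbone hydrogen bond, negative normal ``-n``
  pointing roughly along the sidechain);
* when two beads approach below the Lennard-Jones minimum of the
  candidate contact type and their frame vectors face each other, a
  backbone-backbone (bb), backbone-sidechain (bs/sb) or
  sidechain-sidechain (ss) contact is created;
* the attractive well is switched on linearly over ``t_switch`` (10 tau)
  and switched off the same way once the pair separates beyond
  ``f_cut`` times the contact sigma;
* bb contacts are twice as deep; cysteine pairs can form exclusive
  disulfide bridges (depth 4 eps, minimum 0.59 nm); residues inside
  structured domains additionally carry permanent "static" native
  contacts that never switch off.

Electrostatics use a Debye-Hückel form with a distance-proportional
relative permittivity.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .topology import AMINO_ACIDS, SystemTopology

SIX_ROOT_2 = 2.0 ** (1.0 / 6.0)

# contact kinds
KIND_BB, KIND_BS, KIND_SB, KIND_SS, KIND_DISULFIDE, KIND_STATIC = range(6)
KIND_NAMES = ["bb", "bs", "sb", "ss", "SS", "static"]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("glutensim").joinpath("data", name)))


def _load_residue_table() -> dict:
    radii = np.zeros(20)
    bb_slots = np.zeros(20, dtype=np.intp)
    sc_slots = np.zeros(20, dtype=np.intp)
    charge = np.zeros(20)
    for line in _data_path("residue_params.tsv").read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("residue"):
            continue
        aa, r, b, s, q = line.split("\t")
        k = AMINO_ACIDS.index(aa)
        radii[k], bb_slots[k], sc_slots[k], charge[k] = float(r), int(b), int(s), float(q)
    return {"radii": radii, "bb_slots": bb_slots, "sc_slots": sc_slots,
            "charge": charge}


def _load_table(name: str, periodic: bool) -> dict:
    """Tabulated class potentials -> (spline, derivative-spline) pairs."""
    rows = [ln.split("\t") for ln in _data_path(name).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
    header, data = rows[0], np.asarray(rows[1:], dtype=float)
    x = data[:, 0]
    out = {}
    for c, cls in enumerate(header[1:], start=1):
        y = data[:, c]
        if periodic:
            y = y.copy()
            y[-1] = y[0]
        spl = CubicSpline(x, y, bc_type="periodic" if periodic else "natural")
        out[cls] = (spl, spl.derivative())
    out["_range"] = (x[0], x[-1])
    return out


@dataclass
class ForceFieldConfig:
    """All constants of the force field, in reduced units (nm, eps, tau).

    Defaults follow the published parameterization where printed; the
    per-residue sidechain radii, slot counts and the angle/dihedral
    tables are editable surrogates shipped under ``glutensim/data``.
    """

    epsilon_kcal: float = 1.5          # energy unit, for metric conversions only
    k_bond: float = 5000.0             # eps/nm^2, V = k (r - r_b)^2
    r_b: float = 0.38                  # nm, bond minimum
    r_o: float = 0.5                   # nm, excluded-volume cutoff
    r_min_bb: float = 0.5              # nm, bb contact LJ minimum
    r_min_bs: float = 0.68             # nm, bs contact LJ minimum
    r_min_disulfide: float = 0.59      # nm
    bb_multiplier: float = 2.0         # bb contacts are twice as deep
    disulfide_depth: float = 4.0       # eps
    f_cut: float = 1.5                 # switch-off at r > f_cut * sigma
    t_switch: float = 10.0             # tau, adiabatic ramp time
    align_cos: float = 0.5             # frame-vector alignment threshold
    permittivity_slope: float = 40.0   # nm^-1, eps_r(r) = slope * r
    debye_length: float = 1.0          # nm
    elec_cutoff: float = 2.0           # nm
    coulomb_const: float = 138.935458 / (1.5 * 4.184)  # eps*nm/e^2
    ev_cap_r: float = 0.3              # nm, inner linearization of Eq-2 core;
    # equilibrium pairs essentially never get this close, but capping here
    # keeps the force integrable when compression sweeps beads together
    wall_depth: float = 4.0            # eps, attached-bead well depth
    wall_d_min: float = 0.5            # nm, wall LJ minimum / attachment distance
    wall_detach: float = 2.0           # nm
    wall_cap_r: float = 0.35           # nm, inner cap of the wall repulsion
    unlimited_capacity: bool = False   # disable per-residue slot limits

    sigma0: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.r_b, self.r_o, self.r_min_bb, self.r_min_bs,
               self.r_min_disulfide) <= 0:
            raise ValueError("length parameters must be positive")
        if self.f_cut <= 1:
            raise ValueError("f_cut must exceed 1")
        if self.bb_multiplier < 1:
            raise ValueError("bb_multiplier must be >= 1")
        self.sigma0 = self.r_o * 0.5 ** (1.0 / 6.0)
        self._res = _load_residue_table()
        self._angles = _load_table("angle_potentials.tsv", periodic=False)
        self._dihedrals = _load_table("dihedral_potentials.tsv", periodic=True)

    # -- per-topology lookups ------------------------------------------------
    def charges(self, topology: SystemTopology) -> np.ndarray:
        return self._res["charge"][topology.residue_types]

    def sidechain_radii(self, topology: SystemTopology) -> np.ndarray:
        return self._res["radii"][topology.residue_types]

    def backbone_slots(self, topology: SystemTopology) -> np.ndarray:
        if self.unlimited_capacity:
            return np.full(topology.n_residues, 10 ** 6, dtype=np.intp)
        return self._res["bb_slots"][topology.residue_types]

    def sidechain_slots(self, topology: SystemTopology) -> np.ndarray:
        if self.unlimited_capacity:
            return np.full(topology.n_residues, 10 ** 6, dtype=np.intp)
        return self._res["sc_slots"][topology.residue_types]

    # -- flat-file round trip ------------------------------------------------
    _SCALARS = [
        "epsilon_kcal", "k_bond", "r_b", "r_o", "r_min_bb", "r_min_bs",
        "r_min_disulfide", "bb_multiplier", "disulfide_depth", "f_cut",
        "t_switch", "align_cos", "permittivity_slope", "debye_length",
        "elec_cutoff", "coulomb_const", "ev_cap_r", "wall_depth",
        "wall_d_min", "wall_detach", "wall_cap_r", "unlimited_capacity",
    ]

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {k: getattr(self, k) for k in self._SCALARS}, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ForceFieldConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# scalar potentials (vectorized over r)

def excluded_volume_energy(r, cfg: ForceFieldConfig):
    """Truncated-and-shifted repulsive LJ core: zero at and beyond r_o.

    Below ``cfg.ev_cap_r`` the potential continues linearly (finite cap)
    so that badly overlapping beads during setup cannot overflow.
    """
    r = np.asarray(r, dtype=float)
    rc = np.maximum(r, cfg.ev_cap_r)
    x6 = (cfg.sigma0 / rc) ** 6
    e = np.where(rc < cfg.r_o, 4.0 * x6 * x6 - 4.0 * x6 + 1.0, 0.0)
    fcap = _ev_force_core(np.asarray(cfg.ev_cap_r), cfg)
    e = e + np.where(r < cfg.ev_cap_r, fcap * (cfg.ev_cap_r - r), 0.0)
    return e if e.shape else float(e)


def _ev_force_core(r, cfg):
    x6 = (cfg.sigma0 / r) ** 6
    return np.where(r < cfg.r_o, (48.0 * x6 * x6 - 24.0 * x6) / r, 0.0)


def excluded_volume_force(r, cfg: ForceFieldConfig):
    """Magnitude of the radial force -dV/dr (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    rc = np.maximum(r, cfg.ev_cap_r)
    return _ev_force_core(rc, cfg)


def bond_energy(r, cfg: ForceFieldConfig):
    """Harmonic backbone bond, V = k (r - r_b)^2 (no 1/2 prefactor)."""
    r = np.asarray(r, dtype=float)
    return cfg.k_bond * (r - cfg.r_b) ** 2


def bond_force(r, cfg: ForceFieldConfig):
    """-dV/dr of the harmonic bond."""
    r = np.asarray(r, dtype=float)
    return -2.0 * cfg.k_bond * (r - cfg.r_b)


#: inner linearization of the contact core, as a fraction of sigma; keeps
#: overlap forces integrable just like the excluded-volume cap
CONTACT_CAP_FRAC = 0.7


def contact_energy(r, sigma, depth=1.0):
    """Full Lennard-Jones contact well: depth at r = 2^(1/6) sigma.

    Below ``CONTACT_CAP_FRAC * sigma`` the core continues linearly.
    """
    r = np.asarray(r, dtype=float)
    sigma = np.asarray(sigma)
    cap = CONTACT_CAP_FRAC * sigma
    rr = np.maximum(r, cap)
    x6 = (sigma / rr) ** 6
    e = depth * 4.0 * (x6 * x6 - x6)
    xc6 = CONTACT_CAP_FRAC ** -6.0
    fcap = depth * (48.0 * xc6 * xc6 - 24.0 * xc6) / cap
    return e + np.where(r < cap, fcap * (cap - r), 0.0)


def contact_force(r, sigma, depth=1.0):
    """-dV/dr of the contact well (positive = repulsive), core-capped."""
    r = np.asarray(r, dtype=float)
    sigma = np.asarray(sigma)
    rr = np.maximum(r, CONTACT_CAP_FRAC * sigma)
    x6 = (sigma / rr) ** 6
    return depth * (48.0 * x6 * x6 - 24.0 * x6) / rr


def electrostatic_energy(r, qi, qj, cfg: ForceFieldConfig):
    """Debye-Hückel with distance-proportional relative permittivity.

    eps_r(r) = permittivity_slope * r, hence V ~ exp(-r/lambda_D) / r^2.
    """
    r = np.asarray(r, dtype=float)
    rr = np.maximum(r, 1e-12)
    v = (cfg.coulomb_const * np.asarray(qi) * np.asarray(qj)
         * np.exp(-rr / cfg.debye_length)
         / (cfg.permittivity_slope * rr * rr))
    return np.where(r < cfg.elec_cutoff, v, 0.0)


def electrostatic_force(r, qi, qj, cfg: ForceFieldConfig):
    """-dV/dr of the screened potential."""
    r = np.asarray(r, dtype=float)
    rr = np.maximum(r, 1e-12)
    v = (cfg.coulomb_const * np.asarray(qi) * np.asarray(qj)
         * np.exp(-rr / cfg.debye_length)
         / (cfg.permittivity_slope * rr * rr))
    return np.where(r < cfg.elec_cutoff, v * (2.0 / rr + 1.0 / cfg.debye_length), 0.0)


# ---------------------------------------------------------------------------
# local frames and candidate classification


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without numpy's axis-juggling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _scatter_rows(target: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    n = len(target)
    for k in range(3):
        target[:, k] += np.bincount(idx, vals[:, k], minlength=n)

def local_frames(positions: np.ndarray, topology: SystemTopology, box=None,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bead (n_hat, h_hat, valid) from consecutive bead triples.

    ``h_hat`` is the binormal of the (i-1, i, i+1) triple (backbone
    hydrogen-bond direction); ``-n_hat`` points approximately along the
    sidechain.  Chain ends and collinear triples are flagged invalid and
    form no directional contacts.
    """
    n = len(positions)
    n_hat = np.zeros((n, 3))
    h_hat = np.zeros((n, 3))
    valid = np.zeros(n, dtype=bool)
    prev_ok = np.zeros(n, dtype=bool)
    next_ok = np.zeros(n, dtype=bool)
    for sl in topology.chain_slices():
        if sl.stop - sl.start >= 3:
            prev_ok[sl.start + 1: sl.stop] = True
            next_ok[sl.start: sl.stop - 1] = True
    mid = prev_ok & next_ok
    idx = np.flatnonzero(mid)
    u = positions[idx] - positions[idx - 1]
    v = positions[idx + 1] - positions[idx]
    if box is not None:
        u = box.min_image(u)
        v = box.min_image(v)
    h = _cross(u, v)
    hn = np.sqrt(np.einsum("ij,ij->i", h, h))
    ok = hn > tol
    t = u + v
    tn = np.sqrt(np.einsum("ij,ij->i", t, t))
    ok &= tn > tol
    safe = np.where(ok, hn, 1.0)
    h = h / safe[:, None]
    t = t / np.where(ok, tn, 1.0)[:, None]
    nn = _cross(h, t)  # unit normal, toward the center of curvature
    n_hat[idx] = nn
    h_hat[idx] = h
    valid[idx] = ok
    return n_hat, h_hat, valid


def local_frame(p_prev: np.ndarray, p: np.ndarray, p_next: np.ndarray,
                tol: float = 1e-8):
    """Single-triple convenience wrapper: returns (n_hat, h_hat, valid)."""
    u = np.asarray(p) - np.asarray(p_prev)
    v = np.asarray(p_next) - np.asarray(p)
    h = np.cross(u, v)
    hn = np.linalg.norm(h)
    t = u + v
    tn = np.linalg.norm(t)
    if hn <= tol or tn <= tol:
        return np.zeros(3), np.zeros(3), False
    h = h / hn
    t = t / tn
    return np.cross(h, t), h, True


def classify_pairs(iarr, jarr, rhat, n_hat, h_hat, valid, align_cos):
    """Vectorized contact-kind decision for candidate pairs.

    For each bead of the pair the better-aligned frame vector (``h``
    toward the partner -> backbone side, ``-n`` toward the partner ->
    sidechain side) decides which virtual site engages; either alignment
    must exceed ``align_cos``, otherwise the pair makes no contact.
    Returns an int array with -1 for "no contact".
    """
    ai_h = np.einsum("ij,ij->i", h_hat[iarr], rhat)
    ai_s = np.einsum("ij,ij->i", -n_hat[iarr], rhat)
    aj_h = np.einsum("ij,ij->i", h_hat[jarr], -rhat)
    aj_s = np.einsum("ij,ij->i", -n_hat[jarr], -rhat)
    # |h| alignment is compared in absolute value: the binormal is a
    # pseudo-vector, a hydrogen bond can form on either face
    ai_h, aj_h = np.abs(ai_h), np.abs(aj_h)
    i_back = ai_h >= ai_s
    j_back = aj_h >= aj_s
    ai = np.where(i_back, ai_h, ai_s)
    aj = np.where(j_back, aj_h, aj_s)
    ok = valid[iarr] & valid[jarr] & (ai >= align_cos) & (aj >= align_cos)
    kind = np.where(i_back & j_back, KIND_BB,
                    np.where(i_back & ~j_back, KIND_BS,
                             np.where(~i_back & j_back, KIND_SB, KIND_SS)))
    return np.where(ok, kind, -1)


def classify_candidate(i: int, j: int, frames, r_vec: np.ndarray,
                       align_cos: float = 0.5) -> str:
    """Single-pair wrapper; ``frames`` = (n_hat, h_hat, valid) arrays.

    Returns one of ``"bb" / "bs" / "sb" / "ss" / "none"``.
    """
    n_hat, h_hat, valid = frames
    r = np.linalg.norm(r_vec)
    rhat = (np.asarray(r_vec) / r)[None, :]
    k = classify_pairs(np.array([i]), np.array([j]), rhat, n_hat, h_hat,
                       valid, align_cos)[0]
    return "none" if k < 0 else KIND_NAMES[k]


# ---------------------------------------------------------------------------
# the contact registry

class ContactRegistry:
    """Mutable set of dynamic (and static) contacts with switching state.

    Records are stored in parallel arrays; ``lam`` in [0, 1] is the
    adiabatic switching weight and ``direction`` is +1 (forming) or -1
    (fading).  Static contacts are created once with lam = 1 and never
    change.  The pair interaction contributed by a record is
    ``lam * (V_contact - V_repulsive)`` so that together with the global
    excluded-volume term the pair smoothly interpolates between a purely
    repulsive and a fully attractive well.
    """

    def __init__(self, topology: SystemTopology, cfg: ForceFieldConfig) -> None:
        self.topology = topology
        self.cfg = cfg
        self.i = np.empty(0, dtype=np.intp)
        self.j = np.empty(0, dtype=np.intp)
        self.kind = np.empty(0, dtype=np.intp)
        self.lam = np.empty(0, dtype=float)
        self.direction = np.empty(0, dtype=np.intp)
        self.sigma = np.empty(0, dtype=float)
        self.depth = np.empty(0, dtype=float)
        self._radii = cfg.sidechain_radii(topology)
        self._bb_cap = cfg.backbone_slots(topology)
        self._sc_cap = cfg.sidechain_slots(topology)
        self._cys_partner = np.full(topology.n_residues, -1, dtype=np.intp)
        self._is_cys = np.zeros(topology.n_residues, dtype=bool)
        self._is_cys[topology.cysteines] = True
        if len(topology.static_contacts):
            sc = topology.static_contacts
            self.i = sc[:, 0].astype(np.intp)
            self.j = sc[:, 1].astype(np.intp)
            self.kind = np.full(len(sc), KIND_STATIC, dtype=np.intp)
            self.lam = np.ones(len(sc))
            self.direction = np.zeros(len(sc), dtype=np.intp)
            self.sigma = topology.static_distances / SIX_ROOT_2
            self.depth = np.ones(len(sc))
        self._sync_pairset()

    def __len__(self) -> int:
        return len(self.i)

    def _sync_pairset(self) -> None:
        n = self.topology.n_residues
        self._pairkey = set((self.i * n + self.j).tolist())

    # -- switching -----------------------------------------------------------
    def advance(self, dt: float) -> None:
        """Advance every ramp by dt (tau); drop fully-faded records."""
        dyn = self.kind != KIND_STATIC
        self.lam[dyn] = np.clip(
            self.lam[dyn] + self.direction[dyn] * dt / self.cfg.t_switch, 0.0, 1.0)
        dead = dyn & (self.direction < 0) & (self.lam <= 0.0)
        if np.any(dead):
            # free cysteine partners of removed disulfides
            for a, b, k in zip(self.i[dead], self.j[dead], self.kind[dead]):
                if k == KIND_DISULFIDE:
                    self._cys_partner[a] = -1
                    self._cys_partner[b] = -1
            keep = ~dead
            for name in ("i", "j", "kind", "lam", "direction", "sigma", "depth"):
                setattr(self, name, getattr(self, name)[keep])
            self._sync_pairset()

    # -- slot accounting -----------------------------------------------------
    def _slot_usage(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.topology.n_residues
        bb_used = np.zeros(n, dtype=np.intp)
        sc_used = np.zeros(n, dtype=np.intp)
        for a, b, k in zip(self.i, self.j, self.kind):
            if k == KIND_BB:
                bb_used[a] += 1
                bb_used[b] += 1
            elif k == KIND_BS:
                bb_used[a] += 1
                sc_used[b] += 1
            elif k == KIND_SB:
                sc_used[a] += 1
                bb_used[b] += 1
            elif k == KIND_SS:
                sc_used[a] += 1
                sc_used[b] += 1
        return bb_used, sc_used

    # -- birth / death scan --------------------------------------------------
    def update(self, positions: np.ndarray, box, cand_i: np.ndarray,
               cand_j: np.ndarray) -> None:
        """One birth/death scan at the current configuration.

        ``cand_i/j`` are candidate pairs (i < j) already restricted to a
        generous distance cutoff by the caller's neighbor list; the
        registry applies the classification, distance, sequence-separation,
        capacity and disulfide-exclusivity rules.  Call :meth:`advance`
        separately each integration step to move the ramps.
        """
        cfg = self.cfg
        topo = self.topology
        n = topo.n_residues

        # 1. deaths: existing dynamic contacts beyond f_cut * sigma fade out;
        #    contacts back inside keep (or resume) forming
        if len(self.i):
            d = positions[self.j] - positions[self.i]
            if box is not None:
                d = box.min_image(d)
            r = np.linalg.norm(d, axis=1)
            dyn = self.kind != KIND_STATIC
            out = r > cfg.f_cut * self.sigma
            self.direction[dyn & out] = -1
            self.direction[dyn & ~out] = 1

        # 2. births
        if len(cand_i) == 0:
            return
        key = cand_i * n + cand_j
        fresh = np.array([k not in self._pairkey for k in key.tolist()])
        cand_i, cand_j = cand_i[fresh], cand_j[fresh]
        if len(cand_i) == 0:
            return
        same_chain = topo.chain_ids[cand_i] == topo.chain_ids[cand_j]
        sep_ok = ~same_chain | (np.abs(cand_i - cand_j) >= 3)
        cand_i, cand_j = cand_i[sep_ok], cand_j[sep_ok]
        if len(cand_i) == 0:
            return
        d = positions[cand_j] - positions[cand_i]
        if box is not None:
            d = box.min_image(d)
        r = np.linalg.norm(d, axis=1)
        rhat = d / r[:, None]

        # disulfides first: both beads cysteine, both free, r below minimum
        cys = (self._is_cys[cand_i] & self._is_cys[cand_j]
               & (self._cys_partner[cand_i] < 0) & (self._cys_partner[cand_j] < 0)
               & (r < cfg.r_min_disulfide))
        new_records = []
        order = np.argsort(r[cys], kind="stable")
        ci, cj = cand_i[cys][order], cand_j[cys][order]
        for a, b in zip(ci, cj):
            if self._cys_partner[a] < 0 and self._cys_partner[b] < 0:
                self._cys_partner[a] = b
                self._cys_partner[b] = a
                new_records.append((a, b, KIND_DISULFIDE,
                                    cfg.r_min_disulfide / SIX_ROOT_2,
                                    cfg.disulfide_depth))

        # directional dynamic contacts
        rest = ~cys
        ri, rj, rr, rh = cand_i[rest], cand_j[rest], r[rest], rhat[rest]
        n_hat, h_hat, valid = local_frames(positions, topo, box)
        kind = classify_pairs(ri, rj, rh, n_hat, h_hat, valid, cfg.align_cos)
        sig = np.ones(len(ri))
        sig[kind == KIND_BB] = cfg.r_min_bb / SIX_ROOT_2
        m = (kind == KIND_BS) | (kind == KIND_SB)
        sig[m] = cfg.r_min_bs / SIX_ROOT_2
        m = kind == KIND_SS
        sig[m] = (self._radii[ri[m]] + self._radii[rj[m]]) / SIX_ROOT_2
        within = (kind >= 0) & (rr < sig * SIX_ROOT_2)  # r below the LJ minimum
        ri, rj, rrw, kind, sig = ri[within], rj[within], rr[within], kind[within], sig[within]

        bb_used, sc_used = self._slot_usage()
        order = np.argsort(rrw, kind="stable")  # closest pairs claim slots first
        for t in order:
            a, b, k, s = ri[t], rj[t], kind[t], sig[t]
            need = {KIND_BB: ((a, "b"), (b, "b")), KIND_BS: ((a, "b"), (b, "s")),
                    KIND_SB: ((a, "s"), (b, "b")), KIND_SS: ((a, "s"), (b, "s"))}[k]
            ok = all((bb_used[x] < self._bb_cap[x]) if side == "b"
                     else (sc_used[x] < self._sc_cap[x]) for x, side in need)
            if not ok:
                continue
            for x, side in need:
                if side == "b":
                    bb_used[x] += 1
                else:
                    sc_used[x] += 1
            depth = cfg.bb_multiplier if k == KIND_BB else 1.0
            new_records.append((a, b, k, s, depth))

        if new_records:
            arr = np.asarray([(a, b, k) for a, b, k, _, _ in new_records], dtype=np.intp)
            self.i = np.concatenate([self.i, arr[:, 0]])
            self.j = np.concatenate([self.j, arr[:, 1]])
            self.kind = np.concatenate([self.kind, arr[:, 2]])
            self.sigma = np.concatenate(
                [self.sigma, np.asarray([s for *_, s, _ in new_records])])
            self.depth = np.concatenate(
                [self.depth, np.asarray([dep for *_, dep in new_records])])
            self.lam = np.concatenate([self.lam, np.zeros(len(new_records))])
            self.direction = np.concatenate(
                [self.direction, np.ones(len(new_records), dtype=np.intp)])
            self._sync_pairset()

    # -- energetics ----------------------------------------------------------
    def pair_energy(self, positions: np.ndarray, box) -> float:
        """Sum over records of lam * (V_contact - V_repulsive)."""
        if not len(self.i):
            return 0.0
        d = positions[self.j] - positions[self.i]
        if box is not None:
            d = box.min_image(d)
        r = np.linalg.norm(d, axis=1)
        v = contact_energy(r, self.sigma, self.depth) - excluded_volume_energy(r, self.cfg)
        return float(np.sum(self.lam * v))

    def add_forces(self, positions: np.ndarray, box, forces: np.ndarray) -> float:
        """Accumulate record forces into ``forces``; returns the energy."""
        if not len(self.i):
            return 0.0
        d = positions[self.j] - positions[self.i]
        if box is not None:
            d = box.min_image(d)
        r = np.linalg.norm(d, axis=1)
        v = contact_energy(r, self.sigma, self.depth) - excluded_volume_energy(r, self.cfg)
        fmag = self.lam * (contact_force(r, self.sigma, self.depth)
                           - excluded_volume_force(r, self.cfg))
        fv = (fmag / r)[:, None] * d  # force on j along +d when repulsive
        n = len(forces)
        for k in range(3):
            forces[:, k] += np.bincount(self.j, fv[:, k], minlength=n)
            forces[:, k] -= np.bincount(self.i, fv[:, k], minlength=n)
        return float(np.sum(self.lam * v))

    # -- views ---------------------------------------------------------------
    def active_pairs(self, lam_min: float = 0.0) -> np.ndarray:
        """(n, 2) array of current contact pairs with lam > lam_min."""
        m = self.lam > lam_min
        return np.stack([self.i[m], self.j[m]], axis=1)

    def counts_by_kind(self) -> dict[str, int]:
        return {name: int(np.sum(self.kind == k)) for k, name in enumerate(KIND_NAMES)}


# ---------------------------------------------------------------------------
# bonded terms (bonds handled in the engine's pair loop would be wasteful;
# angles and dihedrals need the tabulated splines, so they live here)

def angle_terms(positions, topology, cfg: ForceFieldConfig, box=None,
                forces: np.ndarray | None = None) -> float:
    """Energy (and optional forces) of all bond-angle triples."""
    tri = topology.angles()
    if not len(tri):
        return 0.0
    cls = topology.residue_classes[tri[:, 1]]
    a, b, c = positions[tri[:, 0]], positions[tri[:, 1]], positions[tri[:, 2]]
    u = a - b
    v = c - b
    if box is not None:
        u = box.min_image(u)
        v = box.min_image(v)
    lu = np.sqrt(np.einsum("ij,ij->i", u, u))
    lv = np.sqrt(np.einsum("ij,ij->i", v, v))
    n1 = u / lu[:, None]
    n2 = v / lv[:, None]
    cosq = np.clip(np.einsum("ij,ij->i", n1, n2), -1.0, 1.0)
    theta = np.arccos(cosq)
    lo, hi = cfg._angles["_range"]
    theta_c = np.clip(theta, lo, hi)
    energy = 0.0
    if forces is not None:
        sinq = np.sqrt(np.maximum(1.0 - cosq * cosq, 1e-12))
    for code, name in ((1, "glycine"), (2, "proline"), (0, "generic")):
        m = cls == code
        if not np.any(m):
            continue
        spl, dspl = cfg._angles[name]
        energy += float(np.sum(spl(theta_c[m])))
        if forces is not None:
            dv = dspl(theta_c[m])
            # dtheta/dx = -(1/sin) dcos/dx
            dca = (n2[m] - cosq[m, None] * n1[m]) / lu[m, None]
            dcc = (n1[m] - cosq[m, None] * n2[m]) / lv[m, None]
            pref = (dv / sinq[m])[:, None]
            fa = pref * dca
            fc = pref * dcc
            _scatter_rows(forces, tri[m, 0], fa)
            _scatter_rows(forces, tri[m, 2], fc)
            _scatter_rows(forces, tri[m, 1], -(fa + fc))
    return energy


def dihedral_terms(positions, topology, cfg: ForceFieldConfig, box=None,
                   forces: np.ndarray | None = None) -> float:
    """Energy (and optional forces) of all dihedral quadruples."""
    quad = topology.dihedrals()
    if not len(quad):
        return 0.0
    # class of the dihedral: proline wins over glycine over generic,
    # judged from the two central residues
    c1 = topology.residue_classes[quad[:, 1]]
    c2 = topology.residue_classes[quad[:, 2]]
    cls = np.where((c1 == 2) | (c2 == 2), 2, np.where((c1 == 1) | (c2 == 1), 1, 0))
    p0, p1, p2, p3 = (positions[quad[:, k]] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    if box is not None:
        b1, b2, b3 = box.min_image(b1), box.min_image(b2), box.min_image(b3)
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    lb2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    m1 = _cross(n1, b2 / lb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(y, x)
    sq1 = np.einsum("ij,ij->i", n1, n1)
    sq2 = np.einsum("ij,ij->i", n2, n2)
    good = (sq1 > 1e-12) & (sq2 > 1e-12)
    energy = 0.0
    for code, name in ((1, "glycine"), (2, "proline"), (0, "generic")):
        m = (cls == code) & good
        if not np.any(m):
            continue
        spl, dspl = cfg._dihedrals[name]
        energy += float(np.sum(spl(phi[m])))
        if forces is not None:
            dv = dspl(phi[m])
            dphi_a = (lb2[m] / sq1[m])[:, None] * n1[m]
            dphi_d = -(lb2[m] / sq2[m])[:, None] * n2[m]
            p = np.einsum("ij,ij->i", b1[m], b2[m]) / (lb2[m] ** 2)
            q = np.einsum("ij,ij->i", b3[m], b2[m]) / (lb2[m] ** 2)
            fa = -dv[:, None] * dphi_a
            fd = -dv[:, None] * dphi_d
            fb = -(1.0 + p)[:, None] * fa + q[:, None] * fd
            fc = p[:, None] * fa - (1.0 + q)[:, None] * fd
            _scatter_rows(forces, quad[m, 0], fa)
            _scatter_rows(forces, quad[m, 1], fb)
            _scatter_rows(forces, quad[m, 2], fc)
            _scatter_rows(forces, quad[m, 3], fd)
    return energy
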