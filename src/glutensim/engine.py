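"""Langevin dynamics between two walls with X/Y periodic boundaries.

The equations of motion are m r'' = F - gamma r' + Gamma with gamma =
2m/tau (overdamped regime) and white noise of variance 2 gamma k_B T.
They are integrated with the Grønbech-Jensen–Farago discretization,
which reduces to velocity Verlet at gamma = 0 and samples the correct
configurational distribution at large time steps; the reduced-unit mass
is 1 and the default step is 0.005 tau.

Walls close the box along Z.  Both walls always repel approaching beads
(truncated LJ, depth 4 eps); once attraction is switched on by the
protocol, a bead coming within d_min = 0.5 nm of a wall acquires an
interaction center whose X/Y stick to the wall at the first-touch
position and whose well (depth 4 eps) ramps on adiabatically, exactly
like a dynamic contact.  A bead straying more than 2 nm from its center
detaches (the center fades out and disappears) and may later reattach
elsewhere.  The forces that the beads exert back on the two walls are
accumulated every step; block-averaging them over 100 ns windows gives
the measured normal and shear force signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import units
from .forcefield import (ForceFieldConfig, ContactRegistry, angle_terms,
                         bond_energy, bond_force, dihedral_terms,
                         electrostatic_energy, electrostatic_force,
                         excluded_volume_energy, excluded_volume_force)
from .topology import AMINO_ACIDS, SystemTopology


class UnstableStepError(RuntimeError):
    """A bead moved more than half the excluded-volume radius in one step."""


@dataclass
class Box:
    """Periodic X/Y extents, wall separation s, and the top-wall shear offset."""

    Lx: float
    Ly: float
    s: float
    shear: float = 0.0

    def min_image(self, d: np.ndarray, inplace: bool = False) -> np.ndarray:
        """Minimum-image displacement; X/Y wrapped, Z untouched.

        ``inplace=True`` mutates ``d`` (used on freshly built temporaries
        in the force loop).
        """
        d = np.asarray(d, dtype=float) if inplace else np.array(d, dtype=float)
        d[..., 0] -= self.Lx * np.round(d[..., 0] / self.Lx)
        d[..., 1] -= self.Ly * np.round(d[..., 1] / self.Ly)
        return d

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        pos = np.array(pos, dtype=float, copy=True)
        pos[:, 0] %= self.Lx
        pos[:, 1] %= self.Ly
        return pos

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.s

    @property
    def wall_area(self) -> float:
        return self.Lx * self.Ly


class WallState:
    """Attachment bookkeeping and force evaluation for both walls."""

    def __init__(self, n_beads: int, cfg: ForceFieldConfig) -> None:
        self.cfg = cfg
        self.attraction_enabled = False
        self.wall = np.full(n_beads, -1, dtype=np.int8)   # -1 none, 0 bottom, 1 top
        self.anchor = np.zeros((n_beads, 2))              # wall-frame x, y
        self.lam = np.zeros(n_beads)
        self.direction = np.zeros(n_beads, dtype=np.int8)
        sig = cfg.wall_d_min * 0.5 ** (1.0 / 6.0)
        self._sig6 = sig ** 6

    def advance(self, dt: float) -> None:
        att = self.wall >= 0
        self.lam[att] = np.clip(
            self.lam[att] + self.direction[att] * dt / self.cfg.t_switch, 0.0, 1.0)
        gone = att & (self.direction < 0) & (self.lam <= 0.0)
        self.wall[gone] = -1

    def update_attachments(self, pos: np.ndarray, box: Box) -> None:
        """Attach close beads (if attraction is on) and mark strays as fading."""
        cfg = self.cfg
        if self.attraction_enabled:
            for w, dist in ((0, pos[:, 2]), (1, box.s - pos[:, 2])):
                new = (self.wall < 0) & (dist < cfg.wall_d_min)
                idx = np.flatnonzero(new)
                if len(idx):
                    self.wall[idx] = w
                    ax = pos[idx, 0] - (box.shear if w == 1 else 0.0)
                    self.anchor[idx, 0] = ax
                    self.anchor[idx, 1] = pos[idx, 1]
                    self.lam[idx] = 0.0
                    self.direction[idx] = 1
        att = np.flatnonzero(self.wall >= 0)
        if len(att):
            r = np.linalg.norm(self._anchor_vec(pos, box, att), axis=1)
            far = r > cfg.wall_detach
            self.direction[att[far]] = -1
            self.direction[att[~far]] = 1

    def _anchor_vec(self, pos: np.ndarray, box: Box, idx: np.ndarray) -> np.ndarray:
        """Min-image displacement bead - interaction center for attached beads."""
        top = self.wall[idx] == 1
        ax = self.anchor[idx, 0] + np.where(top, box.shear, 0.0)
        az = np.where(top, box.s, 0.0)
        d = np.stack([pos[idx, 0] - ax, pos[idx, 1] - self.anchor[idx, 1],
                      pos[idx, 2] - az], axis=1)
        return box.min_image(d)

    def add_forces(self, pos: np.ndarray, box: Box, forces: np.ndarray):
        """Accumulate wall forces on beads; return energy and wall reactions.

        Reactions are (bottom_xz, top_xz): the force the beads exert on
        each wall, i.e. minus what the wall exerts on them.
        """
        cfg = self.cfg
        depth = cfg.wall_depth
        cap = cfg.wall_cap_r
        energy = 0.0
        react = np.zeros((2, 2))  # rows bottom/top, cols (Fx, Fz)

        # always-on repulsion, perpendicular distance, WCA-truncated
        for w, sign in ((0, 1.0), (1, -1.0)):
            d = pos[:, 2] if w == 0 else box.s - pos[:, 2]
            dc = np.maximum(d, cap)
            x6 = self._sig6 / dc ** 6
            act = d < cfg.wall_d_min
            if np.any(act):
                # distances below `cap` are clamped, which caps the force
                e = 4.0 * depth * (x6 * x6 - x6) + depth
                f = 4.0 * depth * (12.0 * x6 * x6 - 6.0 * x6) / dc
                energy += float(np.sum(e[act]))
                fz = sign * f * act
                forces[:, 2] += fz
                react[w, 1] -= float(np.sum(fz))

        # adiabatic attraction toward the interaction centers
        att = np.flatnonzero((self.wall >= 0) & (self.lam > 0.0))
        if len(att):
            d = self._anchor_vec(pos, box, att)
            r = np.linalg.norm(d, axis=1)
            rmin = cfg.wall_d_min
            x6 = self._sig6 / np.maximum(r, 1e-9) ** 6
            tail = r >= rmin
            e = np.where(tail, 4.0 * depth * (x6 * x6 - x6), -depth)
            dedr = np.where(tail, -4.0 * depth * (12.0 * x6 * x6 - 6.0 * x6) / r, 0.0)
            energy += float(np.sum(self.lam[att] * e))
            fmag = -self.lam[att] * dedr  # radial force on bead (negative = inward)
            fv = (fmag / np.maximum(r, 1e-9))[:, None] * d
            np.add.at(forces, att, fv)
            for w in (0, 1):
                m = self.wall[att] == w
                react[w, 0] -= float(np.sum(fv[m, 0]))
                react[w, 1] -= float(np.sum(fv[m, 2]))
        return energy, react


class NeighborList:
    """Chunked O(N^2) pair list with a Verlet skin (X/Y minimum image)."""

    def __init__(self, cutoff: float, skin: float = 0.3, chunk: int = 1024) -> None:
        self.cutoff = cutoff
        self.skin = skin
        self.chunk = chunk
        self.pairs = np.empty((0, 2), dtype=np.intp)
        self._ref = None

    def needs_rebuild(self, pos: np.ndarray) -> bool:
        if self._ref is None or len(self._ref) != len(pos):
            return True
        disp = np.abs(pos - self._ref).max()
        return disp > 0.5 * self.skin

    def rebuild(self, pos: np.ndarray, box: Box, exclude: np.ndarray) -> None:
        """``exclude``: (n, 2) i<j pairs (bonded neighbours) to drop."""
        n = len(pos)
        rc2 = (self.cutoff + self.skin) ** 2
        out_i, out_j = [], []
        for a in range(0, n, self.chunk):
            b = min(a + self.chunk, n)
            d = pos[None, a:b, :] - pos[:, None, :]  # (n, chunk, 3): j - i
            d = box.min_image(d, inplace=True)
            r2 = np.einsum("ijk,ijk->ij", d, d)
            ii, jj = np.nonzero(r2 < rc2)
            jj = jj + a
            keep = ii < jj
            out_i.append(ii[keep])
            out_j.append(jj[keep])
        i = np.concatenate(out_i)
        j = np.concatenate(out_j)
        if len(exclude):
            keys = i * n + j
            excl = np.sort(exclude[:, 0] * n + exclude[:, 1])
            mask = ~np.isin(keys, excl)
            i, j = i[mask], j[mask]
        self.pairs = np.stack([i, j], axis=1)
        self._ref = pos.copy()


@dataclass
class SimulationParams:
    dt: float = 0.005                 # tau
    temperature: float = units.ROOM_TEMPERATURE
    gamma: float = 2.0                # 2 m / tau
    mass: float = 1.0
    contact_interval: int = 10        # steps between birth/death scans
    max_step_displacement: float = 0.25  # 0.5 * r_o


class Simulation:
    """A system of chains + force field + walls, advanced by Langevin steps."""

    def __init__(self, topology: SystemTopology, positions: np.ndarray, box: Box,
                 cfg: ForceFieldConfig | None = None,
                 params: SimulationParams | None = None,
                 rng: np.random.Generator | None = None) -> None:
        self.topology = topology
        self.cfg = cfg or ForceFieldConfig()
        self.params = params or SimulationParams()
        self.box = box
        self.rng = np.random.default_rng() if rng is None else rng
        self.pos = np.array(positions, dtype=float)
        self.vel = np.zeros_like(self.pos)
        self.time = 0.0
        self.registry = ContactRegistry(topology, self.cfg)
        self.walls = WallState(topology.n_residues, self.cfg)
        self.charges = self.cfg.charges(topology)
        self._bond_i = topology.bonds[:, 0]
        self._bond_j = topology.bonds[:, 1]
        # creation scan cutoff: largest possible contact minimum distance
        radii = self.cfg.sidechain_radii(topology)
        self._r_create = max(self.cfg.r_min_bs, self.cfg.r_min_bb,
                             2.0 * radii.max() if len(radii) else 0.0)
        # a chargeless system needs no electrostatic reach in the pair list
        cutoff = (self.cfg.elec_cutoff if np.any(self.charges != 0.0)
                  else max(self._r_create, self.cfg.r_o))
        self.nlist = NeighborList(cutoff=cutoff)
        self._forces = None
        self.wall_reaction = np.zeros((2, 2))
        self._steps_since_scan = 10 ** 9

    # -- forces and energy ---------------------------------------------------
    def _pair_arrays(self):
        if self.nlist.needs_rebuild(self.pos):
            self.nlist.rebuild(self.pos, self.box, self.topology.bonds)
        return self.nlist.pairs[:, 0], self.nlist.pairs[:, 1]

    def _scatter_pair_forces(self, forces, ii, jj, fv) -> None:
        n = len(forces)
        for k in range(3):
            forces[:, k] += np.bincount(jj, fv[:, k], minlength=n)
            forces[:, k] -= np.bincount(ii, fv[:, k], minlength=n)

    def compute_forces(self) -> np.ndarray:
        cfg = self.cfg
        pos = self.pos
        forces = np.zeros_like(pos)

        # bonds
        d = self.box.min_image(pos[self._bond_j] - pos[self._bond_i], inplace=True)
        r = np.linalg.norm(d, axis=1)
        fmag = bond_force(r, cfg)
        fv = (fmag / r)[:, None] * d
        self._scatter_pair_forces(forces, self._bond_i, self._bond_j, fv)

        # local stiffness
        angle_terms(pos, self.topology, cfg, self.box, forces)
        dihedral_terms(pos, self.topology, cfg, self.box, forces)

        # non-bonded pairs
        i, j = self._pair_arrays()
        d = self.box.min_image(pos[j] - pos[i], inplace=True)
        r2 = np.einsum("ij,ij->i", d, d)
        close = r2 < cfg.r_o ** 2
        if np.any(close):
            ii, jj, dd = i[close], j[close], d[close]
            rr = np.sqrt(r2[close])
            fmag = excluded_volume_force(rr, cfg)
            self._scatter_pair_forces(forces, ii, jj, (fmag / rr)[:, None] * dd)
        qq = self.charges[i] * self.charges[j]
        el = (qq != 0.0) & (r2 < cfg.elec_cutoff ** 2)
        if np.any(el):
            ii, jj, dd = i[el], j[el], d[el]
            rr = np.sqrt(r2[el])
            fmag = electrostatic_force(rr, self.charges[ii], self.charges[jj], cfg)
            self._scatter_pair_forces(forces, ii, jj, (fmag / rr)[:, None] * dd)

        # dynamic contacts and walls
        self.registry.add_forces(pos, self.box, forces)
        _, self.wall_reaction = self.walls.add_forces(pos, self.box, forces)
        return forces

    def total_energy(self) -> dict[str, float]:
        """Energy decomposition at the current configuration."""
        cfg = self.cfg
        pos = self.pos
        out: dict[str, float] = {}
        d = self.box.min_image(pos[self._bond_j] - pos[self._bond_i])
        out["bond"] = float(np.sum(bond_energy(np.linalg.norm(d, axis=1), cfg)))
        out["angle"] = angle_terms(pos, self.topology, cfg, self.box)
        out["dihedral"] = dihedral_terms(pos, self.topology, cfg, self.box)
        i, j = self._pair_arrays()
        d = self.box.min_image(pos[j] - pos[i])
        r = np.linalg.norm(d, axis=1)
        out["excluded_volume"] = float(np.sum(excluded_volume_energy(r, cfg)))
        qq = self.charges[i] * self.charges[j]
        m = qq != 0.0
        out["electrostatic"] = float(np.sum(electrostatic_energy(
            r[m], self.charges[i[m]], self.charges[j[m]], cfg)))
        out["contacts"] = self.registry.pair_energy(pos, self.box)
        wf = np.zeros_like(pos)
        out["walls"], _ = self.walls.add_forces(pos, self.box, wf)
        out["kinetic"] = 0.5 * self.params.mass * float(np.sum(self.vel ** 2))
        out["potential"] = sum(v for k, v in out.items() if k != "kinetic")
        out["total"] = out["potential"] + out["kinetic"]
        return out

    # -- contact / wall scans ------------------------------------------------
    def scan_contacts(self) -> None:
        """Birth/death scan of dynamic contacts and wall attachments."""
        i, j = self._pair_arrays()
        d = self.box.min_image(self.pos[j] - self.pos[i])
        r2 = np.einsum("ij,ij->i", d, d)
        m = r2 < self._r_create ** 2
        self.registry.update(self.pos, self.box, i[m], j[m])
        self.walls.update_attachments(self.pos, self.box)
        self._steps_since_scan = 0

    # -- integration ---------------------------------------------------------
    def step(self, n: int = 1) -> None:
        """Advance n Langevin steps (Grønbech-Jensen–Farago discretization)."""
        p = self.params
        dt, m, gamma = p.dt, p.mass, p.gamma
        x = gamma * dt / (2.0 * m)
        a = (1.0 - x) / (1.0 + x)
        b = 1.0 / (1.0 + x)
        noise_sd = np.sqrt(2.0 * gamma * p.temperature * dt)
        if self._forces is None:
            self._forces = self.compute_forces()
        for _ in range(n):
            if self._steps_since_scan >= p.contact_interval:
                self.scan_contacts()
            f = self._forces
            beta = (self.rng.normal(0.0, noise_sd, self.pos.shape)
                    if p.temperature > 0 else 0.0)
            dx = b * dt * self.vel + (b * dt * dt / (2 * m)) * f + (b * dt / (2 * m)) * beta
            maxd = float(np.abs(dx).max()) if dx.size else 0.0
            if maxd > p.max_step_displacement:
                raise UnstableStepError(
                    f"max displacement {maxd:.3f} nm exceeds "
                    f"{p.max_step_displacement} nm at t={self.time:.3f} tau")
            self.pos = self.box.wrap(self.pos + dx)
            self._reflect_walls()
            self.registry.advance(dt)
            self.walls.advance(dt)
            f_new = self.compute_forces()
            self.vel = a * self.vel + (dt / (2 * m)) * (a * f + f_new) + (b / m) * beta
            self._forces = f_new
            self.time += dt
            self._steps_since_scan += 1

    def _reflect_walls(self) -> None:
        # the wall potential makes crossings essentially impossible; this
        # reflection is a last-resort guard for pathological overlaps
        z = self.pos[:, 2]
        low = z < 0.0
        high = z > self.box.s
        if np.any(low):
            self.pos[low, 2] = -z[low]
            self.vel[low, 2] *= -1.0
        if np.any(high):
            self.pos[high, 2] = 2.0 * self.box.s - z[high]
            self.vel[high, 2] *= -1.0

    def invalidate_forces(self) -> None:
        """Call after externally moving walls/positions (protocol stages)."""
        self._forces = None
        self.nlist._ref = None

    # -- measured wall force -------------------------------------------------
    def wall_force_sample(self) -> tuple[float, float]:
        """(shear, normal) force the beads exert on the walls, in eps/nm.

        The shear component is the drive force balancing the beads' pull
        on the moving (top) wall; the normal component is positive under
        tension (walls pulled toward each other) and negative when the
        beads press the walls apart.
        """
        react = self.wall_reaction
        fx = 0.5 * (react[0, 0] - react[1, 0])
        fz = 0.5 * (react[0, 1] - react[1, 1])
        return fx, fz


def measured_wall_force(series: np.ndarray, window: int) -> np.ndarray:
    """Block-average a per-step wall-force series over ``window`` samples.

    The production choice is a 100 ns window, which filters the thermal
    noise out of the wall-force signal.  Raises if the window is longer
    than the series.
    """
    series = np.asarray(series, dtype=float)
    if window > len(series):
        raise ValueError("averaging window longer than series")
    nblocks = len(series) // window
    return series[: nblocks * window].reshape(nblocks, window).mean(axis=1)


# ---------------------------------------------------------------------------
# snapshot / time-series output

def write_xyz(path: str | Path, positions: np.ndarray, topology: SystemTopology,
              comment: str = "") -> None:
    """Plain XYZ with the one-letter residue code as the element field."""
    with open(path, "w") as fh:
        fh.write(f"{len(positions)}\n{comment}\n")
        for k, p in enumerate(positions):
            aa = AMINO_ACIDS[topology.residue_types[k]]
            fh.write(f"{aa} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


def write_pdb(path: str | Path, positions: np.ndarray,
              topology: SystemTopology) -> None:
    """Minimal CA-only PDB trace with chain letters, via MDAnalysis."""
    import MDAnalysis as mda

    one_to_three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}
    n = topology.n_residues
    u = mda.Universe.empty(n, n_residues=n, n_segments=topology.n_chains,
                           atom_resindex=np.arange(n),
                           residue_segindex=topology.chain_ids,
                           trajectory=True)
    resnames = [one_to_three[AMINO_ACIDS[t]] for t in topology.residue_types]
    u.add_TopologyAttr("names", ["CA"] * n)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", topology.index_in_chain + 1)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    u.add_TopologyAttr("chainIDs",
                       [letters[c % 26] for c in topology.chain_ids])
    u.atoms.positions = positions * 10.0  # nm -> Angstrom
    u.atoms.write(str(path))


def write_timeseries(path: str | Path, frame: pd.DataFrame) -> None:
    """Tab-separated time series with a header (time tau, s nm, s' nm, Fx, Fz)."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
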