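"""System construction: sequences -> beads, bonds, cysteines, static contacts.

A simulated system is a set of protein chains, one bead per residue,
placed between two solid walls (Z direction) in a box that is periodic
along X and Y.  This module builds the bead-level bookkeeping from FASTA
sequences plus a composition file (how many copies of each chain), loads
static contact maps for structured domains, and generates the initial
dilute self-avoiding-walk conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residue classes used by the local-stiffness potentials
CLASS_GENERIC, CLASS_GLYCINE, CLASS_PROLINE = 0, 1, 2

#: fixed bond length between consecutive beads (nm)
BOND_LENGTH = 0.38

#: excluded-volume cutoff (nm); also the clash radius of the initial walk
EXCLUDED_VOLUME_CUTOFF = 0.5


@dataclass(frozen=True)
class StructuredDomain:
    """A residue interval (1-based, inclusive) treated as a folded domain."""

    start: int
    end: int
    contact_map: str | None = None  # path or label of the native-contact table


@dataclass
class ChainSpec:
    """One chain type: sequence, copy number and optional structured domains."""

    name: str
    sequence: str
    copies: int = 1
    structured_domains: list[StructuredDomain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.name!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"chain {self.name!r}: illegal residue letters {sorted(bad)}")
        if self.copies < 1:
            raise ValueError(f"chain {self.name!r}: copies must be >= 1")
        last = 0
        for dom in sorted(self.structured_domains, key=lambda d: d.start):
            if dom.start < 1 or dom.end > len(self.sequence) or dom.start > dom.end:
                raise ValueError(f"chain {self.name!r}: domain {dom} out of bounds")
            if dom.start <= last:
                raise ValueError(f"chain {self.name!r}: overlapping structured domains")
            last = dom.end

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")


@dataclass(frozen=True)
class InitialBox:
    """Periodic extents Lx, Ly, wall separation s, and the realized density."""

    Lx: float
    Ly: float
    s: float
    density: float

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.s) <= 0:
            raise ValueError("box extents must be positive")

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.s


@dataclass
class SystemTopology:
    """Flat per-bead arrays describing all chains of the system.

    ``residue_types`` are indices into :data:`AMINO_ACIDS`;
    ``residue_classes`` distinguish glycine/proline/generic for the angle
    and dihedral tables.  ``static_contacts`` is an (n, 2) int array of
    bead ids with ``static_distances`` holding the native Ca-Ca distance
    (nm) that sets the Lennard-Jones minimum of each pair.
    """

    chain_ids: np.ndarray          # (N,) int
    index_in_chain: np.ndarray     # (N,) int, 0-based
    residue_types: np.ndarray      # (N,) int
    residue_classes: np.ndarray    # (N,) int
    bonds: np.ndarray              # (Nb, 2) int
    cysteines: np.ndarray          # (n_cys,) int bead ids
    chain_names: list[str]
    static_contacts: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.intp))
    static_distances: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=float))
    structured_mask: np.ndarray | None = None  # (N,) bool, beads inside a domain

    @property
    def n_residues(self) -> int:
        return len(self.chain_ids)

    @property
    def n_chains(self) -> int:
        return int(self.chain_ids.max()) + 1 if self.n_residues else 0

    def chain_slices(self) -> list[slice]:
        """Contiguous bead-index slice of every chain (cached)."""
        if getattr(self, "_slices_cache", None) is None:
            slices = []
            starts = np.flatnonzero(np.r_[True, np.diff(self.chain_ids) != 0])
            ends = np.r_[starts[1:], self.n_residues]
            for a, b in zip(starts, ends):
                slices.append(slice(int(a), int(b)))
            self._slices_cache = slices
        return self._slices_cache

    def angles(self) -> np.ndarray:
        """(Na, 3) consecutive triples within chains (cached)."""
        if getattr(self, "_angles_cache", None) is None:
            out = []
            for sl in self.chain_slices():
                idx = np.arange(sl.start, sl.stop)
                if len(idx) >= 3:
                    out.append(np.stack([idx[:-2], idx[1:-1], idx[2:]], axis=1))
            self._angles_cache = (np.concatenate(out) if out
                                  else np.empty((0, 3), dtype=np.intp))
        return self._angles_cache

    def dihedrals(self) -> np.ndarray:
        """(Nd, 4) consecutive quadruples within chains (cached)."""
        if getattr(self, "_dihedrals_cache", None) is None:
            out = []
            for sl in self.chain_slices():
                idx = np.arange(sl.start, sl.stop)
                if len(idx) >= 4:
                    out.append(np.stack([idx[:-3], idx[1:-2], idx[2:-1], idx[3:]],
                                        axis=1))
            self._dihedrals_cache = (np.concatenate(out) if out
                                     else np.empty((0, 4), dtype=np.intp))
        return self._dihedrals_cache


def _classify(letter: str) -> int:
    if letter == "G":
        return CLASS_GLYCINE
    if letter == "P":
        return CLASS_PROLINE
    return CLASS_GENERIC


def build_topology(chain_specs: Sequence[ChainSpec]) -> SystemTopology:
    """Expand chain specs (with copy numbers) into flat per-bead arrays."""
    chain_ids, idx_in_chain, rtypes, rclasses, names = [], [], [], [], []
    bonds = []
    cid = 0
    offset = 0
    for spec in chain_specs:
        codes = [AMINO_ACIDS.index(a) for a in spec.sequence]
        classes = [_classify(a) for a in spec.sequence]
        n = len(codes)
        for _ in range(spec.copies):
            chain_ids.extend([cid] * n)
            idx_in_chain.extend(range(n))
            rtypes.extend(codes)
            rclasses.extend(classes)
            names.append(spec.name)
            b = np.arange(offset, offset + n - 1)
            bonds.append(np.stack([b, b + 1], axis=1))
            offset += n
            cid += 1
    rtypes = np.asarray(rtypes, dtype=np.intp)
    topo = SystemTopology(
        chain_ids=np.asarray(chain_ids, dtype=np.intp),
        index_in_chain=np.asarray(idx_in_chain, dtype=np.intp),
        residue_types=rtypes,
        residue_classes=np.asarray(rclasses, dtype=np.intp),
        bonds=np.concatenate(bonds) if bonds else np.empty((0, 2), dtype=np.intp),
        cysteines=np.flatnonzero(rtypes == AMINO_ACIDS.index("C")),
        chain_names=names,
    )
    # structured-domain mask (per copy)
    mask = np.zeros(topo.n_residues, dtype=bool)
    sl = topo.chain_slices()
    ci = 0
    for spec in chain_specs:
        for _ in range(spec.copies):
            for dom in spec.structured_domains:
                mask[sl[ci].start + dom.start - 1: sl[ci].start + dom.end] = True
            ci += 1
    topo.structured_mask = mask
    return topo


# ---------------------------------------------------------------------------
# composition I/O

def load_composition(fasta_path: str | Path, composition_path: str | Path,
                     ) -> list[ChainSpec]:
    """Read chain specs from a FASTA file plus a ``name<TAB>copies`` table.

    Order follows the composition file.  An optional third column declares
    structured domains as ``start-end[:mapref]`` items separated by commas.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    specs: list[ChainSpec] = []
    for line in Path(composition_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        name, copies = parts[0], int(parts[1])
        if name not in records:
            raise KeyError(f"composition references unknown sequence {name!r}")
        domains = []
        if len(parts) > 2 and parts[2]:
            for item in parts[2].split(","):
                rng, _, ref = item.partition(":")
                a, b = rng.split("-")
                domains.append(StructuredDomain(int(a), int(b), ref or None))
        specs.append(ChainSpec(name, records[name], copies, domains))
    return specs


def write_composition(specs: Sequence[ChainSpec], fasta_path: str | Path,
                      composition_path: str | Path) -> None:
    """Inverse of :func:`load_composition` (used for round-trips and fixtures)."""
    recs = [SeqRecord(Seq(s.sequence), id=s.name, description="") for s in specs]
    SeqIO.write(recs, str(fasta_path), "fasta")
    with open(composition_path, "w") as fh:
        for s in specs:
            doms = ",".join(
                f"{d.start}-{d.end}" + (f":{d.contact_map}" if d.contact_map else "")
                for d in s.structured_domains)
            fh.write(f"{s.name}\t{s.copies}" + (f"\t{doms}" if doms else "") + "\n")


def composition_summary(specs: Sequence[ChainSpec]) -> dict:
    """Total residue count and per-record means of chain length / cysteines.

    Means are over distinct sequence records (not chain instances), the
    convention under which the bundled compositions reproduce their
    published summary rows.
    """
    total = sum(s.copies * len(s.sequence) for s in specs)
    return {
        "total_residues": total,
        "mean_length": float(np.mean([len(s.sequence) for s in specs])),
        "mean_cysteines": float(np.mean([s.n_cys for s in specs])),
        "n_chains": sum(s.copies for s in specs),
    }


# ---------------------------------------------------------------------------
# static contact maps

def load_static_contact_map(tsv_path: str | Path, spec: ChainSpec,
                            map_ref: str | None = None) -> list[tuple[int, int, float]]:
    """Read an ``i<TAB>j<TAB>distance_nm`` native-contact table for one chain.

    Indices are 1-based within the chain and must fall inside a declared
    structured domain of ``spec``.  The distance is the native Ca-Ca
    separation that becomes the Lennard-Jones minimum of the pair.
    Pairs must satisfy |i-j| >= 3 unless both residues are cysteines
    (a fixed intra-domain disulfide).
    """
    domains = [d for d in spec.structured_domains
               if map_ref is None or d.contact_map == map_ref]
    entries: list[tuple[int, int, float]] = []
    for ln, line in enumerate(Path(tsv_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i_s, j_s, d_s = line.split("\t")
        i, j, dist = int(i_s), int(j_s), float(d_s)
        if i > j:
            i, j = j, i
        if dist <= 0:
            raise ValueError(f"{tsv_path}:{ln}: non-positive distance {dist}")
        for idx in (i, j):
            if not any(d.start <= idx <= d.end for d in domains):
                raise IndexError(
                    f"{tsv_path}:{ln}: residue {idx} outside structured domains")
        both_cys = spec.sequence[i - 1] == "C" and spec.sequence[j - 1] == "C"
        if j - i < 3 and not both_cys:
            raise ValueError(f"{tsv_path}:{ln}: |i-j| < 3 for non-disulfide pair")
        entries.append((i, j, dist))
    return entries


def attach_static_contacts(topology: SystemTopology, specs: Sequence[ChainSpec],
                           maps: dict[str, list[tuple[int, int, float]]]) -> None:
    """Apply per-chain contact maps to every copy of each chain in place.

    ``maps`` is keyed by chain-spec name; entries are 1-based (i, j, dist).
    """
    pairs, dists = [], []
    sl = topology.chain_slices()
    ci = 0
    for spec in specs:
        entries = maps.get(spec.name, [])
        for _ in range(spec.copies):
            base = sl[ci].start
            for i, j, d in entries:
                pairs.append((base + i - 1, base + j - 1))
                dists.append(d)
            ci += 1
    if pairs:
        topology.static_contacts = np.asarray(pairs, dtype=np.intp)
        topology.static_distances = np.asarray(dists, dtype=float)


# ---------------------------------------------------------------------------
# initial conformation

class PlacementError(RuntimeError):
    """Raised when the self-avoiding-walk generator exhausts its retry budget."""


def generate_initial_conformation(
    topology: SystemTopology,
    density: float = 0.1,
    rng: np.random.Generator | None = None,
    max_chain_retries: int = 200,
    max_step_retries: int = 80,
    growth_factor: float = 1.05,
) -> tuple[np.ndarray, InitialBox]:
    """Place every chain as a self-avoiding random walk in a dilute box.

    The box starts cubic with ``volume = N / density``.  Bonded beads sit
    exactly ``BOND_LENGTH`` apart; any pair of non-bonded beads keeps at
    least ``EXCLUDED_VOLUME_CUTOFF``.  A walk that leaves the box triggers
    a 5% enlargement of all box dimensions and a retry of that chain, so
    the realized density never exceeds the requested one.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng() if rng is None else rng
    n = topology.n_residues
    edge = (n / density) ** (1.0 / 3.0)
    box = np.array([edge, edge, edge])
    placed: list[np.ndarray] = []
    # keep walks out of the walls' repulsive zone along Z
    wall_margin = EXCLUDED_VOLUME_CUTOFF

    def inside(p: np.ndarray) -> bool:
        if np.any(p <= 0) or np.any(p >= box):
            return False
        return wall_margin < p[2] < box[2] - wall_margin

    def too_close(arr: np.ndarray, p: np.ndarray) -> bool:
        # min-image in the periodic X/Y directions, plain distance along Z
        d = arr - p
        d[:, 0] -= box[0] * np.round(d[:, 0] / box[0])
        d[:, 1] -= box[1] * np.round(d[:, 1] / box[1])
        return bool(np.min(np.einsum("ij,ij->i", d, d)) < EXCLUDED_VOLUME_CUTOFF ** 2)

    def clash(p: np.ndarray, chain: list[np.ndarray], skip_last: bool) -> bool:
        for arr in placed:
            if too_close(arr.copy(), p):
                return True
        # against own chain, excluding the bonded predecessor
        own = chain[:-1] if skip_last else chain
        if own:
            if too_close(np.asarray(own, dtype=float), p):
                return True
        return False

    for sl in topology.chain_slices():
        length = sl.stop - sl.start
        for attempt in range(max_chain_retries):
            chain: list[np.ndarray] = []
            lo = np.array([0.05 * box[0], 0.05 * box[1], wall_margin * 1.2])
            hi = np.array([0.95 * box[0], 0.95 * box[1], box[2] - wall_margin * 1.2])
            start = rng.uniform(lo, np.maximum(hi, lo + 1e-9))
            if clash(start, chain, skip_last=False):
                continue
            chain.append(start)
            ok = True
            while len(chain) < length:
                for _ in range(max_step_retries):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    p = chain[-1] + BOND_LENGTH * v
                    if not inside(p):
                        continue
                    if not clash(p, chain, skip_last=True):
                        chain.append(p)
                        break
                else:
                    ok = False
                    break
            if ok and len(chain) == length:
                placed.append(np.asarray(chain))
                break
            # the usual cause of failure is the walk running out of room at
            # the boundary: enlarge the box (chains already placed stay) and
            # retry, so the realized density only ever drops
            box *= growth_factor
        else:
            raise PlacementError(
                f"could not place chain of length {length} after "
                f"{max_chain_retries} attempts")
    positions = np.concatenate(placed)
    realized = n / np.prod(box)
    return positions, InitialBox(Lx=float(box[0]), Ly=float(box[1]),
                                 s=float(box[2]), density=float(realized))
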