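"""Deterministic toy inputs with known ground truth.

Every generator here is seeded and self-validating: the returned object
carries the oracle value it was built to have (entanglement count of a
hook, cavity volume of a shell, planted amplitude and phase of a
rheology signal), so tests never need external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Box
from .topology import ChainSpec

#: uncharged, gluten-flavoured residues used to pad toy sequences
_PAD_ALPHABET = "GPSTAVLFY"


def make_toy_sequences(n_chains: int, length: int, q_fraction: float = 0.35,
                       c_count: int = 2, seed: int = 0) -> list[ChainSpec]:
    """Glutamine-rich toy chains: deterministic composition, seeded order.

    The glutamine count is round(q_fraction * length); cysteines are
    placed away from the termini; the remainder is drawn from an
    uncharged gluten-like alphabet.  Same arguments + seed give
    bit-identical sequences.
    """
    if not 0.0 <= q_fraction <= 1.0:
        raise ValueError("q_fraction must be within [0, 1]")
    n_q = int(round(q_fraction * length))
    if n_q + c_count > length:
        raise ValueError("impossible composition: Q fraction + Cys count too large")
    rng = np.random.default_rng(seed)
    specs = []
    for c in range(n_chains):
        letters = (["Q"] * n_q
                   + ["C"] * c_count
                   + [_PAD_ALPHABET[k] for k in
                      rng.integers(0, len(_PAD_ALPHABET), length - n_q - c_count)])
        order = rng.permutation(length)
        seq = "".join(np.array(letters, dtype="U1")[order])
        specs.append(ChainSpec(name=f"toy{c}", sequence=seq))
    return specs


def make_gluten_like_composition() -> list[ChainSpec]:
    """Synthetic two-record composition matching the published summary of
    the gluten system: 4271 residues in total, record-mean chain length
    384 and record-mean cysteine count 6.5.

    The sequences themselves are synthetic stand-ins (glutamine/proline
    rich repeats), not database gluten sequences.
    """
    def repeat_seq(length: int, n_cys: int) -> str:
        motif = "QQPGQGQQPQQSF"  # Q-rich low-complexity repeat
        seq = (motif * (length // len(motif) + 1))[:length]
        # distribute cysteines evenly, off the termini
        pos = np.linspace(10, length - 10, n_cys, dtype=int)
        chars = list(seq)
        for p in pos:
            chars[p] = "C"
        return "".join(chars)

    return [
        ChainSpec(name="synthA", sequence=repeat_seq(431, 7), copies=6),
        ChainSpec(name="synthB", sequence=repeat_seq(337, 6), copies=5),
    ]


# ---------------------------------------------------------------------------
# geometry fixtures


@dataclass
class GeometryFixture:
    kind: str
    chains: list[np.ndarray] = field(default_factory=list)
    box: Box | None = None
    oracle: dict = field(default_factory=dict)


def _polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline keeping endpoints; vertex gaps >= spacing."""
    pts = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        n = max(1, int(np.floor(np.linalg.norm(seg) / spacing)))
        for k in range(1, n + 1):
            pts.append(a + seg * (k / n))
    return np.asarray(pts)


def make_geometry_fixture(kind: str, seed: int = 0) -> GeometryFixture:
    """Hand-built configurations with known topology/volume.

    ``straight_pair``: two parallel straight chains -> 0 entanglements.
    ``hook_pair``: one straight chain threaded by a chain whose path goes
    over it while both its ends sit below -> exactly 1 entanglement.
    ``shell``: a watertight spherical bead shell; with a 0.38 nm probe
    the interior cavity has radius 1.5 nm.
    ``shell_box``/``shell_box_divided``: a hollow rectangular channel,
    optionally split in two by a bead wall (cavity count 1 vs 2).
    """
    if kind == "straight_pair":
        x = np.linspace(-5, 5, 21)
        c1 = np.stack([x, np.zeros_like(x), np.zeros_like(x)], axis=1)
        c2 = c1 + np.array([0.0, 2.0, 0.0])
        return GeometryFixture(kind, [c1, c2], oracle={"l_k": 0})
    if kind == "hook_pair":
        x = np.linspace(-5, 5, 21)
        c1 = np.stack([x, np.zeros_like(x), np.zeros_like(x)], axis=1)
        hook = np.array([
            [0.0, -4.0, -2.5],
            [0.0, -1.2, -2.5],
            [0.0, -1.2, 1.2],
            [0.0, 1.2, 1.2],
            [0.0, 1.2, -2.5],
            [0.0, 4.0, -2.5],
        ])
        c2 = _polyline(hook, spacing=0.5)
        return GeometryFixture(kind, [c1, c2], oracle={"l_k": 1})
    if kind == "shell":
        probe = 0.38
        unit = _icosphere(subdivisions=2)
        # scale the shell so the closest bead pair sits at 0.5 nm: the
        # near-hexagonal icosphere then has coverage gaps ~0.3 nm, well
        # below the probe radius, so the shell is watertight
        from scipy.spatial import cKDTree
        d, _ = cKDTree(unit).query(unit, k=2)
        r_shell = 0.5 / float(d[:, 1].min())
        pts = r_shell * unit
        box = Box(Lx=2 * (r_shell + 1.0), Ly=2 * (r_shell + 1.0),
                  s=2 * (r_shell + 1.0))
        pts += np.array([box.Lx / 2, box.Ly / 2, box.s / 2])
        r_eff = r_shell - probe
        return GeometryFixture(kind, [pts], box=box,
                               oracle={"n_cavities": 1,
                                       "volume": 4.0 / 3.0 * np.pi * r_eff ** 3,
                                       "r_shell": r_shell, "probe": probe})
    if kind in ("shell_box", "shell_box_divided"):
        # hollow channel [1, 7] x [1, 3] x [1, 3] walled by beads on a
        # 0.5 nm lattice (shared edges deduplicated)
        lo = np.array([1.0, 1.0, 1.0])
        hi = np.array([7.0, 3.0, 3.0])
        step = 0.5
        grids = [np.arange(lo[d], hi[d] + 1e-9, step) for d in range(3)]
        pts = []
        for d in range(3):
            a, b = [k for k in range(3) if k != d]
            ga, gb = np.meshgrid(grids[a], grids[b], indexing="ij")
            for val in (lo[d], hi[d]):
                face = np.zeros((ga.size, 3))
                face[:, a] = ga.ravel()
                face[:, b] = gb.ravel()
                face[:, d] = val
                pts.append(face)
        if kind == "shell_box_divided":
            ga, gb = np.meshgrid(grids[1], grids[2], indexing="ij")
            wall = np.zeros((ga.size, 3))
            wall[:, 0] = 4.0
            wall[:, 1] = ga.ravel()
            wall[:, 2] = gb.ravel()
            pts.append(wall)
        allpts = np.unique(np.round(np.concatenate(pts) / step).astype(int),
                           axis=0) * step
        box = Box(Lx=8.0, Ly=4.0, s=4.0)
        return GeometryFixture(kind, [allpts], box=box,
                               oracle={"n_cavities":
                                       2 if kind == "shell_box_divided" else 1})
    raise ValueError(f"unknown fixture kind {kind!r}")


def _icosphere(subdivisions: int = 2) -> np.ndarray:
    """Vertices of a subdivided icosahedron projected onto the unit sphere."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = [(0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
             (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
             (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
             (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1)]
    verts = list(verts)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = verts[a] + verts[b]
                m /= np.linalg.norm(m)
                verts.append(m)
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.asarray(verts)


# ---------------------------------------------------------------------------
# planted signals


def make_planted_rheology(F0: float, delta: float, omega: float,
                          noise_sd: float = 0.0, n_periods: int = 5,
                          amplitude: float = 1.0, samples_per_period: int = 200,
                          seed: int = 0) -> dict:
    """Strain and force series with known (F0, delta) for fit recovery."""
    if n_periods < 2:
        raise ValueError("need at least two periods")
    rng = np.random.default_rng(seed)
    period = 2.0 * np.pi / omega
    t = np.linspace(0.0, n_periods * period, n_periods * samples_per_period,
                    endpoint=False)
    strain = amplitude * np.cos(omega * t)
    force = F0 * np.cos(omega * t + delta)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, len(t))
    return {"t": t, "strain": strain, "force": force,
            "F0": F0, "delta": delta, "omega": omega, "amplitude": amplitude}


def make_ramp_force(kind: str = "triangle", n: int = 200) -> dict:
    """Piecewise-linear force-distance toys for work-integration tests."""
    s = np.linspace(0.0, 10.0, n)
    if kind == "constant":
        f = np.ones_like(s)
        w_true = s.copy()
    elif kind == "triangle":
        f = np.where(s < 5.0, s, np.maximum(10.0 - s, 0.0))
        w_true = np.where(s < 5.0, s ** 2 / 2.0, 12.5 + 10.0 * (s - 5.0)
                          - (s ** 2 - 25.0) / 2.0)
    elif kind == "rupture":
        f = np.where(s < 4.0, 2.0, 0.0)
        w_true = np.where(s < 4.0, 2.0 * s, 8.0)
    else:
        raise ValueError(f"unknown ramp kind {kind!r}")
    return {"s": s, "force": f, "work_true": w_true}
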