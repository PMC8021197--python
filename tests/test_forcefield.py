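"""Potentials: values at landmarks, gradients, frames, symmetries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import glutensim as g
from glutensim.forcefield import (CONTACT_CAP_FRAC, SIX_ROOT_2, bond_force,
                                  contact_force, electrostatic_force,
                                  excluded_volume_force)


# ---------------------------------------------------------------------------
# landmark values


class TestPotentialLandmarks:
    def test_excluded_volume(self, cfg):
        assert g.excluded_volume_energy(0.5, cfg) == pytest.approx(0.0)
        assert g.excluded_volume_energy(cfg.sigma0, cfg) == pytest.approx(1.0)
        assert g.excluded_volume_energy(0.6, cfg) == 0.0
        assert g.excluded_volume_energy(10.0, cfg) == 0.0

    def test_bond(self, cfg):
        assert g.bond_energy(0.38, cfg) == pytest.approx(0.0)
        # V = k (r - r_b)^2 convention (no 1/2)
        assert g.bond_energy(0.39, cfg) == pytest.approx(0.5)
        assert bond_force(0.38, cfg) == pytest.approx(0.0)

    @pytest.mark.parametrize("r_min,depth", [
        (0.5, 2.0),    # backbone-backbone, doubled strength
        (0.68, 1.0),   # backbone-sidechain
        (0.59, 4.0),   # disulfide
    ])
    def test_contact_depths(self, r_min, depth):
        sigma = r_min / SIX_ROOT_2
        assert g.contact_energy(r_min, sigma, depth) == pytest.approx(-depth)
        # minimum: force vanishes there
        assert contact_force(r_min, sigma, depth) == pytest.approx(0.0, abs=1e-9)

    def test_ss_contact_unit_depth(self):
        sigma = 0.3
        assert g.contact_energy(SIX_ROOT_2 * sigma, sigma, 1.0) == pytest.approx(-1.0)

    def test_electrostatics(self, cfg):
        assert g.electrostatic_energy(0.7, 0.0, 1.0, cfg) == 0.0
        assert (g.electrostatic_energy(0.7, 1.0, -1.0, cfg)
                == g.electrostatic_energy(0.7, -1.0, 1.0, cfg))
        assert g.electrostatic_energy(0.7, 1.0, -1.0, cfg) < 0
        # with eps_r ~ r the closed form gives V(2r)/V(r) = exp(-r/lambda)/4
        r = 0.6
        ratio = (g.electrostatic_energy(2 * r, 1, 1, cfg)
                 / g.electrostatic_energy(r, 1, 1, cfg))
        assert ratio == pytest.approx(np.exp(-r / cfg.debye_length) / 4.0)

    def test_core_caps_are_finite(self, cfg):
        assert np.isfinite(g.excluded_volume_energy(1e-6, cfg))
        assert np.isfinite(g.contact_energy(1e-6, 0.5, 2.0))


# ---------------------------------------------------------------------------
# force = -dV/dr for every scalar term


@pytest.mark.parametrize("name", ["ev", "bond", "contact", "disulfide", "elec"])
def test_scalar_force_is_negative_gradient(name, cfg):
    h = 1e-6
    rng = np.random.default_rng(hash(name) % 2 ** 31)
    if name == "ev":
        rs = rng.uniform(cfg.ev_cap_r + 0.02, cfg.r_o - 0.02, 40)
        e = lambda r: g.excluded_volume_energy(r, cfg)
        f = lambda r: excluded_volume_force(r, cfg)
    elif name == "bond":
        rs = rng.uniform(0.2, 0.6, 40)
        e = lambda r: g.bond_energy(r, cfg)
        f = lambda r: bond_force(r, cfg)
    elif name == "contact":
        rs = rng.uniform(CONTACT_CAP_FRAC * 0.445 + 0.02, 1.5, 40)
        e = lambda r: g.contact_energy(r, 0.445, 2.0)
        f = lambda r: contact_force(r, 0.445, 2.0)
    elif name == "disulfide":
        sig = 0.59 / SIX_ROOT_2
        rs = rng.uniform(CONTACT_CAP_FRAC * sig + 0.02, 1.2, 40)
        e = lambda r: g.contact_energy(r, sig, 4.0)
        f = lambda r: contact_force(r, sig, 4.0)
    else:
        rs = rng.uniform(0.3, cfg.elec_cutoff - 0.05, 40)
        e = lambda r: g.electrostatic_energy(r, 1.0, -1.0, cfg)
        f = lambda r: electrostatic_force(r, 1.0, -1.0, cfg)
    num = -(e(rs + h) - e(rs - h)) / (2 * h)
    np.testing.assert_allclose(f(rs), num, rtol=1e-5, atol=1e-7)


# ---------------------------------------------------------------------------
# local frames and classification


class TestLocalFrame:
    def test_right_angle_binormal_perpendicular_to_plane(self):
        n_hat, h_hat, ok = g.local_frame([0, 0, 0], [1, 0, 0], [1, 1, 0])
        assert ok
        assert abs(h_hat @ [0, 0, 1]) == pytest.approx(1.0)
        assert n_hat @ [0, 0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(n_hat) == pytest.approx(1.0)

    def test_mirror_reflection_flips_binormal(self):
        rng = np.random.default_rng(3)
        a, b, c = rng.normal(size=(3, 3))
        _, h1, _ = g.local_frame(a, b, c)
        mirror = np.diag([1.0, 1.0, -1.0])
        _, h2, _ = g.local_frame(a @ mirror, b @ mirror, c @ mirror)
        # binormal is a pseudo-vector: reflected frame gives -(h reflected)
        np.testing.assert_allclose(h2, -(h1 @ mirror), atol=1e-12)

    def test_collinear_triple_degenerate(self):
        *_, ok = g.local_frame([0, 0, 0], [1, 0, 0], [2, 0, 0])
        assert not ok


def _two_facing_trimers(flip_to_ss=False):
    """Two 3-bead chains, middle beads 0.45 nm apart along z.

    The triples are bent in x-y, so each binormal h is +-z: the middle
    beads face each other through their backbones -> bb.  Rotating each
    trimer by 90 deg about its own x axis points the sidechain (-n)
    along z instead -> ss.
    """
    lo = np.array([[0.0, 0.0, 0.0], [0.35, 0.15, 0.0], [0.7, 0.0, 0.0]])
    hi = lo + np.array([0.0, 0.0, 0.45])
    if flip_to_ss:
        def rotx(pts, center):
            q = pts - center
            q = np.stack([q[:, 0], -q[:, 2], q[:, 1]], axis=1)
            return q + center
        lo = rotx(lo, lo[1])
        hi = rotx(hi, hi[1])
        # make sure -n points outward correctly by checking both signs below
    topo = g.build_topology([g.ChainSpec("a", "QAQ"), g.ChainSpec("b", "QAQ")])
    pos = np.concatenate([lo, hi])
    return topo, pos


def test_classify_facing_backbones_as_bb():
    topo, pos = _two_facing_trimers()
    frames = g.local_frames(pos, topo)
    kind = g.classify_candidate(1, 4, frames, pos[4] - pos[1])
    assert kind == "bb"


def test_classify_facing_sidechains_as_ss():
    topo, pos = _two_facing_trimers(flip_to_ss=True)
    frames = g.local_frames(pos, topo)
    n_hat, _, valid = frames
    assert valid[1] and valid[4]
    r = pos[4] - pos[1]
    kind = g.classify_candidate(1, 4, frames, r)
    if kind != "ss":
        # the rotation may have pointed +n instead of -n at the partner;
        # mirror the upper trimer about its middle bead to flip n
        pos2 = pos.copy()
        pos2[3:] = 2 * pos[4] - pos[3:]
        frames = g.local_frames(pos2, topo)
        kind = g.classify_candidate(1, 4, frames, pos2[4] - pos2[1])
    assert kind == "ss"


def test_classify_misaligned_returns_none():
    # orthogonal offset: neither h nor -n of bead 1 points at the partner
    topo, pos = _two_facing_trimers()
    frames = g.local_frames(pos, topo)
    sideways = np.array([0.45, 0.0, 0.0])
    assert g.classify_candidate(1, 4, frames, sideways) == "none"


def test_classify_degenerate_frame_returns_none():
    topo = g.build_topology([g.ChainSpec("a", "QAQ"), g.ChainSpec("b", "QAQ")])
    pos = np.array([[0, 0, 0], [0.38, 0, 0], [0.76, 0, 0],      # collinear
                    [0, 0, 0.45], [0.35, 0.15, 0.45], [0.7, 0, 0.45]],
                   dtype=float)
    frames = g.local_frames(pos, topo)
    assert not frames[2][1]
    assert g.classify_candidate(1, 4, frames, pos[4] - pos[1]) == "none"


# ---------------------------------------------------------------------------
# global symmetries of the total energy


@pytest.fixture(scope="module")
def frozen_sim():
    from glutensim.engine import Box, Simulation
    specs = g.make_toy_sequences(2, 10, seed=9)
    topo = g.build_topology(specs)
    pos, ib = g.generate_initial_conformation(topo, 0.05, np.random.default_rng(2))
    sim = Simulation(topo, pos, Box(ib.Lx, ib.Ly, ib.s),
                     rng=np.random.default_rng(3))
    sim.scan_contacts()
    sim.registry.lam[:] = 1.0
    return sim


def test_energy_invariant_under_xy_translation_and_z_rotation(frozen_sim):
    sim = frozen_sim
    e0 = sim.total_energy()["potential"]
    pos0 = sim.pos.copy()
    # rigid X/Y translation (walls only constrain Z)
    sim.pos = sim.box.wrap(pos0 + np.array([1.3, -2.1, 0.0]))
    sim.invalidate_forces()
    assert sim.total_energy()["potential"] == pytest.approx(e0, rel=1e-9)
    # rigid rotation about the Z axis through the cluster centroid
    th = 0.77
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    c = pos0.mean(axis=0)
    sim.pos = sim.box.wrap((pos0 - c) @ R.T + c)
    sim.invalidate_forces()
    assert sim.total_energy()["potential"] == pytest.approx(e0, rel=1e-9)
    # full periodic image shift
    sim.pos = pos0 + np.array([sim.box.Lx, 0.0, 0.0])
    sim.box.wrap(sim.pos)
    sim.invalidate_forces()
    assert sim.total_energy()["potential"] == pytest.approx(e0, rel=1e-9)
    sim.pos = pos0
    sim.invalidate_forces()


# ---------------------------------------------------------------------------
# property tests


@given(st.floats(0.31, 2.0))
def test_excluded_volume_nonnegative_and_truncated(r):
    cfg = g.ForceFieldConfig()
    v = g.excluded_volume_energy(r, cfg)
    assert v >= 0.0
    if r >= cfg.r_o:
        assert v == 0.0


@given(st.floats(0.45, 3.0), st.floats(0.35, 0.7))
def test_contact_well_bounded_below_by_depth(r, sigma):
    depth = 2.0
    assert g.contact_energy(r, sigma, depth) >= -depth - 1e-12


def test_config_round_trip(tmp_path, cfg):
    p = tmp_path / "ff.yaml"
    cfg.to_file(p)
    cfg2 = g.ForceFieldConfig.from_file(p)
    for name in g.ForceFieldConfig._SCALARS:
        assert getattr(cfg, name) == getattr(cfg2, name)
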