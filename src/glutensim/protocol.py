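"""The wall-driven rheology protocol.

A run mimics the life of a gluten sample: dilute equilibration of the
freshly generated chains, slow compression to the density of real gluten
(~3.5 residues/nm^3), equilibration, switching on wall adhesion,
optional "kneading" by oscillating one wall (normal Z strain or shear X
strain), a final equilibration during which the post-kneading state is
sampled, and a uniaxial extension to twice the compressed wall
separation that records the force-distance and work-distance curves.

All stage durations live in a :class:`StageSchedule` whose single
``scale`` factor shortens every duration (and speeds every boundary
motion up) by the same amount, so that desk-scale tests exercise the
identical code path as production runs.
"""

from __future__ import annotations

import time as _wallclock
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np

from . import units
from .engine import (Box, Simulation, SimulationParams, UnstableStepError,
                     measured_wall_force)
from .forcefield import ForceFieldConfig
from .topology import (ChainSpec, SystemTopology, build_topology,
                       generate_initial_conformation)

Mode = Literal["none", "normal", "shear"]


@dataclass
class StageSchedule:
    """Durations (tau = ns), speeds (mm/s) and oscillation settings.

    Defaults are the production protocol: 125 us dilute equilibration,
    compression at 2 mm/s to 3.5 residues/nm^3, 150 us equilibration,
    wall adhesion plus another 150 us, five oscillation cycles of
    amplitude 1 nm (period 40 us by default; 100 us of extra
    equilibration replaces them in the oscillation-free control), 75 us
    of final equilibration, then extension to twice the compressed wall
    separation at 0.5 mm/s.
    """

    t_eq1: float = 125_000.0
    compression_speed: float = 2.0        # mm/s
    target_density: float = 3.5           # residues / nm^3
    t_eq2: float = 150_000.0
    t_eq3: float = 150_000.0
    oscillation_amplitude: float = 1.0    # nm
    oscillation_period: float = 40_000.0  # tau
    oscillation_cycles: int = 5
    t_extra_no_osc: float = 100_000.0
    t_eq4: float = 75_000.0
    pull_speed: float = 0.5               # mm/s
    pull_factor: float = 2.0
    scale: float = 1.0                    # desk-scale folding factor

    def __post_init__(self) -> None:
        for name in ("t_eq1", "t_eq2", "t_eq3", "t_eq4", "t_extra_no_osc",
                     "oscillation_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    # scaled quantities -----------------------------------------------------
    def dur(self, name: str) -> float:
        return getattr(self, name) / self.scale

    @property
    def period(self) -> float:
        return self.oscillation_period / self.scale

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    @property
    def compression_speed_nm_tau(self) -> float:
        return units.mm_per_s_to_nm_per_tau(self.compression_speed) * self.scale

    @property
    def pull_speed_nm_tau(self) -> float:
        return units.mm_per_s_to_nm_per_tau(self.pull_speed) * self.scale

    @property
    def force_window(self) -> float:
        """Wall-force averaging window in tau (100 ns at production scale)."""
        return 100.0 / self.scale

    def drive_frequency_kHz(self) -> float:
        """Oscillation frequency implied by the *unscaled* period."""
        return units.period_us_to_frequency_kHz(self.oscillation_period * 1e-3)


@dataclass
class Snapshot:
    time: float
    positions: np.ndarray
    box: Box
    contact_pairs: np.ndarray   # (m, 2) bead ids
    contact_kinds: np.ndarray   # (m,) kind codes
    contact_lambdas: np.ndarray
    contact_sigmas: np.ndarray


@dataclass
class PullCurve:
    """Smoothed force-extension data from the final uniaxial extension."""

    s: np.ndarray          # wall separation (nm), window-averaged
    force: np.ndarray      # eps/nm, window-averaged, tension positive
    work: np.ndarray       # eps (trapezoid integral of force over s)

    def force_nN(self) -> np.ndarray:
        return units.force_to_nN(self.force)

    def work_nN_nm(self) -> np.ndarray:
        return units.force_to_nN(self.work)  # eps = (eps/nm) * nm


@dataclass
class ProtocolResult:
    mode: Mode
    schedule: StageSchedule
    s0: float
    surface_area: float
    timeseries: "np.recarray"
    oscillation: dict | None       # time, strain_offset, force_x/z during drive
    pull: PullCurve
    analysis_snapshots: list[Snapshot]
    pull_snapshots: list[Snapshot]
    stage_log: list[dict]
    simulation: Simulation

    @property
    def total_time(self) -> float:
        return self.stage_log[-1]["t_end"] if self.stage_log else 0.0


class ProtocolAbort(RuntimeError):
    """Raised when a stage cannot be completed (e.g. compression rupture)."""


def _snapshot(sim: Simulation) -> Snapshot:
    reg = sim.registry
    return Snapshot(time=sim.time, positions=sim.pos.copy(),
                    box=replace(sim.box),
                    contact_pairs=np.stack([reg.i, reg.j], axis=1).copy(),
                    contact_kinds=reg.kind.copy(),
                    contact_lambdas=reg.lam.copy(),
                    contact_sigmas=reg.sigma.copy())


class _Recorder:
    """Per-step accumulation of time, wall geometry and wall forces."""

    def __init__(self) -> None:
        self.t, self.s, self.shear, self.fx, self.fz = [], [], [], [], []

    def __call__(self, sim: Simulation) -> None:
        fx, fz = sim.wall_force_sample()
        self.t.append(sim.time)
        self.s.append(sim.box.s)
        self.shear.append(sim.box.shear)
        self.fx.append(fx)
        self.fz.append(fz)

    def as_recarray(self) -> np.recarray:
        return np.rec.fromarrays(
            [np.asarray(x) for x in (self.t, self.s, self.shear, self.fx, self.fz)],
            names="time,s,shear,fx,fz")


def _run(sim: Simulation, duration: float, recorder: _Recorder,
         move: Callable[[int], None] | None = None,
         snap_every: float | None = None,
         snaps: list[Snapshot] | None = None) -> None:
    n_steps = max(1, int(round(duration / sim.params.dt)))
    snap_stride = (max(1, int(round(snap_every / sim.params.dt)))
                   if snap_every else None)
    for k in range(n_steps):
        if move is not None:
            move(k)
        try:
            sim.step(1)
        except UnstableStepError:
            # overlap cascade (e.g. the wall sweeping beads during fast
            # desk-scale compression) or the resulting velocity spike:
            # integrate the same interval with progressively smaller steps
            dt0 = sim.params.dt
            t_target = sim.time + dt0
            try:
                for sub in (10, 100, 1000):
                    small = dt0 / sub
                    n_sub = int(round((t_target - sim.time) / small))
                    if n_sub <= 0:
                        break
                    sim.params.dt = small
                    sim.invalidate_forces()
                    try:
                        sim.step(n_sub)
                        break
                    except UnstableStepError:
                        if sub == 1000:
                            raise
            finally:
                sim.params.dt = dt0
                sim.invalidate_forces()
        recorder(sim)
        if snap_stride and (k + 1) % snap_stride == 0:
            snaps.append(_snapshot(sim))


def compress_box(sim: Simulation, speed_nm_tau: float, target_density: float,
                 recorder: _Recorder | None = None) -> None:
    """Shrink all box dimensions affinely until the target density.

    X and Y bead coordinates rescale with the periodic extents; the Z
    wall sweeps beads ahead of it (their z is never rescaled).  The wall
    separation decreases at the given boundary speed.
    """
    n = sim.topology.n_residues
    density = n / sim.box.volume
    if density >= target_density * 0.99:
        return
    s_final = sim.box.s * (density / target_density) ** (1.0 / 3.0)
    recorder = recorder or _Recorder()
    dt = sim.params.dt
    ds = speed_nm_tau * dt

    def move(_k: int) -> None:
        s_new = max(sim.box.s - ds, s_final)
        factor = s_new / sim.box.s
        sim.box.s = s_new
        sim.box.Lx *= factor
        sim.box.Ly *= factor
        sim.pos[:, 0] *= factor
        sim.pos[:, 1] *= factor
        sim.pos[:, 2] = np.minimum(sim.pos[:, 2], sim.box.s - 1e-6)

    # one spare step so rounding cannot stop short of the target (the move
    # clamps at s_final, so overshoot is impossible)
    duration = (sim.box.s - s_final) / speed_nm_tau + 2 * dt
    _run(sim, duration, recorder, move=move)
    achieved = n / sim.box.volume
    if abs(achieved - target_density) > 0.01 * target_density:
        raise ProtocolAbort(
            f"compression ended at density {achieved:.3f}, "
            f"target {target_density}")


def elongate(sim: Simulation, speed_nm_tau: float, target_s: float,
             recorder: _Recorder, window_steps: int,
             snap_every: float | None = None,
             snaps: list[Snapshot] | None = None) -> PullCurve:
    """Extend the walls to ``target_s`` and integrate the work.

    Returns window-averaged force F(s) (tension positive) and the
    running work W(s) computed by trapezoidal quadrature.  Rupture shows
    up as the force dropping to zero and the work plateauing - it is a
    feature of the data, not an error.
    """
    dt = sim.params.dt
    ds = speed_nm_tau * dt
    start = len(recorder.t)

    def move(_k: int) -> None:
        sim.box.s = min(sim.box.s + ds, target_s)

    duration = (target_s - sim.box.s) / speed_nm_tau
    _run(sim, duration, recorder, move=move, snap_every=snap_every, snaps=snaps)
    s_arr = np.asarray(recorder.s[start:])
    f_arr = np.asarray(recorder.fz[start:])
    w = max(1, min(window_steps, len(f_arr)))
    s_m = measured_wall_force(s_arr, w)
    f_m = measured_wall_force(f_arr, w)
    from scipy.integrate import cumulative_trapezoid
    work = np.concatenate([[0.0], cumulative_trapezoid(f_m, s_m)])
    return PullCurve(s=s_m, force=f_m, work=work)


def run_protocol(
    system: Sequence[ChainSpec] | SystemTopology,
    schedule: StageSchedule,
    mode: Mode = "none",
    seed: int = 0,
    cfg: ForceFieldConfig | None = None,
    params: SimulationParams | None = None,
    initial_density: float = 0.1,
    n_analysis_snapshots: int = 25,
    n_pull_snapshots: int = 25,
) -> ProtocolResult:
    """Execute the full stage sequence and collect everything analysable.

    Every random draw (initial conformation and thermal noise) descends
    from ``seed``, so runs with different ``mode`` share their trajectory
    bit-for-bit up to the end of the pre-oscillation stage.
    """
    if mode not in ("none", "normal", "shear"):
        raise ValueError(f"unknown mode {mode!r}")
    topo = system if isinstance(system, SystemTopology) else build_topology(system)
    cfg = cfg or ForceFieldConfig()
    params = params or SimulationParams()
    ss = np.random.SeedSequence(seed)
    rng_init, rng_dyn = (np.random.default_rng(s) for s in ss.spawn(2))

    pos, box0 = generate_initial_conformation(topo, initial_density, rng_init)
    sim = Simulation(topo, pos, Box(box0.Lx, box0.Ly, box0.s), cfg, params,
                     rng=rng_dyn)
    rec = _Recorder()
    log: list[dict] = []

    def stage(name: str, fn: Callable[[], None]) -> None:
        t0, w0 = sim.time, _wallclock.perf_counter()
        fn()
        log.append({"stage": name, "t_start": t0, "t_end": sim.time,
                    "wallclock_s": _wallclock.perf_counter() - w0})

    # 1: dilute equilibration
    stage("equilibrate_dilute", lambda: _run(sim, schedule.dur("t_eq1"), rec))
    # 2: compression to the working density
    stage("compress", lambda: compress_box(
        sim, schedule.compression_speed_nm_tau, schedule.target_density, rec))
    stage("equilibrate_compressed", lambda: _run(sim, schedule.dur("t_eq2"), rec))
    # 3: wall adhesion
    def enable_adhesion() -> None:
        sim.walls.attraction_enabled = True
        _run(sim, schedule.dur("t_eq3"), rec)
    stage("equilibrate_adhesion", enable_adhesion)

    s0 = sim.box.s
    surface_area = sim.box.wall_area
    osc_data: dict | None = None

    # 4: oscillations (or matched extra equilibration)
    if mode == "none":
        stage("equilibrate_no_oscillation",
              lambda: _run(sim, schedule.dur("t_extra_no_osc"), rec))
    else:
        A = schedule.oscillation_amplitude
        if A >= s0:
            raise ProtocolAbort(f"amplitude {A} nm >= wall separation {s0:.2f} nm")
        period = schedule.period
        omega = schedule.omega
        vmax = A * omega
        dt = params.dt

        def displace(_k: int) -> None:
            if mode == "normal":
                sim.box.s = max(sim.box.s - vmax * dt, s0 - A)
            else:
                sim.box.shear = max(sim.box.shear - vmax * dt, -A)
        stage("move_to_minimum",
              lambda: _run(sim, A / vmax, rec, move=displace))

        t_osc0 = sim.time
        start_idx = len(rec.t)

        def oscillate(_k: int) -> None:
            t = sim.time - t_osc0
            if mode == "normal":
                sim.box.s = s0 - A * np.cos(omega * t)
            else:
                sim.box.shear = -A * np.cos(omega * t)
        stage(f"oscillate_{mode}",
              lambda: _run(sim, schedule.oscillation_cycles * period, rec,
                           move=oscillate))
        osc_data = {
            "t": np.asarray(rec.t[start_idx:]),
            "s": np.asarray(rec.s[start_idx:]),
            "shear": np.asarray(rec.shear[start_idx:]),
            "fx": np.asarray(rec.fx[start_idx:]),
            "fz": np.asarray(rec.fz[start_idx:]),
            "omega": omega, "A": A, "t0": t_osc0,
        }
        # return the moving wall to its rest position
        def restore(_k: int) -> None:
            if mode == "normal":
                sim.box.s = min(sim.box.s + vmax * dt, s0)
            else:
                sim.box.shear = min(sim.box.shear + vmax * dt, 0.0)
        # after an integer number of cycles the wall sits at the minimum
        stage("return_to_rest", lambda: _run(sim, A / vmax, rec, move=restore))

    # 5: final equilibration with analysis snapshots
    analysis_snaps: list[Snapshot] = []
    stage("equilibrate_final", lambda: _run(
        sim, schedule.dur("t_eq4"), rec,
        snap_every=schedule.dur("t_eq4") / n_analysis_snapshots,
        snaps=analysis_snaps))

    # 6: uniaxial extension
    pull_snaps: list[Snapshot] = []
    window_steps = max(1, int(round(schedule.force_window / params.dt)))
    pull_duration = (schedule.pull_factor * s0 - sim.box.s) / schedule.pull_speed_nm_tau
    holder: dict = {}
    stage("elongate", lambda: holder.update(curve=elongate(
        sim, schedule.pull_speed_nm_tau, schedule.pull_factor * s0, rec,
        window_steps, snap_every=pull_duration / n_pull_snapshots,
        snaps=pull_snaps)))

    return ProtocolResult(
        mode=mode, schedule=schedule, s0=s0, surface_area=surface_area,
        timeseries=rec.as_recarray(), oscillation=osc_data,
        pull=holder["curve"], analysis_snapshots=analysis_snaps,
        pull_snapshots=pull_snaps, stage_log=log, simulation=sim)
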