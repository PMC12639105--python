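"""Langevin dynamics with a potential-switching scheduler.

The integrator is BAOAB splitting of underdamped Langevin dynamics with
per-bead unit mass.  State transitions of the motor are modeled by abruptly
replacing the state-dependent potential terms (hydrogen-bond contact set
and loop-target restraints) at fixed step intervals; coordinates and
velocities are untouched at the switch instant and the system then relaxes
on the new energy surface.  All randomness flows from a single seeded
generator, so a scenario + protocol + seed determines the trajectory
bitwise.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ringmotor import _kernels as K
from ringmotor.energetics import (
    ActivePotentials,
    ForceFieldParams,
    make_active_potentials,
)
from ringmotor.synthetic_topology import Assembly, ReferenceState

log = logging.getLogger("ringmotor.engine")

__all__ = [
    "SimState",
    "SwitchProtocol",
    "Trajectory",
    "make_sim",
    "langevin_step",
    "relax",
    "apply_switch",
    "run_protocol",
    "TOY_SWITCH_INTERVAL",
]

#: Default toy switching interval (steps).  Chosen as the smallest interval
#: at which the post-switch energy reaches a plateau in the toy systems
#: (slope test over the last 20% of a segment); see docs/methods.md.
TOY_SWITCH_INTERVAL = 16000

_CHUNK = 25  # steps between neighbor-list rebuilds / noise draws
_FORCE_OVERFLOW = 1.0e5


class EngineError(RuntimeError):
    pass


@dataclass
class SimState:
    """Mutable integration state."""

    assembly: Assembly
    params: ForceFieldParams
    active: ActivePotentials
    pos: np.ndarray
    vel: np.ndarray
    forces: np.ndarray
    step: int
    state_id: int
    rng: np.random.Generator
    dt: float
    energy: float = 0.0
    steps_since_switch: int = 10**9  # large: grips mature before 1st switch

    def refresh_forces(self) -> None:
        self.forces, self.energy = self.active.forces(self.pos)


@dataclass
class SwitchProtocol:
    """Ordered (cyclic) state sequence with a fixed switching interval.

    ``mode`` is ``full`` (switch contacts + conformation),
    ``conformation_only`` (switch loop targets, keep the hydrogen-bond
    contact set: the control for artificial-energy-input effects), or
    ``frozen`` (no potential change; a diffusion null).
    """

    sequence: tuple = (1, 2, 3)
    interval: int = TOY_SWITCH_INTERVAL
    mode: str = "full"
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if len(self.sequence) < 1:
            raise ValueError("sequence must have >= 1 state")
        if self.mode not in ("full", "conformation_only", "frozen"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Trajectory:
    """Recorded frames plus switch-event markers."""

    frames: np.ndarray  # (F, N, 3) float32
    frame_step: np.ndarray  # (F,) int64
    frame_state: np.ndarray  # (F,) int16
    switch_events: list  # [(step, from_state, to_state)]
    seed: int
    scenario: object
    interval: int
    dt: float
    assembly: Optional[Assembly] = field(default=None, repr=False)
    params: Optional[ForceFieldParams] = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# --------------------------------------------------------------------------


def _state_by_id(assembly: Assembly, state_id: int) -> ReferenceState:
    for s in assembly.states:
        if s.state_id == state_id:
            return s
    raise ValueError(f"unknown state id {state_id}")


def make_sim(
    assembly: Assembly,
    params: Optional[ForceFieldParams] = None,
    seed: int = 0,
    state_id: int = 1,
) -> SimState:
    """Initialize a simulation: state-1 potentials and Maxwell-Boltzmann
    velocities (resampled only here, never at switches)."""
    params = params or ForceFieldParams()
    state = _state_by_id(assembly, state_id)
    active = make_active_potentials(state, params, assembly)
    rng = np.random.default_rng(seed)
    pos = assembly.pos.astype(float).copy()
    vel = np.zeros_like(pos)
    mob = assembly.mobile
    vel[mob] = rng.standard_normal((int(mob.sum()), 3)) * np.sqrt(
        params.temperature / assembly.mass[mob, None]
    )
    sim = SimState(
        assembly=assembly, params=params, active=active, pos=pos, vel=vel,
        forces=np.zeros_like(pos), step=0, state_id=state_id, rng=rng,
        dt=params.dt,
    )
    sim.refresh_forces()
    # initial grips are mature on their assembly-time phosphates
    active.well_grip[:] = active.chosen
    return sim


def _run_steps(sim: SimState, n_steps: int) -> None:
    """Advance ``n_steps`` BAOAB steps in chunks, rebuilding neighbor lists
    between chunks.  Halves the timestep (persistently) on force overflow."""
    a = sim.assembly
    mob_u8 = a.mobile.astype(np.uint8)
    inv_m = 1.0 / a.mass
    n_mob = int(a.mobile.sum())
    done = 0
    chunk_no = 0
    while done < n_steps:
        n = min(_CHUNK, n_steps - done)
        sim.active.rebuild_neighbors(sim.pos)
        # sim.forces carries the forces from the last step of the previous
        # chunk (or from refresh_forces after a switch): BAOAB's first
        # half-kick reuses them
        noise = sim.rng.standard_normal((n, n_mob, 3))
        e = K.baoab_chunk(
            sim.pos, sim.vel, sim.forces, mob_u8, inv_m, noise, sim.dt,
            sim.params.gamma, sim.params.temperature,
            *sim.active._kernel_args(sim.pos, sim.forces)[2:],
        )
        done += n
        chunk_no += 1
        sim.step += n
        sim.steps_since_switch += n
        sim.active.update_well_levels(sim.pos, sim.steps_since_switch)
        sim.active.update_loop_targets(sim.steps_since_switch)
        sim.energy = float(e)
        if not np.isfinite(e):
            raise EngineError(f"non-finite energy at step {sim.step}")
        if chunk_no % 8 == 0 or done >= n_steps:
            if not np.all(np.isfinite(sim.pos)):
                bad = np.where(~np.isfinite(sim.pos).any(axis=1))[0]
                raise EngineError(
                    f"non-finite coordinates at step {sim.step}"
                    + (f" (bead {bad[0]})" if len(bad) else "")
                )
            fmax = float(np.abs(sim.forces).max()) if sim.forces.size else 0.0
            if fmax > _FORCE_OVERFLOW:
                sim.dt *= 0.5
                log.warning(
                    "force overflow (%.3g) at step %d: dt halved to %g",
                    fmax, sim.step, sim.dt,
                )


def langevin_step(
    sim: SimState,
    dt: Optional[float] = None,
    gamma: Optional[float] = None,
    temperature: Optional[float] = None,
) -> SimState:
    """One underdamped Langevin (BAOAB) update; deterministic given the
    generator state."""
    if dt is not None:
        sim.dt = float(dt)
    if gamma is not None:
        sim.params = dataclasses.replace(sim.params, gamma=float(gamma))
    if temperature is not None:
        sim.params = dataclasses.replace(
            sim.params, temperature=float(temperature)
        )
    if dt is not None and dt <= 0:
        raise ValueError("dt must be > 0")
    _run_steps(sim, 1)
    return sim


def relax(sim: SimState, n_steps: int = 2000, minimize_iters: int = 300) -> SimState:
    """Steepest-descent minimization followed by thermal equilibration.

    The final potential energy never exceeds the initial one by more than
    thermal fluctuation; divergence raises :class:`EngineError`.
    """
    sim.active.rebuild_neighbors(sim.pos)
    f, e0 = sim.active.forces(sim.pos)
    e = e0
    for it in range(minimize_iters):
        fmax = float(np.abs(f).max()) if f.size else 0.0
        if fmax < 1e-3:
            break
        step = min(0.02, 0.5 / max(fmax, 1e-9))
        trial = sim.pos + step * f * sim.assembly.mobile[:, None]
        f2, e2 = sim.active.forces(trial)
        if e2 <= e:
            sim.pos, f, e = trial, f2, e2
        else:
            # crude backtracking
            trial = sim.pos + 0.2 * step * f * sim.assembly.mobile[:, None]
            f2, e2 = sim.active.forces(trial)
            if e2 <= e:
                sim.pos, f, e = trial, f2, e2
            else:
                break
    if not np.isfinite(e):
        raise EngineError("minimization diverged")
    if n_steps > 0:
        _run_steps(sim, n_steps)
    sim.refresh_forces()
    return sim


def apply_switch(sim: SimState, next_state: int, mode: str = "full") -> SimState:
    """Abruptly switch the state-dependent potentials.

    Coordinates and velocities are untouched; switching to the current
    state leaves the active potentials unchanged.
    """
    state = _state_by_id(sim.assembly, next_state)
    sim.active.set_state(state, mode=mode)
    if mode != "frozen":
        sim.state_id = next_state
        sim.steps_since_switch = 0
        sim.active.update_loop_targets(0)
        if mode == "full":
            sim.active.update_well_levels(sim.pos, 0)
    sim.refresh_forces()
    log.info("switch -> state %s (mode=%s) at step %d", next_state, mode,
             sim.step)
    return sim


def run_protocol(
    assembly: Assembly,
    protocol: SwitchProtocol,
    seed: int = 0,
    params: Optional[ForceFieldParams] = None,
    subsample: int = 100,
    relax_steps: int = 2000,
) -> Trajectory:
    """Run the switching protocol and record a trajectory.

    The run starts with minimization + equilibration in the first state of
    the sequence, records one segment per state dwell, and applies
    ``len(sequence) * n_cycles`` switches; each cycle ends back in the
    first state so the final transition of a cycle is measurable.
    """
    params = params or ForceFieldParams()
    sim = make_sim(assembly, params, seed=seed, state_id=protocol.sequence[0])
    relax(sim, n_steps=relax_steps)
    sim.step = 0  # trajectory clock starts after preparation

    frames, fsteps, fstates = [], [], []
    events = []

    def record():
        frames.append(sim.pos.astype(np.float32).copy())
        fsteps.append(sim.step)
        fstates.append(sim.state_id)

    every = max(1, protocol.interval // max(1, subsample))

    def run_segment():
        remaining = protocol.interval
        while remaining > 0:
            n = min(every, remaining)
            _run_steps(sim, n)
            remaining -= n
            record()

    record()
    run_segment()  # initial dwell in sequence[0]
    L = len(protocol.sequence)
    for c in range(protocol.n_cycles):
        for k in range(L):
            nxt = protocol.sequence[(k + 1) % L]
            events.append((sim.step, sim.state_id, nxt))
            apply_switch(sim, nxt, mode=protocol.mode)
            run_segment()
    return Trajectory(
        frames=np.stack(frames),
        frame_step=np.asarray(fsteps, dtype=np.int64),
        frame_state=np.asarray(fstates, dtype=np.int16),
        switch_events=events,
        seed=seed,
        scenario=assembly.scenario,
        interval=protocol.interval,
        dt=params.dt,
        assembly=assembly,
        params=params,
    )
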