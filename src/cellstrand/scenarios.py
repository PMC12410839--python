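"""End-to-end simulation protocols.

Two experiments are implemented:

* **Invasion** -- a confluent monolayer is seeded in the reservoir,
  relaxed to physical shapes, and then released to follow the
  chemoattractant into the channel.  The run is monitored for
  dissociation events and, by default, terminated as soon as the first
  detachment is confirmed, with an 18-hour observation cap; replicates
  reaching the cap unruptured are right-censored.

* **Jamming** -- the channel entrance stays closed and the reservoir
  wraps periodically in x, so the confluent tissue stays confined.  All
  cells remain followers; their trajectories are recorded for
  mean-squared-displacement analysis of the solid-fluid (jamming)
  transition.

Every replicate is a pure function of (configuration, master seed,
replicate index): the master seed deterministically spawns separate
streams for seeding jitter, the leader lottery, and each cell's
polarity noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .analysis import RuptureEvent, contact_graph, detect_rupture
from .dynamics import (
    FOLLOWER,
    CellRecord,
    center_of_mass_all,
    spawn_cell_rngs,
    stable_dt,
    step_fields,
    step_polarity,
    update_com_velocity,
)
from .energetics import ModelParams, hamiltonian, interface_width
from .fields import (
    ChannelGeometry,
    GridSpec,
    PhaseFieldState,
    build_wall_field,
    tanh_disk,
)
from .states import update_states

__all__ = [
    "RunProtocol",
    "InvasionResult",
    "seed_monolayer",
    "equilibrate",
    "run_invasion",
    "run_jamming",
    "run_invasion_ensemble",
    "monolayer_capacity",
    "calibrate_contact_threshold",
    "OMEGA_BY_WIDTH",
]

# Width-dependent cell-cell adhesion profile (units of the reference
# omega0): adhesion is effectively weaker in narrow confinement.
OMEGA_BY_WIDTH = {6.0: 0.7, 10.0: 0.7, 20.0: 0.8, 50.0: 1.0}


@dataclass(frozen=True)
class RunProtocol:
    """Run schedule shared by both experiments (times in hours)."""

    scenario: str = "invasion"  # "invasion" | "jamming"
    t_max: float = 18.0
    t_eq: float = 0.5
    terminate_on_first_rupture: bool = True
    analysis_interval: float = 0.05  # rupture monitoring cadence (3 min)
    state_interval: float = 0.05  # state-machine update cadence
    record_interval: float = 0.05  # trajectory output cadence

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.scenario not in ("invasion", "jamming"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class InvasionResult:
    """Outcome of one invasion replicate."""

    replicate: int
    event: RuptureEvent
    entered: bool = False
    entry_time: float = float("nan")
    n_leaders: int = 0
    n_guided: int = 0
    failed: bool = False
    max_overshoot: float = 0.0
    trajectory: pd.DataFrame | None = None
    energy: pd.DataFrame | None = None  # per-frame Hamiltonian breakdown
    final_state: PhaseFieldState | None = None
    final_cells: list | None = None


def _lattice_slots(geom: ChannelGeometry, params: ModelParams) -> list:
    """Hexagonal lattice sites filling the reservoir bottom-up."""
    a = 2.0 * params.R  # lattice constant: touching preferred disks
    inset = 0.55 * params.R
    y0 = geom.y0 + inset
    y1 = geom.entrance_y - inset
    slots = []
    row = 0
    y = y0
    while y <= y1 + 1e-9:
        if geom.periodic_x:
            # evenly divide the wrapped width so the seam does not overlap
            n_x = max(1, int(geom.reservoir_w // a))
            ax = geom.reservoir_w / n_x
            off = 0.5 * ax if row % 2 else 0.0
            xs = [geom.x0 + off + k * ax for k in range(n_x)]
        else:
            off = 0.5 * a if row % 2 else 0.0
            xs = []
            x = geom.x0 + inset + off
            while x <= geom.x0 + geom.reservoir_w - inset + 1e-9:
                xs.append(x)
                x += a
        slots.extend((x, y) for x in xs)
        y += a * np.sqrt(3.0) / 2.0
        row += 1
    slots.sort(key=lambda p: (p[1], p[0]))
    return slots


def monolayer_capacity(geom: ChannelGeometry, params: ModelParams) -> int:
    """Number of cells that fill the reservoir to confluence."""
    return max(1, len(_lattice_slots(geom, params)))


def _lattice_positions(
    geom: ChannelGeometry, n_cells: int, params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jittered lattice positions for ``n_cells`` cells."""
    if n_cells == 1:
        # a lone cell sits at the reservoir center, clear of all walls
        pos = np.array(
            [[geom.x0 + 0.5 * geom.reservoir_w, geom.y0 + 0.5 * geom.reservoir_h]]
        )
        return pos + rng.uniform(-0.3, 0.3, size=pos.shape)
    slots = _lattice_slots(geom, params)
    if len(slots) < n_cells:
        raise ValueError(
            f"reservoir holds at most {len(slots)} cells at radius "
            f"{params.R}; requested {n_cells}"
        )
    a = 2.0 * params.R
    pos = np.array(slots[:n_cells])
    pos += rng.uniform(-0.05 * a, 0.05 * a, size=pos.shape)
    return pos


def seed_monolayer(
    geom: ChannelGeometry,
    n_cells: int,
    params: ModelParams,
    grid: GridSpec,
    rng: np.random.Generator,
) -> tuple[PhaseFieldState, list[CellRecord]]:
    """Initial condition: non-overlapping smooth disks on a jittered
    lattice in the reservoir, all cells followers with uniform random
    polarity angles."""
    if n_cells < 1:
        raise ValueError("need at least one cell")
    d = interface_width(params)
    if grid.h > d / 2 + 1e-9:
        raise ValueError(
            f"grid spacing h={grid.h} does not resolve the interface "
            f"(need h <= d/2 = {d / 2:.3f} um)"
        )
    wall = build_wall_field(geom, grid, d)
    pos = _lattice_positions(geom, n_cells, params, rng)
    r0 = 0.95 * params.R
    phi = np.stack([tanh_disk(grid, tuple(p), r0, d) for p in pos])
    state = PhaseFieldState(phi, wall, grid, t=0.0)
    cells = [
        CellRecord(id=i, theta=float(rng.uniform(0.0, 2.0 * np.pi)),
                   state=FOLLOWER, com=tuple(pos[i]))
        for i in range(n_cells)
    ]
    return state, cells


def equilibrate(
    state: PhaseFieldState,
    cells: list[CellRecord],
    params: ModelParams,
    t_eq: float,
    dt: float | None = None,
) -> PhaseFieldState:
    """Relax shapes with self-propulsion off (P = 0, adhesion active).

    The clock is reset to zero afterwards so run time starts at release.
    """
    if t_eq < 0:
        raise ValueError("t_eq must be nonnegative")
    if t_eq == 0:
        return state
    relax = params.with_(p0=0.0)
    if dt is None:
        dt = stable_dt(params, state.grid.h)
    n = int(np.ceil(t_eq / dt))
    for _ in range(n):
        step_fields(state, cells, t_eq / n, relax)
    update_com_velocity(cells, state, dt_frame=0.0)
    state.t = 0.0
    return state


_THRESHOLD_CACHE: dict = {}


def calibrate_contact_threshold(params: ModelParams, h: float) -> float:
    """Contact-area threshold for graph edges at this resolution.

    Set to 10% of h^2 times the peak nodewise overlap phi_i^2 phi_j^2 of
    two equilibrated adhering cells, measured once per (parameters,
    spacing) and cached.
    """
    key = (round(params.alpha, 6), round(params.K, 6), round(params.g, 6),
           round(params.lam, 6), round(params.omega, 6), round(params.R, 4),
           round(h, 6))
    if key in _THRESHOLD_CACHE:
        return _THRESHOLD_CACHE[key]
    d = interface_width(params)
    L = 6.0 * params.R
    n = int(round(L / h))
    grid = GridSpec(n, n, h, boundary_x="periodic", boundary_y="periodic")
    c = L / 2.0
    sep = 2.0 * params.R - 0.4 * d
    phi = np.stack(
        [
            tanh_disk(grid, (c - sep / 2.0, c), 0.95 * params.R, d),
            tanh_disk(grid, (c + sep / 2.0, c), 0.95 * params.R, d),
        ]
    )
    state = PhaseFieldState(phi, np.zeros(grid.shape), grid)
    cells = [CellRecord(id=0, theta=0.0), CellRecord(id=1, theta=np.pi)]
    relax = params.with_(p0=0.0, kappa=0.0)
    dt = stable_dt(params, h)
    for _ in range(int(np.ceil(0.3 / dt))):
        step_fields(state, cells, dt, relax)
    peak = float(np.max(state.phi[0] ** 2 * state.phi[1] ** 2))
    thr = 0.1 * h * h * peak
    _THRESHOLD_CACHE[key] = thr
    return thr


def _replicate_rngs(master_seed: int, replicate: int, n_cells: int):
    """(layout_rng, lottery_rng, per-cell polarity streams) for replicate k."""
    root = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, int(replicate)])
    layout_ss, lottery_ss, pol_ss = root.spawn(3)
    return (
        np.random.default_rng(layout_ss),
        np.random.default_rng(lottery_ss),
        [np.random.default_rng(s) for s in pol_ss.spawn(n_cells)],
    )


def _frame_rows(cells, t):
    return [
        {
            "t": t,
            "id": c.id,
            "state": c.state,
            "x": c.com[0],
            "y": c.com[1],
            "theta": c.theta,
            "n_contacts": c.n_contacts,
        }
        for c in cells
    ]


def run_invasion(config, replicate: int = 0) -> InvasionResult:
    """Run one invasion replicate.

    ``config`` needs attributes ``geometry`` (ChannelGeometry with an open
    entrance), ``params`` (ModelParams), ``protocol`` (RunProtocol),
    ``grid_h``, ``n_cells`` (None = fill reservoir), ``seed``, and
    ``record_trajectories``.
    """
    geom: ChannelGeometry = config.geometry
    params: ModelParams = config.params
    proto: RunProtocol = config.protocol
    if not geom.entrance_open:
        raise ValueError("invasion requires an open channel entrance")
    grid = geom.grid(config.grid_h)
    n_cells = config.n_cells or monolayer_capacity(geom, params)
    layout_rng, lottery_rng, pol_rngs = _replicate_rngs(
        config.seed, replicate, n_cells
    )
    state, cells = seed_monolayer(geom, n_cells, params, grid, layout_rng)
    dt0 = stable_dt(params, grid.h)
    equilibrate(state, cells, params, proto.t_eq, dt=dt0)

    n_sub = max(1, int(np.ceil(proto.analysis_interval / dt0)))
    dt = proto.analysis_interval / n_sub
    n_frames = int(round(proto.t_max / proto.analysis_interval))
    threshold = calibrate_contact_threshold(params, grid.h)

    update_com_velocity(cells, state, dt_frame=0.0)
    prev_candidates: set = set()
    result = InvasionResult(
        replicate=replicate,
        event=RuptureEvent(replicate, proto.t_max, 0, (), censored=True),
    )
    rows = _frame_rows(cells, 0.0) if config.record_trajectories else None
    energy_rows = [] if config.record_trajectories else None
    try:
        for _ in range(n_frames):
            for _ in range(n_sub):
                step_fields(state, cells, dt, params)
                step_polarity(cells, dt, params, pol_rngs)
            t = state.t
            update_com_velocity(cells, state, dt_frame=proto.analysis_interval)
            update_states(state, cells, geom, params, lottery_rng)
            over = float(max(state.phi.max() - 1.0, -state.phi.min(), 0.0))
            result.max_overshoot = max(result.max_overshoot, over)
            if not result.entered:
                ys = [c.com[1] for c in cells if c.alive]
                if ys and max(ys) > geom.entrance_y:
                    result.entered = True
                    result.entry_time = t
            if rows is not None:
                rows.extend(_frame_rows(cells, t))
                e = hamiltonian(state, params)
                energy_rows.append(
                    {"t": t, "e_ch": e.e_ch, "e_area": e.e_area,
                     "e_excl_cc": e.e_excl_cc, "e_excl_wall": e.e_excl_wall,
                     "total": e.total}
                )
            graph = contact_graph(state, threshold, cells)
            confirmed, prev_candidates = detect_rupture(
                graph, cells, geom, prev_candidates
            )
            if confirmed is not None:
                result.event = RuptureEvent(
                    replicate,
                    time=t - 0.5 * proto.analysis_interval,
                    cluster_size=len(confirmed),
                    members=tuple(confirmed),
                )
                if proto.terminate_on_first_rupture:
                    break
    except FloatingPointError:
        result.failed = True
    result.n_leaders = sum(1 for c in cells if c.state == "leader")
    result.n_guided = sum(1 for c in cells if c.state == "guided")
    if rows is not None:
        result.trajectory = pd.DataFrame(rows)
        result.energy = pd.DataFrame(energy_rows)
        result.final_state = state
        result.final_cells = cells
    return result


def run_invasion_ensemble(config, replicates: int, progress=None) -> list[InvasionResult]:
    """Independent invasion replicates; failed replicates are flagged."""
    out = []
    for k in range(replicates):
        out.append(run_invasion(config, replicate=k))
        if progress is not None:
            progress(k, out[-1])
    return out


def run_jamming(config, replicate: int = 0) -> pd.DataFrame:
    """Run one closed-reservoir jamming replicate.

    Returns unwrapped trajectories (t, id, x, y) sampled at the recording
    cadence; all cells stay followers.
    """
    geom: ChannelGeometry = config.geometry
    params: ModelParams = config.params
    proto: RunProtocol = config.protocol
    if geom.entrance_open:
        geom = dataclasses.replace(geom, entrance_open=False)
    if not geom.periodic_x:
        geom = dataclasses.replace(geom, periodic_x=True)
    grid = geom.grid(config.grid_h)
    n_cells = config.n_cells or monolayer_capacity(geom, params)
    layout_rng, _, pol_rngs = _replicate_rngs(config.seed, replicate, n_cells)
    state, cells = seed_monolayer(geom, n_cells, params, grid, layout_rng)
    dt0 = stable_dt(params, grid.h)
    equilibrate(state, cells, params, proto.t_eq, dt=dt0)

    n_sub = max(1, int(np.ceil(proto.record_interval / dt0)))
    dt = proto.record_interval / n_sub
    n_frames = int(round(proto.t_max / proto.record_interval))
    lx, _ = grid.extent

    update_com_velocity(cells, state, dt_frame=0.0)
    unwrapped = {c.id: np.array(c.com, dtype=float) for c in cells}
    rows = [
        {"t": 0.0, "id": c.id, "x": unwrapped[c.id][0], "y": unwrapped[c.id][1]}
        for c in cells
    ]
    prev = {c.id: np.array(c.com, dtype=float) for c in cells}
    for _ in range(n_frames):
        for _ in range(n_sub):
            step_fields(state, cells, dt, params)
            step_polarity(cells, dt, params, pol_rngs)
        update_com_velocity(cells, state, dt_frame=proto.record_interval)
        t = state.t
        for c in cells:
            if not c.alive:
                continue
            cur = np.array(c.com, dtype=float)
            delta = cur - prev[c.id]
            delta[0] -= lx * np.round(delta[0] / lx)  # minimum image in x
            unwrapped[c.id] += delta
            prev[c.id] = cur
            rows.append(
                {"t": t, "id": c.id, "x": unwrapped[c.id][0], "y": unwrapped[c.id][1]}
            )
    return pd.DataFrame(rows)
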