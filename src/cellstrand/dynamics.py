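"""Time integration of the phase-field and polarity dynamics.

Each cell's field obeys an overdamped advection-relaxation equation

    dphi_i/dt + P_i . grad phi_i + dphi_i/dt|_adh = -(1/gamma) dH/dphi_i

where ``P_i = p_i (cos theta_i, sin theta_i)`` is the polarity (the
velocity the cell would have absent all interactions), the adhesion term

    dphi_i/dt|_adh = sum_{j!=i} omega f(grad phi_j) . grad phi_i
                     + kappa f(grad phi_wall) . grad phi_i

pulls interfaces of neighboring cells (and walls) together, and the
right-hand side relaxes toward minima of the Hamiltonian.  The saturating
function ``f(z) = z / (1 + eps |z|^2)`` caps the adhesive advection
velocity at large interface gradients for numerical stability.

The polarity angle of a guided or leader cell follows an
Ornstein-Uhlenbeck process biased toward the chemoattractant direction
``theta0 = pi/2``:

    dtheta_i/dt = -k_theta (theta_i - theta0) + sqrt(2 D_r) xi(t)

Followers have ``k_theta = 0`` (pure rotational diffusion).  The angle is
deliberately not wrapped to (-pi, pi]: the OU process lives on the
unwrapped line, and wrapping would change its stationary law.

Fields advance with synchronous explicit steps (Heun by default): all
cells are updated from the same pre-step configuration, so trajectories
are invariant under permutation of cell ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import ModelParams, functional_derivative_all, interface_width
from .fields import PERIODIC, GridSpec, PhaseFieldState, gradient

__all__ = [
    "CellRecord",
    "THETA_UP",
    "saturating_grad",
    "adhesion_rate",
    "step_fields",
    "field_rhs",
    "support_boxes",
    "step_polarity",
    "center_of_mass",
    "center_of_mass_all",
    "stable_dt",
    "spawn_cell_rngs",
    "point_trajectories",
    "msd_closed_form",
]

THETA_UP = float(np.pi / 2.0)  # direction of increasing chemoattractant (+y)

FOLLOWER = "follower"
GUIDED = "guided"
LEADER = "leader"
STATES = (FOLLOWER, GUIDED, LEADER)


@dataclass
class CellRecord:
    """Per-cell bookkeeping: polarity, phenotypic state, contacts, track."""

    id: int
    theta: float
    state: str = FOLLOWER
    theta0: float = THETA_UP
    n_contacts: int = 0
    com: tuple[float, float] = (np.nan, np.nan)
    vel: tuple[float, float] = (0.0, 0.0)
    was_front: bool = False
    alive: bool = True

    def polarity(self, params: ModelParams) -> tuple[float, float]:
        p = params.polarity_magnitude(self.state)
        return (p * np.cos(self.theta), p * np.sin(self.theta))


def saturating_grad(zeta: np.ndarray, eps: float) -> np.ndarray:
    """Saturating vector map f(z) = z / (1 + eps |z|^2).

    ``zeta`` has the vector components on the first axis (shape
    ``(2, ...)``).  f is linear near zero and its magnitude is bounded by
    ``1 / (2 sqrt(eps))``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    zeta = np.asarray(zeta, dtype=float)
    mag2 = np.sum(zeta * zeta, axis=0, keepdims=True)
    return zeta / (1.0 + eps * mag2)


def _adhesion_rate_all(
    state: PhaseFieldState, cells: list[CellRecord], params: ModelParams
) -> np.ndarray:
    """dphi/dt|_adh for every cell; shape (n_cells, ny, nx)."""
    grid = state.grid
    gx, gy = gradient(state.phi, grid)
    if params.omega != 0.0:
        fx = saturating_grad(np.stack([gx, gy]), params.eps)
        sum_fx = fx[0].sum(axis=0)
        sum_fy = fx[1].sum(axis=0)
        # exclude the cell's own interface gradient from the neighbor sum
        adh = params.omega * ((sum_fx - fx[0]) * gx + (sum_fy - fx[1]) * gy)
    else:
        adh = np.zeros_like(state.phi)
    if params.kappa != 0.0:
        wx, wy = gradient(state.wall, grid)
        fw = saturating_grad(np.stack([wx, wy]), params.eps)
        adh += params.kappa * (fw[0] * gx + fw[1] * gy)
    return adh


def adhesion_rate(
    state: PhaseFieldState, i: int, cells: list[CellRecord], params: ModelParams
) -> np.ndarray:
    """Adhesive advection rate dphi_i/dt|_adh for cell ``i``."""
    if not 0 <= i < state.n_cells:
        raise KeyError(f"unknown cell id {i}")
    return _adhesion_rate_all(state, cells, params)[i]


def stable_dt(params: ModelParams, h: float, safety: float = 0.5) -> float:
    """Largest time step satisfying the explicit stability bounds.

    Combines the diffusive bound ``gamma h^2 / (4K)`` with the advective
    bound ``h / v_max`` and a safety factor.  The worst-case advection
    speed adds the leader polarity and the saturated adhesive advection
    velocities (``|f|`` is bounded by ``1/(2 sqrt(eps))``).
    """
    dt_diff = params.gamma * h * h / (4.0 * params.K) if params.K > 0 else np.inf
    f_max = 1.0 / (2.0 * np.sqrt(params.eps))
    v_max = params.p_leader + (abs(params.omega) + abs(params.kappa)) * f_max
    dt_adv = h / max(v_max, 1e-12)
    # stiffest local reaction rate: double-well wall of the overshoot
    # region plus full exclusion overlap
    rate = (
        3.0 * params.alpha
        + 2.0 * max(params.g, params.g_wall)
        + 8.0 * params.lam / params.preferred_area
    ) / params.gamma
    dt_react = 2.0 / max(rate, 1e-12)
    return safety * min(dt_diff, dt_adv, dt_react)


def _wall_precompute(state: PhaseFieldState, params: ModelParams):
    """Cache the time-independent wall arrays (exclusion and adhesion)."""
    key = (id(state.wall), params.g_wall, params.kappa, params.eps)
    cached = getattr(state, "_wall_cache", None)
    if cached is not None and cached[0] == key:
        return cached[1]
    wall_excl = 2.0 * params.g_wall * state.wall**2
    wx, wy = gradient(state.wall, state.grid)
    fw = saturating_grad(np.stack([wx, wy]), params.eps)
    data = (
        np.ascontiguousarray(wall_excl),
        np.ascontiguousarray(params.kappa * fw[0]),
        np.ascontiguousarray(params.kappa * fw[1]),
    )
    state._wall_cache = (key, data)  # type: ignore[attr-defined]
    return data


def support_boxes(
    phi: np.ndarray,
    periodic_x: bool,
    margin: int = 3,
    tol: float = 1e-6,
) -> np.ndarray:
    """Per-cell bounding boxes of the field supports, padded by ``margin``.

    Returns an ``(n, 4)`` int array of half-open ranges ``(y0, y1, x0, x1)``;
    on a periodic x-axis a wrapping support is returned as a range with
    ``x1 > nx`` (indices taken modulo nx).  Empty cells get empty boxes.
    """
    n, ny, nx = phi.shape
    boxes = np.zeros((n, 4), dtype=np.int64)
    occ_y = (phi > tol).any(axis=2)
    occ_x = (phi > tol).any(axis=1)
    for c in range(n):
        ys = np.flatnonzero(occ_y[c])
        xs = np.flatnonzero(occ_x[c])
        if ys.size == 0:
            continue
        boxes[c, 0] = max(ys[0] - margin, 0)
        boxes[c, 1] = min(ys[-1] + 1 + margin, ny)
        if periodic_x:
            if xs.size == nx:
                boxes[c, 2], boxes[c, 3] = 0, nx
            elif xs[0] == 0 and xs[-1] == nx - 1:
                # support wraps: find the widest empty gap of columns
                occ = occ_x[c]
                gaps = np.flatnonzero(~occ)
                # split gap indices into runs, take the longest
                splits = np.split(gaps, np.flatnonzero(np.diff(gaps) > 1) + 1)
                run = max(splits, key=len)
                x0 = run[-1] + 1 - margin
                x1 = run[0] + nx + margin
                boxes[c, 2], boxes[c, 3] = x0, min(x1, x0 + nx)
            else:
                x0 = xs[0] - margin
                x1 = xs[-1] + 1 + margin
                if x1 - x0 >= nx:
                    x0, x1 = 0, nx
                boxes[c, 2], boxes[c, 3] = x0, x1
        else:
            boxes[c, 2] = max(xs[0] - margin, 0)
            boxes[c, 3] = min(xs[-1] + 1 + margin, nx)
    return boxes


def field_rhs(
    state: PhaseFieldState,
    cells: list[CellRecord],
    params: ModelParams,
    impl: str = "auto",
) -> np.ndarray:
    """Right-hand side dphi_i/dt for every cell (advection + adhesion +
    relaxation), evaluated synchronously from the given configuration.

    ``impl`` selects the fused compiled kernel (``"auto"``/``"numba"``)
    or the pure-numpy reference (``"numpy"``); both give the same values
    to rounding error.
    """
    grid = state.grid
    if impl != "numpy":
        from ._kernels import HAVE_NUMBA, _rhs_kernel

        if HAVE_NUMBA and grid.boundary_y == "walled":
            wall_excl, wadh_x, wadh_y = _wall_precompute(state, params)
            px = np.array([c.polarity(params)[0] for c in cells])
            py = np.array([c.polarity(params)[1] for c in cells])
            out = np.empty_like(state.phi)
            boxes = support_boxes(
                state.phi, periodic_x=grid.boundary_x == PERIODIC
            )
            return _rhs_kernel(
                state.phi,
                out,
                boxes,
                wall_excl,
                wadh_x,
                wadh_y,
                px,
                py,
                grid.h,
                grid.boundary_x == PERIODIC,
                params.alpha,
                params.K,
                params.lam,
                params.preferred_area,
                params.g,
                params.gamma,
                params.omega,
                params.eps,
            )
        if impl == "numba":
            raise RuntimeError("numba kernel unavailable for this configuration")
    gx, gy = gradient(state.phi, grid)
    dphi = -functional_derivative_all(state, params) / params.gamma
    if params.omega != 0.0:
        fx = saturating_grad(np.stack([gx, gy]), params.eps)
        sum_fx = fx[0].sum(axis=0)
        sum_fy = fx[1].sum(axis=0)
        dphi -= params.omega * ((sum_fx - fx[0]) * gx + (sum_fy - fx[1]) * gy)
    if params.kappa != 0.0:
        wx, wy = gradient(state.wall, grid)
        fw = saturating_grad(np.stack([wx, wy]), params.eps)
        dphi -= params.kappa * (fw[0] * gx + fw[1] * gy)
    px = np.array([c.polarity(params)[0] for c in cells])
    py = np.array([c.polarity(params)[1] for c in cells])
    dphi -= px[:, None, None] * gx + py[:, None, None] * gy
    return dphi


def step_fields(
    state: PhaseFieldState,
    cells: list[CellRecord],
    dt: float,
    params: ModelParams,
    method: str = "heun",
    impl: str = "auto",
) -> PhaseFieldState:
    """One synchronous explicit step of the field equation (in place).

    The default Heun (explicit trapezoid) scheme removes the O(dt)
    self-propulsion speed bias of plain forward Euler at roughly twice
    the per-step cost; ``method="euler"`` selects the single-evaluation
    scheme.  All cells are updated from the same pre-step configuration.
    Raises ``FloatingPointError`` if the update produces non-finite
    values (divergence diagnostic).
    """
    k1 = field_rhs(state, cells, params, impl=impl)
    if method == "euler":
        state.phi += dt * k1
    elif method == "heun":
        phi0 = state.phi
        state.phi = phi0 + dt * k1
        k2 = field_rhs(state, cells, params, impl=impl)
        state.phi = phi0 + (0.5 * dt) * (k1 + k2)
    else:
        raise ValueError(f"unknown integrator {method!r}")
    state.t += dt
    if not np.all(np.isfinite(state.phi)):
        raise FloatingPointError(
            f"phase fields diverged at t={state.t:.4f} h (non-finite values)"
        )
    return state


def spawn_cell_rngs(master_seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-cell noise streams from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def step_polarity(
    cells: list[CellRecord],
    dt: float,
    params: ModelParams,
    rngs: list[np.random.Generator],
) -> list[CellRecord]:
    """Euler-Maruyama update of every polarity angle (in place).

    Guided and leader cells relax toward ``theta0`` at rate ``k_theta``;
    followers only diffuse.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    amp = np.sqrt(2.0 * params.D_r * dt)
    for c, rng in zip(cells, rngs):
        kth = params.k_theta if c.state in (GUIDED, LEADER) else 0.0
        c.theta += -kth * (c.theta - c.theta0) * dt + amp * rng.standard_normal()
    return cells


def center_of_mass(
    state: PhaseFieldState, i: int, min_mass: float = 1.0
) -> tuple[float, float]:
    """Phase-weighted center of mass of cell ``i`` (um).

    On periodic axes the position is computed from the first circular
    moment, so it is exact under wrap-around translation.  Raises
    ``ValueError`` for a vanished cell (integrated phi below
    ``min_mass`` um^2).
    """
    if not 0 <= i < state.n_cells:
        raise KeyError(f"unknown cell id {i}")
    xs, ys = center_of_mass_all(state, min_mass=min_mass)
    return (float(xs[i]), float(ys[i]))


def center_of_mass_all(
    state: PhaseFieldState, min_mass: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Centers of mass of all cells; NaN entries mark vanished cells."""
    grid = state.grid
    phi = state.phi
    da = grid.cell_area
    mass = phi.sum(axis=(-2, -1)) * da
    x, y = grid.coords()
    lx, ly = grid.extent
    with np.errstate(invalid="ignore", divide="ignore"):
        if grid.boundary_x == PERIODIC:
            ph = np.exp(2j * np.pi * x / lx)
            cx = np.angle(np.sum(phi * ph, axis=(-2, -1))) * lx / (2 * np.pi) % lx
        else:
            cx = np.sum(phi * x, axis=(-2, -1)) * da / mass
        if grid.boundary_y == PERIODIC:
            ph = np.exp(2j * np.pi * y / ly)
            cy = np.angle(np.sum(phi * ph, axis=(-2, -1))) * ly / (2 * np.pi) % ly
        else:
            cy = np.sum(phi * y, axis=(-2, -1)) * da / mass
    vanished = mass < min_mass
    cx = np.where(vanished, np.nan, cx)
    cy = np.where(vanished, np.nan, cy)
    return cx, cy


def update_com_velocity(
    cells: list[CellRecord],
    state: PhaseFieldState,
    dt_frame: float,
) -> None:
    """Refresh each record's center of mass and finite-difference velocity.

    Displacements are taken minimum-image on periodic axes.
    """
    grid = state.grid
    lx, ly = grid.extent
    cx, cy = center_of_mass_all(state)
    for c in cells:
        x_new, y_new = float(cx[c.id]), float(cy[c.id])
        if not np.isfinite(x_new) or not np.isfinite(y_new):
            c.alive = False
            continue
        x_old, y_old = c.com
        if np.isfinite(x_old) and dt_frame > 0:
            dx = x_new - x_old
            dy = y_new - y_old
            if grid.boundary_x == PERIODIC:
                dx -= lx * np.round(dx / lx)
            if grid.boundary_y == PERIODIC:
                dy -= ly * np.round(dy / ly)
            c.vel = (dx / dt_frame, dy / dt_frame)
        c.com = (x_new, y_new)


def point_trajectories(
    n: int,
    t_max: float,
    dt: float,
    params: ModelParams,
    seed: int,
    state: str = FOLLOWER,
    record_every: int = 1,
    theta0: float = THETA_UP,
) -> tuple[np.ndarray, np.ndarray]:
    """Trajectories of non-interacting point cells (the free limit).

    Integrates the polarity process and advects each cell at its polarity
    velocity, which is the exact behavior of an isolated phase-field cell
    whose shape has relaxed.  Returns ``(times, xy)`` with ``xy`` of shape
    ``(n_frames, n, 2)``.  Used as the closed-form oracle for the
    persistent-random-walk MSD and for effective-diffusivity baselines.
    """
    rngs = spawn_cell_rngs(seed, n)
    cells = [
        CellRecord(id=i, theta=float(rngs[i].uniform(0, 2 * np.pi)), state=state,
                   theta0=theta0)
        for i in range(n)
    ]
    n_steps = int(round(t_max / dt))
    xy = np.zeros((n_steps // record_every + 1, n, 2))
    times = np.zeros(n_steps // record_every + 1)
    pos = np.zeros((n, 2))
    k = 1
    for s in range(1, n_steps + 1):
        for c in cells:
            p = params.polarity_magnitude(c.state)
            pos[c.id, 0] += p * np.cos(c.theta) * dt
            pos[c.id, 1] += p * np.sin(c.theta) * dt
        step_polarity(cells, dt, params, rngs)
        if s % record_every == 0:
            xy[k] = pos
            times[k] = s * dt
            k += 1
    return times[:k], xy[:k]


def msd_closed_form(t: np.ndarray, p0: float, D_r: float) -> np.ndarray:
    """Persistent-random-walk MSD: (2 p0^2 / D_r^2)(D_r t + exp(-D_r t) - 1).

    Long-time slope 2 p0^2 / D_r = 4 D0 with D0 = p0^2 / (2 D_r).
    """
    t = np.asarray(t, dtype=float)
    return 2.0 * p0**2 / D_r**2 * (D_r * t + np.exp(-D_r * t) - 1.0)
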