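"""The Hamiltonian of the multicell phase-field model and its variation.

The free energy of a configuration ``{phi_i}`` in a device with wall field
``phi_wall`` is

    H = H_CH + H_area + H_exclusion

with

    H_CH   = sum_i int [ alpha/4 phi_i^2 (phi_i-1)^2 + K/2 |grad phi_i|^2 ]
    H_area = sum_i lam (1 - int phi_i^2 / (pi R^2))^2
    H_excl = sum_{i>j} int g phi_i^2 phi_j^2 + sum_i int g_wall phi_i^2 phi_wall^2

The Cahn-Hilliard term gives each interface a tension and an equilibrium
width, the area term penalizes deviation from the preferred cell area
pi R^2, and the exclusion terms penalize overlap between cells and between
cells and walls.

The relaxational part of the dynamics is driven by the functional
derivative dH/dphi_i, derived analytically term by term:

    dH_CH/dphi_i   = alpha/2 phi_i (phi_i - 1)(2 phi_i - 1) - K lap(phi_i)
    dH_area/dphi_i = -(4 lam / pi R^2) phi_i (1 - a_i / pi R^2)
    dH_excl/dphi_i = 2 g phi_i sum_{j != i} phi_j^2 + 2 g_wall phi_i phi_wall^2

where ``a_i = int phi_i^2``.  The test suite locks these expressions in
against a central-difference perturbation of H.

Internal units are micrometres and hours throughout.  Rate constants that
the field conventionally quotes per minute (``k_theta``, ``D_r``) are
converted at configuration load time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fields import GridSpec, PhaseFieldState, laplacian, soft_area

__all__ = [
    "ModelParams",
    "EnergyBreakdown",
    "hamiltonian",
    "functional_derivative",
    "functional_derivative_all",
    "interface_width",
    "INTERFACE_WIDTH_PREFACTOR",
]

# The equilibrium 1-D kink of the Cahn-Hilliard term is the logistic
# profile phi(x) = 1/(1 + exp(-x/l)) with decay length l = sqrt(2K/alpha).
# We parameterize the interface width d as the 10-90% crossing distance of
# that kink, d = 2 ln(9) sqrt(2 K / alpha).
INTERFACE_WIDTH_PREFACTOR = 2.0 * np.log(9.0) * np.sqrt(2.0)


@dataclass
class ModelParams:
    """All model constants, in micrometre/hour units.

    Motility and polarity parameters follow the reference invasion
    conditions: base polarity ``p0`` = 13.3 um/h with guided cells at
    2 p0 and leader cells at 3 p0; chemotaxis strength ``k_theta`` =
    0.014 / min = 0.84 / h (1.4 x the reference value ``k_theta0``); the
    rotational diffusion ``D_r`` = 0.0224 / min and radius ``R`` = 6.9 um
    are fixed by requiring a single-cell chemotactic index of about 0.45
    and a default Peclet number p0/(R D_r) of about 1.43.

    The Hamiltonian constants (``alpha``, ``K``, ``lam``, ``g``,
    ``g_wall``, ``gamma``) and the adhesion strengths (``omega``,
    ``kappa``) set the interface width, shape stiffness and adhesion of
    the cells; their defaults are calibrated so that an isolated cell is
    stable and near-circular at area pi R^2, and that a pair of adhering
    cells stays bound under a polarity mismatch of order p0 but can be
    torn apart by a leader-sized mismatch.  See docs/methods.md.
    """

    # Cahn-Hilliard / shape
    alpha: float = 40.0  # double-well height (energy / um^2)
    K: float = 9.32  # gradient stiffness (energy); d ~= 3.0 um
    lam: float = 2000.0  # area-constraint strength (energy)
    R: float = 6.9  # preferred radius (um)
    g: float = 120.0  # cell-cell exclusion strength (energy / um^2)
    g_wall: float = 80.0  # cell-wall exclusion strength (energy / um^2)
    gamma: float = 1.0  # friction (energy h / um^4)
    # adhesion
    omega: float = 100.0  # cell-cell adhesion strength (um^2/h)
    kappa: float = 100.0  # cell-wall adhesion strength (um^2/h)
    eps: float = 1.0  # saturation constant in f (um^2)
    # polarity / states
    p0: float = 13.3  # base polarity magnitude (um/h)
    k_theta: float = 0.84  # chemotaxis strength (1/h) = 0.014/min
    D_r: float = 1.344  # rotational diffusion (1/h) = 0.0224/min
    guided_factor: float = 2.0
    leader_factor: float = 3.0
    # leader lottery
    n_c: float = 256.0  # characteristic contact count (at h_ref spacing)
    h_ref: float = 0.4  # grid spacing the contact count is referenced to (um)
    overlap_threshold: float = 0.25  # phi_i*phi_j threshold for a contact node

    def __post_init__(self) -> None:
        for name in ("alpha", "K", "lam", "g", "g_wall", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    @property
    def preferred_area(self) -> float:
        return float(np.pi * self.R * self.R)

    @property
    def p_guided(self) -> float:
        return self.guided_factor * self.p0

    @property
    def p_leader(self) -> float:
        return self.leader_factor * self.p0

    def polarity_magnitude(self, state: str) -> float:
        return {
            "follower": self.p0,
            "guided": self.p_guided,
            "leader": self.p_leader,
        }[state]

    def n_c_effective(self, h: float) -> float:
        """Contact-count scale rescaled to grid spacing ``h``.

        The characteristic count ``n_c`` is quoted at the reference
        spacing ``h_ref``; contact nodes along a junction scale as 1/h,
        so the threshold is rescaled proportionally.
        """
        return self.n_c * self.h_ref / h

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def interface_width(params: ModelParams) -> float:
    """Equilibrium interface width d = 2 ln(9) sqrt(2K/alpha) (um).

    Defined as the 10-90% crossing distance of the 1-D equilibrium kink of
    the Cahn-Hilliard term.
    """
    if params.alpha <= 0 or params.K <= 0:
        raise ValueError("alpha and K must be positive")
    return INTERFACE_WIDTH_PREFACTOR * np.sqrt(params.K / params.alpha)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Hamiltonian value split by term."""

    e_ch: float
    e_area: float
    e_excl_cc: float
    e_excl_wall: float

    @property
    def total(self) -> float:
        return self.e_ch + self.e_area + self.e_excl_cc + self.e_excl_wall


def _forward_grad_sq(phi: np.ndarray, grid: GridSpec) -> np.ndarray:
    """|grad phi|^2 by forward differences over node pairs.

    This quadrature makes the gradient energy exactly adjoint to the
    five-point Laplacian on periodic axes, so the analytic functional
    derivative is the exact discrete gradient of H (the perturbation
    oracle then agrees to rounding even on rough fields).
    """
    h = grid.h
    out = np.zeros_like(phi)
    dx = (np.roll(phi, -1, axis=-1) - phi) / h
    if grid.boundary_x != "periodic":
        dx[..., :, -1] = 0.0  # no wrap pair on walled axes
    dy = (np.roll(phi, -1, axis=-2) - phi) / h
    if grid.boundary_y != "periodic":
        dy[..., -1, :] = 0.0
    out += dx * dx + dy * dy
    return out


def hamiltonian(state: PhaseFieldState, params: ModelParams) -> EnergyBreakdown:
    """Evaluate H term by term on the midpoint quadrature rule."""
    grid = state.grid
    phi = state.phi
    da = grid.cell_area
    well = 0.25 * params.alpha * phi**2 * (phi - 1.0) ** 2
    grad2 = 0.5 * params.K * _forward_grad_sq(phi, grid)
    e_ch = float(np.sum(well + grad2) * da)

    areas = soft_area(phi, grid)
    areas = np.atleast_1d(areas)
    e_area = float(params.lam * np.sum((1.0 - areas / params.preferred_area) ** 2))

    phi2 = phi**2
    sumsq = phi2.sum(axis=0)
    # sum_{i>j} phi_i^2 phi_j^2 = ((sum phi^2)^2 - sum phi^4)/2
    cross = 0.5 * (sumsq**2 - np.sum(phi2**2, axis=0))
    e_cc = float(params.g * np.sum(cross) * da)
    e_wall = float(params.g_wall * np.sum(sumsq * state.wall**2) * da)
    return EnergyBreakdown(e_ch, e_area, e_cc, e_wall)


def functional_derivative_all(
    state: PhaseFieldState, params: ModelParams
) -> np.ndarray:
    """dH/dphi_i for every cell at once; shape (n_cells, ny, nx)."""
    grid = state.grid
    phi = state.phi
    phi2 = phi**2
    sumsq = phi2.sum(axis=0)
    areas = np.atleast_1d(soft_area(phi, grid))

    dch = 0.5 * params.alpha * phi * (phi - 1.0) * (2.0 * phi - 1.0) - params.K * laplacian(
        phi, grid
    )
    a0 = params.preferred_area
    darea = (-4.0 * params.lam / a0) * phi * (1.0 - areas / a0)[:, None, None]
    dexcl = 2.0 * params.g * phi * (sumsq - phi2)
    dwall = 2.0 * params.g_wall * phi * state.wall**2
    return dch + darea + dexcl + dwall


def functional_derivative(
    state: PhaseFieldState, i: int, params: ModelParams
) -> np.ndarray:
    """dH/dphi_i for cell ``i`` (analytic variation of every term)."""
    if not 0 <= i < state.n_cells:
        raise KeyError(f"unknown cell id {i}")
    return functional_derivative_all(state, params)[i]
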