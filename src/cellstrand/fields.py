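"""Grids, discrete differential operators, and microchannel wall fields.

Every spatial quantity in the simulator lives on a regular node-centered
grid with spacing ``h`` (micrometres).  Arrays are indexed ``[iy, ix]`` with
node ``(0, 0)`` at the lower-left corner; ``x`` increases along axis 1 and
``y`` (the direction of increasing chemoattractant) along axis 0.  Phase
fields are dimensionless scalars in [0, 1]; the cell interface is tracked
at the 1/2 level set.

The microchannel device is encoded as an auxiliary wall field
``phi_wall`` that is 1 inside forbidden regions and 0 in free space, with
the same smooth (logistic/tanh) interface profile as the cells so that
exclusion and adhesion forces do not pin to the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "ChannelGeometry",
    "PhaseFieldState",
    "build_wall_field",
    "gradient",
    "laplacian",
    "soft_area",
    "LOGISTIC_WIDTH_FACTOR",
]

# 10-90% crossing distance of the logistic kink 1/(1+exp(-x/l)) is
# 2*ln(9)*l; interfaces parameterized by their 10-90% width d therefore use
# decay length l = d / LOGISTIC_WIDTH_FACTOR.
LOGISTIC_WIDTH_FACTOR = 2.0 * np.log(9.0)

PERIODIC = "periodic"
WALLED = "walled"


@dataclass(frozen=True)
class GridSpec:
    """Regular 2-D grid: ``nx`` by ``ny`` nodes at spacing ``h`` (um)."""

    nx: int
    ny: int
    h: float
    boundary_x: str = WALLED
    boundary_y: str = WALLED

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"grid spacing must be positive, got h={self.h}")
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must have at least 8 nodes per axis")
        for b in (self.boundary_x, self.boundary_y):
            if b not in (PERIODIC, WALLED):
                raise ValueError(f"unknown boundary flag {b!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical domain size (Lx, Ly) in um."""
        return (self.nx * self.h, self.ny * self.h)

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinate arrays (x, y), each of shape (ny, nx)."""
        x = np.arange(self.nx) * self.h
        y = np.arange(self.ny) * self.h
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class ChannelGeometry:
    """Microfluidic device layout: seeding reservoir plus one channel.

    The reservoir occupies the bottom of the domain; the channel of width
    ``channel_w`` sits centered above it, its mouth at
    ``y = entrance_y``.  ``entrance_open=False`` closes the mouth so all
    cells stay confined in the reservoir (the jamming protocol).  With
    ``periodic_x=True`` the reservoir wraps in x and has no side walls.

    All lengths in micrometres.
    """

    reservoir_w: float = 60.0
    reservoir_h: float = 40.0
    channel_w: float = 20.0
    channel_len: float = 40.0
    entrance_open: bool = True
    periodic_x: bool = False
    wall_pad: float = 4.0  # wall material beyond the free space, each side

    def __post_init__(self) -> None:
        if self.reservoir_w <= 0 or self.reservoir_h <= 0:
            raise ValueError("reservoir dimensions must be positive")
        if self.channel_w <= 0 or self.channel_len < 0:
            raise ValueError("channel dimensions must be positive")
        if self.entrance_open and self.channel_w > self.reservoir_w:
            raise ValueError("channel wider than reservoir")

    @property
    def entrance_y(self) -> float:
        """y-coordinate of the channel mouth (top of the reservoir)."""
        return self.y0 + self.reservoir_h

    @property
    def x0(self) -> float:
        return 0.0 if self.periodic_x else self.wall_pad

    @property
    def y0(self) -> float:
        return self.wall_pad

    @property
    def channel_x0(self) -> float:
        cx = self.x0 + 0.5 * self.reservoir_w
        return cx - 0.5 * self.channel_w

    @property
    def channel_x1(self) -> float:
        return self.channel_x0 + self.channel_w

    def domain_size(self) -> tuple[float, float]:
        lx = self.reservoir_w + (0.0 if self.periodic_x else 2 * self.wall_pad)
        ly = self.reservoir_h + self.channel_len + 2 * self.wall_pad
        return (lx, ly)

    def grid(self, h: float) -> GridSpec:
        """Build a grid spanning the device at spacing ``h``."""
        lx, ly = self.domain_size()
        return GridSpec(
            nx=int(round(lx / h)),
            ny=int(round(ly / h)),
            h=h,
            boundary_x=PERIODIC if self.periodic_x else WALLED,
            boundary_y=WALLED,
        )

    def free_rectangles(self) -> list[tuple[float, float, float, float]]:
        """Free-space region as a union of axis-aligned rectangles.

        Each rectangle is (x0, y0, x1, y1).
        """
        big = 1e6
        if self.periodic_x:
            res = (-big, self.y0, big, self.entrance_y)
        else:
            res = (self.x0, self.y0, self.x0 + self.reservoir_w, self.entrance_y)
        rects = [res]
        if self.entrance_open and self.channel_len > 0:
            rects.append(
                (
                    self.channel_x0,
                    self.entrance_y,
                    self.channel_x1,
                    self.entrance_y + self.channel_len,
                )
            )
        return rects


@dataclass
class PhaseFieldState:
    """All per-cell phase fields plus the wall field and simulation clock.

    ``phi`` has shape ``(n_cells, ny, nx)``; ``wall`` has shape ``(ny, nx)``.
    """

    phi: np.ndarray
    wall: np.ndarray
    grid: GridSpec
    t: float = 0.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.wall = np.asarray(self.wall, dtype=float)
        if self.phi.ndim != 3 or self.phi.shape[1:] != self.grid.shape:
            raise ValueError(
                f"phi shape {self.phi.shape} does not match grid {self.grid.shape}"
            )
        if self.wall.shape != self.grid.shape:
            raise ValueError("wall field shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.phi.shape[0]

    def copy(self) -> "PhaseFieldState":
        return PhaseFieldState(self.phi.copy(), self.wall.copy(), self.grid, self.t)


def _rect_signed_distance(x: np.ndarray, y: np.ndarray, rect) -> np.ndarray:
    """Signed distance to a rectangle: negative inside, positive outside."""
    x0, y0, x1, y1 = rect
    dx = np.maximum(x0 - x, x - x1)
    dy = np.maximum(y0 - y, y - y1)
    outside = np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0))
    inside = np.minimum(np.maximum(dx, dy), 0.0)
    return outside + inside


def build_wall_field(geom: ChannelGeometry, grid: GridSpec, d: float) -> np.ndarray:
    """Construct ``phi_wall`` for the device on the given grid.

    The field is 1 in wall material, 0 in free space (reservoir and, when
    the entrance is open, the channel), with a logistic interface whose
    10-90% width is ``d``.

    Raises ``ValueError`` if the free-space region does not fit inside the
    grid extent.
    """
    lx, ly = grid.extent
    for x0, y0, x1, y1 in geom.free_rectangles():
        if y0 < -1e-9 or y1 > ly + 1e-9:
            raise ValueError("geometry exceeds grid extent in y")
        if not geom.periodic_x and (x0 < -1e-9 or x1 > lx + 1e-9):
            raise ValueError("geometry exceeds grid extent in x")
    x, y = grid.coords()
    dist = np.full(grid.shape, np.inf)
    for rect in geom.free_rectangles():
        dist = np.minimum(dist, _rect_signed_distance(x, y, rect))
    ell = d / LOGISTIC_WIDTH_FACTOR
    # dist > 0 in wall material -> phi_wall -> 1
    return 1.0 / (1.0 + np.exp(np.clip(-dist / ell, -60, 60)))


def _shift(f: np.ndarray, axis: int, n: int, periodic: bool) -> np.ndarray:
    """Shift so that result[i] = f[i + n], with wrap or edge replication."""
    if periodic:
        return np.roll(f, -n, axis=axis)
    pad_axis = f.ndim + axis if axis < 0 else axis
    sl = [slice(None)] * f.ndim
    out = np.empty_like(f)
    if n > 0:
        sl_src = list(sl)
        sl_src[pad_axis] = slice(n, None)
        sl_dst = list(sl)
        sl_dst[pad_axis] = slice(None, -n)
        out[tuple(sl_dst)] = f[tuple(sl_src)]
        sl_edge = list(sl)
        sl_edge[pad_axis] = slice(-n, None)
        sl_rep = list(sl)
        sl_rep[pad_axis] = slice(-1, None)
        out[tuple(sl_edge)] = f[tuple(sl_rep)]
    elif n < 0:
        sl_src = list(sl)
        sl_src[pad_axis] = slice(None, n)
        sl_dst = list(sl)
        sl_dst[pad_axis] = slice(-n, None)
        out[tuple(sl_dst)] = f[tuple(sl_src)]
        sl_edge = list(sl)
        sl_edge[pad_axis] = slice(None, -n)
        sl_rep = list(sl)
        sl_rep[pad_axis] = slice(0, 1)
        out[tuple(sl_edge)] = f[tuple(sl_rep)]
    else:
        out[...] = f
    return out


def gradient(f: np.ndarray, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Second-order central-difference gradient ``(df/dx, df/dy)``.

    Works on single fields ``(ny, nx)`` or stacks ``(..., ny, nx)``.  On
    walled axes the edge nodes use second-order one-sided stencils; on
    periodic axes the stencil wraps.
    """
    if f.shape[-2:] != grid.shape:
        raise ValueError(f"field shape {f.shape} does not match grid {grid.shape}")
    h2 = 2.0 * grid.h
    px = grid.boundary_x == PERIODIC
    py = grid.boundary_y == PERIODIC
    fx = (_shift(f, -1, 1, px) - _shift(f, -1, -1, px)) / h2
    fy = (_shift(f, -2, 1, py) - _shift(f, -2, -1, py)) / h2
    if not px:
        fx[..., :, 0] = (-3 * f[..., :, 0] + 4 * f[..., :, 1] - f[..., :, 2]) / h2
        fx[..., :, -1] = (3 * f[..., :, -1] - 4 * f[..., :, -2] + f[..., :, -3]) / h2
    if not py:
        fy[..., 0, :] = (-3 * f[..., 0, :] + 4 * f[..., 1, :] - f[..., 2, :]) / h2
        fy[..., -1, :] = (3 * f[..., -1, :] - 4 * f[..., -2, :] + f[..., -3, :]) / h2
    return fx, fy


def laplacian(f: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Five-point Laplacian; zero-flux mirror closure at walled edges."""
    if f.shape[-2:] != grid.shape:
        raise ValueError(f"field shape {f.shape} does not match grid {grid.shape}")
    px = grid.boundary_x == PERIODIC
    py = grid.boundary_y == PERIODIC
    out = (
        _shift(f, -1, 1, px)
        + _shift(f, -1, -1, px)
        + _shift(f, -2, 1, py)
        + _shift(f, -2, -1, py)
        - 4.0 * f
    )
    if not px:
        # mirror ghost: f[-1] := f[1]  (edge replication already gives f[0];
        # correct to the symmetric ghost node)
        out[..., :, 0] += f[..., :, 1] - f[..., :, 0]
        out[..., :, -1] += f[..., :, -2] - f[..., :, -1]
    if not py:
        out[..., 0, :] += f[..., 1, :] - f[..., 0, :]
        out[..., -1, :] += f[..., -2, :] - f[..., -1, :]
    return out / (grid.h * grid.h)


def soft_area(phi: np.ndarray, grid: GridSpec) -> float | np.ndarray:
    """Phase-field area ``integral of phi^2 d2r`` by the midpoint rule.

    For a stack ``(n, ny, nx)`` returns one area per cell.
    """
    if phi.shape[-2:] != grid.shape:
        raise ValueError("field shape does not match grid")
    a = np.sum(phi * phi, axis=(-2, -1)) * grid.cell_area
    return float(a) if np.ndim(a) == 0 else a


def tanh_disk(
    grid: GridSpec, center: tuple[float, float], radius: float, d: float
) -> np.ndarray:
    """A smooth disk: 1 inside radius, 0 outside, 10-90% interface width d.

    Respects periodic axes via minimum-image distances.
    """
    x, y = grid.coords()
    lx, ly = grid.extent
    dx = x - center[0]
    dy = y - center[1]
    if grid.boundary_x == PERIODIC:
        dx -= lx * np.round(dx / lx)
    if grid.boundary_y == PERIODIC:
        dy -= ly * np.round(dy / ly)
    r = np.hypot(dx, dy)
    ell = d / LOGISTIC_WIDTH_FACTOR
    return 1.0 / (1.0 + np.exp(np.clip((r - radius) / ell, -60, 60)))
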