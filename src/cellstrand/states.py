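"""The follower -> guided -> leader cell-state machine.

Cells in the seeding reservoir cannot sense the chemoattractant and stay
followers.  A cell near the channel mouth (within one cell radius below
the entrance line) or inside the channel becomes guided: its chemotaxis
term switches on and its polarity magnitude doubles.  When a guided cell
arrives at the invading front it draws once from the contact-inhibited
leader lottery

    P_leader = max(1 - n_i / n_c, 0)

where ``n_i`` is its current cell-cell contact count, and on success is
promoted to a leader (triple polarity magnitude).  Transitions are
monotone: no cell ever reverts to an earlier state.
"""

from __future__ import annotations

import numpy as np

from .dynamics import FOLLOWER, GUIDED, LEADER, CellRecord, THETA_UP
from .energetics import ModelParams
from .fields import ChannelGeometry, PhaseFieldState

__all__ = [
    "classify_region",
    "count_contacts",
    "count_contacts_all",
    "leader_probability",
    "update_states",
    "is_front_cell",
]

SEEDING = "seeding"
ENTRANCE = "entrance"
CHANNEL = "channel"


def classify_region(
    position: tuple[float, float],
    geom: ChannelGeometry,
    band_depth: float,
) -> str:
    """Classify a free-space position as seeding / entrance / channel.

    The entrance band extends ``band_depth`` below the channel mouth.
    Raises ``ValueError`` for positions inside wall material.
    """
    x, y = position
    ent = geom.entrance_y
    if y >= ent:
        if not geom.entrance_open or not (geom.channel_x0 <= x <= geom.channel_x1):
            raise ValueError(f"position ({x:.2f}, {y:.2f}) lies inside a wall")
        return CHANNEL
    if y < geom.y0 - 1e-9:
        raise ValueError(f"position ({x:.2f}, {y:.2f}) lies below the reservoir")
    if geom.entrance_open and y >= ent - band_depth:
        return ENTRANCE
    return SEEDING


def count_contacts_all(
    state: PhaseFieldState, overlap_threshold: float = 0.25
) -> np.ndarray:
    """Cell-cell contact node counts ``n_i`` for every cell.

    A node contributes to ``n_i`` if ``phi_i * phi_j`` exceeds the
    threshold for at least one neighbor ``j``; the contribution is
    symmetric between i and j by construction.
    """
    phi = state.phi
    n = state.n_cells
    counts = np.zeros(n, dtype=int)
    if n < 2:
        return counts
    total = phi.sum(axis=0)
    for i in range(n):
        other = total - phi[i]
        # max_j phi_i phi_j >= phi_i * max_j phi_j; using the sum as an
        # upper bound would overcount only where three cells overlap, which
        # exclusion suppresses -- still, use the exact pairwise maximum.
        best = np.zeros_like(phi[i])
        for j in range(n):
            if j == i:
                continue
            np.maximum(best, phi[j], out=best)
        counts[i] = int(np.count_nonzero(phi[i] * best > overlap_threshold))
    return counts


def count_contacts(
    state: PhaseFieldState, i: int, overlap_threshold: float = 0.25
) -> int:
    """Contact node count for cell ``i`` (union over neighbors)."""
    if not 0 <= i < state.n_cells:
        raise KeyError(f"unknown cell id {i}")
    phi = state.phi
    mask = np.zeros(state.grid.shape, dtype=bool)
    for j in range(state.n_cells):
        if j != i:
            mask |= phi[i] * phi[j] > overlap_threshold
    return int(np.count_nonzero(mask))


def leader_probability(ni: float, nc: float) -> float:
    """Contact-inhibited leadership probability max(1 - n_i/n_c, 0)."""
    if nc <= 0:
        raise ValueError("characteristic contact count nc must be positive")
    if ni < 0:
        raise ValueError("contact count must be nonnegative")
    return float(min(max(1.0 - ni / nc, 0.0), 1.0))


def is_front_cell(i: int, cells: list[CellRecord], R: float) -> bool:
    """Front predicate: no other channel cell sits well above cell i.

    Cell ``i`` (already known to be in the channel) is at the invading
    front when no other cell in the same cross-section (|dx| < R) has its
    center of mass more than R/2 above it.
    """
    xi, yi = cells[i].com
    for c in cells:
        if c.id == i or not c.alive:
            continue
        if c.region != CHANNEL:  # type: ignore[attr-defined]
            continue
        xj, yj = c.com
        if abs(xj - xi) < R and yj > yi + 0.5 * R:
            return False
    return True


def update_states(
    state: PhaseFieldState,
    cells: list[CellRecord],
    geom: ChannelGeometry,
    params: ModelParams,
    rng: np.random.Generator,
    band_depth: float | None = None,
) -> list[CellRecord]:
    """One pass of the state machine (called once per update interval).

    Promotes reservoir cells that reached the entrance band or channel to
    guided, then runs the leader lottery for cells newly arrived at the
    invading front.  Leader promotion is permanent; the lottery is drawn
    once per front-arrival event (tracked by ``was_front``).
    """
    if band_depth is None:
        band_depth = params.R
    counts = None
    nc_eff = params.n_c_effective(state.grid.h)
    # annotate regions first (used by the front predicate)
    for c in cells:
        if not c.alive:
            c.region = SEEDING  # type: ignore[attr-defined]
            continue
        try:
            c.region = classify_region(c.com, geom, band_depth)  # type: ignore[attr-defined]
        except ValueError:
            # center of mass transiently inside the smoothed wall band
            # (e.g. squeezed against the mouth ceiling): guided at most,
            # never leader-eligible
            c.region = ENTRANCE  # type: ignore[attr-defined]
    for c in cells:
        if not c.alive:
            continue
        region = c.region  # type: ignore[attr-defined]
        if c.state == FOLLOWER and region in (ENTRANCE, CHANNEL):
            c.state = GUIDED
            c.theta0 = THETA_UP
        if c.state == GUIDED and region == CHANNEL:
            front = is_front_cell(c.id, cells, params.R)
            if front and not c.was_front:
                if counts is None:
                    counts = count_contacts_all(state, params.overlap_threshold)
                c.n_contacts = int(counts[c.id])
                p = 0.0 if nc_eff <= 0 else leader_probability(c.n_contacts, nc_eff)
                if rng.random() < p:
                    c.state = LEADER
            c.was_front = front
        elif c.state == GUIDED:
            c.was_front = False
    return cells
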