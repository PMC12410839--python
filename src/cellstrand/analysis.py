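"""Rupture statistics, survival analysis, and jamming diagnostics.

A dissociation ("rupture") is detected from the cell-cell contact graph:
cells are nodes, and an edge joins two cells whose squared-field overlap
integral exceeds a small calibrated contact-area threshold.  A connected
component that contains no cell in the seeding region, is disjoint from
the bulk component, and persists for two consecutive analysis frames is a
rupture; the event records its time, size, and members.

Survival curves S(t) -- the probability that a channel has had no rupture
by time t -- use the Kaplan-Meier product-limit estimator with Greenwood
95% confidence bands (replicates that reach the observation limit
without rupture enter as right-censored).

Jamming is quantified by the normalized long-time diffusivity

    Deff = lim_{t->inf} MSD(t) / (4 D0 t),      D0 = p0^2 / (2 D_r)

fit on the late-time window t > 3/D_r; tissues with Deff below 0.012 are
classified solid (jammed).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import CellRecord, center_of_mass_all
from .energetics import ModelParams
from .fields import ChannelGeometry, PhaseFieldState
from .states import SEEDING, classify_region

__all__ = [
    "RuptureEvent",
    "SurvivalCurve",
    "MSDResult",
    "contact_graph",
    "detect_rupture",
    "kaplan_meier",
    "cluster_size_stats",
    "size_vs_time",
    "msd_and_diffusivity",
    "classify_jamming",
    "chemotactic_index",
    "peclet",
    "JAMMING_THRESHOLD",
    "CLUSTER_CATEGORIES",
]

JAMMING_THRESHOLD = 0.012
CLUSTER_CATEGORIES = ("1", "2", "3", "4", "5", "6-10", ">10")


@dataclass(frozen=True)
class RuptureEvent:
    """First-dissociation record for one replicate."""

    replicate: int
    time: float  # h; censoring time when censored
    cluster_size: int  # 0 when censored
    members: tuple[int, ...] = ()
    censored: bool = False


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier estimate with a 95% confidence band."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    final_survival: float  # Ks, the estimate at the end of observation

    def at(self, t: float) -> float:
        """S(t) (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclass(frozen=True)
class MSDResult:
    """Time-and-ensemble averaged MSD and the fitted diffusivity."""

    lags: np.ndarray  # h
    msd: np.ndarray  # um^2
    fit_window: tuple[float, float]
    D0: float  # um^2/h
    Deff: float  # dimensionless


def contact_graph(
    state: PhaseFieldState,
    threshold: float,
    cells: list[CellRecord] | None = None,
) -> nx.Graph:
    """Undirected graph with an edge where the overlap integral
    ``int phi_i^2 phi_j^2 d2r`` exceeds ``threshold``.

    Pairs whose centers are farther apart than one cell diameter plus two
    interface widths cannot overlap measurably and are skipped.
    """
    g = nx.Graph()
    n = state.n_cells
    g.add_nodes_from(range(n))
    if n < 2:
        return g
    da = state.grid.cell_area
    cx, cy = center_of_mass_all(state)
    lx, ly = state.grid.extent
    px = state.grid.boundary_x == "periodic"
    phi2 = state.phi**2
    # generous reach: supports extend ~R + d/2 from the center
    reach = 2.0 * np.sqrt(np.max(phi2.sum(axis=(1, 2))) * da / np.pi) + 6.0 * state.grid.h
    for i in range(n):
        if not np.isfinite(cx[i]):
            continue
        for j in range(i + 1, n):
            if not np.isfinite(cx[j]):
                continue
            dx = cx[i] - cx[j]
            if px:
                dx -= lx * np.round(dx / lx)
            if np.hypot(dx, cy[i] - cy[j]) > reach:
                continue
            if float(np.sum(phi2[i] * phi2[j])) * da > threshold:
                g.add_edge(i, j)
    return g


def detect_rupture(
    graph: nx.Graph,
    cells: list[CellRecord],
    geom: ChannelGeometry,
    previous: set[frozenset] | None = None,
    band_depth: float | None = None,
) -> tuple[object | None, set[frozenset]]:
    """Find a persistent detached component.

    A component is a rupture candidate when it contains no seeding-region
    cell and is disjoint from the bulk (the component holding the
    seeding-region cells, or the bottom-most cell when the reservoir is
    empty).  A candidate seen in two consecutive analysis frames is
    confirmed; ties break toward the component with the highest mean y.

    Returns ``(confirmed_members_or_None, candidates)`` where
    ``candidates`` must be passed back as ``previous`` on the next frame.
    """
    if band_depth is None:
        band_depth = 0.0
    alive = [c for c in cells if c.alive and np.isfinite(c.com[0])]
    if not alive:
        return None, set()

    def region_of(c: CellRecord) -> str:
        try:
            return classify_region(c.com, geom, band_depth)
        except ValueError:
            return "entrance"

    seeding_ids = {c.id for c in alive if region_of(c) == SEEDING}
    comps = [set(cc) for cc in nx.connected_components(graph)]
    alive_ids = {c.id for c in alive}
    comps = [cc & alive_ids for cc in comps]
    comps = [cc for cc in comps if cc]
    if seeding_ids:
        bulk = set()
        for cc in comps:
            if cc & seeding_ids:
                bulk |= cc
    else:
        bottom = min(alive, key=lambda c: c.com[1]).id
        bulk = next((cc for cc in comps if bottom in cc), set())
    candidates = {frozenset(cc) for cc in comps if not (cc & bulk) and cc != bulk}
    confirmed = None
    if previous:
        persistent = [cc for cc in candidates if cc in previous]
        if persistent:
            com = {c.id: c.com for c in alive}
            persistent.sort(
                key=lambda cc: -float(np.mean([com[i][1] for i in cc]))
            )
            confirmed = tuple(sorted(persistent[0]))
    return confirmed, candidates


def kaplan_meier(events: list[RuptureEvent], alpha: float = 0.05) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood confidence band."""
    if not events:
        raise ValueError("kaplan_meier requires at least one record")
    from lifelines import KaplanMeierFitter

    durations = np.array([e.time for e in events], dtype=float)
    observed = np.array([not e.censored for e in events], dtype=bool)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, event_observed=observed)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    lo = ci.iloc[:, 0].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].to_numpy(dtype=float)
    return SurvivalCurve(times, surv, lo, hi, final_survival=float(surv[-1]))


def _category(size: int) -> str:
    if size <= 5:
        return str(size)
    if size <= 10:
        return "6-10"
    return ">10"


def cluster_size_stats(events: list[RuptureEvent]) -> dict:
    """Cluster-size histogram over the standard categories plus mean +- SE.

    Censored replicates are excluded.  Categories 6-10 and >10 group
    together similar-sized large clusters.
    """
    sizes = np.array([e.cluster_size for e in events if not e.censored], dtype=float)
    if sizes.size == 0:
        raise ValueError("no uncensored rupture events")
    probs = {cat: 0.0 for cat in CLUSTER_CATEGORIES}
    for s in sizes:
        probs[_category(int(s))] += 1.0 / sizes.size
    mean = float(np.mean(sizes))
    se = float(np.std(sizes, ddof=1) / np.sqrt(sizes.size)) if sizes.size > 1 else 0.0
    return {"probabilities": probs, "mean_size": mean, "se": se, "n": int(sizes.size)}


def size_vs_time(
    events: list[RuptureEvent], bin_width: float = 1.0
) -> pd.DataFrame:
    """Mean cluster size (+- SE) binned by rupture time; empty bins omitted."""
    obs = [(e.time, e.cluster_size) for e in events if not e.censored]
    if not obs:
        return pd.DataFrame(columns=["t_mid", "mean_size", "se", "n"])
    df = pd.DataFrame(obs, columns=["time", "size"])
    df["bin"] = np.floor(df["time"] / bin_width).astype(int)
    rows = []
    for b, grp in df.groupby("bin"):
        se = grp["size"].std(ddof=1) / np.sqrt(len(grp)) if len(grp) > 1 else 0.0
        rows.append(
            {
                "t_mid": (b + 0.5) * bin_width,
                "mean_size": grp["size"].mean(),
                "se": float(0.0 if np.isnan(se) else se),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)


def ensemble_msd(trajectories: pd.DataFrame, max_lag_frac: float = 0.5):
    """Time-and-ensemble averaged MSD from unwrapped trajectories.

    ``trajectories`` columns: t, id, x, y (positions already unwrapped on
    periodic axes).  Returns (lags, msd).
    """
    pivot_x = trajectories.pivot_table(index="t", columns="id", values="x", sort=True)
    pivot_y = trajectories.pivot_table(index="t", columns="id", values="y", sort=True)
    times = pivot_x.index.to_numpy(dtype=float)
    X = pivot_x.to_numpy()
    Y = pivot_y.to_numpy()
    n_frames = X.shape[0]
    max_lag = max(2, int(n_frames * max_lag_frac))
    lags = np.arange(1, max_lag)
    msd = np.empty(lags.size)
    for k, lag in enumerate(lags):
        dx = X[lag:] - X[:-lag]
        dy = Y[lag:] - Y[:-lag]
        msd[k] = np.nanmean(dx * dx + dy * dy)
    dt_frame = float(np.median(np.diff(times)))
    return lags * dt_frame, msd


def msd_and_diffusivity(
    trajectories: pd.DataFrame,
    params: ModelParams,
    fit_start: float | None = None,
    max_lag_frac: float = 0.5,
) -> MSDResult:
    """MSD plus the normalized effective diffusivity Deff = slope / (4 D0).

    An ordinary least-squares line (not forced through the origin) is fit
    to MSD(t) on the late-time window t > 3/D_r.  Raises ``ValueError``
    when the window holds fewer than 5 MSD samples.
    """
    lags, msd = ensemble_msd(trajectories, max_lag_frac=max_lag_frac)
    if fit_start is None:
        fit_start = 3.0 / params.D_r
    mask = lags > fit_start
    if int(mask.sum()) < 5:
        raise ValueError(
            f"late-time fit window t > {fit_start:.2f} h holds "
            f"{int(mask.sum())} samples (< 5); run longer"
        )
    slope, _ = np.polyfit(lags[mask], msd[mask], 1)
    D0 = params.p0**2 / (2.0 * params.D_r)
    deff = max(float(slope), 0.0) / (4.0 * D0)
    return MSDResult(
        lags=lags,
        msd=msd,
        fit_window=(float(lags[mask][0]), float(lags[-1])),
        D0=float(D0),
        Deff=deff,
    )


def classify_jamming(deff: float, threshold: float = JAMMING_THRESHOLD) -> str:
    """'solid' below the threshold, 'fluid' at or above it."""
    if deff < 0:
        raise ValueError("effective diffusivity must be nonnegative")
    return "solid" if deff < threshold else "fluid"


def chemotactic_index(D_r: float, k_theta: float) -> float:
    """CI = <cos theta> = exp(-D_r / (2 k_theta)) for the OU polarity.

    Both rates must be in the same units.  D_r = 0 gives perfect
    chemotaxis (CI = 1).
    """
    if k_theta <= 0:
        raise ValueError("k_theta must be positive")
    if D_r < 0:
        raise ValueError("D_r must be nonnegative")
    return float(np.exp(-D_r / (2.0 * k_theta)))


def peclet(p0: float, R: float, D_r: float) -> float:
    """Peclet number Pe = p0 / (R D_r): persistence length over cell size."""
    if R <= 0 or D_r <= 0:
        raise ValueError("R and D_r must be positive")
    if p0 < 0:
        raise ValueError("p0 must be nonnegative")
    return float(p0 / (R * D_r))
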