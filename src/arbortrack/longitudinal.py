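"""Longitudinal arbor dynamics: gain/loss events, rates and retractions.

Assembles per-arbor time series of skeletons and morphometry, matches
terminal branches between consecutive imaging sessions, and computes the
dynamic quantities of interest: event rates under different sampling
intervals (coarse sampling censors branches both gained and lost within one
interval, biasing rates downward), time to first change, bulb-led
retraction traces and their outcomes, arbor-complexity transitions, the
min/max branch-count correlation, and whole-arbor persistence per taste bud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from arbortrack.morphometry import (
    MIN_TERMINAL_LENGTH_UM,
    HullMetrics,
    SwellingAnnotation,
    convex_hull_metrics,
    enumerate_terminal_branches,
    total_cable_length,
)
from arbortrack.skeleton import SkeletonTree

__all__ = [
    "ArborMorphometry",
    "ArborTimeSeries",
    "RemodelingEventObserved",
    "RetractionTrace",
    "match_terminal_branches",
    "observed_events",
    "change_rate",
    "time_to_first_change",
    "subsample_series",
    "track_retraction",
    "swelling_outcomes",
    "complexity_transitions",
    "minmax_branch_correlation",
    "arbor_persistence",
]

#: Maximum tip displacement (μm) for two terminal branches at consecutive
#: timepoints to be considered the same branch.
TIP_TOLERANCE_UM = 5.0

#: Maximum path-overlap distance (μm) for two branches to be accepted as
#: the same tube. A branch that merely elongated or shortened keeps a
#: near-zero path distance (one polyline is a prefix of the other), whereas
#: two distinct branches diverge from their branch point and score several
#: μm, so this is kept tight — a loose value would fuse a genuine loss with
#: a nearby gain into a false persistence.
MATCH_TOLERANCE_UM = 2.0


def _branch_path_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric path-overlap distance between two branch polylines (μm).

    The minimum of the two directed mean nearest-point distances: ≈0 when
    one branch is a sub- or super-segment of the other (growth, retraction,
    or a branch whose proximal branch point vanished), large when the tubes
    are genuinely different.
    """
    d = cdist(a, b)
    return float(min(d.min(axis=1).mean(), d.min(axis=0).mean()))

#: A tracked retraction stops once the per-interval shortening falls below
#: this (μm). Half the skeleton sampling step: the slowest retractions span
#: ~100 h, so a 12-h session pair may shorten by well under a micrometre and
#: a larger epsilon would cut those traces short.
STOP_EPSILON_UM = 0.5

COMPLEXITY_BOUNDS = ((1, 3), (4, 6), (7, None))


@dataclass
class ArborMorphometry:
    """Per-arbor, per-timepoint scalar summary."""

    arbor_id: int
    time_h: float
    n_terminal: int
    total_length: float
    hull: HullMetrics | None = None


@dataclass
class ArborTimeSeries:
    """Ordered skeleton snapshots of one arbor with per-timepoint morphometry."""

    arbor_id: int
    times_h: list[float]
    trees: list[SkeletonTree]
    morphometry: list[ArborMorphometry]
    sampling_interval_h: float

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.trees):
            raise ValueError("one tree per timepoint required")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("timepoints must be strictly increasing")

    @classmethod
    def from_trees(
        cls,
        arbor_id: int,
        times_h: list[float],
        trees: list[SkeletonTree],
        min_length_um: float = MIN_TERMINAL_LENGTH_UM,
        with_hull: bool = False,
    ) -> "ArborTimeSeries":
        morpho = []
        for t, tree in zip(times_h, trees):
            hull = convex_hull_metrics(tree.positions()) if with_hull else None
            morpho.append(
                ArborMorphometry(
                    arbor_id,
                    t,
                    len(enumerate_terminal_branches(tree, min_length_um)),
                    total_cable_length(tree),
                    hull,
                )
            )
        interval = float(times_h[1] - times_h[0]) if len(times_h) > 1 else float("nan")
        return cls(arbor_id, list(times_h), list(trees), morpho, interval)

    def n_terminal(self) -> np.ndarray:
        return np.array([m.n_terminal for m in self.morphometry])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.morphometry:
            row = {
                "arbor_id": m.arbor_id,
                "time_h": m.time_h,
                "n_terminal": m.n_terminal,
                "length_um": m.total_length,
            }
            if m.hull is not None:
                row.update(
                    hull_volume_um3=m.hull.volume,
                    x_width=m.hull.x_width,
                    y_width=m.hull.y_width,
                    z_height=m.hull.z_height,
                )
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RemodelingEventObserved:
    """Observed branch bookkeeping for one inter-session interval.

    ``matches`` pairs terminal-branch ids (prev, next); branches unmatched in
    the later session are gains, unmatched in the earlier one are losses, so
    Δn_terminal = gains − losses holds identically.
    """

    arbor_id: int
    t_start: float
    t_end: float
    gains: int
    losses: int
    matches: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RetractionTrace:
    """A branch followed from swelling onset until it stops retracting."""

    arbor_id: int
    branch_id: int
    onset_time_h: float
    times_h: list[float]
    lengths_um: list[float]
    end_time_h: float
    total_retraction_um: float
    outcome: str  # retracted | not_retracted


# -- branch matching ----------------------------------------------------------


def match_terminal_branches(
    prev: SkeletonTree,
    next: SkeletonTree,
    tip_tolerance_um: float = TIP_TOLERANCE_UM,
    min_length_um: float = MIN_TERMINAL_LENGTH_UM,
    match_tolerance_um: float = MATCH_TOLERANCE_UM,
    arbor_id: int = 0,
    t_start: float = 0.0,
    t_end: float = 0.0,
) -> RemodelingEventObserved:
    """Match terminal branches across two sessions of the same arbor.

    A one-to-one assignment minimizing total tip displacement is computed
    (Hungarian algorithm); an assigned pair is accepted only when the tips
    lie within ``tip_tolerance_um`` *and* the branch polylines overlap to
    within ``match_tolerance_um`` (two different branches whose tips happen
    to be close are not the same branch). Branches left over then get one
    rescue pass on path overlap alone, which recognises a branch that
    elongated or shortened past the tip tolerance between sessions. What
    remains unmatched in the later tree counts as gains; in the earlier
    tree, as losses.
    """
    b_prev = enumerate_terminal_branches(prev, min_length_um)
    b_next = enumerate_terminal_branches(next, min_length_um)
    matches: list[tuple[int, int]] = []
    un_prev = list(range(len(b_prev)))
    un_next = list(range(len(b_next)))

    if b_prev and b_next:
        tips_p = np.array([b.tip for b in b_prev])
        tips_n = np.array([b.tip for b in b_next])
        cost = cdist(tips_p, tips_n)
        path_cost = np.array(
            [[_branch_path_distance(p.points, q.points) for q in b_next] for p in b_prev]
        )
        # pad to square so unmatched rows/cols cost the tolerance
        n = max(len(b_prev), len(b_next))
        padded = np.full((n, n), float(tip_tolerance_um))
        padded[: len(b_prev), : len(b_next)] = np.minimum(cost, 2 * tip_tolerance_um)
        rows, cols = linear_sum_assignment(padded)
        for r, c in zip(rows, cols):
            if (
                r < len(b_prev)
                and c < len(b_next)
                and cost[r, c] <= tip_tolerance_um
                and path_cost[r, c] <= match_tolerance_um
            ):
                matches.append((b_prev[r].branch_id, b_next[c].branch_id))
                un_prev.remove(r)
                un_next.remove(c)
        # rescue on path overlap: same tube, tip moved beyond tolerance
        for r in list(un_prev):
            if not un_next:
                break
            d_path = [path_cost[r, c] for c in un_next]
            k = int(np.argmin(d_path))
            if d_path[k] <= match_tolerance_um:
                c = un_next[k]
                matches.append((b_prev[r].branch_id, b_next[c].branch_id))
                un_prev.remove(r)
                un_next.remove(c)

    return RemodelingEventObserved(
        arbor_id=arbor_id,
        t_start=t_start,
        t_end=t_end,
        gains=len(un_next),
        losses=len(un_prev),
        matches=matches,
    )


def observed_events(
    series: ArborTimeSeries, tip_tolerance_um: float = TIP_TOLERANCE_UM
) -> list[RemodelingEventObserved]:
    """Branch matching over every consecutive pair of sessions."""
    return [
        match_terminal_branches(
            series.trees[k],
            series.trees[k + 1],
            tip_tolerance_um,
            arbor_id=series.arbor_id,
            t_start=series.times_h[k],
            t_end=series.times_h[k + 1],
        )
        for k in range(len(series.trees) - 1)
    ]


# -- rates and first change ---------------------------------------------------


def change_rate(
    series: ArborTimeSeries,
    events: list[RemodelingEventObserved] | None = None,
    tip_tolerance_um: float = TIP_TOLERANCE_UM,
) -> float:
    """Observed terminal-branch events per hour: (Σ gains + Σ losses) / elapsed."""
    if len(series.times_h) < 2:
        raise ValueError("change_rate needs at least two timepoints")
    if events is None:
        events = observed_events(series, tip_tolerance_um)
    total = sum(e.gains + e.losses for e in events)
    return total / (series.times_h[-1] - series.times_h[0])


def time_to_first_change(
    series: ArborTimeSeries,
    events: list[RemodelingEventObserved] | None = None,
    tip_tolerance_um: float = TIP_TOLERANCE_UM,
) -> float | None:
    """Elapsed time (h) to the end of the first interval with any gain or
    loss; None when the arbor is stable throughout (right-censored)."""
    if len(series.times_h) < 2:
        raise ValueError("time_to_first_change needs at least two timepoints")
    if events is None:
        events = observed_events(series, tip_tolerance_um)
    for e in events:
        if e.gains + e.losses > 0:
            return e.t_end - series.times_h[0]
    return None


def subsample_series(series: ArborTimeSeries, interval_h: float) -> ArborTimeSeries:
    """Keep every k-th session from t0, emulating a coarser imaging interval.

    ``interval_h`` must be an integer multiple of the native interval.
    Derived quantities recomputed on the result quantify sampling censoring.
    """
    native = series.sampling_interval_h
    k = interval_h / native
    if abs(k - round(k)) > 1e-9 or k < 1:
        raise ValueError(
            f"interval {interval_h} h is not a multiple of the native {native} h"
        )
    k = int(round(k))
    idx = list(range(0, len(series.times_h), k))
    return ArborTimeSeries(
        series.arbor_id,
        [series.times_h[i] for i in idx],
        [series.trees[i] for i in idx],
        [series.morphometry[i] for i in idx],
        interval_h,
    )


# -- retraction tracking ------------------------------------------------------


def track_retraction(
    series: ArborTimeSeries,
    annotation: SwellingAnnotation,
    stop_epsilon_um: float = STOP_EPSILON_UM,
    tip_tolerance_um: float = TIP_TOLERANCE_UM,
) -> RetractionTrace:
    """Follow a swelling-annotated branch until it stops retracting.

    Starting at the session where the swelling was observed, the branch is
    re-identified in each later session via branch matching and its length
    recorded, until it disappears or shortens by less than
    ``stop_epsilon_um`` between consecutive sessions. The total retraction is
    the onset length minus the final length; a branch with no net shortening
    is scored ``not_retracted``.
    """
    try:
        k0 = series.times_h.index(annotation.time_h)
    except ValueError:
        raise ValueError(f"no session at t = {annotation.time_h} h") from None
    branches = {
        b.branch_id: b
        for b in enumerate_terminal_branches(series.trees[k0], min_length_um=0.0)
    }
    if annotation.branch_id not in branches:
        raise ValueError(
            f"branch {annotation.branch_id} not found at onset session t = "
            f"{annotation.time_h} h"
        )
    cur_id = annotation.branch_id
    times = [series.times_h[k0]]
    lengths = [branches[cur_id].length]
    for k in range(k0, len(series.trees) - 1):
        ev = match_terminal_branches(
            series.trees[k],
            series.trees[k + 1],
            tip_tolerance_um,
            min_length_um=0.0,
        )
        nxt = {p: n for p, n in ev.matches}.get(cur_id)
        if nxt is None:  # branch disappeared
            times.append(series.times_h[k + 1])
            lengths.append(0.0)
            break
        nxt_branches = {
            b.branch_id: b
            for b in enumerate_terminal_branches(series.trees[k + 1], min_length_um=0.0)
        }
        new_len = nxt_branches[nxt].length
        shrink = lengths[-1] - new_len
        if shrink < stop_epsilon_um:
            break
        times.append(series.times_h[k + 1])
        lengths.append(new_len)
        cur_id = nxt
    total = max(0.0, lengths[0] - lengths[-1])
    return RetractionTrace(
        arbor_id=series.arbor_id,
        branch_id=annotation.branch_id,
        onset_time_h=times[0],
        times_h=times,
        lengths_um=lengths,
        end_time_h=times[-1],
        total_retraction_um=total,
        outcome="retracted" if total > 0 else "not_retracted",
    )


def swelling_outcomes(traces: list[RetractionTrace]) -> tuple[float, float]:
    """Fractions of swelling-bearing branches that did and did not retract."""
    if not traces:
        raise ValueError("no retraction traces given")
    n_ret = sum(t.outcome == "retracted" for t in traces)
    return n_ret / len(traces), 1.0 - n_ret / len(traces)


# -- cohort summaries ---------------------------------------------------------


def _complexity_group(n: int, bounds=COMPLEXITY_BOUNDS) -> str:
    for lo, hi in bounds:
        if hi is None:
            if n >= lo:
                return f"{lo}+"
        elif lo <= n <= hi:
            return f"{lo}-{hi}"
    return f"{bounds[0][0]}-{bounds[0][1]}"  # counts below the lowest bound


def complexity_transitions(
    series_list: list[ArborTimeSeries],
    times_h: tuple[float, ...] = (0.0, 120.0, 240.0),
    bounds=COMPLEXITY_BOUNDS,
) -> pd.DataFrame:
    """Group each arbor by terminal-branch count at the requested sessions.

    Returns a per-arbor table of group labels (Sankey-ready: each consecutive
    column pair defines one set of flows). Arbors missing a session raise.
    """
    rows = []
    for s in series_list:
        labels = {}
        for t in times_h:
            if t not in s.times_h:
                raise ValueError(f"arbor {s.arbor_id} has no session at t = {t} h")
            n = s.morphometry[s.times_h.index(t)].n_terminal
            labels[f"t{int(t)}"] = _complexity_group(n, bounds)
        rows.append({"arbor_id": s.arbor_id, **labels})
    return pd.DataFrame(rows)


def transition_counts(groups: pd.DataFrame, col_a: str, col_b: str) -> pd.DataFrame:
    """Group-to-group flow counts between two sessions of a transition table."""
    return groups.groupby([col_a, col_b]).size().reset_index(name="n")


def minmax_branch_correlation(series_list: list[ArborTimeSeries]) -> float:
    """R² between each arbor's maximum and minimum terminal-branch count.

    A high value means arbors fluctuate within a band set by their own
    baseline complexity rather than wandering freely. Returns NaN when the
    minima have zero variance (undefined slope).
    """
    if len(series_list) < 3:
        raise ValueError("need at least three arbors")
    mins = np.array([s.n_terminal().min() for s in series_list], dtype=float)
    maxs = np.array([s.n_terminal().max() for s in series_list], dtype=float)
    if np.all(mins == mins[0]):
        return float("nan")
    res = _sstats.linregress(mins, maxs)
    return float(res.rvalue**2)


@dataclass
class PersistenceReport:
    counts: pd.DataFrame  # bud_id × session arbor counts
    totals: list[int]
    gained: int
    lost: int
    any_gain: bool


def arbor_persistence(bud_counts: pd.DataFrame) -> PersistenceReport:
    """Arbor-count stability per taste bud across sessions.

    ``bud_counts`` is wide-form: one row per bud (index = bud id), one column
    per session in chronological order, values = labeled arbors present.
    Tallies total arbors per session and per-bud gains/losses; any gain is
    flagged (whole arbors were never seen to be added in vivo).
    """
    counts = bud_counts.astype(int)
    diffs = counts.diff(axis=1).iloc[:, 1:]
    gained = int(diffs.clip(lower=0).to_numpy().sum())
    lost = int((-diffs.clip(upper=0)).to_numpy().sum())
    return PersistenceReport(
        counts=counts,
        totals=[int(v) for v in counts.sum(axis=0)],
        gained=gained,
        lost=lost,
        any_gain=gained > 0,
    )
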