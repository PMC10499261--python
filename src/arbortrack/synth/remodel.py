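"""Stochastic terminal-branch remodeling of arbors in continuous time.

Each arbor carries two independent Poisson clocks — one for terminal-branch
gains, one for retraction initiations — matching the per-arbor event-rate
summaries the analysis estimates. Gains sprout a new branch from an interior
point of the arbor and elongate at a fixed growth speed; retractions shorten
a fully grown terminal branch linearly to its branch point over a duration
drawn from a configured range (12–108 h by default, the span observed for
bulb-led retractions in vivo). A retraction is preceded by a tip swelling
("retraction bulb", tip radius inflated well past the 3× detection rule)
with probability ``p_bulb``; transient bulbs that resolve without
retraction (growth cones) ride along at odds (1 − p_bulb) : p_bulb, so the
same fraction of bulb episodes is followed by retraction.

Bookkeeping convention: a branch is *countable* as a terminal branch once
its length reaches 2 μm (sub-resolution stubs are not observable). The event
log records ``gain`` at the moment a growing branch crosses that length
upward and ``retraction_end`` at the moment a retracting branch crosses it
downward, so that between any two snapshots the change in countable-branch
number equals gains minus completed retractions, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arbortrack.morphometry import MIN_TERMINAL_LENGTH_UM, enumerate_terminal_branches
from arbortrack.skeleton import SkeletonNode, SkeletonTree
from arbortrack.synth.arbor import make_arbor_skeleton, grow_path, sample_branch_direction

__all__ = ["SimulationConfig", "EventLog", "simulate_remodeling", "simulate_cohort"]

EVENT_TYPES = ("gain", "retraction_start", "retraction_end", "bulb_onset")

#: Tip radius during a bulb episode, as a multiple of the branch baseline
#: radius — kept strictly above the 3× detection rule.
BULB_RADIUS_RATIO = 3.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one remodeling simulation.

    Rates are per arbor per hour; durations and intervals in hours. The
    defaults mirror the in vivo conditions under study: ten days of imaging
    at 12-hour sessions, a true combined gain+loss rate of one event per
    8 hours (the rate seen once sampling is fast enough to avoid censoring),
    90% of retractions preceded by a bulb, and retraction durations spanning
    12–108 hours.
    """

    seed: int = 0
    n_arbors: int = 26
    initial_terminal_branches: int | tuple[int, int] = (2, 6)
    gain_rate: float = 1.0 / 16.0
    retraction_rate: float = 1.0 / 16.0
    p_bulb: float = 0.9
    retraction_duration_range: tuple[float, float] = (12.0, 108.0)
    growth_speed: float = 2.0  # μm/h
    duration_h: float = 240.0
    snapshot_interval_h: float = 12.0
    extent_um: tuple[float, float, float] = (30.0, 30.0, 40.0)
    branch_length_range_um: tuple[float, float] = (4.0, 10.0)
    bulb_lead_h: float = 3.0  # bulb onset precedes shortening by this much
    transient_bulb_rate: float | None = None  # None → derived from p_bulb
    transient_bulb_dwell_h: float = 12.0
    # homeostatic mode: events that would push the countable-branch count
    # more than ``homeostatic_band`` away from its starting value are
    # suppressed, bounding each arbor's fluctuation around its own baseline
    # complexity; with False the two clocks run independently (whether the
    # real process is coupled is not established, so both are available)
    homeostatic: bool = False
    homeostatic_band: int = 1

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.retraction_rate < 0:
            raise ValueError("rates must be ≥ 0")
        if not 0.0 <= self.p_bulb <= 1.0:
            raise ValueError("p_bulb must lie in [0, 1]")
        lo, hi = self.retraction_duration_range
        if not (0 < lo <= hi <= self.duration_h):
            raise ValueError(
                "retraction_duration_range must lie within (0, duration_h]"
            )
        if self.duration_h <= 0 or self.snapshot_interval_h <= 0:
            raise ValueError("duration_h and snapshot_interval_h must be positive")
        if self.growth_speed <= 0:
            raise ValueError("growth_speed must be positive")

    def resolved_transient_bulb_rate(self) -> float:
        """Explicit transient-bulb (growth-cone) Poisson rate, if configured.

        When left at None, transient bulbs are instead coupled to accepted
        retraction initiations (one with probability 1 − p_bulb each), which
        keeps the fraction of bulb episodes that end in retraction equal to
        ``p_bulb`` exactly, whatever fraction of retraction attempts the
        eligibility and homeostatic rules suppress.
        """
        return self.transient_bulb_rate or 0.0


@dataclass
class EventLog:
    """Ground-truth ledger of remodeling events.

    Records (arbor_id, event_type, time_h, branch_id) with event types
    ``gain`` (branch crossed countable length upward), ``retraction_start``
    (shortening began), ``retraction_end`` (branch crossed countable length
    downward) and ``bulb_onset`` (tip swelling appeared).
    """

    records: list[tuple[int, str, float, int]] = field(default_factory=list)

    def add(self, arbor_id: int, event_type: str, time_h: float, branch_id: int) -> None:
        if event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {event_type!r}")
        self.records.append((int(arbor_id), event_type, float(time_h), int(branch_id)))

    def extend(self, other: "EventLog") -> None:
        self.records.extend(other.records)

    def sort(self) -> None:
        self.records.sort(key=lambda r: (r[0], r[2], r[1], r[3]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["arbor_id", "event_type", "time_h", "branch_id"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventLog":
        return cls(
            [
                (int(r.arbor_id), str(r.event_type), float(r.time_h), int(r.branch_id))
                for r in df.itertuples()
            ]
        )

    def events_in(
        self,
        arbor_id: int | None = None,
        t0: float = -np.inf,
        t1: float = np.inf,
        types: tuple[str, ...] | None = None,
    ) -> list[tuple[int, str, float, int]]:
        """Events with t0 < time ≤ t1 (half-open on the left), filtered."""
        return [
            r
            for r in self.records
            if (arbor_id is None or r[0] == arbor_id)
            and t0 < r[2] <= t1
            and (types is None or r[1] in types)
        ]


@dataclass
class _Branch:
    bid: int
    base_key: int  # original node id of the attachment (stable sibling grouping)
    base_pos: np.ndarray
    base_core_children: bool  # core continues past the base (no exposure risk)
    path: np.ndarray  # (m, 3) target polyline, base excluded
    radius: float
    born_t: float | None = None  # None: existed fully grown at t = 0
    full_length: float = 0.0
    arc: np.ndarray = None  # type: ignore[assignment]  # cumulative arc at path points
    retract_start: float = np.inf
    retract_duration: float = np.inf
    bulb_episodes: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seg0 = np.linalg.norm(self.path[0] - self.base_pos)
        segs = np.linalg.norm(np.diff(self.path, axis=0), axis=1)
        self.arc = np.concatenate([[seg0], seg0 + np.cumsum(segs)])
        self.full_length = float(self.arc[-1])

    def grown_length(self, t: float, speed: float) -> float:
        if self.born_t is None:
            return self.full_length
        if t < self.born_t:
            return 0.0
        return min(self.full_length, speed * (t - self.born_t))

    def length(self, t: float, speed: float) -> float:
        L = self.grown_length(t, speed)
        if t >= self.retract_start:
            frac = 1.0 - (t - self.retract_start) / self.retract_duration
            L = self.full_length * max(0.0, frac)
        return L

    def fully_grown(self, t: float, speed: float) -> bool:
        return self.born_t is None or speed * (t - self.born_t) >= self.full_length

    def bulb_active(self, t: float) -> bool:
        return any(t0 <= t <= t1 for t0, t1 in self.bulb_episodes)

    def visible_points(self, t: float, speed: float) -> np.ndarray:
        """Polyline points (excluding base) visible at time t, with the tip
        interpolated to the exact current length."""
        L = self.length(t, speed)
        if L <= 0:
            return np.empty((0, 3))
        keep = self.arc < L - 1e-9
        pts = self.path[keep]
        # interpolated tip at exactly arc length L
        arc_full = np.concatenate([[0.0], self.arc])
        path_full = np.vstack([self.base_pos, self.path])
        tip = np.array(
            [np.interp(L, arc_full, path_full[:, k]) for k in range(3)]
        )
        return np.vstack([pts, tip]) if len(pts) else tip[None, :]


def _decompose(tree: SkeletonTree) -> tuple[list[_Branch], list[int]]:
    """Split a tree into retractable terminal branches and the static core."""
    branches = []
    branch_nodes: set[int] = set()
    for k, tb in enumerate(enumerate_terminal_branches(tree, min_length_um=0.0)):
        base_id = tb.node_ids[0]
        branches.append(
            _Branch(
                bid=k + 1,
                base_key=base_id,
                base_pos=tree.node(base_id).position.copy(),
                base_core_children=False,  # fixed up below
                path=tb.points[1:].copy(),
                radius=float(np.median(tb.radii[1:])) if len(tb.radii) > 1 else 0.4,
            )
        )
        branch_nodes.update(tb.node_ids[1:])
    core_ids = [n.id for n in tree if n.id not in branch_nodes]
    core_set = set(core_ids)
    for b in branches:
        b.base_core_children = any(
            c in core_set for c in tree.children(b.base_key)
        )
    return branches, core_ids


def simulate_remodeling(
    tree: SkeletonTree,
    cfg: SimulationConfig,
    arbor_id: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[list[SkeletonTree], EventLog]:
    """Run the continuous-time remodeling process on one arbor.

    Returns skeleton snapshots at ``0, Δ, 2Δ, …, duration_h`` for
    Δ = ``cfg.snapshot_interval_h``, plus the ground-truth :class:`EventLog`.
    Identical (tree, cfg, rng seed) reproduce identical output.
    """
    if len(tree) == 0:
        raise ValueError("cannot remodel an empty tree")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    branches, core_ids = _decompose(tree)
    next_bid = len(branches) + 1
    core_pos = {i: tree.node(i).position for i in core_ids}
    core_set = set(core_ids)

    # gains attach to upper core nodes (the in-bud portion of the arbor)
    zs = np.array([core_pos[i][2] for i in core_ids])
    z_floor = np.quantile(zs, 0.6) if len(zs) > 1 else zs[0]
    attach_candidates = [i for i in core_ids if core_pos[i][2] >= z_floor] or core_ids
    all_pos = tree.positions()

    def _poisson_times(rate: float) -> list[float]:
        times, t = [], 0.0
        if rate <= 0:
            return times
        while True:
            t += rng.exponential(1.0 / rate)
            if t > cfg.duration_h:
                return times
            times.append(t)

    gain_times = _poisson_times(cfg.gain_rate)
    retract_times = _poisson_times(cfg.retraction_rate)
    false_bulb_times = _poisson_times(cfg.resolved_transient_bulb_rate())
    schedule = sorted(
        [(t, "gain", k) for k, t in enumerate(gain_times)]
        + [(t, "retract", k) for k, t in enumerate(retract_times)]
        + [(t, "false_bulb", k) for k, t in enumerate(false_bulb_times)]
    )

    log = EventLog()
    min_len = MIN_TERMINAL_LENGTH_UM

    def countable(b: _Branch, t: float) -> bool:
        return b.length(t, cfg.growth_speed) >= min_len

    def stable(b: _Branch, t: float) -> bool:
        return (
            b.fully_grown(t, cfg.growth_speed)
            and not np.isfinite(b.retract_start)
            and countable(b, t)
        )

    n_baseline = sum(1 for b in branches if b.full_length >= min_len)

    for t, kind, _ in schedule:
        if cfg.homeostatic and kind in ("gain", "retract"):
            # count where the arbor is headed, not where it is: branches in
            # flight (growing below the countable floor, or retracting but
            # still visible) are scored by their eventual state
            n_eff = sum(
                1
                for b in branches
                if not np.isfinite(b.retract_start) and b.full_length >= min_len
            )
            n_vis = sum(
                1 for b in branches if b.length(t, cfg.growth_speed) >= min_len
            )
            hi = n_baseline + cfg.homeostatic_band
            lo = n_baseline - cfg.homeostatic_band
            if kind == "gain" and (n_eff >= hi or n_vis >= hi):
                continue
            if kind == "retract" and (n_eff <= lo or n_vis <= lo):
                continue
        if kind == "gain":
            attach = int(rng.choice(attach_candidates))
            apos = core_pos[attach]
            parent = tree.node(attach).parent
            pdir = (
                apos - tree.node(parent).position
                if parent is not None
                else np.array([0.0, 0.0, 1.0])
            )
            pdir = pdir / max(np.linalg.norm(pdir), 1e-9)
            d = sample_branch_direction(rng, pdir, existing=all_pos, origin=apos)
            d = d + np.array([0.0, 0.0, 0.3])
            d /= np.linalg.norm(d)
            target = rng.uniform(*cfg.branch_length_range_um)
            path = grow_path(
                rng, apos, d, target, np.asarray(cfg.extent_um), avoid=all_pos
            )
            b = _Branch(
                bid=next_bid,
                base_key=attach,
                base_pos=apos.copy(),
                base_core_children=any(
                    c in core_set for c in tree.children(attach)
                ),
                path=path,
                radius=0.4,
                born_t=t,
            )
            next_bid += 1
            branches.append(b)
            t_up = t + min_len / cfg.growth_speed
            if t_up <= cfg.duration_h:
                log.add(arbor_id, "gain", t_up, b.bid)
        elif kind in ("retract", "false_bulb"):
            stable_now = [b for b in branches if stable(b, t)]
            n_countable = sum(countable(b, t) for b in branches)
            if kind == "retract":
                # never retract a branch whose loss could expose a bare core
                # path as a spurious new terminal branch, and never empty the
                # arbor of countable branches entirely
                eligible = [
                    b
                    for b in stable_now
                    if n_countable >= 2
                    and (
                        b.base_core_children
                        or any(
                            o is not b and o.base_key == b.base_key and stable(o, t)
                            for o in branches
                        )
                    )
                ]
                if not eligible:
                    continue
                b = eligible[int(rng.integers(len(eligible)))]
                duration = rng.uniform(*cfg.retraction_duration_range)
                has_bulb = rng.random() < cfg.p_bulb
                start = t + cfg.bulb_lead_h if has_bulb else t
                if start >= cfg.duration_h:
                    start_ok = False
                else:
                    start_ok = True
                if has_bulb:
                    log.add(arbor_id, "bulb_onset", t, b.bid)
                if not start_ok:
                    continue
                b.retract_start = start
                b.retract_duration = duration
                if has_bulb:
                    b.bulb_episodes.append((t, start + duration))
                log.add(arbor_id, "retraction_start", start, b.bid)
                t_down = start + duration * (1.0 - min_len / b.full_length)
                if t_down <= cfg.duration_h:
                    log.add(arbor_id, "retraction_end", t_down, b.bid)
                # transient (growth-cone) bulbs ride along with accepted
                # retractions at odds (1 − p_bulb) : p_bulb, so the fraction
                # of bulb episodes followed by retraction equals p_bulb
                if (
                    cfg.transient_bulb_rate is None
                    and 0.0 < cfg.p_bulb < 1.0
                    and rng.random() < (1.0 - cfg.p_bulb)
                ):
                    others = [
                        o for o in stable_now if o is not b and not o.bulb_active(t)
                    ]
                    if others:
                        o = others[int(rng.integers(len(others)))]
                        o.bulb_episodes.append((t, t + cfg.transient_bulb_dwell_h))
                        log.add(arbor_id, "bulb_onset", t, o.bid)
            else:  # transient bulb: swelling that resolves without retraction
                eligible = [b for b in stable_now if not b.bulb_active(t)]
                if not eligible:
                    continue
                b = eligible[int(rng.integers(len(eligible)))]
                b.bulb_episodes.append((t, t + cfg.transient_bulb_dwell_h))
                log.add(arbor_id, "bulb_onset", t, b.bid)

    n_snaps = int(np.floor(cfg.duration_h / cfg.snapshot_interval_h)) + 1
    times = [k * cfg.snapshot_interval_h for k in range(n_snaps)]
    snapshots = [
        _snapshot(tree, core_ids, branches, t, cfg.growth_speed) for t in times
    ]
    log.sort()
    return snapshots, log


def _snapshot(
    tree: SkeletonTree,
    core_ids: list[int],
    branches: list[_Branch],
    t: float,
    growth_speed: float,
) -> SkeletonTree:
    """Materialize the arbor state at time t as a SkeletonTree."""
    nodes: list[SkeletonNode] = []
    id_map: dict[int, int] = {}
    for old in sorted(core_ids):
        n = tree.node(old)
        new_id = len(nodes) + 1
        id_map[old] = new_id
        parent = None if n.parent is None else id_map[n.parent]
        nodes.append(SkeletonNode(new_id, n.position.copy(), n.radius, parent))
    for b in sorted(branches, key=lambda b: b.bid):
        pts = b.visible_points(t, growth_speed)
        if len(pts) == 0:
            continue
        parent = id_map[b.base_key]
        bulb = b.bulb_active(t)
        for k, p in enumerate(pts):
            new_id = len(nodes) + 1
            radius = b.radius
            if bulb and k == len(pts) - 1:
                radius = BULB_RADIUS_RATIO * b.radius
            nodes.append(SkeletonNode(new_id, p, radius, parent))
            parent = new_id
    return SkeletonTree(nodes)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[dict[int, list[SkeletonTree]], list[float], EventLog]:
    """Simulate ``cfg.n_arbors`` independent arbors under one configuration.

    Per-arbor randomness flows from ``cfg.seed`` through named substreams,
    so any single arbor can be regenerated independently. Returns snapshot
    series keyed by arbor id, the snapshot times, and the merged event log.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_arbors)
    series: dict[int, list[SkeletonTree]] = {}
    log = EventLog()
    times: list[float] = []
    for arbor_id, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        if isinstance(cfg.initial_terminal_branches, tuple):
            lo, hi = cfg.initial_terminal_branches
            n0 = int(rng.integers(lo, hi + 1))
        else:
            n0 = int(cfg.initial_terminal_branches)
        tree = make_arbor_skeleton(rng, n0, cfg.extent_um)
        snaps, alog = simulate_remodeling(tree, cfg, arbor_id=arbor_id, rng=rng)
        series[arbor_id] = snaps
        log.extend(alog)
        if not times:
            n_snaps = len(snaps)
            times = [k * cfg.snapshot_interval_h for k in range(n_snaps)]
    log.sort()
    return series, times, log
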