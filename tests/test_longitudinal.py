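"""Branch matching, event rates, retraction traces and cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from arbortrack import longitudinal as lg
from arbortrack.morphometry import SwellingAnnotation
from arbortrack.skeleton import SkeletonNode, SkeletonTree
from arbortrack.synth import SimulationConfig, make_arbor_skeleton, simulate_cohort


def _path_tree(points, radius=0.5, start_id=1):
    nodes = [SkeletonNode(start_id, np.asarray(points[0], float), radius, None)]
    for k, p in enumerate(points[1:], start=start_id + 1):
        nodes.append(SkeletonNode(k, np.asarray(p, float), radius, k - 1))
    return SkeletonTree(nodes)


def _tree_with_branch(extra_branch_len=0.0):
    """Vertical stem with one horizontal branch; optionally a second branch."""
    nodes = []
    for k in range(1, 12):
        nodes.append(
            SkeletonNode(k, np.array([10.0, 10.0, float(k - 1)]), 0.5, k - 1 if k > 1 else None)
        )
    for j, t in enumerate(np.arange(1.0, 9.0), start=12):
        nodes.append(SkeletonNode(j, np.array([10.0 + t, 10.0, 10.0]), 0.4, j - 1 if j > 12 else 6))
    if extra_branch_len > 0:
        base = len(nodes) + 1
        for j, t in enumerate(np.arange(1.0, extra_branch_len + 1.0), start=base):
            nodes.append(
                SkeletonNode(j, np.array([10.0, 10.0 + t, 8.0]), 0.4, j - 1 if j > base else 9)
            )
    return SkeletonTree(nodes)


@pytest.fixture(scope="module")
def cohort():
    """Shared simulated cohort: 30 arbors, 4-h sessions over 240 h, total
    event rate 1/8 h⁻¹."""
    cfg = SimulationConfig(
        seed=21, n_arbors=30, gain_rate=1 / 16, retraction_rate=1 / 16,
        duration_h=240.0, snapshot_interval_h=4.0, homeostatic=True,
    )
    series_trees, times, log = simulate_cohort(cfg)
    series = [
        lg.ArborTimeSeries.from_trees(aid, times, snaps)
        for aid, snaps in series_trees.items()
    ]
    return series, log, cfg


class TestMatching:
    def test_identical_trees_no_events(self):
        t = _tree_with_branch()
        ev = lg.match_terminal_branches(t, t.copy())
        assert (ev.gains, ev.losses) == (0, 0)

    def test_added_branch_is_one_gain(self):
        prev = _tree_with_branch()
        next_ = _tree_with_branch(extra_branch_len=5.0)
        ev = lg.match_terminal_branches(prev, next_)
        assert (ev.gains, ev.losses) == (1, 0)

    def test_event_labels_agree_with_ground_truth_ledger(self, cohort):
        """Matched gains/losses agree with the generator's event log in ≥95%
        of intervals."""
        series, log, cfg = cohort
        agree = total = 0
        for s in series[:10]:  # 10 arbors × 60 intervals = 600 intervals
            for e in lg.observed_events(s):
                g = len(log.events_in(s.arbor_id, e.t_start, e.t_end, ("gain",)))
                l = len(log.events_in(s.arbor_id, e.t_start, e.t_end, ("retraction_end",)))
                agree += (e.gains, e.losses) == (g, l)
                total += 1
        assert total >= 100
        assert agree / total >= 0.95

    def test_bookkeeping_identity_every_interval(self, cohort):
        """Δ terminal-branch count = gains − losses, exactly, per interval."""
        series, _, _ = cohort
        for s in series:
            counts = s.n_terminal()
            for k, e in enumerate(lg.observed_events(s)):
                assert counts[k + 1] - counts[k] == e.gains - e.losses


class TestRates:
    def test_no_events_zero_rate(self):
        t = _tree_with_branch()
        s = lg.ArborTimeSeries.from_trees(0, [0.0, 12.0], [t, t.copy()])
        assert lg.change_rate(s) == 0.0

    def test_one_gain_in_one_interval(self):
        prev = _tree_with_branch()
        next_ = _tree_with_branch(extra_branch_len=5.0)
        s = lg.ArborTimeSeries.from_trees(0, [0.0, 12.0], [prev, next_])
        assert lg.change_rate(s) == pytest.approx(1 / 12)

    def test_single_timepoint_rejected(self):
        s = lg.ArborTimeSeries.from_trees(0, [0.0], [_tree_with_branch()])
        with pytest.raises(ValueError):
            lg.change_rate(s)
        with pytest.raises(ValueError):
            lg.time_to_first_change(s)

    def test_rate_recovery_within_10_percent(self, cohort):
        """4-h sampling recovers the generator's realized countable-event
        rate to within 10% (mean over 30 arbors)."""
        series, log, cfg = cohort
        df = log.to_frame()
        realized = (
            (df.event_type == "gain").sum() + (df.event_type == "retraction_end").sum()
        ) / (cfg.n_arbors * cfg.duration_h)
        est = np.mean([lg.change_rate(s) for s in series])
        assert est == pytest.approx(realized, rel=0.10)


class TestFirstChange:
    def test_change_in_first_interval(self):
        prev = _tree_with_branch()
        next_ = _tree_with_branch(extra_branch_len=5.0)
        s = lg.ArborTimeSeries.from_trees(
            0, [0.0, 12.0, 24.0], [prev, next_, next_.copy()]
        )
        assert lg.time_to_first_change(s) == 12.0

    def test_stable_series_censored(self):
        t = _tree_with_branch()
        s = lg.ArborTimeSeries.from_trees(0, [0.0, 12.0, 24.0], [t, t.copy(), t.copy()])
        assert lg.time_to_first_change(s) is None


class TestSubsampling:
    def test_identity_at_native_interval(self, cohort):
        series, _, _ = cohort
        s = series[0]
        sub = lg.subsample_series(s, s.sampling_interval_h)
        assert sub.times_h == s.times_h

    def test_non_multiple_rejected(self, cohort):
        series, _, _ = cohort
        with pytest.raises(ValueError, match="multiple"):
            lg.subsample_series(series[0], 6.0)

    def test_censoring_by_construction(self):
        """A branch present only at the 1-h sessions between two 4-h sessions
        is invisible at 4-h sampling: 2 events at 1 h, 0 at 4 h."""
        bare = _tree_with_branch()
        with_b = _tree_with_branch(extra_branch_len=5.0)
        trees = [bare, bare.copy(), with_b, with_b.copy(), bare.copy()]
        s = lg.ArborTimeSeries.from_trees(0, [0.0, 1.0, 2.0, 3.0, 4.0], trees)
        fine_events = sum(e.gains + e.losses for e in lg.observed_events(s))
        coarse = lg.subsample_series(s, 4.0)
        coarse_events = sum(e.gains + e.losses for e in lg.observed_events(coarse))
        assert fine_events == 2
        assert coarse_events == 0

    def test_rate_monotone_in_sampling_interval(self, cohort):
        """Mean estimated rate never increases as the sampling interval
        coarsens (4 → 12 → 24 h), over ≥100 simulated arbor-series."""
        series, _, _ = cohort
        assert len(series) * len(series[0].times_h) > 100
        means = []
        for interval in (4.0, 12.0, 24.0):
            rates = [
                lg.change_rate(lg.subsample_series(s, interval)) for s in series
            ]
            means.append(np.mean(rates))
        assert means[0] >= means[1] >= means[2]


class TestRetractionTraces:
    def _series_with_lengths(self, lengths):
        """One stem plus a single branch whose length follows ``lengths``."""
        trees = []
        for L in lengths:
            nodes = [SkeletonNode(1, np.array([5.0, 5.0, 0.0]), 0.5, None)]
            for k in range(2, 10):
                nodes.append(SkeletonNode(k, np.array([5.0, 5.0, float(k - 1)]), 0.5, k - 1))
            # second fixed branch so the tree always has a branch point
            for j, t in enumerate(np.arange(1.0, 6.0), start=10):
                nodes.append(SkeletonNode(j, np.array([5.0 + t, 5.0, 8.0]), 0.4, j - 1 if j > 10 else 5))
            if L > 0:
                base = len(nodes) + 1
                steps = np.arange(1.0, L + 0.5, 1.0)
                for j, t in enumerate(steps, start=base):
                    nodes.append(SkeletonNode(j, np.array([5.0, 5.0 + t, 8.0]), 0.4, j - 1 if j > base else 7))
            trees.append(SkeletonTree(nodes))
        times = [12.0 * k for k in range(len(lengths))]
        return lg.ArborTimeSeries.from_trees(0, times, trees)

    def test_total_retraction_arithmetic(self):
        s = self._series_with_lengths([20, 12, 6, 6, 6])
        ann = SwellingAnnotation(branch_id=self._branch_id(s, 0), time_h=0.0,
                                location="tip", width_ratio=3.5, is_swelling=True)
        trace = lg.track_retraction(s, ann)
        assert trace.total_retraction_um == pytest.approx(14.0, abs=0.5)
        assert trace.outcome == "retracted"

    def test_stable_branch_not_retracted(self):
        s = self._series_with_lengths([15, 15, 15])
        ann = SwellingAnnotation(self._branch_id(s, 0), 0.0, "tip", 3.2, True)
        trace = lg.track_retraction(s, ann)
        assert trace.outcome == "not_retracted"
        assert trace.total_retraction_um == 0.0

    def test_unknown_branch_rejected(self):
        s = self._series_with_lengths([15, 15])
        ann = SwellingAnnotation(99999, 0.0, "tip", 3.2, True)
        with pytest.raises(ValueError, match="not found"):
            lg.track_retraction(s, ann)

    @staticmethod
    def _branch_id(series, k):
        from arbortrack.morphometry import enumerate_terminal_branches

        branches = enumerate_terminal_branches(series.trees[k], 0.0)
        # the tracked branch grows along +y from (5, 5, 8)
        return max(branches, key=lambda b: b.tip[1]).branch_id


class TestSwellingOutcomes:
    def test_all_retracted(self):
        traces = [self._trace("retracted")] * 5
        assert lg.swelling_outcomes(traces) == (1.0, 0.0)

    def test_fraction_arithmetic(self):
        traces = [self._trace("retracted")] * 55 + [self._trace("not_retracted")] * 6
        frac, rest = lg.swelling_outcomes(traces)
        assert round(100 * frac) == 90

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lg.swelling_outcomes([])

    @staticmethod
    def _trace(outcome):
        return lg.RetractionTrace(0, 1, 0.0, [0.0], [5.0], 0.0,
                                  5.0 if outcome == "retracted" else 0.0, outcome)


class TestSimulatedSwellingOutcomes:
    def test_fraction_retracted_within_binomial_ci(self):
        """Detected bulb episodes end in retraction at the generator's
        p_bulb = 0.9, within the binomial 95% CI at n ≈ 500.

        Onsets in the final 36 h are excluded (no follow-up time); tracking
        uses a near-zero stop epsilon because skeleton-level lengths are
        exact, so any true shortening is meaningful.
        """
        from arbortrack.pipeline import detect_swelling_onsets

        cfg = SimulationConfig(seed=3, n_arbors=40, duration_h=240.0,
                               snapshot_interval_h=12.0)
        series_trees, times, _ = simulate_cohort(cfg)
        outcomes = []
        for aid, snaps in series_trees.items():
            s = lg.ArborTimeSeries.from_trees(aid, times, snaps)
            for ann in detect_swelling_onsets(s):
                if ann.time_h > cfg.duration_h - 36.0:
                    continue  # right-censored: too little follow-up
                trace = lg.track_retraction(s, ann, stop_epsilon_um=0.05)
                outcomes.append(trace.outcome)
        n = len(outcomes)
        assert n >= 300
        frac = sum(o == "retracted" for o in outcomes) / n
        halfwidth = 1.96 * np.sqrt(0.9 * 0.1 / n)
        assert abs(frac - 0.9) <= halfwidth


class TestCohortSummaries:
    def test_complexity_groups_stable_arbor(self):
        t2 = make_arbor_skeleton(1, 2)
        t3 = make_arbor_skeleton(1, 3)
        s = lg.ArborTimeSeries.from_trees(0, [0.0, 120.0, 240.0], [t2, t3, t2.copy()])
        table = lg.complexity_transitions([s])
        assert (table.loc[0, ["t0", "t120", "t240"]] == "1-3").all()

    def test_complexity_seven_plus(self):
        t7 = make_arbor_skeleton(2, 7)
        s = lg.ArborTimeSeries.from_trees(1, [0.0, 120.0, 240.0], [t7, t7.copy(), t7.copy()])
        table = lg.complexity_transitions([s])
        assert (table.loc[0, ["t0", "t120", "t240"]] == "7+").all()

    def test_missing_timepoint_names_arbor(self):
        t = make_arbor_skeleton(1, 2)
        s = lg.ArborTimeSeries.from_trees(7, [0.0, 120.0], [t, t.copy()])
        with pytest.raises(ValueError, match="arbor 7"):
            lg.complexity_transitions([s])

    def test_homeostatic_cohort_keeps_groups(self, cohort):
        """Most arbors stay in their starting complexity group over 240 h."""
        series, _, _ = cohort
        table = lg.complexity_transitions(series)
        stay = (table["t0"] == table["t240"]).mean()
        assert stay >= 0.7

    def test_minmax_r2_affine_relation(self):
        series = []
        for k, n in enumerate([2, 3, 4, 5, 6]):
            lo = make_arbor_skeleton(k, n)
            hi = make_arbor_skeleton(k, n + 1)
            series.append(lg.ArborTimeSeries.from_trees(k, [0.0, 12.0], [lo, hi]))
        assert lg.minmax_branch_correlation(series) == pytest.approx(1.0)

    def test_minmax_r2_simulated_cohort(self, cohort):
        series, _, _ = cohort
        assert lg.minmax_branch_correlation(series) > 0.5

    def test_minmax_zero_variance_nan(self):
        series = []
        for k in range(3):
            t = make_arbor_skeleton(k, 3)
            series.append(lg.ArborTimeSeries.from_trees(k, [0.0, 12.0], [t, t.copy()]))
        assert np.isnan(lg.minmax_branch_correlation(series))


class TestArborPersistence:
    def test_constant_counts(self):
        counts = pd.DataFrame({0: [2, 1], 60: [2, 1]})
        rep = lg.arbor_persistence(counts)
        assert rep.gained == 0 and rep.lost == 0 and not rep.any_gain

    def test_two_lost_none_gained(self):
        rng = np.random.default_rng(0)
        t0 = rng.multinomial(33, np.ones(18) / 18)
        t60 = t0.copy()
        t60[np.argmax(t0)] -= 1
        t60[np.argsort(t0)[-2]] -= 1
        counts = pd.DataFrame({0: t0, 60: t60})
        rep = lg.arbor_persistence(counts)
        assert rep.totals == [33, 31]
        assert rep.lost == 2 and rep.gained == 0

    def test_no_gain_process_never_flags(self):
        rng = np.random.default_rng(5)
        t = rng.integers(0, 4, size=12)
        frames = {0: t}
        cur = t.copy()
        for sess in (10, 20, 30):
            drop = rng.random(12) < 0.1
            cur = np.maximum(cur - drop.astype(int), 0)
            frames[sess] = cur.copy()
        rep = lg.arbor_persistence(pd.DataFrame(frames))
        assert rep.gained == 0 and not rep.any_gain
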