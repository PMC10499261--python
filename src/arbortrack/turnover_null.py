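"""Null model: arbor remodeling expected from taste-bud-cell turnover alone.

If terminal branches retracted only when a connected taste bud cell died,
the expected number of retractions per arbor in a window would be the mean
number of connected cells (1.6) times the fraction of cells lost in that
window (about half per 10 days) — i.e. fewer than one retraction per arbor
per 10 days. Observed remodeling rates are compared against this
expectation; ratios well above 1 indicate remodeling is not driven by cell
turnover.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json
import math

from arbortrack.synth.turnover import TurnoverParams

__all__ = ["NullComparison", "expected_losses_per_arbor", "compare_observed_to_null"]


@dataclass
class NullComparison:
    expected_per_arbor_window: float
    observed_per_arbor_window: float
    ratio: float  # inf when the null expectation is 0 but events were seen
    exceeds_null: bool
    window_days: float
    mean_connections_per_arbor: float
    loss_fraction: float

    def to_json(self) -> str:
        d = asdict(self)
        if math.isinf(d["ratio"]):
            d["ratio"] = "inf"
        return json.dumps(d, indent=2)


def expected_losses_per_arbor(
    tp: TurnoverParams, loss_fraction: float | None = None
) -> float:
    """Expected cell-death-triggered retractions per arbor per window.

    ``mean_connections_per_arbor × loss_fraction``; the loss fraction
    defaults to the lifespan distribution's CDF at the window (0.5 for the
    default 10-day median lifespan over a 10-day window), giving
    1.6 × 0.5 = 0.8 under the default parameters.
    """
    if loss_fraction is None:
        loss_fraction = tp.loss_fraction()
    if not 0.0 <= loss_fraction <= 1.0:
        raise ValueError("loss_fraction must lie in [0, 1]")
    return tp.mean_connections_per_arbor * loss_fraction


def compare_observed_to_null(
    observed_rate: float,
    tp: TurnoverParams,
    loss_fraction: float | None = None,
) -> NullComparison:
    """Compare an observed per-arbor-per-window event rate with the null.

    ``observed_rate`` is in events·arbor⁻¹·window⁻¹ for the same window as
    ``tp.window_days``. The ratio observed/expected is flagged as exceeding
    the null when above 1; a zero expectation with positive observations
    yields an infinite ratio.
    """
    if observed_rate < 0:
        raise ValueError("observed_rate must be ≥ 0")
    if loss_fraction is None:
        loss_fraction = tp.loss_fraction()
    expected = expected_losses_per_arbor(tp, loss_fraction)
    if expected == 0:
        ratio = math.inf if observed_rate > 0 else 0.0
    else:
        ratio = observed_rate / expected
    return NullComparison(
        expected_per_arbor_window=expected,
        observed_per_arbor_window=observed_rate,
        ratio=ratio,
        exceeds_null=ratio > 1.0,
        window_days=tp.window_days,
        mean_connections_per_arbor=tp.mean_connections_per_arbor,
        loss_fraction=loss_fraction,
    )
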