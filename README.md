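# arbortrack

Longitudinal morphometry and remodeling dynamics of taste-neuron arbors
from 3D in vivo image stacks.

Taste bud cells are one of the fastest renewing cell populations in the
body (median lifespan ≈ 10 days), yet each cell must connect to the axon of
a taste ganglion neuron to signal. The portion of the axon inside the taste
bud — the *arbor* — can be followed for days to months with two-photon
imaging of sparsely labeled neurons. `arbortrack` implements the desk half
of such a study for people analysing (or simulating) this kind of data:

* **synthetic ground truth** — tubular arbor geometries (radius
  ~0.3–0.5 μm), a continuous-time stochastic model of terminal-branch
  gain and retraction (with retraction bulbs), rendering into anisotropic
  image stacks (80 × 80 μm fields, 512 × 512 px, 0.5–1 μm z-steps, PSF +
  shot noise), and a taste-bud-cell turnover simulator;
* **segmentation** — multiscale Hessian (vesselness) filtering, hysteresis
  thresholding, connected components, manual component exclusion, and an
  FWHM mask refinement;
* **morphometry** — 3D thinning to a rooted centerline tree (SWC
  compatible), total cable length, convex hull volume/extents,
  terminal-branch enumeration, width profiles and the ≥3× end-swelling
  rule;
* **longitudinal analysis** — terminal-branch matching across imaging
  sessions, gain/loss event rates, time-to-first-change,
  sampling-interval censoring, retraction traces and bulb outcomes,
  complexity-group transitions, arbor-count persistence;
* **a turnover null model** — expected retractions per arbor per window =
  (mean synapsed cells per arbor) × (fraction of cells lost in the
  window); observed rates are compared against it;
* **normality-gated statistics** — Shapiro–Wilk gate, then t test / ANOVA
  + Tukey or Mann–Whitney / Kruskal–Wallis.

The remodeling model: each arbor carries independent Poisson clocks for
branch gains (rate λ_g) and retraction initiations (rate λ_r), in events
·arbor⁻¹·h⁻¹. New branches elongate at a fixed speed; retractions shorten
a branch linearly to its branch point over 12–108 h, preceded by a tip
swelling (≥3× branch width) with probability `p_bulb` = 0.9. A branch
counts as a *terminal branch* once ≥2 μm long. Under the turnover null,
E[retractions/arbor/10 d] = 1.6 × 0.5 = 0.8 — observed remodeling is
several-fold faster, which is the scientific point the pipeline measures.

## Worked example

Simulate and analyse a small cohort (8 arbors imaged every 12 h for 10
days, homeostatic remodeling):

```sh
arbortrack full --out-dir demo --seed 7
# or in Python:
# from arbortrack.pipeline import config_from_dict, run_pipeline
# run_pipeline(config_from_dict({'mode': 'full', 'seed': 7, 'out_dir': 'demo',
#     'simulation': {'n_arbors': 8, 'homeostatic': True}}))
```

The run directory contains one SWC skeleton per arbor per session
(`arbor0_t000.swc` … `arbor7_t240.swc`), the ground-truth event ledger
(`events.csv`), per-session morphometry (`morphometry.csv`), observed
gain/loss events, retraction traces, and `summary.json`:

```json
"rate":        {"median_events_per_h": 0.05, "mean_events_per_h": 0.046}
"time_to_first_change": {"all_changed_within_h": 48.0}
"bulb_outcomes": {"n_swellings": 48, "fraction_retracted": 0.854}
"null_comparison": {"expected_per_arbor_window": 0.8,
                    "observed_per_arbor_window": 5.125,
                    "ratio": 6.4, "exceeds_null": true}
```

Reading: at 12-h sampling each arbor gained or lost a terminal branch
about once every 20 h (median 0.05 events/h), every arbor changed within
48 h, 85% of detected end-bulbs were followed by retraction, and bulb-led
retractions ran 6.4× faster than cell turnover alone would predict
(0.8 per arbor per 10 days) — the observed remodeling cannot be driven by
taste-bud-cell death.

Other CLI subcommands (`simulate`, `render`, `segment`, `morphometry`,
`events`, `null`, `stats`) expose the individual stages; see
`arbortrack <cmd> --help`.

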