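# Methods

This note records the models, parameter choices and numerical decisions
behind `arbortrack`, in the spirit of a methods appendix: what is assumed,
what is a default and why, and what passing the test suite does and does
not establish.

## Remodeling model

Each arbor is modeled as a static core (the axon segment below and through
the papilla, plus internal branches) carrying dynamic terminal branches.
Two independent Poisson clocks run per arbor:

* **gains** at rate λ_g (events·arbor⁻¹·h⁻¹): a new branch sprouts from an
  interior point of the in-bud portion of the arbor and elongates at a
  constant `growth_speed` (default 2 μm/h) to a target length drawn from
  4–10 μm;
* **retraction initiations** at rate λ_r: a fully grown terminal branch
  shortens linearly to its branch point over a duration drawn uniformly
  from 12–108 h, matching the span observed for bulb-led retractions in
  vivo.

Defaults are λ_g = λ_r = 1/16 h⁻¹ (combined 1 event per 8 h, the rate seen
in vivo once sampling is fast enough to avoid censoring) over 240 h with
12-h snapshots.

**Countability.** A branch is a countable terminal branch once its length
reaches 2 μm; shorter stubs are below what segmentation and thinning can
resolve. The event ledger records `gain` at the upward crossing of this
floor and `retraction_end` at the downward crossing, which makes the
bookkeeping identity — change in countable-branch count between snapshots
equals gains minus completed retractions — hold *exactly*, and lets every
downstream estimate be checked against ground truth rather than against a
nominal rate (edge effects and eligibility rules make the realized event
rate a few percent below nominal in any finite window).

**Retraction bulbs.** With probability `p_bulb` = 0.9 a retraction is
preceded (by `bulb_lead_h` = 3 h) by a tip swelling rendered at 3.5× the
branch radius — strictly above the 3× detection rule so the detector's
behaviour, not the generator's margin, is what is tested. Transient bulbs
that resolve without retraction (growth cones) are generated alongside
accepted retractions at odds (1 − p_bulb) : p_bulb, so the fraction of
bulb episodes followed by retraction equals `p_bulb` exactly even though
eligibility rules suppress some retraction attempts; an independent
Poisson stream is available via `transient_bulb_rate` instead.

**Eligibility.** A retraction is suppressed when it would empty the arbor
of countable branches or expose a bare internal path as a spurious
"terminal branch" (a branch may only retract if its branch point retains
another stable branch or a continuing core). This is what keeps the
snapshot/ledger identity exact.

**Homeostatic mode.** Whether gain and retraction are physiologically
coupled is not established, so both modes exist. With
`homeostatic=True`, events that would push the (eventual or currently
visible) countable count beyond ±1 (`homeostatic_band`) of its starting
value are suppressed. Independent clocks make the branch count an
unbounded random walk; the bounded mode is the one under which
cohort-stability properties (most arbors keep their complexity group over
10 days; min/max branch count correlated across arbors, R² ≈ 0.9 in the
test cohort) hold, and that is how they are asserted.

## Synthetic arbors and rendering

Arbors enter at the volume floor (the basement-membrane side), climb a
~12 μm stem and branch into the requested number of terminal branches
(lengths 8–16 μm, divergence 40–80°) inside a 30 × 30 × 40 μm volume.
Branches steer to keep ≥4 μm clearance from the rest of the arbor and
attachments stay ≥6 μm from any tip and ≥3 μm apart — below these
separations, sub-micron tubes fuse irrecoverably once blurred by the PSF,
and real analyses would equally fail there (the in vivo protocol excluded
taste buds where labeled arbors intermingled). Total cable lengths come
out around 60–90 μm, matching the scale of real arbors.

Rendering sweeps spheres at the node radii (samples every half of the
smallest voxel pitch), blurs with an anisotropic Gaussian PSF (default
σ = 0.25, 0.25, 0.8 μm — two-photon-like lateral/axial asymmetry), adds a
background level, and applies shot (Poisson) or Gaussian noise, seeded.
Default geometry mirrors the acquisition format: 80 × 80 μm fields at
512 × 512 px and 0.5 μm z-steps to 70 μm depth; tests use a 30 μm field at
the same pixel pitch to keep volumes small.

What the generator does **not** emulate: background fluorescence from
epithelium (beyond a flat level), labeled keratinocytes (tests inject
bright blobs explicitly where needed), cross-session registration error
(snapshots are in a common frame; identity comes from labels), motion or
bleaching. Passing the recovery tests therefore shows the pipeline is
correct on resolvable, registered data — not that it would survive heavy
background or registration failure.

## Cell turnover and the null model

Lifespans default to a log-normal with median 10 days (σ_log = 0.5; the
family is a choice — only the median and the "half lost in 10 days"
statement are constrained, and at the median the loss fraction is 0.5 for
any continuous family). An exponential option (mean 10 d, loss fraction
1 − e⁻¹ ≈ 0.63 at 10 d) is provided. The simulator starts a cohort of
cells at age 0; each death immediately spawns a replacement unless
`blocked_entry` is set (emulating Hh-pathway inhibition, after which the
population shrinks monotonically).

The null model: E[retractions/arbor/window] = mean connections per arbor
(1.6) × loss fraction (0.5 per 10 d) = 0.8. `compare_observed_to_null`
reports observed/expected; with the printed in vivo counts (55 bulb-led
retractions in 12 arbors over 10 days) the ratio is ≈5.7.

## Segmentation

* Tubularity: Frangi-type vesselness from scale-normalized Gaussian
  Hessians at scales {0.5, 1, 2} μm, computed with per-axis sigmas in
  physical units (anisotropy handled without resampling), α = β = 0.5,
  structure cutoff c = half the maximal Frobenius norm per scale; maximum
  over scales, normalized to [0, 1]. An exactly constant stack returns a
  zero response.
* Threshold: hysteresis with high = Otsu on the nonzero response and
  low = 0.5 × high; 26-connected components, size floor 64 voxels, labels
  sorted by size.
* `refine_mask`: the detection mask is a PSF halo ~10× the true tube
  volume, which merges neighbouring branches and triples width estimates.
  Refinement keeps mask voxels reaching half the *local* intensity peak
  (1 μm window; local because peak brightness depends on tube orientation
  under an anisotropic PSF) above background, hysteresis-connected down to
  half that cut, with a mask-constrained binary closing to bridge gaps
  where a dim limb meets a bright junction.

## Skeletonization and measures

3D thinning deletes structures 1–2 voxels thick outright, which a
sub-micron tube at 0.5–1 μm z-steps routinely is; the mask's z axis is
therefore upsampled ×2 (linear) before thinning. The skeleton voxel graph
(26-connectivity) is reduced to a tree; cycles from self-touching tubes
are broken by keeping the maximum spanning tree under local thickness
(dropping the thinnest edge of each loop). The root is the endpoint
nearest the stack floor, ties broken by smallest (x, y). Radii come from
the distance transform of the original mask. Spur pruning is adaptive:
leaf paths shorter than max(1 μm, 2 × local tube diameter at their branch
point) are removed — fat junction blobs shed proportionally longer
thinning spurs than thin shafts.

Terminal branches are leaf paths back to the most peripheral branch point
(or root), counted when ≥2 μm. Width profiles sample twice the distance
transform (max-pooled over the immediate neighbourhood, compensating the
half-voxel underestimate of off-peak reads) every ≤0.5 μm of arc; the
baseline is the median over the proximal half, and a swelling is an
ending at ≥3× baseline (inclusive), located at the tip if the maximum
falls in the distal 20% of arc. Convex hulls are Qhull on foreground
voxel centers; degenerate inputs get volume 0 with bounding-box extents.

On 50 random rendered noiseless arbors, the full chain (render → filter →
segment → refine → skeletonize → enumerate) recovers the generator's
terminal-branch count exactly in 46/50 (92%); failures are arbors whose
branches pass close enough to fuse under the PSF.

## Branch matching and event rates

Terminal branches are matched across sessions by a Hungarian assignment
on tip distance (tolerance 5 μm), but an assigned pair is accepted only if
the two polylines also overlap to within 2 μm of path distance (minimum of
the two directed mean nearest-point distances). Tip distance alone fuses a
genuine loss with a nearby gain — in a ~15 μm arbor, concurrent loss+gain
pairs frequently fall within any usable tip tolerance — and misses
branches that elongated past the tolerance; both errors biased estimated
event rates ~25% low. A rescue pass on path overlap recognises
elongating/retracting branches whose tip moved far while the tube stayed
the same. Per-interval gains/losses agree with the ground-truth ledger in
≈98% of intervals, and the 4-h-sampling rate estimate recovers the
realized ledger rate within 5%.

A branch gained and fully lost inside one observation interval is
unobservable by construction; this censoring is why estimated rates fall
monotonically as the sampling interval coarsens (asserted over 100
simulated arbors at 4 → 12 → 24 h).

Retraction traces follow a swelling-bearing branch through the matching
chain until it disappears or shortens by less than `stop_epsilon_um`
between sessions. The default epsilon is 0.5 μm (half the skeleton
sampling step): the slowest retractions span ~100 h and can legitimately
shorten by under 1 μm per 12-h interval, so a larger epsilon would cut
them short. On exact (skeleton-level) lengths a near-zero epsilon is
appropriate and is what the simulation tests use. Traces with onsets too
close to the end of the series have no follow-up time and are excluded
(36 h) when outcome fractions are compared to the generative `p_bulb`.

## Gated statistics

All groups must pass Shapiro–Wilk at α = 0.05 for the parametric branch
(Student t for 2 groups; one-way ANOVA with Tukey HSD for more); otherwise
Mann–Whitney U or Kruskal–Wallis (no post hoc on the rank branch).
Constant-valued groups are rejected as degenerate. The full gate-then-test
procedure holds its type-I error at 5% ± 2% over 2,000 null replicates.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: cohorts of 26–200
arbors, 120–240 h, volumes of ≈96³ voxels, 50 rendered arbors for the
end-to-end chain, 2,000 replicates for the type-I check. All randomness
flows from a single root seed through named substreams (`SeedSequence`
spawning per arbor), so identical configurations are byte-identical on
rerun; every output file carries the config hash and seed.

## Known limitations

* The tubularity filter is a standard multiscale Hessian vesselness; the
  original acquisition pipeline's filter is unpublished, so agreement is
  established against synthetic phantoms, not against that code.
* Branch matching assumes a common coordinate frame; real longitudinal
  stacks need registration (out of scope) before it applies.
* The remodeling model treats gains and retractions as memoryless; real
  branches may have refractory or age-dependent behaviour that the
  per-arbor rate summaries cannot distinguish.
* Counts, not identities: when two branches exchange positions within one
  interval the matcher can swap them without affecting event counts.
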