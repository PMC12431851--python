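# Methods

This note records the models implemented by durokit, the conventions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations. It states no empirical result that
the test suite and demo pipeline do not themselves compute.

## Units and coordinate conventions

Coordinates are micrometres with the origin at the lower-left corner;
times are seconds; moduli are pascals; angles are degrees. Angular bins are
half-open (a, b] with 0° on the gradient axis. Stiffness grids are row-major
with pixel centres at (i + 0.5)·pitch. The AFM module works in SI (m, N, Pa)
internally; µm/nN appear only at I/O edges. Substrate patterns vary along +x
by convention; analyses of rotated data rotate the point sets (all track
metrics are rotation-invariant, which the suite verifies to 1e-9), not the
pattern.

## Hertz elastography

Force–indentation curves are modelled by spherical Hertz contact,
F = (4/3)·E/(1 − ν²)·√R·δ^(3/2), with R = 2.5 µm (5 µm sphere), ν = 0.4 for
tissue, and fitting restricted to F ≤ 16 nN — all overridable. The model is
linear in the reduced modulus E* = E/(1 − ν²) against δ^(3/2), so the fit is
the closed-form through-origin least-squares slope in that space; no
iterative optimizer, hence no initialization or convergence fragility.
Curves with fewer than 8 usable in-range samples return `valid=False` rather
than raising; invalid fits become missing (NaN) map cells.

Contact-point estimation on raw approach traces uses a baseline-threshold
crossing (baseline mean + 3σ over the first 30 % of samples, sustained for
4 samples) followed by a model-based refinement: because the Hertzian onset
is shallow (δ^(3/2)), the raw crossing is systematically late at finite
noise, so candidate contact points in a window around the crossing are
scored by the whole-trace residual of the piecewise model (flat baseline,
Hertz-shaped rise) and the minimizer is returned. Both thresholds are
configuration knobs recorded in provenance. Degenerate traces (no sustained
rise) are flagged invalid, not raised.

## Substrate models

The transition between soft and stiff regions is modelled as a **linear
ramp**: fabrication protocols constrain only the end moduli and the
transition distance, so the ramp shape is a declared modelling choice. The
step-stripe unit cell is soft plateau → ramp up → stiff plateau → ramp down
(defaults 200 µm soft, 40 µm ramps, 100 µm stiff, i.e. 4→40 kPa over 40 µm
= 900 Pa·µm⁻¹); the shallow gradient is one ramp over 1,000 µm (36 Pa·µm⁻¹);
the island kind blends a circular soft core into the stripe field across one
transition width. The island factory defaults to 1 kPa soft / 25 kPa stiff;
both the 1–10 kPa and 1/25 kPa parameterizations reported for such gels are
expressible. Stiffness is everywhere bounded by [E_soft, E_stiff]
(property-tested). Local gradients are analytic for the piecewise-linear
kinds and central finite differences (0.05 µm step, one-sided at borders)
for island and measured-field kinds.

Region labels: plateau points are `soft`/`stiff`; transition-band points are
excluded by default (`transition`) because assay protocols do not state how
boundary cells are binned — a midpoint-split rule is selectable. Field-kind
patterns have no plateaus and always split at the modulus midpoint.

## Average-slope statistic

The per-sample "average slope" summarizes an elastograph as the mean
magnitude of n (default 50) transect slopes. Published protocols state the
count but not the sampling scheme, so the scheme here is explicit and
recorded in every `SlopeSummary`:

* seeded random start points inside the map;
* each transect runs along the **local steepest-ascent direction** of the
  map gradient (falling back to the map's dominant axial gradient direction
  on plateaus), clipped to the map extent. Directions sampled uniformly
  instead would average |cos θ| ≈ 2/π of the true gradient magnitude and
  could not reproduce the nominal gradient of a calibration substrate, which
  the suite requires to 2 %;
* the profile (bilinear interpolation at half-pitch steps) is decomposed
  into maximal strictly monotone runs — ties and plateaus break runs, with
  differences below 1e-9 of the profile scale treated as ties so float
  round-off cannot fabricate micro-runs;
* one least-squares slope per run of ≥ 3 points, with one sample trimmed
  from each end of runs of ≥ 5 points (the extremum samples are biased on
  discretized ramps; trimming is a no-op on exactly collinear runs);
* NaN gaps split profiles; sampling stops at n slopes or a transect budget
  of 20·n; a uniform map yields zero slopes and average 0.

An optional centred moving-average pre-smoothing window (default 1 = off)
exists for noisy measured maps, where pixel noise otherwise fragments
plateaus into spurious shallow runs; it is off by default so calibration
substrates are reproduced exactly.

Peaks and valleys are local extrema of the (optionally Gaussian-smoothed)
field whose excursion from the map median exceeds a prominence threshold,
reported sorted by excursion. Smoothing attenuates shallow foci, so the
demo uses unsmoothed detection with a 2.5 kPa prominence.

## Migration metrics

Directionality (straightness) is net displacement / path length ∈ [0, 1].
The FMI divides the net-displacement component along the gradient axis by
the **accumulated path length** — the standard chemotaxis-tool convention —
so |FMI| ≤ directionality and FMI_∥² + FMI_⊥² ≤ directionality². The
per-track angle entering rose histograms is the end-to-end angle (one event
per track, matching count-per-trajectory rose diagrams); a per-step variant
can be built from the same primitives. Speeds use actual timestamps.
Coverage filtering keeps tracks observed for strictly more than 10 % of the
recording. Drift correction subtracts the cumulative per-interval median
displacement of all simultaneously observed tracks: a rigid common
translation is removed exactly, at the cost of also removing any true
common-mode median motion — the same trade-off made by standard
drift-correction plugins. The invasion fraction (tracks starting outside
and ending inside the invaded side of a boundary polyline) is a declared
operationalization; published "invasion index" readouts rarely state a
formula, so this is not claimed as a reproduction.

## Durotaxis assay

The index is the raw stiff/soft count ratio by default — faithful to the
"ratio of cells" convention even though default stripes have unequal areas —
with density normalization (counts divided by region area fractions) as an
explicit option; the suite shows density normalization restores an index of
1 for uniformly random cells on unequal stripes. Transition-band cells are
excluded and reported in `n_excluded`. A zero soft count is reported as a
`saturated` flag, never as infinity. Timecourses normalize to the earliest
observation (the 4-h plating baseline, which scores 1 by construction when
occupancy is equal). Multi-field observations are pooled by summed counts
rather than averaged per-field indices.

## Tumour metrics

The metastatic index is Σ(selected metastatic-site flux)/(primary flux) per
animal, with the site set parameterized (default liver + lung; liver + GI is
a supported alternative) because different primary-tumour models read out
different sites. Animals with missing or zero primary flux yield per-animal
error records without aborting the batch. The fibre "curvature ratio" is
chord/arc length (the straightness convention used by fibre-extraction
tools); orientation is the axial (mod-180°) end-to-end chord angle, robust
to waviness, with a per-segment tangent variant deliberately omitted from
the default path; the alignment score is the resultant length of doubled
axial angles (1 = one shared axis, ~0 = uniform).

## Synthetic generators

Each generator derives an independent random stream from the root seed (via
a per-generator stream id), so outputs are byte-identical across reruns and
adding a generator never perturbs existing fixtures. Defaults encode the
assay conditions the analyses target: 16 nN Hertzian curves with the probe
constants above; 5 µm map pitch; healthy fields as a 4 kPa baseline with
smooth ±1.4 kPa variation (15 µm correlation length), which lands their
average slopes in the tens of Pa·µm⁻¹; fibrotic fields as the baseline plus
Gaussian foci (σ = 10 µm, peaks up to 40 kPa, valleys down to 0.5 kPa,
minimum separation 3.5σ); walkers as 75 cells recorded for 24 h at 5-min
frames, 0.5 µm·min⁻¹ mean speed with 10 % CV and a 30-min heading
persistence time. The 2 % multiplicative force noise and 10 % speed CV are
modelling choices — published protocols provide no noise model.

The walker bias is an explicit stand-in for mechanosensing, not a molecular
clutch model: each step the heading relaxes toward the local gradient
direction by the saturating weight b·|∇E|/(1 + b·|∇E|) before rotational
diffusion is applied; boundaries reflect. Consequences used as checks: zero
bias (or a uniform substrate — the gradient, not the bias parameter, carries
the signal) gives an unbiased persistent walk; mean FMI increases
monotonically with bias strength; strong bias on the shallow gradient gives
mean FMI well above 0.3 with the rose mode at 0°.

What the generators do **not** emulate: instrument-specific AFM noise and
drift, adhesion/viscoelastic deviations from Hertzian contact, cell–cell
interactions, proliferation and apoptosis, 3-D motion, and stop-at-the-peak
mechanosensory switching. Passing tests therefore demonstrate correctness of
the quantification chain on data with known ground truth, not biological
fidelity of the walkers.

## Problem sizes

The statistical checks run at desk scale: 200 curves per modulus for Hertz
recovery, 20 seeded fields for focus recovery, 500 walkers per bias level
over a 24-h simulated recording for the FMI dose response, 10-animal flux
tables. The bundled demo (1,600 simulated indentations, 75 + 150 walkers)
completes in seconds on one CPU.

## Known limitations

* Tissue-derived values (average slopes of real fibrotic organs, cell-line
  index thresholds, animal metastasis counts) require the original raw data
  and are out of scope; the package reproduces design values of engineered
  substrates and generator ground truth.
* The average-slope statistic depends on the declared sampling scheme;
  numbers from other schemes (manual transects, fixed directions) will
  differ on heterogeneous maps even when calibration substrates agree.
* `region_of` on a linear-gradient pattern labels the whole interior as
  transition under the default rule (there are no plateaus); use the
  midpoint rule for occupancy counts on such gels.
* Fit refinement estimates a single contact point per trace and assumes a
  flat pre-contact baseline (no hydrodynamic slope).
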