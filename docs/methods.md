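# Methods

This note documents the models, estimators and numerical choices behind
`sirspread`, and what the simulation-based tests do and do not establish.

## Occupancy model

Occupancy (the probability a molecule is visited by the fusion protein at a
position) is

    occ(x) = clamp( bg + Σ_s peak_s · e^(−d(x,s)/λ) · a^(n_b(x,s)), 0, 1 )

* `d(x,s)` — distance from the **nearest edge** of recruitment interval
  *s*, zero inside it. Silencers and telomeric elements are intervals, not
  points, and observed methylation is flat-topped over them, so decay
  starts at the interval edge.
* `λ` (decay length, bp) — the spread length scale. Default **2500 bp**:
  spreading from silencer-sized intervals must plausibly cover the
  ~2.4–3.3 kb silenced domains between silencer pairs, which a decay length
  of a few hundred bp cannot. Recovery scenarios that probe the estimator
  set λ explicitly (e.g. 800 bp).
* `a` (boundary attenuation, default 0) — applied once per boundary element
  whose midpoint lies strictly between the site interval and *x*; the
  simplest composable boundary model. `a = 1` makes boundaries inert
  (verified by a property test); `a = 0` annihilates spread past the
  element.
* `bg` (default 0.005) — nonspecific background visits; with the default
  per-visit rate and emission model this lands the control-region
  methylation at ~1.4%, the right order for a no-recruitment control.
* Per-molecule methylation is Bernoulli(occ × accessibility × r) with
  per-visit methylation efficiency **r = 0.8**. The Bernoulli
  factorization is a modeling choice — the real enzyme's per-visit
  efficiency and the protein's dwell-time structure are unknown — and r
  trades off directly against peak occupancy; only their product is
  identified by methylation data.

### Accessibility

Positions within ±73 bp of a nucleosome dyad (a 147 bp core) get
`core_accessibility` (default 0.25), everything else
`linker_accessibility` (default 1.0). With dyads every 165 bp this yields
18 bp linkers and the ~165 bp accessibility periodicity observed on single
molecules. No remodeling, breathing or fuzziness is modeled: the field is
binary and static.

### Emission model

The base caller emits a probability, not a state. Methylated adenines draw
from Beta(α, 1), unmethylated from Beta(1, β) — right- and left-skewed
unimodal laws on [0,1] — with

    α = log(1 − TPR)/log(θ),   β = log(FPR)/log(1 − θ)

so that P(p > θ) equals the configured true-positive rate (default 0.9)
and false-positive rate (default 0.01) at the binarization threshold
θ = 0.8. Only the threshold-exceedance behavior is pinned by observation;
the shapes are the simplest laws satisfying it.

### Time scaling

For a sample taken t minutes after induction, the in-interval (recruitment)
part of each site term is scaled by t/(t + h_kind) and the decayed (spread)
part by t/(t + h_spread); background is not scaled, so t = 0 gives
background-only methylation. Defaults: recruitment halftimes 10 min,
spread halftime 120 min. This is a deterministic saturation curve — no
cell-cycle or replication dynamics.

### Read sampler

Reads are placed with uniform per-base coverage including contig edges
(start ~ U[−(L−1), contig_len−1], clipped), lengths Gamma-distributed
(mean 8 kb, CV 0.3, floor 1 kb). Each read is assigned a strand and
reports one call per adenine of that strand under its footprint; adenines
are independent Bernoulli(0.31) masks per strand. "Target coverage" is
total read depth, so per-strand per-position call coverage is roughly half
of it. All randomness derives from one top-level seed via
(seed, purpose-label) hashing; identical configs are byte-identical.

## Pipeline estimators

* **Binarization** is strict: methylated iff p > θ. p = θ exactly is
  unmethylated.
* **Aggregation** counts emitted calls per (position, strand); percent =
  100 · methylated/coverage. Strands are kept separate by default with a
  merge option (whether real aggregate plots merged strands is not
  determinable; inference here uses merged tracks). Coverage filtering is
  inclusive (≥ 10×).
* **Smoothing** is a tricube local-linear smoother on position with
  observation weights = coverage. Its flexibility is pinned by the
  effective number of parameters — the hat-matrix trace — calibrated to a
  target (default 100) by bisection on the span; the span can be pinned
  directly instead. For tracks over 5000 positions the trace is estimated
  on a ≤ 2000-point uniform subgrid of evaluation points (self-weights
  averaged and scaled by n). Where a local linear system is ill-posed (all
  kernel mass on one position, possible at very small spans) the smoother
  falls back to the local weighted mean; the farthest neighbor always has
  tricube weight 0. Replicate loops calibrate the span once per scenario
  and pin it thereafter — the grid is a property of the genome, not of a
  replicate.
* **Background** = mean + k·SD of the percent track over control
  positions (k = 2 by default). The +2 SD margin makes the level an upper
  envelope for boundary walking; the spread-length fit instead holds the
  *mean* background (k = 0) fixed, since the exponential's asymptote is
  the central background, not its envelope.
* **Boundary** = first position, walking from the anchor edge, where the
  smoothed track stays ≤ background over ≥ 300 bp (~2 nucleosomes). A
  run-length criterion is robust to smoothing wiggles where a derivative
  criterion is not. `at_anchor` means the very first position beyond the
  edge already starts a qualifying run; `unbounded` means the window ended
  first (boundary reported at the window edge). Raising the background
  level can only shorten the extent (tested).
* **Response classification** compares two conditions at one anchor:
  shift = extent_b − extent_a, ratio = mean smoothed signal over the
  shared above-background domain (anchor interval + common spread region).
  Defaults: `extended` iff shift > 500 bp and ratio > 1.25;
  `increased_only` iff |shift| ≤ 500 and ratio > 1.25; else `unchanged`.
  The categories are descriptive in origin; these thresholds were fixed
  against the simulator's behavior (smoothing jitter moves called
  boundaries by tens of bp, never hundreds) and are plain configuration.
  A mirrored retraction (shift < −500, ratio < 1/1.25) is reported as
  `extended` with a `reversed` flag, making the classifier symmetric under
  swapping conditions.
* **Differential methylation** uses Fisher's exact test per shared
  position on (methylated, unmethylated) counts — exact because coverage
  sits near the 10× floor — with Benjamini–Hochberg correction across
  tested positions.
* **Periodicity**: residual = percent − smoothed trend, nearest-neighbor
  interpolated to a 1 bp grid (adenine spacing is irregular), biased-
  normalized autocorrelation up to 400 bp. The repeat length is the first
  local maximum in [50, 400] bp that exceeds the 95th percentile of the
  max-autocorrelation null obtained by permuting residuals across
  positions (100 permutations); sub-band wiggles are not peaks. Note the
  trend smoother (enp 100 over a ~25 kb window, ~250 bp resolution)
  partially tracks a 165 bp oscillation; the residual retains enough of it
  that recovery is exact at 100× coverage.
* **Onset** = earliest sampled time from which raw percent exceeds
  background for ≥ 2 consecutive sampled times; never-sustained positions
  are censored. Raw (unsmoothed) tracks are the default so that onset is
  not borrowed from neighbors.
* **Spread fit**: least squares of smoothed percent beyond the anchor edge
  against bg + A·e^(−d/λ) with bg fixed, A ∈ [0, 200], λ ∈ [10, 10⁵] bp
  (scipy `curve_fit`). Windows whose fitted amplitude is below 1 percent
  point are reported censored.
* **ChIP normalization** divides depth by the median over non-excluded
  positions (exclusion intervals supplied as half-open intervals);
  idempotent and scale-equivariant by construction.

## Study conditions in the evaluation scenarios

Each scenario adds a featureless 6 kb control contig for background
estimation. Coverages follow the readout being tested: 50× for boundary /
spread-length / contrast work, 100× for periodicity, 30× for time courses.
Geometry: boundary element 5 kb from the anchor (boundary recovery);
doubled peak 0.45 → 0.9 against a boundary 3 kb out (overexpression);
spread-deficient = λ collapsed to 1 bp with peaks intact (contrast);
silencer/promoter/silencer spaced 8 kb apart with interior intervals
≥ 2.5 kb from any recruitment edge (time course) — the wide spacing keeps
interior positions dominated by a single site's spread term, which is what
the onset contrast is about. These problem sizes (12–26 kb contigs,
20–100 replicates) are desk-scale choices that keep each evaluation in the
tens of seconds while leaving comfortable statistical margins.

## What the simulator does not capture

Passing tests show the estimators recover the truth of *this* generative
model. Real data differ in ways the model deliberately omits: mappability
and alignment artifacts, read-quality and modification-calling biases that
vary along the genome and between molecules (emission noise here is i.i.d.
given the state), nucleosome positioning heterogeneity between cells (the
accessibility field is shared by all molecules), replication/cell-cycle
structure in time courses, strand-specific enzymology, and overlapping
loci with interacting boundaries. Results on real data therefore warrant
the usual caution even where every test here is green.

## Known limitations

* Boundary semantics are an operationalization — "sustained return to
  background" — since no numeric definition exists to import; calls
  within ~one smoothing bandwidth (±~100 bp at the defaults) of a true
  sharp boundary should be considered equivalent.
* The spread fit holds the background fixed; a misestimated background
  biases λ̂ (mitigated by using the control-region mean).
* `require_full_span` judges a read's footprint by its outermost calls on
  the contig, which is conservative for reads ending exactly at the window
  edge.
* The per-read text dialect is pinned to one column set; modBAM (MM/ML)
  input is out of scope in this version.
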