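# Methods

This note documents the models and procedures implemented in `mrmflow`, the
parameters that matter, the choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Scope and assumptions

The pipeline targets single-batch MRM/SRM studies on a triple quadrupole:
one chromatogram per transition per injection, pooled QC samples injected
periodically, and a user-curated compound library carrying the molecular
formula, transition, and reference retention time of each analyte. Core
assumptions:

- **Channels are configured, not measured.** Transition m/z values are
  matched across runs and against the library by rounding to one decimal and
  comparing exactly; no tolerance window. A QqQ panel is a fixed method, so
  two runs of the same study cannot disagree on a channel's m/z.
- **Peak height is the quantifier.** Heights are read from the unsmoothed
  trace at the apex scan; trapezoidal areas are computed and stored but
  unused downstream. On QqQ data, apex height is more robust than area to
  integration-boundary error on partially resolved isomers.
- **Negative intensities are floored to zero on read.** Detector baseline
  artifacts would otherwise corrupt both the centroid (a weighted mean) and
  segment correlations.
- Single batch only: no multi-batch harmonization, no detector-saturation or
  carryover modeling, no spectral matching.

## Reference selection: chromatographic centroid

For a trace with intensities `I(n)` at times `t(n)`, the centroid ("gravity")
is `Σ I(n)·t(n) / Σ I(n)`; an all-zero trace has no centroid and is excluded.
A run's aggregate gravity is the **unweighted mean over transitions with
signal** — the per-file aggregation is an open design point (only
per-transition centroids are well defined a priori); the unweighted mean is
robust to channels that are empty in some runs, and a per-transition
selection mode is available behind a flag. The reference is the QC whose
aggregate gravity is nearest the midpoint `(min+max)/2` of the QC gravities;
ties break to the lowest injection order for reproducibility. Without any QC
carrying signal, selection is a hard error instructing a manual choice.

## COW alignment

Correlation optimized warping with three parameters:

| parameter | default | meaning |
|---|---|---|
| `segment_size` | 0.5 min | reference segment length; set near the peak width |
| `slack` | 1 scan | allowed per-segment length change in the query |
| `border_limit` | constant | out-of-range lookups take the edge intensity |

The reference is cut into fixed segments; dynamic programming places query
boundaries so each warped segment's length differs from its nominal length
by at most `slack` scans (deviations accumulate along the run, which is what
lets a 1-scan slack absorb a multi-scan global shift) and keeps at least two
scans, maximizing the summed per-segment Pearson correlation of the linearly
interpolated query against the reference segment. Numerical choices:

- **Zero-variance segments contribute correlation 0**, not NaN, keeping the
  objective finite over blank regions.
- **DP ties resolve toward the unwarped boundary positions**, so
  self-alignment of a trace with per-segment variance returns the identity
  path exactly. On traces with long exactly-flat stretches the warp in those
  stretches is underdetermined; the tie-break makes it deterministic.
- **Resampling is linear interpolation**; no smoothing is applied during
  warping.
- One warp per run is estimated on the run's pseudo-TIC (the summed
  intensity over all its transitions) and applied to every channel.
  Per-transition warps would let empty channels warp arbitrarily; they
  remain available as a mode. A run with no signal anywhere falls back to
  the identity warp and is logged.

DP optimality is verified against brute-force enumeration of all feasible
boundary assignments on short traces (exact agreement), and apex recovery on
shifted Gaussians is verified to within one scan.

## Peak detection and propagation

The representative trace (the aligned reference QC, per transition) is
smoothed with a triangular ("linear weighted") moving average, weights
`level+1−|j|` over ±`level` scans (default 2), renormalized at the trace
edges. Local maxima become peaks; edges are the nearest flanking local
minima, with plateau points counting as minima so flat baselines yield tight
edges. Filters: minimum width 5 scans (edge to edge), minimum apex rise 100
counts above the higher edge.

Propagation assigns, per representative peak and sample, the apex as the
argmax within the representative's edges; the alternative `local_minimum`
edge mode descends from the assigned apex to the flanking minima of the
sample's own smoothed trace. Every (peak, sample) cell is reported: apex
intensities below the minimum height are kept and flagged `gap_filled`
(absolute-apex criterion for the flag, apex-above-baseline for
representative detection — keeping the gap-fill rule simple and auditable).
This guarantees a rectangular matrix and effects gap filling from the QC
peak's position and width.

## Identification

Score `exp(−½((RT_act − RT_lib)/σ)²)` with σ the user RT tolerance
(default 0.2 min; the equation's width parameter and the user tolerance are
the same quantity — only one tolerance is ever defined). The score is 1 at
zero deviation, strictly positive, and falls below the 0.7 acceptance
threshold just beyond one tolerance of deviation (`exp(−0.5) ≈ 0.607`).
Candidates must share the feature's transition exactly. Assignment is
globally greedy by descending score, ties by smaller |ΔRT| then library
order; each library entry annotates at most one feature and vice versa.
Scores are computed on post-alignment retention times, since library RTs
describe the chromatography the reference represents. Rejected candidates
are retained in the result for curation.

## Isotope estimation and correction

The nominal-mass envelope of a formula is the product of per-element isotope
polynomials raised to the atom counts, computed by truncated convolution
(exponentiation by squaring), binned at integer mass offsets 0..6 and
normalized to the monoisotopic term. **Cross-terms are retained**: the
~0.01-percentage-point M+2 difference between two phospholipids two
hydrogens apart is a ¹³C×²H cross-term effect that an independent-element
approximation would miss. Abundances follow current IUPAC representative
values (C 0.9893/0.0107, H 0.999885/0.000115, N 0.99636/0.00364,
O 0.99757/0.00038/0.00205, P 1.0, S 0.9499/0.0075/0.0425/–/0.0001); the
table is replaceable.

Candidate interference pairs require: offset k ∈ 1..6 on the rounded
precursor difference (QqQ panels are built on unit ladders), identical
product ion and polarity, apex co-elution within 1 s, and an annotated
parent (the formula is what makes a theoretical ratio computable).
Correction, per sample: expected = parent height × r_k; a child taller than
its parent is `not_isotope` (left untouched); otherwise the expected share
is subtracted and the explained fraction recorded. A corrected abundance at
or below `purity_threshold` (default 0.05, configurable — chosen to absorb
integration noise while leaving a substantial co-eluting isomer clearly
retained) of the observed child makes the cell a pure isotopic peak. The
feature-level verdict is a **majority vote across samples** (whether
dismissal is per-sample or per-feature is an open point; per-feature keeps
the matrix semantics uniform, and the per-sample mode remains available),
and pure-isotope features are flagged out of downstream statistics.

## Drift normalization

Per feature, LOESS (degree 1, tricube weights, span 0.5 as a fraction of the
QC points — the span is not prescribed anywhere, 0.5 is the common default
and configurable) is fitted to QC abundance vs injection order, and a cubic
interpolating spline through the smoothed QC points defines `drift(order)`.
Corrected value = raw × `reference_level` / drift, with `reference_level`
the median of the smoothed QC values (drift-robust; the post-correction
scale is otherwise arbitrary). Fewer than 4 usable QCs degrade gracefully:
the smoother becomes the identity on the QC points and linear interpolation
replaces the spline. Fewer than 2 leaves the feature uncorrected (logged).
Evaluation outside the first/last QC is clamped to the boundary value —
cubic extrapolation is unstable. The method is a hard error without QC
injections; internal-standard ratio normalization
(`value / IS × median(IS)`, samples with non-positive IS left untouched and
logged) is the QC-free alternative. Correction operates on isotope-corrected
heights: detect → identify → isotope-resolve → normalize.

## PCA and reporting

Sample scores from a full-SVD PCA of the column-centered (by default
unit-variance scaled; preprocessing is not prescribed, unit variance keeps
high-abundance lipids from dominating) matrix. Features flagged pure-isotope
anywhere, or gap-filled in more than half the samples (gap-filled zeros
otherwise dominate the variance; configurable), are excluded. Component
signs are fixed by making the largest-magnitude loading positive, so scores
are reproducible and invariant to feature order. The run report counts
annotated features, unknowns, pure-isotope dismissals, and gap-filled cells.

## Synthetic studies

The generator emulates the batch structure the pipeline is built for:
pooled QCs (per-class mean composition) at every `qc_every`-th injection,
Gaussian peaks (default 0.5 min FWHM, matching the segment-size guidance) on
a uniform 0.05 min grid (≈5 scans across a minimal peak) over 0–45 min by
default, a smooth monotone RT warp per run (global shift, linear stretch, or
a two-knot monotone spline — spanning what small-slack COW can and cannot
fully undo), a multiplicative linear intensity decay over the injection
sequence, i.i.d. Gaussian noise, isomer pairs sharing a transition, and M+k
isotopic companions emitted at the theoretical ratio. All true heights, apex
positions, and warps are returned as truth tables; a fixed seed gives
byte-identical files.

What it does **not** emulate: tailing/fronting peak shapes, width changes
under warping (peaks are repositioned, not reshaped), heteroscedastic or
correlated noise, detector saturation, carryover, and spectral interference
other than nominal-mass isotopologues. Passing tests therefore demonstrate
the algorithms' correctness against their own model, not instrument-grade
robustness.

Test and acceptance runs use scaled-down studies (8–24 biological runs,
2–6 compounds, 10–30 min grids) chosen to exercise every code path —
reference selection among several QCs, drift spanning ±0.3 min, 30 % decay,
isomer and isotope interference — while keeping the default suite fast.

## Known limitations

- Reverse-phase-style defaults only; no parameter presets for HILIC/PFPP.
- The peak model has no deconvolution of co-eluting shoulders and no
  baseline subtraction; edges come from local minima of the smoothed trace.
- Isotope correction requires an annotated (formula-bearing) parent;
  unannotated abundant species cannot seed corrections.
- The identification score is used directly as a confidence value; it is not
  calibrated to a posterior probability.
- Drift models are per-feature and assume the QCs bracket the biological
  samples in injection order; leading/trailing samples use clamped values.
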