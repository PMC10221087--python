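# Methods

This note records the models implemented in `codonaffinity`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## Binding occupancy from distance series

The binding statistic is the pooled fraction of trajectory frames in which
the closest atom of the nucleotide is within r_c of the closest atom of the
nearest amino-acid copy. Conventions:

- **Threshold comparison is strict** (`d < r_c`, default r_c = 5 Å). The
  boundary has measure zero for continuous distances; the choice is fixed
  for bit-reproducibility.
- **Pooling**: runs contribute frames to the point estimate (a run with
  more frames weighs more); the pooled fraction equals the frame-weighted
  mean of per-run fractions.
- **Uncertainty**: parallel runs are treated as independent experiments.
  Runs are resampled with replacement (default 100,000 draws), the pooled
  fraction recomputed per pseudo-replicate, and the 2.5th–97.5th
  percentiles reported. A single run is rejected — it carries no
  between-run variance. On planted two-state data the interval covers the
  true occupancy in ≈93% of replicate datasets (the percentile bootstrap
  over 100 runs is slightly conservative near nominal level).
- **Geometry**: minimum-image distances in an orthorhombic (cubic) box;
  triclinic boxes are out of scope. Atom subsets (e.g. restricting the
  nucleotide to its ring nitrogens) are configuration supplied by the
  caller, not hard-coded chemistry, because ring-atom labelling varies
  between preparation pipelines.

## Monte Carlo volume fractions and adjustment

Under a uniform geometric null the expected time within r_c grows with
molecular size, so raw occupancies are not comparable across systems. The
volume fraction of a molecule — the fraction of the box within r_c of any
selected atom — is estimated with uniform random points (default 100,000)
evaluated at randomly chosen frames (default 150), reporting the mean and
the 95% range over frames.

- **One point cloud is reused across frames.** The across-frame range then
  measures conformational flexibility alone; a rigid molecule gets an
  exactly zero-width range. The cost is that Monte Carlo error does not
  average down with frames for near-rigid molecules; the default 100,000
  points give a relative standard error below 2% for fractions above
  ~0.005.
- **Divisor mode**: the adjusted measure defaults to
  B / (V_aa · V_nt) (`product`); `sum` and `aa_only` are available.
  Whether one combined volume or both volumes should be divided out is a
  genuinely open design point; `product` is the default because it
  linearizes the geometric null in synthetic tests — with a point-like
  nucleotide, the null expectation of B is ≈ n_copies · V_aa, so dividing
  by both volume fractions makes differently sized amino acids agree (the
  package's null-trajectory test shows agreement within a few percent,
  asserted at 20%).

## Genetic-code model

The standard RNA code table (61 sense codons, stop codons excluded,
selenocysteine/pyrrolysine not modelled) ships built-in; tables are
overridable from tabular text for reassignment experiments. Codons are
grouped into *codon families* by their first two bases; expansion yields
one allocation per family — 23 allocations: 20 amino acids plus one extra
each for hexacodonic Leu, Arg and Ser. Anticodons are written 5'→3' as
reverse complements by default, so anticodon base 1 pairs with codon
base 3; under this convention the anticodon-1 cognate set of a family is
degenerate (the complements of the family's third bases) and allocations
carry a base *set*, scored by the best rank in the set. An `aligned`
convention (anticodon base i = complement of codon base i) is available
because published "anticodon base 1" analyses are ambiguous about the
indexing; neither convention is asserted as the original one. Under both
conventions the anticodon middle base is the Watson–Crick complement of
the codon middle base, which is what the headline statistics use.

## Preference statistics

- Within-row ranks use average ranks for exact ties, and a row has a
  "first choice" only when a strict maximum exists; ties propagate as
  average ranks into rank sums.
- First-choice enrichment and depletion use exact binomial tails with an
  explicit (k, n, p, tail) parameterization rather than hard-coded
  constants: the three standard tests are (k, 20, 1/4, upper) for
  cognate-first counts, (k, 23, 1/4, lower) for cognate-last counts over
  the expanded allocations, and (k, 20, 3/4, upper) for "best with at
  least one cognate base at codon/anticodon positions 1–2".
- The randomization null assigns each allocation an independent uniform
  rank (200,000 draws by default; null mean 2.5 per allocation for four
  columns). The summary statistic is the fraction of null sums *strictly
  greater* than the observed sum (lower sum = stronger preference); the
  ≥-count is also exposed. For dinucleotide schemes, a constraint can
  force an amino acid's several cognate dinucleotides to receive distinct
  ranks within a draw; it is ignored with a warning for mononucleotide
  schemes, where same-amino-acid allocations represent different codon
  families rather than competing columns.
- Directionality contrasts (XY vs YX dinucleotides) bootstrap the two
  systems' runs independently and report the adjusted-binding difference
  with a percentile 95% interval and an excludes-zero flag.

## Hydrophobicity

Composite hydrophobicity is the mean within-scale rank (1 = most
hydrophobic, ties averaged, orientation flags resolved before ranking),
making the composite invariant to monotone transformations of any scale.
Four public scales ship as fixtures (Kyte–Doolittle, Hopp–Woods —
a hydrophilicity scale, stored with a reversed orientation flag —
Eisenberg consensus, Janin); larger compilations can be supplied as
tabular text, since the mechanism rather than any particular table is
what the module provides. Regressions are ordinary least squares with an
intercept; rank-deficient designs are rejected with the condition number
reported.

## NMR titration fitting

The observed shift change is the exact one-site fast-exchange isotherm
(population-weighted average of free and bound shifts; the bound fraction
comes from the quadratic for the complex concentration). Fitting follows
the ensemble protocol: 500 bounded least-squares fits, each dropping one
uniformly chosen titration point, d_max started at 0 and K_D started
uniformly in a configurable interval (default 0.5–1.5), both parameters
bounded below by zero and unbounded above. The reported K_D is the
ensemble mean with the central 95% ensemble range; non-convergent fits
are excluded and counted. Fits are reported per proton probe and never
averaged across probes, because probes on opposite sides of a nucleobase
can disagree about the same interaction.

Two caveats are deliberate:

- **Units.** The start interval is in concentration units (mM by default)
  to be dimensionally consistent with the binding equation; the interval
  is configurable.
- **The ensemble range is not a confidence interval.** Perturbing one
  point per fit understates full sampling variability: in simulations at
  noise 0.005 ppm the 95% ensemble range covers the true K_D in only
  ~40% of replicate datasets. The ensemble mean itself is nearly unbiased
  (|relative bias| < 5% across K_D 0.5–50 mM at noise 0.002 ppm on the
  0.1–100 mM titration design). Treat the range as a stability
  diagnostic, not coverage.

## Synthetic-data generators

`gen_distance_series` emits closest-approach distances directly from a
two-state Markov chain (alternating geometric dwells, initialized from
the stationary law), so the planted occupancy is exact ground truth
rather than an emergent property. Bound-state distances come from a
truncated-Gaussian mixture at 1.9, 2.5 and 4.0 Å (sd 0.15/0.25/0.35,
weights 0.3/0.4/0.3, truncated to (0, 5) Å); free-state distances are
Gaussian(5.5, 1.0) truncated below at 5 Å. Mode locations mirror the
binding-mode and free-in-solution distances seen in solvated
amino-acid–nucleotide simulations; the shapes, weights and dwell times
are this package's choices, as only the mode locations are constrained by
observation. Defaults are 100 runs of 10,000 frames with mean bound dwell
20 frames. Runs use independently spawned child seeds; all generators are
pure functions of parameters and seed.

`gen_box_trajectory` separates geometric correctness from statistical
correctness: rigid random-walk molecules in a periodic cube (Metropolis
square-well attraction optional; zero attraction gives exactly the
uniform-placement null). It exercises the minimum-image and Monte Carlo
volume code on real coordinates. Neither generator models force fields,
water, ions or kinetics — passing tests demonstrate that the estimators
and nulls are correct, not that any particular molecular system behaves
this way.

`gen_titration` adds Gaussian noise to the exact isotherm on the
measurement design (receptor 0.1 mM, ligand 0.1–100 mM, log-spaced by
default).

## Pipeline and problem sizes

The demo pipeline plants the strongest *adjusted* binding on the cognate
anticodon-middle base for ten (configurable) non-hexacodonic amino acids;
occupancies are the planted adjusted ladder (4 : 3 : 2 : 1.2) multiplied
by synthetic per-molecule volume divisors and scaled to a 0.5 maximum, so
the volume-adjustment stage must divide the sizes back out before the
planted ranks reappear. Ten planted cognates among 23 allocations give an
exact enrichment p of 0.0408.

Default pipeline sizes (20 runs × 2,000 frames per system, mean bound
dwell 5 frames) were set from the stationary-chain standard error so that
the occupancy estimator's SE (~0.006) is several times smaller than the
smallest planted occupancy gap (~0.04), making rank recovery reliable
rather than marginal. The test suite and the acceptance script use these
sizes and 100-replicate/200-replicate simulations where distributional
properties (bootstrap coverage, null calibration) are asserted.

Reports embed the resolved configuration and package version; identical
configurations produce byte-identical JSON.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- No per-binding-mode kinetics: everything below the threshold is pooled.
- The ensemble K_D range understates uncertainty (see above).
- No multiple-testing correction across charge states or position
  schemes; tests are reported per scheme.
- The bundled hydrophobicity scales are a small public subset; composite
  ranks from larger compilations will differ in detail.
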