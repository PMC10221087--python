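# codonaffinity

Tools for quantifying **weak stereochemical binding preferences between
amino acids and RNA nucleotides**, and for testing whether those
preferences line up with the genetic code. The question behind the
package is an old one in origin-of-life research: if amino acids bind
their *cognate* bases (the nucleotides occupying particular codon or
anticodon positions in the modern code) even slightly better than chance,
random RNA sequences could have templated non-random peptides — a route
to the emergence of genetic information.

The package is a library first (with an `examples/` directory of short
narrative scripts) plus a thin `codonaffinity` CLI for running the stages
from a shell. It is aimed at structural bioinformaticians who have
trajectory-derived distance series or NMR titration tables and want the
statistics, and at anyone who wants to probe the statistical machinery on
synthetic data with known ground truth.

## What it computes

**Binding occupancy from trajectories.** Binding of a nucleotide to a pool
of amino-acid copies in a periodic box is approximated by the fraction of
frames in which the closest-approach distance (closest atom to closest
atom, minimum image) is below a threshold r_c = 5 Å:

    B = (1/N) Σ_t 1[ d_min(t) < r_c ]

Parallel runs are the unit of replication: runs are resampled with
replacement (default 100,000 times) for a percentile 95% interval.

**Monte Carlo volume adjustment.** Large molecules are near each other for
purely geometric reasons. The fraction V of the box within r_c of a
molecule is estimated by uniform random points (default 100,000, repeated
over 150 frames to absorb flexibility), and the adjusted binding measure
is B / (V_aa · V_nt) (modes `sum` and `aa_only` are switchable).

**Preference statistics against the code.** Adjusted values are ranked
within each amino acid (1 = strongest). Cognate first-choice counts are
tested with exact binomial tails; the sum of cognate ranks over the 23
codon-family allocations (20 amino acids + 1 extra each for hexacodonic
Leu/Arg/Ser) is compared with 200,000 randomized rank assignments, with a
no-identical-ranks constraint available for multiple cognate
dinucleotides, plus XY-vs-YX dinucleotide directionality contrasts.

**Hydrophobicity regression.** Composite hydrophobicity = mean
within-scale rank across scales (bundled: Kyte–Doolittle, Hopp–Woods,
Eisenberg, Janin; user tables accepted), regressed against adjusted
binding by OLS together with the volume fractions.

**NMR K_D inference.** Chemical-shift-perturbation titrations are fitted
to the exact one-site fast-exchange isotherm

    d_obs = d_max [ (K_D + L + P) − √((K_D + L + P)² − 4 P L) ] / (2 P)

by a 500-fit leave-one-out ensemble (one point dropped per fit, K_D
started uniformly in 0.5–1.5 mM, both parameters bounded below at 0);
partners are compared by sampling one K_D per ensemble and ranking 10,000
times (lower K_D = stronger binding).

**Synthetic data.** Every input can be generated with planted truth:
two-state (bound/free) Markov-chain distance series with controllable
occupancy and the observed binding-mode geometry (~1.9/2.5/4 Å modes,
free peak near 5.5 Å), random-walk rigid molecules in a periodic cube for
the geometry code, and noisy titration curves.

## Worked example

```sh
python examples/genetic_code_statistics.py
```

```
anticodon middle-base usage over the 20 amino acids: {'A': 5, 'C': 5, 'G': 4, 'U': 7}
hexacodonic amino acids: ['L', 'R', 'S']
allocations after hexacodonic expansion: 23
enrichment p (10 first choices): 0.0139
depletion p (2 last choices): 0.0492
p (19/20 best with >=1 cognate): 0.0243
```

U is the most common anticodonic middle base (7 of 20 amino acids); with
10 of the 23 allocations ranking their cognate anticodon-middle base
first, the uniform-preference null is rejected at p = 0.0139, with a
matching depletion of cognate last choices (p = 0.0492), and 19 of 20
amino acids binding best to at least one cognate base gives p = 0.0243.

The full synthetic chain:

```sh
python examples/full_pipeline.py        # or: codonaffinity run-all --seed 1
```

```
codonaffinity 0.1.0 pipeline report
allocations: 23  cognate first choices: 10 (p=0.04078)  cognate last: 6 (p=0.6537)
best binder cognate at >=1 of codon/anticodon positions 1-2: 17 of 20 (p=0.2252)
rank-sum: observed 51.0, null mean 57.5, stronger than 86.6% of 200000 randomized assignments
```

Ten amino acids were planted with their cognate anticodon-middle base as
strongest binder; the pipeline recovers all ten and flags the enrichment
(p = 0.0408 ≤ 0.05). The other examples cover trajectory reduction,
volume adjustment, hydrophobicity regression and K_D fitting.

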