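# Methods

## Model overview

The predictor labels each residue of a protein chain with one of eight
shape-string states — named regions of the Ramachandran plane — from two
families of categorical features: six binned chemical-shift letters and
eight binned shape-profile letters. A linear-chain conditional random
field (CRF) couples the per-residue evidence with learned state-transition
weights, which is what lets segmented structure (helices, strands) emerge
from noisy per-residue signals.

The assumptions, in order of importance:

* chemical shifts are informative about the local backbone state once
  rescaled per (amino acid, atom) combination;
* shape states are locally persistent (segments), so first-order label
  transitions carry real signal;
* shape evidence from similar sequences transfers positionally (the
  profile), and short sequence motifs can carry conserved structure even
  without overall similarity (hallmark patterns).

## Preprocessing

Each (amino acid, atom) combination gets a linear rescaling by the
training-corpus minimum and maximum — 120 (x_min, x_max) pairs. Query
values outside the training range are **clipped** to the nearer extreme
before rescaling, which doubles as outlier control. Vacant cells pass
through untouched and become the feature letter `N`.

The rescaled [0, 1] value is discretized into ten equal bins, letters
`L A D C Q M V W P G` in ascending-bin order; bins are half-open
`[k/10, (k+1)/10)` with the last bin closed. Two conventions here are
deliberate choices rather than forced ones and are worth restating: the
ascending letter order, and the half-open binning. Discretization is
coarse on purpose — it absorbs the small shift perturbations that pH,
temperature, and referencing differences introduce between experiments.

Degenerate (single observation) or absent scale entries encountered at
prediction time emit `N` with a logged warning instead of aborting, so
sparse corpora stay usable; `normalize()` called directly on such an entry
raises, because silent vacancies are only acceptable as an explicit
featurization policy.

## Shape strings and the torsion-region table

The published φ/ψ boundaries of the original shape-string alphabet are not
available in machine-readable form, so the shipped
`data/torsion_regions.tsv` is a documented approximation: a set of
disjoint rectangles covering the full torus (lower-inclusive /
upper-exclusive bounds, ±180° edges closed), with a glycine-only override
for state G listed first. Consequences worth knowing:

* the table is **data, not code** — tests and the synthetic generator
  treat the configured table as ground truth, and users can substitute
  their own;
* the G override spans the whole positive-φ half-plane, so glycine can
  never receive the turn letter T under the default table, and non-glycine
  residues never receive G.

Record↔structure alignment (transferring observed shape letters onto a
shift record across chain breaks) uses global alignment with identity
scoring hostile to substitutions (match +1, mismatch −10, gap open −5,
extend −1). A substitution can tie with a double gap under any affine
scheme, so "unalignable" is flagged both for aligned mismatches and for
regions where both sequences skip residues. Zero tolerance for
substitutions is a choice: entries that do not correspond exactly are
reported, not silently relabeled.

## Hallmark patterns and profiles

Mining enumerates every length-2–4 substring (overlaps and within-sequence
repeats counted) and keeps those with support ≥ `min_support` (default
100, matching the scale of corpus the method is designed for; small
corpora should lower it). Each position's modal shape letter is scored
with the one-sided binomial upper tail P[X ≥ k], X ~ Binomial(n, p₀), with
n the support and p₀ the letter's background frequency in the mining
corpus itself. The significance cutoff `max_p` defaults to 0.01. Both
null and cutoff are configuration, since neither is canonical: a uniform
null would inflate significance for common letters like A.

Profiles tally hits into 8 boxes per residue. The built-in hit source is
an exact k-mer matcher (default k = 6) over an annotated corpus — a
desk-scale stand-in for a database similarity search with identical
downstream counting — restricted to the `top_n` (default 10) subjects with
the most matched positions. Positions without any primary evidence are
scanned against the hallmark library; pattern matches contribute their
conserved letters with the same unit weight as primary hits. The `flank`
parameter (default 5) records the ± context width for external secondary
hit sources; the built-in scan does not re-anchor matches in the corpus.
An adapter (`TabularHitSource`) accepts externally produced hit tables for
users with a real alignment pipeline. Box fractions are discretized with
the same ten-letter scheme as the shifts, for uniformity; an all-zero
position emits eight `N`.

During training, each chain's own corpus entry is excluded from its hit
source: profiles must summarize evidence from *other* chains, or the CRF
learns to copy a leaked answer.

## The CRF

Observation features are the 14 (or fewer, under ablation) letters per
residue at every offset in [−window, +window] (default window 3); offsets
outside the chain emit a boundary token. One weight per
(slot, letter value, state) plus an 8×8 transition matrix. Training
maximizes the L2-penalized conditional log-likelihood (penalty
0.5·λ‖w‖², λ default 1.0) with L-BFGS (default 200 iterations); gradients
come from forward–backward marginals computed over a padded batch so the
recursions loop over time steps rather than chains. The objective is
smooth and convex and optimization starts from zero weights, so training
is deterministic; the stored seed is provenance, not an input to the
optimizer. Decoding is Viterbi; reported probabilities are
forward–backward marginals (which may disagree with the Viterbi path at
individual positions — both are exposed).

`X`-labeled positions are missing supervision, not a ninth class:
training sequences are split at X runs, and at prediction time every
position receives one of the 8 letters.

Numerical notes: all message passing is in log space with the max-trick;
partition function and Viterbi are verified against exhaustive enumeration
over all 8^L paths for L ≤ 6, and the analytic gradient against finite
differences.

## Evaluation

S8/S3 are residue-weighted accuracies; reference-X positions are excluded.
S3 uses the collapse [S,R,U,V]→S, [A,K]→H, [T,G]→T, and S3 ≥ S8 holds for
every pair by containment.

SOV uses the 1999 δ convention, δ = min(maxov−minov, minov, ⌊len(s₁)/2⌋,
⌊len(s₂)/2⌋), with integer floors. Reference-X positions are excluded and
split segments on both strings (the prediction is masked at reference-X
positions first — otherwise a prediction segment spanning an undefined gap
would be penalized for the reference's missing data). When chains are
pooled, they are joined with an X separator so segments never merge across
chains.

The bootstrap resamples ⌈0.8·n⌉ evaluation chains **without replacement**
1,000 times (defaults), recomputes the metric over the pooled residues,
and reports the mean and the ddof=1 standard deviation of the distribution
as the ± value.

## Synthetic corpora

The generator emulates the data model the predictor assumes: shape strings
from a first-order Markov chain with self-transition bias 0.8 (mean
segment length 5) and an imbalanced stationary distribution (A 40%, S 20%,
R 12%, T 10%, K 7%, U 4%, V 4%, G 3%) chosen to mimic the qualitative
helix-dominant imbalance of real structure-annotated corpora; Gaussian
shift emissions with per-(aa, atom) base means fixed by an internal
constant seed and per-(state, atom) mean offsets scaled by a separation
parameter `s` in SD units (s = 0 is the null corpus; the default s = 3
gives well-separated states); per-cell vacancies at a configurable
missingness rate (default 10%); and torsions drawn uniformly inside each
state's core rectangle (half-degree inset), so shape assignment
round-trips exactly. A Student-t emission option stresses the min/max
clipping path with heavy tails.

Glycine is emitted iff the state is G — shape G is glycine-specific and
its region overlaps the turn region, so any other placement would break
the assignment round trip.

What passing tests on this generator demonstrate: the estimator,
featurization, decoding, and scoring machinery are correct, and the CRF
recovers planted structure when the emission signal exists (held-out S8
≥ 90% at high separation; collapse to the majority-class rate on the null
corpus). What they do not demonstrate: performance on real BMRB
assignments, whose shift–structure relationship is weaker,
nearest-neighbour dependent, and corrupted by referencing errors, and
whose sequence families give profiles far more power than unrelated random
chains do.

## Experiment harness and problem sizes

Cross-validation splits at **chain** level (residue-level splits would
leak sequence context across folds). The ablation harness runs the
leave-one-shift-out table (six single-omission conditions plus the
all-six-shifts row, shift features only) and a feature-family comparison
(shifts / profile / combined) under shared folds.

The shipped experiments use 200 training and 50 held-out chains of length
50–150 for parameter recovery, and a 100-iteration L-BFGS budget — sizes
at which every reported behaviour is stable across seeds while a full run
of suite plus acceptance script stays comfortably on one CPU core.

## Known limitations

* The torsion-region table is an approximation; downstream work that needs
  the original alphabet's exact boundaries must supply its own table.
* The built-in k-mer hit source is a stand-in for a proper similarity
  search; it finds only exact matches and its profiles are weak for
  queries unrelated to the reference corpus.
* Secondary (pattern-anchored) profile hits contribute conserved letters
  directly rather than re-aligning flanked segments against the corpus.
* No chemical-shift re-referencing or secondary-shift computation; the
  min/max clipping is the only outlier control.
* Bootstrap SE is the dispersion of the resampled-metric distribution; at
  very small chain counts (resample size = corpus size) it degenerates to
  zero.
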