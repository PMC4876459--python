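# Methods

This note documents the models, conventions, defaults and known
limitations of the pedprio pipeline.

## Coordinates and interval conventions

Marker and variant positions are 1-based on input (VCF / linkage-file
convention); all internal intervals are 0-based half-open, converted
exactly once at the I/O boundary.  An IBD segment is the span of a
maximal run of markers with `P(IBD=1) + P(IBD=2) > threshold`
(strictly greater; default threshold 0.5), from the first to the last
qualifying marker inclusive.  This is the conservative reading of
"region spanned by the markers": segments are *not* extended to the
midpoints of the flanking non-qualifying markers, and a single
qualifying marker yields a 1-bp segment, which is retained.  Genetic
positions are piecewise-linearly interpolated between map anchors and
clamped (never extrapolated) outside the anchored range, which avoids
negative cM values at chromosome ends.

The sib exclusion is defined on pairwise tracks only: a region is
removed when some unaffected sib is pairwise-IBD with *both* patients
there.  True three-way sharing of one haplotype cannot be resolved
from pairwise probabilities, so this conjunction rule is an
approximation that can occasionally exclude a region where the sib
shares different haplotypes with each patient.

## Filter cascade

All five filters are pointwise predicates, so the survivor set is
invariant under stage permutation; the report fixes the order
frequency → consequence → conservation → regions → carrier for the
per-stage accounting.  Asymmetries where annotations are missing are
deliberate: a variant absent from every frequency panel is **kept**
(absence cannot certify commonness) while an SNV without a GERP score
is **removed** (conservation cannot be certified); indels are exempt
from the GERP rule because GERP is a per-site substitution score.
The frequency rule uses ≥ (a variant at exactly the 0.5% threshold is
excluded), the conservation rule uses < (GERP exactly 2.0 is kept).
"Non-frameshift" variants are modelled as the in-frame indel class of
the standard annotation vocabulary.  Multi-allelic records must be
split to one alt allele per record before input.  A variant with no
genotype for the carrier sample is retained and flagged rather than
excluded.

## Random walk with restart

The network is normalised symmetrically, A = D^−1/2 W D^−1/2, with the
rows/columns of degree-0 nodes set to zero.  Under this normalisation
the iterate p^t is *not* a probability distribution (columns of A do
not sum to 1); scores are relative affinities, which is all ranking
requires.  The fixed-point iteration p ← (1−r)Ap + rp⁰ starts from
uniform seed mass 1/s and stops when the L1 change drops below the
tolerance (default 1e-6, configurable; non-convergence at the 10 000
iteration cap is flagged, not fatal).  The spectral radius of (1−r)A
is at most 1−r = 0.5 at the default restart, so convergence is
geometric.  Useful identities used as oracles: an isolated seed's
steady score is exactly r; r = 1 returns p⁰; rescaling all edge weights
by a constant leaves A (hence all scores) unchanged; the fixed point
equals r(I − (1−r)A)^−1 p⁰.

Duplicate undirected edges merge by maximum weight and self-loops are
dropped.  Candidates absent from the network are scored 0 and ranked
last (with a warning): this inflates apparent LOOCV performance when
decoys fall outside the network, and is visible in the per-run
warnings.  Ties receive mean ranks; the set-valued top-fraction
operation (⌈fraction·n⌉ genes, default 20%) breaks boundary ties by
lexicographic gene id so results are deterministic.

## Evaluation protocols

LOOCV removes each seed in turn, re-runs the walk with the remaining
seeds, and hides the left-out gene among 199 decoys (configurable)
drawn without replacement from the gene universe with probability
proportional to CDS length — long genes accumulate more rare variants,
so length-weighted decoys mimic a realistic filter output.  Sampling
uses the exponential-sort construction (keys Exp(1)/length, keep the n
smallest), equivalent to sequential draws with renormalisation;
inclusion probabilities are therefore approximately, not exactly,
proportional to length.  Percentile rank is rank/(1+n_decoys) with
mean-rank ties.  How many decoy redraws to average per left-out gene
is a free choice; the default is one, configurable via `repeats`.

Null calibration replaces candidate scores with i.i.d. Uniform(0,1)
draws per repeat (`randomize_scores`), making the left-out gene
exchangeable with the decoys: detection at cutoff q then equals q in
expectation and the mean percentile is (2+n_decoys)/(2(1+n_decoys)) ≈
0.5.  A plain permutation of the realised scores would *not* be a
correct null here because tied zero scores (isolated genes) collapse
the rank distribution.

Case replication evaluates one confirmed disease gene that must not be
among the seeds (leakage guard): 1000 independent decoy draws, one walk,
reporting the mean percentile and the top-10% fraction.  A single
integer seed drives all stochastic steps, so both protocols are
bit-reproducible.

## Synthetic data

The generator emulates the full study design with planted truth.

* **Pedigree** (default): a five-generation kindred branch with two
  affected relatives related as first cousins once removed — kinship
  coefficient 1/32, i.e. P(IBD=1) = 1/8 at a locus — each with one
  unaffected elder sib, matching the roles the filters need
  (patient pair, proband carrier check, two sib exclusions).
* **Genome**: 10 chromosomes × 120 cM, markers every 1 cM, with a fixed
  1 Mb/cM physical scaling.  This is a scaled-down stand-in for a
  ~5000-marker genome-wide linkage panel; it preserves the expected
  ~1/8 shared fraction (~150 cM) while keeping a full pipeline run in
  milliseconds.
* **Meiosis**: crossovers are a Poisson process on the cM axis (Haldane
  model, no interference), founder haplotypes uniquely labelled; the
  true pairwise IBD state at a marker is the number of allele positions
  sharing a founder label.  Supported pedigrees are non-inbred (an
  individual's two labels always differ).
* **Probability tracks**: the true state receives 1−ε, the other two
  ε/2 each (default ε = 0.05; ε = 0.5 is rejected).  Because
  1−ε > 0.5 for every admissible ε, threshold-0.5 calling recovers the
  true runs exactly — real multipoint posteriors are smoother and can
  blur segment ends, which this confusion model does not emulate.
* **Exome table**: 200 background variants with independent attribute
  mixtures (30% common in some panel, 25% non-functional class, 25% of
  SNVs weakly conserved, 50% carried by the proband, half of the rare
  variants absent from every panel — mirroring that a typical exome
  yields on the order of 10² ultra-rare functional variants, more than
  half absent from controls) plus exactly one causal variant: a rare,
  conserved missense SNV placed inside a region truly shared by the
  patients and surviving the sib exclusion, carried by both patients.
  Gene drops are retried (rarely needed) until such a region exists.
* **Network**: a two-block stochastic block model over 400 genes with a
  40-gene module (edge probability 0.3 inside, 0.01 outside, unit
  weights) containing the disease gene and the 20 seed genes; CDS
  lengths are lognormal (log-mean 7.2, log-sd 0.8, median ≈ 1.3 kb).

Because attributes are generated independently, the expected number of
background survivors of the frequency/consequence/conservation stages
factorises, which the tests exploit as an analytic oracle.

What passing on synthetic data does **not** show: performance on real
pedigrees with genotyping error, segment-boundary uncertainty,
population-specific allele frequencies, or a real interaction network's
degree heterogeneity and annotation bias.  The evaluation statistics
here characterise the method under the stated generative model, not
any particular database.

## Pipeline and determinism

`run_all` always computes both filtering strategies side by side —
survivors in patient-shared regions, and survivors after sib exclusion
plus the proband carrier check (a subset of the former by
construction) — and reports the intersection of the sib-excluded
survivors' genes with the top-fraction network genes.  Every threshold,
the seed and the package version are logged to `run.json`; two runs
with identical inputs and configuration produce byte-identical outputs
(all orderings are explicit, no iteration-order dependence).

## Problem sizes used in validation

The test and acceptance runs use: 50 random graphs (n ≤ 200) for the
walk-vs-direct-solve oracle; 1000 random tracks/region pairs against
per-base membership on 10-kb toy chromosomes; 100 random variant tables
for cascade permutation invariance; 1000 LOOCV null trials and 100
signal trials on the default synthetic network; 200 gene-drop
replicates for the sib-state and kinship checks; and 100 seeded
kindreds end to end.  The walk runs at tolerance 1e-12 where it is
compared with the direct solve (the default 1e-6 stopping rule leaves a
residual of its own order, which would mask the comparison).
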