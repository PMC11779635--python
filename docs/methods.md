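# Methods

## The inference problem

A cemetery used by one community over several generations preserves, in the
genomes of the buried, a record of the community's marriage customs. The
package treats three complementary signals:

1. **Uniparental asymmetry.** mtDNA passes mother→child, the Y
   father→son. Female philopatry (matrilocality) therefore drives
   within-community mtDNA diversity down while male in-migration keeps Y
   diversity high; patrilocality mirrors the pattern.
2. **Kinship asymmetry.** In a matrilocal community, buried women are
   enmeshed in the local pedigree while many buried men married in from
   elsewhere, so women carry more and closer kinship links.
3. **Between-community exchange.** If men move at marriage, relatives
   detected between neighbouring sites are connected through migrant men and
   should rarely share an mtDNA haplotype, while within-site relatives often
   do.

## Statistics

**Haplotype diversity.** h = n/(n−1) · (1 − Σ p_i²), where p_i are sample
haplotype frequencies. The n/(n−1) factor makes h exactly the probability
that two haplotypes drawn without replacement differ, i.e. the fraction of
discordant unordered pairs (verified exhaustively in the tests). The biased
variant (no correction) is available by flag. Sites are first pruned of
first-degree relatives — greedy removal of the individual with the most
remaining first-degree links, ties to the smallest id — because a clutch of
siblings would otherwise depress h for purely demographic reasons.

**Pairwise kinship from IBD.** Segments are merged per pair and per
haplotype "channel" (the haplotype index of the lexicographically smaller
sample), bridging inter-segment gaps up to `gap_cm` (default 1 cM). IBD2 is
the intersection of the two channel unions, IBD1 the symmetric remainder;
φ = f_IBD1/4 + f_IBD2/2. Degrees use power-of-two bins
(d ⇔ φ ∈ (2^−(d+3/2), 2^−(d+1/2)]), "unrelated" below the degree-7 edge, 0
for identical-level sharing. Degree-1 pairs are split into parent–offspring
(f_IBD2 < 0.02 and f_IBD1 > 0.9) versus full siblings. Physical coordinates
are converted to genetic ones with a per-chromosome constant rate estimated
from the table itself; for the package's own synthetic dialect (1 cM = 1 Mb)
this is exact, for external data it is a linear approximation. X-chromosome
segments are excluded from autosomal kinship and reported separately.

**Weighted relatedness.** Per individual, Σ 1/d over relatives of degree
d ≤ 7 (an identical-level pair weighs 1). Sex differences are tested with
Welch's two-sided t-test on the scores and Fisher's exact two-sided test on
the 2×2 sex × dominant-matriline table (in multi-site panels each
individual is tested against their own site's modal matriline); both
delegated to scipy and checked
in the suite against a from-scratch Satterthwaite computation and an
exhaustive hypergeometric-tail enumeration.

**Matriline minimum births.** Observed de novo subclades k of a dominant
matriline bound the number of births N to lineage mothers: with per-birth
mutation probability μL (default μ = 4.72×10⁻⁷ per site per generation,
L = 16,569 bp), the count is Poisson(NμL) and the bound is the smallest N
with P(X ≥ k) ≥ confidence (default 0.5, the median — a deliberately
conservative "at least" reading). The estimator is monotone in all four
arguments; a Monte-Carlo backend cross-checks the analytic search. At k = 4
subclades and the defaults the bound is N = 470. It ignores subclade
survival and incomplete sampling, both of which would only push the true N
higher — it is a lower bound.

## Simulators

**Deme model.** Non-overlapping generations; `n_demes` demes of fixed size
(25 females + 25 males by default, 10 demes, 50 generations). Each
generation: every female (male) independently moves to a uniformly chosen
other deme with probability m_f (m_m) — migration happens before pairing,
matching marriage-time dispersal; random monogamous within-deme pairing;
offspring pick a parental couple uniformly, refilling the fixed deme sizes.
mtDNA follows mothers, Y follows fathers; founders carry all-distinct
labels and there is no mutation, so drift and migration are the only
forces. h is computed per deme on a sample (default 10 per sex) and
averaged over demes. A replicate in which a deme loses one sex entirely is
flagged and re-run. The implementation is vectorised across replicates; 100
replicates of the default configuration take well under a second.

Defaults are desk-scale choices giving stable envelopes at equilibrium-ish
diversity; all are configurable, and the inference is over the migration
grid, not these constants.

**Rejection inference.** For each grid cell (m_f, m_m) (default step 0.05
or 0.1), simulate the model and accept the cell when both observed
diversities fall inside the central `coverage` interval (default 95%) of
the simulated (h_mt, h_Y). Marginal accepted intervals are the min/max of
the accepted cells; an empty region is reported, not raised; coverage = 1
means no rejection. Accepted intervals shrink (weakly) with more replicates
at fixed coverage.

**Pedigree communities.** Residence-ruled pedigrees of default depth 6
(seven generations). One founding couple per site; children of the lineage
sex (daughters under matrilocality, sons under patrilocality, a fair coin
under mixed residence) reproduce locally with in-marrying spouses, who are
unrelated founders with distinct haplotypes; non-lineage children are
buried in the natal community with probability 0.5, otherwise they emigrate
and may marry into another simulated site (multi-site fixtures). Offspring
counts are Poisson(2.5), monogamous unions, no close-kin marriage — an
outbreeding community. A community whose local lineage dies out before the
requested depth is a failed draw (such a cemetery would not show continuous
use); generation is retried with a derived seed.

**Gene dropping** has two backends with one transmission model (Poisson
crossovers, mean = map length/100, uniform positions, no interference; 22
autosomes rescaled to 3,545 cM total, X = 180 cM; X recombines only in
females, passes intact father→daughter, never father→son):

- *segment-level*: exact founder-segment mosaics; backs `drop_genomes` and
  the emitted IBD tables (maximal shared founder segments, half-open
  synthetic coordinates at 1 cM = 1 Mb, ROH as within-individual sharing).
- *grid-level*: founder identity tracked at 1-cM bin midpoints, vectorised
  across replicates; backs the kinship-coefficient Monte Carlo
  (10,000-replicate distributions in seconds). Sampling at bin midpoints is
  unbiased for mean realized kinship because the locus-wise sharing
  probability is the kinship coefficient at every position; only
  segment-length geometry is discretised.

Expected coefficients come from standard path-counting recursions
(φ(a,a) = (1+F_a)/2; X variant with hemizygous males contributing their
single allele with probability 1), which serve as the independent oracle
for both backends.

**Regime classification.** A community's pair table is summarised as
(mean φ by sex pair FF/MM/FM, fraction unrelated by sex pair, mean X-to-
autosomal kinship ratio). Distances to per-regime reference simulations are
Euclidean after component-wise standardisation by the pooled reference
spread; scores are softmax(−distance). The seven components were chosen so
that the matrilocal/patrilocal contrast appears twice (kinship by sex and
its censoring) and the X ratio separates mixed residence; the classifier is
exactly mirror-symmetric under a sex-label swap with swapped references.

## Network consensus

Sites are nodes; the edge weight between two sites is the summed
total-IBD of cross-site pairs (pairs below `min_pair_cm`, default 12 cM,
contribute zero) divided by the number of cross-site pairs. Leiden
(RBConfiguration, igraph/leidenalg) runs `n_runs` = 100 times with distinct
seeds; the run-averaged co-assignment matrix is thresholded at 0.5 and its
connected components form the consensus partition, refined hierarchically
at 0.75 and 1.0. The default resolution is picked by a plateau heuristic
(longest run of candidate resolutions yielding a constant cluster count).
The maximum-clade-credibility summary selects the run whose clusters
maximise the summed log frequency of occurrence across runs, with
deterministic lexicographic tie-breaking, and exports newick with clade
supports. Thresholding the co-assignment at 1.0 recovers the strict
all-runs-agree partition.

## What the synthetic data do and do not show

The generator reproduces the *structure* the analyses rely on: residence-
ruled pedigrees, label inheritance with subclades, realistic IBD segment
sharing down to distant relatives, ROH from consanguinity, and multi-site
marriage exchange. It does not model phasing/imputation error, segment
detection power (IBD tables are exact down to the emission threshold),
haplogroup misassignment, radiocarbon uncertainty, population growth or
overlapping generations. Passing tests therefore demonstrate correctness of
the estimators and the recoverability of residence signals under the stated
model, not robustness to the error processes of real ancient-DNA pipelines
(segment-detection noise would blur degree assignments near bin edges
first).

## Numerical choices and degenerate cases

- Parent–offspring realized kinship and mother–son realized X kinship are
  deterministic (0.25 and 0.5); tests compare them exactly rather than by
  Monte-Carlo error.
- h is undefined for n < 2 and signalled; screens flag groups with < 3
  sites or degenerate variance instead of failing.
- Degree-boundary pairs are the dominant error mode of degree
  classification (realized-kinship variance straddles bin edges); accuracy
  is assessed on third-degree-or-closer pairs, where it exceeds 95%.
- Problem sizes in tests and the acceptance script (e.g. 100 replicates
  per grid cell, 15–50 classification trials per regime, depth-4 fixture
  communities) are chosen as the smallest sizes at which the Monte-Carlo
  bounds above are meaningful; every size is a parameter.
- All randomness flows from explicit seeds through
  `numpy.random.Generator`; fixtures are bit-reproducible and the fixture
  writer records its full configuration in a provenance sidecar.

## Known limitations

- The minimum-births bound conditions on neither subclade survival nor
  sampling, and its default confidence (0.5) is one defensible reading of
  "at least"; both are exposed as parameters.
- The per-chromosome constant genetic-rate approximation in the IBD reader
  is exact only for the synthetic dialect.
- The deme model has no mutation; it cannot be used where haplotype
  innovation over the simulated horizon matters.
- Consensus hierarchy extraction (thresholded co-assignment) and MCC
  tie-breaking are one concrete choice among several reasonable ones;
  alternatives would differ only in tree shape, not in the flat consensus
  partition.
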