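# Methods

## Problem and model

`famvar` analyses nonsynonymous variation in a diploid cohort at *equivalent
positions* of protein families: residues of different proteins aligned to the
same column of a family (profile-style) alignment. The underlying idea is
that when many members of a redundant family — olfactory receptors being the
canonical case — accumulate variants at the same structural position, the
position likely tunes individual-level phenotypes rather than core viability.
The package provides the statistics for detecting such positions, the
receptor-pharmacology scoring that links one of them (the GPCR DRY-motif
arginine, R3.50 in Ballesteros–Weinstein numbering) to receptor inactivity,
fingerprint clustering of individuals by their loss-of-function spectra, and
an agent-based model of odorant-driven behaviour.

### Enrichment statistic

Let `A` be the total pooled alternate-allele count (missense only) over a
proteome of `P` residues. Under uniform placement a column mapped in `I`
domain instances expects

    E = A / P * I          (whole family: E = A / P * I * L, L = model length)

and enrichment is the base-2 log-odds `log2(O / E)` of the observed pooled
count `O`. Significance is an upper-tail binomial test with `n = A` trials
and success probability given by a *shuffle prior*: every protein's missense
alleles are relocated uniformly at random within that protein, and the prior
is the mean fraction of alleles landing on the target over `n_shuffles`
shuffles (default 100, seeded). The shuffle construction makes the prior
inherit the cohort's distribution of alleles over proteins, so proteins that
are variant-rich for reasons unrelated to the family (length, mutability)
are weighted accordingly; its analytic limit is
`Σ_p A_p · m_p / L_p / A` with `m_p` target residues in protein `p`, which
the implementation falls back to when a finite shuffle estimate is exactly
zero for a column with observed alleles (otherwise the p-value would
degenerate to 0). P-values are Benjamini–Hochberg corrected in a single
global family across all *tested* positions — those with at least 50
observed or 5 expected alleles, the count floor being applied before the
correction so the tested set defines the BH family. A position is reported
enriched when `log_odds >= 1` and `Q <= 0.01` (both inclusive), optionally
also requiring >= 10 member genes with variants.

Choices made where the procedure was genuinely open:

* **Log base.** Base 2 everywhere (enrichment threshold 1 = a doubling;
  cluster-enrichment threshold 0.6 ≈ 1.5-fold), exposed as configuration.
* **Binomial trials.** `n` = total pooled allele count; upper tail, since
  the question is enrichment.
* **BH scope.** One global correction across families, not per family.
* **Conservation.** A column is conserved when its modal residue frequency
  (over members aligned there) reaches 0.5 by default; "strong consensus"
  is not a quantified notion, so the threshold is configurable. Modal ties
  break alphabetically.
* **Stop-gain/frameshift records** are excluded from enrichment counting
  (they are fewer and positionally less certain) but retained as
  loss-of-function classes for fingerprints and odor-response scoring.

### Receptor screen statistics

Positive receptor–odorant screens carry a log10 molar EC50 in [-9, 0]
(-9, i.e. 1 nM, is the strongest potency represented); negatives carry a
missing value. Potency-weighted counting uses `w = -log10(EC50)/9`, clamped
to [0, 1]. At a conserved column, receptors split into canonical (consensus
residue) and non-canonical; the fold enrichment is the ratio of positive
rates and significance is the *lower* hypergeometric tail on the
non-canonical group — the probability of that many or fewer positives —
computed from unweighted counts. On the published DRY contingency
(1 of 1089 non-canonical vs 102 of 8815 canonical screens) this yields
P = 8.0e-5 and a 12.6-fold enrichment, which the acceptance script
recomputes.

Individual odor responses average per-allele contributions over every
(binding receptor, allele copy) pair: a functional allele contributes the
potency weight, a loss-of-function allele (conserved-arginine missense,
stop-gain, frameshift) contributes zero — so heterozygous loss halves and
homozygous loss silences one receptor. The averaging denominator is the
number of allele pairs (2 x binding receptors); this per-allele reading is
a documented choice, as is treating negative screens as zero-weight trials.
Population matrices are group means normalised per odorant by the maximum
group mean.

### Fingerprints and clustering

Individuals are encoded as fixed-order binary carrier vectors over a
selected variant set (default loss-of-function variants); a diploid 0/1/2
mode exists. Distances are sums of absolute differences (Hamming in binary
mode), clustering is complete linkage (scipy), cluster cuts remove merges
above a bit depth, and per-cluster variant enrichment is
`log2(freq_in / freq_out)` of carrier frequencies with a ±0.6 report
threshold; enrichment can equally be computed against external labels such
as super-populations. Note that complete linkage is only input-order
invariant when pairwise distances are tie-free; with the heavily tied
distances of binary fingerprints the merge order (and hence marginal
cluster boundaries) follows scipy's deterministic index-based tie-breaking.

### Agent-based model

Animals on a hard-walled grid (default 200×200, one animal per cell; 40
founders in a centred block; 50 odorant point sources) carry diploid
genotypes over 100 receptor loci. Each allele responds to 1–14 odorants
with ±1 (attraction/repulsion, equal probability); diploidy resolves per
locus as the sign of the two alleles' summed responses, so conflicting
alleles cancel. The drive on animal `a` is

    m_a = Σ_i Σ_j AR_ij / d_ia · (o_i − p_a) / ‖o_i − p_a‖

summing over odorants `i` and the animal's receptors `j`. Each step every
animal (in a fresh random permutation) moves one grid point: with
probability `fraction_odor_driven` along the unit vector of `m_a` with
components rounded to {−1, 0, 1}, otherwise to a uniform random
8-neighbour; moves into occupied or out-of-bounds cells are cancelled, and
an odorant on the animal's own cell contributes nothing (no 0-distance
term). After movement, adjacent opposite-sex pairs (each animal mating at
most once per step) mate with probability 0.3 provided one parent has at
least 5 empty neighbouring cells; the offspring takes one allele per locus
from each parent, mutating to a uniform random pool allele with probability
0.05 per allele, and is placed in an empty cell adjacent to that parent.
There is no death process, so population changes only by birth. Genetic
diversity is reported as the mean pairwise allele-slot mismatch fraction
(allele pairs order-normalised per locus; populations above 200 are
subsampled), and spatial community count as connected components at
Chebyshev distance <= 2 — both reporting choices, as the source procedure
names no metric. Update order, boundary handling, offspring placement and
the per-move random-vs-driven mixing are likewise interpretations and are
kept behind configuration where reasonable.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of the real inputs: a cohort with
five super-population labels (default weights 0.26/0.20/0.20/0.20/0.14), a
proteome organised into families whose members carry one domain instance
with occasional deletions and insertions, per-haplotype missense alleles at
a uniform base rate with planted per-column multipliers, gene-level
stop-gain/frameshift alleles, coding sequences that translate exactly to
the proteins, and a receptor screen with distinct positive rates for
canonical and non-canonical receptors (defaults 102/8815 and 1/1089).
The default per-residue per-haplotype rate of 4.2e-4 matches the pooled
allele density of a large human cohort (≈23M alleles over ≈11M residues
across ≈5000 haplotypes). Diploidy arises from two independent haplotypes,
so homozygosity occurs by chance; there is no linkage disequilibrium,
recombination map, mutation spectrum (CpG bias enters only through planted
multipliers or codon statistics), or realistic gene naming. Passing tests
therefore demonstrate the statistics' behaviour under known ground truth —
calibration, power, recovery — not performance on the correlational
structure of real genomes.

Sub-population fingerprint structure is planted through marker genes:
stop-gains with per-haplotype frequency 0.8 inside one sub-population
(carrier frequency ≈0.96) and 0.01 outside — a deliberately well-separated
regime in which complete-linkage cuts should recover the planted groups
essentially perfectly.

## Problem sizes and numerics

The reference study conditions used by the tests and the acceptance script
are 1000 individuals x 20 families (~220 proteins, ~16k residues, ~8-9k
variant records) for calibration and power, 500 individuals for cluster
recovery, and the default 200x200 agent world run for 200 steps; these
sizes give stable statistics at interactive runtimes. Determinism is
per-seed throughout (numpy Generator streams; one independent stream per
pipeline stage). Degenerate inputs are handled explicitly: zero observed
alleles give log-odds of -inf and p = 1; columns aligned in no member have
undefined consensus; odorants with no binding receptor give undefined
responses; zero outside-carrier frequencies give signed-infinite cluster
log-odds (reported, not dropped).

## Known limitations

* The shuffle prior treats every individual's alleles as exchangeable
  within a protein; it does not model per-site mutability.
* The whole-family binomial test shares trials across columns of the same
  family, so family-level and column-level p-values are not independent.
* Complete-linkage order invariance holds only up to distance ties (above).
* The odor-response model ignores cell-surface-expression defects and
  non-canonical signalling, and fits no dose-response curves.
* The agent model has no mortality or carrying-capacity term; population
  growth is limited only by space and the mating rule.
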