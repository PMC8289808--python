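# Methods

## Mutation catalogs

Somatic SNVs are classified on the pyrimidine strand: a record whose
reference allele is A or G is the complementary-strand description of a
T- or C-reference event, so the substitution and both flanking bases are
reverse-complemented before binning. The 96 channels are ordered
canonically — C>A, C>G, C>T, T>A, T>C, T>G, each with the 16 trinucleotide
contexts sorted alphabetically by 5' then 3' base — so public SBS
signature matrices load without permutation.

Coordinates are 1-based and closed (VCF convention). Multi-allelic VCF
rows are expanded to one record per SNV allele; indel/MNV alleles are
skipped and tallied. Mutations whose trinucleotide context contains N, or
that sit at a sequence end, are excluded from the catalog and counted in
`n_excluded` rather than being forced into an invented context; the
conservation invariant `counts + n_excluded + non-SNV skips = input
records` holds for every input. A reference-allele mismatch is a hard
error by default (it almost always signals a build or coordinate mix-up)
with an explicit `skip_ref_mismatch` escape hatch.

## Signature refitting

Refitting is non-negative least squares on **raw counts**:
`min ‖M − S·w‖₂, w ≥ 0`, solved by an active-set method (scipy). Raw
counts (rather than frequency-normalized profiles) weight each mutation
equally and keep the fitted weights on the mutation-count scale; relative
contributions are defined as `w / Σw` so they always sum to 1 regardless
of residual mass. No sparsity pruning or bootstrap is applied — the
output is the plain refit. Reconstruction quality is the cosine
similarity between catalog and reconstruction; for the degenerate case of
a zero reconstruction the quality is reported as 0 with a warning rather
than raising, since a downstream QC gate is the intended consumer.

NNLS correctness is cross-checked in the tests against an independent
dense grid search over the contribution simplex (step 0.01, optimal
non-negative scale per grid point in closed form): the NNLS residual is
never worse, and the grid never improves on it by more than the grid
resolution.

Signature files use the tab-separated COSMIC v3 layout (96 labelled rows ×
named columns). Columns must sum to 1 within 1e-3 — public releases are
rounded to four or five decimals — and are renormalized to exact unit sum
on load; anything further off is rejected as corrupt.

## Clustered mutations and kataegis

Two mutations of one sample on one chromosome within 1000 bp (inclusive)
are clustered; maximal chains of consecutive within-distance mutations
form one cluster. Chaining (transitive closure) rather than all-pairs
grouping matches rainfall-plot practice and is verified against a
brute-force O(n²) transitive closure in the tests. Each mutation belongs
to at most one cluster; singletons are not clusters; clusters never span
chromosomes or samples. A kataegic region is a single cluster — no
secondary merge window is applied.

Clustered catalogs are refit like genome-wide ones, but samples typically
have few clustered mutations and refit poorly, so downstream summaries
are restricted to samples whose clustered-catalog cosine exceeds 0.75
(strict inequality). The hotspot scan counts, per cluster, members
matching WRC>NY, RC>NY and WRC>N, and flags clusters with ≥ 2 matches per
class; the nesting WRC>NY ⊆ RC>NY and WRC>NY ⊆ WRC>N holds by
construction and is property-tested.

## AID motif classification

The motif product notation is read as: the mutated base is the C of
RC/WRC written 5'→3' on the strand carrying the C; "N" leaves a position
free; "Y" constrains the product, and since C>C is not a mutation the
only admissible pyrimidine product is T. Concretely, on the pyrimidine
strand:

* RC>NY — ref C, 5' neighbor ∈ {A,G}, alt = T;
* WRC>NY — additionally the base two 5' of the C ∈ {A,T};
* WRC>N — the WRC context with any alternate allele.

G-reference records are reverse-complemented first, so both strands are
evaluated symmetrically (property-tested over all enumerated contexts).
This reading of the ambiguous product notation is an interpretive choice;
the alternate-allele constraint is a parameter (`alt_constraint`) so the
looser reading is testable.

Gene motif content counts every position that is the mutated-C of the
motif on either strand, overlaps included, and divides by gene length.
The expected-fraction denominator over *all* positions is the literal
reading of "motif frequency in the gene sequence"; a `denominator="cg"`
switch restricts it to C:G positions for sensitivity analysis (the motif
can only fire at C:G pairs, so the default is the more conservative
baseline for enrichment).

## Enrichment statistics

Per gene, Fisher's exact test on
`[[n_in_motif, n_out_motif], [motif_sites, non_motif_sites]]`, two-sided
by default (`sided="greater"` available since the alternative of interest
is enrichment), exact hypergeometric computation (verified against a
factorial-formula enumeration over every 2×2 table with row sums ≤ 30).
Genes need ≥ 3 qualifying (non-synonymous) mutations — an exact test on
fewer is uninformative. Benjamini–Hochberg step-up correction runs across
all genes passing that floor in the run; significance is q < α = 0.05.
Cohort-vs-cohort motif frequency uses the same exact test on the 2×2
cohort table.

## Synthetic cohorts

The generator emulates the features the pipeline measures and nothing
else:

* **Reference**: i.i.d. bases at 40% GC (human-like), 2 Mb by default.
  No repeat structure, chromatin, replication timing, or transcription
  covariates — so passing tests demonstrate algorithmic correctness, not
  robustness to alignment artifacts or covariate-driven targeting in real
  genomes.
* **Background SNVs**: channels drawn from `S·w` for a known mixture `w`
  (defaults 0.4/0.3/0.3 over an SBS1-like NpCpG C>T signature, a flat
  signature, and an AID-like RC-context C>T signature), each placed
  uniformly on a genome position carrying the required trinucleotide,
  without site collisions. Where the genome shows the purine, the record
  is emitted as the complementary description, so roughly half the
  records exercise strand normalization. 20 samples × 100 mutations on
  2 Mb gives a mean inter-mutation gap of 20 kb and a per-sample
  clustered-mutation median of ~10 — the same order as the real cohorts
  this emulates, keeping background kataegis calls rare but non-zero.
* **Kataegis**: n C>T mutations (default 40) in a ~2 kb window, a fraction
  `motif_bias` (default 0.4) at RC>NY sites and the rest at non-motif C:G
  sites, with consecutive gaps guaranteed ≤ 1000 bp so the event is
  recovered as exactly one cluster. Background mutations are kept > 1 kb
  away from injected regions so recovery is exact rather than
  probabilistic.
* **Gene screen**: per-gene mutations land in-motif with probability p*
  where p*/(1−p*) = OR · motif_sites/non_motif_sites; OR = 1 is the exact
  null. Defaults: 50 genes of 1.5 kb, one with OR 8 at 20 mutations, the
  rest null — the configuration whose detection power and false-positive
  rate the acceptance checks measure.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` substreams (reference / kataegis / background
/ genes), so identical configs give byte-identical outputs while stages
remain independently reproducible. The truth manifest lists every emitted
mutation, the injected cluster coordinates and the per-gene in-motif
counts.

## Numerical and degenerate-case choices

* Cosine similarity errors on all-zero vectors (undefined) and clips tiny
  negative rounding to [0, 1].
* An all-zero catalog cannot be refit (error); an all-zero *clustered*
  catalog yields a flagged row failing QC instead, since that is a normal
  cohort occurrence.
* Fisher tests with zero observed mutations return p = 1.
* BH input outside [0, 1] is an error, not clamped.
* Cohort percentages round half-up to one decimal (the convention of the
  clinical tables they reproduce); `round()`'s banker's rounding is
  deliberately avoided.
* Duplicate (chrom, pos) within one sample is rejected in rainfall —
  one site cannot carry two point mutations in a single catalog.

## Problem sizes used in the checks

Simulation-based checks run at 5000 mutations per catalog (20 replicates)
for parameter recovery — large enough that multinomial sampling error on
a 3-signature mixture sits well inside the ±0.05 recovery tolerance —
and at 20 seeds × 50 genes (power) / 10 seeds × 100 genes (size) for the
motif screen. Cluster detection is cross-checked on 100 random position
sets of up to 500 positions; the Fisher cross-check enumerates all
245,520 tables with row sums ≤ 30.

## Known limitations

* The generator's i.i.d. reference understates context autocorrelation of
  real genomes; motif-site fractions in real genes differ from simulated
  ones.
* Signature refitting inherits NNLS's behavior under collinear bases:
  with the full COSMIC set, individual contributions of similar
  signatures (e.g. flat ones) are less identifiable than aggregate ones.
  The synthetic basis used in tests is well-separated by design.
* Ig loci are not treated specially; catalogs built from reads misaligned
  in those regions are the caller's responsibility.
* No de novo signature extraction, consequence annotation, or variant
  calling — all three are consumed as inputs.
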