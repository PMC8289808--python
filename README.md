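# aidsig

Detection of AID (activation-induced cytidine deaminase) mutagenic
footprints in somatic SNV catalogs from leukemia genomes — or any cohort of
single-nucleotide variants with a reference sequence.

AID normally diversifies immunoglobulin genes in germinal-center B cells,
but its off-target activity mutates proto-oncogenes and leaves a
recognizable footprint: C>T/C>G mutations concentrated at WRC/RC hotspot
motifs (W = A/T, R = A/G; the mutated base is the C), localized
hypermutation clusters (kataegis), and the single-base-substitution
signatures SBS9/SBS84/SBS85. `aidsig` implements the three complementary
searches for that footprint used in leukemia genomics:

1. **Signature refitting.** Each sample's SNVs are reduced to the canonical
   96-channel trinucleotide catalog (six pyrimidine-strand substitution
   classes × 16 contexts) and expressed as a non-negative combination of
   fixed reference signatures by non-negative least squares:

       minimise ‖ M − S·w ‖₂   s.t.  w ≥ 0

   where `M` is the 96-vector of counts and `S` the 96×K signature matrix
   (e.g. COSMIC v3 SBS1–30 + SBS84/85). Relative contributions are the
   normalized weights; refit quality is the cosine similarity between `M`
   and the reconstruction `S·w`. The AID-associated contribution is the sum
   over SBS9 + SBS84 + SBS85.
2. **Clustered mutations / kataegis.** Mutations of one sample within
   1000 bp of each other are chained into clusters; rainfall data
   (position vs distance to the previous mutation) is exported, clustered
   catalogs are refit separately with a strict cosine > 0.75 quality gate,
   and each cluster is scanned for multiple RC>NY / WRC>NY / WRC>N hotspot
   mutations.
3. **Per-gene motif enrichment.** For each gene with enough non-synonymous
   mutations, the observed in-motif/out-of-motif mutation split is tested
   against the motif content of the gene sequence (both strands) with
   Fisher's exact test, Benjamini–Hochberg-corrected across genes. A
   two-cohort comparison (e.g. your cohort's KRAS vs an external mutation
   database) uses the same exact test.

Because real patient WGS is access-controlled, the package ships a
first-class synthetic-data generator (`aidsig.simulate`) that emits
multi-sample cohorts with *known* signature mixtures, injected kataegis
with a controlled motif bias, and genes with a controlled in-motif odds
ratio — plus a ground-truth manifest — so every stage is testable end to
end.

The core stages are sklearn-style estimators (`CatalogBuilder`,
`SignatureRefitter`, `KataegisDetector`, `MotifEnrichmentScreen`) that
compose with sklearn pipelines; plain functions (`build_catalog`, `refit`,
`find_clusters`, `run_gene_screen`, …) wrap them for script use.

## Worked example

Simulate a 6-sample cohort (2 Mb reference, ~100 SNVs/sample drawn from a
0.4/0.3/0.3 mixture of SBS1-like/flat/AID-like signatures, one injected
40-mutation kataegis at 40% RC>NY bias, a 50-gene screen with one
odds-ratio-8 gene) and run the full pipeline:

```sh
aidsig simulate --seed 42 --n-samples 6 --outdir demo
aidsig report --snvs demo/snvs.tsv --reference demo/reference.fa \
    --signatures demo/signatures.tsv --gene-fasta demo/genes.fa \
    --gene-snvs demo/gene_snvs.tsv --outdir demo_out
```

`demo_out/refit.tsv` — genome-wide relative contributions per sample:

```
         SBS1   SBS5  SBS84  cosine  n_mutations  aid_contribution
S001    0.296  0.321  0.383   0.898        140.0             0.383
S002    0.435  0.305  0.259   0.970        100.0             0.259
S003    0.416  0.146  0.437   0.967        100.0             0.437
S004    0.424  0.374  0.202   0.965        100.0             0.202
```

Contributions scatter around the true mixture (0.4/0.3/0.3) at n = 100
mutations per sample; S001 carries the injected kataegis (40 extra C>T
mutations), which inflates its AID-like contribution.

`demo_out/clustered_refit.tsv` — refits restricted to clustered mutations,
gated at cosine > 0.75:

```
sample  n_clustered  cosine  passes_qc  SBS1  SBS5  SBS84  aid_contribution
  S001           44   0.541      False 0.142 0.547  0.310             0.310
  S002           15   0.843       True 0.466 0.250  0.283             0.283
  S003           14   0.827       True 0.545 0.405  0.050             0.050
```

Small clustered catalogs refit unreliably — exactly why the quality gate
exists. The injected event is still caught by the motif scan,
`demo_out/hotspots.tsv`: S001's 40-member cluster carries 16 RC>NY hotspot
mutations (`multiple_RC>NY = True`), against the expected ≤ 2–3 for
background clusters.

`demo_out/motif_screen.tsv` — per-gene enrichment (sorted by in-motif
count):

```
    gene  n_mut  n_in_motif  motif_site_count  non_motif_site_count  p_value  q_value  significant
GENE0001     20          16               311                  1189   0.0000   0.0000         True
GENE0005      5           4               290                  1210   0.0061   0.1514        False
```

The odds-ratio-8 gene (GENE0001: 16/20 mutations at RC>NY sites vs ~21%
of its sequence being target sites) survives BH correction; null genes do
not.

Every default mirrors the analysis the package implements: 1000 bp
clustering distance, cosine > 0.75 QC, RC>NY motif, min 3 mutations per
gene, α = 0.05, two-sided Fisher. All are overridable on the CLI or via
`RunConfig`.

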