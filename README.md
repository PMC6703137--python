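# sepfun — integrative functional annotation of sepsis GWAS loci

Sepsis GWAS are chronically underpowered: small, heterogeneous patient
cohorts mean that apart from a single genome-wide significant variant
(rs4957796 in the *FER* intron), the available association signal lives in
*suggestive* loci (P < 10⁻⁵). `sepfun` is a pipeline for squeezing
biological meaning out of those loci by layering orthogonal molecular
evidence on top of them. It is written for statistical geneticists and
functional genomicists who have GWAS summary statistics, a phased reference
panel, and public QTL/expression resources, and want a reproducible,
auditable prioritization of candidate causal genes.

## What it computes

1. **Locus clumping.** Suggestive SNPs (P < p_max, default 10⁻⁵) are merged
   into independent loci by transitive single linkage: SNPs chained within
   1 Mb on one chromosome form one locus, represented by its lowest-P lead.
2. **LD proxy expansion.** From phased haplotypes, pairwise LD is computed
   as D = p_AB − p_A·p_B, D′ = |D|/D_max, r² = D²/(p_A q_A p_B q_B); every
   variant within ±500 kb of a lead with r² ≥ 0.95 and D′ = 1 joins its
   proxy set.
3. **Evidence integration.** The locus SNP set (lead + proxies) is
   intersected with a whole-blood cis-eQTL catalog (P < 1.829×10⁻⁵, the
   catalog's FDR-0.05 cutoff) and a stimulated-PBMC cytokine-QTL catalog
   (nominal P < 0.05; Bonferroni 0.05/n_loci for the stringent tier).
   Genes in the 200 kb cis window (lead ± 100 kb) are overlaid with
   differential expression in pathogen-stimulated PBMCs (FDR ≤ 0.05,
   |FC| ≥ 2) and in severe-vs-mild sepsis patients (|FC| > 1.5, FDR < 0.05,
   discovery OR validation cohort). A gene is **prioritized** if it is an
   eQTL gene or a stimulation-responsive cis gene; patient DE and cytokine
   evidence annotate the table. Every flag carries provenance.
4. **LD-aware gene and pathway scores.** Per gene, T = Σᵢ χ²₁(pᵢ) over the
   window SNPs, with the null T ~ Σⱼ λⱼ χ²₁ (λ = eigenvalues of the LD
   correlation matrix R) evaluated by multivariate-normal Monte Carlo
   (add-one estimator) or a Satterthwaite scaled-χ² fit. Significant genes
   feed a hypergeometric pathway test with Benjamini–Hochberg q-values.
5. **Motif disruption.** Allele probe pairs are scanned against MEME-format
   PWMs in log₂-odds space on both strands; per motif the best
   variant-overlapping window score is compared between alleles
   (Δ = best_alt − best_ref, in bits).

A synthetic-data module generates every input with planted ground truth
(block-copy founder haplotypes, sharp threshold margins) so the whole
pipeline is testable offline, including a preset that reproduces the
headline study geometry: 39 loci, 13 with eQTL genes totalling 45, 9 with
cytokine effects (2 past Bonferroni), 55 prioritized genes.

## Worked example

The packaged per-locus QTL evidence table for the 39 suggestive sepsis loci
ships with the package; `analysis/01_annotate_sepsis_loci.py` annotates it:

```text
$ python analysis/01_annotate_sepsis_loci.py
39 suggestive lead SNPs -> 39 independent loci
13 loci regulate 45 unique genes in whole blood; busiest loci: rs12490944 (14 genes), rs41461846 (10 genes), rs3844280 (5 genes)
9 loci alter production of 6 cytokines at nominal P < 0.05; 2 loci (rs13380717, rs2237499) survive Bonferroni at 0.05/39
33% of loci have eQTL genes, 23% affect cytokine production (summary -> results/sepsis_loci/summary.json)
```

One third of the loci act on steady-state blood expression and about a
quarter shape stimulated cytokine release — with only rs2237499 (IL-1β
after LPS) and rs13380717 (IFN-γ after *C. albicans* hyphae) robust to
multiple testing. `analysis/02_run_simulated_pipeline.py` runs the full
pipeline (clump → proxies → integrate → score → enrich → report) on the
headline synthetic study and checks the result against the generator's
truth manifest:

```text
39 loci | 13 eQTL loci (33%) with 45 genes | 12 eQTL genes also PBMC-DE | 55 prioritized | 7 patient-DE | 9 cytokine loci (23%), 2 past Bonferroni
truth-manifest check passed
```

`analysis/03_motif_disruption_probes.py` scores the packaged rs4957796
probe pair (risk allele T vs alternative C at offset 16 of a 33 bp
AT-rich context) against illustrative synthetic motifs: an A/T-box motif
loses ≈4.1 bits of log-odds score on the C allele while a GC-box motif
gains the same — the substitution trades A/T-factor affinity for G/C
context — and a TATA-like motif is rescued by an alternative alignment
(Δ = 0), illustrating why best-window deltas, not single-column intuition,
are reported.

The same stages are available as a CLI (`sepfun simulate|clump|proxies|
integrate|score|enrich|motif|run`), e.g. `sepfun run --config config.yaml`.

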