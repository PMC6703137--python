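# Methods

## Problem setting

Three sepsis GWAS (28-day survival in two adult cohorts; onset in extremely
premature infants) yielded one genome-wide significant variant and a set of
suggestive associations. The pipeline treats those suggestive loci as the
unit of analysis and asks, for each, whether orthogonal molecular data —
whole-blood cis-eQTLs, pathogen-stimulated cytokine QTLs, stimulated-PBMC
transcriptomes, and severe-vs-mild patient transcriptomes — converge on
candidate causal genes.

## Locus definition

Suggestive SNPs are those with association P strictly below `p_max`.
Two thresholds circulate for "suggestive" in this literature — 10⁻⁵ and
9.99×10⁻⁵ — so `p_max` is a parameter; the default is the stricter 10⁻⁵.
Clumping merges SNPs by **transitive single linkage**: two SNPs share a
locus when a chain of same-chromosome pairs, each ≤ `window_bp` (default
1 Mb), connects them. The phrase "within 1 Mb of each other" does not by
itself fix the chaining semantics; single linkage was chosen because it is
the unique order-independent closure of the pairwise relation, and the test
suite pins it to a brute-force connected-components oracle. On a sorted
chromosome the components are exactly runs of consecutive gaps ≤ window, so
the implementation is a single sweep. The lead SNP is the minimum-P member;
ties break by position, then rsID, so output is deterministic. Consequence
of chaining: two lead SNPs of *different* loci are always > 1 Mb apart, but
members of one locus may span much more than 1 Mb.

## LD and proxy SNPs

LD statistics come from phased haplotype counts, never from genotype EM:
with allele-1 frequencies p_A, p_B and joint frequency p_AB,
D = p_AB − p_A p_B; D_max = min(p_A q_B, q_A p_B) for D > 0 and
min(p_A p_B, q_A q_B) otherwise; D′ = |D| / D_max; r² = D² / (p_A q_A p_B q_B).
Monomorphic variants raise an error instead of producing NaN — silent NaN
propagation into proxy sets is the one failure mode this module is designed
to make impossible. D′ and r² are clamped to [0, 1] against ulp-level
overshoot, and the D′ = 1 criterion is tested with absolute tolerance 10⁻⁹
because D′ is a ratio of counts.

Proxy selection replaces a HaploReg-style browser lookup with an explicit
computation over the panel: all variants within ±`window_bp` (default
500 kb — browsers do not document their window, and cis-eQTL signal decays
well before that) with r² ≥ 0.95 and D′ ≥ 1 − 10⁻⁹. The proxy set excludes
the lead; the `snp_set` used downstream re-adds it.

## Evidence integration

* **cis-eQTL**: a locus hits a gene when *any* SNP of its snp_set carries a
  catalog record with P < 1.829×10⁻⁵ (the source catalog's genome-wide
  FDR-0.05 cutoff). Matching is by rsID because public eQTL catalogs are
  rsID-keyed; positional matching is out of scope.
* **cis window**: lead ± 100 kb (a 200 kb window *surrounding* the locus,
  consistent with the observation that most lead eQTL SNPs lie within
  100 kb of their gene). Overlap is half-open and strand-agnostic.
* **PBMC stimulation DE**: FDR ≤ 0.05 and |log₂FC| ≥ 1, i.e. ≥ 2-fold in
  either direction, in at least one stimulation×time condition (OR over
  contrasts). Thresholds are inclusive, following the "≤ / ≥" phrasing of
  the source analysis.
* **Patient severity DE**: |FC| > 1.5 strictly and FDR < 0.05, in the
  discovery OR the validation cohort.
* **Cytokine QTL**: one hit per locus × trait with nominal P < 0.05; the
  stringent tier uses the exact Bonferroni threshold 0.05/n_tests. For 39
  loci this is 1.282×10⁻³, not the rounded 0.0012 sometimes printed; both
  admit the same hits on the packaged table, and a regression test checks a
  p-value between the two thresholds is treated as significant.

The prioritized set is (eQTL genes) ∪ (cis-window genes passing PBMC DE).
Patient DE and cytokine-locus membership are annotations, not inclusion
criteria. Every true flag in the evidence matrix carries provenance
(evidence class, source record key, passing p/FDR), so the table is
auditable record by record.

Whether the original eQTL intersection used leads only or all proxies is
not documented; both modes exist (`snp_set = lead | proxies`) and the
packaged-table analyses use lead-only, since that table is keyed by lead.

## LD-aware gene scores and pathway enrichment

The gene statistic is T = Σᵢ F⁻¹_{χ²₁}(1 − pᵢ) over the SNPs in the gene ±
100 kb window. Under the null the SNP z-scores are N(0, R) with R the
panel's signed LD correlation matrix, so T is the quadratic form
Σⱼ λⱼ χ²₁ with λⱼ the eigenvalues of R. Two evaluators:

* **Monte Carlo** (default 10⁵ replicates): sample z ~ N(0, R) via Cholesky
  of R + 10⁻⁸ I, estimate P[Σ zⱼ² ≥ T] with the add-one estimator
  (k+1)/(n+1), which cannot return 0 and has binomial standard error.
* **Satterthwaite**: a·χ²_ν matched to the first two moments
  (a = Σλ²/Σλ, ν = (Σλ)²/Σλ²). Accurate to a few percent in the bulk,
  weaker in the far tail; cross-method agreement is tested with an
  allowance of ~15% relative on top of 3 MC standard errors.

This is a *Pascal-style* reconstruction — sum-of-χ² gene statistic with an
LD-corrected null and a hypergeometric pathway test — not a replication of
the Pascal software's internals (its sum/max duality, Davies inversion and
fused pathway scores are not reproduced, and no claim is made about
matching its published q-values). The key property, verified in tests, is
duplicate-SNP invariance: adding a perfect proxy doubles T and the null
together, leaving the gene p unchanged, where naive independent combination
would spuriously sharpen it.

Pathway enrichment takes the genes with score p < 0.05 (or a top-N rule),
intersects each GMT set with the scored universe, and computes the
hypergeometric upper tail P[X ≥ overlap]; q-values are Benjamini–Hochberg
across tested pathways (step-up with monotonicity, via statsmodels).

## Motif disruption

Windows of length L on both strands are scored in bits:
score = Σⱼ log₂((f_{bⱼ,j} + c·bg_{bⱼ}) / (bg_{bⱼ}(1 + c))) with pseudocount
c = 10⁻⁴ (small enough to leave well-determined columns untouched, large
enough to keep zero-probability entries finite). For an allele probe pair
the per-motif impact is Δ = best_alt − best_ref over windows **overlapping
the variant base**; windows elsewhere cancel exactly (locality), Δ is
antisymmetric under allele swap, and |Δ| is reverse-complement invariant —
all three are asserted on the packaged rs4957796 probes. Best-window (max)
aggregation is used rather than a sum because an EMSA probe interrogates a
single site. No PWM library is bundled and no binding-call threshold is
imposed: the published prediction names candidate factors (ARID5A, BBX,
E4BP4, FOXL1, Jundm2, Mef2, TBP, p300, …) but not the matrices, so the
module reports ranked deltas for any MEME-minimal input instead of
asserting a specific factor's Δ.

## Synthetic data

The generator's job is to make every stage exactly predictable, not to be
demographically realistic. Haplotypes follow a block-copy founder model:
per block, each haplotype copies one of `n_founders` (default 4) founders
and mutates each allele with probability `mutation_rate` (default 0.01);
blocks are 2 Mb apart (beyond both the clump and proxy windows), SNPs 1 kb
apart within a block. Monomorphic columns are repaired by flipping a single
random haplotype, which preserves the ≤3-haplotype-class structure and
hence D′ = 1 within mutation-free blocks. `simulate_study` then plants, per
locus: a lead (GWAS p ~ U(10⁻⁹, 10⁻⁶) against background U(10⁻⁴, 1)),
exact-copy proxy columns (r² = 1) with all other block columns perturbed
until r² < 0.5, QTL links placed alternately on the lead and its first
proxy (so both intersection paths are exercised), genes placed inside the
cis window (decoy genes outside it, decoy records an order of magnitude
past each threshold on the wrong side). Margins of roughly 10× around every
threshold make recovery tests deterministic rather than statistical.

What this does *not* emulate: realistic allele-frequency spectra,
recombination gradients, overlapping genes, winner's-curse effect-size
inflation, correlated DE across contrasts, or rsID/position errors in real
catalogs. Passing recovery tests therefore demonstrates that the pipeline's
*logic* is faithful (filters, windows, set algebra, thresholds), not that
it is robust to the noise structure of real data.

`headline_preset` fixes the study geometry to the published skeleton
(39 loci; 13 eQTL loci with per-locus gene counts 14, 10, 5, 3, 2×4, 1×5
summing to 45; 9 cytokine loci over 6 cytokines, 2 past Bonferroni; 12/45
eQTL genes plus 10 cis-only genes stimulation-responsive → 55 prioritized;
7 patient-DE genes, 1 up / 6 down). Counts are seed-invariant; identities
(rsIDs, gene labels) are not.

## Numerical and I/O conventions

Gene intervals are 0-based half-open everywhere internally (GFF3 converted
at the boundary); variant positions are 1-based; the two conventions meet
only in the cis-window query, which converts the lead position once.
PWM rows are renormalized if within 10⁻³ of summing to 1 and rejected
otherwise; the MEME-minimal reader is hand-written because the available
library parser rounds probabilities through integer counts and silently
renormalizes malformed rows, losing exactly the information this validation
needs. All writers emit deterministically sorted, repr-precision output so
reruns are byte-identical; all percentage reporting rounds half-up at one
decimal and to the nearest integer. The packaged locus table carries rsIDs
only — the source reports no genome build — so lead positions are
synthetic, deterministic placeholders (one chromosome per study, 2 Mb
spacing) that clump to one locus per lead by construction.

## Problem sizes

Default analysis and test sizes: 120-haplotype panels, 8 SNPs per block,
39 blocks for the preset (312 variants); Monte Carlo gene scores use 10⁵
replicates where a p-value is asserted against a closed form and 2×10³–2×10⁴
in end-to-end drivers, where only the score table's existence and
determinism matter. These sizes keep the full suite in the single-digit
seconds while leaving every statistical assertion at ≥3 standard errors of
slack.

## Known limitations

* Gene scores use the same panel as proxy selection; panel misspecification
  propagates to both.
* The Satterthwaite tail is anti-conservative for strongly rank-deficient
  R; use the MC method when the window contains many near-duplicate SNPs.
* Cytokine trait labels are treated as opaque strings; two labels for the
  same biological trait count as two traits.
* The evidence matrix is per (locus, gene); a gene in two loci appears
  twice by design (provenance differs), and consumers counting unique genes
  must deduplicate, as `summarize_counts` does.
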