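# Methods

`v2gtier` implements a post-GWAS variant-to-gene (V2G) prioritization
pipeline for non-coding disease loci: starting from full GWAS summary
statistics and a phased haplotype reference panel, it defines LD-based
analysis regions, colocalizes the GWAS signal with tissue-level eQTLs,
filters colocalized variant–gene pairs by confluent regulatory context,
validates the survivors against independent data sources with effect-allele
harmonization, and ranks them with an additive evidence tier. This note
documents the models, the parameters that matter, the synthetic-data
generator's scope, and the numerical choices.

## Region definition (LD pruning and expansion)

Genome-wide significant variants (two-sided p < 5×10⁻⁸, strict) are pruned
to pairwise-independent *tags* by a greedy walk in ascending p-value order
(ties by chromosome, position): a variant is accepted iff its r² to every
already-accepted tag within ±500 kb is below 0.7. r² is computed from
haplotype counts, r² = D²/(p_A(1−p_A)p_B(1−p_B)) with D = p_AB − p_A·p_B.
The p-ascending greedy order is the standard clumping convention; pruning
is idempotent by construction.

Each tag is expanded into an analysis region: proxies are panel variants
with r² ≥ 0.7 to the tag, within 1 Mb, and within 1000 variants of the tag
by position rank on the chromosome (the rank-distance reading of the
"within 1000 variants" rule; configurable). Region bounds span the
outermost proxies, and *every* panel variant inside the bounds — associated
or not — is carried into colocalization, since the colocalization model
needs the full local signal shape. GWAS variants absent from the panel
carry no LD information and can be neither tags nor proxies; they are
logged and excluded.

## Genomic partition

Coding gene models (BED12; the thick region is the CDS, `thickStart ==
thickEnd` marks non-coding transcripts) are decomposed into seven primary
classes made disjoint by ordered subtraction of the merged higher classes:

5′UTR exon > 5′UTR intron > 3′UTR exon > 3′UTR intron > promoter >
mRNA exon > mRNA intron.

Promoters are the 1000 bp (configurable) immediately upstream of the TSS,
strand-aware. UTR exon/intron pieces are exon/intron intervals clipped to
the genomic UTR span on the appropriate side of the CDS. A variant takes
the single highest class containing it, or "intergenic"; repeat and
lncRNA exon/intron overlaps are independent flags, never primary classes.
Coordinates follow one rule everywhere: variants are 1-based, intervals
0-based half-open, and containment is `pos − 1 ∈ [start, end)`.

## Colocalization

Per region and per (gene, tissue, source) eQTL group — pre-filtered to
nominally significant genes, defined as best-SNP p < 0.05 (the nominal
threshold is configurable; only its existence, not its value, is pinned by
the method) — the pipeline computes a Bayesian colocalization over the
five standard hypotheses (H0 no signal, H1 GWAS only, H2 eQTL only, H3 two
distinct causal variants, H4 one shared causal variant) under the
one-causal-variant-per-trait assumption.

Each SNP's evidence is a Wakefield approximate Bayes factor with prior
effect variance W:

    log ABF = ½ log(V/(V+W)) + ½ z² W/(V+W),   V = se².

Defaults: per-SNP priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, and W = 0.15² (the
quantitative-trait convention), all configurable; W can be set per trait if
a binary-trait scale is preferred. Posteriors come from enumerating causal
configurations, which reduces to S1 = Σeᵃ, S2 = Σeᵇ, S12 = Σeᵃ⁺ᵇ and
weights {1, p1·S1, p2·S2, p1p2(S1·S2 − S12), p12·S12}.

Numerics: everything runs in log space with log-sum-exp. The H3 weight is
the one delicate term — when a single SNP dominates both traits,
S1·S2 − S12 cancels catastrophically — so for loci up to 4000 SNPs it is
summed exactly over the off-diagonal pair terms (O(n²)), with the
log1p(−exp·) form as the large-locus fallback. This keeps posteriors within
1e−8 relative error of brute-force enumeration (tested). Per-SNP H4
posteriors are the softmax of a+b.

A V2G pair is called when PP(H4) > 0.7, the best per-SNP posterior exceeds
0.5, the locus holds more than one variant (all strict), and the pair's
variant is the per-SNP argmax. The locus-level FDR is 1 − PP(H4), so the
stringent PP(H4) = 0.95 operating point corresponds to FDR = 5%.

## TFBS disruption

Motifs are probability PWMs (HOMER-like text; probabilities floored at
0.001 and renormalized so scores stay finite). A window is scored as
Σ log2(p_i(base)/background) against a uniform background. For a variant,
every motif placement covering the position is scored on both strands for
each allele; per-allele scores are the *maxima over placements* and the
delta is ref_max − alt_max. Comparing maxima (rather than same-placement
deltas) is the one free choice here: it is robust when the variant shifts
the optimal offset. A variant is TFBS-positive when |delta| > 2 for any
motif (strict; gain of binding counts). The threshold is on this log2
scale and exposed as a flag, since published motif pipelines differ in
score scale.

## Confluence

A colocalized pair survives only if the variant disrupts ≥1 TFBS, overlaps
≥1 enhancer interval, and some overlapping enhancer's tissue label maps to
the pair's eQTL tissue under an explicit, config-supplied many-to-many
tissue map (defaulting to exact label match). The map is explicit because
tissue vocabulary reconciliation across annotation providers is a data
contract, not an algorithm. TFBS and enhancer overlap are independent
criteria on the variant; the motif instance is not required to lie inside
the enhancer.

## In silico validation

Harmonization orients every Z-score to the ALT allele of the canonical
`chrom:pos:ref:alt` identity; REF-reported records flip sign. Strand-
ambiguous (A/T, C/G) variants are never flipped silently: they are flagged
and excluded from consistency counting when the reporting strand is
unknown. Harmonization is idempotent.

Directionality consistency averages harmonized Z within each
(source, brain-region group) — groups are a config-supplied mapping from
tissue label to region group — and compares each group's sign with a
reference sign, by default the mean harmonized Z across the discovery
panel's tissues (a majority-vote reference is an easy alternative; the
mean-reference choice mirrors an averaged-reference display column).
A pair is inconsistent when more than half (strict) of the informative
groups disagree; zero or missing Z leaves the denominator. Pairs with no
usable reference are undetermined and not counted.

The raw-vs-harmonized comparison uses McNemar's test on paired
inconsistency flags: χ² = (b−c)²/(b+c) on the discordant counts, no
continuity correction, with the exact two-sided binomial automatically
substituted when b+c < 25. Percent reduction is rounded to an integer.

Structural support is dual-anchor: an interaction supports a pair iff the
variant sits in one anchor and the gene's promoter (TSS−1000 bp,
strand-aware — the same definition the partition uses; gene-body anchoring
is configurable) overlaps the other, in either orientation. TAD support
requires variant and TSS inside the same TAD interval. Replication in an
external eQTL source requires same variant, same gene, and the same
harmonized sign as the reference direction.

Variant evidence profiles are four booleans: histone-mark peak overlap
with q < 0.05, ATAC peak membership, effect prediction (CADD > 10 strict,
or RegulomeDB rank 1a–1e), and association in an independent GWAS of the
trait. Gene evidence is nomination-list membership and brain expression.
"Validated" means at least one category is present.

## Tiering

Overall tier = V2G_eQTL (1–4) + V2G_EPI (0–2) + V (0–4) + G (0–2).
The eQTL component gives one point each for external-source directionality
consistency, external brain-eQTL presence, external/discovery agreement,
and a negative consistent Z, floored at 1 — a colocalized pair starts with
one point (the published range starts at 1 without naming the guaranteed
feature; the floor is the documented reading). The EPI component counts
distinct supporting interaction sources, capped at 2 to honor its stated
range. The components sum to at most 12 arithmetically while the stated
overall range ends at 11; a total of 12 is emitted with a warning rather
than clamped, since no constraint making 12 unreachable is specified.
Ranking is by descending overall tier, then descending PP(H4), then
variant id — fully deterministic.

## Synthetic data

The generator produces the full input surface so every stage is testable
offline.

*Haplotypes*: a template-copying model — a few random template haplotypes;
each simulated haplotype copies one template within blocks of `block_len`
variants, switches templates at block boundaries with probability
`switch_prob`, and flips each allele with `mutation_prob`. Defaults
(200 haplotypes, 60 variants, blocks of 12, switch 0.1, mutation 0.01,
MAF floor 0.05, ~1 kb spacing) give blocky LD that decays with distance —
the property pruning and expansion depend on — at a scale where a full
pipeline run takes well under a second. Columns failing the MAF floor have
their template alleles redrawn (copying assignments kept). Alt alleles are
drawn to be non-complementary to ref, so panel variants are never
strand-ambiguous and the planted-motif and harmonization truths are exact;
ambiguous-allele handling is exercised with hand-built records instead.

*Summary statistics*: simulated at the Z level with the standard
LD-propagation (RSS) model, z ~ MVN(R·λ, R) where R is the panel's signed
allelic correlation matrix and λ places non-centrality `ncp` (default 8)
on the causal column. Marginally z_j ~ N(r_jc·ncp, 1); the correlated
noise is what makes the causal variant identifiable among its proxies,
exactly as in real summary statistics. Signed correlation (not r²) drives
propagation so directionality is meaningful. beta = z·se with
se = 1/√n_samples (default n = 10 000); effect alleles are reported as ALT.

*Scenarios*: `shared` plants one causal column for GWAS and eQTL,
`distinct` two columns with r² < 0.1, `null` none. Causal columns are
chosen to have no near-perfect LD partner (max partner r² < 0.9) because a
perfect proxy is statistically unidentifiable by any method — recovery
tests would otherwise measure panel degeneracy, not pipeline behaviour.
All generators are pure functions of (parameters, seed); per-operation
RNG streams are spawned from the scenario seed.

*Annotation bundle*: writes a truth-consistent file set — the causal
variant inside an enhancer whose tissue matches the eQTL tissue, under a
motif built so the allelic delta clears the threshold (a center column
preferring ref 0.8 vs alt 0.05, surrounded by a controlled genomic
neighborhood so no alternative placement rescues the alt allele), inside
an interaction anchor paired with the target gene's promoter, plus TADs,
external eQTL tables (half deliberately REF-oriented to exercise
harmonization), evidence tables satisfying all variant/gene criteria, and
decoy tracks that overlap nothing.

What the generator does *not* emulate: realistic human LD maps or
recombination hotspots, allele-frequency spectra, indels, multi-causal
architectures, case-control ascertainment, or the metadata heterogeneity
of real annotation providers. Passing tests therefore demonstrate the
pipeline's logic and statistics are correct under their stated
assumptions, not that real-data yields (counts of tags, pairs, genes)
would be reproduced.

## Problem sizes in the test suite

Recovery power is estimated with 100 replicates per scenario kind at the
default panel scale, posterior normalization over 1000 randomized loci,
oracle equivalence on loci of up to 8 SNPs, harmonization behaviour over
50 sign-scrambled cohorts, and tier monotonicity over the exhaustive
4096-point evidence-flag lattice. The full suite runs in a few seconds on
one core.

## Known limitations

* One causal variant per trait per region (no SuSiE-style multi-causal
  colocalization, no conditional analysis).
* Tissue matching and brain-region grouping are config contracts, not
  learned mappings.
* The PWM delta scale is log2 with a uniform background; thresholds from
  pipelines using other scales need rescaling via the exposed flag.
* Strand-ambiguous variants are conservatively excluded from directionality
  evidence rather than resolved by frequency matching.
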