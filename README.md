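# v2gtier

Post-GWAS variant-to-gene (V2G) prioritization for non-coding disease loci.

Most trait-associated variants found by genome-wide association studies sit
outside protein-coding sequence, and linkage disequilibrium (LD) hides the
causal variant among dozens of statistical proxies. `v2gtier` is a pipeline
for analysts who want to go from full GWAS summary statistics to a ranked
shortlist of candidate causal variant → effector gene pairs, each carrying
an explicit, auditable evidence trail suitable for choosing wet-lab
validation targets.

The pipeline runs four stages:

1. **Preprocess** — LD-prune genome-wide significant variants
   (p < 5×10⁻⁸) to pairwise-independent tags (r² < 0.7 within ±500 kb,
   greedy by ascending p), then expand each tag into an analysis region
   containing its proxies (r² ≥ 0.7, ≤1 Mb, ≤1000 variants by rank).
2. **Characterize** — per region and per (gene, tissue), Bayesian
   colocalization of the GWAS and eQTL signals from Wakefield approximate
   Bayes factors, log ABF = ½log(V/(V+W)) + ½z²W/(V+W), enumerated over
   single-causal configurations into posteriors P(H0)…P(H4). A pair is
   called when PP(H4) > 0.7, the best per-SNP posterior exceeds 0.5, and
   the locus has >1 variant; the locus FDR is 1 − PP(H4). Called pairs
   must then survive a confluence filter: the variant disrupts a
   transcription-factor binding site (|Δ PWM log-odds| > 2, per-allele
   maxima over placements and strands) *and* overlaps an enhancer whose
   tissue matches the eQTL tissue.
3. **Validate** — harmonize external eQTL Z-scores to the ALT allele,
   test directionality consistency across brain-region groups (inconsistent
   when >50% of groups disagree with the reference sign), compare raw vs
   harmonized inconsistency with McNemar's test, and collect dual-anchor
   enhancer–promoter interaction / TAD support, independent eQTL
   replication, and variant/gene evidence profiles (histone q < 0.05,
   ATAC, CADD > 10 or RegulomeDB 1a–1e, independent GWAS; gene nomination
   and brain expression).
4. **Tier** — overall tier = V2G_eQTL (1–4) + V2G_EPI (0–2) + V (0–4) +
   G (0–2), ranked descending with deterministic tie-breaks.

A synthetic-data module generates LD-structured haplotype panels
(template-copying model), summary statistics with planted shared / distinct
/ null causal configurations (z ~ MVN(R·λ, R)), and truth-consistent
annotation bundles, so the entire pipeline is testable with no downloads.

## Worked example

Generate a synthetic study with a planted shared-causal variant and run the
pipeline on it:

```bash
v2gtier simulate --kind shared --seed 7 --out demo
v2gtier run --config demo/run.yaml
```

which prints:

```
regions: 2  candidates: 5  coloc pairs: 1  confluent: 1  tiered: 1
report: demo/report/run_summary.json
```

Three of 60 simulated GWAS variants are genome-wide significant; pruning
keeps 2 tags, expansion yields 5 candidate variants in 2 regions. One
(variant, gene, tissue) pair colocalizes, survives the confluence filter,
and is tiered. `demo/report/ranked_pairs.tsv` holds the ranked output:

```
rank  vid             gene_id  tissue        source  pp_h4   v2g_eqtl_tier  v2g_epi_tier  v_tier  g_tier  overall_tier
1     chr1:38379:A:G  GENE1    brain_cortex  GTEx    0.9977  3              2             4       2       11
```

This is the planted pair: the causal variant colocalizes with the planted
eQTL at PP(H4) = 0.998, its external eQTL evidence is present, consistent
and replicating (eQTL tier 3 — the Z is positive, so the negative-Z
feature does not score), it appears in both planted interaction sources
(EPI tier 2), and the evidence tables satisfy all four variant and both
gene criteria (V tier 4, G tier 2), for an overall tier of 11. The other
tables in `demo/report/` record the per-stage evidence (tags, regions,
colocalization posteriors, TFBS deltas, confluence audit trail,
validation verdicts), and `run_summary.json` echoes the full configuration
with per-stage funnel counts.

## Layout

| module | role |
| --- | --- |
| `core_types_io` | domain types, coordinate rules, TSV/BED/BED12/BEDPE/FASTA/motif I/O |
| `synthetic_data` | haplotype panels, planted summary statistics, annotation bundles |
| `ld_regions` | r², greedy pruning, proxy expansion |
| `genome_partition` | hierarchical disjoint element classification |
| `colocalization` | ABFs, H0–H4 posteriors, per-SNP posteriors, V2G calls |
| `tfbs_scan` | PWM scoring, allele deltas, disruption calls |
| `confluence` | enhancer overlap + tissue-context filter |
| `insilico_validation` | harmonization, directionality, McNemar, EPI/TAD, replication, evidence |
| `tiering` | component tiers, overall tier, ranking |
| `pipeline` / `cli` | four-stage orchestration, config, `v2gtier` command |

See `docs/methods.md` for the models, defaults, and numerical choices.
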