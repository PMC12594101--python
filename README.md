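# reporterscreen

Analysis of FACS-sorted reporter CRISPR-Cas9 screens in Python: from
barcoded amplicon reads to a directed gene-regulatory network.

## The problem

In a reporter screen, a fluorescent knock-in (e.g. mOrange or GFP fused
via a self-cleaving peptide) reports one gene's expression in a clonal
cell line. Cells are transduced with a genome-wide sgRNA library at low
MOI (one guide per cell), and the bottom and top ~5% of cells by
reporter fluorescence are sorted. A gene whose knockout *lowers* the
reporter is an **activator** (its guides are enriched in the low bin); a
gene whose knockout *raises* it is a **repressor** (high bin). Running
dozens of such screens against different reporters yields a directed,
signed regulatory network, and cross-screen overlap analysis reveals
groups of genes sharing activators or repressors.

`reporterscreen` implements the full analysis:

- **Counting** — builds the artificial amplicon reference
  (`stagger + 8-nt index + Template1 + sgRNA + Template2`, 12 staggered
  primers per guide) and demultiplexes 75-bp single-end reads into
  per-(replicate, bin) sgRNA counts by fixed-position Hamming matching.
- **Scoring** — median-of-ratios normalization; per-guide replicate-mean
  log2(low/high) ratios with a non-targeting-control empirical null;
  per-gene **α-RRA**: with a gene's guide percentile ranks
  r₍₁₎ ≤ … ≤ r₍ₘ₎ and s guides passing the selection threshold α,

      ρ = min_{k=1..s} P( Beta(k, m−k+1) ≤ r₍ₖ₎ ),

  with permutation p-values (guides redrawn from the full rank pool) and
  per-direction Benjamini–Hochberg FDR. The `pos` direction (low bin)
  scores activators, `neg` (high bin) repressors.
- **Filtering** — strict RRA score cutoff (default 10⁻³); removal of
  hits lying between the centromere and the knock-in locus (Cas9 cutting
  there can delete the reporter allele, a reporter-loss artifact); removal
  of transcriptionally inactive genes (rpkm < 0.1); the >5%-MFI
  validation-labeling rule.
- **Network** — one regulator→target edge per retained hit with sense
  and −log10(score) weight; activator-only / repressor-only /
  context-dependent regulator classes; TSV/SIF/GraphML export.
- **Co-regulation** — shared-activator and shared-repressor overlap and
  Jaccard matrices across screens; average-linkage clustering into the
  two-group partition (group 1 shares activators, group 2 repressors);
  multi-screen Venn queries; treated-vs-untreated regulator intersection.
- **Synthetic data** — a generator that emulates the whole experiment
  (log-normal reporter, multiplicative knockout effects, 5% tail sorting,
  multinomial sequencing, centromere-proximal artifact), so every stage
  is testable with known ground truth.

## Worked example

```python
import reporterscreen as rs

annotation = rs.make_genome(2, 100, seed=11)
library = rs.make_library(annotation, guides_per_gene=4, n_controls=50, seed=12)
reporter = annotation.genes["gene"].iloc[0]
truth = rs.plant_truth(annotation, reporter, n_activators=5, n_repressors=5,
                       effect_size=2.0, seed=13)
screen = rs.simulate_screen(library, truth, reporter,
                            rs.ScreenConfig(replicates=6,
                                            cells_per_replicate=100_000,
                                            reads_per_bin=50_000, seed=14))
norm = rs.normalize(screen.counts)
guides = rs.sgrna_scores(norm, rs.default_design(screen.counts))
genes = rs.gene_rra(guides, library, rs.RraConfig(n_permutations=2000, seed=15))
print(genes.nsmallest(5, "neg_score")[["gene", "neg_score", "neg_fdr"]])
```

prints

```
    gene    neg_score  neg_fdr
G01_0050 1.915686e-08  0.01999
G02_0087 7.359299e-08  0.01999
G01_0079 2.011010e-07  0.01999
G01_0048 2.496541e-07  0.01999
G01_0065 3.065097e-07  0.01999
```

— the five smallest `neg` (high-bin) RRA scores, i.e. the strongest
repressor calls, which here are exactly the five planted repressors
(`rs.plant_truth` planted G01_0048, G01_0050, G01_0065, G01_0079,
G02_0087). `neg_fdr` is the BH-adjusted permutation p-value; 0.02 is the
floor imposed by 2,000 permutations across 200 genes.

The `examples/` directory holds one short script per capability
(simulation, counting, scoring, filtering, network, co-regulation, full
pipeline); each prints the numbers it computes and what they mean. A thin
CLI mirrors the stages:

```sh
reporterscreen fixture --size tiny --seed 7 -o demo
reporterscreen run --config demo/config.yaml
```

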