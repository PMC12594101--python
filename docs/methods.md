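# Methods

## Screen model and sign conventions

A reporter screen measures one gene's expression through a fluorescent
knock-in. After low-MOI library transduction, the bottom and top
`sort_fraction` tails of the reporter distribution are sorted and each
bin is sequenced. Throughout the package:

- the **pos** direction compares low-bin to high-bin enrichment and
  identifies **activators** (knockout lowers the reporter);
- the **neg** direction identifies **repressors** (knockout raises it);
- in the synthetic truth tables, `effect` is the log2 fold-change of the
  reporter upon knockout, so activators have `effect < 0` and repressors
  `effect > 0`.

## Counting

Amplicons have a fixed structure: `stagger (1–9 nt) + 8-nt index +
Template1 (24 nt) + sgRNA (20 nt) + Template2`, with twelve stock
staggered primers allowing six replicates × two bins per lane. Because
every element sits at a known offset once the primer is identified,
counting uses positional Hamming matching rather than general alignment:
the stagger+index prefix must match exactly one primer with zero
mismatches, the Template1 region tolerates up to `max_mismatch`
(default 2) substitutions, and the guide region is assigned to its
unique best library match within the same budget — ties and misses are
tallied under reason codes, never fractionally assigned. This makes
counting exactly reproducible and gives a zero-error round trip against
the read simulator. Indels and quality-aware matching are out of scope;
reads shorter than the full amplicon are matched on the available
prefix.

## Normalization and per-guide statistics

Size factors are median-of-ratios: factor_j = median over guides with
all-positive counts of count_ij / geometric-mean_i. When fewer than
`min_common` (100) guides are positive everywhere — common in very small
simulations — the code falls back to total-count scaling. The per-guide
statistic is the replicate-mean log2((low + 0.5)/(high + 0.5)) on
normalized counts. Each guide receives a one-sided empirical p-value per
direction against the non-targeting controls,
p = (1 + #{controls ≥ score}) / (1 + #controls), and a percentile rank
r ∈ (0, 1] within each direction's ordering of *all* guides (ties broken
by sgRNA id for stability). Controls are mandatory: they are the null.

## Gene-level α-RRA

For a gene with sorted guide ranks r₍₁₎ ≤ … ≤ r₍ₘ₎ and s guides passing
the selection threshold α (default 0.05, applied to the control-based
empirical p), the statistic is

    ρ = min_{k=1..s} P( Beta(k, m−k+1) ≤ r₍ₖ₎ ),        ρ = 1 if s = 0.

Beta(k, m−k+1) is the distribution of the k-th order statistic of m
uniforms, so each term asks how surprisingly small the k-th best rank
is. Significance comes from a permutation null that redraws m guides
without replacement from the full observed pool (ranks *and* their
empirical p-values, so the α-selection is re-applied per draw), pooled
across genes with equal m; p = (1 + #{ρ* ≤ ρ}) / (1 + n_perm), which
enforces the exact lower bound 1/(n_perm + 1). An `exhaustive=True` mode
enumerates all C(n, m) combinations for small pools and returns the
exact enumeration fraction; the test suite checks it against an
independent closed-form enumeration on a 3-gene toy. FDR is
Benjamini–Hochberg per direction.

Two properties follow from the construction and are tested: ρ is
monotone (improving a selected guide's rank never increases ρ), and the
null is *conservative*, not uniform — a null gene has zero α-selected
guides with probability ≈ (1−α)^m ≈ 0.81 at m = 4, giving a large atom
at p = 1. The calibration check therefore bounds the empirical CDF of
null p-values by the nominal level plus binomial slack rather than
asserting exact uniformity; at the default conditions ≤ 0.5% of null
genes reach p < 10⁻³ per direction.

This scoring stage deliberately replaces a negative-binomial per-guide
test with the control-based empirical statistic above: it is fully
specified, deterministic under a seed, and uses the non-targeting
control list directly. Rank-level agreement on strong hits, not numeric
identity with other RRA implementations, is the design goal.

## Hit filtering

1. **RRA cutoff** — strict `score < 1e-3` per direction. A gene may
   appear as both activator and repressor only if it passes both
   directions.
2. **Centromere-interval filter** — Cas9 cutting between the centromere
   and the knock-in locus can delete the reporter-bearing chromosome
   arm, producing complete reporter loss in a cell subset that mimics an
   activator hit. The excluded region is the closed span from the
   centromere edge nearest the target through the target gene's far
   coordinate; a hit is removed when its gene body *overlaps* the span
   (midpoint and containment conventions were the open alternatives;
   overlap is the most conservative). The knock-in gene itself is
   exempt — self-hits are kept and surface as flagged self-loops in the
   network. Coordinates are 0-based half-open internally.
3. **Inactivity filter** — hits with rpkm < 0.1 removed (strict);
   genes missing from the expression table are retained, since only
   measured inactivity is evidence.

Filters are pure per-gene predicates, hence order-independent, and every
removal is logged with a reason so |input| = |output| + |removals|.

## Network and co-regulation

Each retained hit becomes a regulator → target edge with sense
(1 activation / 0 repression), its RRA score, and weight −log10(score).
Classes: a regulator with ≥1 activating and ≥1 repressing edge (to any
targets) is context-dependent. Overlap matrices count regulators of one
sense shared by screen pairs; companion Jaccard matrices divide by the
union so hit-rich screens do not dominate. Screen clustering uses
average linkage on distance 1 − mean(Jaccard_act, Jaccard_rep), cut at
k = 2; the cluster with the higher mean within-group activator Jaccard
is group 1. The published orderings of such heatmaps are typically
partly manual; the deterministic rule plus the reported silhouette makes
the partition reproducible. All-identical screens (zero distances) yield
a degenerate tree and are reported `unassigned` rather than forced into
two groups.

## Synthetic-data generator

The generator emulates the experimental design, not any particular
dataset:

- **Infection** — exactly one guide per cell. At MOI 0.3 roughly 84% of
  infected cells carry a single guide (Poisson); multi-infection is not
  modeled.
- **Library representation** — guide frequencies drawn once per screen
  from Dirichlet(α) with αᵢ = 300·Uᵢ, Uᵢ ~ Uniform(0,1), giving
  realistic moderate skew shared across replicates (the plasmid pool is
  common to all).
- **Reporter** — log-normal baseline (defaults μ = 7.0, σ = 0.6 on the
  natural-log scale, i.e. arbitrary FACS units with ~60% CV), multiplied
  by 2^effect of the cell's targeted gene. FACS intensities are
  log-scale, hence multiplicative effects.
- **Artifact** — cells carrying guides against a flagged
  centromere-proximal gene lose the reporter entirely (value 0) with
  penetrance f (default 0.6), a bimodal loss mirroring reporter-allele
  deletion; ties among zeros are broken randomly before sorting.
- **Sorting and sequencing** — per replicate, the bottom and top
  `sort_fraction` (default 5%) of cells by reporter value are selected;
  each bin is a Multinomial(reads_per_bin, sorted-cell guide
  composition) draw.

Defaults are 6 replicates, 10⁶ cells and 2×10⁵ reads per bin — a
desk-scale rendering of screens that sorted millions of cells per bin;
the 5% tails of 10⁶ cells give 10× coverage of an 8,100-guide library,
and a warning fires below that. The generator does **not** model PCR
duplication, sequencing error beyond optional uniform substitution,
doublets, cell-cycle or viability effects; passing tests demonstrate
correctness of the analysis under the stated statistical model, not
robustness to every artifact of real screens.

## Problem sizes and numerical choices

The test suite and the acceptance script run the scoring stage at 2,000
genes × 4 guides + 100 controls, 6 replicates, 10,000 permutations
(seconds per screen); unit tests use 50–200-gene screens. The
Brunello-scale reference check builds all 929,292 records (12 × 77,441)
in memory. Pseudocount 0.5 on bin ratios; score ties broken by sgRNA id;
permutation sampling rejects duplicate draws (collision probability is
negligible at pool sizes ≥ a few hundred, so rejection is cheap);
exhaustive enumeration is refused above 5×10⁵ combinations. Seeds
propagate from a single configuration value to every stochastic stage;
all outputs are bit-reproducible, which the pipeline manifest verifies
by hashing every artifact.

## Known limitations

- The per-guide statistic ignores count overdispersion across
  replicates; very low-depth screens will be noisier than the empirical
  control null suggests.
- The permutation null pools genes of equal guide count; this assumes
  exchangeability of guides across genes, which planted simulations
  satisfy but strong library-wide composition effects could violate.
- The centromere filter needs centromere coordinates and gene bodies; it
  does not model partial-arm deletions or per-cut-site deletion sizes.
- Group labeling (which cluster is "group 1") relies on within-group
  activator Jaccard and can be ambiguous when both blocks share both
  senses equally.
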