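# Methods

## Scope and model

`tmamine` re-implements, as a reusable library, the data-mining layer of a
case/control shotgun-metagenome study of TMA-synthesis capacity: everything
downstream of read mapping. Read QC, assembly, gene prediction and the
alignment runs themselves (DIAMOND/BLASTP) are out of scope; the package
consumes their tabular outputs.

## Abundance profiling

Genes are retained when their mapped reads summed **across all samples** reach
`min_total_reads` (default 2). The threshold's basis (per sample vs. total) is
genuinely ambiguous in the field's usual phrasing; total-across-samples is the
more permissive reading and is exposed as a parameter.

Gene abundance is the pure ratio `count / length_bp` with no per-kilobase
rescaling: every downstream statistic (OR, rank-sum, Spearman) is invariant
to a global scale, so the constant would be cosmetic.

Feature abundance sums the abundances of the genes annotated to the feature.
Relative abundance is computed **within one feature universe at a time** (KOs,
modules, enzyme families, genera separately): each universe is the natural
comparison family for its figures and tests, and mixing universes would make
the proportions depend on annotation coverage elsewhere. Module membership is
many-to-many, so a gene's abundance may legitimately count into several
modules; mass conservation holds per feature, not across the module universe.

## Annotation

KO assignment considers hits with **bit score strictly > 60** whose subject
carries a KO label and takes the highest-scoring one. The tabular `bitscore`
column is treated as the HSP score; raw HSP scores are not available in
outfmt-6 output. Enzyme-family assignment applies three strict best-hit
filters — E-value < 1e-5, identity > 50 %, coverage > 50 % — with coverage
defined on the **query** (`100 × alignment_length / query_length`), since the
catalog gene is the object being annotated. Ties on bit score break by smaller
e-value, then lexicographically smallest subject id, making annotation
deterministic under any row order. A gene may hold both a KO and an enzyme
family: the two searches are independent passes against different references.

## Taxon attribution

For each gene, hits with `e_value ≤ 10 × min(e_value)` are the valid matches;
the gene is placed at the LCA of their taxa. A top e-value of exactly 0
admits only other exact zeros — no epsilon is injected, because inflating a
zero would silently widen the window by an arbitrary amount. Genes whose LCA
lies above genus are reported with their rank but excluded from genus
abundance (MEGAN-like conservatism); consequently genus-level mass is bounded
by the total mass of attributed genes. No minimum number of valid matches is
imposed — a single confident hit assigns — but `n_valid_matches` is emitted so
users can filter. MEGAN's min-support/min-score knobs are deliberately not
emulated; only the 10× rule is.

## Odds-ratio enrichment

For feature *k* within one universe,

    OR(k) = [Σ_{s∈AF} A_sk / Σ_{s∈AF} Σ_{i≠k} A_si] /
            [Σ_{s∈CTR} A_sk / Σ_{s∈CTR} Σ_{i≠k} A_si].

The orientation question is real: the formula can be written with either arm
in the numerator, and the two readings are exact reciprocals. This package
puts the **case (AF) ratio in the numerator** so that the classification
labels — AF-enriched at OR > 2, CTR-enriched at OR < 0.5, both strict —
read in the natural direction; `orientation="printed"` flips to the literal
control-numerator form for anyone who wants the reciprocal convention. The
complement sum `Σ_{i≠k}` is always taken within the same universe as *k*;
complements across universes would double-count genes shared between KOs and
the modules containing them.

Zero handling: when any of the four sums is 0 the default `pseudo` mode
substitutes half the smallest nonzero sum of its kind (feature sums and
complement sums pooled separately across features and arms), keeping every OR
finite and classifiable — the same spirit as a half-minimum pseudocount in
compositional analysis. `zero_mode="exact"` yields 0/∞ instead, and an
all-zero matrix is an error.

Note that OR is a statistic of *shares*: scaling a sample's whole column (a
depth change) cancels after relative normalization, but perturbing a single
feature shifts every other feature's OR slightly. This compositional echo is
visible in the worked example (planted enrichment induces small apparent
depletions elsewhere) and is why classification requires the OR threshold,
not the q-value alone.

## Rank-sum tests, q-values, Z-scores

Per feature, a two-sided Wilcoxon rank-sum test compares the two contrast
arms: the exact null distribution when both arms have ≤ 12 samples and the
data are tie-free, otherwise the tie-corrected normal approximation
(`scipy.stats.mannwhitneyu`). All-tied data is defined as p = 1. BH
correction (`statsmodels`) is applied within each feature universe and each
contrast separately — each (universe, contrast) pair is one testing family.
The three built-in contrasts are CTR vs AF, PAF vs psAF, and persistent < 12
months vs > 12 months; subtype contrasts report rank-sum statistics only (the
OR is a case/control construct). Z-score profiles standardize each feature
row with the sample standard deviation (ddof = 1); zero-variance rows map to
zero.

## Correlation network

Spearman correlation is computed as Pearson on midrank-transformed rows, with
two-sided p from the t approximation `t = r √((n−2)/(1−r²))`; |r| = 1 maps to
p = 0 and constant rows to (r = 0, p = 1). Correlations use all samples
pooled (cohort-wide associations); within-group networks are available by
subsetting samples first. BH runs over the entire tested block (e.g. all
genus × enzyme pairs), then edges require q < 0.05 **and** |r| > 0.4, both
strict, with a `strong` flag at |r| > 0.6 and a significance tier ("+" for
q < 0.05, "**" for q < 0.01). The tripartite network keeps only genera and
functions with at least one enzyme edge; node order is by descending edge
count then id, so exports are stable. The export is a neutral node-link JSON
plus a TSV edge list — no plotting dependency.

## Synthetic study generator

The generator emulates the study design the pipeline targets: 50 controls and
50 AF patients, the AF arm split 30/12/8 into paroxysmal, persistent < 12 m
and persistent > 12 m. Defaults: 200 KOs × 3 genes (600 genes), lengths
uniform on 300–3000 bp, 25 modules (many-to-many KO membership), 40 genera
under 4 phyla.

Counts: `mean(g, s) = depth_s · (length_g/1000) · reads_per_kb · expr_g ·
effect_gs`, with `expr_g` log-normal (σ = 1), `depth_s` log-normal
(σ = 0.15), `reads_per_kb = 30`, and negative-binomial observation noise with
shape 8 (variance m + m²/8). Shotgun gene counts are overdispersed and
length-proportional; this is the simplest model with those two properties.
The real catalog's abundance distribution is unknown, so these parameters are
configuration, not fact — they give counts in the tens-to-hundreds with
realistic noise, and nothing downstream assumes the model's form.

Planted effects multiply the mean of a feature's genes by `fold_change` in
one arm (default study: 12 orthologs and 4 enzyme-harboring genera, one per
family, at fold 4 in AF). Every annotated gene gets one true hit passing all
filters; decoys arrive at `decoy_hit_rate = 0.1` in flavors that each fail
exactly one defense: sub-threshold bit scores, subjects without a KO label,
enzyme hits failing one of identity/coverage/e-value, and taxonomy hits to a
wrong genus with the e-value inflated 50–10⁴× beyond the valid-match window.
Ground truth maps one genus per gene — ambiguity enters only through decoys,
so recovery is well defined.

One `numpy` generator stream, seeded once, drives all draws in a fixed order
(lengths → KO assignment → genus assignment → enzyme-gene choice → baselines
→ depths → counts → functional hits → taxonomic hits), so a fixed seed gives
byte-identical bundles.

**What the generator does not emulate:** real taxonomic correlation structure
between genes of one genome, strain-level mosaicism, horizontal transfer,
compositional zero-inflation at low depth, or realistic alignment-score
distributions. Passing tests therefore demonstrate the statistics and filters
behave as specified under a controlled data-generating process — not that the
pipeline's biological conclusions transfer to any particular real cohort.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 50 + 50 design at 600 genes ×
200 KOs; null calibration uses 20 seeds (4 000 feature tests) and oracle
comparisons use ~200–1000 random matrices and 100 random LCA queries on
500-node trees. These sizes make every statistical margin wide (planted
recovery and genus attribution sit at 100 %, the null AF-call rate at 0)
while the whole suite runs in seconds.

Tolerances: oracle equivalence for the OR is asserted at 1e-12 relative;
relative-abundance columns at 1e-9; Z-score moments at 1e-9. Wilcoxon's
exact/asymptotic switch is at arm size 12. The `pseudo` OR mode is the
default because classifiable ORs are what the enrichment tables exist for.

## Known limitations

* The fourth feature map (protein → taxonomy node) is a simple TSV; NCBI
  `nodes.dmp/names.dmp` parsing is not implemented.
* Covariates (age, diabetes) are not modeled; enrichment is marginal.
* Subtype-stratified ORs are intentionally absent — subtype contrasts are
  rank-sum only.
* Correlation edges are associations on compositional data; no causal or
  directional reading is supported.
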