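# Methods

This note documents the models and procedures implemented in
`chromadapt`, the defaults chosen where the underlying study design
leaves them open, and what the synthetic-data generator does and does
not emulate.

## Study design and coordinates

The design is a 2 × 2 × 4 × 2 factorial: varieties {sensitive,
tolerant}, treatments {C, D}, stages {ID, MD, SD, RW}, two biological
replicates. Replicates are merged for chromatin analyses, giving 16
Hi-C samples; expression analyses keep replicates for testing and
average them (FPKM) for descriptive quantities. All genomic
coordinates are 0-based half-open (BED dialect) in memory and on disk;
GFF3 output converts to 1-based inclusive as the format requires.

## Differential expression and drought-induced genes

The internal caller tests each gene on log2(x + 1) transformed
abundances with a moderated t statistic: per-gene pooled variances are
shrunk toward the across-gene median with `prior_df = 10`
pseudo-degrees of freedom, and p-values use a t distribution with
(residual + prior) degrees of freedom, followed by Benjamini–Hochberg
correction. A plain per-gene Welch test was considered and rejected:
with two replicates per arm it has two residual degrees of freedom and
essentially no power after multiplicity correction, which defeats the
design it must serve. Variance moderation is the standard remedy for
exactly this regime. External DE tables (from any tool) can be loaded
in place of the internal caller; only the direction contract matters
downstream: `direction ≠ ns` implies `padj ≤ alpha` and a matching
fold-change sign. Defaults: `alpha = 0.05`, `lfc_threshold = 1`
(log2).

A gene is *drought-induced* when it is non-ns in at least one of ID,
MD, SD and all its non-ns stages agree in direction. RW is reserved
for recovery: induced genes that are ns at RW are *recovered*, non-ns
are *still differential*, and genes absent from the RW table are
counted as *missing* rather than dropped. The recovered /
still-differential counts of the two varieties form a 2×2 table tested
by Pearson chi-square with 1 df; the Yates continuity correction is
off by default but exposed, since the qualitative conclusion should
never hinge on it. The descriptive "expressed gene" floor is FPKM ≥ 1,
configurable — no principled universal value exists.

## Homoeolog bias

Bias states use `log2((At + ε) / (Dt + ε))` with pseudocount
`ε = 0.1`, cutoff `|ratio| ≥ 1` (twofold), and an expression floor:
pairs with both homoeologs below 1 FPKM are called unbiased, because a
ratio of near-zero quantities is noise. All three knobs are
configurable and recorded in the output metadata. The bias-change
index is the drought state minus the control state per pair
(in [−2, +2]); its sum over pairs is the genome-wide bias value,
positive meaning an A_t-ward shift. Stability classes over the four
stages require a *strict* inequality in the same direction at every
stage; exact ties count as "not higher", so an all-tie pair is
dynamic. Pairs with a missing homoeolog measurement are excluded and
counted (`n_excluded`), not silently treated as unbiased.

## A/B compartments

Per chromosome: observed/expected normalization by the per-distance
mean (a deterministic, dependency-light stand-in for loess-smoothed
z-scoring that has the same contract at this scale), Pearson
correlation matrix, first eigenvector. All-zero bins are masked before
normalization; bins whose O/E profile has zero variance are masked
after. The eigenvector sign is fixed by its covariance with a per-bin
orientation track (gene density by default): the A compartment is the
gene-rich, active state, so gene-rich bins are made positive. The
covariance rule was chosen over "mean over above-median bins" because
gene-density tracks at fine bins are frequently 0/1-valued, where the
above-median set can be empty; covariance degrades gracefully and
flips sign exactly under track negation. A bin is A where the oriented
value is > 0, B where < 0; exactly 0 is masked — the sign rule is
strict on both sides. Tracks whose first PC explains < 10% of the
correlation variance are flagged `low_signal` (no plaid structure).

Four-stage switch strings are classified by their first and last
letters (equal & constant → stable; equal & non-constant → ABA/BAB;
unequal → AB/BA), which reproduces the enumerated 2/4/4/3/3 partition
of the 16 strings exactly; the enumeration is pinned in the tests.
Genes belong to a switch region on any ≥ 1-bp overlap with a
non-stable bin.

## TAD comparison

The separation score for bin edge *i* and window *w* is the mean
contact between the *w* bins upstream and *w* bins downstream of the
edge, z-normalized per chromosome and averaged over windows (defaults
100 kb and 200 kb at 20-kb bins). Lower = stronger insulation. The
optional caller takes local minima below `z_cut = −0.8` (minima closer
than 3 bins keep the deepest) as boundaries and tiles the chromosome
between them. These two caller constants are algorithmic choices of
this package's caller, not properties of the comparison algebra, which
accepts TAD sets from any caller.

Boundary matching flanks each position by ±40 kb (80 kb total) and
declares two boundaries conserved on ≥ 1 bp of region overlap.
One-to-many cases resolve by best reciprocal overlap; ties break by
smaller position distance, then leftmost partner. Pan-boundary maps
accrete ID → MD → SD → RW (a flag permits other orders for sensitivity
checks), then re-map each stage onto the final set by one-sided best
overlap — re-mapping must be one-sided, or a boundary matched during
accretion could fail a reciprocal test against later additions and map
nowhere. The representative position of an entry comes from the
earliest contributing stage.

Fusion requires a drought TAD whose outer boundaries match (flank
rule) the outer boundaries of ≥ 2 gap-free consecutive control TADs
with ≥ 1 internal control boundary unmatched in drought; neo-TAD is
the symmetric condition with roles swapped, which makes the
fusion/neo duality hold structurally. Outer-boundary conservation is
strict (both ends), per the stricter reading of the definition; the
flank is configurable. Hotspots tile the genome in non-overlapping
10-Mb windows (merging "consecutive" regions presupposes discrete
adjacent windows), qualify strictly above 8 boundaries of one type,
and merge adjacent qualifying tiles. The cross-sample pan set over 16
samples runs reciprocal-best matching between every pair of sets and
takes connected components of the match graph — equivalent to merging
per-reference unions, and symmetric in the inputs, hence
order-invariant.

## Network integration

Edge filtering is strictly greater than 0.2, following the stated
threshold wording. Hubs maximize the sum of incident *intra-module*
edge weights, ties broken lexicographically. Module detection is out
of scope: connected components of the filtered network act as a
clearly labelled stand-in for an external co-expression tool's modules
in fully synthetic runs. Module profiles z-score each gene across
samples (zero-variance genes masked) and average over module genes.
Fisher enrichment is one-sided (greater), since enrichment is the
question being asked, with BH across terms. The target screen is pure
set algebra: per-variety intersection of the three evidence sets, then
shared/specific across varieties; the TAD-change evidence uses genes
within 20 kb per side of dg/dl boundaries by default (10 kb
selectable for the narrower boundary-region convention).

## Synthetic-data generator

The generator emulates the full study at desk scale. Defaults: 2
chromosomes per subgenome × 6 Mb at 20-kb bins, 800 genes, homoeolog
fraction 0.8 (320 pairs), 12 TADs per chromosome, intra-TAD
enrichment 2.0, distance-decay exponent 1.0, checkerboard amplitude
0.3 with a 600-kb block period, multiplicative log-normal contact
noise (σ = 0.1), and 2 fusion + 2 neo events per drought sample.
These sizes keep a complete 16-sample study within seconds on one CPU
while leaving every structure several bins wide.

Expression: negative-binomial counts (gamma–Poisson, dispersion 0.1)
around log-normal gene baselines (log2 mean 5, SD 1.5). A gene is
drought-down with probability 0.30, drought-up with 0.15; planted
log2 effects deepen with stage (ID 1.0, MD 1.8, SD 2.5) and
responsive D_t genes get an extra −0.5 — the subgenome asymmetry. The
extra shift is validated to stay below every per-stage magnitude so
truth labels always match the model's sign. At RW each responsive
gene has recovered with probability 0.3 (sensitive) or 0.85
(tolerant); unrecovered genes retain the SD-level effect. Homoeolog
partners inherit each other's response class with probability 0.9 and
diverge from a shared baseline with log2 SD 1.0 — uncorrelated draws
would make opposite-direction pairs an order of magnitude more common
than observed in real allotetraploids and leave the planted
subgenome asymmetry statistically invisible at 320 pairs. Gene-rich
bins are A-compartment (3:1 placement preference, +1 log2 baseline
boost) and boundary-proximal genes get +0.75 log2, reproducing the
qualitative A-versus-B and boundary-expression contrasts.

Contacts: matrix = depth × (1+d)^−γ × compartment checkerboard ×
intra-TAD enrichment × noise, symmetric and positive by construction.
Compartment switch points snap to TAD boundaries (as compartment
transitions do in real genomes); an independent periodic checkerboard
would put genuine insulation edges mid-TAD, which any honest caller
reports as boundaries the truth set does not know about. Homoeologous
chromosome pairs share one partition (synteny). Drought samples carry
planted fusions (internal boundary removed) and neo events (boundary
added mid-TAD), chosen so no two removals are adjacent and no event
touches a compartment switch point; the last D-subgenome chromosome
is never perturbed, serving as a negative control for false event
calls. One RNG child stream per output family (genome, expression,
contacts) derives from the master seed, so regenerating one family
never perturbs another, and identical configs reproduce byte-identical
outputs.

What the generator does *not* emulate: read-level noise and mapping
artifacts, sequence content, ligation-junction chemistry, copy-number
or mappability-driven masked regions, nested/hierarchical TADs,
compartment strength varying along the chromosome, or stage-dependent
compartment switching (the planted phase is constant across stages, so
pipeline switch tables on synthetic data are legitimately all-stable;
the switch taxonomy is validated by exhaustive enumeration and
constructed tracks instead). Passing planted-recovery tests therefore
demonstrates correctness of the algebra and calling machinery under a
clean generative model, not performance on sequencing artifacts.

## Known limitations

- The separation-score caller is deliberately minimal (single-scale
  local minima); real data with nested domains needs an external
  caller, whose TAD sets the comparison algebra accepts directly.
- The moderated-t DE caller assumes roughly log-scale homoscedastic
  replicates; severely depth-imbalanced libraries should be called
  externally and loaded as tables.
- `.cool`/HDF5 matrix input is not supported; matrices travel as dense
  text with a JSON sidecar, which is adequate at the scales this
  package targets.
- The hotspot tiling is fixed-grid, so a cluster straddling a tile
  edge can split below threshold; this is inherent to the
  discrete-window definition implemented.
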