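# Methods

## Scientific problem

GC-biased gene conversion (gBGC) is a meiotic repair bias that
preferentially transmits G/C alleles at GC:AT heterozygous sites.  In
genomic regions with high recombination rates it drives GC-content
upward regardless of the fitness effects of the fixed alleles.  A
lineage that acquires unusually strong or unusually stable recombination
hotspots therefore leaves a characteristic molecular signature in its
protein-coding genes: an excess of weak-to-strong (AT→GC, "WS")
substitutions relative to strong-to-weak (SW), an elevation of *all*
substitution categories (the mutagenic side-effect of recombination),
spatial clustering of the affected genes, and a climb of those genes
toward the top of the GC3 distribution of their wider gene families.

This package detects that signature on a fixed rodent species tree with
a human outgroup: two gerbil species (*Psammomys obesus*, *Meriones
unguiculatus*) are compared against two murine species (*Mus musculus*,
*Rattus norvegicus*), with substitution rates measured along the path
from the murine–gerbil divergence (the `Muridae` node) to each focal
tip.

## Model

Codon evolution follows the YN98 codon model with F3X4 frequencies: the
instantaneous rate of a single-nucleotide change from codon *i* to codon
*j* is

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous]

where π_j is the stationary frequency of the target codon (product of
position-specific nucleotide frequencies renormalized over the 61 sense
codons of the standard genetic code), κ the transition/transversion
ratio and ω = dN/dS.  Multi-position changes have rate zero; stop codons
are outside the state space.  The matrix is scaled to one expected
substitution per codon site per unit branch length.

For forward simulation only, the model is extended with a weak-to-strong
bias multiplier `ws_bias ≥ 1` applied to all WS entries (synonymous and
nonsynonymous alike, since gBGC acts regardless of deleterious effect),
plus an overall `rate_multiplier` that emulates recombination-associated
mutagenesis.  Both are applied *after* scaling, so biased branches have
a genuinely higher realized substitution rate — matching the observation
that all mutational categories are elevated in GC-skewed genes.  The
fitted model always has `ws_bias = 1`; the elevated WS counts of biased
data are recovered by the substitution mapping, not by the fit.

Each single-nucleotide change between sense codons is classified by the
(from, to) bases at the changed position — A/T are weak, G/C strong —
into WS, SW, WW or SS, crossed with synonymous/nonsynonymous for eight
mutational categories.

## Rate estimation

Per gene, the species tree is pruned to the species present, and branch
lengths plus κ and ω are estimated by maximum likelihood under
YN98(F3X4) with empirical positional frequencies (pooled over the
alignment, with a pseudocount of 0.5 per base so the symmetrized
eigendecomposition is defined).  The likelihood uses Felsenstein pruning
over compressed site patterns with per-node scaling; the reversibility
of the model gives transition matrices from a single symmetric
eigendecomposition per (κ, ω).  Branch lengths are optimized by L-BFGS-B
with an analytic gradient (outside/inside partial vectors), alternating
with Nelder–Mead over (log κ, log ω), for two rounds with a convergence
tolerance of 1e-6 log-likelihood units.  κ is bounded to [0.05, 100] and
ω to [1e-4, 20]; unbounded optimization can escape to a degenerate
reducible-chain corner on pathological near-constant alignments.
Alignments with no variable site return all branch lengths exactly zero.
Codons containing N, gaps or stops are treated as missing data.

Expected substitution counts per branch and category are computed
analytically (no stochastic mapping): for label set *C*,

    E[N_C | data] = Σ_sites Σ_ij  G_i · M_C(t)_ij · D_j / f_site ,
    M_C(t) = ∫₀ᵗ e^{Qs} Q_C e^{Q(t-s)} ds ,

where Q_C restricts Q to the category's changes and the integral has a
closed form in the eigenbasis.  By linearity the eight categories sum
exactly to the total expected substitutions per branch.  Each category's
rate divides its expected count by the category-specific mutational
opportunity: Nei–Gojobori-style site counts (each sense single-nucleotide
neighbour contributes 1/3 site to its category) averaged over the
posterior ancestral codon distribution at the branch's parent node.
Whether rates are per-site or per-opportunity is a convention; the
per-species × category normalization downstream makes the outlier
analysis invariant to it.  Focal-species rates sum branch rates along
the unique path from the `Muridae` node to the tip.  Rates above 1
(saturation) are reported as computed, never capped.

## Outlier calling and comparisons

Raw rates are divided by the mean of their species × category over all
genes with a finite value (mean, not median, with no trimming); genes
with normalized dS_WS strictly greater than 2.5 are outliers.  The
strict inequality leaves boundary genes unflagged.  Downstream
comparisons: one-tailed Wilcoxon rank-sum of outliers vs non-outliers
for the other categories, chi-squared co-occurrence of flags (2×2,
no continuity correction), Kruskal–Wallis across species on GC3 with
Dunn z-tests and Benjamini–Hochberg correction as follow-up, and the
"chimney" fraction — the share of dS_WS outliers with dS_WS > dS_SW.

Alignment filters (in order): drop alignments whose longest ungapped
sequence is under 400 bp; mask sequences whose gap count exceeds 40% of
the non-gap length of the longest sequence; drop alignments with more
than two non-protected species masked or missing (the outgroup and four
focal species are protected).

## Spatial statistics

The permutation null reassigns the observed number of outliers to random
genes of the analyzed universe without replacement.  Two statistics:

* **mean inter-outlier distance** — midpoint-to-midpoint distance of
  consecutive outliers within chromosomes, averaged; chromosomes with
  fewer than two outliers contribute nothing; cross-chromosome pairs are
  excluded (left-tail test);
* **island gene count** — number of outlier genes in maximal runs of ≥ 2
  genes consecutive in the universe's gene order and all flagged
  (right-tail test).  Adjacency is defined on the analyzed universe, not
  all annotated genes, so the null permutes over exactly the same
  objects.

Monte-Carlo p-values use the (k+1)/(N+1) estimator; when C(n, k) ≤ 1e5
the null is enumerated exhaustively and p is exact (k/N over all
placements).  Because the island count is a small integer, heavy ties
make the plain Monte-Carlo p-value super-uniform and lumpy; a
tie-randomized p-value (strict exceedances plus a uniform share of the
ties), which is exactly uniform under the null, is also returned and is
what the calibration diagnostics test.  Default N is 10,000; 10⁶ is
available by flag.

The sliding-window scan tiles each chromosome from zero with 1 Mb
windows stepped by 0.25 Mb (a 0.5 Mb/0.1 Mb secondary configuration is
exposed through the same flags); a gene belongs to a window when its
midpoint lies in [start, end); windows with ≥ 4 genes and mean
normalized dS_WS strictly above 2.5 qualify, and overlapping or abutting
qualifying windows are collapsed into regions.  The mean/WS-category
combination is the primary definition; the window statistic (median) and
category are options.

Subtelomeres are the 5 Mb at either end of each chromosome (gene
midpoint rule; 2×2 chi-squared without continuity correction).  On a
genetic map the margin is 2.85 cM, derived as 5 Mb × 0.57 cM/Mb (the
genome-average mouse recombination rate); a gene is flagged when its cM
position is within the margin of either end of its linkage group's
observed span.  Unmapped genes are reported separately.

## Family GC3 ranking

Each focal-species gene is ranked by GC3 within its gene family's
comparator sequences: rank = 1 + number of comparators with GC3 ≥ the
focal value.  Ties count against the focal gene (pessimistic rule,
chosen to make the "top three" classification conservative).  Enrichment
tests: per-species top-3 proportions with a chi-squared across species,
one-tailed rank-sum of family ranks for outliers vs non-outliers, and
top-3 × outlier contingency tests (Fisher per species; chi-squared for
the cross-species comparison of outlier shares among top-3 genes, since
the exact test is only implemented for 2×2 tables).

## Synthetic data: what it emulates and what it does not

The generator produces the full input bundle deterministically from a
seed: per-gene codon alignments evolved by event-resolved CTMC sampling
(so true per-branch per-category substitution counts are available as an
estimator oracle), a genome layout, a genetic map (cM = Mb × 0.57), gene
families with independently evolved neutral paralogs, and a ground-truth
table.

Default study conditions, chosen once: 200 genes on five 50 Mb
chromosomes; gene lengths log-normal around 300 codons (floor 140
codons, so no gene falls under the 400 bp quality filter by
construction); κ = 3, ω = 0.15, mildly GC-rich F3X4 frequencies
(stationary GC3 ≈ 0.53); the 11-taxon tree has gerbil paths of 0.30 and
murine paths of 0.20 substitutions/site from the `Muridae` node,
consistent with the ~21 My divergence.  gBGC is applied on the
Gerbillinae stem *and* both gerbil terminal branches, since the skewed
regions predate the within-gerbil divergence.  The frozen recovery
conditions plant two 3 Mb regions of 14 evenly spaced genes each
(14% of genes) with `ws_bias = 6` and `rate_multiplier = 2`; even
spacing guarantees every interior 1 Mb window holds ≥ 4 genes.  A tenth
of the remaining genes is placed inside terminal 5 Mb windows to
exercise the subtelomere statistics.

The genome scale (200 genes, 250 Mb) is deliberately reduced relative
to a real mammalian gene set; it preserves gene density, window
geometry, and subtelomere fractions while keeping a full pipeline run
on one CPU in minutes.  What the simulation does *not* emulate: indels
and alignment error (alignments are gap-free unless corrupted
deliberately), rate heterogeneity across sites, CpG-context mutation,
isochore-scale base-composition heterogeneity, karyotype differences
between species, and real orthology/paralogy structure (families are
star-shaped neutral paralogs).  Passing recovery tests therefore
demonstrate the correctness of the inference machinery under the model,
not robustness to real-data artefacts.

Because the planted genes enter the per-species mean, mean-normalization
compresses their normalized values; with ≥ ~40% of genes planted the
threshold of 2.5 becomes unreachable.  The recovery conditions keep the
planted fraction at 14%, where planted genes normalize to ≈ 4–5.

## Numerical choices

* Transition matrices and expected-count integrals come from one
  symmetric eigendecomposition per (κ, ω); divided differences with
  |Δλ| < 1e-10 fall back to the confluent limit t·e^{λt}.
* Likelihood scaling is per node and per pattern (log-sum bookkeeping);
  negative round-off in transition probabilities is clipped at zero.
* Branch-length bounds [0, 20]; pairwise-mismatch initialization;
  ftol 1e-10 within L-BFGS-B, outer tolerance 1e-6 log-likelihood.
* Degenerate inputs: an all-zero species × category mean makes that
  category's normalization undefined (reported, not silently dropped);
  zero-opportunity categories get rate 0; chromosomes shorter than twice
  the subtelomere margin are wholly subtelomeric and warned about.
* Ties at the 2.5 threshold are not outliers (strict inequality).

## Known limitations

* The two root-adjacent branches are confounded (reversible model);
  this does not affect path sums from `Muridae`, which is never adjacent
  to the root here.
* κ and ω are point-estimated per gene with modest optimizer budgets;
  they are nuisance parameters for the category rates, which are robust
  to small residual misfit.
* The expected-count estimator is conditioned on the fitted model being
  the generating one; under strong unmodelled gBGC it attributes the
  excess WS changes correctly in direction but the absolute rates on
  biased branches inherit the model misfit (by design — the same is true
  of the original analysis stack).
* Exhaustive permutation mode is limited to C(n, k) ≤ 1e5 placements.
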