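# Methods

This note documents the models and procedures implemented in `crossbiome`,
the choices made where several defensible readings existed, and what the
synthetic-data tests do and do not demonstrate.

## Problem setting

Aquatic bacteria partition sharply among freshwater (<0.5 PSU), brackish
(0.5–30 PSU) and marine (>30 PSU) biomes, and lineages cross between these
salinity classes only rarely. Given a biome-labeled, time-calibrated
phylogeny of metagenome-assembled genomes (MAGs), pairwise ANI, predicted
proteomes and a KO (KEGG Orthology) gene-function table, the pipeline
quantifies: how distinct the biome-specific species pools are, where on the
tree the most recent cross-biome transitions happened, in which direction,
and which proteome-level and gene-content changes accompany them.

## Species clustering and overlap (clustering)

Genomes are clustered agglomeratively on the distance d = 100 − ANI with
the dendrogram cut at 100 − threshold (threshold 95% by default, the
operational bacterial species boundary). Complete linkage is the default
(hclust's default); single and average linkage are selectable. Missing ANI
pairs — aligners skip distant pairs — are treated as distance 100 and can
never merge. Clustering is delegated to `scipy.cluster.hierarchy`; ties at
equal merge heights are broken by scipy's deterministic condensed-order
rule, so results are reproducible for a fixed input order (random real-
valued ANI essentially never ties).

Cluster overlap between two biomes is `shared / mean(total_A, total_B)`,
where a biome's total counts every cluster containing that biome (shared
clusters count toward both). On the published cluster counts this
reproduces the printed 0.7% (freshwater–brackish) and 0.5%
(brackish–marine) to one decimal. Two sharing proportions are compared by
a two-sided Fisher exact test on the 2×2 table conditioned on the side
with fewer clusters: `[[shared_1, smaller_total_1 − shared_1], [shared_2,
smaller_total_2 − shared_2]]`.

## MSG detection (treeops)

Polytomies (from near-identical genomes) are resolved in seeded random
order and all zero-length branches set to ε = 5×10⁻⁴, so the tree is
strictly bifurcating with positive branch lengths; the resolution seed is
recorded because topology near polytomies can affect sister-pair
detection. The tree is then pruned to one representative per ANI cluster
(or per biome within clusters spanning biomes), chosen as the genome with
the highest completeness − contamination (ties to the smallest id);
degree-2 nodes are suppressed with branch lengths summed.

A monobiomic sister group (MSG) pair is an internal node whose two child
clades are each monobiomic for different biomes — the signature of a most
recent cross-biome transition. A single postorder sweep enumerates every
such node; child clades of distinct qualifying nodes are provably
disjoint, so each transition is counted once. Each pair carries its type
(FB/BM/FM, unordered), MRCA age when node ages are annotated, and the
deepest taxonomic rank shared by all members (ranks with missing
annotation are skipped upward). Within each MSG of ≥2 tips, the two child
clades of the MSG's own node (its oldest internal split) serve as the
same-biome "no transition" comparison pair.

## Permutation null (nulls)

Tip biome labels are shuffled (multiset preserved) and MSG pairs
re-detected on the fixed topology; the rounded mean per-type count over
iterations is the expected number. One-sided empirical probabilities count
iterations strictly below/above the observed count over n_iter; ties count
toward neither side (so p_low + p_high ≤ 1), and an empirical 0 means
"< 1/n_iter" and is flagged. Observed type counts are compared to expected
type fractions with a one-sample chi-squared test (df = 2, no continuity
correction); a zero expected fraction with nonzero observations yields an
infinite statistic, flagged rather than masked.

## Mk-ARD ancestral states and directions (ancestral)

The biome character follows a 3-state continuous-time Markov model with
six free rates (all-rates-different). The likelihood is computed by
Felsenstein's pruning algorithm with per-node rescaling; P(t) = exp(Qt) is
obtained from one eigendecomposition of Q per evaluation (scipy expm
fallback near defective Q), with transition probabilities floored at
1e-300 so numerically unresolvable entries cannot zero out a subtree.

Two root treatments are implemented. Fitting maximizes the likelihood
under FitzJohn-style conditional weighting (each root state weighted by
its share of the root partial likelihoods). Marginal (empirical-Bayes)
reconstruction at internal nodes uses the flat unnormalized root, which is
also what an exhaustive sum over internal-state assignments computes; the
oracle tests compare against that enumeration exactly. The six rates are
optimized by multi-start L-BFGS-B on log-rates. The bounds [1e-8, 1e3] are
per unit *mean* branch length: branch lengths are internally normalized to
mean 1 (and the fitted Q rescaled back), which keeps the optimization
well-conditioned whether branch lengths are substitutions/site or Ma.
Monomorphic tip data short-circuit to the zero-rate boundary.

Transition directions use a biome-balanced downsampling protocol: per
iteration, one random tip is kept from every MSG; additional non-MSG tips
are then drawn so each biome has the same tip count (the smallest
per-biome count after MSG collapsing); the model is refitted on the
restricted tree and the marginal at each pair's MRCA recorded. Marginals
are averaged over iterations; per type a Wilcoxon rank-sum test compares
the two origin-biome likelihood vectors across pairs (rank-sum rather than
a paired test is a deliberate fidelity choice to the procedure being
reproduced). A pair is called "into X" when the other biome's mean origin
probability exceeds 0.5 — i.e. beats both alternatives combined. If a
biome's MSG representatives alone exceed the balance target (possible only
in engineered datasets), all representatives are kept with a warning
rather than failing; a biome with zero tips is an error.

## Proteome physicochemistry (proteome)

Per protein, the isoelectric point is the root of the
Henderson–Hasselbalch net-charge function over the N-terminus, C-terminus
and C, D, E, H, K, R, Y side chains, with the pepstats-compatible pK set
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1; overridable from a TSV). The charge is strictly decreasing in pH,
so bisection on [0, 14] converges to the unique root; iteration stops at
|charge| < 1e-4 (≈ ±0.003 pH, ample for 2-decimal reporting) or 100
halvings. A vectorized implementation runs the bisection across a whole
proteome at once and agrees with the scalar reference to tolerance.

Per genome: pI frequencies in 19 half-open 0.5-pH bins over [3.0, 12.5)
(outliers clamped into the terminal bins and counted), protein classes
acidic [3.0, 5.5) / neutral [5.5, 8.5) / basic [8.5, 12.5], and residue and
category frequencies over the concatenated proteome (non-canonical
residues excluded from numerator and denominator). Categories satisfy
polar ⊇ charged = acidic + basic. MSG profiles are unweighted means over
member genomes (weighting by proteome size is a documented open choice;
unweighted matches "average values over MAGs").

Pairwise comparisons orient every difference as value(more saline) −
value(less saline). Per transition type and per quantity (bin, class,
category, residue), a Wilcoxon signed-rank test asks whether the per-pair
delta is located away from zero (zero deltas dropped), Bonferroni-
corrected across the quantities tested within the type.

The total pI distribution change is the L1 distance between bin vectors
(∈ [0, 2]). Its relationship with divergence time is fitted as
y = α + β ln t per group (including the within-MSG "no transition" group);
the separation time between a transition group and the no-transition
reference is the earliest time on a 200-point log grid from which their
±1 SE mean-prediction bands no longer overlap anywhere to the right
(reported as none if they still overlap at the largest observed time).

For post-transition convergence, Δy = (cross-transition pI difference) −
(within-MSG pI difference) and Δt the corresponding age gap. Candidate
thresholds τ scan the observed Δt; the reported threshold is the largest τ
for which the one-sided signed-rank test of {Δy : Δt ≤ τ} > 0 is not
significant at 0.05 — the age gap up to which the transition has not yet
produced a measurable excess shift. The ≤ orientation is the one that
reproduces a planted changepoint (the excess lives at large Δt; a ≥-side
scan would always contain it and never localize the onset). τ candidates
with fewer than 5 points are dropped with a warning; "excess even at the
smallest gap" is reported as −inf ("< min").

## Gene content (genes)

Repertoire overlap between two genomes is 2·|shared KOs| / (|KOs A| +
|KOs B|). Overlap–time relationships are fitted per group as both
log(overlap) ~ t and overlap ~ t; groups are compared by least-squares
means — adjusted group means at the grand-mean time from a common-slope
ANCOVA with pooled residual variance. Gene-number differences across MSG
pairs (mean distinct proteins per MSG, saline minus fresher) are tested
per type with a signed-rank test, Bonferroni across the three types.

The paired differential-KO procedure: per iteration and type, one random
genome per MSG in each pair; the more complete genome's present KOs are
censored by independent Bernoulli deletion at rate 1 − c_low/c_high so
both genomes are observed at the same effective completeness (exact-count
thinning would match the count rather than the expectation; the Bernoulli
reading of "randomly downsampled to the level of the less complete MAG"
is adopted and the correction is switchable). Each KO present in ≥1 genome
of ≥1 MSG of the type is tested with a paired Wilcoxon across pairs —
which on binary data reduces to a sign test: exact binomial for ≤25
informative pairs, normal approximation with continuity correction above.
p-values are Benjamini–Hochberg adjusted within each iteration; the mean q
over iterations is compared to 0.1. Types with fewer than 5 pairs are
skipped with a warning. The completeness correction is the point of the
procedure: biome-correlated completeness otherwise manufactures
significant absences out of assembly gaps, and the test suite demonstrates
exactly that contrast.

The phylogeny-unaware counterpart thins every representative genome's
present KOs to the 75% completeness floor (retention 0.75/(c/100)), then
rank-sum-tests each KO between two biomes' species with BH correction. On
clade-structured data it flags taxonomically confounded KOs that the
paired analysis correctly ignores — reproducing, at desk scale, why the
paired design is the headline method. A gain–loss map marks each
significant KO as present in an MSG when >0.5 of the MSG's species carry
it (strictly greater, so a 1-of-2 split counts as absent).

## Synthetic data (simulate)

The generator produces, from one integer seed (per-step seeds are base
seed + step index): a Yule species tree scaled to a fixed age with node
ages; a biome history evolved by exponential waiting times under a 3×3
rate matrix; per-species ANI clusters (geometric sizes, within 97 ± 0.5%,
between 85 ± 2%, distant pairs omitted); i.i.d.-residue proteomes whose
D/E frequency rises (+2%/salinity step split between D and E) and proline
falls with salinity, which propagates to acidic pI classes by
construction; and a KO matrix of 60 core KOs (present everywhere), 120
accessory KOs evolving by equal-rate gain/loss along the tree (the source
of taxonomic confounding), and 10 planted differential KOs per transition
type (presence 0.95 in one biome of the type vs 0.05 in the other, 0.5 in
the third), all censored per genome at completeness/100 with completeness
uniform on [75, 100].

The demo study conditions are 200 species on a 1,000-Ma tree with
transition rates of (4–7)×10⁻³ per Ma — higher than the rare transitions
of the real compendium, deliberately, so that every transition type is
represented by enough sister pairs at desk scale. Because the per-type
pair count is topology- and history-dependent, the generator conditions
the (tree, biome history) draw on at least 16 sister pairs per type,
redrawing with derived seeds — the synthetic analogue of conditioning on
an observed study design. Below roughly 12 pairs per type the planted-KO
sign test cannot clear BH correction at any effect size, so unconditioned
histories would make recovery a coin flip of the seed rather than a test
of the method.

The direction-recovery scenario is constructed rather than simulated
forward, for an identifiability reason worth recording: under a
stationary Markov history the F→B and B→F *fluxes* equalize regardless of
rate asymmetry, so "strong F→B rate" plants no net direction; and truly
irreversible rates let brackish absorb the tree, leaving too few
independent recent pairs. The scenario instead joins three deep
monobiomic Yule regions as ((F, B), M) and grafts 40 freshwater→brackish
cherries (short stems, so the freshwater context sits directly above each
transition node) inside the freshwater region. The pure regions supply
long-timescale rate context; without enough such context surviving the
biome balancing, the globally best ML solution is a saturated symmetric
F↔B rate pair that explains the all-transition cherries as noise — a
failure mode we observed directly and sized the regions to defeat.

What the synthetic tests do not show: real proteomes are not i.i.d.
residue strings (no domain structure, no membrane/soluble split), real KO
repertoires are not independent Bernoulli draws, real trees are not pure
Yule, and real transition rates are far lower than the demo's. Passing
recovery tests demonstrates that the estimators find planted effects of
realistic sign and magnitude under the model's own assumptions — not that
those assumptions hold in nature.

## Problem sizes and runtime

Default test-suite sizes are desk-scale choices: 200 random trees (≤12
tips) for the MSG oracle in unit tests and 1,000 in the acceptance run;
40 + 100 random trees for the likelihood/marginal enumeration oracles;
150-tip trees × 5 replicates for rate-ordering recovery; 40-pair
scenarios for KO and confound recovery; 2–4 balanced-downsampling
iterations for direction inference (each iteration is internally a full
ML refit, and the planted scenario is decisive per iteration); 10,000
permutations for the worked 4-tip example.

## Known limitations

- The ARD fit reports the best of a finite number of quasi-Newton starts;
  the 3-state ARD surface is multimodal and a pathological dataset can in
  principle hide a better mode.
- Empirical p-values are limited to 1/n_iter resolution; zero is reported
  with a flag, not as (k+1)/(n+1).
- Marginal reconstruction is empirical-Bayes at the point estimate Q̂ (no
  rate uncertainty), matching the delegated behavior it reproduces.
- The least-squares-means contrast assumes a common slope across groups;
  strongly non-parallel groups would need an interaction model.
- Node ages are consumed, never estimated; trees without age annotations
  simply report missing ages.
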