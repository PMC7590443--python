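# Methods

## Data model and preprocessing

A scent dataset is a samples × compounds matrix of non-negative,
internal-standard-normalised amounts (arbitrary units) plus per-sample
metadata: species, individual, ripeness (`ripe`/`unripe`), site.  Missing
cells in delimited input are read as 0 — these are occurrence-style wide
tables in which an empty cell means "not detected", not "not measured".
"Present" means amount strictly > 0; no additional noise floor is imposed,
on the assumption that detection thresholds were applied upstream during
peak integration.

### Compound filtering

Four independent removal rules, each with a tunable threshold and each
logged to a machine-readable TSV (compound, rule, statistic):

| rule | default | removes |
|---|---|---|
| control contaminant | — | compounds whose mean amount in control (blank-chamber) samples is ≥ their mean in fruit samples |
| ubiquity | 0.9 | compounds present in > 90% of all non-control samples |
| rarity | 0.25 | compounds present in exactly one species and in < 25% of the dataset's samples |
| max share | 0.01 | compounds never exceeding 1% of any species' total emission (species-mean shares) |

The ubiquity rationale: a volatile detected in essentially every sample
across distantly related species is more plausibly a laboratory or ambient
contaminant than a genuine fruit compound.  "Predominantly in controls" has
no standard numeric definition; we operationalise it as mean(control) ≥
mean(fruit), the weakest rule that still removes anything that blanks emit
at fruit-like levels.  The rarity rule's "< 25% of the samples" is read
against the whole dataset's sample count, not the single species' samples.
Filtering is idempotent; the rules are applied to a dataset only when its
acquisition protocol warrants them (they are flags, not defaults, in the
pipeline).

### Normalisation and class aggregation

Species profiles are computed **mean-then-normalise**: arithmetic mean
amount per species (absences counting as zero), then division by the
species' total emission.  The alternative order (normalise each sample,
then average) changes the weighting of individuals with different total
emission; it is exposed as `normalize_per_sample` but is not the default.
All-zero species rows are kept as zeros and reported rather than dropped.

Class aggregation sums compound relative amounts into seven
biosynthesis-based classes — aliphatics (fatty-acid derivatives),
aromatics, C5-branched, terpenoids, nitrogen/sulfur, miscellaneous cyclic,
unknown — in a fixed canonical order so outputs are byte-stable.  Row sums
are conserved exactly.

## Ordination

Scent composition is zero-inflated, so species are compared by Bray–Curtis
dissimilarity on relative amounts (range [0, 1]; a semimetric).  Principal
coordinates analysis is classical scaling: double-centre −½D², symmetric
eigendecomposition, scores = eigenvectors × √eigenvalue.  All axes with
eigenvalue above 1e-8 (relative to the largest) are retained and passed
downstream — no truncation to a few axes, since the signal statistic is
rotation-invariant and benefits from the full embedding.  Negative
eigenvalues (inevitable for Bray–Curtis) are dropped without Cailliez or
Lingoes correction; this is the minimal-assumption default, the discarded
squared-distance mass is reported as `reconstruction_residual`, and a
correction would only rescale axes that the permutation test treats
symmetrically anyway.  A pair of all-zero profiles gets distance 0 (with a
warning): identical emptiness.

Hierarchical clustering (default UPGMA; complete, single and Ward
available — the linkage is a configuration knob, never hard-coded) supports
tanglegram comparison.  Input rows are sorted by label before
agglomeration so equal-distance merges resolve identically regardless of
input order.  Dendrograms export to Newick with root-to-tip distance equal
to half the merge height (so cophenetic distances in the tree equal the
linkage heights); drawing is out of scope.

## Phylogenetic signal

The covariance matrix C has C_ij = depth of the most recent common
ancestor of tips i and j.  Polytomies are left unresolved: C depends only
on MRCA depths, so no arbitrary resolution is needed, and the statistic is
computed on the tree as given.  C⁻¹ and C^(−1/2) come from a symmetric
eigendecomposition; if the smallest eigenvalue falls below 1e-10 of the
largest the matrix is declared singular with a message pointing at the
usual cause (duplicated tips / zero-depth species) rather than silently
regularised.

Blomberg's *K* and Kmult are implemented exactly as in the README's
formulas.  The permutation test shuffles the rows of the score matrix
uniformly over tips (equivalently: shuffles tip labels), which preserves
the internal correlation of the multivariate data while destroying its
phylogenetic arrangement; 1000 permutations by default.  The add-one rule
p = (1 + #{K_perm ≥ K_obs})/(1 + n_perm) keeps p in (0, 1]; ties are
counted with a 1e-9 relative tolerance so that permutation-invariant
configurations (e.g. the star tree, where every permutation gives exactly
K = 1) report p = 1 rather than a float-noise artefact.  Whether rows are
shuffled before or after the PCoA is immaterial — a row permutation
commutes with the whole Bray–Curtis/PCoA construction up to relabelling —
so the cheaper post-PCoA shuffle is used.

Tree/name matching normalises case and space↔underscore differences.  A
genus-level fallback (grafting an unmatched species onto a seeded-random
congener tip) exists for megatree work but is off by default.

## Synthetic data

The generators produce the statistical shape the analyses assume, not the
biochemistry:

- **Trees**: Yule (pure birth) via dendropy, scaled to unit depth.  The
  simulator stops at the n-th speciation, which leaves zero-length sister
  branches; the clock is run one further exponential waiting time so all
  tips are distinct and C is well-conditioned.
- **Brownian traits**: multivariate normal with covariance σ²C via
  Cholesky, σ² = 1 per unit depth by default.
- **Scent tables**: 30 species × 3 individuals × 120 compounds by default;
  compound classes drawn from a mix dominated by aliphatics, terpenoids and
  aromatics with a small unknown sliver; presence Bernoulli(1 − 0.7)
  (strongly zero-inflated, as in real headspace tables); positive amounts
  log-normal (strictly positive and right-skewed like integrated peak
  areas); individuals = species profile × log-normal noise (SD 0.3 on the
  log scale).  With `phylo_signal > 0`, per-compound Brownian effects enter
  both log amounts and the presence pattern (latent-threshold model at the
  same expected sparsity) — presence had to be structured too, because with
  70% zeros Bray–Curtis is dominated by support mismatch and amount-only
  structure washes out.
- **Paired ripe/unripe profiles**: class weights from a Gaussian copula —
  latent normals correlated at r = 2 sin(πρ_s/6), the closed-form inverse
  of the Spearman–Pearson relation for bivariate Gaussians — pushed through
  a log-normal transform (log-scale SD 1.0) and closed to compositions.
  Closure couples the classes and costs a few hundredths of rank
  correlation relative to the latent target (recovered mean ≈ 0.67 at
  target 0.7, comfortably inside the ±0.1 validation band).  Within each
  class, the ripe stage keeps an unripe compound with probability
  1 − turnover (default turnover 0.8) and otherwise swaps in a different
  class member, reproducing the signature pattern of similar class budgets
  built from different molecules.

What passing these tests does *not* show: real scent tables have
instrument batch effects, correlated compound co-occurrence within
biosynthetic cascades, and detection limits that censor rather than zero
small peaks; none of these are emulated.

## Developmental-constraint statistics

Spearman's ρ per class uses midranks (standard definition; the choice only
matters under ties) and the two-sided t-approximation test; an exact
permutation test is available behind `method="exact"` for small species
counts.  The unknown class is excluded without renormalising the remaining
shares, and its mean share is reported so negligibility is checked, not
assumed.  The weighted mean Σw_kρ_k/Σw_k normalises the weights by their
own sum (they sum to slightly under 1 after excluding unknown); the
unnormalised variant is available via `normalize=False` and differs by less
than the unknown share itself.  Classes with no rank variation in either
stage have undefined ρ and drop out of both sums.

## Problem sizes and numerical checks

The validation battery uses: the exact three-taxon instance (K = 101/96);
star-tree identities (K = 1, p = 1); 500 Brownian replicates on a 64-tip
tree (mean Kmult within [0.9, 1.1]); 500 signal-free runs × 200
permutations on 32 tips (rejection rate 0.05 ± 0.02); 200 generator round
trips at ρ = 0.7, 30 species (mean recovered ρ within ±0.1); and oracle
equivalence of Bray–Curtis (element-wise loop, 1e-14), PCoA (Euclidean
reconstruction, 1e-8), UPGMA (textbook hand trace, 1e-12) and Spearman
(midrank-then-Pearson enumeration, 1e-12).  These sizes give Monte-Carlo
standard errors several times smaller than the corresponding tolerance
bands while keeping the whole battery around a minute.

## Known limitations

- Reproducing published site-level Kmult values requires the original
  supplementary tables and a pruned megatree; point estimates additionally
  drift with megatree version and polytomy structure.
- Bray–Curtis + PCoA discards the negative-eigenvalue part of the
  embedding; datasets where that mass is large (heavily saturated
  dissimilarities) lose information before the signal test.
- The permutation test's power falls with very few species (< ~10) or when
  a single PCoA axis dominates; no small-sample correction is applied.
- No phylogenetically corrected version of the ripe/unripe correlation is
  provided (the raw cross-species Spearman is the designed estimand).
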