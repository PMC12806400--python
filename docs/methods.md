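# Methods

This note documents the statistical procedures, the synthetic data model,
and the design decisions taken where the screening recipe is genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Screening model

All screening operates on genus-level **relative abundances** stored as
proportions in [0, 1]; the conventional "0.1 %" major-taxon threshold is
therefore 0.001 internally and converted only at the report boundary.
Columns are closed per sample (`to_relative_abundance`), an idempotent,
scale-invariant operation; an all-zero sample is a fatal input error rather
than something to impute.

**Taxon–compound associations.** Spearman rank correlation is the default
(Pearson by flag): abundances are compositional and far from normal, and
only monotone association is claimed. Each (taxon, compound) pair over the
shared samples yields (ρ, p); constant vectors are flagged degenerate and
recorded as ρ = 0, p = 1 rather than dropped, so the output always has one
row per pair. Benjamini–Hochberg correction is applied **within each
compound-class family** (esters together, amino acids together, ...): the
group definitions query classes separately, so the class is the natural
error-rate family. The family choice, like every other open parameter, is
written to `manifest.json` with a `paper_unstated` flag.

**Group rules.** "Strong positive correlation" is operationalized as
ρ ≥ 0.6 and BH q < 0.05, both configurable. The Flavor group demands an
ester hit *and* an acid hit (acid or organic-acid class) — a conjunction
that substantially reduces false positives from shared succession trends.
The Amino-acid group demands ≥ 2 amino-acid hits for the same reason. The
Major threshold is strict (mean > 0.001; a mean of exactly 0.001 is
excluded). Replicates enter correlations as individual samples (maximum
power, declared in the manifest) rather than as replicate means.

**Co-occurrence network.** All genus pairs, bacteria and fungi in a single
correlation family, edges at |ρ| ≥ 0.6 and BH q < 0.05 with the sign
retained. "Strong nodal" taxa are defined by **strength** (weighted degree,
Σ|ρ|), the simplest defensible reading; betweenness-style definitions are
out of scope. The hub cutoff is the 0.8 quantile of the *distinct* positive
strength values — taken over distinct values so that a star topology (one
high-strength center among many tied leaves) selects the center alone;
ties at the cutoff are all included, and isolated nodes never qualify.

**Cross-reference and substitution.** The candidate rule is a user-visible
set expression over the four group names with `|`, `&` and parentheses
(`&` binds tighter). The library default is
`(flavor | amino_acid) & cooccurring & major`. On data generated by this
package that intersection is empty by construction, because producers and
hubs are planted as disjoint roles (letting them overlap leaks the producer
signal into hub partners and destroys screening precision); the
demonstration configuration therefore uses
`((flavor | amino_acid) & major) | (cooccurring & major)`, which mirrors a
SynCom containing both flavor producers and co-occurring organisms. The
source study's cross-referencing is not formalized and its "statistical
significance" for the final community has no stated test; the package
reports per-member supporting statistics and deliberately does not invent a
community-level test. Culturability substitution replaces each unculturable
candidate with the highest-evidence culturable taxon sharing at least one
functional group (evidence = best qualifying correlation where available,
with network strength/abundance as a strictly lower-ranked fallback); every
decision is logged and no unculturable taxon survives to the final set.

## Permutation statistics

Mantel and ANOSIM are implemented in-package because their conventions are
pinned: permutation p-values use (1 + #exceedances)/(1 + permutations) so
p > 0 always, ranks use average ties, and both support exhaustive
enumeration for small n (all n! relabelings; the identity permutation is
included in the count). ANOSIM is R = (r̄_between − r̄_within)/(n(n−1)/4) on
the ranks of all n(n−1)/2 distances. The test suite cross-checks both
statistics against scikit-bio. Alpha diversity uses natural-log Shannon
entropy, Pielou evenness H/ln S (0 for single-taxon samples), and observed
genera; Bray–Curtis and Jaccard distances come from scipy's `pdist`.

## Raup–Crick null model

Presence is abundance > 0; the regional pool is every genus observed in at
least one analyzed sample, weighted by its occurrence count. For a pair
with richness (n₁, n₂), null communities are assembled at those richnesses
by sequential frequency-weighted sampling without replacement. The
implementation uses the Gumbel-top-k formulation — perturb log-weights with
Gumbel noise and keep the top k — which is distributionally identical to
sequential renormalized draws and vectorizes over replicates; the test
suite verifies it against exhaustive enumeration of the sequential process
on an 8-species pool (agreement within 0.02 at 10⁵ replicates). Ties use
the half-weight convention, which pins the fully saturated pool (every
genus in every sample) to RC = 0 exactly. Replicates default to 999. Each
pair's null draws come from an independent sub-stream keyed on the sorted
sample-label pair (CRC32), so RC values are invariant to sample order and
evaluation order, and the matrix is exactly symmetric because each pair is
computed once.

## NMDS

Nonmetric SMACOF: at each iteration the configuration distances are
isotonically regressed on the input dissimilarities (ties in the
dissimilarities are collapsed into weighted blocks — the "secondary"
approach — using scipy's PAV), the disparities are rescaled to fixed sum of
squares, and a Guttman transform updates the configuration. The reported
figure is Kruskal stress-1, √(Σ(d̂ − d)²/Σd²), recomputed at the final
centered coordinates; the best of `restarts` random initializations (10 by
default) is returned. RC matrices are mapped to dissimilarities by
(RC + 1)/2 before embedding — rank-preserving, so the ordination is
unaffected by the shift. Degenerate zero distances contribute zero weight
in the Guttman step.

## Synthetic fermentation model

The generator's defaults are the study conditions: two arms (`CK`,
`Lpscw`), days (0, 3, 10, 30, 45), three replicates, 20 bacterial and 10
fungal genera, multinomial depth 50 000, producer effect size 5 and
compound noise SD 0.05.

Latent genus abundances are log-normal around smooth succession curves
(logistic up, logistic down, or Gaussian bump over the day index — a
parametric choice; no mechanistic growth model is implied), closed to
proportions, thresholded at a 10⁻⁴ detection limit, and optionally
resampled multinomially. Planted structure:

* **Producers** (4) are abundant genera (log-base mean 1.8 ≈ 5–15 %
  relative abundance): the compound drive `effect_size × abundance` must
  clear the measurement noise floor, as it does for real dominant flavor
  producers. Odd producers drive an (ester, acid) pair; even producers a
  pair of free amino acids. Driven concentrations inherit the producer's
  replicate-level abundance noise exactly, which is what lets the screen
  separate the true producer from genera that merely share its trend.
* **Hubs** (3) are persistent keystone-like genera: low idiosyncratic noise
  (0.25 log-units), damped succession, and a loading of 1.2 on a bounded
  (uniform) per-sample factor shared with 6 partner genera (loadings
  0.9–1.05, noise 0.7). The factor is bounded and the clique bases are
  drawn from moderate distributions because a genus that episodically
  dominates the composition cancels, through closure, the very correlation
  being planted. The asymmetry (hub factor-share ≈ 0.97 vs partner ≈ 0.8)
  is what makes the hub the strongest node of its clique under the 0.6
  edge threshold.
* **Background** genera pair up into weak two-genus partnerships and carry
  succession occupancy windows (absent 1–3 edge days, or outside a bump
  window): real fermentations show genus turnover, the windows give the
  presence/absence structure that Raup–Crick reads, and the partnerships
  populate the lower tail of the strength distribution as real co-occurrence
  networks do.
* **Arm contrast**: producers double as the inoculum, boosted by 1.0
  log-units in `Lpscw` after day 0, and every non-physicochemical compound
  receives a per-compound arm offset that ramps with fermentation day
  (SD 2.0), emulating flavor profiles diverging late in fermentation. With
  realistic succession the day effect still dominates pooled-day rank
  separation, so ANOSIM R on generated data is significant but moderate
  (≈ 0.1–0.25) — smaller than values reported from real fermentations.
* **Assembly switch**: `shuffle_fungi_arm` permutes the fungal
  sub-composition of every sample in one arm, erasing deterministic fungal
  presence structure there while leaving the marginal pool intact; this
  plants the within-arm RC contrast (clean arm |RC| large, shuffled arm
  near 0) that the assembly analysis should detect.
* Physicochemical rows are always `pH` (monotone fall), `reducing_sugar`
  (monotone fall) and `lactic_acid` (rise then plateau) with small
  replicate noise.

One root seed drives seven independent sub-streams (roles, trajectories,
abundance noise, compounds, physicochemistry, shuffling, sequencing depth),
so outputs are byte-reproducible and changing one component leaves the
others untouched.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and chimeras, strain-level
dynamics, absolute biomass, batch effects between fermentation rounds,
compound–compound chemistry, and taxon interactions beyond linear shared
factors. Recovery results certify the screening logic under the stated
noise model, not field performance.

## Numerical choices and limitations

* Average ranks for all ties; permutation p never 0 (+1 convention).
* BH q-values come from statsmodels (`fdr_bh`).
* Degenerate (constant) vectors: ρ recorded as 0 with p = 1, never an edge.
* NMDS convergence: stop when stress-1 improves by < 10⁻⁶ within a restart
  (300 iterations max); `converged` reports the best restart's status.
* Problem sizes in the shipped tests and acceptance script (20-seed
  recovery panels, 999 null replicates, 500-trial Mantel calibration,
  10⁵-replicate enumeration checks) were chosen as the smallest sizes at
  which the checked quantities are stable to well within their asserted
  tolerances.
* The hub definition (strength quantile over distinct values) and the
  cross-reference rule are heuristics standing in for choices the original
  screening narrative leaves informal; both are configurable and recorded
  in the run manifest.
* Raup–Crick here is the presence/absence formulation; abundance-weighted
  variants (RC_bray) and phylogenetic null models (βNTI) are out of scope.
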