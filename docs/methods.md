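# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions taken where the problem left them open.

## Setting

A cohort of children (ages 24–72 months) undergoing ABA therapy carries, per
child: sociodemographics (age, gender), SRS-2 assessment T-scores (five
subscales plus a total, all on the T-score scale [30, 100]), a VB-MAPP
aggregate milestone score in [0, 170], a clinician treatment plan expressed
as Level-1 domain codes and Level-2 `domain.target` codes, and mastery
records (whether/when each planned target was mastered, over a six-month
horizon with assessments at months 0, 4, 6). Treatment codes are stored as
integer pairs, never floats: `5.13` is the thirteenth target of domain 5,
which float parsing would conflate with `5.1`.

The recommendation task: given a child's intake profile (and, in the
steady-state setting, the cohort's accumulated plan/outcome history),
propose domain and target codes, to be compared against the clinician plan
(ground truth) and against mastery outcomes.

## Patient-similarity model

Feature vector (fixed order): encoded age, encoded gender, five SRS-2
subscale T-scores, SRS-2 total, VB-MAPP aggregate — nine entries. Cosine
similarity is scale-sensitive to the *relative* magnitude of features, so
the default encoding min-max scales age and VB-MAPP to [0, 1] over the
cohort, divides T-scores by 100 (they are already standardised), and encodes
gender as 0/1; without this, raw age in months (24–72) would dominate every
inner product. Raw and z-score encodings are available as configuration.

For an index child, the k = 3 highest-PSM children are retrieved (ties
broken by ascending participant id). Their plans are aggregated by
PSM-weighted union: each candidate code is scored by the summed PSM of the
neighbours whose plan contains it, ranked by score, then neighbour count,
then ascending code. How the three neighbours' plans are combined was a
genuinely open choice; the weighted union is the default because it yields a
single ranked list with scores usable by ranking metrics, and a per-neighbour
pass-through view is retained for neighbour-wise psychometrics (each
neighbour's plan evaluated separately against the index child's plan).
Vectors default to the month-0 assessment: this model's role is the
cold-start recommendation at intake.

## Implicit-feedback ALS model

Plans are implicit feedback: there are no explicit ratings, only the fact
that a clinician included code *i* in child *u*'s plan. The interaction
matrix sets r_ui > 0 exactly for planned codes, with magnitude the child's
SRS-2 total T-score rescaled linearly from [30, 100] to [1, 10] — the
assessment severity stands in for interaction strength. Preferences are
binary, p_ui = 1[r_ui > 0]; confidence is c_ui = 1 + α·r_ui.

The objective is the confidence-weighted L2 cost over **all** cells (zeros
enter at confidence 1) plus ridge penalties. Summing over all cells, rather
than observed cells only, is what makes an absent interaction weakly
informative rather than ignored, and is the formulation whose per-row solves
are closed-form; an observed-cells-only cost mode exists for comparison but
the solver always alternates exact minimisations of the all-cells objective,
so the training log is non-increasing by construction (this is asserted in
tests, and the converged cost is cross-checked against an independent
general-purpose optimiser on a tiny instance).

Hyperparameters:

| parameter | target level | domain level | notes |
|---|---|---|---|
| latent factors | 20 | 22 | chosen per level |
| regularization λ | 0.10 | 0.10 | ridge on both factor matrices |
| sweeps | 200 | 150 | fixed budget; `tol=1e-4` relative-cost stop as safety valve |
| α | 40 | 40 | not fixed by the source study ("tuned"); 40 follows the implicit-feedback ALS literature; a masked-P@5 grid-search helper is provided |

Factors are initialised to 0.01 × seeded standard normals. Each half-sweep
solves x_u ← (YᵀC_uY + λI)⁻¹ YᵀC_u p_u via the standard decomposition
YᵀC_uY = YᵀY + Yᵀ(C_u − I)Y, so only nonzero-confidence items enter the
per-row correction. λ = 0 with degenerate data raises a numeric error
advising λ > 0.

Validation masks ~20 % of positives, stratified per patient (a patient with
a single interaction keeps it) so nobody is entirely unseen; masking is
deterministic per seed. Recommendations are the top-5 unobserved codes by
r̂_ui, ties by ascending code. Domain-level and target-level models are fit
independently (they have separate hyperparameters).

**Sparsity ratio** is the fraction of *zero* cells. (The phrase "ratio of
nonzero to zero entries" sometimes attached to this quantity is inconsistent
with quoting 0.94 for a sparse matrix and a 0.995 performance threshold;
fraction-of-zeros makes both coherent, and that is what is implemented.)

## Evaluation stack

Set-valued recommendations against the clinician plan yield TP/FP/TN/FN over
a code universe (all codes observed at that level in the cohort), hence
precision, recall, accuracy, F1. AUC uses the rank-sum identity with
midranks, which equals the all-pairs P(positive outscores negative) count
exactly; for the set-valued similarity recommender, candidates are ranked by
aggregate PSM score with relevance = membership in the child's own plan —
a reconstruction, flagged as such, since no ranking rule is canonical there.

Rank metrics: P@k; AP@k = (1/m′) Σ_{j≤k} P@j·rel(j) with m′ = min(m, k)
(the min keeps AP@k ≤ 1 on truncated lists; AP = 0 when the user has no
relevant items); MAP@k averages AP@k over users; DCG@k = Σ G_i/log₂(i+1)
with zero-padding for short lists; NDCG = DCG/IDCG, defined 0 when IDCG = 0.
k = 5 is the default evaluation depth.

Commonality defaults to the precision-style reading, 100·|rec ∩ truth|/|rec|
("share of recommended codes that are relevant"); recall and Jaccard modes
are selectable and always reported with the mode name. Treatment
effectiveness over a month window counts a recommended target as effective
if a mastered record for it falls inside the window; a recommended domain
counts if at least one of its targets does. Undefined cases (empty
recommendation, zero denominators, single-class labels) raise instead of
returning 0: these percentages feed clinical summaries where a silent zero
misleads.

## Synthetic cohort generator

The study's records are not public, so the generator produces cohorts with
the one property the models need: similar profiles ⇒ overlapping plans ⇒
correlated mastery. A linear latent-factor model was chosen deliberately as
the *weakest* such structure, so recovery tests are informative:

1. gender ~ Bernoulli(24/29), age ~ Uniform(24, 72) months;
2. latent deficits z ~ N(0, I₆); fixed loading matrices (entries
   N(0, 1/k)) map z to the five SRS-2 subscales and to the 22-domain
   catalogue;
3. subscale T = 65 + 8·(loading·z) + N(0, σ²), clipped to [30, 100], with
   σ = 4 T-score points by default (a plausible short-term retest
   variability); total T = subscale mean + noise; VB-MAPP = 85 − 30·mean(z)
   + noise, clipped to [0, 170] — decreasing in deficit;
4. the plan is a *deterministic* function of the projected domain deficits:
   domains above a 0.5 threshold (count clipped to 2–8, strongest first),
   1–3 targets per domain in ascending easy-to-complex order, more targets
   for stronger deficits. Determinism encodes the modelling assumption that
   two identical children receive identical plans;
5. each planned target is mastered with probability logistic around a 0.7
   base rate, decreasing in the domain deficit; days-to-mastery is
   lognormal(3, 0.5) (median ≈ 20 days); month uniform on 1–6.

All randomness flows from one root seed through named substreams, so a
cohort is byte-reproducible. Plan-size and targets-per-domain ranges mirror
the observed per-participant table rows (1–8 domains, up to 14 targets).

What the generator does **not** emulate: psychometrically calibrated SRS-2 /
VB-MAPP distributions, longitudinal assessment drift across months 0/4/6,
gender- or age-dependent skill structure (gender affects only the sampling
ratio; nothing in the source constrains more), clinician idiosyncrasies, or
dropout. Tests passing on synthetic cohorts therefore demonstrate *model
correctness and recoverability under the stated assumptions*, not clinical
performance on real children. Published per-participant results are engaged
only through the packaged fixture tables and their summary arithmetic.

`neighbor_structure_strength` validates a generated cohort: the Spearman
correlation between pairwise feature cosine similarity and pairwise plan
Jaccard overlap, with a plan-shuffling permutation test. Default cohorts at
n ≥ 100 give a strictly positive correlation with permutation p < 0.01; the
correlation is modest (ρ ≈ 0.07 at n = 200) because age and gender enter
the feature vector but not the plan, diluting the cosine exactly as they
would in practice.

`planted_block_interactions` provides the ALS recovery benchmark: users in
one of B groups hold positives only inside their own item block. A
B-factor model separates blocks essentially perfectly, but cannot
distinguish a held-out positive from a never-owned same-block item, so
achievable masked-item hit rate is bounded by top-n/(block candidates) —
with 4 blocks of 10 items and 5 positives per user the ideal P@5 uplift over
a uniform ranker is 5.8×, and the fitted model achieves ≈ 5.7×.

## Numerical and reporting choices

- Ties everywhere break deterministically (ascending participant id,
  ascending code) so repeated runs are identical.
- Report bundles contain no timestamps; wall-clock timing goes to the
  logging stream. A fixed root seed yields byte-identical bundles.
- Cohort CSV reading forces `float_precision="round_trip"` and string dtype
  for code columns; write∘read is the identity on validated cohorts.
- Empty cohort files are rejected rather than producing empty cohorts.
- Fixture CSVs are checksum-pinned; the packaged per-participant tables are
  verbatim transcriptions, including oddities (a `0.0` target code, targets
  whose domain is absent from the printed domain column), and are never
  validated against cohort invariants. One published average row prints the
  age mean at a coarser precision than its siblings; that cell is excluded
  from the ±0.01 arithmetic comparison.
- Experiment problem sizes: recovery statistics use 200-participant cohorts
  and 20 replicate seeds — large enough for stable means and paired tests,
  small enough to iterate quickly on a laptop.

## Known limitations

- α, the rating map, and the feature encoding are defensible defaults, not
  tuned values; the study data needed to tune them are unavailable.
- The per-neighbour AUC reconstruction and the commonality denominator are
  interpretations of ambiguous definitions; both are configurable and
  reported with their mode.
- The ALS solver is dense and exact — appropriate at clinic scale (tens of
  patients, hundreds of codes); it is not engineered for web-scale matrices.
- Month-window treatment effectiveness depends on mastery records observed
  only for planned targets, so codes recommended outside the clinician plan
  can never count as mastered; TE is therefore bounded above by commonality
  in any retrospective evaluation of this kind.
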