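# Methods

## Model and assumptions

The package treats a DDI as an unordered pair of domain-family identifiers
(canonical lexicographic order, self-pairs allowed) and every evidence
source as a set of such pairs with optional per-pair raw scores. Three
assumptions drive the design:

1. **Structural DDIs are truth.** The gold-standard positive (GSP) set is
   the union of the structural datasets; it calibrates dataset confidence
   and labels the evaluation. No attempt is made to model structural
   false positives.
2. **Dataset agreement is informative only where datasets are
   comparable.** All set comparisons (weighted overlap) are restricted to
   DDIs whose both domains occur in the other dataset's domain universe,
   so a method that never saw a domain family is not penalized for missing
   its interactions.
3. **Evidence combines additively after damping.** The reliability
   `R_i = Σ_d C_d · ID_{d,i} · P_{d,i}` grows with the number, accuracy
   and internal score of supporting datasets, while the independence
   factor caps the contribution of mutually redundant sources: two
   identical datasets contribute exactly one dataset's worth (each term is
   halved because Wo between them is 1).

## Parameters that matter

| parameter | where | default | why |
|---|---|---|---|
| `score_direction` | manifest, per dataset | `higher` | p-value-like sources exist; orientation is explicit metadata, never guessed from data |
| `min_reliability` | coverage/queries | 0 | coverage compares whole databases; structural rows always pass the filter |
| `holdout_fraction` | `split_gold_standard` | off | the published procedure calibrates and labels with the same GSP; the split is offered for circularity-free evaluation |
| `CorpusSpec.n_gsp` | generator | 2000 | ≈1/3 scale-down of a realistic structural corpus relative to ~80k possible pairs over 400 domains |
| `DatasetSpec.tp_fraction` | generator | 0.05–0.6 across 8 datasets | spans the confidence range observed for real prediction methods |
| `DatasetSpec.score_noise` | generator | 0.3 | true/false positives drawn from Beta(1+4s, 1) / Beta(1, 1+4s), s = 1 − noise; 0.3 gives strong but imperfect within-dataset ranking |
| `ppi_ddi_coverage_target` | generator | 0.5 | matches the regime where roughly half the interactome is DDI-explicable |

## Numerical choices

* **Zero-denominator weighted overlap → 0.** No comparable DDIs is read
  as evidence of no similarity, not perfect similarity.
* **Ordinal scaling** is min–max on average ranks: ties get the mean of
  their rank positions, values are `(rank − 1)/(n − 1)`, and a dataset
  with a single scored DDI maps it to 1.0 (its best DDI keeps the top
  score). The output depends only on the rank order of the oriented raw
  scores.
* **Imputation for score-less datasets** bins DDIs by their total number
  of supporting predicted datasets (structural sources never count) and
  assigns the mean scaled score of *scored* evidence in the same bin; an
  empty bin falls back to the global mean of all scaled scores. The bin
  average is computed globally across datasets rather than per dataset —
  the alternative per-dataset reading is defensible but leaves small
  datasets with empty bins almost everywhere.
* **Independence** uses the dataset-level Wo matrix, not a
  neighborhood-restricted variant, and sums over *all* other supporters
  including score-less ones.
* **Duplicate rows** within a file, and collisions created by identifier
  mapping, keep the most confident raw score under the dataset's declared
  orientation (max for `higher`, min for `lower`) — deterministic and
  evidence-preserving.
* **Serialization** fixes sort order (reliability descending, then pair)
  and formats: supporters at full float precision, reliability at 6
  decimals, Wo/confidence exports at 4. Integration is therefore
  byte-deterministic for a given manifest. Reading a table back
  reproduces supporters exactly and reliability to 1e-6.
* **Accuracy sweep** defaults to all distinct scores as cutoffs, predicts
  positive at `R ≥ cutoff`, excludes structural-only rows (they carry no
  reliability), and breaks accuracy ties toward the smallest cutoff.
* **Clustering** of the Wo matrix is average-linkage on distance
  `1 − Wo` with dataset labels processed in lexicographic order, making
  equal-height merges deterministic; dendrograms serialize to Newick with
  branch lengths `parent height − child height`.
* **GSP-only DDIs** are emitted with reliability 0 and `structural=1`
  rather than an artificial maximal score; a DDI that is both structural
  and predicted keeps its predicted reliability *and* the flag.

## What the synthetic corpus does and does not emulate

The generator produces the statistical structure the scoring scheme
assumes: a GSP drawn uniformly from the domain-pair space, predicted
datasets whose `tp_fraction` of DDIs come from the GSP, raw scores under
which true positives stochastically outrank false ones, optional
near-duplicate dataset pairs (`redundancy_with`) reproducing the
redundancy the independence score exists to damp, score-less and
p-value-oriented datasets, a proteome with 1–4 domains per protein, and a
PPI list rejection-sampled toward a target DDI-coverage fraction (realized
coverage is reported in `truth.json`, not forced). Written corpora are
identifier-obfuscated (legacy aliases plus obsolete-domain rows) together
with the mapping table that undoes both, so the unification step is
exercised end to end.

It does **not** emulate real Pfam domain-frequency distributions (domains
are drawn uniformly), real interactome topology (PPIs have no degree
structure), correlated errors between non-copied datasets, or
dataset-specific score distributions. A green test on this corpus
establishes that the formulas are implemented correctly and behave as
designed under their own assumptions — not that the scheme's published
database-scale numbers (confidence table, best cutoff, coverage rates)
would be reproduced, since those depend on the real source datasets.

Because domain universes in the default corpus are nearly complete, the
confidence score essentially equals each dataset's generating
true-positive fraction; the parameter-recovery test (Spearman ρ of the
two rankings across seeds) is correspondingly strict.

## Known limitations

* Confidence calibration and ROC labeling share the same gold standard
  (as published); use `split_gold_standard` when an unbiased AUC matters.
* The accuracy sweep loops over every distinct score; on corpora with
  ~10⁵ distinct reliabilities a coarser cutoff grid should be passed.
* Independence damps pairwise redundancy only; three mutually
  overlapping datasets are each damped by the sum of their two overlaps,
  which can over-correct relative to a joint model.
* The imputation fallback (global mean) is a package choice where the
  source procedure is silent; imputed records are flagged so downstream
  users can filter them.
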