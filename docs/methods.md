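# Methods

## The modeling problem

Given a table of compounds with measured activities — half-maximal
inhibitory concentrations (IC50, nM) against a protein target, or the
logBB blood–brain partitioning ratio — the package fits a regression
from molecular structure to activity and uses it to screen untested
libraries. Three endpoints are treated symmetrically: EGFR inhibition,
PI3Kp110β inhibition, and BBB permeation; a screening "mode" combines
their predictions into a single keep/reject decision per molecule.

## Activity scales

IC50 values vary over ~5 orders of magnitude and are censored in
practice: assays rarely resolve potencies below ~1 nM or report numbers
beyond ~10 µM. The spIC50 scale encodes this directly:

    spIC50 = 0                       IC50 ≥ 10,000 nM
    spIC50 = (4 − log10 IC50) / 4    1 ≤ IC50 ≤ 10,000 nM
    spIC50 = 1                       IC50 ≤ 1 nM

Both clamp branches are written inclusively; at the boundaries the two
adjacent branches agree numerically, so the ordering of the cases does
not matter. The −pIC50 representation is the exact affine map
−pIC50 = −log10(10⁻⁹ · 10^(4−4·spIC50)) = 5 + 4·spIC50, with range
[5, 9]; `pic50_to_sp` is its algebraic inverse. Models are trained on
spIC50 (targets) or raw logBB (permeation); threshold logic converts
between representations exactly, so no precision is lost at the
screening stage.

Duplicate measurements of the same canonical structure are merged by
geometric mean on IC50 (a log-scale quantity, so this is the arithmetic
mean on the modeling scale) and arithmetic mean on logBB (already
logarithmic). Salt "exclusion" is implemented as keep-largest-fragment,
with ties broken by heavy-atom count, then molecular weight, then
lexicographic canonical SMILES, making curation deterministic and
idempotent.

## Fingerprints

Molecules are encoded as hashed binary atom-pair fingerprints (RDKit
generator defaults: topological distances 1–30, folded to 256/512/1024
bits), with hashed Morgan (radius 2) as an alternative. Because the
structure is parsed before hashing, any SMILES of the same molecule
yields identical bits. The hashing parameters are recorded in each
serialized model's metadata so saved models are reproducible.

## Feature ranking

Bits are ranked by unscaled out-of-bag (OOB) permutation variable
importance. The implementation grows its own bootstrap ensemble of
`DecisionTreeRegressor`s (mtry = p/3, the convention of R-style random
forest regression) rather than using a stock forest, because the stock
implementation does not expose OOB permutation importance: for each
tree, each feature the tree splits on is permuted over that tree's OOB
rows and the resulting increase in OOB MSE is recorded; a feature's
importance is the increase averaged over all trees (features a tree
never uses contribute exactly zero). No normalization by the importance
standard error is applied. Ties are broken by bit index, so the ranking
is a deterministic function of (data, seed). With a constant response
the importances are all zero; the ranking degrades to bit order and a
warning is emitted.

## Stepwise SVM and model selection

For each k in a grid, an RBF-kernel SVM regressor (C = 1, ε = 0.1,
γ = 1/k — the defaults of the classic e1071 R implementation, with γ the
reciprocal of the feature count) is fit on the top-k ranked bits and
scored by 5-fold cross-validated RMSE. Fold assignment comes from one
seeded shuffle and is identical across all k, so curve points differ
only in the feature prefix. The selected-features (SF) model is the
smallest k attaining the minimum CV RMSE (parsimony tie-break), refit on
the full training set. The default grid is every k from 1 to
min(nbits, 200) with a configurable stride; examples and tests use
coarser grids (e.g. {5, 10, 15, 20, 30, 50, 80, 120, 256}), which
resolve the minimum well on the synthetic benchmarks.

External validation on the 25% hold-out (75/25 seeded random split)
reports PVE = 1 − SSres/SStot (SStot about the observed hold-out mean),
RMSE, and the squared Pearson correlation r². PVE and RMSE satisfy
PVE = 1 − n·RMSE²/SStot identically; the tests assert this to 1e−10.
Validation refuses datasets that share a canonical SMILES with the
training set.

## Applicability domain

A query is compared by Tanimoto similarity against every training
fingerprint (full bit space, not just selected bits). Under the default
`distance` rule, a prediction is in-domain when 1 − max-similarity ≤
0.7. The threshold's wording is ambiguous between a distance and a
similarity reading in common usage, so a `similarity` rule
(in-domain ⇔ max-similarity ≥ threshold) is also provided; the default
follows the distance reading. Two degenerate cases anchor the scale:
threshold 0 admits only exact fingerprint duplicates, threshold 1
admits everything. Empty-fingerprint queries (no on bits) compare with
similarity 1 to an empty training fingerprint and 0 otherwise.

## Screening cascade

`screen_library` runs stages in a fixed order: curate → fingerprint →
predict with AD verdict (all required models: the mode's targets plus
BBB) → PAINS match → threshold selection → annotation. Out-of-domain and
PAINS-flagged molecules are carried through prediction (their predicted
values appear in the report) but rejected at the selection stage with
rules `ad` and `pains`; unparsable structures reject as `parse`;
optional user-supplied blocklists (ids or canonical SMILES — standing in
for purchasability or prior-publication exclusions) reject as
`blocklist`. Threshold checks are inclusive (≥) and are applied logBB
first, then potency, so each rejection names a single deterministic
rule. All comparisons being inclusive matters: the bundled reference
panel contains boundary-grazing values (logBB 0.203 against a 0.2
cutoff) that must be kept.

The dual-target rule recovers spIC50 from each target's −pIC50 via the
exact inverse transform and keeps molecules whose product
spIC50(EGFR) × spIC50(PI3K) is at least 0.1 (and logBB ≥ −0.2). The
product is symmetric in the two targets.

PAINS matching uses the RDKit filter catalogs, families A+B+C combined.
Catalog contents are implementation- and version-dependent: 4 of the 27
bundled reference candidates match alerts in this catalog
(`mannich_A`, `anil_di_alk_D`, `ene_six_het_A`), so the panel's
selection counts are defined at the threshold-selection stage, not
after a PAINS pass.

Annotation uses average-isotope molecular weight, non-hydrogen atom
count, and a Lipinski violation count over MW > 500, cLogP > 5 (Crippen
estimate), H-bond donors > 5, acceptors > 10. Ligand efficiency is
|docking score| / heavy atoms — the absolute value makes both
negative-better and positive-better scoring conventions yield positive
efficiencies. The bundled panel's printed ligand-efficiency column is
not reproduced by this formula for several rows (e.g. 58.15/18 ≈ 3.23 vs
a printed 3.994); the formula is implemented as stated and the printed
column is carried as data, not recomputed.

## Synthetic benchmarks

The generator stands in for curated ChEMBL-style IC50 extracts, a
published logBB dataset, and purchasable screening libraries. Molecules
are assembled by seeded random single-bond joining of 2–4 fragments from
a ~30-fragment drug-like pool (quinazoline, morpholine, aniline, azole,
and halobenzene motifs typical of kinase-inhibitor chemotypes);
infeasible attachments are resampled within a bounded retry budget and
duplicates dropped, so every emitted SMILES is valid and unique.

Activity is planted directly on fingerprint bits: informative bits are
drawn among bits with prevalence in [0.1, 0.9] (so the signal is
learnable), and latent = β₀ + Σ βⱼ·bitⱼ + N(0, σ²). Planting on bits
rather than named substructures makes the ground truth exact by
construction — the fragments only make the libraries look realistic.
For logBB the response is the latent value itself (defaults β₀ = −0.5,
β = 0.4 put responses mostly within [−2, 1.5], the range typical of
experimental BBB data); for IC50 the latent value is clamped to [0, 1],
mapped to −pIC50 = 5 + 4·latent and IC50 = 10^(9 − pIC50) nM, and
re-scaled through the censored transform — so a realistic fraction of
molecules sits exactly at the 1 nM and 10,000 nM censoring bounds.
Gaussian noise on the latent (log-like) scale matches the roughly
log-normal error structure of real potency assays.

Standard benchmark conditions are n = 300 molecules, 5 informative bits
with β = 0.3 and intercept −0.2, σ = 0.05, 256-bit atom-pair
fingerprints, 75/25 split. All artifacts (library.smi, activities.csv,
truth.json, split.json) are byte-identical across runs with the same
config.

What the benchmarks do *not* emulate: ChEMBL assay heterogeneity
(mixed assay formats, inter-lab variance), activity cliffs, realistic
property distributions of purchasable libraries, or any relationship
between a molecule's pharmacophore and its planted activity. Passing
recovery tests therefore demonstrates that the pipeline's statistics
work as specified — not that real-data models of these endpoints will
reach any particular accuracy.

## Numerical and design choices

* Split sizes use round(n · fraction), clamped so both parts are
  non-empty; fewer than 4 records refuse to split.
* Random state: every stochastic step (split, bootstrap, fold shuffle,
  generator) takes an integer seed and uses an isolated NumPy
  `default_rng`; per-tree sklearn seeds are drawn below 2³¹.
* Serialized models are a directory of metadata JSON (endpoint, scheme,
  nbits, seeds, selected bits, training SMILES) plus the fitted
  regressor and the training fingerprint matrix; a loaded model
  reproduces predictions exactly.
* Empty inputs: curating zero rows yields an empty dataset; curating a
  non-empty input whose rows are all dropped raises, naming the
  failure.

## Known limitations

* No structure standardization beyond salt stripping and
  canonicalization (no tautomer or charge normalization), no 3D
  chemistry, no docking — docking scores enter only as user-supplied
  numbers for calibration and ligand efficiency.
* No hyperparameter search: the SVM settings are fixed by convention;
  on data with very different noise scales they may be far from
  optimal.
* PAINS outcomes depend on the catalog version shipped with the
  cheminformatics toolkit.
* The permutation-importance ranking is O(trees × used-features ×
  OOB-rows); with 1024-bit fingerprints and large n it is the slowest
  step.
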