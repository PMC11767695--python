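# Methods

## Problem and model

Hydrolysis — reaction of an organic chemical with water, enzymatically or
abiotically — is one of the main degradation routes of environmental
organics, agrochemicals in particular. `hydrosom` predicts, for a query
molecule, (1) which atoms are hydrolysis sites of metabolism (SOM) and
(2) which single-step hydrolysis products form, ranked by the predicted
site probabilities.

The system has two coupled parts:

* **Site classifiers.** Binary per-atom classifiers trained on atoms
  labelled SOM+ (a hydrolysis transformation occurs at this atom) or SOM−
  (same element class, no transformation). Four datasets are trained:
  N-, O- and C-Hydrolysis restricted to one element each, and
  Global-Hydrolysis over all tracked classes {N, O, C, S, X}, where
  X = F/Cl/Br/I. Sulfur and halogen atoms appear only in the global set
  because standalone S/X corpora are too small to train on.
* **Rule engine.** A knowledge base of one-reactant reaction SMARTS, one
  per hydrolyzable-group family (amide, nitrile, urea, carbamate, ester,
  carbonate, oxime, phosphoester, terminal alkyne, thioether, acid
  chloride, haloalkane). Each rule names its reaction-center atom via an
  atom map (`center_map`); applying the rule at a matched center yields
  the product fragments of one hydrolysis step.

At prediction time the classifier assigns every tracked heavy atom a
probability; rules are applied at matched centers whose probability is at
least the threshold τ, and each resulting transformation is scored with
its site's probability. Ranking by that score is what controls the
combinatorial explosion of unconstrained rule application.

## Atom representation

Each atom is a 1032-length vector: a 1024-bit Morgan-type circular
fingerprint of the environments rooted at that atom up to radius 3 bonds
(RDKit Morgan generator, `fromAtoms` restricted), concatenated with eight
interpretable atomic descriptors:

| descriptor | meaning | units |
|---|---|---|
| `gasteiger_charge` | Gasteiger–Marsili sigma partial charge | e |
| `crippen_logp` | Crippen atomic logP contribution | — |
| `crippen_mr` | Crippen atomic molar refractivity (polarizability surrogate) | cm³/mol |
| `pauling_en` | Pauling electronegativity of the element | — |
| `heavy_degree` | heavy-atom degree | count |
| `attached_h` | attached hydrogens (implicit + explicit) | count |
| `is_aromatic` | aromatic flag | 0/1 |
| `min_ring_size` | smallest ring containing the atom (0 if acyclic) | count |

The descriptors favour what each quantity *means* chemically: charge and
electronegativity capture electrophilicity of the environment,
refractivity captures polarizability, the topological counts capture
steric context. Sigma/pi charge partitioning schemes from other toolkits
would serve the same role; the set here is computable from RDKit alone and
is versioned (`FEATURE_VERSION`), so a trained bundle refuses vectors from
a different feature contract. Fingerprint bit positions are a property of
the hashing dialect and are likewise not portable across toolkits. No
scaling is applied at featurization time; tree ensembles dominate the
model set and any scaling belongs inside a model's own pipeline.

## SOM labelling

The corpus format gives parent → observed products; it does not mark
atoms. Labels are derived by rule matching: an atom is SOM+ exactly when
some rule applied at that atom yields a product set sharing at least one
*organic* fragment with the observed products (canonical, stereo-stripped
SMILES equality). Small inorganic by-products (CO2, ammonia, hydrogen
halides, hydroxylamine) are excluded as evidence because they are common
to many rule families and could vouch for the wrong site. Records that no
rule explains are flagged and excluded from training tables, never
silently dropped. Multi-fragment parents (salts) are reduced to their
largest organic fragment first; stereochemistry is ignored throughout
because the rules carry none.

Known limitation: when a molecule carries two groups that release an
identical organic fragment and only one actually reacted, fragment-level
evidence marks both sites positive. The synthetic generator sidesteps this
by construction (below); on real corpora, curated atom-level annotations
would be preferable where available.

## Rule base

The shipped base (14 rules, JSON, user-replaceable) reconstructs the
standard hydrolysis chemistry of the covered families; every rule carries
a golden reactant → product pair that `validate_rulebase` and the test
suite check. Notable choices:

* **Carbamates** hydrolyse fully to alcohol/phenol + amine + CO2 (the
  carbamic-acid intermediate decarboxylates spontaneously). Two rules
  share the products but differ in center: the ester oxygen (O class) and
  the nitrogen (N class), so both classifiers can score the group. They
  share the `carbamate` family, so they count as one transformation.
* **Phosphoesters**: hydroxide substitution at phosphorus with the
  leaving-group oxygen as center, matching the S_N2-at-P mechanism of
  organophosphate hydrolysis; the single generic rule matches each ester
  oxygen in turn, which covers phosphates and phosphorothionates alike.
* **Nitriles** get both the hydration (→ amide) and full hydrolysis
  (→ acid + NH3) rules; they share the `nitrile` family so a nitrile
  carbon yields one ranked transformation (the hydration product is
  reported first).
* **Mass balance** is asserted per rule: total product heavy atoms equal
  parent heavy atoms + `balance_delta`, the number of water-derived
  oxygens (+1 for all rules except full nitrile hydrolysis, +2).
* Aromatic perception follows RDKit defaults; rules are written against
  aromatic forms, and SMARTS use uppercase (aliphatic) atoms where ring
  systems must not match (e.g. thiophene sulfur is not a thioether).

## Transformation counting

A *transformation* is one (rule family, reaction center) event. Two
candidate products merge when they share a family and either their centers
are automorphism-equivalent (RDKit canonical ranks without tie-breaking)
or their major fragments coincide. The major fragment of a transformation
is its largest organic fragment; CO2 and similar are kept but flagged
`inorganic`. This collapse is what makes a symmetric dimethyl phosphate
count its two methyl cleavages once while keeping chemically distinct
leaving groups separate. Ties in the ranking break by rule id, then site
index, so output order is deterministic.

## Feature selection

Three univariate filters fitted on training rows only, in fixed order:
exact zero-variance removal; ANOVA F-test keeping the ceil(50%) of
survivors with the highest F; two-sided Welch t-test keeping survivors
with p < 0.05. Welch (unequal variance) is the safer default under the
heavy class imbalance of these datasets; a pooled-variance variant would
change little on near-binary columns. Ties at the F cutoff break toward
the lower column index so the fit is a pure function of its inputs. No
multiple-testing correction is applied at the t stage — the raw 0.05 rule
is deliberate, as the goal is pre-filtering, not inference. Fingerprint
bits pass through the same numeric tests as continuous descriptors.

## Model protocol

Eight families: LightGBM, random forest, decision tree, extra trees, LDA,
AdaBoost, QDA, gradient boosting (scikit-learn implementations; LightGBM
in deterministic single-thread mode). Pre-training evaluates each with
stratified k-fold CV (atom-level stratification within training
molecules; fold assignment seeded) on mean accuracy; the top five proceed
to a seeded random search (default configuration always candidate 0) over
per-family spaces; the gradient-boosting space spans learning rates
1.0 → 0.05 and 50 → 300 trees, the regime where slow learning pays off.
QDA gets a small ridge (`reg_param = 1e-3`) by default because collinear
fingerprint bits make an unregularised class covariance rank-deficient.

The final model per dataset is chosen on the held-out test molecules by
MCC first (the one metric that uses all four confusion cells, and the
right criterion under imbalance), accuracy second, fixed family order
third. Train/test splitting is molecule-grouped (8:2 by molecule count,
seeded): atom-level splitting would leak near-identical environments
across the boundary. No resampling or class weighting is applied — the
rarity of SOM+ atoms is signal, not bias — though a `class_weight` switch
exists for the families that support it.

Metrics: ACC = (TP+TN)/(TP+TN+FP+FN), Recall = TP/(TP+FN),
Precision = TP/(TP+FP), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
computed exactly on integer counts; a metric whose denominator is zero is
reported as 0 with an explicit flag.

The probability threshold τ defaults to 0.5 — a neutral choice, recorded
in every output and adjustable per run; product sets grow monotonically as
τ decreases.

## Synthetic corpus

Real curated hydrolysis corpora (pathway handbooks, reaction databases)
are not redistributable, so the package ships a generator that emulates
their *site/label structure*: small scaffolds (benzene, toluene, pyridine,
cyclopentane, C3–C5 alkanes) decorated with 1–3 hydrolyzable groups and
0–2 inert decoys (ethers, amines, alcohols, ketones, fluorine). Observed
products are computed by applying the shipped rules at every matched
site, so ground truth is a deterministic function of structure and the
labeller recovers it with exact closure — generator and labeller share
only the rule base, not the site choices. The default mix is set so the
global SOM+:SOM− ratio sits near 0.24, the imbalance regime of curated
corpora where reactive sites are much rarer than inert atoms; the
achieved ratio is reported and generation fails loudly if it drifts
beyond ±0.10 of the request. An optional label-flip rate (default 0)
exists purely as test machinery for robustness studies.

What the generator does **not** emulate: realistic agrochemical property
distributions, competing sites with context-dependent reactivity,
unreacted hydrolyzable groups, multi-step pathways, or measurement noise
in product identification. Because sites are deterministic functions of
substructure, near-perfect held-out MCC on synthetic data demonstrates
that the pipeline is wired correctly (features separate, selection keeps
the informative columns, models fit, no leakage across the molecule
split) — it does not certify accuracy on real chemicals, where the same
functional group reacts in one molecule and survives in another.

## Problem sizes and numerical choices

Default study conditions used by the tests and the acceptance script:
300-molecule corpus (seed-pinned), molecule-grouped 8:2 split, 5-fold CV
for pre-training and tuning, 10 tuning configurations, top-5 families —
sizes at which the full Global pipeline trains in a few minutes on one
CPU while leaving every protocol stage exercised. Production-scale runs
would raise folds to 10 and configurations to 50 via the CLI flags.
Degenerate inputs fail explicitly rather than silently: empty corpora,
single-molecule splits, all-constant feature matrices, empty retained
feature sets and all-zero confusion matrices each raise a named error.

## Single-step scope

The engine predicts one hydrolysis step. Sequential pathways are obtained
by re-running on a chosen product; no automatic iteration is performed,
which keeps the product space small and auditable. Kinetics, pH and
temperature dependence, and non-hydrolytic biotransformations are out of
scope.
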