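# hydrosom

Hydrolysis site-of-metabolism prediction and metabolite generation for
environmental organic chemicals.

Hydrolysis — biotic or abiotic reaction with water — is one of the main
degradation routes of organic chemicals, agrochemicals especially, and
knowing *where* a molecule hydrolyses and *what* it turns into is central
to assessing its environmental fate. Identifying hydrolysis products
experimentally (LC/MS workflows) is slow and expensive; pure rule-based
predictors instead drown users in candidate metabolites. `hydrosom`
combines the two ideas: machine-learned per-atom classifiers score every
heavy atom with a hydrolysis-site probability, and a SMARTS transformation
rule base generates the products only at high-scoring sites, ranked by
those probabilities.

It is aimed at computational chemists and environmental-fate researchers
who work from SMILES/SDF inputs on the command line or from Python.

## Model

Each heavy atom of a tracked class (N, O, C, S, X = halogens) is encoded
as a 1032-length vector: a 1024-bit Morgan-type circular fingerprint of
the environments rooted at that atom (radius 3) plus 8 interpretable
atomic descriptors (Gasteiger charge, Crippen logP/MR contributions,
electronegativity, degree, H count, aromaticity, ring size). Features
pass a three-stage univariate filter fitted on training atoms only
(zero-variance removal → top-50% by ANOVA F → Welch t-test p < 0.05).
Eight classifier families (LightGBM, RF, DT, ET, LDA, AdaBoost, QDA, GBC)
are pre-trained with stratified k-fold CV; the top five are tuned by
seeded random search and the final model per dataset is picked on
held-out molecules by MCC,

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

Four models are trained: N-, O-, C-Hydrolysis (single element each) and
Global-Hydrolysis (all classes; sulfur and halogens live only here).
At prediction time, rules are applied at matched reaction centers whose
probability ≥ τ (default 0.5); each transformation is scored with its
site probability and symmetric/equivalent transformations are collapsed.
Details, assumptions and limitations: [docs/methods.md](docs/methods.md).

Because the curated hydrolysis corpora the approach is designed for are
not redistributable, the package ships a synthetic-corpus generator with
exact per-atom ground truth (see the methods note for what it does and
does not emulate); all training-dependent numbers below refer to it.

## Worked example

Predict hydrolysis products of the herbicide desmedipham in pure
rule-engine mode (no trained model: every site scores 1.0):

```
$ printf 'CCOC(=O)Nc1cccc(OC(=O)Nc2ccccc2)c1 desmedipham\n' > demo.smi
$ hydrosom predict demo.smi --out demo_preds
wrote 6 product rows for 1 molecule(s)
```

`demo_preds.csv` then contains two ranked transformations (both carbamate
cleavages), three fragments each:

```
molecule_id,rank,transformation_id,product_smiles,score,rule_id,...,fragment_role
desmedipham,1,T1,Nc1cccc(OC(=O)Nc2ccccc2)c1,1.0,R05_carbamate_o,...,major
desmedipham,1,T1,CCO,1.0,R05_carbamate_o,...,minor
desmedipham,1,T1,O=C=O,1.0,R05_carbamate_o,...,inorganic
desmedipham,2,T2,CCOC(=O)Nc1cccc(O)c1,1.0,R05_carbamate_o,...,major
desmedipham,2,T2,Nc1ccccc1,1.0,R05_carbamate_o,...,minor
desmedipham,2,T2,O=C=O,1.0,R05_carbamate_o,...,inorganic
```

Transformation T2's major fragment is ethyl (3-hydroxyphenyl)carbamate —
the known alkaline-hydrolysis product of desmedipham — and T1 is the
cleavage of the other carbamate to 3-aminophenyl phenylcarbamate. The
`environments` column (aquatic/plant/animal) carries each rule's reaction
systems.

Full pipeline on synthetic data:

```
hydrosom generate-fixtures --n 300 --seed 7 --out corpus.tsv
hydrosom train --corpus corpus.tsv --out run/ --datasets Global-Hydrolysis \
        --folds 5 --n-configs 10 --seed 7
hydrosom predict demo.smi --bundle run/Global-Hydrolysis/bundle --out preds
hydrosom validate-rules
```

`train` writes the CV accuracy table, tuning log, per-candidate test
metrics, confusion counts, a reusable model bundle and a manifest
(seeds + versions) that makes the run reproducible byte for byte.

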