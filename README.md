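# speciesid

Species classification and misclassification screening for genotyped plant
genetic-resources collections.

Gene banks conserve hundreds of thousands of accessions of crops and their
wild relatives, and their documentation inevitably contains species
misclassifications — morphological identification is hard, and accession
histories involve exchanges and regenerations. As collections are genotyped
(resequencing SNPs, AFLPs, ...), those data can be used to find and correct
wrong labels *without a gold-standard training set*: classifiers are trained
on the collection's own, imperfect labels and asked whether they can improve
them. `speciesid` implements that workflow end to end for curators and the
researchers supporting them.

## What it does

Given a genotype matrix (biallelic SNP dosages from VCF, or 0/1 dominant
markers from a delimited table) and an accession → species label table,
`speciesid` provides:

- **Five classifiers**, each predicting a species per accession or abstaining
  with an explicit `AMBIGUOUS` call:
  - **1-NN** — label of the nearest accession by divergent-site count
    (pairwise deletion of missing data);
  - **conservative 3-NN** — k=3 nearest neighbours by Euclidean distance on
    imputed codes, *with the query itself among the neighbours* and a
    minimum of l=2 votes. One agreeing neighbour confirms an a-priori label;
    two dissenters are needed to overturn it, and a species needs only 2
    correctly labelled accessions for an unambiguous confirmation;
  - **NJ** — Saitou–Nei neighbour joining on divergent-site distances, then
    majority vote in the smallest subtree containing the query (one
    escalation to the next subtree, else ambiguous);
  - **Random Forest** — 10,000 CART trees (gini, mtry = √p, bootstrap with
    replacement), each accession called by the ~3,680 trees it was
    out-of-bag for;
  - **Naive Bayes** — categorical per-marker conditionals with Laplace
    smoothing (α=1), resubstitution or leave-one-out.
- **An outlier screen**: Random-Forest proximities (fraction of trees in
  which two accessions co-terminate) feed a class-relative outlyingness
  score, n / Σ prox², median/MAD-standardised per species; scores above 10
  are flagged. Advisory only — most-common-allele imputation is a known
  false-positive source for this screen.
- **A label-noise benchmark**: curate species below a minimum size,
  subsample each species to 2/4/6/8/10 accessions, corrupt 6.25/12.5/18.75%
  of the labels, classify, and score against the *true* labels; 5,000
  replicates per cell by default (75,000 perturbed datasets).
- **Comparison statistics**: Friedman Aligned Ranks omnibus test across
  classifiers, Finner step-down p-value correction, and a multiple
  comparison against the best classifier as control.
- **A synthetic-data generator**: Balding–Nichols species structure — per
  marker an ancestral frequency p, per species p_s ~ Beta(p(1−F)/F,
  (1−p)(1−F)/F), genotypes Binomial(2, p_s) — with configurable species
  counts, representation, missingness and injected label errors.

## Worked example

Simulate a 4-species collection (8 accessions each, 600 markers, divergence
F=0.6) with 3 of 32 labels deliberately corrupted, then ask the two
recommended classifiers which labels look wrong:

```
$ speciesid simulate --n-species 4 --per-species 8 --markers 600 \
    --divergence 0.6 --error-rate 0.09375 --seed 29 --out-dir data
simulated 32 accessions x 600 markers in data

$ speciesid classify --matrix data/genotypes.tsv --labels data/labels.tsv \
    --methods 3nn,nj --out-dir run
7 disagreement(s); report in run/disagreements.tsv

$ cat run/disagreements.tsv
accession   a_priori  classifier  predicted
sp01_a002   sp02      3nn         sp01
sp01_a002   sp02      nj          sp01
sp01_a006   sp01      nj          sp02
sp03_a004   sp02      3nn         sp03
sp03_a004   sp02      nj          sp03
sp04_a005   sp02      3nn         sp04
sp04_a005   sp02      nj          sp04
```

The three accessions whose labels were corrupted (`sp01_a002`,
`sp03_a004`, `sp04_a005` — see `data/labels_true.tsv`) are exactly the ones
the conservative 3-NN disagrees with, and its predictions restore the true
species. NJ finds the same three but additionally re-labels `sp01_a006`, a
*correctly* labelled accession sitting near a corrupted one — the collateral
damage that makes subtree-majority classification the weaker curation tool.

Other entry points: `speciesid import` (VCF → matrix with call-rate/MAF/
depth filters), `speciesid filter` (dominant-marker heterozygosity + MAF
filter, random thinning), `speciesid outliers` (proximity screen),
`speciesid benchmark` and `speciesid stats` (the noise-injection grid and
its statistical analysis). Every command takes `--seed` and logs input
digests for reproducibility. All of this is equally usable as a library;
see `docs/methods.md` for the underlying models and conventions.

## Acceptance script

`scripts/acceptance.py` recomputes the package's data-free headline quantity
from scratch — it constructs fixtures of m = 1, 2, 3 correctly labelled,
well-separated conspecifics, runs the conservative 3-NN rule on each, and
reports the smallest m that yields an unambiguous correct confirmation:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
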