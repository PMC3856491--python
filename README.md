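# gepess

Essential-protein prediction from protein–protein interaction (PPI)
networks by **gene expression programming (GEP)**.

Essential proteins are those whose loss is lethal to the cell; in yeast
roughly a quarter of the proteins in the DIP interaction network are
essential. Many single signals correlate with essentiality — a protein's
centrality in the PPI network, its co-expression with interaction
partners, its subcellular compartment, how conserved it is across
organisms — but no single feature predicts well on its own. `gepess`
combines them with an evolutionary symbolic classifier that is fully
interpretable: the trained model *is* a readable arithmetic expression
over named features.

The package is aimed at computational/systems biologists who want to
train, inspect, and evaluate such classifiers on their own network and
annotation tables, or to study the method itself on synthetic data with a
known planted signal.

## The method

**Features.** For every protein the package computes seven network
centralities — degree (DC), betweenness (BC), closeness (CC), subgraph
(SC), eigenvector (EC), information (IC), and the edge-clustering-based
NC — plus three composite scores and 16 subcellular localization
indicators. With ECC(u,v) = |N(u) ∩ N(v)| / min(d_u−1, d_v−1) the edge
clustering coefficient and PCC(u,v) the Pearson correlation of the two
proteins' expression profiles:

- NC(v) = Σ_{u∈N(v)} ECC(v,u)
- PeC(v) = Σ_{u∈N(v)} ECC(v,u) · max(PCC(v,u), 0)
- WDC(v) = Σ_{u∈N(v)} [λ·ECC(v,u) + (1−λ)·PCC(v,u)], λ = 0.5
- ION: fixed point of S(i) = (1−α)·O(i) + α·Σ_{j∈N(i)} W(j,i)·S(j),
  where O is the max-normalized conservation (orthology) score and
  W(j,i) is j's ECC share toward i; α = 0.85.

Every feature is divided by its maximum absolute value, so the table
lives in [−1, 1].

**Classifier.** A GEP chromosome is a fixed-length Karva string over the
function set {+, −, ×, ÷, =, √, log, exp, |·|, max, min} and the terminal
set {feature names} ∪ {0.1, 0.2, 0.5, 1.0}. A head of length h = 20 and a
terminal-only tail of h+1 = 21 symbols guarantee that level-order
decoding always yields a valid expression tree. Fitness of a chromosome:
score every training protein, call the top k essential (k = number of
training positives), and take

SSPN = SN · SP · PPV · NPV

of the resulting confusion counts. Evolution keeps the best chromosome
unchanged (elitism), truncates to the fittest 30% ("eugenic" selection),
and refills the population through one-point recombination, per-position
mutation, and IS/RIS transposition. Evaluation uses stratified 10-fold
cross-validation, ROC/AUC, and the standard rate suite
(SN, SP, FPR, PPV, NPV, F-measure, ACC, MCC) at the top-k cutoff.

## Worked example

The synthetic generator builds a desk-scale dataset with the structure
the method assumes — a modular scale-free network, co-expressed modules,
nucleus/ER enrichment and high conservation among essentials — and plants
ground-truth labels through a known expression:

```python
from gepess import EssentialityGEP, GepConfig
from gepess.synthetic import SyntheticSpec, generate_dataset

data = generate_dataset(SyntheticSpec(rng_seed=7))
model = EssentialityGEP(data.features, data.labels, GepConfig.desk(rng_seed=7))
res = model.fit()
print(res.summary())
```

```
======================================================================
                     GEP essentiality classifier
======================================================================
Proteins:    500    Essential:   114    Nonessential:   386
Features:     26    Population: 200    Generations: 50
Head length: 20    Genes: 1    Chromosome length: 41
Mutation: 0.25    Crossover: 0.1    Eugenic fraction: 0.3    Seed: 7
----------------------------------------------------------------------
Best training fitness (SSPN): 0.595069
Expression:
  Min(WDC,Min(ION,nucleus))
----------------------------------------------------------------------
Training metrics at k = |essential|:
  SN=0.8158  SP=0.9456  FPR=0.0544  PPV=0.8158  NPV=0.9456  F_measure=0.8158  ACC=0.9160  MCC=0.7614  AUC=0.8852
======================================================================
```

The evolved classifier is the readable expression
`Min(WDC, Min(ION, nucleus))`: a protein scores high only if it is
simultaneously topologically embedded (WDC), conserved (ION), and
nuclear — exactly the kind of feature combination the generator planted.
The metric row shows the counting identity SN = PPV and SP = NPV that
always holds when the rank cutoff equals the number of true positives.
`res.predict()`, `res.evaluate()`, `model.cross_validate(k=10)`,
`res.plot_history()` and `res.plot_roc()` hang off the same objects.

The same pipeline is available from the shell:

```sh
gepess simulate --seed 1 --out data/
gepess featurize --network data/network.tsv --expression data/expression.tsv \
    --localization data/localization.tsv --orthology data/orthology.tsv \
    --out features.tsv
gepess train --features features.tsv --labels data/essential.txt --out run/
gepess predict --features features.tsv --expression-file run/expression.txt \
    --out ranking.tsv
gepess evaluate --features features.tsv --labels data/essential.txt \
    --scores ranking.tsv
```

`gepess published-score` applies the fixed classifier expression reported
for the yeast network (see `gepess.karva.PUBLISHED_CLASSIFIER`) to any
feature table.

## Input formats

- **Network**: two-column tab-separated edge list; `#` comments ignored;
  self-interactions and duplicate edges dropped with a logged count.
- **Essential proteins**: one ID per line.
- **Expression**: TSV, proteins × samples, header row; partial coverage
  allowed.
- **Localization**: TSV, proteins × 16 compartments, 0/1 values.
- **Orthology**: TSV with one nonnegative conservation-score column.

ID matching is exact and case-sensitive throughout. See
`docs/methods.md` for the model's assumptions, parameter choices, and
limitations.
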