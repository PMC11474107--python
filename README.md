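# sisdta

Drug–target binding-affinity (DTA) regression over **directed similarity
graphs**, built around an asymmetric containment similarity between
molecular substructure sets.

## The idea

For drugs $r_i, r_j$ represented as sets of circular (ECFP/Morgan)
substructure environments, the structure-inclusive similarity

$$\mathrm{SIS}_{i,j} = \frac{|r_i \cap r_j|}{|r_j|}$$

measures how much of drug $j$'s structural information drug $i$ contains —
and therefore how much $i$ can usefully *collect from* $j$ in a
message-passing model. Unlike Tanimoto similarity it is asymmetric: phenol
contains every substructure of benzene, so phenol collects benzene's
information at weight 1.0, while benzene collects only 3 of phenol's 11
substructures (weight 0.27). Thresholding these weights produces a
directed drug graph that passes useful information forward while
suppressing noise from substructures the receiver does not share.

The package implements, end to end:

* substructure enumeration (RDKit Morgan environments, ECFP4 convention)
  and fingerprint folding;
* SIS plus comparison kernels (Tanimoto/Jaccard, bounded Euclidean,
  normalized Smith–Waterman for protein sequences);
* directed graph construction: threshold δ → k-NN backfill of orphan nodes
  → self-loops → symmetric normalization $\hat{D}^{-1/2}\hat{A}\hat{D}^{-1/2}$;
* a NumPy graph-convolution network with multi-view fusion, an autoencoder
  bottleneck with reconstruction loss, and a regression head trained on the
  joint objective $\tfrac1q\sum(Y-\hat{Y})^2 + \tfrac1q\sum(H^I-H^D)^2$;
* DTA metrics (MSE, RMSE, CI, $r_m^2$, Spearman) and threshold-sweep
  reports;
* a seeded synthetic-data generator so everything runs with no downloads.

Intended users: cheminformatics / ML researchers studying
similarity-graph-based DTA models who want a small, fully tested,
dependency-light reference implementation.

## Worked example

```python
import numpy as np
from sisdta import enumerate_substructures, sis_matrix, build_relationship_graph
from sisdta.synthetic import SyntheticSpec, generate_dataset
from sisdta.similarity import similarity_matrix
from sisdta.model import train, predict
from sisdta.evaluate import evaluate_predictions

benzene = enumerate_substructures("c1ccccc1", mol_id="benzene")
phenol  = enumerate_substructures("Oc1ccccc1", mol_id="phenol")
print(len(benzene), len(phenol))          # 3 11
S = sis_matrix([benzene, phenol])
print(np.round(S.values, 4))
# [[1.     0.2727]      <- benzene collects 27% of phenol's information
#  [1.     1.    ]]     <- phenol collects all of benzene's

# synthetic dataset with planted bilinear structure: 20 drugs x 10 proteins
synth = generate_dataset(SyntheticSpec(seed=1))
ds = synth.dataset
S_d = sis_matrix(synth.drug_sets)                                  # directed drug graph
S_p = similarity_matrix([synth.protein_sequences[p] for p in ds.protein_ids],
                        "smith_waterman", entity_ids=ds.protein_ids)
_, A_d = build_relationship_graph(S_d, delta=0.6, k=5)
_, A_p = build_relationship_graph(S_p, delta=0.6, k=5, symmetric=True)

model, history = train(ds, synth.drug_views, synth.protein_views, A_d, A_p, seed=1)
pairs, y = ds.test_pairs()
print(evaluate_predictions(y, predict(model, pairs)).to_text())
```

Output:

```
metric           value
mse           0.914188
rmse          0.956132
ci            0.839080
rm2           0.720835
spearman      0.872303
n_pairs             30
```

The held-out concordance index of 0.84 and Spearman of 0.87 show the model
recovering the planted low-rank affinity structure from the noisy feature
views after propagation over the two similarity graphs; MSE is on the scale
of the label variance left after rank-3 structure plus noise.

The same pipeline is available from the shell:

```bash
sisdta simulate --seed 1 --out data/
sisdta build-graph --smiles smiles.json --similarity sis --delta 0.6 --k 5 --out graph/
sisdta train --data data/ --seed 1 --out run/
sisdta evaluate --data data/ --model run/model.npz --out eval/
sisdta sweep --data data/ --deltas 0.2,0.4,0.6,0.8 --out sweep/
```

Every command logs a `manifest.json` with its config, seed, and input
checksums.

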