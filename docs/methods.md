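# Methods

## Problem and model

Drug–target binding affinity (DTA) regression predicts a continuous binding
strength (pKd or a KIBA-style integrated score) for a compound–protein pair.
The model in this package rests on the guilt-by-association premise: similar
drugs, and similar targets, tend to share interaction profiles, so each
entity can borrow information from its neighbors in a similarity graph
before a regression head sees the pair.

The departure from the usual symmetric-similarity construction is the edge
weight. For two drugs with circular-substructure sets $r_i$ and $r_j$, the
structure-inclusive similarity

$$\mathrm{SIS}_{i,j} = \frac{|r_i \cap r_j|}{|r_j|}$$

is the fraction of $r_j$'s substructures that $r_i$ contains — the amount of
information $i$ can collect from $j$. It is asymmetric: a molecule that
contains all of another's substructures (phenol ⊇ benzene) collects weight
1 from it, while the smaller molecule collects only the contained fraction
(3/11 ≈ 0.27) back. Thresholding these weights yields a *directed* graph in
which noisy, mostly-disjoint neighbors are silenced in one direction but not
necessarily the other. Tanimoto/Jaccard, a bounded Euclidean kernel
$1/(1+d)$, and normalized Smith–Waterman ($SW_{ab}/\sqrt{SW_{aa}SW_{bb}}$,
for protein sequences) are provided as symmetric comparison kernels behind
the same matrix interface.

### Substructure enumeration

Substructure sets are RDKit Morgan environments with duplicate environments
removed. The default radius is 2 (the ECFP4 diameter convention): it is the
radius at which benzene yields exactly 3 unique environments and phenol 11,
which pins down the convention unambiguously; radius is a configuration
knob. SIS always operates on the *unfolded* identifier sets — folding to
1024 bits is available for feature matrices, but hash collisions would
corrupt containment semantics, so folded vectors are never the SIS operand.

### Graph construction

From a similarity matrix $S$ the relationship graph is built in four steps:

1. **Threshold**: keep edge $(i,j)$ iff $S_{i,j} \ge \delta$. Adjacency
   orientation is "row collects from column", so a node's row lists its
   information sources. Defaults: $\delta = 0.6$ for Davis-like data,
   0.7 for KIBA-like.
2. **k-NN backfill** (k = 5 by default): any node left with fewer than
   $\min(k, N-1)$ in-neighbors is reattached to its most similar
   non-neighbors at their *original* sub-threshold weights, so orphan
   drugs still receive information but at appropriately low weight. Ties
   break by descending similarity then ascending node index —
   deterministic and seed-free. Backfill counts in-neighbors (sources),
   because the failure mode being repaired is a node that cannot *learn*
   from anyone.
3. **Self-loops** with weight 1 (a molecule trivially contains itself).
4. **Symmetric degree normalization** $\hat{D}^{-1/2}\hat{A}\hat{D}^{-1/2}$
   with $\hat{D}_{ii} = \sum_j \hat{A}_{ij}$, computed as written even for
   asymmetric $\hat{A}$.

For proteins the same machinery runs on the symmetric normalized
Smith–Waterman matrix with mirrored backfill, preserving symmetry end to
end.

### Network and objective

Each feature view flagged `propagate` passes through a two-layer graph
convolution $X' = \sigma(\hat{D}^{-1/2}\hat{A}\hat{D}^{-1/2} X \Theta)$
(ReLU between layers, linear output); raw views (e.g. precomputed sequence
embeddings) are concatenated unchanged. The drug and protein embeddings of
a pair are concatenated into $H^I$, an autoencoder bottleneck produces a
latent code and a reconstruction $H^D$, and a two-layer head maps the
latent code to $\hat{Y}$. The objective is the equally weighted sum

$$\mathcal{L} = \frac{1}{q}\sum_k (Y_k - \hat{Y}_k)^2
             + \frac{1}{q}\sum_k (H^I_k - H^D_k)^2,$$

where the vector residual reduces by the mean over components so both terms
share scale. The reconstruction term acts as a regularizer that forces the
latent code to retain pair information. A `recon_weight` override exists
but defaults to the 1:1 form.

The network is implemented directly in NumPy: the architecture is a fixed
computation graph, so the forward and backward passes are written out
explicitly and verified against central finite differences in the test
suite (all parameter gradients agree to ~1e-10 on dense test problems).
Training is full-batch Adam. Defaults: two GCN layers of widths 64→32 per
propagated view, latent 32, head width 32, lr 0.01, 200 epochs. With
full-batch training an epoch is a single Adam step, so the conventional
stochastic-training rate of 1e-3 undertrains badly at 200 steps; 0.01 is
the standard choice for full-batch GCN optimization and is the package
default. The output bias is initialized to the mean training label. All
parameter initialization derives from one integer seed; identical seeds
give bitwise-identical loss histories and predictions.

### Metrics

* MSE / RMSE as usual.
* Concordance index: over all ordered pairs with $y_i > y_j$, score 1 if
  $\hat{y}_i > \hat{y}_j$, 0.5 on prediction ties, normalized by the pair
  count. This is the pairwise (Pahikkala-style) form; for continuous
  predictions it coincides with the Gönen–Heller estimator.
* $r_m^2 = r^2(1 - \sqrt{|r^2 - r_0^2|})$ with $r$ the Pearson correlation
  (with intercept) and $r_0^2 = 1 - \sum(y - k\hat{y})^2 / \sum(y -
  \bar{y})^2$ the through-origin coefficient of determination,
  $k = \sum y\hat{y} / \sum \hat{y}^2$. This is the form used throughout
  the DTA benchmarking literature.
* Spearman via average-tie ranks.

Pairs with missing affinity are excluded from training and from every
metric. Fold files are inputs and are never silently re-randomized.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes so that the whole
system is testable offline:

* **Affinities** follow a bilinear latent model $y_{ij} = u_i \cdot v_j +
  \varepsilon$, $\varepsilon \sim N(0, \sigma^2)$ — the simplest model in
  which similar entities have similar affinity profiles, which is exactly
  the premise the graph model exploits.
* **Substructure sets** are abstract integer sets (not chemistry): drugs
  come in pairs where the odd member is a strict superset of the even
  member, so the asymmetric kernel always has containment pairs to
  exercise; pairs draw identifiers from disjoint ranges. The latent
  factors mirror this structure ($u_{2t+1} = u_{2t} + $ small noise), so
  substructure similarity is informative about affinity — without this
  alignment, propagation over the drug graph would inject pure noise and
  the graph could only hurt.
* **Protein sequences** descend from two ancestor sequences by point
  mutation, and protein latents are drawn around two matching family
  centers, giving the Smith–Waterman graph the same kind of informative
  block structure.
* **Feature views** are noisy linear images of the latent factors, so the
  signal is learnable from features alone and graph propagation acts as
  denoising.

Standard conditions: 20 drugs × 10 proteins, latent rank 3, label noise
0.1, 10% missing cells, 1/6 held-out test, remaining cells in 5 training
folds. Under these conditions the default model reaches held-out Spearman
0.75–0.94 across seeds in well under a second of training.

What passing these tests does *not* show: real chemical fingerprints are
far sparser and higher-dimensional, real affinity matrices are not low
rank, real similarity–affinity coupling is much weaker, and benchmark-scale
training (thousands of entities, 10⁵ pairs) raises optimization questions
the desk-scale tests never touch. The synthetic results validate the
mechanism, not benchmark performance.

## Numerical choices and degenerate inputs

* Empty substructure sets are a hard error everywhere the SIS denominator
  needs them — never silently similarity 0.
* Similarity matrices validate range [0, 1], unit diagonal, finiteness;
  precomputed matrices are validated on input and round-trip through CSV
  at 10 significant digits.
* Degree normalization refuses zero row sums with a message pointing at
  self-loop addition.
* Smith–Waterman defaults: BLOSUM62, gap open 10, extend 1 (a gap of
  length L costs 10 + (L−1)·1); scores clamp at 0 so sequences with no
  positive-scoring local alignment get normalized similarity 0. Datasets
  that ship precomputed similarity matrices should prefer them.
* The Euclidean kernel uses $1/(1+d)$: bounded on $[0,1]$ and monotone in
  distance, which thresholding requires. A Gaussian kernel
  $\exp(-d^2/\sigma^2)$ would serve equally; the choice is configuration,
  not substance.
* The autoencoder acts on the concatenated pair feature (one autoencoder,
  not per-entity); the latent width must be strictly smaller than the
  pair width.

## Known limitations

* Full-batch training only; no minibatching, dropout, or early stopping.
* The GCN depth (2) and all widths are defaults, not tuned claims.
* Embedding views (Mol2Vec-style for drugs, protein-language-model vectors
  for proteins) are consumed as precomputed tables; the seeded random
  projection stand-in has no chemical or biological content.
* Davis-style pKd transformation (−log₁₀(Kd/10⁹)) is provided but raw
  benchmark ingestion at full scale is untested against the public
  distributions.
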