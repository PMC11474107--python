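"""Seeded synthetic data covering every input the pipeline consumes.

Two kinds of data live here:

* A small frozen fixture of real molecules (benzene, phenol and a dozen
  drug-like SMILES) and two short protein sequences with GO annotations,
  used wherever chemically meaningful substructures matter.
* A seeded generator of abstract datasets with *planted* structure:
  affinities follow a bilinear latent model y_ij = u_i · v_j + ε so that
  similar entities have similar affinity profiles (the guilt-by-association
  premise the graph model relies on), feature views are noisy linear images
  of the latent factors (so the signal is learnable), and some drug
  substructure sets are built as strict subsets of others so the asymmetric
  similarity has containment pairs to exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .featurize import FeatureView, Molecule, ProteinSet, SubstructureSet
from .io import PairDataset

# Frozen fixture: ids and SMILES are stable across releases.
FIXTURE_SMILES: dict[str, str] = {
    "benzene": "c1ccccc1",
    "phenol": "Oc1ccccc1",
    "toluene": "Cc1ccccc1",
    "aniline": "Nc1ccccc1",
    "benzoic_acid": "OC(=O)c1ccccc1",
    "catechol": "Oc1ccccc1O",
    "pyridine": "c1ccncc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "ethanol": "CCO",
    "acetic_acid": "CC(=O)O",
}

FIXTURE_PROTEINS: dict[str, str] = {
    "kin1": "MGSNKSKPKDASQRRRSLEPAENVHGAGGGAFPASQTPSKPASADGHRGPSAAFAPAAAE",
    "kin2": "MGCIKSKRKDNLNDDGVDMKTQPVRNTERTIYVRDPTSGKQQRWIPASQTPSKPASADGH",
}

FIXTURE_GO: dict[str, set[str]] = {
    "kin1": {"GO:0004672", "GO:0005524", "GO:0006468"},
    "kin2": {"GO:0004672", "GO:0005524", "GO:0016301"},
}


@dataclass(frozen=True)
class FixtureSet:
    molecules: list[Molecule]
    proteins: ProteinSet


def make_fixture() -> FixtureSet:
    """The frozen small-molecule/protein fixture; identical on every call."""
    molecules = [Molecule(id=k, smiles=v) for k, v in FIXTURE_SMILES.items()]
    proteins = ProteinSet(sequences=dict(FIXTURE_PROTEINS), go_terms={k: set(v) for k, v in FIXTURE_GO.items()})
    return FixtureSet(molecules=molecules, proteins=proteins)


@dataclass
class SyntheticSpec:
    """Generator settings; defaults define the standard desk-scale conditions."""

    m_drugs: int = 20
    n_proteins: int = 10
    latent_dim: int = 3
    noise_sd: float = 0.1
    missing_fraction: float = 0.1
    drug_view_dims: int = 16
    protein_view_dims: int = 16
    view_noise_sd: float = 0.1
    go_vocab_size: int = 12
    test_fraction: float = 1 / 6
    n_train_folds: int = 5
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.m_drugs < 2 or self.n_proteins < 2:
            raise ConfigError("need at least 2 drugs and 2 proteins")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigError("missing_fraction must lie in [0, 1)")
        if self.noise_sd < 0 or self.view_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        return self


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, generated from one seed."""

    spec: SyntheticSpec
    dataset: PairDataset
    drug_sets: list[SubstructureSet]
    drug_views: list[FeatureView]
    protein_views: list[FeatureView]
    protein_sequences: dict[str, str]
    go_terms: dict[str, set[str]]
    latents: dict = field(default_factory=dict)


def generate_go_annotations(n_proteins: int, vocab_size: int, seed: int) -> dict[str, set[str]]:
    """Random GO term sets; every protein gets at least one term."""
    if vocab_size < 1:
        raise ConfigError("vocab_size must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = [f"GO:{i:07d}" for i in range(vocab_size)]
    out: dict[str, set[str]] = {}
    for p in range(n_proteins):
        n_terms = int(rng.integers(1, max(2, vocab_size // 2) + 1))
        terms = rng.choice(vocab_size, size=min(n_terms, vocab_size), replace=False)
        out[f"P{p:03d}"] = {vocab[t] for t in terms}
    return out


def _random_substructure_sets(m: int, rng: np.random.Generator) -> list[frozenset[int]]:
    """Random integer identifier sets with planted strict-containment pairs.

    Even-indexed drugs 2t get a base set; drugs 2t+1 get a strict superset,
    so every adjacent even/odd pair exercises the asymmetric containment
    weight (subset→superset direction carries weight 1).  Identifier ranges
    are disjoint across pairs, so the similarity graph links exactly the
    drugs whose latent factors are also built to be close — the
    guilt-by-association structure the graph model assumes.
    """
    sets: list[frozenset[int]] = []
    for i in range(m):
        if i % 2 == 1:
            base = set(sets[i - 1])
            lo = (i // 2) * 1000 + 500  # private range of this pair
            extra = rng.integers(lo, lo + 400, size=int(rng.integers(3, 9)))
            sets.append(frozenset(base | set(int(x) for x in extra)))
        else:
            lo = (i // 2) * 1000
            size = int(rng.integers(3, 12))
            sets.append(frozenset(int(x) for x in rng.integers(lo, lo + 400, size=size)))
    return sets


def _mutated_sequences(n: int, rng: np.random.Generator, length: int = 60) -> dict[str, str]:
    """Protein sequences derived from two ancestors by point mutation, so the
    normalized alignment similarity matrix has non-trivial block structure."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    ancestors = [rng.choice(alphabet, size=length) for _ in range(2)]
    seqs = {}
    for p in range(n):
        parent = ancestors[p % 2].copy()
        n_mut = int(rng.integers(2, max(3, length // 6)))
        pos = rng.choice(length, size=n_mut, replace=False)
        parent[pos] = rng.choice(alphabet, size=n_mut)
        seqs[f"P{p:03d}"] = "".join(parent)
    return seqs


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset with planted bilinear affinities."""
    spec = (spec or SyntheticSpec()).validate()
    rng = np.random.default_rng(spec.seed)
    m, n, r = spec.m_drugs, spec.n_proteins, spec.latent_dim
    drug_ids = [f"D{i:03d}" for i in range(m)]
    protein_ids = [f"P{j:03d}" for j in range(n)]

    # Planted bilinear affinity.  Latent factors carry the same neighborhood
    # structure as the similarity inputs (containment pairs of drugs, two
    # ancestral protein families), so graph propagation is informative —
    # the guilt-by-association premise holds by construction.
    U = rng.standard_normal((m, r))
    for i in range(1, m, 2):  # superset drug stays latently close to its subset
        U[i] = U[i - 1] + 0.3 * rng.standard_normal(r)
    family_centers = rng.standard_normal((2, r))
    V = family_centers[np.arange(n) % 2] + 0.5 * rng.standard_normal((n, r))
    Y = U @ V.T + spec.noise_sd * rng.standard_normal((m, n))

    # missingness mask
    n_missing = int(round(spec.missing_fraction * m * n))
    if n_missing:
        flat = rng.choice(m * n, size=n_missing, replace=False)
        Y.ravel()[flat] = np.nan

    # feature views: noisy linear images of the latent factors
    Md = rng.standard_normal((r, spec.drug_view_dims))
    Mp = rng.standard_normal((r, spec.protein_view_dims))
    Xd = U @ Md + spec.view_noise_sd * rng.standard_normal((m, spec.drug_view_dims))
    Xp = V @ Mp + spec.view_noise_sd * rng.standard_normal((n, spec.protein_view_dims))

    go = generate_go_annotations(n, spec.go_vocab_size, int(rng.integers(2**31)))
    sequences = _mutated_sequences(n, rng)
    sets = [
        SubstructureSet(molecule_id=drug_ids[i], identifiers=s)
        for i, s in enumerate(_random_substructure_sets(m, rng))
    ]

    # folds over labeled cells, row-major
    n_labeled = int(np.sum(~np.isnan(Y)))
    order = rng.permutation(n_labeled)
    n_test = max(1, int(round(spec.test_fraction * n_labeled)))
    test = sorted(int(i) for i in order[:n_test])
    remaining = order[n_test:]
    folds = [sorted(int(i) for i in remaining[f :: spec.n_train_folds]) for f in range(spec.n_train_folds)]

    dataset = PairDataset(
        drug_ids=drug_ids,
        protein_ids=protein_ids,
        affinities=Y,
        train_folds=folds,
        test_indices=test,
    )
    drug_views = [
        FeatureView(name="drug_latent", entity_ids=drug_ids, matrix=Xd, propagate=True),
    ]
    protein_views = [
        FeatureView(name="protein_latent", entity_ids=protein_ids, matrix=Xp, propagate=True),
    ]
    return SyntheticDataset(
        spec=spec,
        dataset=dataset,
        drug_sets=sets,
        drug_views=drug_views,
        protein_views=protein_views,
        protein_sequences=sequences,
        go_terms=go,
        latents={"U": U, "V": V},
    )


def write_synthetic(directory, synth: SyntheticDataset) -> None:
    """Write a generated dataset in the exact formats the readers consume."""
    import json
    from pathlib import Path

    from .io import write_dataset, write_embedding_tsv

    directory = Path(directory)
    write_dataset(
        directory,
        synth.dataset,
        ligands=None,
        proteins=synth.protein_sequences,
        go_terms={k: sorted(v) for k, v in synth.go_terms.items()},
    )
    for v in synth.drug_views:
        write_embedding_tsv(directory / f"drug_view_{v.name}.tsv", v.entity_ids, v.matrix)
    for v in synth.protein_views:
        write_embedding_tsv(directory / f"protein_view_{v.name}.tsv", v.entity_ids, v.matrix)
    (directory / "drug_sets.json").write_text(
        json.dumps({s.molecule_id: sorted(s.identifiers) for s in synth.drug_sets}),
        encoding="utf-8",
    )
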