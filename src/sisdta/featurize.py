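"""Molecule and protein featurization.

Drugs are represented by their sets of circular (Morgan/ECFP) substructure
environments and by a folded binary fingerprint; proteins by a binary
gene-ontology (GO) annotation matrix.  Dense sequence-embedding views
(e.g. Mol2Vec for drugs, protein-language-model vectors for targets) are
consumed as precomputed tables; a seeded random-projection stand-in is
provided so the whole pipeline runs without external artifacts.

The substructure *set* — not the folded bit vector — is the operand of the
structure-inclusive similarity: folding collisions would corrupt the
containment semantics.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

#: Morgan radius reproducing the ECFP4 convention (diameter 4).
DEFAULT_RADIUS = 2
#: Folded fingerprint length.
DEFAULT_FP_LENGTH = 1024

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class Molecule:
    """A drug identified by a SMILES string."""

    id: str
    smiles: str


@dataclass(frozen=True)
class SubstructureSet:
    """The set of unique circular atom-environment identifiers of one molecule."""

    molecule_id: str
    identifiers: frozenset[int]
    max_radius: int = DEFAULT_RADIUS

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.identifiers)


@dataclass(frozen=True)
class FingerprintVector:
    """A substructure set folded to a fixed-length binary vector."""

    molecule_id: str
    bits: np.ndarray  # uint8, shape (length,)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass
class FeatureView:
    """A named entities x dims feature matrix.

    ``propagate`` records whether the view is passed through the similarity
    graph (GCN) before fusion, or concatenated raw.
    """

    name: str
    entity_ids: list[str]
    matrix: np.ndarray
    propagate: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise InputError(f"view {self.name!r}: matrix must be 2-D")
        if self.matrix.shape[0] != len(self.entity_ids):
            raise InputError(
                f"view {self.name!r}: {self.matrix.shape[0]} rows but "
                f"{len(self.entity_ids)} entity ids"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise InputError(f"view {self.name!r}: non-finite entries")

    @property
    def dims(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ProteinSet:
    """Protein sequences and GO term annotations keyed by id."""

    sequences: dict[str, str]
    go_terms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, seq in self.sequences.items():
            bad = set(seq.upper()) - AMINO_ALPHABET
            if bad:
                raise InputError(
                    f"protein {pid!r}: illegal residue(s) {sorted(bad)}"
                )

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)


def _mol_from_smiles(smiles: str, mol_id: str = "?"):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"molecule {mol_id!r}: unparseable SMILES {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise InputError(f"molecule {mol_id!r}: empty molecule")
    return mol


def enumerate_substructures(
    smiles: str, max_radius: int = DEFAULT_RADIUS, mol_id: str = "?"
) -> SubstructureSet:
    """Enumerate the unique circular atom environments of a molecule.

    Environments are hashed Morgan identifiers up to ``max_radius`` bonds;
    duplicate environments covering identical bond sets are removed, per the
    standard ECFP generation procedure.  With the default radius benzene
    yields 3 identifiers and phenol 11.
    """
    if max_radius < 0:
        raise ConfigError("max_radius must be >= 0")
    mol = _mol_from_smiles(smiles, mol_id)
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max_radius)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    identifiers = frozenset(ao.GetBitInfoMap())
    return SubstructureSet(molecule_id=mol_id, identifiers=identifiers, max_radius=max_radius)


def fold_fingerprint(s: SubstructureSet, length: int = DEFAULT_FP_LENGTH) -> FingerprintVector:
    """Fold an identifier set to a fixed-length binary vector by modular hashing."""
    if length < 1:
        raise ConfigError("fingerprint length must be >= 1")
    bits = np.zeros(length, dtype=np.uint8)
    for ident in s.identifiers:
        bits[ident % length] = 1
    return FingerprintVector(molecule_id=s.molecule_id, bits=bits)


def fingerprint_view(
    sets: Sequence[SubstructureSet], length: int = DEFAULT_FP_LENGTH, propagate: bool = True
) -> FeatureView:
    """Stack folded fingerprints into the m x length structural view S_fp."""
    matrix = np.stack([fold_fingerprint(s, length).bits for s in sets]).astype(float)
    return FeatureView(
        name="ecfp",
        entity_ids=[s.molecule_id for s in sets],
        matrix=matrix,
        propagate=propagate,
    )


def build_go_matrix(proteins: ProteinSet, propagate: bool = True) -> FeatureView:
    """Binary protein x GO-term matrix over the dataset-local term vocabulary.

    Columns are the sorted union of all observed terms; entry (i, t) is 1 iff
    protein i carries term t.  Proteins without annotations get an all-zero
    row (logged as a warning).
    """
    ids = proteins.ids
    if not ids:
        raise InputError("protein set is empty")
    vocab = sorted({t for terms in proteins.go_terms.values() for t in terms})
    col = {t: j for j, t in enumerate(vocab)}
    matrix = np.zeros((len(ids), len(vocab)), dtype=float)
    for i, pid in enumerate(ids):
        terms = proteins.go_terms.get(pid, set())
        if not terms:
            logger.warning("protein %s has no GO annotations; all-zero row", pid)
        for t in terms:
            matrix[i, col[t]] = 1.0
    view = FeatureView(name="go", entity_ids=list(ids), matrix=matrix, propagate=propagate)
    view.columns = vocab  # type: ignore[attr-defined]
    return view


def _read_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a delimited id + numbers table, tolerating CRLF, BOM, TSV or CSV."""
    text = Path(path).read_text(encoding="utf-8-sig").replace("\r\n", "\n")
    sample = text.splitlines()[0] if text.strip() else ""
    delim = "\t" if "\t" in sample else ","
    ids, rows = [], []
    for rec in csv.reader(io.StringIO(text), delimiter=delim):
        if not rec or not any(f.strip() for f in rec):
            continue
        ids.append(rec[0].strip())
        rows.append([float(x) for x in rec[1:]])
    return ids, np.asarray(rows, dtype=float)


def load_embedding_view(
    path: str | Path,
    entity_ids: Sequence[str],
    expected_dims: int | None = None,
    name: str = "embedding",
    propagate: bool = False,
) -> FeatureView:
    """Load a precomputed per-entity embedding table, reordered to ``entity_ids``."""
    ids, matrix = _read_table(path)
    index = {e: i for i, e in enumerate(ids)}
    missing = [e for e in entity_ids if e not in index]
    if missing:
        raise InputError(f"embedding table {path}: missing entity ids {missing}")
    if expected_dims is not None and matrix.shape[1] != expected_dims:
        raise InputError(
            f"embedding table {path}: width {matrix.shape[1]} != expected {expected_dims}"
        )
    reordered = matrix[[index[e] for e in entity_ids]]
    return FeatureView(name=name, entity_ids=list(entity_ids), matrix=reordered, propagate=propagate)


def random_projection_view(
    entities: Sequence[SubstructureSet] | ProteinSet,
    dims: int,
    seed: int,
    name: str = "random_projection",
    propagate: bool = False,
) -> FeatureView:
    """Seeded Gaussian stand-in for a learned sequence-embedding view.

    Deterministic given (entities, dims, seed); used where no precomputed
    embedding table is supplied.
    """
    if dims < 1:
        raise ConfigError("dims must be >= 1")
    if isinstance(entities, ProteinSet):
        ids = entities.ids
    else:
        ids = [s.molecule_id for s in entities]
    rng = np.random.default_rng(seed)
    matrix = rng.standard_normal((len(ids), dims))
    return FeatureView(name=name, entity_ids=ids, matrix=matrix, propagate=propagate)


# ---------------------------------------------------------------------------
# readers for the raw id->value map formats


def read_smiles_map(path: str | Path) -> list[Molecule]:
    """Read drugs from JSON ({id: smiles}) or a 2-column TSV."""
    text = Path(path).read_text(encoding="utf-8-sig").replace("\r\n", "\n")
    if text.lstrip().startswith("{"):
        data = json.loads(text)
        return [Molecule(id=k, smiles=v) for k, v in data.items()]
    mols = []
    for line in text.splitlines():
        if not line.strip():
            continue
        mol_id, smiles = line.split("\t")[:2]
        mols.append(Molecule(id=mol_id.strip(), smiles=smiles.strip()))
    return mols


def read_protein_set(seq_path: str | Path, go_path: str | Path | None = None) -> ProteinSet:
    """Read protein sequences (FASTA or JSON map) and optional GO-term JSON."""
    text = Path(seq_path).read_text(encoding="utf-8-sig").replace("\r\n", "\n")
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        sequences = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(io.StringIO(text), "fasta")
        }
    else:
        sequences = json.loads(text)
    go: dict[str, set[str]] = {}
    if go_path is not None:
        raw = json.loads(Path(go_path).read_text(encoding="utf-8-sig"))
        go = {k: set(v) for k, v in raw.items()}
    return ProteinSet(sequences=sequences, go_terms=go)
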