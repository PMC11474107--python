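"""Entity-by-entity similarity kernels and matrices.

The central kernel is the structure-inclusive similarity (SIS): the fraction
of a *source* molecule's substructures contained in a *collector* molecule,

    SIS(collector, source) = |collector ∩ source| / |source|.

It is asymmetric — a superset molecule collects weight 1 from any of its
subsets, while the subset collects only the contained fraction back.  The
symmetric comparison kernels (Tanimoto/Jaccard, a bounded Euclidean map, and
normalized Smith–Waterman for protein sequences) share the same matrix
container so graph construction is kernel-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, DomainError, InputError
from .featurize import AMINO_ALPHABET, SubstructureSet

KINDS = ("sis", "tanimoto", "jaccard", "euclidean", "smith_waterman", "precomputed")


@dataclass
class SimilarityMatrix:
    """Square entity x entity weight matrix in [0, 1] with unit diagonal.

    ``values[i, j]`` is the weight entity i collects from entity j; for the
    symmetric kernels the orientation is immaterial.
    """

    entity_ids: list[str]
    values: np.ndarray
    kind: str
    symmetric: bool = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise InputError(
                f"similarity matrix shape {self.values.shape} != ({n}, {n})"
            )
        if np.any(~np.isfinite(self.values)):
            raise InputError("similarity matrix has non-finite entries")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise InputError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0):
            raise InputError("similarity matrix diagonal must be 1")
        self.symmetric = bool(np.allclose(self.values, self.values.T))

    @property
    def n(self) -> int:
        return len(self.entity_ids)


def sis_weight(collector: SubstructureSet, source: SubstructureSet) -> float:
    """Weight ``collector`` collects from ``source``: |collector ∩ source| / |source|."""
    if not source.identifiers:
        raise DomainError(
            f"molecule {source.molecule_id!r}: empty substructure set (division by zero)"
        )
    return len(collector.identifiers & source.identifiers) / len(source.identifiers)


def sis_matrix(sets: Sequence[SubstructureSet]) -> SimilarityMatrix:
    """Pairwise SIS matrix; entry (i, j) is the weight i collects from j."""
    for s in sets:
        if not s.identifiers:
            raise DomainError(f"molecule {s.molecule_id!r}: empty substructure set")
    n = len(sets)
    values = np.empty((n, n))
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            values[i, j] = 1.0 if i == j else sis_weight(a, b)
    return SimilarityMatrix([s.molecule_id for s in sets], values, kind="sis")


def jaccard(a: SubstructureSet, b: SubstructureSet) -> float:
    """|a ∩ b| / |a ∪ b| on identifier sets; symmetric."""
    union = a.identifiers | b.identifiers
    if not union:
        raise DomainError("Jaccard undefined: both sets empty")
    return len(a.identifiers & b.identifiers) / len(union)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard on binary bit vectors (the Tanimoto coefficient)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"bit vector lengths differ: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        raise DomainError("Tanimoto undefined: both vectors empty")
    return int(np.sum(a & b)) / union


def euclidean_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Bounded similarity 1 / (1 + d) with d the Euclidean distance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"vector lengths differ: {a.shape} vs {b.shape}")
    return 1.0 / (1.0 + float(np.linalg.norm(a - b)))


_ALIGNER_CACHE: dict[tuple, object] = {}


def _aligner(matrix_name: str, gap_open: float, gap_extend: float):
    key = (matrix_name, gap_open, gap_extend)
    if key not in _ALIGNER_CACHE:
        from Bio import Align
        from Bio.Align import substitution_matrices

        aln = Align.PairwiseAligner()
        aln.mode = "local"
        aln.substitution_matrix = substitution_matrices.load(matrix_name)
        aln.open_gap_score = -gap_open
        aln.extend_gap_score = -gap_extend
        _ALIGNER_CACHE[key] = aln
    return _ALIGNER_CACHE[key]


def _check_sequence(seq: str, which: str) -> str:
    if not seq:
        raise InputError(f"{which}: empty sequence")
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in AMINO_ALPHABET:
            raise InputError(f"{which}: illegal residue {ch!r} at position {pos}")
    return seq


def smith_waterman_score(
    seq_a: str, seq_b: str, matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 1.0
) -> float:
    """Optimal local-alignment (Smith–Waterman) score; 0 if nothing aligns positively."""
    seq_a = _check_sequence(seq_a, "sequence a")
    seq_b = _check_sequence(seq_b, "sequence b")
    score = float(_aligner(matrix, gap_open, gap_extend).score(seq_a, seq_b))
    return max(score, 0.0)


def smith_waterman_normalized(
    seq_a: str, seq_b: str, matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 1.0
) -> float:
    """SW(a,b) / sqrt(SW(a,a) * SW(b,b)); 1 for identical sequences."""
    ab = smith_waterman_score(seq_a, seq_b, matrix, gap_open, gap_extend)
    aa = smith_waterman_score(seq_a, seq_a, matrix, gap_open, gap_extend)
    bb = smith_waterman_score(seq_b, seq_b, matrix, gap_open, gap_extend)
    if aa <= 0 or bb <= 0:
        raise DomainError("self-alignment score must be positive for normalization")
    return min(ab / np.sqrt(aa * bb), 1.0)


def similarity_matrix(
    features,
    kind: str,
    entity_ids: Sequence[str] | None = None,
    **params,
) -> SimilarityMatrix:
    """Dispatch to a per-pair kernel and assemble the full matrix.

    ``features`` is a list of SubstructureSet (sis/jaccard), a 2-D array of
    row vectors (tanimoto/euclidean), a list of sequences (smith_waterman),
    or an already-square array (precomputed, validated only).
    """
    if kind not in KINDS:
        raise ConfigError(f"unknown similarity kind {kind!r}; expected one of {KINDS}")
    if kind == "sis":
        return sis_matrix(features)
    if kind == "precomputed":
        if entity_ids is None:
            raise ConfigError("precomputed matrices need entity_ids")
        return SimilarityMatrix(list(entity_ids), np.asarray(features, float), kind="precomputed")

    if kind == "jaccard":
        ids = [s.molecule_id for s in features]
        kernel = lambda i, j: jaccard(features[i], features[j])  # noqa: E731
    elif kind == "tanimoto":
        rows = np.asarray(features)
        ids = list(entity_ids) if entity_ids is not None else [str(i) for i in range(len(rows))]
        kernel = lambda i, j: tanimoto(rows[i], rows[j])  # noqa: E731
    elif kind == "euclidean":
        rows = np.asarray(features, dtype=float)
        ids = list(entity_ids) if entity_ids is not None else [str(i) for i in range(len(rows))]
        kernel = lambda i, j: euclidean_similarity(rows[i], rows[j])  # noqa: E731
    else:  # smith_waterman
        seqs = list(features)
        ids = list(entity_ids) if entity_ids is not None else [str(i) for i in range(len(seqs))]
        kernel = lambda i, j: smith_waterman_normalized(seqs[i], seqs[j], **params)  # noqa: E731

    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = kernel(i, j)
    return SimilarityMatrix(ids, values, kind=kind)


def write_similarity_csv(S: SimilarityMatrix, path: str | Path) -> None:
    """Square CSV with a header row of entity ids; 10 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("," + ",".join(S.entity_ids) + "\n")
        for eid, row in zip(S.entity_ids, S.values):
            fh.write(eid + "," + ",".join(f"{v:.10g}" for v in row) + "\n")


def read_similarity_csv(path: str | Path, kind: str = "precomputed") -> SimilarityMatrix:
    text = Path(path).read_text(encoding="utf-8-sig").replace("\r\n", "\n")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split(",")[1:]
    values = np.array([[float(x) for x in ln.split(",")[1:]] for ln in lines[1:]])
    return SimilarityMatrix([h.strip() for h in header], values, kind=kind)
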