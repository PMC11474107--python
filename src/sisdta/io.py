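"""Dataset container, readers and writers.

The on-disk layout mirrors the widely distributed DTA benchmark format: a
JSON map of drug id → SMILES, a JSON map of protein id → sequence, an
optional JSON map of protein id → GO terms, a drugs × proteins affinity CSV
with NaN for unmeasured cells, and a fold-index JSON addressing the labeled
cells in row-major order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class PairDataset:
    """Affinity labels over the drug × protein grid with fold assignments.

    ``train_folds`` and ``test_indices`` index into the row-major list of
    labeled (non-missing) cells.
    """

    drug_ids: list[str]
    protein_ids: list[str]
    affinities: np.ndarray  # (m, n) with NaN = missing
    train_folds: list[list[int]]
    test_indices: list[int]

    def __post_init__(self) -> None:
        self.affinities = np.asarray(self.affinities, dtype=float)
        m, n = len(self.drug_ids), len(self.protein_ids)
        if self.affinities.shape != (m, n):
            raise InputError(
                f"affinity matrix shape {self.affinities.shape} != ({m}, {n})"
            )
        n_labeled = len(self.labeled_cells())
        if n_labeled == 0:
            raise InputError("affinity matrix has no labeled cells")
        all_idx = [i for fold in self.train_folds for i in fold] + list(self.test_indices)
        if any(i < 0 or i >= n_labeled for i in all_idx):
            raise InputError("fold index addresses a missing or out-of-range cell")
        if len(set(all_idx)) != len(all_idx):
            raise InputError("folds overlap")
        logger.info(
            "dataset: %d drugs x %d proteins, %d labeled cells (%.1f%% missing)",
            m, n, n_labeled, 100.0 * (1 - n_labeled / (m * n)),
        )

    def labeled_cells(self) -> list[tuple[int, int]]:
        """Row-major (drug index, protein index) positions of labeled cells."""
        rows, cols = np.nonzero(~np.isnan(self.affinities))
        return list(zip(rows.tolist(), cols.tolist()))

    def _pairs_for(self, flat_indices) -> tuple[list[tuple[str, str]], np.ndarray]:
        cells = self.labeled_cells()
        pairs, y = [], []
        for idx in flat_indices:
            i, j = cells[idx]
            pairs.append((self.drug_ids[i], self.protein_ids[j]))
            y.append(self.affinities[i, j])
        return pairs, np.asarray(y)

    def training_pairs(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        flat = [i for fold in self.train_folds for i in fold]
        return self._pairs_for(flat)

    def test_pairs(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        return self._pairs_for(self.test_indices)


@dataclass
class RunConfig:
    """End-to-end run settings, serialized verbatim into every manifest."""

    fingerprint_radius: int = 2
    fingerprint_length: int = 1024
    drug_similarity: str = "sis"
    protein_similarity: str = "smith_waterman"
    delta_drug: float = 0.6
    delta_protein: float = 0.6
    k: int = 5
    affinity_transform: str = "none"  # or "pkd"
    gcn_hidden: int = 64
    gcn_out: int = 32
    latent_dim: int = 32
    head_hidden: int = 32
    lr: float = 1e-2
    epochs: int = 200
    seed: int = 0

    def validate(self) -> "RunConfig":
        from .errors import ConfigError

        if not 0 <= self.delta_drug <= 1 or not 0 <= self.delta_protein <= 1:
            raise ConfigError("thresholds must lie in [0, 1]")
        if self.k < 0 or self.epochs < 0 or self.fingerprint_length < 1:
            raise ConfigError("k, epochs and fingerprint_length must be non-negative")
        if self.affinity_transform not in ("none", "pkd"):
            raise ConfigError(f"unknown affinity transform {self.affinity_transform!r}")
        return self


def pkd_transform(kd_nanomolar: np.ndarray) -> np.ndarray:
    """Davis-style transform: pKd = −log10(Kd / 1e9) for Kd in nM."""
    return -np.log10(np.asarray(kd_nanomolar, dtype=float) / 1e9)


def read_dataset(directory: str | Path) -> PairDataset:
    """Read a dataset directory (affinities.csv + folds.json at minimum)."""
    directory = Path(directory)
    aff = pd.read_csv(directory / "affinities.csv", index_col=0)
    drug_ids = [str(x) for x in aff.index]
    protein_ids = [str(x) for x in aff.columns]
    ligands_path = directory / "ligands.json"
    if ligands_path.exists():
        ligands = json.loads(ligands_path.read_text(encoding="utf-8-sig"))
        if len(ligands) != len(drug_ids):
            raise InputError(
                f"SMILES map has {len(ligands)} drugs but affinity matrix has {len(drug_ids)} rows"
            )
    folds = json.loads((directory / "folds.json").read_text(encoding="utf-8-sig"))
    return PairDataset(
        drug_ids=drug_ids,
        protein_ids=protein_ids,
        affinities=aff.to_numpy(dtype=float),
        train_folds=folds["train_folds"],
        test_indices=folds["test"],
    )


def write_dataset(directory: str | Path, dataset: PairDataset, ligands: dict[str, str] | None = None,
                  proteins: dict[str, str] | None = None, go_terms: dict[str, list[str]] | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        dataset.affinities, index=dataset.drug_ids, columns=dataset.protein_ids
    ).to_csv(directory / "affinities.csv")
    (directory / "folds.json").write_text(
        json.dumps({"train_folds": dataset.train_folds, "test": dataset.test_indices}),
        encoding="utf-8",
    )
    if ligands is not None:
        (directory / "ligands.json").write_text(json.dumps(ligands, indent=1), encoding="utf-8")
    if proteins is not None:
        (directory / "proteins.json").write_text(json.dumps(proteins, indent=1), encoding="utf-8")
    if go_terms is not None:
        (directory / "go_terms.json").write_text(
            json.dumps({k: sorted(v) for k, v in go_terms.items()}, indent=1), encoding="utf-8"
        )


def write_embedding_tsv(path: str | Path, ids: list[str], matrix: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for eid, row in zip(ids, np.asarray(matrix, dtype=float)):
            fh.write(eid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(directory: str | Path, config: dict, seed: int, inputs: list[str | Path]) -> Path:
    """JSON manifest recording config, seed, input checksums and version."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "sisdta",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).is_file()},
    }
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out
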