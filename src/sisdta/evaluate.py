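"""Regression metrics for affinity prediction and the threshold-sweep report.

Metrics follow the conventions of the DTA benchmarking literature:

* MSE / RMSE — ordinary squared-error statistics.
* CI (concordance index) — fraction of pairs with distinct true affinities
  that the predictions rank in the same order, prediction ties scoring 1/2.
* rm² — external-validation index r²·(1 − sqrt(|r² − r₀²|)), where r² is the
  squared Pearson correlation with intercept and r₀² the coefficient of
  determination of the best through-origin proportional fit ŷ → k·ŷ.
* Spearman — Pearson correlation of average-tie ranks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DomainError, InputError


def _validated(y_true, y_pred, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise InputError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if len(y_true) < min_n:
        raise InputError(f"need at least {min_n} points, got {len(y_true)}")
    return y_true, y_pred


def mse(y_true, y_pred) -> float:
    y_true, y_pred = _validated(y_true, y_pred)
    return float(np.mean((y_true - y_pred) ** 2))


def rmse(y_true, y_pred) -> float:
    return float(np.sqrt(mse(y_true, y_pred)))


def spearman(y_true, y_pred) -> float:
    y_true, y_pred = _validated(y_true, y_pred)
    return float(stats.spearmanr(y_true, y_pred).statistic)


def concordance_index(y_true, y_pred) -> float:
    """Pairwise concordance over pairs with distinct true values; ties in the
    predictions count 1/2.  Vectorized over all O(n²) ordered pairs."""
    y_true, y_pred = _validated(y_true, y_pred)
    gt = y_true[:, None] > y_true[None, :]  # pair (i, j): y_i > y_j
    Z = int(gt.sum())
    if Z == 0:
        raise DomainError("concordance index undefined: all true values equal")
    pred_diff = y_pred[:, None] - y_pred[None, :]
    score = np.where(pred_diff > 0, 1.0, np.where(pred_diff == 0, 0.5, 0.0))
    return float((score * gt).sum() / Z)


def rm2_index(y_true, y_pred) -> float:
    """r²·(1 − sqrt(|r² − r₀²|)) with r₀² from the through-origin fit y ≈ k·ŷ."""
    y_true, y_pred = _validated(y_true, y_pred, min_n=3)
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise DomainError("rm2 undefined for a constant vector")
    r = float(stats.pearsonr(y_true, y_pred).statistic)
    r2 = r * r
    k = float(np.sum(y_true * y_pred) / np.sum(y_pred**2))
    ss_res0 = float(np.sum((y_true - k * y_pred) ** 2))
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    r02 = 1.0 - ss_res0 / ss_tot
    return r2 * (1.0 - np.sqrt(abs(r2 - r02)))


@dataclass
class MetricsReport:
    """All metrics of one evaluation run plus run metadata."""

    mse: float
    rmse: float
    ci: float
    rm2: float
    spearman: float
    n_pairs: int
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "MetricsReport":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))

    def to_text(self) -> str:
        lines = [f"{'metric':<10}{'value':>12}"]
        for name in ("mse", "rmse", "ci", "rm2", "spearman"):
            lines.append(f"{name:<10}{getattr(self, name):>12.6f}")
        lines.append(f"{'n_pairs':<10}{self.n_pairs:>12d}")
        return "\n".join(lines)


def evaluate_predictions(y_true, y_pred, metadata: dict | None = None) -> MetricsReport:
    y_true, y_pred = _validated(y_true, y_pred)
    return MetricsReport(
        mse=mse(y_true, y_pred),
        rmse=rmse(y_true, y_pred),
        ci=concordance_index(y_true, y_pred),
        rm2=rm2_index(y_true, y_pred),
        spearman=spearman(y_true, y_pred),
        n_pairs=len(y_true),
        metadata=metadata or {},
    )


def threshold_sweep(
    dataset,
    drug_views,
    protein_views,
    drug_similarity,
    protein_similarity,
    deltas,
    k: int = 5,
    model_config=None,
    optimizer_config=None,
    seed: int = 0,
) -> list[MetricsReport]:
    """One full train/evaluate cycle per threshold δ with shared seed/splits.

    Returns one MetricsReport per δ, mirroring a per-threshold comparison
    table (threshold, MSE, CI, rm²)."""
    from .graphs import build_relationship_graph
    from .model import train, predict

    if not deltas:
        raise InputError("need at least one threshold")
    reports = []
    test_pairs, y_test = dataset.test_pairs()
    for delta in deltas:
        _, A_d = build_relationship_graph(drug_similarity, delta=delta, k=k, symmetric=False)
        _, A_p = build_relationship_graph(
            protein_similarity, delta=delta, k=k, symmetric=protein_similarity.symmetric
        )
        model, _ = train(
            dataset, drug_views, protein_views, A_d, A_p,
            model_config=model_config, optimizer_config=optimizer_config, seed=seed,
        )
        y_hat = predict(model, test_pairs)
        rep = evaluate_predictions(y_test, y_hat, metadata={"delta": delta, "k": k, "seed": seed})
        reports.append(rep)
    return reports


def write_sweep_csv(reports: list[MetricsReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold,mse,ci,rm2\n")
        for rep in reports:
            fh.write(f"{rep.metadata.get('delta')},{rep.mse:.6f},{rep.ci:.6f},{rep.rm2:.6f}\n")
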