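"""Hyperparameter selection by k-fold cross-validated held-out negative
log-likelihood over a grid of (latent side, RBF side, lambda) candidates."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from . import gtm

__all__ = ["CandidateConfig", "SelectionResult", "DEFAULT_GRID", "DEFAULT_FOLDS",
           "cv_score", "grid_search"]

DEFAULT_FOLDS = 10


@dataclass(frozen=True)
class CandidateConfig:
    side: int = 15
    rbf_side: int = 14
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("side must be >= 2")
        if self.rbf_side < 1:
            raise ValueError("rbf_side must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


#: Illustrative search grid around the default configuration.  The default
#: candidate (side 15 -> 225 nodes, 14x14 -> 196 RBFs, lambda 1) is always
#: present.
DEFAULT_GRID: list[CandidateConfig] = [
    CandidateConfig(side, rbf, lam)
    for side, rbf in [(10, 8), (12, 10), (15, 14), (20, 18)]
    for lam in [0.1, 1.0, 10.0]
]


@dataclass
class SelectionResult:
    table: pd.DataFrame            # one row per candidate, fold columns + mean/std
    selected: CandidateConfig
    folds: int
    seed: int

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def selected_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "side": self.selected.side,
            "rbf_side": self.selected.rbf_side,
            "lambda": self.selected.lam,
            "folds": self.folds,
            "seed": self.seed,
        }, indent=2))


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Single seeded shuffle, then contiguous near-equal blocks."""
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(block) for block in np.array_split(perm, folds)]


def cv_score(
    data: np.ndarray,
    config: CandidateConfig,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[float]:
    """Per-fold held-out mean negative log-likelihood for one candidate.

    Subjects are shuffled once with the seed and split into near-equal
    contiguous folds; for each fold the model is fitted on the complement
    and the mean per-subject NLL evaluated on the held-out subjects.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds ({folds}) cannot exceed the number of subjects ({n})")
    scores: list[float] = []
    for test_idx in _fold_indices(n, folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        model, _ = gtm.fit(
            data[mask], side=config.side, rbf_side=config.rbf_side,
            lam=config.lam, seed=seed, max_iter=max_iter, tol=tol,
        )
        _, ll = gtm.e_step(model, data[test_idx])
        scores.append(-ll / len(test_idx))
    return scores


def grid_search(
    data: np.ndarray,
    grid: list[CandidateConfig] | None = None,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    rule: str = "one_se",
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SelectionResult:
    """Score every candidate with the same fold partition and select one.

    Selection operationalises "good held-out mean with minimal fold spread":
    under the default one-standard-error rule, among candidates whose mean
    NLL lies within one standard error of the best mean, the candidate with
    the smallest fold standard deviation wins; remaining ties break toward
    fewer latent nodes, then fewer RBFs, then stronger regularisation.
    ``rule='mean'`` picks the best mean outright.
    """
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    if not grid:
        raise ValueError("candidate grid is empty")
    if rule not in {"one_se", "mean"}:
        raise ValueError(f"unknown selection rule {rule!r}")
    rows = []
    for cfg in grid:
        try:
            scores = cv_score(data, cfg, folds=folds, seed=seed,
                              max_iter=max_iter, tol=tol)
        except (ValueError, np.linalg.LinAlgError) as err:
            rows.append({"side": cfg.side, "rbf_side": cfg.rbf_side, "lambda": cfg.lam,
                         "failed": str(err)})
            continue
        row = {"side": cfg.side, "rbf_side": cfg.rbf_side, "lambda": cfg.lam,
               "failed": ""}
        for i, s in enumerate(scores):
            row[f"fold{i}"] = s
        row["mean_nll"] = float(np.mean(scores))
        row["std_nll"] = float(np.std(scores, ddof=1))
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["failed"] == ""].copy()
    if ok.empty:
        raise RuntimeError("every candidate configuration failed to fit")
    best = ok.loc[ok["mean_nll"].idxmin()]
    if rule == "mean":
        eligible = ok[ok["mean_nll"] == best["mean_nll"]]
    else:
        se = best["std_nll"] / np.sqrt(folds)
        eligible = ok[ok["mean_nll"] <= best["mean_nll"] + se]
    # smallest fold spread, then fewer nodes, fewer RBFs, larger lambda
    eligible = eligible.sort_values(
        by=["std_nll", "side", "rbf_side", "lambda"],
        ascending=[True, True, True, False],
        kind="mergesort",
    )
    sel = eligible.iloc[0]
    selected = CandidateConfig(int(sel["side"]), int(sel["rbf_side"]), float(sel["lambda"]))
    return SelectionResult(table=table, selected=selected, folds=folds, seed=seed)
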