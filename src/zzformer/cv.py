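"""Repeated five-fold cross-validation with train/validation/test rotation.

Protocol: each round partitions the samples into five near-equal folds with
a round-specific seed (``base_seed + round``).  Within a round every fold
serves as the test set exactly once; the validation fold is the next fold
cyclically, and the remaining three folds train the model.  Twenty rounds of
five folds give 100 independent training-validation-testing runs.  Models
flagged as not needing a validation fold (e.g. tree ensembles) train on all
four non-test folds.  Features are standardized per run on the training rows
only.

Grid search uses one dedicated round (a seed disjoint from the evaluation
rounds) and selects the configuration maximizing the mean over folds of
(train C-index + validation C-index), ties broken by enumeration order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .data_io import SurvivalCohort, apply_standardizer, fit_standardizer
from .evaluation import concordance_index
from .model import ModelConfig
from .training import TrainConfig, ZeroEventsError, train_linear_cox, train_model

__all__ = ["FoldPlan", "CVResult", "ModelSpec", "ZZFormerSpec", "LinearCoxSpec",
           "make_fold_plan", "run_cv", "grid_search"]


@dataclass(frozen=True)
class FoldPlan:
    """Round x fold role assignment realizing the repeated-CV protocol."""

    n_samples: int
    n_folds: int
    n_rounds: int
    base_seed: int
    folds: tuple  # folds[r][f] -> tuple of sample indices

    @property
    def n_runs(self) -> int:
        return self.n_folds * self.n_rounds

    def roles(self, rnd: int, test_fold: int):
        """(train_rows, val_rows, test_rows) for one run."""
        val_fold = (test_fold + 1) % self.n_folds
        test = np.asarray(self.folds[rnd][test_fold])
        val = np.asarray(self.folds[rnd][val_fold])
        train = np.concatenate(
            [self.folds[rnd][f] for f in range(self.n_folds)
             if f not in (test_fold, val_fold)]
        )
        return train, val, test

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_samples": self.n_samples,
                "n_folds": self.n_folds,
                "n_rounds": self.n_rounds,
                "base_seed": self.base_seed,
                "folds": [[list(map(int, f)) for f in rnd] for rnd in self.folds],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        folds = tuple(tuple(tuple(f) for f in rnd) for rnd in d.pop("folds"))
        return cls(folds=folds, **d)


def make_fold_plan(n_samples: int, n_folds: int = 5, n_rounds: int = 20,
                   base_seed: int = 0) -> FoldPlan:
    """Balanced random partitions, deterministic from ``base_seed``."""
    if n_samples < n_folds:
        raise ValueError(f"n_samples={n_samples} < n_folds={n_folds}")
    rounds = []
    for r in range(n_rounds):
        perm = np.random.default_rng(base_seed + r).permutation(n_samples)
        rounds.append(tuple(tuple(map(int, f)) for f in np.array_split(perm, n_folds)))
    return FoldPlan(n_samples, n_folds, n_rounds, base_seed, tuple(rounds))


class ModelSpec(Protocol):
    """Adapter contract a survival learner plugs into the harness with."""

    name: str
    needs_validation: bool

    def fit(self, train: SurvivalCohort, val: SurvivalCohort | None, seed: int): ...

    # fit returns a fitted object exposing predict_risk(X) -> np.ndarray


@dataclass(frozen=True)
class ZZFormerSpec:
    """Harness adapter for the transformer."""

    token_dim: int = 64
    num_heads: int = 8
    num_blocks: int = 2
    dropout: float = 0.1
    learning_rate: float = 0.002
    weight_decay: float = 0.3
    max_epochs: int = 200
    patience: int = 20
    name: str = "ZZFormer"
    needs_validation: bool = True

    def fit(self, train, val, seed: int):
        mcfg = ModelConfig(n_features=train.n_genes, token_dim=self.token_dim,
                           num_heads=self.num_heads, num_blocks=self.num_blocks,
                           dropout=self.dropout)
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           weight_decay=self.weight_decay,
                           max_epochs=self.max_epochs,
                           patience=min(self.patience, self.max_epochs),
                           seed=seed)
        model, _ = train_model(train, val, mcfg, tcfg)
        return model


@dataclass(frozen=True)
class LinearCoxSpec:
    """Harness adapter for the linear-Cox baseline."""

    learning_rate: float = 0.01
    weight_decay: float = 0.3
    max_epochs: int = 200
    patience: int = 20
    name: str = "LinearCox"
    needs_validation: bool = True

    def fit(self, train, val, seed: int):
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           weight_decay=self.weight_decay,
                           max_epochs=self.max_epochs,
                           patience=min(self.patience, self.max_epochs),
                           seed=seed)
        model, _ = train_linear_cox(train, val, tcfg)
        return model


@dataclass
class CVResult:
    """Per-run records plus the mean +/- sd aggregate of the test C-index."""

    records: pd.DataFrame  # round, fold, model, train_c, val_c, test_c, seed, status
    n_failed: int = 0

    def aggregate(self) -> pd.DataFrame:
        ok = self.records[self.records["status"] == "ok"]
        return (
            ok.groupby("model")["test_c"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_runs="count")
            .reset_index()
        )


def _score(model, cohort: SurvivalCohort | None) -> float:
    if cohort is None or cohort.n_samples == 0:
        return np.nan
    try:
        return concordance_index(
            model.predict_risk(cohort.X), cohort.time, cohort.event
        ).cindex
    except ValueError:
        return np.nan


def run_cv(cohort: SurvivalCohort, spec: ModelSpec, plan: FoldPlan) -> CVResult:
    """Execute every (round, fold) run of the plan for one model spec."""
    rows = []
    n_failed = 0
    for rnd in range(plan.n_rounds):
        for fold in range(plan.n_folds):
            train_rows, val_rows, test_rows = plan.roles(rnd, fold)
            if not spec.needs_validation:
                train_rows = np.concatenate([train_rows, val_rows])
                val_rows = np.array([], dtype=int)
            run_seed = plan.base_seed + 1000 * rnd + fold
            std = fit_standardizer(cohort, train_rows)
            z = apply_standardizer(std, cohort)
            row = {"round": rnd, "fold": fold, "model": spec.name, "seed": run_seed,
                   "train_c": np.nan, "val_c": np.nan, "test_c": np.nan}
            try:
                train = z.subset(train_rows)
                val = z.subset(val_rows) if val_rows.size else None
                fitted = spec.fit(train, val, seed=run_seed)
                row["train_c"] = _score(fitted, train)
                row["val_c"] = _score(fitted, val)
                row["test_c"] = _score(fitted, z.subset(test_rows))
                row["status"] = "ok"
            except (ZeroEventsError, ValueError) as exc:
                row["status"] = f"failed: {exc}"
                n_failed += 1
            rows.append(row)
    return CVResult(records=pd.DataFrame(rows), n_failed=n_failed)


DEFAULT_GRID = {
    "token_dim": [32, 64],
    "num_heads": [4, 8],
    "num_blocks": [1, 2],
    "dropout": [0.1, 0.3],
    "learning_rate": [0.01, 0.002],
    "weight_decay": [0.05, 0.1, 0.3],
}


def grid_search(cohort: SurvivalCohort, grid: dict[str, list], plan: FoldPlan,
                spec_factory: Callable[..., ModelSpec] = ZZFormerSpec,
                score: str = "train_plus_val") -> tuple[dict, pd.DataFrame]:
    """One-round grid search; returns (best point, per-point score table).

    The default selection score for a grid point is the mean over folds of
    (train C + val C); ``score='val'`` uses the validation C alone.  Ties go
    to the earliest enumerated point.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if plan.n_rounds != 1:
        raise ValueError("grid search uses a one-round fold plan")
    if score not in ("train_plus_val", "val"):
        raise ValueError(f"unknown score {score!r}")
    keys = list(grid)
    rows = []
    best_point, best_score = None, -np.inf
    for values in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        res = run_cv(cohort, spec_factory(**point), plan)
        ok = res.records[res.records["status"] == "ok"]
        per_fold = (ok["train_c"] + ok["val_c"]) if score == "train_plus_val" else ok["val_c"]
        score_val = float(per_fold.mean()) if len(ok) else -np.inf
        rows.append(point | {"score": score_val, "n_ok": len(ok)})
        if score_val > best_score:
            best_point, best_score = point, score_val
    return best_point, pd.DataFrame(rows)


def save_cv_result(result: CVResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"runs": out / "cv_runs.csv", "summary": out / "cv_summary.csv"}
    result.records.to_csv(paths["runs"], index=False)
    result.aggregate().to_csv(paths["summary"], index=False)
    return paths
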