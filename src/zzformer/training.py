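"""Cox partial-likelihood training loop.

The loss is the negative log partial likelihood

    L = - sum_{i: delta_i = 1} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ],

with risk sets inclusive of tied times (Breslow's convention; with continuous
simulated times ties have probability zero anyway).  The partial likelihood
couples samples through the risk sets, so the default training regime is
full-cohort batches; gradients flow through a log-sum-exp-stabilized
computation.  Optimization is Adam with L2 weight decay.  Early stopping
monitors the validation C-index (falling back to validation loss when the
validation fold has too few events to rank) and restores the
best-validation-epoch weights.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .data_io import SurvivalCohort
from .evaluation import concordance_index
from .model import ModelConfig, ZZFormer

__all__ = [
    "TrainConfig",
    "TrainRecord",
    "LinearCox",
    "cox_nll",
    "cox_nll_grad",
    "cox_nll_tensor",
    "train_model",
    "train_linear_cox",
]


class ZeroEventsError(ValueError):
    """The Cox partial likelihood is undefined without observed events."""


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults: lr 0.002, Adam + weight decay)."""

    learning_rate: float = 0.002
    weight_decay: float = 0.1
    max_epochs: int = 200
    patience: int = 20
    min_epochs: int = 0
    warmup_loss_drop: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if self.min_epochs < 0:
            raise ValueError("min_epochs must be non-negative")


@dataclass
class TrainRecord:
    """Per-epoch trajectory; ``selected_epoch`` is 1-based (0 = untrained)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_cindex: list[float] = field(default_factory=list)
    selected_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_cindex": self.val_cindex,
            }
        )


def _risk_matrix(time: np.ndarray, event: np.ndarray):
    """Rows of the risk-set indicator for event subjects: R[e, j] = t_j >= t_e."""
    ev = np.flatnonzero(event == 1)
    if ev.size == 0:
        raise ZeroEventsError("no observed events: partial likelihood undefined")
    return ev, (time[None, :] >= time[ev, None]).astype(np.float64)


def cox_nll(risks, time, event) -> float:
    """Negative log partial likelihood (sum over events), stabilized."""
    r = np.asarray(risks, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    if not np.isfinite(r).all():
        raise ValueError("risk scores must be finite")
    ev, R = _risk_matrix(time, event)
    c = r.max()
    log_den = c + np.log(R @ np.exp(r - c))
    return float(-(r[ev] - log_den).sum())


def cox_nll_grad(risks, time, event) -> np.ndarray:
    """Closed-form gradient: dL/dr_k = -delta_k + sum_e R[e,k] exp(r_k) / den_e."""
    r = np.asarray(risks, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    ev, R = _risk_matrix(time, event)
    c = r.max()
    e = np.exp(r - c)
    den = R @ e
    g = (R / den[:, None]).sum(axis=0) * e
    g[ev] -= 1.0
    return g


def cox_nll_tensor(risks: Tensor, time, event, normalize: bool = False) -> Tensor:
    """Differentiable loss on an autodiff tensor; optionally per-event mean."""
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    ev, R = _risk_matrix(time, event)
    c = float(risks.data.max())  # constant shift: exact by shift invariance
    e = (risks - c).exp()
    log_den = (Tensor(R) @ e).log() + c
    loss = -(risks[ev] - log_den).sum()
    return loss * (1.0 / ev.size) if normalize else loss


def _evaluate_fold(model, cohort: SurvivalCohort | None):
    if cohort is None:
        return np.nan, np.nan
    risks = model.forward(cohort.X, training=False).data
    try:
        loss = cox_nll(risks, cohort.time, cohort.event) / max(int(cohort.event.sum()), 1)
    except ZeroEventsError:
        loss = np.nan
    try:
        ci = concordance_index(risks, cohort.time, cohort.event).cindex
    except ValueError:
        ci = np.nan
    return loss, ci


def _fit_loop(model, train: SurvivalCohort, val: SurvivalCohort | None,
              tcfg: TrainConfig) -> TrainRecord:
    if int(train.event.sum()) < 1:
        raise ZeroEventsError("training cohort has no observed events")
    record = TrainRecord()
    if tcfg.max_epochs == 0:
        return record
    opt = Adam(model.parameters(), lr=tcfg.learning_rate,
               weight_decay=tcfg.weight_decay,
               decay_mask=getattr(model, "decay_mask", lambda: None)())
    drop_rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 0x5EED]))
    best_score, best_state, best_epoch, since_best = -np.inf, None, 0, 0
    use_val = val is not None
    for epoch in range(1, tcfg.max_epochs + 1):
        opt.zero_grad()
        risks = model.forward(train.X, training=True, rng=drop_rng)
        loss = cox_nll_tensor(risks, train.time, train.event, normalize=True)
        if not np.isfinite(loss.data):
            raise TrainingDivergedError(f"non-finite training loss at epoch {epoch}")
        loss.backward()
        opt.step()
        record.train_loss.append(float(loss.data))
        vl, vc = _evaluate_fold(model, val)
        record.val_loss.append(vl)
        record.val_cindex.append(vc)
        # epochs where the model is still near its initialization are not
        # eligible for selection: a validation C-index spike at a barely
        # trained epoch would otherwise freeze the model there
        warmed_up = (epoch > tcfg.min_epochs
                     and loss.data <= (1 - tcfg.warmup_loss_drop) * record.train_loss[0]
                     ) or epoch == tcfg.max_epochs
        if use_val and warmed_up:
            score = vc if np.isfinite(vc) else -vl
            if score > best_score:
                best_score, best_epoch, since_best = score, epoch, 0
                best_state = copy.deepcopy(model.state_dict())
            else:
                since_best += 1
                if since_best > tcfg.patience:
                    break
    if use_val and best_state is not None:
        model.load_state_dict(best_state)
        record.selected_epoch = best_epoch
    else:
        record.selected_epoch = len(record.train_loss)
    return record


def train_model(train: SurvivalCohort, val: SurvivalCohort | None,
                mcfg: ModelConfig, tcfg: TrainConfig) -> tuple[ZZFormer, TrainRecord]:
    """Train the transformer; reproducible from ``tcfg.seed``."""
    model = ZZFormer(mcfg, seed=tcfg.seed)
    record = _fit_loop(model, train, val, tcfg)
    return model, record


class LinearCox:
    """Degenerate single-linear-layer risk model: PI = beta^T x.

    Trained with the same loss and loop as the transformer; serves as the
    in-repo proportional-hazards baseline.
    """

    def __init__(self, n_features: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.beta = Tensor(0.01 * rng.standard_normal(n_features), requires_grad=True)
        self.n_features = n_features

    def parameters(self):
        return [self.beta]

    def decay_mask(self):
        return [True]  # the coefficient vector is the model; always regularized

    def state_dict(self):
        return {"beta": self.beta.data.copy()}

    def load_state_dict(self, state):
        self.beta.data = np.asarray(state["beta"], dtype=np.float64).copy()

    @property
    def coef_(self) -> np.ndarray:
        return self.beta.data.copy()

    def forward(self, X, training: bool = False, rng=None) -> Tensor:
        return Tensor(np.atleast_2d(X)) @ self.beta

    def predict_risk(self, X) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=np.float64)) @ self.beta.data


def train_linear_cox(train: SurvivalCohort, val: SurvivalCohort | None,
                     tcfg: TrainConfig) -> tuple[LinearCox, TrainRecord]:
    model = LinearCox(train.n_genes, seed=tcfg.seed)
    record = _fit_loop(model, train, val, tcfg)
    return model, record
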