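"""Sampling Shapley attribution of the Prognosis Index to individual genes.

The model is treated as a cooperative game over features: the value of a
coalition S for sample x is the expected PI when genes in S take x's values
and the remaining genes are filled in from background samples.  Coalitions
are drawn from the Shapley kernel distribution (size k with probability
proportional to (G-1)/(k(G-k))), coalition values are regressed on the
membership indicators, and the local-accuracy constraint
``baseline + sum(phi) = PI(x)`` is enforced exactly by eliminating one
coefficient in the least-squares solve.  For a linear risk model the
attributions converge to ``beta_j * (x_j - mean_background(x_j))``, the
closed-form Shapley value, which the test suite uses as the strongest
oracle.  An exact enumerator is provided for small feature counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AttributionResult", "shapley_attributions", "rank_genes", "exact_shapley"]


@dataclass
class AttributionResult:
    genes: list[str]
    attributions: np.ndarray  # explained samples x genes
    baseline: float  # expected PI over the background
    predictions: np.ndarray  # PI of each explained sample

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.attributions).mean(axis=0)

    @property
    def mean_signed(self) -> np.ndarray:
        return self.attributions.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "mean_abs": self.mean_abs,
             "mean_signed": self.mean_signed}
        )


def _predict_chunked(predict, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
    out = np.empty(X.shape[0])
    for lo in range(0, X.shape[0], chunk):
        out[lo:lo + chunk] = np.asarray(predict(X[lo:lo + chunk])).ravel()
    return out


def _sample_masks(G: int, n_coalitions: int, rng: np.random.Generator) -> np.ndarray:
    """Draw coalition indicators from the Shapley kernel size distribution.

    Masks are drawn in antithetic pairs (each with its complement, whose
    kernel weight is identical) — the standard variance-reduction device for
    kernel-weighted coalition sampling.
    """
    sizes = np.arange(1, G)
    pk = (G - 1) / (sizes * (G - sizes))
    pk /= pk.sum()
    half = (n_coalitions + 1) // 2
    ks = rng.choice(sizes, size=half, p=pk)
    Z = np.zeros((2 * half, G), dtype=np.float64)
    for i, k in enumerate(ks):
        Z[2 * i, rng.choice(G, size=k, replace=False)] = 1.0
        Z[2 * i + 1] = 1.0 - Z[2 * i]
    return Z[:n_coalitions]


def _coalition_values(predict, x: np.ndarray, Z: np.ndarray,
                      background: np.ndarray) -> np.ndarray:
    """Mean PI over background rows with coalition genes set to x."""
    vals = np.zeros(Z.shape[0])
    for b in background:
        vals += _predict_chunked(predict, Z * x + (1.0 - Z) * b)
    return vals / background.shape[0]


def shapley_attributions(model, X_explain: np.ndarray, background: np.ndarray,
                         genes: list[str] | None = None, n_coalitions: int = 2048,
                         seed: int = 0) -> AttributionResult:
    """Kernel-weighted sampling Shapley estimates for each explained sample.

    ``model`` needs a ``predict_risk(X) -> array`` method.  ``background`` is
    an (n_background x G) matrix of reference samples; pass its mean row to
    trade fidelity for speed on expensive models.  The same sampled
    coalitions are reused for every explained sample (paired estimates).
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=np.float64))
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    G = X_explain.shape[1]
    if background.shape[1] != G:
        raise ValueError(
            f"gene-space mismatch: explained {G} vs background {background.shape[1]}"
        )
    if genes is None:
        genes = [f"G{j:05d}" for j in range(G)]
    if len(genes) != G:
        raise ValueError("gene list length does not match feature count")
    predict = model.predict_risk
    rng = np.random.default_rng(seed)
    Z = _sample_masks(G, n_coalitions, rng)
    baseline = float(_predict_chunked(predict, background).mean())
    preds = _predict_chunked(predict, X_explain)

    # eliminate the last coefficient to enforce local accuracy exactly:
    # y - base - z_G (f - base) = sum_{j<G} (z_j - z_G) phi_j
    # the sampled design is shared by all explained samples, so factor it once
    A = Z[:, :-1] - Z[:, -1:]
    A_pinv = np.linalg.pinv(A)
    phis = np.zeros((X_explain.shape[0], G))
    for s, x in enumerate(X_explain):
        y = _coalition_values(predict, x, Z, background)
        rhs = y - baseline - Z[:, -1] * (preds[s] - baseline)
        sol = A_pinv @ rhs
        phis[s, :-1] = sol
        phis[s, -1] = (preds[s] - baseline) - sol.sum()
    return AttributionResult(genes=list(genes), attributions=phis,
                             baseline=baseline, predictions=preds)


def exact_shapley(model, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by subset enumeration; feasible for G <= 12."""
    x = np.asarray(x, dtype=np.float64).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    G = x.size
    if G > 12:
        raise ValueError("exact enumeration limited to G <= 12")
    predict = model.predict_risk

    def value(mask: np.ndarray) -> float:
        Xm = np.where(mask, x, background)
        return float(np.asarray(predict(Xm)).mean())

    fact = [math.factorial(i) for i in range(G + 1)]
    phi = np.zeros(G)
    for bits in range(1 << G):
        mask = np.array([(bits >> j) & 1 for j in range(G)], dtype=bool)
        s = int(mask.sum())
        v = value(mask)
        for j in range(G):
            if mask[j]:
                # S = mask without j contributes +v to phi_j with weight w(|S|)
                w = fact[s - 1] * fact[G - s] / fact[G]
                phi[j] += w * v
            else:
                w = fact[s] * fact[G - s - 1] / fact[G]
                phi[j] -= w * v
    return phi


def rank_genes(result: AttributionResult, top_k: int | None = None) -> list[str]:
    """Genes by decreasing mean |attribution|; stable tie-break by input order."""
    order = np.argsort(-result.mean_abs, kind="stable")
    ranked = [result.genes[i] for i in order]
    if top_k is not None:
        if top_k > len(ranked):
            import warnings

            warnings.warn(f"top_k={top_k} exceeds gene count; clipping", stacklevel=2)
        ranked = ranked[:top_k]
    return ranked
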