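"""Concordance index for right-censored survival data.

The statistic counts ordered pairs (i, j) with T_i > T_j and the event of j
observed; such a pair is concordant when the model assigned j — the subject
who died earlier — the higher risk (eta_i < eta_j).  The default ``strict``
tie policy gives tied predictions no credit, matching the indicator-function
definition; ``half`` gives them 0.5 (Harrell's convention).  Pairs with tied
survival times are not comparable and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConcordanceResult", "concordance_index", "brute_force_cindex"]


class UndefinedMetricError(ValueError):
    """No comparable pair exists (e.g. everything censored)."""


@dataclass(frozen=True)
class ConcordanceResult:
    cindex: float
    comparable_pairs: int
    concordant_pairs: float  # may be fractional under the half-credit policy


def _validate(risks, time, event):
    risks = np.asarray(risks, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    if not (risks.shape == time.shape == event.shape) or risks.ndim != 1:
        raise ValueError("risks, time, event must be 1-D arrays of equal length")
    if not np.isfinite(risks).all():
        raise ValueError("risk scores must be finite")
    return risks, time, event


def concordance_index(risks, time, event, tie_policy: str = "strict") -> ConcordanceResult:
    """Vectorized O(n^2) concordance index."""
    if tie_policy not in ("strict", "half"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    risks, time, event = _validate(risks, time, event)
    # comparable[i, j] == True for ordered pairs T_i > T_j with delta_j = 1
    comparable = (time[:, None] > time[None, :]) & (event[None, :] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pair: concordance undefined")
    conc = (risks[:, None] < risks[None, :]) & comparable
    n_conc = float(conc.sum())
    if tie_policy == "half":
        ties = (risks[:, None] == risks[None, :]) & comparable
        n_conc += 0.5 * float(ties.sum())
    return ConcordanceResult(n_conc / n_comp, n_comp, n_conc)


def brute_force_cindex(risks, time, event, tie_policy: str = "strict") -> ConcordanceResult:
    """Explicit double-loop oracle with the same contract; tests only."""
    risks, time, event = _validate(risks, time, event)
    n = len(risks)
    n_comp = 0
    n_conc = 0.0
    for i in range(n):
        for j in range(n):
            if time[i] > time[j] and event[j] == 1:
                n_comp += 1
                if risks[i] < risks[j]:
                    n_conc += 1.0
                elif risks[i] == risks[j] and tie_policy == "half":
                    n_conc += 0.5
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pair: concordance undefined")
    return ConcordanceResult(n_conc / n_comp, n_comp, n_conc)
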