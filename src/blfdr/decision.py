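"""Rejection rules and scoring for local false discovery rate vectors.

The oracle procedure treats multiple testing as a compound decision problem:
sort the per-link posterior null probabilities ascending and reject the
largest prefix whose running mean stays at or below the target level q.  The
mean posterior null probability over the rejected set then estimates the
FDR of the decision, so the procedure controls FDR at q by construction
(given the probabilities themselves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DecisionResult", "oracle_reject", "storey_pi0", "score_decisions"]


@dataclass
class DecisionResult:
    """Outcome of the oracle rule at level q."""

    blfdr: np.ndarray
    rejected: np.ndarray
    q: float
    k_rejections: int
    mean_blfdr_rejected: float

    def to_frame(self, table=None) -> pd.DataFrame:
        df = pd.DataFrame({"blfdr": self.blfdr, "rejected": self.rejected.astype(int)})
        if table is not None:
            df = pd.concat([table.to_frame(), df], axis=1)
        return df


def oracle_reject(blfdr, q: float) -> DecisionResult:
    """Reject the k links with smallest null probability whose running mean <= q.

    Ties at the cutoff are broken by original index order (stable sort), so
    among exactly tied values the earliest links enter first.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    blfdr = np.asarray(blfdr, dtype=float)
    if blfdr.ndim != 1 or np.any(blfdr < 0) or np.any(blfdr > 1):
        raise ValueError("blfdr must be a vector of probabilities")
    order = np.argsort(blfdr, kind="stable")
    cum_mean = np.cumsum(blfdr[order]) / np.arange(1, blfdr.size + 1)
    ok = np.nonzero(cum_mean <= q)[0]
    k = int(ok[-1] + 1) if ok.size else 0
    rejected = np.zeros(blfdr.size, dtype=bool)
    rejected[order[:k]] = True
    mean_rej = float(cum_mean[k - 1]) if k > 0 else 0.0
    return DecisionResult(blfdr=blfdr, rejected=rejected, q=q,
                          k_rejections=k, mean_blfdr_rejected=mean_rej)


def storey_pi0(p_values, lam: float = 0.025) -> float:
    """Conservative estimate of the null proportion: #{p > lam} / (m (1-lam)).

    Capped at 1.  lam = 0.025 matches screening two-sided p-values at 0.05.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return float(min(1.0, np.mean(p > lam) / (1.0 - lam)))


def score_decisions(rejected, truth) -> dict:
    """False discovery proportion, sensitivity and specificity vs known truth.

    FDP is 0 by convention when nothing is rejected.
    """
    rejected = np.asarray(rejected).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if rejected.shape != truth.shape:
        raise ValueError("rejected and truth must have equal length")
    n_rej = rejected.sum()
    n_alt = truth.sum()
    n_null = (~truth).sum()
    false_rej = (rejected & ~truth).sum()
    true_rej = (rejected & truth).sum()
    return {
        "FDP": float(false_rej / max(n_rej, 1)),
        "sensitivity": float(true_rej / max(n_alt, 1)),
        "specificity": float((~rejected & ~truth).sum() / max(n_null, 1)),
    }
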