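"""Bayes factors to local false discovery rates and hit calls.

Genes are treated as draws from a two-group mixture: null with prior
probability ``pi0`` and differential with probability ``1 - pi0``.  The
local false discovery rate of a gene is then its posterior null
probability

    lfdr_g = pi0 / (pi0 + (1 - pi0) * BF_g),

with ``BF_g`` the gene's Bayes factor.  ``pi0`` is estimated by a simple
EM fixed point (the mean of the current lfdrs), clipped to [0.5, 1] so a
dense-signal screen cannot drive the null proportion anti-conservatively
low.  Hits are genes with lfdr strictly below the chosen threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LfdrResult", "estimate_pi0", "compute_lfdr", "call_hits"]


@dataclass(frozen=True)
class LfdrResult:
    genes: tuple
    log_bf: np.ndarray
    lfdr: np.ndarray
    pi0: float

    def __post_init__(self):
        lb = np.asarray(self.log_bf, float)
        lf = np.asarray(self.lfdr, float)
        if not (len(self.genes) == len(lb) == len(lf)):
            raise ValueError("ragged LfdrResult arrays")
        object.__setattr__(self, "log_bf", lb)
        object.__setattr__(self, "lfdr", lf)


def _lfdr_from_logbf(log_bf: np.ndarray, pi0: float) -> np.ndarray:
    """lfdr = pi0 / (pi0 + (1-pi0) BF), evaluated in log space."""
    if pi0 >= 1.0:
        return np.ones_like(log_bf)
    # lfdr = 1 / (1 + exp(log_bf + log((1-pi0)/pi0)))
    t = log_bf + np.log1p(-pi0) - np.log(pi0)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(t))


def estimate_pi0(log_bfs, tol: float = 1e-6, max_iter: int = 10_000,
                 clip: tuple = (0.5, 1.0)) -> float:
    """EM estimate of the null proportion from gene-level Bayes factors.

    Iterates ``pi0 <- mean_g lfdr_g(pi0)`` to its fixed point, then clips
    to ``clip`` (default [0.5, 1]).
    """
    log_bfs = np.asarray(log_bfs, float)
    if len(log_bfs) < 10:
        raise ValueError(f"need >=10 genes to estimate pi0, got {len(log_bfs)}")
    if np.any(~np.isfinite(log_bfs)):
        i = int(np.argmax(~np.isfinite(log_bfs)))
        raise ValueError(f"non-finite log Bayes factor at position {i}")
    if np.allclose(log_bfs, 0.0, atol=1e-12):
        # evidence uniformly uninformative: the likelihood in pi0 is flat,
        # so return the conservative boundary
        return clip[1]
    pi0 = 0.9
    for _ in range(max_iter):
        new = float(np.mean(_lfdr_from_logbf(log_bfs, pi0)))
        if abs(new - pi0) < tol:
            pi0 = new
            break
        pi0 = new
    return float(np.clip(pi0, *clip))


def compute_lfdr(genes, log_bfs, pi0: float | None = None) -> LfdrResult:
    """Local false discovery rates for a list of genes.

    ``pi0=None`` estimates the null proportion by EM first.
    """
    log_bfs = np.asarray(log_bfs, float)
    if pi0 is None:
        pi0 = estimate_pi0(log_bfs)
    if not (0 < pi0 <= 1):
        raise ValueError(f"pi0 must lie in (0, 1], got {pi0}")
    lfdr = _lfdr_from_logbf(log_bfs, pi0)
    return LfdrResult(genes=tuple(genes), log_bf=log_bfs, lfdr=lfdr,
                      pi0=float(pi0))


def call_hits(result: LfdrResult, threshold: float = 0.05) -> pd.DataFrame:
    """Flag genes with lfdr strictly below ``threshold``.

    Returns a DataFrame (gene, log_bf, lfdr, hit); the comparison is
    strict, so a gene sitting exactly at the threshold is not a hit.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return pd.DataFrame({
        "gene": list(result.genes),
        "log_bf": result.log_bf,
        "lfdr": result.lfdr,
        "hit": result.lfdr < threshold,
    })
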