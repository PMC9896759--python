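"""Count preprocessing: fold changes and control-anchored lethality scores.

For every endpoint sample the raw counts are turned into per-guide fold
changes relative to that sample's T=0 partner,

    fc_s = (C_s0 - C_s) / C_s0,

the proportion of cells carrying guide ``s`` lost since T=0 (1 = complete
lethality, 0 = no effect, negative = proliferation).  Fold changes are then
rescaled per sample so that the median over negative-control guides sits at
0 and the median over positive-control guides at 1,

    l_s = (fc_s - fc_neg) / (fc_pos - fc_neg),

giving *lethality scores* comparable across samples and cell lines.  An
optional rank-mean quantile normalization equalizes score distributions
across samples when they differ strongly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ControlSet, CountScreen, SampleSheet, ValidationError

__all__ = [
    "FoldChangeMatrix",
    "LethalityMatrix",
    "DegenerateControlsError",
    "compute_fold_changes",
    "lethality_scores",
    "quantile_normalize",
]


class DegenerateControlsError(ValueError):
    """Positive and negative control medians coincide in some sample."""


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Per-guide fold changes for every endpoint sample.

    ``values`` is guides x endpoint-samples; entries are NaN where the
    effective T0 count was zero (possible only with ``pseudocount=0``).
    """

    values: np.ndarray
    guide_ids: tuple
    sample_ids: tuple
    t0_partner: tuple  # T0 sample used per column
    pseudocount: float
    depth_normalized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.guide_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class LethalityMatrix:
    """Control-anchored lethality scores, guides x endpoint samples."""

    values: np.ndarray
    guide_ids: tuple
    sample_ids: tuple
    fc_neg: np.ndarray  # per-sample negative-control median fold change
    fc_pos: np.ndarray  # per-sample positive-control median fold change
    quantile_normalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.guide_ids),
                            columns=list(self.sample_ids))


def compute_fold_changes(
    screen: CountScreen,
    sheet: SampleSheet,
    pseudocount: float = 1.0,
    depth_normalize: bool = True,
) -> FoldChangeMatrix:
    """Fold changes relative to each endpoint sample's T0 partner.

    ``depth_normalize`` scales every sample to the mean total count across
    samples before the ratio is formed, so that differences in sequencing
    depth do not masquerade as fitness effects; ``pseudocount`` is added to
    all counts of all samples to bound the ratio when T0 counts are low.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = screen.counts.astype(float)
    if depth_normalize:
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            bad = screen.sample_ids[int(np.argmin(totals))]
            raise ValidationError(f"sample {bad!r} has an all-zero column")
        counts = counts * (totals.mean() / totals)
    counts = counts + pseudocount

    endpoints = sheet.endpoint_samples
    sample_ids, partners, cols = [], [], []
    for _, row in endpoints.iterrows():
        s = row["sample"]
        partner = row["t0_partner"]
        if s not in screen.sample_ids:
            raise ValidationError(f"sheet sample {s!r} absent from count matrix")
        if partner not in screen.sample_ids:
            raise ValidationError(f"T0 partner {partner!r} absent from count matrix")
        c0 = counts[:, screen.sample_index(partner)]
        ct = counts[:, screen.sample_index(s)]
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = (c0 - ct) / c0
        fc[c0 == 0] = np.nan
        sample_ids.append(s)
        partners.append(partner)
        cols.append(fc)
    values = np.column_stack(cols) if cols else np.empty((screen.n_guides, 0))
    return FoldChangeMatrix(
        values=values,
        guide_ids=screen.guide_ids,
        sample_ids=tuple(sample_ids),
        t0_partner=tuple(partners),
        pseudocount=float(pseudocount),
        depth_normalized=bool(depth_normalize),
    )


def lethality_scores(
    fc: FoldChangeMatrix,
    controls: ControlSet,
    gene_of_guide: Mapping[str, str],
) -> LethalityMatrix:
    """Affinely rescale fold changes so control medians anchor 0 and 1."""
    genes = np.array([gene_of_guide[g] for g in fc.guide_ids])
    pos_mask = np.isin(genes, list(controls.positive_genes))
    neg_mask = np.isin(genes, list(controls.negative_genes))
    if not pos_mask.any() or not neg_mask.any():
        raise ValidationError("control sets have no guides in this matrix")

    n_samples = fc.values.shape[1]
    fc_neg = np.empty(n_samples)
    fc_pos = np.empty(n_samples)
    scores = np.empty_like(fc.values)
    for j in range(n_samples):
        col = fc.values[:, j]
        neg_vals = col[neg_mask & np.isfinite(col)]
        pos_vals = col[pos_mask & np.isfinite(col)]
        if neg_vals.size == 0 or pos_vals.size == 0:
            raise ValidationError(
                f"sample {fc.sample_ids[j]!r} lacks usable control fold changes"
            )
        fn, fp = np.median(neg_vals), np.median(pos_vals)
        if fp == fn:
            raise DegenerateControlsError(
                f"sample {fc.sample_ids[j]!r}: positive and negative control "
                f"medians coincide ({fp:g})"
            )
        fc_neg[j], fc_pos[j] = fn, fp
        scores[:, j] = (col - fn) / (fp - fn)
    return LethalityMatrix(
        values=scores,
        guide_ids=fc.guide_ids,
        sample_ids=fc.sample_ids,
        fc_neg=fc_neg,
        fc_pos=fc_pos,
    )


def quantile_normalize(l: LethalityMatrix, enabled: bool = True) -> LethalityMatrix:
    """Rank-mean quantile normalization across samples.

    Each sample's values are replaced by the mean, over samples, of the
    sorted values at the same rank.  Ties are broken by stable row order,
    so every sample becomes an exact permutation of the shared reference
    distribution — which makes the operation exactly idempotent, also in
    the presence of tied values.  Rows containing any missing value are
    carried through untouched.  With ``enabled=False`` this is the
    identity.
    """
    if not enabled:
        return l
    if l.values.shape[1] < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input")
        return l
    values = l.values.copy()
    row_ok = np.all(np.isfinite(values), axis=1)
    sub = values[row_ok, :]
    if sub.shape[0] == 0:
        return l
    order_stats = np.sort(sub, axis=0)
    reference = order_stats.mean(axis=1)
    normed = np.empty_like(sub)
    for j in range(sub.shape[1]):
        order = np.argsort(sub[:, j], kind="mergesort")
        normed[order, j] = reference
    values[row_ok, :] = normed
    return LethalityMatrix(
        values=values,
        guide_ids=l.guide_ids,
        sample_ids=l.sample_ids,
        fc_neg=l.fc_neg,
        fc_pos=l.fc_pos,
        quantile_normalized=True,
    )
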