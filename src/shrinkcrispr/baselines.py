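"""A drugZ-style guide-level z-score baseline for benchmarking.

The algorithm follows the published drugZ procedure: per replicate,
samples are scaled to a common read depth (1e7), a pseudocount (default
5) is added, and per-guide log2 fold changes treated-vs-control are
formed.  Guide variability is estimated empirical-Bayes style: guides
are sorted by control-arm reads and the standard deviation of fold
changes is computed in half-overlapping bins of 800 guides, forced to be
non-decreasing as read counts fall (low-count guides are noisier).  Each
guide's fold change divided by its binned standard deviation gives a
z-score; z-scores are summed per gene over guides and replicates and
scaled by the square root of their number (``normZ``), then re-centred
and re-scaled across genes.  As in the original tool, one-sided normal
p-values are reported for each direction — depletion ("synthetic") and
enrichment ("suppressor") — alongside a two-sided p-value, each with
Benjamini-Hochberg q-values.  The default hit call is the union of the
two one-sided tests at the chosen level.

For the paired design the treated and control endpoint of a replicate
are compared directly.  For the independent design, which drugZ was not
built for, replicate pairing is positional (replicate r of one condition
against replicate r of the other) — the way such tools are run in
practice on unpaired data; initial-abundance variation then leaks into
the fold changes, which is exactly the failure mode the mixed-model
analysis avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountScreen, SampleSheet

__all__ = ["BaselineResult", "drugz_scores", "call_baseline_hits"]

_DEPTH = 1e7


@dataclass(frozen=True)
class BaselineResult:
    """Per-gene normZ scores with one- and two-sided p- and BH q-values."""

    table: pd.DataFrame

    def __post_init__(self):
        for col in ("gene", "n_obs", "sumZ", "normZ", "pvalue",
                    "pvalue_synth", "pvalue_supp", "qvalue",
                    "qvalue_synth", "qvalue_supp"):
            if col not in self.table.columns:
                raise ValueError(f"baseline table missing column {col!r}")


class PairingError(ValueError):
    """Replicates of the two conditions cannot be matched."""


def _replicate_pairs(sheet: SampleSheet):
    """(control_sample, treated_sample) endpoint pairs per replicate."""
    endpoints = sheet.endpoint_samples
    conds = sheet.conditions
    if len(conds) != 2:
        raise PairingError(f"need exactly 2 conditions, found {list(conds)}")
    ref, other = sheet.reference, [c for c in conds if c != sheet.reference][0]
    pairs = []
    by_cond = {c: endpoints.loc[endpoints["condition"] == c].sort_values("replicate")
               for c in (ref, other)}
    reps_ref = list(by_cond[ref]["replicate"])
    reps_other = list(by_cond[other]["replicate"])
    if len(reps_ref) != len(reps_other):
        raise PairingError(
            f"unequal replicate counts: {len(reps_ref)} vs {len(reps_other)}")
    # positional pairing (coincides with replicate-label pairing when labels match)
    for (_, r_ref), (_, r_oth) in zip(by_cond[ref].iterrows(),
                                      by_cond[other].iterrows()):
        pairs.append((r_ref["sample"], r_oth["sample"]))
    return pairs


def _eb_std(fc: np.ndarray, ctrl_reads: np.ndarray,
            bin_size: int = 800) -> np.ndarray:
    """Binned empirical-Bayes standard deviation of fold changes.

    Guides are sorted by control-arm reads (descending); the std of each
    half-overlapping bin of ``bin_size`` guides is assigned to its
    central half and made non-decreasing toward low counts.
    """
    n = len(fc)
    order = np.argsort(-ctrl_reads, kind="mergesort")
    fc_sorted = fc[order]
    half = max(bin_size // 2, 1)
    std_sorted = np.empty(n)
    prev = 0.0
    for start in range(0, n, half):
        lo = max(start - half, 0)
        hi = min(start + half, n)
        s = float(np.std(fc_sorted[lo:hi]))
        s = max(s, prev)  # low-count guides cannot look less noisy
        std_sorted[start:min(start + half, n)] = s
        prev = s
    std_sorted = np.maximum(std_sorted, 1e-12)
    out = np.empty(n)
    out[order] = std_sorted
    return out


def drugz_scores(screen: CountScreen, sheet: SampleSheet,
                 pseudocount: float = 5.0, bin_size: int = 800) -> BaselineResult:
    """Gene-level drugZ-style normZ scores, p-values and q-values."""
    counts = screen.counts.astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("a sample has zero total reads")
    normed = counts * (_DEPTH / totals)

    genes = np.array([screen.gene_of_guide[g] for g in screen.guide_ids])
    zscores = []
    for ctrl_sample, treat_sample in _replicate_pairs(sheet):
        ci = screen.sample_index(ctrl_sample)
        ti = screen.sample_index(treat_sample)
        ctrl = normed[:, ci] + pseudocount
        treat = normed[:, ti] + pseudocount
        fc = np.log2(treat / ctrl)
        std = _eb_std(fc, ctrl_reads=normed[:, ci], bin_size=bin_size)
        zscores.append(fc / std)
    Z = np.column_stack(zscores)                  # guides x replicates

    df = pd.DataFrame({"gene": genes})
    df["sumZ"] = Z.sum(axis=1)
    df["n_obs"] = Z.shape[1]
    agg = df.groupby("gene", sort=True).agg(
        sumZ=("sumZ", "sum"), n_obs=("n_obs", "sum")).reset_index()
    normz = agg["sumZ"].to_numpy() / np.sqrt(agg["n_obs"].to_numpy())
    # re-centre and re-scale across genes, as drugZ does
    sd = normz.std()
    if sd > 0:
        normz = (normz - normz.mean()) / sd
    tiny = np.nextafter(0, 1)
    p_two = np.clip(2.0 * stats.norm.sf(np.abs(normz)), tiny, 1.0)
    p_synth = np.clip(stats.norm.cdf(normz), tiny, 1.0)   # depletion
    p_supp = np.clip(stats.norm.sf(normz), tiny, 1.0)     # enrichment
    table = pd.DataFrame({
        "gene": agg["gene"], "n_obs": agg["n_obs"], "sumZ": agg["sumZ"],
        "normZ": normz,
        "pvalue": p_two, "pvalue_synth": p_synth, "pvalue_supp": p_supp,
        "qvalue": _bh_adjust(p_two), "qvalue_synth": _bh_adjust(p_synth),
        "qvalue_supp": _bh_adjust(p_supp),
    })
    return BaselineResult(table=table)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_baseline_hits(result: BaselineResult, level: float = 0.05,
                       adjusted: bool = False, side: str = "both") -> set:
    """Genes called at ``level`` (q-values if ``adjusted``, else raw p).

    ``side="both"`` (default) unions the two one-sided tests, each at
    ``level`` — how the tool's synthetic/suppressor outputs are read in
    practice; ``"synthetic"``/``"suppressor"`` use one direction;
    ``"two-sided"`` uses the two-sided p-value.
    """
    if not (0 < level <= 1):
        raise ValueError(f"level must lie in (0, 1], got {level}")
    cols = {"both": ("_synth", "_supp"), "synthetic": ("_synth",),
            "suppressor": ("_supp",), "two-sided": ("",)}
    if side not in cols:
        raise ValueError(f"unknown side {side!r}")
    prefix = "qvalue" if adjusted else "pvalue"
    t = result.table
    hits: set = set()
    for suffix in cols[side]:
        hits |= set(t.loc[t[prefix + suffix] < level, "gene"])
    return hits
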