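"""Model/Results interface for a full screen analysis.

:class:`ShrinkCrisprModel` is constructed from a raw count screen, its
sample sheet and the assay control genes; :meth:`ShrinkCrisprModel.fit`
runs the pipeline — fold changes, control-anchored lethality scores,
optional quantile normalization, per-gene empirical-Bayes mixed-model
fits, Bayes factors and lfdr — and returns a
:class:`ShrinkCrisprResults` carrying per-gene estimates, uncertainties
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import genemodel, inference, preprocess
from .io import (ControlSet, CountScreen, SampleSheet, read_control_genes,
                 read_counts, read_sample_sheet, write_results)

__all__ = ["ShrinkCrisprModel", "ShrinkCrisprResults"]


class ShrinkCrisprModel:
    """Differential-fitness model for a pooled CRISPR screen.

    Parameters
    ----------
    screen : CountScreen
        Guide x sample integer counts with a guide-to-gene map.
    sheet : SampleSheet
        Condition / replicate / timepoint / T0-partner metadata; its
        ``design`` ("paired" or "independent") states whether the two
        conditions of a replicate share one T=0 measurement.
    controls : ControlSet
        Essential (positive) and non-essential (negative) control genes
        anchoring the lethality-score scale.
    pseudocount : float
        Added to all counts before fold changes to tame low T=0 counts.
    depth_normalize : bool
        Scale samples to a common total count before fold changes.
    quantile_normalize : bool
        Equalize lethality-score distributions across samples; only
        needed when they differ strongly.
    test_controls : bool
        Also test the control genes (default False: they are scale
        anchors, not hypotheses).
    """

    def __init__(self, screen: CountScreen, sheet: SampleSheet,
                 controls: ControlSet, *, pseudocount: float = 1.0,
                 depth_normalize: bool = True,
                 quantile_normalize: bool = False,
                 timepoints: Optional[Sequence[str]] = None,
                 test: str = "condition",
                 test_controls: bool = False,
                 allow_single_guide: bool = False):
        controls.validate_against(screen)
        self.screen = screen
        self.sheet = sheet
        self.controls = controls
        self.pseudocount = float(pseudocount)
        self.depth_normalize = bool(depth_normalize)
        self.quantile_normalize = bool(quantile_normalize)
        self.timepoints = timepoints
        self.test = test
        self.test_controls = bool(test_controls)
        self.allow_single_guide = bool(allow_single_guide)
        self._lethality = None

    @classmethod
    def from_files(cls, counts_path, sheet_path, positive_controls_path,
                   negative_controls_path, design: str,
                   reference: str = "", **kwargs) -> "ShrinkCrisprModel":
        """Build the model from the four standard input files."""
        screen = read_counts(counts_path)
        sheet = read_sample_sheet(sheet_path, design=design, reference=reference)
        controls = read_control_genes(positive_controls_path,
                                      negative_controls_path)
        return cls(screen, sheet, controls, **kwargs)

    @property
    def lethality(self) -> preprocess.LethalityMatrix:
        """Control-anchored lethality scores (computed lazily, cached)."""
        if self._lethality is None:
            fc = preprocess.compute_fold_changes(
                self.screen, self.sheet,
                pseudocount=self.pseudocount,
                depth_normalize=self.depth_normalize)
            l = preprocess.lethality_scores(fc, self.controls,
                                            self.screen.gene_of_guide)
            l = preprocess.quantile_normalize(l, enabled=self.quantile_normalize)
            self._lethality = l
        return self._lethality

    def gene_specs(self):
        """Per-gene observation bundles plus the exclusion report."""
        exclude = () if self.test_controls else tuple(
            self.controls.positive_genes | self.controls.negative_genes)
        return genemodel.build_gene_specs(
            self.lethality, self.sheet, self.screen.gene_of_guide,
            timepoints=self.timepoints, exclude_genes=exclude,
            allow_single_guide=self.allow_single_guide)

    def fit(self, *, lfdr_threshold: float = 0.05,
            pi0: Optional[float] = None,
            integration: str = "grid",
            hyperparameters: Optional[genemodel.HyperParameters] = None,
            ) -> "ShrinkCrisprResults":
        """Fit every gene and convert Bayes factors to lfdr hit calls.

        ``pi0=None`` estimates the null proportion by EM; pass a float to
        fix it.  ``integration`` selects how variance components are
        integrated ("grid" (default), "ghq", "laplace" or "plugin").
        """
        specs, exclusions = self.gene_specs()
        hp = hyperparameters
        if hp is None:
            hp = genemodel.fit_hyperparameters(specs)
        fits = genemodel.fit_genes(specs, hp, test=self.test,
                                   integration=integration)
        log_bf = np.array([f.log_bf for f in fits])
        lfdr_res = inference.compute_lfdr([f.gene for f in fits], log_bf,
                                          pi0=pi0)
        table = pd.DataFrame({
            "gene": [f.gene for f in fits],
            "n_guides": [f.n_guides for f in fits],
            "beta_hat": [f.beta_hat for f in fits],
            "beta_sd": [f.beta_sd for f in fits],
            "log_bf": log_bf,
            "lfdr": lfdr_res.lfdr,
        })
        table["hit"] = table["lfdr"] < lfdr_threshold
        if fits and fits[0].design == "longitudinal":
            table["beta_time"] = [f.beta_time for f in fits]
            table["beta_interaction"] = [f.beta_interaction for f in fits]
        return ShrinkCrisprResults(
            model=self, table=table, fits=fits,
            hyperparameters=hp, pi0=lfdr_res.pi0,
            lfdr_threshold=float(lfdr_threshold),
            exclusions=exclusions, integration=integration,
        )


@dataclass
class ShrinkCrisprResults:
    """Fitted screen: per-gene effects, Bayes factors, lfdr and hits."""

    model: ShrinkCrisprModel
    table: pd.DataFrame
    fits: list
    hyperparameters: genemodel.HyperParameters
    pi0: float
    lfdr_threshold: float
    exclusions: pd.DataFrame
    integration: str

    @property
    def hits(self) -> pd.DataFrame:
        return self.table.loc[self.table["hit"]].reset_index(drop=True)

    def hit_genes(self, threshold: Optional[float] = None) -> set:
        thr = self.lfdr_threshold if threshold is None else threshold
        return set(self.table.loc[self.table["lfdr"] < thr, "gene"])

    def results_table(self) -> pd.DataFrame:
        """The writeable per-gene results table (sorted, canonical columns)."""
        out = self.table[["gene", "n_guides", "beta_hat", "log_bf", "lfdr",
                          "hit"]].copy()
        return out.sort_values(["lfdr", "gene"], kind="mergesort").reset_index(drop=True)

    def save(self, path) -> None:
        write_results(self.results_table(), path)

    def summary(self) -> str:
        """Human-readable fit summary (top genes, hyperparameters, pi0)."""
        t = self.results_table()
        lines = [
            "ShrinkCRISPR differential fitness results",
            "=" * 45,
            f"design:           {self.model.sheet.design}",
            f"genes tested:     {len(t)}",
            f"genes excluded:   {len(self.exclusions)}",
            f"pi0 (null prop.): {self.pi0:.3f}",
            f"v_beta:           {self.hyperparameters.v_beta:.4g}",
            f"integration:      {self.integration}",
            f"hits (lfdr < {self.lfdr_threshold:g}): {int(t['hit'].sum())}",
            "",
            "top genes by lfdr:",
        ]
        top = t.head(10)
        lines.append(f"{'gene':<16}{'n_guides':>9}{'beta_hat':>12}"
                     f"{'log_bf':>10}{'lfdr':>10}")
        for _, row in top.iterrows():
            lines.append(
                f"{row['gene']:<16}{int(row['n_guides']):>9}"
                f"{row['beta_hat']:>12.4f}{row['log_bf']:>10.2f}"
                f"{row['lfdr']:>10.4f}")
        return "\n".join(lines)
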