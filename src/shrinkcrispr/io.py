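"""Readers and writers for the tabular artifacts of a pooled CRISPR screen.

The count-matrix dialect is the MAGeCK-style TSV (``sgRNA<TAB>gene<TAB>``
followed by one column per sample), chosen because the widely used screen
analysis tools consume it.  Sample metadata travels in a small tab-delimited
sample sheet (`sample  condition  replicate  timepoint  t0_partner`), and
assay controls as plain one-gene-per-line text files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountScreen",
    "SampleSheet",
    "ControlSet",
    "FormatError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_control_genes",
    "write_control_genes",
    "write_results",
    "read_results",
]

RESULTS_COLUMNS = ["gene", "n_guides", "beta_hat", "log_bf", "lfdr", "hit"]


class FormatError(ValueError):
    """A file does not follow the expected dialect (header, columns)."""


class ValidationError(ValueError):
    """Parsed content violates an invariant of the domain types."""


@dataclass(frozen=True)
class CountScreen:
    """A guide x sample matrix of non-negative integer sgRNA counts.

    Parameters
    ----------
    guide_ids : sequence of str
        Unique sgRNA identifiers, one per row of ``counts``.
    gene_of_guide : mapping str -> str
        Maps every guide to exactly one gene symbol.
    counts : ndarray of int, shape (n_guides, n_samples)
    sample_ids : sequence of str
        Unique sample identifiers, one per column of ``counts``.
    """

    guide_ids: tuple
    gene_of_guide: Mapping[str, str]
    counts: np.ndarray
    sample_ids: tuple

    def __post_init__(self):
        guides = tuple(self.guide_ids)
        samples = tuple(self.sample_ids)
        object.__setattr__(self, "guide_ids", guides)
        object.__setattr__(self, "sample_ids", samples)
        if len(set(guides)) != len(guides):
            dup = _first_duplicate(guides)
            raise ValidationError(f"duplicate guide id {dup!r}")
        if len(set(samples)) != len(samples):
            dup = _first_duplicate(samples)
            raise ValidationError(f"duplicate sample id {dup!r}")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(guides), len(samples)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(guides)} guides x {len(samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        missing = [g for g in guides if g not in self.gene_of_guide]
        if missing:
            raise ValidationError(f"guide {missing[0]!r} has no gene assignment")

    @property
    def n_guides(self) -> int:
        return len(self.guide_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def genes(self) -> tuple:
        """Gene symbols in order of first appearance among the guides."""
        seen, out = set(), []
        for g in self.guide_ids:
            gene = self.gene_of_guide[g]
            if gene not in seen:
                seen.add(gene)
                out.append(gene)
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.sample_ids))
        df.insert(0, "gene", [self.gene_of_guide[g] for g in self.guide_ids])
        df.insert(0, "sgRNA", list(self.guide_ids))
        return df

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: condition, replicate, timepoint and T0 pairing.

    ``design`` is either ``"paired"`` (the two arms of a replicate share one
    T0 measurement, as in drug-sensitizing screens) or ``"independent"``
    (each condition/replicate has its own T0, as when comparing cell lines).
    """

    table: pd.DataFrame
    design: str
    reference: str = ""

    def __post_init__(self):
        df = self.table.copy()
        required = ["sample", "condition", "replicate", "timepoint", "t0_partner"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"sample sheet missing column {col!r}")
        if self.design not in ("paired", "independent"):
            raise ValidationError(f"unknown design {self.design!r}")
        df["sample"] = df["sample"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["timepoint"] = df["timepoint"].astype(str)
        df["t0_partner"] = df["t0_partner"].fillna("").astype(str)
        df["replicate"] = df["replicate"].astype(int)
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        samples = set(df["sample"])
        t0_mask = df["timepoint"].str.upper().eq("T0")
        for _, row in df.iterrows():
            if row["timepoint"].upper() == "T0":
                continue
            partner = row["t0_partner"]
            if not partner:
                raise ValidationError(f"sample {row['sample']!r} has no t0_partner")
            if partner not in samples:
                raise ValidationError(
                    f"sample {row['sample']!r} names unknown t0_partner {partner!r}"
                )
            if not df.loc[df["sample"] == partner, "timepoint"].str.upper().eq("T0").all():
                raise ValidationError(
                    f"t0_partner {partner!r} of {row['sample']!r} is not a T0 sample"
                )
        # Paired design: both conditions of a replicate share a single T0.
        non_t0 = df.loc[~t0_mask]
        if self.design == "paired":
            per_rep = non_t0.groupby("replicate")["t0_partner"].nunique()
            if (per_rep > 1).any():
                rep = per_rep[per_rep > 1].index[0]
                raise ValidationError(
                    f"paired design but replicate {rep} has per-condition T0 partners"
                )
        conditions = list(dict.fromkeys(non_t0["condition"]))
        if len(conditions) < 1:
            raise ValidationError("sample sheet has no endpoint samples")
        ref = self.reference or conditions[0]
        if ref not in conditions:
            raise ValidationError(f"reference condition {ref!r} not present")
        object.__setattr__(self, "table", df)
        object.__setattr__(self, "reference", ref)

    @property
    def conditions(self) -> tuple:
        non_t0 = self.table.loc[~self.table["timepoint"].str.upper().eq("T0")]
        return tuple(dict.fromkeys(non_t0["condition"]))

    @property
    def timepoints(self) -> tuple:
        """Ordered non-T0 timepoint labels."""
        non_t0 = self.table.loc[~self.table["timepoint"].str.upper().eq("T0")]
        return tuple(sorted(set(non_t0["timepoint"])))

    @property
    def endpoint_samples(self) -> pd.DataFrame:
        return self.table.loc[~self.table["timepoint"].str.upper().eq("T0")].copy()

    def t0_partner_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["t0_partner"].iloc[0]


@dataclass(frozen=True)
class ControlSet:
    """Essential (positive) and non-essential (negative) control gene symbols."""

    positive_genes: frozenset
    negative_genes: frozenset

    def __post_init__(self):
        pos = frozenset(self.positive_genes)
        neg = frozenset(self.negative_genes)
        overlap = pos & neg
        if overlap:
            raise ValidationError(
                f"control sets overlap: {sorted(overlap)[:3]}"
            )
        object.__setattr__(self, "positive_genes", pos)
        object.__setattr__(self, "negative_genes", neg)

    def validate_against(self, screen: CountScreen) -> None:
        """Check every referenced control gene has at least one guide."""
        present = set(screen.gene_of_guide[g] for g in screen.guide_ids)
        for name, genes in (("positive", self.positive_genes),
                            ("negative", self.negative_genes)):
            if not genes:
                raise ValidationError(f"empty {name} control set")
            missing = genes - present
            if missing:
                raise ValidationError(
                    f"{name} control gene {sorted(missing)[0]!r} has no guide in the screen"
                )


def _first_duplicate(items: Iterable) -> object:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_counts(path, delimiter: str | None = None) -> CountScreen:
    """Read a MAGeCK-style count matrix.

    The first two columns are the guide id and gene symbol; the remaining
    columns are integer counts, one per sample.  ``delimiter=None``
    auto-detects tab vs comma from the header line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file / missing header")
    if delimiter is None:
        delimiter = "\t" if "\t" in header else ","
    if len(header.rstrip("\n").split(delimiter)) < 3:
        raise FormatError(f"{path}: header must have guide, gene and >=1 sample column")
    first = header.split(delimiter)[2]
    try:
        float(first)
        header_is_numeric = True
    except ValueError:
        header_is_numeric = False
    if header_is_numeric:
        raise FormatError(f"{path}: missing header row (numeric first line)")
    df = pd.read_csv(path, sep=delimiter)
    guide_col, gene_col = df.columns[:2]
    sample_cols = list(df.columns[2:])
    counts = df[sample_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric count entries")
    if np.any(~np.isfinite(counts.astype(float))):
        raise ValidationError(f"{path}: non-finite count entries")
    if np.any(counts != np.floor(counts)):
        raise ValidationError(f"{path}: non-integer count entries")
    if counts.size and counts.min() < 0:
        raise ValidationError(f"{path}: negative count entries")
    guides = [str(g) for g in df[guide_col]]
    genes = [str(g) for g in df[gene_col]]
    return CountScreen(
        guide_ids=tuple(guides),
        gene_of_guide=dict(zip(guides, genes)),
        counts=counts.astype(np.int64),
        sample_ids=tuple(str(c) for c in sample_cols),
    )


def write_counts(screen: CountScreen, path) -> None:
    screen.to_frame().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path, design: str, reference: str = "") -> SampleSheet:
    """Read a tab-delimited sample sheet and validate it under ``design``.

    The reference condition is the first condition level in file order
    unless ``reference`` overrides it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(table=df, design=design, reference=reference)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    cols = ["sample", "condition", "replicate", "timepoint", "t0_partner"]
    sheet.table[cols].to_csv(path, sep="\t", index=False)


def read_control_genes(positive_path, negative_path) -> ControlSet:
    """Read two one-gene-per-line files (positive then negative controls)."""

    def _read(p):
        lines = Path(p).read_text().splitlines()
        return [ln.strip() for ln in lines if ln.strip()]

    return ControlSet(
        positive_genes=frozenset(_read(positive_path)),
        negative_genes=frozenset(_read(negative_path)),
    )


def write_control_genes(controls: ControlSet, positive_path, negative_path) -> None:
    Path(positive_path).write_text("\n".join(sorted(controls.positive_genes)) + "\n")
    Path(negative_path).write_text("\n".join(sorted(controls.negative_genes)) + "\n")


def _validate_results(table: pd.DataFrame) -> pd.DataFrame:
    for col in RESULTS_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"results table missing column {col!r}")
    lfdr = table["lfdr"].to_numpy(float)
    if np.any(~np.isfinite(lfdr)) or lfdr.min() < 0 or lfdr.max() > 1:
        raise ValidationError("lfdr values must lie in [0, 1]")
    if table["gene"].duplicated().any():
        raise ValidationError("results table has duplicated genes")
    return table


def write_results(table: pd.DataFrame, path) -> None:
    """Write a per-gene results table.

    Rows are sorted by ascending lfdr, ties broken alphabetically by gene;
    floats are written in scientific notation with 6 significant digits.
    """
    table = _validate_results(table)
    out = table[RESULTS_COLUMNS].copy()
    out = out.sort_values(["lfdr", "gene"], kind="mergesort").reset_index(drop=True)
    out["hit"] = out["hit"].astype(bool)
    buf = _io.StringIO()
    out.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    Path(path).write_text(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["hit"] = df["hit"].astype(bool)
    return _validate_results(df)
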