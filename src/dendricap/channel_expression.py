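"""Ion-channel gene-expression screen.

Consumes published differential-expression statistics (fold change
mutant/wild-type, p, q per gene) — it never recomputes them.  The screen
subsets a cerebellar expression table to the voltage-gated ion-channel
superfamily (145 genes with official IUPHAR classification, shipped as a
pinned data file), flags genes with q <= 0.05 (inclusive) as
significantly altered, builds the log2 fold-change heat-map matrix, and
intersects the significant sets at two ages to find persistently
dysregulated channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ValidationError

Q_CUTOFF = 0.05

GENE_COLUMNS = ["gene", "fold_change", "p_value", "q_value"]


@dataclass
class GeneTable:
    """Expression statistics for one timepoint (gene symbols unique)."""

    records: pd.DataFrame
    timepoint: str = ""
    missing: list = field(default_factory=list)

    def __post_init__(self):
        cols = [c for c in GENE_COLUMNS if c not in self.records.columns]
        if cols:
            raise ValidationError(f"gene table missing columns: {cols}")
        if self.records["gene"].duplicated().any():
            dups = self.records.loc[self.records["gene"].duplicated(), "gene"]
            raise ValidationError(f"duplicate gene symbols: {sorted(set(dups))}")
        fc = self.records["fold_change"]
        if (fc[fc.notna()] <= 0).any():
            raise ValidationError("fold changes must be strictly positive")
        self.records = self.records.reset_index(drop=True)

    @property
    def genes(self) -> list:
        return self.records["gene"].tolist()

    @property
    def significant_genes(self) -> list:
        if "significant" not in self.records.columns:
            raise ValidationError("table not flagged; call flag_significant first")
        return self.records.loc[self.records["significant"] == True, "gene"].tolist()  # noqa: E712


def load_channel_list(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged voltage-gated channel list (gene, subfamily); 145 rows.

    Pinned snapshot of the IUPHAR voltage-gated ion channel superfamily;
    a caller may substitute its own file.
    """
    if path is None:
        with resources.files("dendricap.data").joinpath("vgic_channels.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def read_gene_table(path: str | Path, timepoint: str = "") -> GeneTable:
    """Read an expression table from CSV/TSV/XLSX.

    Fold changes are oriented mutant relative to wild-type.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    return GeneTable(records=df, timepoint=timepoint)


def subset_channels(table: GeneTable, channel_list) -> GeneTable:
    """Restrict a table to the channel list, preserving the list's order.

    ``channel_list`` may be a sequence of symbols or a DataFrame with a
    ``gene`` column (and optionally ``subfamily``, which is merged in).
    Genes absent from the table are reported in ``.missing``, not fatal.
    """
    if isinstance(channel_list, pd.DataFrame):
        symbols = channel_list["gene"].tolist()
        subfamilies = (
            dict(zip(channel_list["gene"], channel_list["subfamily"]))
            if "subfamily" in channel_list.columns
            else {}
        )
    else:
        symbols = list(channel_list)
        subfamilies = {}
    if not symbols:
        raise ValidationError("channel_list must be non-empty")
    by_gene = table.records.set_index("gene")
    present = [g for g in symbols if g in by_gene.index]
    missing = [g for g in symbols if g not in by_gene.index]
    sub = by_gene.loc[present].reset_index()
    if subfamilies:
        sub["subfamily"] = sub["gene"].map(subfamilies)
    return GeneTable(records=sub, timepoint=table.timepoint, missing=missing)


def flag_significant(table: GeneTable, q_cut: float = Q_CUTOFF) -> GeneTable:
    """Annotate each row: significant iff q <= q_cut (inclusive).

    Rows with missing q are flagged unevaluable (significant = NA).
    """
    if not 0 <= q_cut <= 1:
        raise ValidationError(f"q_cut must be in [0, 1], got {q_cut}")
    df = table.records.copy()
    q = df["q_value"]
    df["evaluable"] = q.notna()
    df["significant"] = pd.array(
        np.where(q.notna(), q <= q_cut, None), dtype="boolean"
    )
    return GeneTable(records=df, timepoint=table.timepoint, missing=list(table.missing))


def log2_heatmap_matrix(
    tables: list[GeneTable], significant_only: bool = False
) -> pd.DataFrame:
    """Genes x timepoints matrix of log2 fold changes.

    With ``significant_only`` a gene is kept only for timepoints at which
    it is significant (others are NaN), and rows that are significant
    nowhere are dropped — mirroring heat maps restricted to significantly
    altered channels.
    """
    if not tables:
        raise ValidationError("at least one table required")
    cols = {}
    for tab in tables:
        df = tab.records
        if (df["fold_change"] <= 0).any():
            raise ValidationError("fold_change must be > 0 for log2 conversion")
        series = pd.Series(
            np.log2(df["fold_change"].to_numpy(float)), index=df["gene"]
        )
        if significant_only:
            sig = set(tab.significant_genes)
            series = series.where(series.index.isin(sig))
        cols[tab.timepoint or f"t{len(cols)}"] = series
    mat = pd.DataFrame(cols)
    if significant_only:
        mat = mat.dropna(how="all")
    return mat


def persistent_dysregulated(
    table_a: GeneTable, table_b: GeneTable
) -> pd.DataFrame:
    """Genes significant at both timepoints, with direction at each.

    Returns a DataFrame (gene, direction at each timepoint as 'up'/'down').
    """
    sig_a = set(table_a.significant_genes)
    sig_b = set(table_b.significant_genes)
    both = sorted(sig_a & sig_b)
    fca = table_a.records.set_index("gene")["fold_change"]
    fcb = table_b.records.set_index("gene")["fold_change"]
    label_a = f"direction_{table_a.timepoint or 'a'}"
    label_b = f"direction_{table_b.timepoint or 'b'}"
    return pd.DataFrame(
        {
            "gene": both,
            label_a: ["up" if fca[g] > 1 else "down" for g in both],
            label_b: ["up" if fcb[g] > 1 else "down" for g in both],
        }
    )
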