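"""Isoform fractions, the differential-expression filter, and the
dIF-vs-log2FC independence analysis.

Isoform fraction (IF) is an isoform's share of its gene's total expression
in one condition; dIF = IF(knockdown) − IF(control).  A low correlation
between dIF and the gene-level log2 fold change indicates that isoform
switching is largely decoupled from transcriptional regulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats


@dataclass
class DERecord:
    """One gene's differential-expression result (gene_id, log2FC, q-value)."""

    gene_id: str
    log2fc: float
    qvalue: float
    significant: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue {self.qvalue} outside [0, 1]")


@dataclass
class IsoformRecord:
    isoform_id: str
    gene_id: str
    expr_ctrl: float
    expr_kd: float
    if_ctrl: Optional[float]
    if_kd: Optional[float]
    dif: Optional[float]


def isoform_fractions(isoform_expr: pd.DataFrame) -> list[IsoformRecord]:
    """Per-isoform fractions and dIF from an expression table.

    Expects columns ``isoform_id``, ``gene_id``, ``ctrl``, ``kd``.  Gene
    expression per condition is the sum of its isoforms; IF is missing when
    that sum is zero, and dIF is missing when either IF is.
    """
    for col in ("isoform_id", "gene_id", "ctrl", "kd"):
        if col not in isoform_expr.columns:
            raise ValueError(f"isoform table missing column {col!r}")
    if (isoform_expr[["ctrl", "kd"]] < 0).any().any():
        raise ValueError("negative expression values")
    gene_totals = isoform_expr.groupby("gene_id")[["ctrl", "kd"]].sum()
    records: list[IsoformRecord] = []
    for row in isoform_expr.itertuples(index=False):
        tot_ctrl = gene_totals.at[row.gene_id, "ctrl"]
        tot_kd = gene_totals.at[row.gene_id, "kd"]
        if_ctrl = row.ctrl / tot_ctrl if tot_ctrl > 0 else None
        if_kd = row.kd / tot_kd if tot_kd > 0 else None
        dif = None if if_ctrl is None or if_kd is None else if_kd - if_ctrl
        records.append(
            IsoformRecord(
                isoform_id=row.isoform_id,
                gene_id=row.gene_id,
                expr_ctrl=float(row.ctrl),
                expr_kd=float(row.kd),
                if_ctrl=if_ctrl,
                if_kd=if_kd,
                dif=dif,
            )
        )
    return records


def de_filter(
    records: Sequence[DERecord],
    q_threshold: float = 0.05,
    lfc_threshold: float = 0.6,
) -> list[DERecord]:
    """Flag records significant iff q < q_threshold AND |log2FC| >
    lfc_threshold, both strict.  Returns the full list with flags set."""
    out = []
    for r in records:
        out.append(
            DERecord(
                gene_id=r.gene_id,
                log2fc=r.log2fc,
                qvalue=r.qvalue,
                significant=(r.qvalue < q_threshold and abs(r.log2fc) > lfc_threshold),
            )
        )
    return out


def top_switching_isoforms(
    isoforms: Sequence[IsoformRecord],
) -> list[IsoformRecord]:
    """One record per gene: the isoform with the largest |dIF| (the gene's
    switching isoform), ties broken by isoform_id.  Genes whose dIFs are all
    missing are dropped."""
    best: dict[str, IsoformRecord] = {}
    for iso in isoforms:
        if iso.dif is None:
            continue
        cur = best.get(iso.gene_id)
        if cur is None or (-abs(iso.dif), iso.isoform_id) < (
            -abs(cur.dif), cur.isoform_id
        ):
            best[iso.gene_id] = iso
    return list(best.values())


def dif_expression_correlation(
    isoforms: Sequence[IsoformRecord], de: Sequence[DERecord]
) -> tuple[float, float, int]:
    """Pearson correlation of switching-isoform dIF against gene log2FC.

    Reduced to one isoform per gene (largest |dIF|) before joining on
    gene_id: a gene's dIFs sum to zero by construction, so correlating every
    isoform against the same gene-level log2FC would cancel exactly and the
    statistic would be vacuous.  Returns (r, two-sided p, n joined genes)."""
    lfc_by_gene = {r.gene_id: r.log2fc for r in de}
    xs, ys = [], []
    for iso in top_switching_isoforms(isoforms):
        if iso.gene_id not in lfc_by_gene:
            continue
        xs.append(iso.dif)
        ys.append(lfc_by_gene[iso.gene_id])
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} joined records with non-missing dIF; need >= 3"
        )
    result = stats.pearsonr(xs, ys)
    return float(result.statistic), float(result.pvalue), len(xs)
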