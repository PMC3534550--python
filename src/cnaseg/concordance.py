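"""CNA vs differential-expression concordance tables.

The direct-comparison analysis crosses the direction of the top
differentially expressed genes (up / down by sign of logFC, ranked by
FDR-adjusted p-value) with the copy-number class of the SNPs — or
segments — overlapping each gene. Copy-number classes collapse the five
log2-ratio bins to three: amplification (> 0.2), deletion (< -0.2), no
variation (the closed [-0.2, 0.2] band). A table cell counts
(direction, class) pairs; *concordant* cells are up & amplification and
down & deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult

__all__ = [
    "ConcordanceTable",
    "select_top_genes",
    "snp_gene_concordance",
    "segment_gene_concordance",
    "concordance_percent",
    "cn_class",
]

CN_CLASSES = ("amplification", "deletion", "no variation")


def cn_class(x: np.ndarray, band: float = 0.2) -> np.ndarray:
    """Three-way CN class of log2-ratios: amp (> band), del (< -band), else none."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, "no variation", dtype=object)
    out[x > band] = "amplification"
    out[x < -band] = "deletion"
    return out


@dataclass
class ConcordanceTable:
    """(direction x CN class) contingency counts.

    ``unit`` records whether cells count SNPs or segments. ``n_genes``
    holds, per direction, how many selected genes had at least one
    overlapping unit (the table's second column).
    """

    counts: pd.DataFrame  # index up/down, columns amplification/deletion/no variation
    unit: str = "SNPs"
    n_genes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(
            index=["up", "down"], columns=list(CN_CLASSES), fill_value=0
        ).astype(int)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def concordant(self) -> int:
        return int(self.counts.loc["up", "amplification"] + self.counts.loc["down", "deletion"])

    def to_frame(self) -> pd.DataFrame:
        """Printable layout: genes, amp, del, no-variation, total per direction."""
        df = self.counts.copy()
        df.insert(0, "n_genes", [self.n_genes.get("up", 0), self.n_genes.get("down", 0)])
        df["total"] = self.row_totals
        return df


def select_top_genes(de_table: pd.DataFrame, n: int = 500) -> pd.DataFrame:
    """Top-n differentially expressed genes.

    Ranked by adjusted p ascending, ties by |logFC| descending, then gene
    id; a ``direction`` column (sign of logFC) is added. If fewer than
    ``n`` genes exist, all are returned (with a warning).
    """
    required = {"gene_id", "chrom", "start", "end", "logFC", "adj_p"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    df = de_table.copy()
    df["_abs_lfc"] = df["logFC"].abs()
    df = df.sort_values(
        ["adj_p", "_abs_lfc", "gene_id"], ascending=[True, False, True]
    ).drop(columns="_abs_lfc")
    if len(df) < n:
        import warnings

        warnings.warn(f"only {len(df)} genes available; requested {n}", stacklevel=2)
    out = df.head(n).reset_index(drop=True)
    out["direction"] = np.where(out["logFC"] >= 0, "up", "down")
    return out


def snp_gene_concordance(
    track: pd.DataFrame, genes: pd.DataFrame, band: float = 0.2
) -> ConcordanceTable:
    """SNP-level concordance: one count per (SNP inside gene) pair.

    ``track`` is a CNA track (``chrom pos log2ratio``); ``genes`` carries
    1-based inclusive intervals with a ``direction`` column. A SNP inside
    k overlapping genes contributes k counts.
    """
    counts = pd.DataFrame(0, index=["up", "down"], columns=list(CN_CLASSES))
    genes_hit = {"up": set(), "down": set()}
    by_chrom = {c: sub for c, sub in track.groupby("chrom")}
    for g in genes.itertuples(index=False):
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        inside = (pos >= g.start) & (pos <= g.end)
        if not inside.any():
            continue
        genes_hit[g.direction].add(g.gene_id)
        classes = cn_class(sub["log2ratio"].to_numpy()[inside], band)
        for cls, cnt in zip(*np.unique(classes, return_counts=True)):
            counts.loc[g.direction, cls] += int(cnt)
    return ConcordanceTable(
        counts, unit="SNPs", n_genes={d: len(s) for d, s in genes_hit.items()}
    )


def segment_gene_concordance(
    result: SegmentationResult, genes: pd.DataFrame, band: float = 0.2
) -> ConcordanceTable:
    """Segment-level concordance: one count per overlapping (segment, gene) pair.

    Overlap is a nonempty intersection of the gene interval with the
    segment's probe span (both 1-based inclusive); the segment mean is
    classed with the same thresholds as SNPs.
    """
    counts = pd.DataFrame(0, index=["up", "down"], columns=list(CN_CLASSES))
    genes_hit = {"up": set(), "down": set()}
    for g in genes.itertuples(index=False):
        segs = result.segments.get(g.chrom, [])
        for seg in segs:
            if seg.start_bp <= g.end and g.start <= seg.end_bp:
                genes_hit[g.direction].add(g.gene_id)
                cls = cn_class(np.array([seg.mean]), band)[0]
                counts.loc[g.direction, cls] += 1
    return ConcordanceTable(
        counts, unit="segments", n_genes={d: len(s) for d, s in genes_hit.items()}
    )


def concordance_percent(table: ConcordanceTable) -> float:
    """100 * (up&amplification + down&deletion) / grand total, 1 decimal."""
    total = table.grand_total
    if total == 0:
        raise ValueError("concordance undefined on an all-zero table")
    return round(100.0 * table.concordant / total, 1)
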