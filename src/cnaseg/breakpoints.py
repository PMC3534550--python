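"""Breakpoints and inter-segment regions (ISRs) from a segmentation.

Each junction between two adjacent segments is a breakpoint; the genomic
gap between the last probe of the left segment and the first probe of the
right one is the inter-segment region — the window that must contain the
actual DNA break. ISRs whose flanking segment means differ by at least a
threshold (default 0.8, a strong copy-number step) are kept for sequence
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import SegmentationResult

__all__ = [
    "Breakpoint",
    "ISR",
    "extract_breakpoints",
    "extract_isrs",
    "breakpoint_overlap",
    "export_isr_fasta",
    "breakpoints_to_bed",
    "isrs_to_bed",
]


@dataclass(frozen=True)
class Breakpoint:
    """Junction between two adjacent segments."""

    chrom: str
    left_pos: int  # last probe of the left segment (bp)
    right_pos: int  # first probe of the right segment (bp)
    left_mean: float
    right_mean: float

    def __post_init__(self) -> None:
        if self.left_pos >= self.right_pos:
            raise ValueError("left probe must precede right probe")

    @property
    def midpoint(self) -> int:
        return (self.left_pos + self.right_pos) // 2

    @property
    def delta(self) -> float:
        return self.right_mean - self.left_mean


@dataclass(frozen=True)
class ISR:
    """Inter-segment region: the open gap between adjacent segments."""

    chrom: str
    start: int  # position of the last probe of the left segment (bp)
    end: int  # position of the first probe of the right segment (bp)
    delta: float
    passes: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_breakpoints(result: SegmentationResult) -> list[Breakpoint]:
    """One breakpoint per adjacent segment pair, in genomic order."""
    out: list[Breakpoint] = []
    for chrom, segs in result.segments.items():
        for left, right in zip(segs, segs[1:]):
            out.append(
                Breakpoint(
                    chrom=chrom,
                    left_pos=left.end_bp,
                    right_pos=right.start_bp,
                    left_mean=left.mean,
                    right_mean=right.mean,
                )
            )
    return out


def extract_isrs(
    result: SegmentationResult, min_delta: float = 0.8
) -> list[ISR]:
    """ISRs for every junction; ``passes`` iff |delta mean| >= min_delta."""
    if min_delta < 0:
        raise ValueError("min_delta must be >= 0")
    out = []
    for bp in extract_breakpoints(result):
        delta = bp.delta
        out.append(
            ISR(
                chrom=bp.chrom,
                start=bp.left_pos,
                end=bp.right_pos,
                delta=delta,
                passes=bool(abs(delta) >= min_delta),
            )
        )
    return out


def breakpoint_overlap(
    a: list[Breakpoint], b: list[Breakpoint], tol: int = 0
) -> tuple[int, float]:
    """How many breakpoints of ``b`` recur in ``a``.

    A breakpoint of ``b`` is *common* when some breakpoint of ``a`` on the
    same chromosome has its midpoint within ``tol`` bp. Matching is greedy
    nearest-first and one-to-one on the ``a`` side (ties to the leftmost
    ``a`` breakpoint). Returns ``(n_common, n_common / len(b))`` — 0.0 when
    ``b`` is empty.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if not b:
        return 0, 0.0
    a_by_chrom: dict[str, list[int]] = {}
    for bp in a:
        a_by_chrom.setdefault(bp.chrom, []).append(bp.midpoint)
    used: dict[str, set[int]] = {c: set() for c in a_by_chrom}

    n_common = 0
    # nearest-first: process candidate matches by distance, then position
    candidates = []
    for bi, bp in enumerate(b):
        mids = a_by_chrom.get(bp.chrom, [])
        for ai, mid in enumerate(mids):
            d = abs(mid - bp.midpoint)
            if d <= tol:
                candidates.append((d, mid, bi, bp.chrom, ai))
    matched_b: set[int] = set()
    for d, mid, bi, chrom, ai in sorted(candidates):
        if bi in matched_b or ai in used[chrom]:
            continue
        matched_b.add(bi)
        used[chrom].add(ai)
        n_common += 1
    return n_common, n_common / len(b)


def export_isr_fasta(
    isrs: list[ISR],
    genome: dict[str, str],
    passing_only: bool = True,
) -> str:
    """FASTA of ISR sequences (forward strand, 0-based half-open slices).

    Headers are ``chrom:start-end|delta=<value>``. Raises if an ISR falls
    outside the supplied sequence.
    """
    records = []
    for isr in isrs:
        if passing_only and not isr.passes:
            continue
        seq = genome.get(isr.chrom)
        if seq is None or isr.end > len(seq) or isr.start < 0:
            raise ValueError(
                f"ISR {isr.chrom}:{isr.start}-{isr.end} outside the genome sequence"
            )
        records.append(
            f">{isr.chrom}:{isr.start}-{isr.end}|delta={isr.delta:.4f}\n"
            f"{seq[isr.start:isr.end]}\n"
        )
    return "".join(records)


def breakpoints_to_bed(breakpoints: list[Breakpoint]) -> str:
    """BED of breakpoint midpoints (midpoint +/- 1 bp, 0-based half-open)."""
    lines = []
    for bp in breakpoints:
        mid = bp.midpoint
        score = int(round(abs(bp.delta) * 100))
        lines.append(f"{bp.chrom}\t{max(mid - 1, 0)}\t{mid + 1}\tbreakpoint\t{score}\t+")
    return "\n".join(lines) + ("\n" if lines else "")


def isrs_to_bed(isrs: list[ISR], passing_only: bool = True) -> str:
    """BED of ISRs, score = |delta mean| * 100 rounded."""
    lines = []
    for isr in isrs:
        if passing_only and not isr.passes:
            continue
        score = int(round(abs(isr.delta) * 100))
        lines.append(f"{isr.chrom}\t{isr.start}\t{isr.end}\tISR\t{score}\t+")
    return "\n".join(lines) + ("\n" if lines else "")
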