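"""Genome map and copy-number profile containers.

A :class:`GenomeMap` describes the array layout: ordered chromosomes with
lengths and, per chromosome, a strictly increasing list of probe positions.
A :class:`CopyNumberProfile` is the ground-truth piecewise-constant integer
copy state along each chromosome (diploid baseline 2), stored as maximal
intervals that tile the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeMap", "CopyNumberProfile", "uniform_map"]


@dataclass
class GenomeMap:
    """Array layout: chromosomes with lengths and probe positions.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    positions
        Mapping ``chrom -> int array`` of strictly increasing probe
        positions (bp, 1-based).
    """

    chromosomes: list[tuple[str, int]]
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if set(self.positions) - set(names):
            raise ValueError("probe positions on unknown chromosome")
        for chrom, length in self.chromosomes:
            pos = np.asarray(self.positions.get(chrom, ()), dtype=np.int64)
            self.positions[chrom] = pos
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 1 or pos[-1] > length):
                raise ValueError(
                    f"probe positions on {chrom} must be strictly increasing within [1, {length}]"
                )

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def n_probes(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    @property
    def total_bp(self) -> int:
        return int(sum(l for _, l in self.chromosomes))

    def probe_frame(self) -> pd.DataFrame:
        """Probe table with ``probe_id``, ``chrom``, ``pos`` in genome order."""
        rows = []
        for chrom in self.chrom_names:
            pos = self.positions[chrom]
            rows.append(
                pd.DataFrame(
                    {
                        "probe_id": [f"{chrom}_p{i:06d}" for i in range(len(pos))],
                        "chrom": chrom,
                        "pos": pos,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def midpoint_boundaries(self, chrom: str) -> np.ndarray:
        """Interval boundaries snapped to inter-probe midpoints.

        Returns ``len(probes)+1`` boundaries: 0, midpoints between adjacent
        probes, and the chromosome length — so probe *i* owns the bp
        interval ``[b[i], b[i+1])``.
        """
        pos = self.positions[chrom]
        length = self.lengths[chrom]
        if pos.size == 0:
            return np.array([0, length], dtype=np.int64)
        mids = (pos[:-1] + pos[1:]) // 2
        return np.concatenate([[0], mids, [length]]).astype(np.int64)


@dataclass
class CopyNumberProfile:
    """Piecewise-constant integer copy state per chromosome.

    ``intervals[chrom]`` is a list of ``(start_bp, end_bp, state)`` with
    0-based half-open coordinates that tile the chromosome; adjacent
    intervals carry different states (maximal segments).
    """

    intervals: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def validate(self, genome: GenomeMap) -> None:
        for chrom, length in genome.chromosomes:
            ivs = self.intervals.get(chrom, [])
            if not ivs:
                raise ValueError(f"no intervals for {chrom}")
            if ivs[0][0] != 0 or ivs[-1][1] != length:
                raise ValueError(f"intervals do not span {chrom}")
            for (s0, e0, c0), (s1, e1, c1) in zip(ivs, ivs[1:]):
                if e0 != s1:
                    raise ValueError(f"gap/overlap at {chrom}:{e0}")
                if c0 == c1:
                    raise ValueError(f"non-maximal intervals at {chrom}:{e0}")
            for s, e, c in ivs:
                if e <= s or c < 0:
                    raise ValueError(f"bad interval {chrom}:{s}-{e} state {c}")

    @classmethod
    def from_probe_states(cls, genome: GenomeMap, states: dict[str, np.ndarray]) -> "CopyNumberProfile":
        """Build maximal bp intervals from per-probe states.

        Interval boundaries are snapped to inter-probe midpoints; the first
        and last interval extend to the chromosome ends.
        """
        intervals: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, _ in genome.chromosomes:
            st = np.asarray(states[chrom], dtype=int)
            bounds = genome.midpoint_boundaries(chrom)
            ivs: list[tuple[int, int, int]] = []
            if st.size == 0:
                ivs.append((int(bounds[0]), int(bounds[-1]), 2))
            else:
                run_start = 0
                for i in range(1, len(st) + 1):
                    if i == len(st) or st[i] != st[run_start]:
                        ivs.append((int(bounds[run_start]), int(bounds[i]), int(st[run_start])))
                        run_start = i
            intervals[chrom] = ivs
        return cls(intervals)

    def state_at(self, chrom: str, pos: int) -> int:
        """Copy state at a bp position (0-based)."""
        for s, e, c in self.intervals[chrom]:
            if s <= pos < e:
                return c
        raise ValueError(f"position {chrom}:{pos} not covered")

    def probe_states(self, genome: GenomeMap) -> dict[str, np.ndarray]:
        """Per-probe copy state arrays (probe positions are 1-based)."""
        out = {}
        for chrom in genome.chrom_names:
            pos = genome.positions[chrom]
            ivs = self.intervals[chrom]
            starts = np.array([s for s, _, _ in ivs])
            states = np.array([c for _, _, c in ivs])
            idx = np.searchsorted(starts, pos - 1, side="right") - 1
            out[chrom] = states[idx]
        return out

    def altered_fraction(self, genome: GenomeMap) -> float:
        """Fraction of genome bp with copy state != 2."""
        altered = sum(
            e - s
            for chrom in genome.chrom_names
            for s, e, c in self.intervals[chrom]
            if c != 2
        )
        return altered / genome.total_bp

    def to_bed(self) -> str:
        """BED (0-based half-open) with copy state in the score column."""
        lines = []
        for chrom, ivs in self.intervals.items():
            for s, e, c in ivs:
                lines.append(f"{chrom}\t{s}\t{e}\tstate\t{c}\t+")
        return "\n".join(lines) + ("\n" if lines else "")


def uniform_map(
    n_chromosomes: int = 10,
    probes_per_chromosome: int = 200,
    chrom_length: int = 10_000_000,
) -> GenomeMap:
    """Evenly spaced probe map — convenient default layout for simulation."""
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chromosomes)]
    spacing = chrom_length // (probes_per_chromosome + 1)
    pos = np.arange(1, probes_per_chromosome + 1) * spacing
    positions = {name: pos.copy() for name, _ in chroms}
    return GenomeMap(chroms, positions)
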