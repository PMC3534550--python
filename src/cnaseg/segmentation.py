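"""Circular binary segmentation (CBS) of log2-ratio tracks.

A chromosome's ordered log2-ratios are split recursively: the candidate
change is the circular arc maximizing the pooled-variance two-sample
t-statistic between the arc and its complement; its significance is
assessed by permuting the values within the chromosome. (The pooled
statistic, rather than the Welch variant, keeps short near-constant arcs
from dominating: with a per-arc variance a 2-3 probe arc of nearly equal
values gets an unbounded t under both the data and the permutation null,
which wrecks power at real change points.) A split is accepted when the
add-one permutation p-value is at most ``alpha``. After recursion, splits
whose adjacent segment means differ by less than ``undo_sd`` times a
robust probe-level noise estimate are undone (the "sd.undo" rule).

Defaults mirror the configuration the analysis contract fixes:
``alpha = 0.001``, ``undo_sd = 0.5``, at least two probes per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cna import CategoryScheme, classify_cna

__all__ = [
    "CbsParams",
    "Segment",
    "SegmentationResult",
    "CBSSegmenter",
    "max_t_statistic",
    "permutation_pvalue",
    "segment_chromosome",
    "undo_splits",
    "estimate_noise",
    "classify_segments",
    "segment_track",
]


@dataclass(frozen=True)
class CbsParams:
    """Tuning parameters of the segmentation."""

    alpha: float = 0.001
    n_permutations: int = 10_000
    undo_sd: float = 0.5
    min_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1.0 / self.alpha:
            raise ValueError("n_permutations must be >= 1/alpha")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.undo_sd < 0:
            raise ValueError("undo_sd must be >= 0")


@dataclass
class Segment:
    """Contiguous probe run with its mean log2-ratio.

    ``start_idx``/``end_idx`` are 0-based half-open probe indices within
    the chromosome; ``start_bp``/``end_bp`` are the positions of the first
    and last member probe (1-based inclusive, SEG convention).
    """

    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    n_probes: int
    mean: float
    category: str | None = None


@dataclass
class SegmentationResult:
    """Per-chromosome segment lists for one sample."""

    sample_id: str
    segments: dict[str, list[Segment]] = field(default_factory=dict)
    noise: float = float("nan")  # global probe-level sd estimate

    def all_segments(self) -> list[Segment]:
        return [s for segs in self.segments.values() for s in segs]

    def n_segments(self) -> int:
        return len(self.all_segments())

    def counts_per_chromosome(self) -> pd.Series:
        return pd.Series({c: len(v) for c, v in self.segments.items()}, name=self.sample_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_probes, s.mean, s.category)
            for s in self.all_segments()
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean", "category"],
        )

    def to_seg(self) -> str:
        """SEG text (tab-delimited, 1-based inclusive coordinates)."""
        df = self.to_frame().drop(columns="category")
        return df.to_csv(sep="\t", index=False, float_format="%.6f")


@lru_cache(maxsize=64)
def _arc_index(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All circular arcs [i, j) with both arc and complement >= min_width.

    Returned in lexicographic (i, j) order so that first-max selection
    implements the smallest-i, smallest-j tie-break.
    """
    i = np.arange(n + 1)
    j = np.arange(n + 1)
    width = j[None, :] - i[:, None]
    mask = (width >= min_width) & (width <= n - min_width)
    ii, jj = np.nonzero(mask)
    return ii.astype(np.int64), jj.astype(np.int64), (jj - ii).astype(np.float64)


def _arc_t_all(values: np.ndarray, min_width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """|pooled-variance two-sample t| for every admissible arc of one vector."""
    n = len(values)
    ii, jj, nA = _arc_index(n, min_width)
    s = np.concatenate([[0.0], np.cumsum(values)])
    ss = np.concatenate([[0.0], np.cumsum(values * values)])
    sumA = s[jj] - s[ii]
    ssA = ss[jj] - ss[ii]
    nB = n - nA
    meanA = sumA / nA
    meanB = (s[-1] - sumA) / nB
    ss_within = np.clip(
        (ssA - nA * meanA**2) + (ss[-1] - ssA - nB * meanB**2), 0.0, None
    )
    pooled = ss_within / (n - 2.0) if n > 2 else np.zeros_like(ss_within)
    denom = np.sqrt(pooled * (1.0 / nA + 1.0 / nB))
    diff = np.abs(meanA - meanB)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero = denom == 0.0
    t[zero & (diff > 1e-12)] = np.inf
    t[zero & (diff <= 1e-12)] = 0.0
    return ii, jj, t


def max_t_statistic(values: np.ndarray, min_width: int = 2) -> tuple[int, int, float]:
    """Arg-max circular arc of the |pooled two-sample t| statistic.

    Returns ``(i, j, T)``: the arc ``values[i:j)`` maximizing the absolute
    two-sample t-statistic against its complement, ties broken by smallest
    ``i`` then smallest ``j``. Arcs leaving either side with fewer than
    ``min_width`` probes are excluded. A zero-variance (constant) input
    yields ``T = 0``.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    n = len(values)
    if n < 2 * min_width:
        raise ValueError(f"need at least {2 * min_width} values")
    ii, jj, t = _arc_t_all(values, min_width)
    m = t.max()
    # float-tolerant tie detection (complementary arcs give the same |t|
    # up to rounding); first candidate = lexicographic (i, j) tie-break
    if np.isinf(m):
        cand = np.isinf(t)
    elif m == 0.0:
        cand = np.ones_like(t, dtype=bool)
    else:
        cand = t >= m * (1.0 - 1e-10)
    k = int(np.argmax(cand))
    return int(ii[k]), int(jj[k]), float(t[k])


def _max_t_batch(mat: np.ndarray, min_width: int) -> np.ndarray:
    """Row-wise max |pooled t| over all arcs for a batch of vectors."""
    b, n = mat.shape
    ii, jj, nA = _arc_index(n, min_width)
    s = np.zeros((b, n + 1))
    np.cumsum(mat, axis=1, out=s[:, 1:])
    ss = np.zeros((b, n + 1))
    np.cumsum(mat * mat, axis=1, out=ss[:, 1:])
    sumA = s[:, jj] - s[:, ii]
    ssA = ss[:, jj] - ss[:, ii]
    nB = n - nA
    meanA = sumA / nA
    meanB = (s[:, -1:] - sumA) / nB
    ss_within = np.clip(
        (ssA - nA * meanA**2) + (ss[:, -1:] - ssA - nB * meanB**2), 0.0, None
    )
    pooled = ss_within / (n - 2.0) if n > 2 else np.zeros_like(ss_within)
    denom = np.sqrt(pooled * (1.0 / nA + 1.0 / nB))
    diff = np.abs(meanA - meanB)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero = denom == 0.0
    t[zero & (diff > 1e-12)] = np.inf
    t[zero & (diff <= 1e-12)] = 0.0
    return t.max(axis=1)


def permutation_pvalue(
    values: np.ndarray,
    t_obs: float,
    params: CbsParams | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Add-one permutation p-value of the max arc statistic.

    ``p = (1 + #{T* >= T_obs}) / (1 + n_done)``. Permutations run in
    batches; the loop stops early once enough exceedances have accrued
    that ``p > alpha`` is guaranteed even if every remaining permutation
    fell below ``T_obs``. Deterministic given the generator state.
    """
    params = params or CbsParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    values = np.asarray(values, dtype=float)
    n_perm = params.n_permutations
    # p <= alpha requires count <= alpha*(1+n_perm) - 1; one more exceedance
    # makes p > alpha certain.
    k_stop = int(np.floor(params.alpha * (1 + n_perm) - 1.0)) + 1
    count = 0
    done = 0
    batch = 16  # geometric schedule keeps the early-stop overshoot small
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = rng.permuted(np.broadcast_to(values, (b, len(values))).copy(), axis=1)
        t_star = _max_t_batch(perms, params.min_width)
        count += int(np.sum(t_star >= t_obs))
        done += b
        if count >= k_stop:
            break
        batch = min(batch * 4, 1024)
    return (1 + count) / (1 + done)


def estimate_noise(values: np.ndarray) -> float:
    """Robust probe-level noise sd: MAD of first differences / (1.4826*sqrt(2)).

    First-differencing removes the piecewise-constant signal except at the
    (few) breakpoints, which the median absolute deviation ignores.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values to estimate noise")
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / np.sqrt(2.0))


def _segment_means(boundaries: list[int], values: np.ndarray) -> np.ndarray:
    return np.array(
        [values[a:b].mean() for a, b in zip(boundaries[:-1], boundaries[1:])]
    )


def undo_splits(
    boundaries: list[int],
    values: np.ndarray,
    undo_sd: float,
    sigma: float,
) -> list[int]:
    """Merge adjacent segments whose mean difference is below ``undo_sd * sigma``.

    Repeatedly removes the internal boundary with the smallest adjacent
    |mean difference| while that difference is under the threshold; means
    are recomputed after every merge. ``undo_sd = 0`` disables merging.
    """
    bounds = list(boundaries)
    if undo_sd <= 0 or sigma <= 0:
        return bounds
    thresh = undo_sd * sigma
    while len(bounds) > 2:
        means = _segment_means(bounds, values)
        diffs = np.abs(np.diff(means))
        k = int(np.argmin(diffs))
        if diffs[k] < thresh:
            del bounds[k + 1]
        else:
            break
    return bounds


def _recursive_boundaries(
    values: np.ndarray, params: CbsParams, seed_seq: np.random.SeedSequence
) -> list[int]:
    """Change-point indices from the recursive split procedure (pre-undo)."""
    n = len(values)
    cuts: set[int] = set()
    # explicit stack of (lo, hi) runs; deterministic seeds per run
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        m = hi - lo
        if m < 2 * params.min_width:
            continue
        seg = values[lo:hi]
        i, j, t_obs = max_t_statistic(seg, params.min_width)
        if t_obs == 0.0:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed_seq.entropy, spawn_key=(lo, hi))
        )
        p = permutation_pvalue(seg, t_obs, params, rng)
        if p > params.alpha:
            continue
        points = sorted({lo + i, lo + j} - {lo, hi})
        if not points:
            continue
        cuts.update(points)
        edges = [lo, *points, hi]
        for a, b in zip(edges[:-1], edges[1:]):
            stack.append((a, b))
    return [0, *sorted(cuts), n]


def segment_chromosome(
    values: np.ndarray,
    positions: np.ndarray,
    params: CbsParams | None = None,
    chrom: str = "chr",
    seed_seq: np.random.SeedSequence | None = None,
) -> list[Segment]:
    """Segment one chromosome's ordered log2-ratios.

    Recursively splits at significant max-t arcs, then applies the sd-undo
    merge with a noise sd estimated from the chromosome's first
    differences. The returned segments partition the probes in genomic
    order.
    """
    params = params or CbsParams()
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions)
    if len(values) != len(positions):
        raise ValueError("values and positions must align")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    n = len(values)
    seed_seq = seed_seq or np.random.SeedSequence([params.seed])

    if n < 2 * params.min_width:
        bounds = [0, n]
    else:
        bounds = _recursive_boundaries(values, params, seed_seq)
        if len(bounds) > 2:
            sigma = estimate_noise(values)
            bounds = undo_splits(bounds, values, params.undo_sd, sigma)

    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segs.append(
            Segment(
                chrom=chrom,
                start_idx=a,
                end_idx=b,
                start_bp=int(positions[a]),
                end_bp=int(positions[b - 1]),
                n_probes=b - a,
                mean=float(values[a:b].mean()),
            )
        )
    return segs


def _chrom_seed(base_seed: int, sample_id: str, chrom: str) -> np.random.SeedSequence:
    import zlib

    return np.random.SeedSequence(
        [base_seed, zlib.crc32(sample_id.encode()), zlib.crc32(chrom.encode())]
    )


def segment_track(
    track: pd.DataFrame,
    params: CbsParams | None = None,
    sample_id: str = "sample",
) -> SegmentationResult:
    """Segment a per-probe CNA track (columns ``chrom pos log2ratio``).

    Chromosomes are processed independently in order of first appearance;
    per-chromosome permutation seeds derive from (seed, sample, chrom) so
    reruns are bit-identical.
    """
    params = params or CbsParams()
    result = SegmentationResult(sample_id=sample_id)
    diffs = []
    for chrom in track["chrom"].unique():
        sub = track[track["chrom"] == chrom]
        values = sub["log2ratio"].to_numpy(float)
        positions = sub["pos"].to_numpy()
        result.segments[chrom] = segment_chromosome(
            values,
            positions,
            params,
            chrom=str(chrom),
            seed_seq=_chrom_seed(params.seed, sample_id, str(chrom)),
        )
        if len(values) >= 2:
            diffs.append(np.diff(values))
    if diffs:
        d = np.concatenate(diffs)
        mad = np.median(np.abs(d - np.median(d)))
        result.noise = float(mad * 1.4826 / np.sqrt(2.0))
    return result


def classify_segments(
    result: SegmentationResult, scheme: CategoryScheme | None = None
) -> tuple[SegmentationResult, pd.Series]:
    """Bin segment means with the probe-level scheme; tabulate fractions."""
    scheme = scheme or CategoryScheme()
    means = np.array([s.mean for s in result.all_segments()])
    labels, table = classify_cna(means, scheme)
    for seg, lab in zip(result.all_segments(), labels):
        seg.category = str(lab)
    return result, table


class CBSSegmenter(BaseEstimator):
    """Circular-binary-segmentation estimator.

    Parameters
    ----------
    alpha : float, default 0.001
        Permutation significance level for accepting a split.
    n_permutations : int, default 10000
        Permutations per tested split (must be >= 1/alpha).
    undo_sd : float, default 0.5
        sd-undo multiplier: adjacent segments closer than
        ``undo_sd * sigma`` in mean are re-merged.
    min_width : int, default 2
        Minimum probes on each side of a candidate split.
    random_state : int, default 0
        Base seed for the permutation streams.

    Attributes
    ----------
    result_ : SegmentationResult
        Segments per chromosome after :meth:`fit`.
    noise_ : float
        Global robust probe-level sd estimate.
    """

    def __init__(
        self,
        alpha: float = 0.001,
        n_permutations: int = 10_000,
        undo_sd: float = 0.5,
        min_width: int = 2,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.undo_sd = undo_sd
        self.min_width = min_width
        self.random_state = random_state

    def _params(self) -> CbsParams:
        return CbsParams(
            alpha=self.alpha,
            n_permutations=self.n_permutations,
            undo_sd=self.undo_sd,
            min_width=self.min_width,
            seed=self.random_state,
        )

    def fit(self, X, y=None, positions=None, sample_id: str = "sample") -> "CBSSegmenter":
        """Segment a track.

        ``X`` is either a DataFrame with ``chrom pos log2ratio`` columns or
        a 1-D array of ordered values (``positions`` optional; defaults to
        the probe index).
        """
        if isinstance(X, pd.DataFrame):
            track = X
        else:
            values = np.asarray(X, dtype=float).ravel()
            pos = np.asarray(positions) if positions is not None else np.arange(1, len(values) + 1)
            track = pd.DataFrame({"chrom": "chr", "pos": pos, "log2ratio": values})
        self.result_ = segment_track(track, self._params(), sample_id=sample_id)
        self.noise_ = self.result_.noise
        return self

    def predict(self, X=None) -> np.ndarray:
        """Per-probe fitted segment means, in the fitted track's order."""
        if not hasattr(self, "result_"):
            raise ValueError("CBSSegmenter is not fitted")
        out = []
        for segs in self.result_.segments.values():
            for s in segs:
                out.extend([s.mean] * s.n_probes)
        return np.array(out)

    def fit_predict(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X, y, **kwargs).predict()
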