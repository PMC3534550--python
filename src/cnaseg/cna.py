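"""Per-SNP copy-number-alteration calling and five-bin classification.

The pipeline's CNA measure is the log2-ratio of a sample's total probe
intensity (A + B allele channels summed) against a reference track built as
the arithmetic mean of designated normal samples. Ratios are classified
into five bins: unchanged (closed band [-0.2, 0.2]), slightly
increased/decreased (open bands out to +/-0.6), highly increased/decreased
(|x| >= 0.6).

:class:`CnaCaller` is the estimator surface: ``fit`` learns the reference
from the normal samples of an intensity table, ``transform`` turns sample
totals into log2-ratio tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CategoryScheme",
    "CnaCaller",
    "total_intensity",
    "build_reference",
    "compute_log2_ratio",
    "classify_cna",
    "fold_change",
    "CATEGORIES",
]

CATEGORIES = (
    "highly decreased",
    "slightly decreased",
    "unchanged",
    "slightly increased",
    "highly increased",
)


@dataclass(frozen=True)
class CategoryScheme:
    """Five-bin log2-ratio classification.

    ``unchanged`` is the closed band ``[-lo, lo]``; the ``highly`` bins are
    closed outward at ``+/-hi`` (``x >= hi`` / ``x <= -hi``); the
    ``slightly`` bins are the open remainders.
    """

    lo: float = 0.2
    hi: float = 0.6
    labels: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("need 0 < lo < hi")
        if len(self.labels) != 5:
            raise ValueError("exactly five labels required")

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Label an array of log2-ratios; NaN maps to the empty string."""
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, "", dtype=object)
        out[x <= -self.hi] = self.labels[0]
        out[(-self.hi < x) & (x < -self.lo)] = self.labels[1]
        out[(-self.lo <= x) & (x <= self.lo)] = self.labels[2]
        out[(self.lo < x) & (x < self.hi)] = self.labels[3]
        out[x >= self.hi] = self.labels[4]
        return out


def _sample_names(table: pd.DataFrame) -> list[str]:
    names = []
    for col in table.columns:
        if col.startswith("intensity_A:"):
            names.append(col.split(":", 1)[1])
    for s in names:
        if f"intensity_B:{s}" not in table.columns:
            raise ValueError(f"sample {s!r} missing B-allele column")
    return names


def total_intensity(table: pd.DataFrame) -> pd.DataFrame:
    """Sum the A and B allele channels per probe, per sample.

    Input columns: ``probe_id chrom pos`` plus ``intensity_A:<s>`` /
    ``intensity_B:<s>`` pairs. Output: ``probe_id chrom pos`` plus one
    total column per sample.
    """
    samples = _sample_names(table)
    if not samples:
        raise ValueError("no intensity_A:/intensity_B: sample columns found")
    out = table[["probe_id", "chrom", "pos"]].copy()
    for s in samples:
        a = table[f"intensity_A:{s}"].to_numpy(float)
        b = table[f"intensity_B:{s}"].to_numpy(float)
        if np.nanmin(a) < 0 or np.nanmin(b) < 0:
            raise ValueError(f"negative intensities in sample {s!r}")
        out[s] = a + b
    return out


def build_reference(totals: pd.DataFrame, normal_ids: list[str]) -> pd.Series:
    """Per-probe reference: arithmetic mean of the normal samples' totals."""
    if not normal_ids:
        raise ValueError("at least one normal sample id required")
    missing = [s for s in normal_ids if s not in totals.columns]
    if missing:
        raise ValueError(f"unknown normal sample id(s): {missing}")
    ref = totals[list(normal_ids)].mean(axis=1)
    ref.name = "reference"
    return ref


def compute_log2_ratio(
    sample_totals: pd.Series | np.ndarray,
    reference: pd.Series | np.ndarray,
    epsilon: float = 1.0,
) -> np.ndarray:
    """log2((total + eps) / (ref + eps)); ``eps`` guards dead probes."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    t = np.asarray(sample_totals, dtype=float)
    r = np.asarray(reference, dtype=float)
    return np.log2((t + epsilon) / (r + epsilon))


def classify_cna(
    log2_ratios: np.ndarray, scheme: CategoryScheme | None = None
) -> tuple[np.ndarray, pd.Series]:
    """Bin log2-ratios and tabulate per-category fractions.

    NaN ratios are excluded from the fraction denominator and reported
    under the index entry ``"excluded"`` (as a count, not a fraction).
    """
    scheme = scheme or CategoryScheme()
    x = np.asarray(log2_ratios, dtype=float)
    labels = scheme.classify(x)
    ok = ~np.isnan(x)
    n_ok = int(ok.sum())
    fracs = {}
    for cat in scheme.labels:
        fracs[cat] = float((labels[ok] == cat).sum()) / n_ok if n_ok else np.nan
    table = pd.Series(fracs, name="fraction")
    table["excluded"] = float((~ok).sum())
    return labels, table


def fold_change(x: float | np.ndarray) -> float | np.ndarray:
    """Linear fold change for a log2-ratio: 2**x."""
    return np.exp2(x)


class CnaCaller(TransformerMixin, BaseEstimator):
    """Log2-ratio CNA caller with a mean-of-normals reference.

    Parameters
    ----------
    normal_ids : list of str
        Sample names whose mean total intensity forms the reference.
    epsilon : float, default 1.0
        Pseudocount (intensity units) added to numerator and denominator.
    scheme : CategoryScheme, optional
        Five-bin classification scheme; defaults to the +/-0.2, +/-0.6 bands.

    Attributes
    ----------
    reference_ : pandas.Series
        Per-probe reference intensity after :meth:`fit`.
    probe_index_ : pandas.DataFrame
        ``probe_id chrom pos`` of the fitted probe set.
    """

    def __init__(
        self,
        normal_ids: list[str] | None = None,
        epsilon: float = 1.0,
        scheme: CategoryScheme | None = None,
    ):
        self.normal_ids = normal_ids
        self.epsilon = epsilon
        self.scheme = scheme

    def fit(self, X: pd.DataFrame, y=None) -> "CnaCaller":
        """Learn the reference from the normal samples of an intensity table."""
        if not self.normal_ids:
            raise ValueError("normal_ids must name at least one sample")
        totals = total_intensity(X)
        self.probe_index_ = totals[["probe_id", "chrom", "pos"]].copy()
        self.totals_ = totals
        self.reference_ = build_reference(totals, list(self.normal_ids))
        return self

    def transform(self, X: pd.DataFrame) -> dict[str, pd.DataFrame]:
        """Per-sample CNA tracks: ``probe_id chrom pos log2ratio category``."""
        if not hasattr(self, "reference_"):
            raise ValueError("CnaCaller is not fitted")
        totals = total_intensity(X)
        if not totals["probe_id"].equals(self.probe_index_["probe_id"]):
            raise ValueError("probe set differs from the fitted table")
        scheme = self.scheme or CategoryScheme()
        tracks = {}
        for s in [c for c in totals.columns if c not in ("probe_id", "chrom", "pos")]:
            ratio = compute_log2_ratio(totals[s], self.reference_, self.epsilon)
            track = self.probe_index_.copy()
            track["log2ratio"] = ratio
            track["category"] = scheme.classify(ratio)
            tracks[s] = track
        return tracks

    def fraction_table(self, tracks: dict[str, pd.DataFrame]) -> pd.DataFrame:
        """Stage-comparison table: five-bin fractions per sample (columns)."""
        scheme = self.scheme or CategoryScheme()
        cols = {}
        for s, track in tracks.items():
            _, fr = classify_cna(track["log2ratio"].to_numpy(), scheme)
            cols[s] = fr
        return pd.DataFrame(cols)
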