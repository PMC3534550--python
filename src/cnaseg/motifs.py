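"""ZOOPS-EM motif discovery and simple-repeat annotation in ISR sequences.

The discovery model is zero-or-one-occurrence-per-sequence (ZOOPS): each
sequence either contains exactly one instance of a width-``w`` motif,
drawn column-wise from a position weight matrix (PWM), at a uniformly
random site on either strand — or it is pure background. EM alternates
posterior site occupancies (E) with PWM/prior re-estimation (M); the data
log-likelihood is non-decreasing by construction and is asserted per
iteration. Restarts are seeded from recurrent exact words, since
recurrence across sequences is precisely the ZOOPS signal.

Simple tandem repeats (unit 1-6 bp, e.g. the [CT]n / [CA]n microsatellites
typical of fragile breakpoint regions) are annotated by a maximal-run
scanner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "PWM",
    "MotifHit",
    "RepeatAnnotation",
    "ZoopsMotif",
    "discover_motif_zoops",
    "discover_best_width",
    "information_content",
    "find_tandem_repeats",
    "write_minimal_meme",
    "parse_minimal_meme",
]

ALPHABET = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


@dataclass
class PWM:
    """Position weight matrix: 4 x w letter probabilities over A,C,G,T."""

    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be >= 0")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """Predicted motif occurrence in one sequence."""

    seq_index: int
    offset: int  # 0-based, on the forward strand
    strand: str  # '+' or '-'
    score: float  # log-odds, bits
    posterior: float


@dataclass(frozen=True)
class RepeatAnnotation:
    """Maximal simple tandem repeat run."""

    start: int  # 0-based
    unit: str  # canonical (lexicographically smallest rotation)
    copies: int
    length: int  # unit length * copies
    partial: bool  # one extra partial terminal copy follows

    @property
    def end(self) -> int:
        return self.start + self.length


def information_content(pwm: PWM, background: np.ndarray | None = None) -> float:
    """Total information content, bits: sum_cols sum_b p*log2(p/q_b)."""
    q = np.asarray(background if background is not None else pwm.background, float)
    p = pwm.matrix
    if np.any((q == 0) & (p.sum(axis=1) > 0)):
        raise ValueError("zero background frequency with nonzero motif probability")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log2(p / q[:, None]), 0.0)
    return float(term.sum())


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    if np.any(out < 0):
        raise ValueError("sequences must be over ACGT")
    return out


class ZoopsMotif(BaseEstimator):
    """ZOOPS expectation-maximization motif finder.

    Parameters
    ----------
    width : int, default 15
        Motif width in bp (the analysis contract constrains 15-40).
    max_iter : int, default 200
        Maximum EM iterations per restart.
    tol : float, default 1e-6
        Stop when the log-likelihood gain falls below this.
    n_word_seeds : int, default 10
        Restarts seeded from the most recurrent exact w-mers.
    n_random_seeds : int, default 5
        Additional restarts seeded from random windows.
    both_strands : bool, default True
        Scan the reverse complement as extra candidate sites.
    pseudocount : float, default 0.01
        Per-cell smoothing added in the M-step.
    random_state : int, default 0

    Attributes
    ----------
    pwm_ : PWM
        Discovered motif (best restart by final log-likelihood).
    hits_ : list of MotifHit
        Sites with posterior occupancy > 0.5.
    log_likelihood_ : float
        Final penalized (Dirichlet-MAP) data log-likelihood, up to the
        constant background term.
    ll_trace_ : list of float
        Per-iteration penalized log-likelihood of the winning restart;
        non-decreasing by the EM/MAP guarantee.
    prior_ : float
        Fitted per-sequence occupancy probability.
    """

    def __init__(
        self,
        width: int = 15,
        max_iter: int = 200,
        tol: float = 1e-6,
        n_word_seeds: int = 10,
        n_random_seeds: int = 5,
        both_strands: bool = True,
        pseudocount: float = 0.01,
        random_state: int = 0,
    ):
        self.width = width
        self.max_iter = max_iter
        self.tol = tol
        self.n_word_seeds = n_word_seeds
        self.n_random_seeds = n_random_seeds
        self.both_strands = both_strands
        self.pseudocount = pseudocount
        self.random_state = random_state

    # -- internal ---------------------------------------------------------

    def _prepare(self, seqs: list[str]):
        w = self.width
        if not seqs:
            raise ValueError("no sequences")
        if min(len(s) for s in seqs) < w:
            raise ValueError("motif width exceeds the shortest sequence")
        enc = [_encode(s) for s in seqs]
        windows = []  # per sequence: (n_sites, w) letters; forward then rc
        meta = []  # per sequence: (m_fwd, n_sites)
        for e, s in zip(enc, seqs):
            m = len(e) - w + 1
            fw = np.lib.stride_tricks.sliding_window_view(e, w)
            if self.both_strands:
                rc = np.lib.stride_tricks.sliding_window_view(_encode(revcomp(s)), w)
                win = np.concatenate([fw, rc], axis=0)
            else:
                win = fw
            windows.append(np.ascontiguousarray(win))
            meta.append(m)
        counts = np.bincount(np.concatenate(enc), minlength=4).astype(float)
        bg = (counts + 1.0) / (counts.sum() + 4.0)
        return enc, windows, meta, bg

    def _seed_pwms(self, seqs, enc, rng) -> list[np.ndarray]:
        w = self.width
        words: Counter[str] = Counter()
        for s in seqs:
            su = s.upper()
            for k in range(len(su) - w + 1):
                words[su[k : k + w]] += 1
        seeds = [wd for wd, _ in words.most_common(self.n_word_seeds)]
        for _ in range(self.n_random_seeds):
            i = int(rng.integers(len(seqs)))
            off = int(rng.integers(len(seqs[i]) - w + 1))
            seeds.append(seqs[i].upper()[off : off + w])
        pwms = []
        for word in seeds:
            mat = np.full((4, w), 0.1)
            for j, b in enumerate(word):
                mat[ALPHABET.index(b), j] = 0.7
            pwms.append(mat)
        return pwms

    def _em(self, pwm, windows, meta, bg):
        gamma = 0.5
        log_bg = np.log(bg)
        ll_trace: list[float] = []
        prev_obj = -np.inf
        w = self.width
        col = np.arange(w)
        n_seq = len(windows)
        # Beta(1, 1 + n/2) prior on the occupancy: with no real motif
        # the likelihood is flat in gamma (a PWM equal to the background
        # fits any occupancy), and the prior pulls gamma to zero along that
        # ridge; with genuine sites the data term dominates.
        beta_b = 1.0 + 0.5 * n_seq
        for _ in range(self.max_iter):
            log_ratio = np.log(pwm) - log_bg[:, None]  # (4, w)
            counts = np.zeros((4, w))
            q_sum = 0.0
            ll = 0.0
            posts = []
            for win, m in zip(windows, meta):
                n_sites = win.shape[0]
                r = np.exp(log_ratio[win, col].sum(axis=1))  # odds ratio per site
                site_prior = gamma / n_sites
                denom = (1.0 - gamma) + site_prior * r.sum()
                post = site_prior * r / denom
                posts.append(post)
                q_sum += post.sum()
                ll += np.log(denom)  # background log-lik of the sequence cancels
                for j in range(w):
                    np.add.at(counts[:, j], win[:, j], post)
            # the smoothed M-step maximizes the MAP objective — LL plus the
            # Dirichlet term on the PWM and the Beta term on the occupancy;
            # that penalized likelihood is the monotone quantity
            obj = (
                ll
                + self.pseudocount * float(np.log(pwm).sum())
                + (beta_b - 1.0) * np.log1p(-gamma)
            )
            counts += self.pseudocount
            pwm = counts / counts.sum(axis=0, keepdims=True)
            gamma = min(max(q_sum / (n_seq + beta_b - 1.0), 1e-6), 1.0 - 1e-6)
            ll_trace.append(obj)
            if obj < prev_obj - 1e-8:
                raise AssertionError("EM objective decreased")
            if obj - prev_obj < self.tol and np.isfinite(prev_obj):
                break
            prev_obj = obj
        return pwm, gamma, ll_trace, posts

    # -- public -----------------------------------------------------------

    def fit(self, X: list[str], y=None) -> "ZoopsMotif":
        """Discover one motif in a list of DNA sequences."""
        seqs = list(X)
        enc, windows, meta, bg = self._prepare(seqs)
        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 523]))
        best = None
        for seed_pwm in self._seed_pwms(seqs, enc, rng):
            pwm, gamma, trace, posts = self._em(seed_pwm, windows, meta, bg)
            if best is None or trace[-1] > best[2][-1]:
                best = (pwm, gamma, trace, posts)
        pwm, gamma, trace, posts = best

        hits = []
        log_ratio = np.log(pwm) - np.log(bg)[:, None]
        col = np.arange(self.width)
        for idx, (win, m, post) in enumerate(zip(windows, meta, posts)):
            k = int(np.argmax(post))
            if post[k] > 0.5:
                if k < m:
                    offset, strand = k, "+"
                else:
                    # site k indexes the reverse-complement scan
                    offset, strand = len(enc[idx]) - self.width - (k - m), "-"
                score_bits = float(log_ratio[win[k], col].sum() / np.log(2.0))
                hits.append(MotifHit(idx, offset, strand, score_bits, float(post[k])))

        self.background_ = bg
        self.pwm_ = PWM(pwm, background=bg, n_sites=len(hits))
        self.hits_ = hits
        self.prior_ = float(gamma)
        self.ll_trace_ = trace
        self.log_likelihood_ = float(trace[-1])
        return self


def discover_motif_zoops(
    seqs: list[str],
    w: int = 15,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    both_strands: bool = True,
) -> tuple[PWM, list[MotifHit], float]:
    """Functional wrapper over :class:`ZoopsMotif` for a single width."""
    est = ZoopsMotif(
        width=w, max_iter=max_iter, tol=tol, random_state=seed, both_strands=both_strands
    ).fit(seqs)
    return est.pwm_, est.hits_, est.log_likelihood_


def discover_best_width(
    seqs: list[str],
    min_w: int = 15,
    max_w: int = 40,
    step: int = 5,
    seed: int = 0,
    **kwargs,
) -> ZoopsMotif:
    """Outer width loop: fit each candidate width, keep the best model.

    Widths are compared by a penalized log-likelihood
    ``LL - 0.5 * 3w * log(total sites)`` (3 free parameters per PWM
    column), an E-value-free model-size correction.
    """
    total_sites = sum(len(s) for s in seqs)
    best_est, best_score = None, -np.inf
    for w in range(min_w, max_w + 1, step):
        if w > min(len(s) for s in seqs):
            break
        est = ZoopsMotif(width=w, random_state=seed, **kwargs).fit(seqs)
        score = est.log_likelihood_ - 0.5 * 3 * w * np.log(total_sites)
        if score > best_score:
            best_est, best_score = est, score
    if best_est is None:
        raise ValueError("no admissible width")
    return best_est


# -- simple tandem repeats ------------------------------------------------


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    return unit not in (unit + unit)[1:-1]


def find_tandem_repeats(
    seq: str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_total: int = 8,
) -> list[RepeatAnnotation]:
    """Maximal simple tandem repeats with unit length 1-6 bp.

    A run is maximal when extending either end breaks the period; the
    reported length counts whole copies only, with ``partial`` flagging a
    trailing incomplete copy. Units are reported as their
    lexicographically smallest rotation; only primitive units (not
    themselves a repetition) are emitted. Non-ACGT characters break runs.
    """
    if min_unit < 1 or max_unit < min_unit or min_total < 1:
        raise ValueError("repeat parameters must be positive and ordered")
    s = seq.upper()
    n = len(s)
    valid = [c in ALPHABET for c in s]
    out: list[RepeatAnnotation] = []
    for k in range(min_unit, max_unit + 1):
        start = 0
        while start + 2 * k <= n:
            if not all(valid[start : start + k]):
                start += 1
                continue
            # left-maximality: the period must not extend to start-1
            if start >= 1 and valid[start - 1] and s[start - 1] == s[start - 1 + k]:
                start += 1
                continue
            unit = s[start : start + k]
            if not _is_primitive(unit):
                start += 1
                continue
            end = start + k
            while end < n and valid[end] and s[end] == s[end - k]:
                end += 1
            run = end - start
            copies, rem = divmod(run, k)
            if copies >= 2 and copies * k >= min_total:
                out.append(
                    RepeatAnnotation(
                        start=start,
                        unit=_canonical_rotation(unit),
                        copies=copies,
                        length=copies * k,
                        partial=rem > 0,
                    )
                )
            # advance by one: a phase-shifted run with a different unit can
            # start inside this one (left-maximality filters the rest)
            start += 1
    out.sort(key=lambda r: (r.start, len(r.unit)))
    return out


# -- MEME minimal format --------------------------------------------------


def write_minimal_meme(
    pwms: list[PWM], background: np.ndarray | None = None
) -> str:
    """Serialize PWMs in MEME minimal motif format."""
    bg = np.asarray(
        background if background is not None else (pwms[0].background if pwms else np.full(4, 0.25)),
        float,
    )
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)),
        "",
    ]
    for k, pwm in enumerate(pwms, start=1):
        lines.append(f"MOTIF motif_{k}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {max(pwm.n_sites, 1)} E= 0"
        )
        for j in range(pwm.width):
            lines.append(" ".join(f"{pwm.matrix[b, j]:.6f}" for b in range(4)))
        lines.append("")
    return "\n".join(lines) + "\n"


def parse_minimal_meme(text: str) -> tuple[list[PWM], np.ndarray]:
    """Parse MEME minimal format back into PWMs (round-trip reader)."""
    lines = text.splitlines()
    bg = np.full(4, 0.25)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[2 * k + 1]) for k in range(4)])
            i += 2
        elif line.startswith("MOTIF"):
            i += 1
            header = lines[i].split()
            w = int(header[header.index("w=") + 1])
            nsites = int(header[header.index("nsites=") + 1])
            mat = np.zeros((4, w))
            for j in range(w):
                i += 1
                row = [float(x) for x in lines[i].split()]
                mat[:, j] = row
            mat = mat / mat.sum(axis=0, keepdims=True)
            pwms.append(PWM(mat, background=bg, n_sites=nsites))
            i += 1
        else:
            i += 1
    return pwms, bg
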