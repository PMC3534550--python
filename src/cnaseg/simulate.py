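"""Synthetic data generators for the staged tumor model.

The generators emulate what the analysis pipeline consumes, with known
ground truth:

* piecewise-constant integer copy-number profiles on a diploid baseline,
  with a stage-dependent altered-genome fraction (normal ~0%, transgenic
  ~20-25%, tumor ~40%, cell line ~46%);
* allele-summarized array intensities where the total signal is
  proportional to the *mixture* copy number ``c_eff = f*c + (1-f)*2``
  (``f`` = tumor-cell fraction), with multiplicative log-normal noise;
* differential-expression tables optionally coupled to copy number;
* inter-segment-region (ISR) DNA sequences with motifs planted under a
  zero-or-one-occurrence-per-sequence (ZOOPS) scheme.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome import CopyNumberProfile, GenomeMap

__all__ = [
    "SimulationConfig",
    "STAGES",
    "simulate_profile",
    "simulate_intensities",
    "simulate_expression",
    "simulate_isr_sequences",
    "pwm_from_consensus",
    "random_genes",
]

ALPHABET = "ACGT"
STAGES = ("normal", "transgenic", "tumor", "cell_line")


@dataclass
class SimulationConfig:
    """Parameters of the staged synthetic model.

    Stage altered fractions default to the four-stage progression of the
    mouse model: no alteration in normals, ~22% in transgenic hyperplasia,
    ~40% in tumors, ~46% in tumor-derived cell lines.
    """

    n_chromosomes: int = 10
    probes_per_chromosome: int = 200
    chrom_length: int = 10_000_000
    altered_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "normal": 0.0,
            "transgenic": 0.22,
            "tumor": 0.40,
            "cell_line": 0.46,
        }
    )
    copy_states: tuple[int, ...] = (0, 1, 3, 4, 6)
    mean_segment_probes: float = 20.0
    noise_sd: float = 0.15  # sd of log2 intensity noise
    baseline: float = 1000.0
    tumor_cell_fraction: float = 1.0
    allele_freq: float = 0.5
    expression_coupling: float = 0.0
    expression_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for stage, frac in self.altered_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"altered fraction for {stage} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 < self.tumor_cell_fraction <= 1.0:
            raise ValueError("tumor cell fraction must be in (0, 1]")
        if self.mean_segment_probes < 1:
            raise ValueError("mean segment length must be >= 1 probe")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _stage_rng(cfg: SimulationConfig, stage: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, STAGES.index(stage), salt])
    )


def simulate_profile(
    genome: GenomeMap, cfg: SimulationConfig, stage: str
) -> CopyNumberProfile:
    """Draw a ground-truth copy-number profile for a model stage.

    Altered segments (geometric length in probes, state drawn from the
    configured palette) are placed on the diploid baseline until the
    altered bp fraction reaches the stage's target; boundaries snap to
    inter-probe midpoints. Raises if the target cannot be reached.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    target = cfg.altered_fraction[stage]
    rng = _stage_rng(cfg, stage, salt=1)

    states = {c: np.full(len(genome.positions[c]), 2, dtype=int) for c in genome.chrom_names}
    bounds = {c: genome.midpoint_boundaries(c) for c in genome.chrom_names}
    probe_bp = {c: np.diff(bounds[c]) for c in genome.chrom_names}
    total_bp = genome.total_bp

    if target == 0.0:
        return CopyNumberProfile.from_probe_states(genome, states)
    if not cfg.copy_states or all(s == 2 for s in cfg.copy_states):
        raise ValueError("cannot reach a nonzero altered fraction without non-diploid states")

    chrom_names = genome.chrom_names
    weights = np.array([len(genome.positions[c]) for c in chrom_names], dtype=float)
    weights /= weights.sum()
    geom_p = min(1.0, 1.0 / cfg.mean_segment_probes)

    altered_bp = 0
    attempts = 0
    max_attempts = 20_000
    while altered_bp < target * total_bp:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not reach altered fraction {target} for stage {stage}: "
                "segment placement exhausted (fraction or segment-length "
                "distribution infeasible for this map)"
            )
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        st = states[chrom]
        n = len(st)
        if n == 0:
            continue
        length = int(rng.geometric(geom_p))
        start = int(rng.integers(0, n))
        end = min(start + length, n)
        if np.any(st[start:end] != 2):
            continue
        # truncate the final segment so the altered fraction lands on the
        # target instead of overshooting by up to a whole segment
        need = target * total_bp - altered_bp
        bp_cum = np.cumsum(probe_bp[chrom][start:end])
        cut = int(np.searchsorted(bp_cum, need)) + 1
        end = min(end, start + cut)
        state = int(cfg.copy_states[rng.integers(len(cfg.copy_states))])
        st[start:end] = state
        altered_bp += int(probe_bp[chrom][start:end].sum())

    return CopyNumberProfile.from_probe_states(genome, states)


def simulate_intensities(
    genome: GenomeMap,
    profile: CopyNumberProfile,
    cfg: SimulationConfig,
    sample: str = "sample",
    stage: str = "tumor",
) -> pd.DataFrame:
    """Simulate allele-summarized probe intensities for one sample.

    Expected total intensity at a probe with true copy state ``c`` is
    ``baseline * c_eff / 2`` with ``c_eff = f*c + (1-f)*2`` — the copy
    number seen by the array when only a fraction ``f`` of cells carry the
    alteration. Noise is multiplicative: the log2 signal gets independent
    Normal(0, noise_sd) jitter. The total splits into A/B channels through
    a simulated genotype (AA/AB/BB at the configured allele frequency).

    Returns a frame ``probe_id chrom pos intensity_A:<sample>
    intensity_B:<sample>``.
    """
    rng = _stage_rng(cfg, stage, salt=zlib.crc32(sample.encode()))
    f = cfg.tumor_cell_fraction
    probe_states = profile.probe_states(genome)

    frames = []
    for chrom in genome.chrom_names:
        c = probe_states[chrom].astype(float)
        c_eff = f * c + (1.0 - f) * 2.0
        n = len(c_eff)
        eps = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
        total = cfg.baseline * (c_eff / 2.0) * np.exp2(eps)
        p = cfg.allele_freq
        geno = rng.choice(3, size=n, p=[p * p, 2 * p * (1 - p), (1 - p) ** 2])
        share_a = np.array([1.0, 0.5, 0.0])[geno]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": genome.positions[chrom],
                    f"intensity_A:{sample}": total * share_a,
                    f"intensity_B:{sample}": total * (1.0 - share_a),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    probe_ids = genome.probe_frame()["probe_id"]
    out.insert(0, "probe_id", probe_ids.values)
    return out


def random_genes(
    genome: GenomeMap,
    n: int = 500,
    mean_length: int = 30_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene coordinates on the map (1-based inclusive intervals)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    chrom_names = genome.chrom_names
    lengths = genome.lengths
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    rows = []
    for i in range(n):
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        glen = max(1000, int(rng.exponential(mean_length)))
        start = int(rng.integers(1, max(2, lengths[chrom] - glen)))
        rows.append((f"gene{i:05d}", chrom, start, start + glen - 1))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def simulate_expression(
    profile: CopyNumberProfile,
    genes: pd.DataFrame,
    cfg: SimulationConfig,
    genome: GenomeMap | None = None,
) -> pd.DataFrame:
    """Differential-expression table with tunable copy-number coupling.

    With coupling ``kappa``, ``E[logFC] = kappa * log2(c_eff/2)`` where
    ``c_eff`` is the mixture copy number at the gene midpoint; independent
    Normal noise is added on top. Adjusted p-values come from a z-test of
    each logFC against the noise sd, Benjamini-Hochberg corrected.

    Returns ``gene_id chrom start end logFC adj_p`` (one row per gene).
    """
    from scipy import stats

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 211]))
    kappa = cfg.expression_coupling
    sd = cfg.expression_noise_sd
    f = cfg.tumor_cell_fraction

    log_dosage = np.empty(len(genes))
    for i, row in enumerate(genes.itertuples(index=False)):
        mid = (int(row.start) + int(row.end)) // 2
        c = profile.state_at(row.chrom, mid - 1)  # bp positions are 1-based
        c_eff = f * c + (1.0 - f) * 2.0
        log_dosage[i] = np.log2(max(c_eff, 1e-6) / 2.0)

    noise = rng.normal(0.0, sd, size=len(genes)) if sd > 0 else np.zeros(len(genes))
    logfc = kappa * log_dosage + noise
    z = logfc / max(sd, 1e-9)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    adj_p = multipletests(pvals, method="fdr_bh")[1]

    out = genes[["gene_id", "chrom", "start", "end"]].copy()
    out["logFC"] = logfc
    out["adj_p"] = adj_p
    return out


def pwm_from_consensus(consensus: str, match_prob: float = 1.0) -> np.ndarray:
    """4 x w letter-probability matrix concentrated on a consensus string."""
    consensus = consensus.upper()
    if not set(consensus) <= set(ALPHABET):
        raise ValueError("consensus must be over ACGT")
    w = len(consensus)
    off = (1.0 - match_prob) / 3.0
    pwm = np.full((4, w), off)
    for j, base in enumerate(consensus):
        pwm[ALPHABET.index(base), j] = match_prob
    return pwm


def _sample_from_pwm(pwm: np.ndarray, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=pwm[:, j] / pwm[:, j].sum()) for j in range(pwm.shape[1])]
    return "".join(ALPHABET[c] for c in cols)


def simulate_isr_sequences(
    n: int,
    length: int,
    motif: str | np.ndarray,
    occupancy: float,
    seed: int = 0,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[list[str], list[tuple[int, int]]]:
    """Background DNA with a motif planted under the ZOOPS scheme.

    ``motif`` is either a 4 x w probability matrix or a consensus/repeat-unit
    string (converted to a deterministic matrix). Exactly
    ``floor(occupancy * n)`` sequences receive one planted instance at a
    uniformly random offset (forward strand); the planted ``(sequence_index,
    offset)`` pairs are returned alongside the sequences.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    pwm = pwm_from_consensus(motif) if isinstance(motif, str) else np.asarray(motif, float)
    w = pwm.shape[1]
    if w > length:
        raise ValueError("motif width exceeds sequence length")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 389]))
    bg = np.asarray(background, float)
    bg = bg / bg.sum()

    n_plant = int(np.floor(occupancy * n))
    planted_idx = set(rng.choice(n, size=n_plant, replace=False).tolist()) if n_plant else set()

    seqs: list[str] = []
    planted: list[tuple[int, int]] = []
    for i in range(n):
        letters = rng.choice(4, size=length, p=bg)
        seq = list("".join(ALPHABET[b] for b in letters))
        if i in planted_idx:
            off = int(rng.integers(0, length - w + 1))
            seq[off : off + w] = _sample_from_pwm(pwm, rng)
            planted.append((i, off))
        seqs.append("".join(seq))
    return seqs, planted
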