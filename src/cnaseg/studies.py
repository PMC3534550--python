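"""Calibration and recovery studies on synthetic data.

Each study regenerates its inputs from a seed and measures one property of
the pipeline: type-I behavior of the segmentation's permutation test on
pure noise, breakpoint recovery on planted segments, planted-motif
recovery by the ZOOPS EM, and end-to-end determinism plus the staged
altered-fraction progression. Problem sizes are chosen for single-CPU
desk-scale runs; the same functions back the test suite and the
reproduction script.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from .cna import CategoryScheme
from .motifs import ZoopsMotif, revcomp
from .pipeline import PipelineConfig, run_all, simulate_dataset
from .segmentation import CbsParams, segment_chromosome
from .simulate import SimulationConfig, simulate_isr_sequences

__all__ = [
    "null_calibration_study",
    "breakpoint_recovery_study",
    "motif_recovery_study",
    "staged_pipeline_study",
]


def null_calibration_study(
    n_chromosomes: int = 1000,
    n_probes: int = 200,
    noise_sd: float = 0.2,
    params: CbsParams | None = None,
    seed: int = 0,
) -> dict:
    """Segment pure-noise chromosomes; count spurious splits.

    Under the null, the fraction of chromosomes split at all should be
    consistent with ``alpha`` and the median segment count should be 1.
    """
    params = params or CbsParams(n_permutations=2000)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1009]))
    positions = np.arange(1, n_probes + 1)
    seg_counts = []
    for k in range(n_chromosomes):
        values = rng.normal(0.0, noise_sd, n_probes)
        segs = segment_chromosome(
            values, positions, params, chrom=f"null{k}",
            seed_seq=np.random.SeedSequence([seed, 1013, k]),
        )
        seg_counts.append(len(segs))
    seg_counts = np.array(seg_counts)
    return {
        "n_chromosomes": n_chromosomes,
        "n_split": int((seg_counts > 1).sum()),
        "split_rate": float((seg_counts > 1).mean()),
        "median_segments": float(np.median(seg_counts)),
        "alpha": params.alpha,
    }


def breakpoint_recovery_study(
    n_replicates: int = 100,
    n_probes: int = 100,
    seg_probes: int = 15,
    delta: float = 0.6,
    noise_sd: float = 0.2,
    tol_probes: int = 2,
    params: CbsParams | None = None,
    seed: int = 0,
) -> dict:
    """Plant one elevated segment per replicate; measure boundary recovery.

    The planted step is ``delta = 3 * noise_sd`` by default. A replicate is
    recovered when both planted boundaries have a found boundary within
    ``tol_probes`` probes.
    """
    params = params or CbsParams(n_permutations=2000)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2003]))
    positions = np.arange(1, n_probes + 1)
    recovered = 0
    for k in range(n_replicates):
        start = int(rng.integers(10, n_probes - seg_probes - 10))
        values = rng.normal(0.0, noise_sd, n_probes)
        values[start : start + seg_probes] += delta
        segs = segment_chromosome(
            values, positions, params, chrom=f"rep{k}",
            seed_seq=np.random.SeedSequence([seed, 2011, k]),
        )
        found = {s.start_idx for s in segs[1:]}
        ok = all(
            any(abs(f - b) <= tol_probes for f in found)
            for b in (start, start + seg_probes)
        )
        recovered += ok
    return {
        "n_replicates": n_replicates,
        "n_recovered": recovered,
        "recovery_rate": recovered / n_replicates,
        "delta_over_sigma": delta / noise_sd,
    }


def motif_recovery_study(
    n_replicates: int = 20,
    n_seqs: int = 50,
    seq_len: int = 300,
    width: int = 15,
    occupancy: float = 0.9,
    seed: int = 0,
) -> dict:
    """Plant a random information-rich consensus; count exact recoveries.

    Each replicate draws a fresh random 15-mer consensus, plants it in
    ``occupancy`` of the sequences, runs the ZOOPS EM and checks the
    recovered consensus (either strand). The per-iteration penalized
    log-likelihood is checked to be non-decreasing in every run.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3001]))
    recovered = 0
    monotone = True
    for k in range(n_replicates):
        consensus = "".join(rng.choice(list("ACGT"), width))
        seqs, _ = simulate_isr_sequences(
            n_seqs, seq_len, consensus, occupancy, seed=int(rng.integers(2**31))
        )
        est = ZoopsMotif(width=width, random_state=k).fit(seqs)
        trace = np.array(est.ll_trace_)
        monotone = monotone and bool(np.all(np.diff(trace) >= -1e-8))
        if est.pwm_.consensus in (consensus, revcomp(consensus)):
            recovered += 1
    return {
        "n_replicates": n_replicates,
        "n_recovered": recovered,
        "ll_always_nondecreasing": monotone,
    }


def staged_pipeline_study(
    seed: int = 0,
    n_chromosomes: int = 3,
    probes_per_chromosome: int = 150,
    n_permutations: int = 1000,
    out_dir: str | Path | None = None,
) -> dict:
    """Full staged run, twice, measuring determinism and stage progression.

    Returns the per-sample altered probe fraction (1 - unchanged) in stage
    order and whether the two manifests' file checksums are identical.
    """
    cfg = SimulationConfig(
        n_chromosomes=n_chromosomes,
        probes_per_chromosome=probes_per_chromosome,
        chrom_length=5_000_000,
        seed=seed,
    )
    table, profiles, gmap = simulate_dataset(cfg)

    def one_run(tag: str, base: Path) -> dict:
        pconf = PipelineConfig(
            normal_ids=["Normal1", "Normal2"],
            cbs=CbsParams(n_permutations=n_permutations, seed=seed),
            seed=seed,
            out_dir=str(base / tag),
        )
        return run_all(pconf, table)

    with tempfile.TemporaryDirectory() as tmp:
        base = Path(out_dir) if out_dir is not None else Path(tmp)
        base.mkdir(parents=True, exist_ok=True)
        m1 = one_run("run1", base)
        m2 = one_run("run2", base)
        import pandas as pd

        fractions = pd.read_csv(base / "run1" / "snp_fractions.tsv", sep="\t", index_col=0)

    order = ["Normal1", "Transgenic1", "Tumor1", "CellLine1"]
    altered = [float(1.0 - fractions.loc["unchanged", s]) for s in order]
    return {
        "identical_checksums": m1["files"] == m2["files"],
        "stage_order": order,
        "altered_fraction_by_stage": altered,
        "monotone_nondecreasing": all(a <= b + 1e-12 for a, b in zip(altered, altered[1:])),
        "planted_fraction_by_stage": [
            profiles[s].altered_fraction(gmap) for s in order
        ],
    }
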