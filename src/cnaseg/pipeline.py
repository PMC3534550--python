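"""End-to-end orchestration: CNA calling -> segmentation -> breakpoints/ISRs
-> concordance -> motif discovery, with a reproducibility manifest.

``run_all`` executes whichever stages its inputs allow: the intensity
table drives CNA and segmentation; a gene/DE table adds the concordance
tables; a genome FASTA adds ISR sequence export and motif discovery.
Reruns with identical inputs and seed are bit-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .breakpoints import (
    breakpoints_to_bed,
    export_isr_fasta,
    extract_breakpoints,
    extract_isrs,
    isrs_to_bed,
)
from .cna import CategoryScheme, CnaCaller
from .concordance import (
    concordance_percent,
    segment_gene_concordance,
    select_top_genes,
    snp_gene_concordance,
)
from .motifs import ZoopsMotif, write_minimal_meme
from .segmentation import CbsParams, SegmentationResult, classify_segments, segment_track

logger = logging.getLogger("cnaseg")

__all__ = ["PipelineConfig", "run_all", "stage_summary", "simulate_dataset"]


@dataclass
class PipelineConfig:
    """Run configuration for the full pipeline."""

    normal_ids: list[str] = field(default_factory=list)
    analysis_ids: list[str] | None = None  # None = all samples in the table
    scheme: CategoryScheme = field(default_factory=CategoryScheme)
    cbs: CbsParams = field(default_factory=CbsParams)
    isr_min_delta: float = 0.8
    overlap_tol: int = 0
    top_n_genes: int = 500
    motif_width: int = 15
    epsilon: float = 1.0
    seed: int = 0
    out_dir: str = "cnaseg_out"

    def __post_init__(self) -> None:
        if not self.normal_ids:
            raise ValueError("at least one normal sample id is required")


def stage_summary(
    tracks: dict[str, pd.DataFrame],
    results: dict[str, SegmentationResult],
    scheme: CategoryScheme | None = None,
) -> dict[str, pd.DataFrame]:
    """Cross-sample summary tables.

    Returns the per-sample five-bin probe fraction table, the matching
    segment-level table, and per-chromosome segment counts.
    """
    scheme = scheme or CategoryScheme()
    from .cna import classify_cna

    probe_cols, seg_cols, count_cols = {}, {}, {}
    for s, track in tracks.items():
        _, fr = classify_cna(track["log2ratio"].to_numpy(), scheme)
        probe_cols[s] = fr
    for s, res in results.items():
        _, fr = classify_segments(res, scheme)
        seg_cols[s] = fr
        count_cols[s] = res.counts_per_chromosome()
    return {
        "snp_fractions": pd.DataFrame(probe_cols),
        "segment_fractions": pd.DataFrame(seg_cols),
        "segment_counts": pd.DataFrame(count_cols).fillna(0).astype(int),
    }


def run_all(
    config: PipelineConfig,
    intensities: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    genome: dict[str, str] | None = None,
) -> dict:
    """Run every stage the inputs allow; write outputs and a manifest.

    Returns the manifest dict (also written as ``manifest.json``); file
    checksums make determinism checkable by rerunning.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "params": {
            "alpha": config.cbs.alpha,
            "n_permutations": config.cbs.n_permutations,
            "undo_sd": config.cbs.undo_sd,
            "min_width": config.cbs.min_width,
            "isr_min_delta": config.isr_min_delta,
            "top_n_genes": config.top_n_genes,
            "epsilon": config.epsilon,
        },
        "stages": [],
        "files": {},
    }

    def _register(name: str, path: Path) -> None:
        manifest["files"][name] = cio.sha256_file(path)

    logger.info("seed=%d normals=%s", config.seed, config.normal_ids)

    # CNA stage
    caller = CnaCaller(
        normal_ids=list(config.normal_ids), epsilon=config.epsilon, scheme=config.scheme
    ).fit(intensities)
    tracks = caller.transform(intensities)
    if config.analysis_ids is not None:
        tracks = {s: t for s, t in tracks.items() if s in config.analysis_ids}
    for s, track in tracks.items():
        p = out / f"cna_{s}.tsv"
        cio.write_track_tsv(track, p)
        _register(f"cna_{s}", p)
    manifest["stages"].append("cna")
    logger.info("cna: %d samples, %.1fs", len(tracks), time.time() - t0)

    # Segmentation stage
    cbs = CbsParams(
        alpha=config.cbs.alpha,
        n_permutations=config.cbs.n_permutations,
        undo_sd=config.cbs.undo_sd,
        min_width=config.cbs.min_width,
        seed=config.seed,
    )
    results: dict[str, SegmentationResult] = {}
    for s, track in tracks.items():
        res = segment_track(track, cbs, sample_id=s)
        classify_segments(res, config.scheme)
        results[s] = res
        p = out / f"segments_{s}.seg"
        p.write_text(res.to_seg())
        _register(f"segments_{s}", p)
    manifest["stages"].append("segment")

    summaries = stage_summary(tracks, results, config.scheme)
    for name, df in summaries.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format="%.6f")
        _register(name, p)
    logger.info("segment: %.1fs", time.time() - t0)

    # Breakpoints / ISRs
    all_isrs = {}
    for s, res in results.items():
        bps = extract_breakpoints(res)
        isrs = extract_isrs(res, config.isr_min_delta)
        all_isrs[s] = isrs
        (out / f"breakpoints_{s}.bed").write_text(breakpoints_to_bed(bps))
        (out / f"isrs_{s}.bed").write_text(isrs_to_bed(isrs))
        _register(f"breakpoints_{s}", out / f"breakpoints_{s}.bed")
        _register(f"isrs_{s}", out / f"isrs_{s}.bed")
    manifest["stages"].append("isr")

    # Concordance (needs gene table)
    if genes is not None:
        top = select_top_genes(genes, config.top_n_genes)
        for s in tracks:
            t1 = snp_gene_concordance(tracks[s], top, band=config.scheme.lo)
            t2 = segment_gene_concordance(results[s], top, band=config.scheme.lo)
            frame = pd.concat(
                {"SNPs": t1.to_frame(), "segments": t2.to_frame()}, names=["unit"]
            )
            p = out / f"concordance_{s}.tsv"
            frame.to_csv(p, sep="\t")
            _register(f"concordance_{s}", p)
            manifest.setdefault("concordance_percent", {})[s] = {
                "SNPs": concordance_percent(t1) if t1.grand_total else None,
                "segments": concordance_percent(t2) if t2.grand_total else None,
            }
        manifest["stages"].append("concordance")
    else:
        logger.warning("no gene table: concordance stage skipped")

    # Motif discovery (needs genome sequence)
    if genome is not None:
        for s, isrs in all_isrs.items():
            passing = [i for i in isrs if i.passes]
            if not passing:
                continue
            fasta = export_isr_fasta(isrs, genome)
            p = out / f"isr_{s}.fasta"
            p.write_text(fasta)
            _register(f"isr_{s}_fasta", p)
            seqs = [i for i in fasta.split("\n") if i and not i.startswith(">")]
            usable = [q for q in seqs if len(q) >= config.motif_width]
            if len(usable) >= 2:
                est = ZoopsMotif(
                    width=config.motif_width, random_state=config.seed
                ).fit(usable)
                pm = out / f"motifs_{s}.meme"
                pm.write_text(write_minimal_meme([est.pwm_]))
                _register(f"motifs_{s}", pm)
        manifest["stages"].append("motif")
    else:
        logger.warning("no genome FASTA: motif stage skipped")

    manifest["runtime_s"] = round(time.time() - t0, 2)
    cio.write_manifest({k: v for k, v in manifest.items() if k != "runtime_s"}, out / "manifest.json")
    logger.info("done in %.1fs", time.time() - t0)
    return manifest


def simulate_dataset(cfg, stages_samples: dict[str, str] | None = None):
    """Four-stage synthetic dataset: intensity table + ground-truth profiles.

    ``stages_samples`` maps sample name -> stage; defaults to two normals
    plus one sample per later stage. Returns ``(intensities, profiles,
    genome_map)``.
    """
    from .genome import uniform_map
    from .simulate import simulate_intensities, simulate_profile

    stages_samples = stages_samples or {
        "Normal1": "normal",
        "Normal2": "normal",
        "Transgenic1": "transgenic",
        "Tumor1": "tumor",
        "CellLine1": "cell_line",
    }
    gmap = uniform_map(cfg.n_chromosomes, cfg.probes_per_chromosome, cfg.chrom_length)
    profiles = {}
    table = None
    for sample, stage in stages_samples.items():
        profile = simulate_profile(gmap, cfg, stage)
        profiles[sample] = profile
        frame = simulate_intensities(gmap, profile, cfg, sample=sample, stage=stage)
        if table is None:
            table = frame
        else:
            table = table.merge(frame, on=["probe_id", "chrom", "pos"], validate="1:1")
    return table, profiles, gmap
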