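"""End-to-end pipeline: QC -> MAF -> LD -> inbreeding -> Ne -> marker density.

Driven by a single YAML/dict config; every stage writes its tab-separated
table and the whole run is reproducible from (input, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inbreeding import inbreeding_coefficients, inbreeding_table
from .ld import (
    DEFAULT_BIN_EDGES_BP,
    DEFAULT_WINDOW_BP,
    LDDecay,
    bin_ld_decay,
    ld_maf_sensitivity,
    ld_sample_size_sensitivity,
    pairwise_ld,
)
from .maf import MafSpectrum, maf_spectrum
from .model import GenotypeDataset
from .ne import NeConfig, estimate_ne_trajectory, required_marker_count
from .plink import read_plink_binary, read_plink_text
from .qc import QCConfig, QCReport, apply_qc, marker_summary
from .reference import BOVINE_GENOME_BP
from .simulate import SimConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Aggregated outputs of one pipeline run."""

    config: dict[str, Any]
    version: str
    seed: int | None
    qc: QCReport
    marker_summary: pd.DataFrame
    maf: MafSpectrum
    ld_decay: LDDecay
    inbreeding: pd.DataFrame
    mean_f: float
    ne_trajectory: pd.DataFrame
    density_recommendation: dict[str, float]
    maf_sensitivity: pd.DataFrame | None = None
    sample_size_sensitivity: pd.DataFrame | None = None


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _load_dataset(cfg: dict[str, Any]) -> GenotypeDataset:
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        for key in ("founder_maf_range", "low_freq_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        dataset, _ = simulate(SimConfig(**sim_kwargs))
        return dataset
    prefix = Path(cfg["plink_prefix"])
    if prefix.with_suffix(".bed").exists():
        return read_plink_binary(
            prefix.with_suffix(".bed"),
            prefix.with_suffix(".bim"),
            prefix.with_suffix(".fam"),
        )
    return read_plink_text(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))


def run_all(config: dict[str, Any] | str | Path, outdir: str | Path | None = None) -> RunReport:
    """Run every stage in fixed order and (optionally) write output tables.

    ``config`` is a dict or path to a YAML file with optional blocks
    ``simulate`` / ``plink_prefix``, ``qc``, ``ld``, ``ne``, ``sensitivity``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(config)
    seed = cfg.get("seed", cfg.get("simulate", {}).get("seed"))

    dataset = _load_dataset(cfg)
    logger.info("loaded %d individuals x %d markers", dataset.n_individuals, dataset.n_markers)

    qc_cfg = QCConfig(**cfg.get("qc", {}))
    filtered, qc_report = apply_qc(dataset, qc_cfg)
    lengths = cfg.get("chromosome_lengths_mb")
    if lengths is not None:
        lengths = {int(k): float(v) for k, v in lengths.items()}
    summary = marker_summary(filtered, lengths)
    qc_report.summary = summary

    spectrum = maf_spectrum(filtered)

    ld_cfg = cfg.get("ld", {})
    window = int(ld_cfg.get("window_bp", DEFAULT_WINDOW_BP))
    edges = tuple(ld_cfg.get("bin_edges_bp", DEFAULT_BIN_EDGES_BP))
    pairs = pairwise_ld(filtered, window_bp=window, method=ld_cfg.get("method", "em"))
    decay = bin_ld_decay(pairs, edges)

    records, mean_f = inbreeding_coefficients(filtered)
    f_table = inbreeding_table(records)

    ne_kwargs = dict(cfg.get("ne", {}))
    ne_kwargs.setdefault("n", filtered.n_individuals)
    ne_cfg = NeConfig(**ne_kwargs)
    trajectory = estimate_ne_trajectory(pairs, ne_cfg)

    dens_cfg = cfg.get("density", {})
    genome_bp = float(dens_cfg.get("genome_size_bp", BOVINE_GENOME_BP))
    span_bp = float(dens_cfg.get("ld_span_bp", 50_000))
    density = {
        "genome_size_bp": genome_bp,
        "ld_span_bp": span_bp,
        "required_snps": required_marker_count(genome_bp, span_bp),
    }

    sens_cfg = cfg.get("sensitivity", {})
    maf_sens = sample_sens = None
    if sens_cfg.get("maf", False):
        maf_sens = ld_maf_sensitivity(filtered, window_bp=window, edges_bp=edges)
    if sens_cfg.get("sample_size", False):
        sizes = tuple(
            s for s in sens_cfg.get("sizes", (10, 25, 50, 75, 90))
            if s <= filtered.n_individuals
        )
        sample_sens = ld_sample_size_sensitivity(
            filtered, sizes=sizes, seed=int(seed or 0), window_bp=window, edges_bp=edges
        )

    report = RunReport(
        config=cfg,
        version=__version__,
        seed=seed,
        qc=qc_report,
        marker_summary=summary,
        maf=spectrum,
        ld_decay=decay,
        inbreeding=f_table,
        mean_f=mean_f,
        ne_trajectory=trajectory,
        density_recommendation=density,
        maf_sensitivity=maf_sens,
        sample_size_sensitivity=sample_sens,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: RunReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.marker_summary.to_csv(outdir / "marker_summary.tsv", sep="\t", index=False)
    report.maf.per_chromosome.to_csv(outdir / "maf_spectrum.tsv", sep="\t", index=False)
    report.ld_decay.genome.to_csv(outdir / "ld_decay.tsv", sep="\t", index=False)
    report.ld_decay.per_chromosome.to_csv(
        outdir / "ld_decay_per_chromosome.tsv", sep="\t", index=False
    )
    report.inbreeding.to_csv(outdir / "inbreeding.tsv", sep="\t", index=False)
    report.ne_trajectory.to_csv(outdir / "ne_trajectory.tsv", sep="\t", index=False)
    if report.maf_sensitivity is not None:
        report.maf_sensitivity.to_csv(outdir / "ld_maf_sensitivity.tsv", sep="\t", index=False)
    if report.sample_size_sensitivity is not None:
        report.sample_size_sensitivity.to_csv(
            outdir / "ld_sample_size_sensitivity.tsv", sep="\t", index=False
        )
    headline = {
        "version": report.version,
        "seed": report.seed,
        "n_markers_input": report.qc.n_input,
        "n_markers_retained": report.qc.n_retained,
        "removed": report.qc.removed,
        "mean_maf": report.maf.mean_maf,
        "mean_r2_all_pairs": report.ld_decay.mean_r2_all,
        "n_ld_pairs": report.ld_decay.n_pairs,
        "mean_f": report.mean_f,
        "density": report.density_recommendation,
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(headline, fh, indent=2, default=float)
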