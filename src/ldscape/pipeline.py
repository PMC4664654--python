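"""End-to-end pipeline: QC -> LD scan -> decay -> blocks -> phase -> Ne -> tree.

Runs every stage per population, writes fixed-column TSV reports with '%.6g'
numeric formatting for hash stability, and finishes with a MANIFEST listing
the sha256 of every output: identical inputs and config give an identical
MANIFEST.  A stage whose output files already exist is skipped, so deleting
one output and re-running recomputes only that stage.
"""
from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blocks as blocks_mod
from . import crosspop, decay, ne, qc
from .io import GenotypeMatrix, attach_populations, read_plink, read_population_labels
from .ldcore import EmSettings, windowed_ld_scan

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Inputs and stage parameters of one pipeline run."""

    bfile: str | Path
    out_dir: str | Path
    pops_file: str | Path | None = None
    qc_config: qc.QcConfig = field(default_factory=qc.QcConfig)
    em_settings: EmSettings = field(default_factory=EmSettings)
    ld_window_bp: int = 1_000_000
    decay_classes_kb: tuple[tuple[float, float], ...] = decay.DEFAULT_CLASSES_KB
    maf_thresholds: tuple[float, ...] = (0.05, 0.1, 0.2)
    block_params: blocks_mod.BlockParams = field(default_factory=blocks_mod.BlockParams)
    phase_bin_width_kb: float = 10.0
    phase_fit_range_kb: tuple[float, float] = (0.0, 500.0)
    ne_settings: ne.NeSettings = field(default_factory=ne.NeSettings)
    genome_length_bp: float = 2.49e9
    r2_threshold: float = 0.20


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages and return the report directory.

    Stage failures abort with the stage name attached to the exception.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        g = read_plink(cfg.bfile)
        if cfg.pops_file is not None:
            g = attach_populations(g, read_population_labels(cfg.pops_file))
        if g.population is None:
            raise ValueError("no population labels: provide a pops file or .fam family ids")

        stage = "qc"
        report = qc.apply_qc(g, cfg.qc_config)
        qc_path = out / "qc_summary.tsv"
        if not qc_path.exists():
            _write_tsv(report.summary_frame(), qc_path)
            for pop, r in report.per_population.items():
                _write_tsv(qc.chromosome_summary(r.retained), out / f"chromosomes.{pop}.tsv")
                _write_tsv(qc.maf_spectrum(r.retained), out / f"maf_spectrum.{pop}.tsv")
        pops = {p: r.retained for p, r in report.per_population.items()}

        stage = "ld"
        scans: dict[str, pd.DataFrame] = {}
        for pop, gp in pops.items():
            path = out / f"pairs.{pop}.tsv"
            scans[pop] = windowed_ld_scan(gp, cfg.ld_window_bp, cfg.em_settings)
            if not path.exists():
                _write_tsv(scans[pop], path)

        stage = "decay"
        for pop, scan in scans.items():
            for thr in cfg.maf_thresholds:
                path = out / f"decay.{pop}.maf{thr:g}.tsv"
                if path.exists():
                    continue
                table = decay.bin_decay(scan, cfg.decay_classes_kb, thr, population=pop)
                _write_tsv(table, path)

        stage = "density"
        rows = []
        for pop, scan in scans.items():
            table = decay.bin_decay(scan, cfg.decay_classes_kb, cfg.maf_thresholds[0], population=pop)
            d = decay.required_marker_density(table, cfg.genome_length_bp, cfg.r2_threshold)
            rows.append(
                {
                    "population": pop,
                    "spacing_bp": d.spacing_bp,
                    "marker_count": d.marker_count,
                    "below_panel_resolution": d.below_panel_resolution,
                }
            )
        path = out / "marker_density.tsv"
        if not path.exists():
            _write_tsv(pd.DataFrame(rows), path)

        stage = "blocks"
        for pop, gp in pops.items():
            bed_path = out / f"blocks.{pop}.tsv"
            sum_path = out / f"blocks_summary.{pop}.tsv"
            if bed_path.exists() and sum_path.exists():
                continue
            blist, summary = blocks_mod.find_blocks(gp, cfg.block_params, cfg.em_settings)
            _write_tsv(blocks_mod.blocks_to_frame(blist, gp), bed_path)
            _write_tsv(summary.to_frame(pop), sum_path)

        stage = "phase"
        pop_names = sorted(pops)
        estimates: dict[tuple[str, str], crosspop.DivergenceEstimate] = {}
        if len(pop_names) < 2:
            logger.info("single population: phase and tree stages skipped")
        else:
            div_rows = []
            for a, b in itertools.combinations(pop_names, 2):
                path = out / f"phase.{a}.{b}.tsv"
                stream = crosspop.shared_pair_phase(
                    pops[a], pops[b], cfg.ld_window_bp, cfg.em_settings
                )
                table = crosspop.phase_correlation(
                    stream, cfg.phase_bin_width_kb,
                    morgans_per_bp=cfg.ne_settings.morgans_per_bp,
                )
                if not path.exists():
                    _write_tsv(table, path)
                est = crosspop.estimate_divergence_time(
                    table, cfg.phase_fit_range_kb, cfg.ne_settings.morgans_per_bp
                )
                estimates[(a, b)] = est
                div_rows.append(
                    {
                        "pop1": a, "pop2": b, "T": est.T, "slope": est.slope,
                        "intercept": est.intercept, "r0_sq_proxy": est.r0_sq_proxy,
                        "n_bins_used": est.n_bins_used,
                    }
                )
            path = out / "divergence.tsv"
            if not path.exists():
                _write_tsv(pd.DataFrame(div_rows), path)

            stage = "tree"
            path = out / "divergence_nj.nwk"
            if not path.exists() and len(pop_names) >= 3:
                labels, mat = crosspop.divergence_matrix(estimates, pop_names)
                path.write_text(crosspop.nj_tree(labels, mat) + "\n")

        stage = "ne"
        for pop, scan in scans.items():
            path = out / f"ne.{pop}.tsv"
            if path.exists():
                continue
            traj = ne.ne_trajectory(scan, cfg.ne_settings)
            traj = traj.copy()
            traj.insert(0, "population", pop)
            _write_tsv(traj, path)

        stage = "manifest"
        manifest_path = out / "MANIFEST"
        entries = sorted(
            p for p in out.iterdir() if p.is_file() and p.name != "MANIFEST"
        )
        manifest_path.write_text(
            "".join(f"{_sha256(p)}  {p.name}\n" for p in entries)
        )
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
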