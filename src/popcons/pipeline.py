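"""End-to-end orchestration: QC -> diversity -> structure -> Ne -> prioritisation.

A single :class:`PipelineConfig` carries every stage threshold (defaults are
the standard reduced-representation SNP workflow values) and a master seed
from which per-stage seeds are derived deterministically, so each stage is
independently reproducible. Individual-level ordination and the dendrogram
use every sample surviving QC; per-population statistics use only localities
with at least ``min_locality_n`` samples.

Note the Ne stage deliberately runs on the *unpruned* locus set (restricted
to QC-surviving samples): LD pruning would destroy the very signal the
LD-based estimator measures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import diversity, io, ne, prioritize, qc, structure
from .dataset import DatasetError, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of the full analysis."""

    genotype_table: str | None = None
    metadata: str | None = None
    vcf: str | None = None
    output_dir: str = "popcons_output"
    # QC
    min_callrate: float = 0.90
    min_mac: int = 3
    max_ho: float = 0.6
    kinship_threshold: float = 0.25
    ld_max_corr: float = 0.5
    ld_window_bp: int = 100_000
    max_sample_missingness: float = 0.25
    # per-population stages
    min_locality_n: int = 5
    callable_sites: int | None = None
    # structure
    fst_bootstraps: int = 1000
    # Ne
    maf: float = 0.05
    recomb_rate_per_bp: float = 1e-8
    alpha: float = ne.DEFAULT_ALPHA
    generation_time: float = 1.95
    ne_drop_frac: float = 0.1
    ne_bootstrap_reps: int = 10
    ne_min_pairs: int = 50
    # prioritisation
    rarefaction_g: int = 10
    prioritize_n_per_pop: int = 4
    prioritize_reps: int = 100
    budgets: tuple[int, ...] = (1, 2, 3, 4)
    # stage toggles
    run_diversity: bool = True
    run_structure: bool = True
    run_ne: bool = True
    run_prioritize: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "budgets" in raw:
            raw["budgets"] = tuple(raw["budgets"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        order = ["qc", "fst", "ne", "prioritize", "simulate"]
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(order))
        return int(
            np.random.default_rng(children[order.index(stage)]).integers(2**31)
        )


def _load_input(config: PipelineConfig) -> GenotypeDataset:
    if config.vcf:
        return io.read_vcf(config.vcf, config.metadata)
    if config.genotype_table and config.metadata:
        return io.read_genotype_table(config.genotype_table, config.metadata)
    raise DatasetError("config must provide a vcf or a genotype_table + metadata")


def run_pipeline(
    config: PipelineConfig, ds: GenotypeDataset | None = None
) -> dict:
    """Run every enabled stage and write the report bundle to output_dir.

    Returns a summary dict (also written as ``summary.json``) whose entries
    all come from the stage output objects.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ds is None:
        ds = _load_input(config)
    summary: dict = {"n_loci_input": ds.n_loci, "n_samples_input": ds.n_samples}

    # ---- QC ----------------------------------------------------------------
    try:
        filtered, report = qc.run_qc_cascade(
            ds,
            min_callrate=config.min_callrate,
            min_mac=config.min_mac,
            max_ho=config.max_ho,
            kinship_threshold=config.kinship_threshold,
            ld_max_corr=config.ld_max_corr,
            ld_window_bp=config.ld_window_bp,
            max_sample_missingness=config.max_sample_missingness,
        )
    except DatasetError as exc:
        raise DatasetError(f"stage qc: {exc}") from exc
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    report.to_json(out / "filter_report.json")
    io.write_genotype_table(
        filtered, out / "filtered_genotypes.tsv", out / "filtered_metadata.tsv"
    )
    summary["n_loci_filtered"] = filtered.n_loci
    summary["n_samples_filtered"] = filtered.n_samples
    summary["missing_fraction_filtered"] = filtered.missing_fraction()

    populations = io.split_by_locality(filtered, config.min_locality_n)
    summary["populations"] = {k: v.n_samples for k, v in populations.items()}

    # ---- diversity ---------------------------------------------------------
    if config.run_diversity and populations:
        try:
            table = diversity.diversity_table(
                populations, callable_sites=config.callable_sites
            )
        except DatasetError as exc:
            raise DatasetError(f"stage diversity: {exc}") from exc
        table.to_csv(out / "diversity_table.tsv", sep="\t")
        summary["diversity"] = {
            pop: {"H_E": row["H_E"], "H_O": row["H_O"], "F_IS": row["F_IS"]}
            for pop, row in table.iterrows()
        }

    # ---- structure ---------------------------------------------------------
    if config.run_structure:
        try:
            dist = structure.prevosti_distance(filtered)
            ordination = structure.pcoa(dist, n_axes=2)
            newick = structure.upgma_dendrogram(dist)
            fst = (
                structure.pairwise_fst(
                    populations,
                    n_bootstrap=config.fst_bootstraps,
                    seed=config.stage_seed("fst"),
                )
                if len(populations) >= 2
                else None
            )
        except DatasetError as exc:
            raise DatasetError(f"stage structure: {exc}") from exc
        dist.to_csv(out / "prevosti_distance.tsv", sep="\t")
        ordination.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        (out / "dendrogram.nwk").write_text(newick + "\n")
        summary["pcoa_percent_variance"] = [float(x) for x in ordination.percent_variance]
        if fst is not None:
            fst.to_table().to_csv(out / "fst_table.tsv", sep="\t")
            summary["fst"] = {
                f"{a}~{b}": float(fst.theta.loc[a, b])
                for i, a in enumerate(fst.theta.index)
                for b in fst.theta.index[i + 1 :]
            }
        from .plots import plot_pcoa

        plot_pcoa(
            ordination,
            {s.sample_id: s.locality for s in filtered.samples},
            out / "pcoa.png",
        )

    # ---- Ne ----------------------------------------------------------------
    if config.run_ne and populations:
        keep_samples = set(filtered.sample_ids)
        unpruned = ds.take_samples(
            [j for j, s in enumerate(ds.samples) if s.sample_id in keep_samples]
        )
        trajectories: dict[str, ne.NeTrajectory] = {}
        rows = []
        for name, idx in unpruned.localities().items():
            if name not in populations:
                continue
            pop_ds = unpruned.take_samples(idx)
            try:
                traj = ne.bootstrap_trajectory(
                    pop_ds,
                    population=name,
                    drop_frac=config.ne_drop_frac,
                    reps=config.ne_bootstrap_reps,
                    seed=config.stage_seed("ne"),
                    maf=config.maf,
                    recomb_rate_per_bp=config.recomb_rate_per_bp,
                    alpha=config.alpha,
                    min_pairs=config.ne_min_pairs,
                    generation_time=config.generation_time,
                )
            except DatasetError as exc:
                logger.warning("stage ne: population %s skipped (%s)", name, exc)
                continue
            trajectories[name] = traj
            rows.append(traj.table.assign(population=name))
        if rows:
            import pandas as pd

            pd.concat(rows, ignore_index=True).to_csv(
                out / "ne_trajectories.tsv", sep="\t", index=False
            )
            from .plots import plot_ne_trajectories

            plot_ne_trajectories(trajectories, out / "ne_trajectories.png")
            summary["ne_populations"] = sorted(trajectories)

    # ---- prioritisation ----------------------------------------------------
    if config.run_prioritize and len(populations) >= 2:
        try:
            ar = prioritize.loo_contribution(populations, g=config.rarefaction_g)
            budgets = tuple(b for b in config.budgets if b <= len(populations))
            solutions = prioritize.prioritize_resampled(
                populations,
                n_per_pop=config.prioritize_n_per_pop,
                reps=config.prioritize_reps,
                budgets=budgets,
                g=config.rarefaction_g,
                seed=config.stage_seed("prioritize"),
            )
        except DatasetError as exc:
            raise DatasetError(f"stage prioritize: {exc}") from exc
        ar.to_frame().to_csv(out / "allelic_richness.tsv", sep="\t")
        cov = prioritize.coverage_table(solutions)
        cov.to_csv(out / "coverage_solutions.tsv", sep="\t", index=False)
        from .plots import plot_coverage

        plot_coverage(cov, out / "coverage.png")
        summary["ar_total"] = ar.ar_total
        summary["ar_contribution"] = ar.contribution
        summary["coverage_mean_proportion"] = {
            int(b): sol.mean_proportion for b, sol in solutions.items()
        }

    summary["config"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
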