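"""End-to-end driver ordering the analysis stages.

simulate (or ingest) -> genotype -> coverage gate -> per-position F_ST ->
minor-allele gate(s) -> per-site aggregation -> threshold sweep, LOESS
profiles and the sister-site diagnostic.  Every stage logs record counts;
the summary conserves them (sites in = passing + failing at every gate).
All randomness is derived from the single pipeline seed, so a rerun with
the same configuration writes identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .filters import coverage_gate
from .fst import FstRecord, haplotype_fst_from_counts, pool_to_snp_sites, site_fst_records, wc_theta_from_genotype_counts
from .genotyping import call_consensus, filter_bases
from .scan import loess_profile, records_frame, site_table, sister_correlation, threshold_sweep
from .simulate import SimulatedTruth, simulate_populations, simulate_read_stacks, stage_rng

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def true_genotype_records(
    truth: SimulatedTruth, estimator: str = "haplotype"
) -> pd.DataFrame:
    """Per-SNP F_ST records straight from the simulated true genotypes.

    A vectorised shortcut past the sequencing and consensus-calling layers:
    one record per polymorphic site, with clipped ``fst``, pooled
    ``minor_allele_count`` and sister-pair bookkeeping columns
    (``pair_id``, ``side``).  Used for large desk-scale simulations where
    simulating reads would dominate the runtime.
    """
    pm = truth.pooled_minor()
    n = truth.config.n_genomes_per_pop
    poly = pm["polymorphic"]
    if estimator == "haplotype":
        raw = haplotype_fst_from_counts(pm["minor_a"], n, pm["minor_b"], n)
    elif estimator == "theta":
        g = truth.genotype_counts()
        raw = wc_theta_from_genotype_counts(
            g["hom_ref"][:, 0], g["het"][:, 0], g["hom_alt"][:, 0],
            g["hom_ref"][:, 1], g["het"][:, 1], g["hom_alt"][:, 1],
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    keep = poly & np.isfinite(raw)
    ann = truth.annotations
    idx = np.nonzero(keep)[0]
    return pd.DataFrame(
        {
            "site_id": [ann[i].site_id for i in idx],
            "chromosome": [ann[i].chromosome for i in idx],
            "position": truth.snp_position[idx],
            "estimator": estimator,
            "minor_allele_count": pm["mac"][idx],
            "fst_raw": raw[idx],
            "fst": np.clip(raw[idx], 0.0, 1.0),
            "pair_id": [f"{ann[i].chromosome}:{ann[i].cut_position}" for i in idx],
            "side": [ann[i].side for i in idx],
        }
    )


def run_pipeline(config: rio.PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write every stage output to ``outdir``.

    Returns a summary dictionary with per-stage record counts and output
    paths (also written to ``summary.json``).  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "counts": {}, "outputs": {}}
    counts = summary["counts"]
    outputs = summary["outputs"]

    ann_by_site: dict[str, object] = {}

    # ---- stage: simulate / ingest -----------------------------------------
    truth = None
    if config.genotypes_path is None:
        try:
            truth = simulate_populations(config.sim)
            rio.write_annotations_tsv(truth.annotations, outdir / "annotations.tsv")
            freq = pd.DataFrame(
                {
                    "site_id": truth.site_ids,
                    "chromosome": [a.chromosome for a in truth.annotations],
                    "position": truth.snp_position,
                    "ancestral_freq": truth.ancestral_freq,
                    "freq_pop1": truth.pop_freq[:, 0],
                    "freq_pop2": truth.pop_freq[:, 1],
                    "ref": truth.ref_base,
                    "alt": truth.alt_base,
                }
            )
            rio.write_table_tsv(freq, outdir / "true_frequencies.tsv")
            outputs["annotations"] = "annotations.tsv"
            outputs["true_frequencies"] = "true_frequencies.tsv"
            counts["simulated_sites"] = truth.n_sites
            ann_by_site = {a.site_id: a for a in truth.annotations}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", str(exc)) from exc

    # ---- stage: genotype ---------------------------------------------------
    try:
        if config.genotypes_path is not None:
            pools = rio.read_genotype_matrix(
                config.genotypes_path,
                dialect=config.genotypes_dialect,
                popmap=config.popmap_path,
            )
            if config.annotations_path:
                ann_by_site = {
                    a.site_id: a
                    for a in rio.read_annotations_tsv(config.annotations_path)
                }
            counts["ingested_sites"] = len(pools)
        elif config.use_stacks:
            stacks = simulate_read_stacks(truth, config.sim)
            rio.write_stacks_tsv(stacks, outdir / "stacks.tsv")
            outputs["stacks"] = "stacks.tsv"
            genotypes = [
                call_consensus(filter_bases(s, config.genotyping), config.genotyping)
                for s in stacks
            ]
            rio.write_genotypes_tsv(genotypes, outdir / "genotypes.tsv")
            outputs["genotypes"] = "genotypes.tsv"
            pools = {}
            for g in genotypes:
                pools.setdefault(g.site_id, []).append(g)
            counts["stacks"] = len(stacks)
        else:
            genotypes = [
                g for i in range(truth.n_sites) for g in truth.to_pool(i)
            ]
            rio.write_genotypes_tsv(genotypes, outdir / "genotypes.tsv")
            outputs["genotypes"] = "genotypes.tsv"
            pools = {}
            for g in genotypes:
                pools.setdefault(g.site_id, []).append(g)
        counts["genotyped_individuals"] = sum(len(p) for p in pools.values())
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("genotype", str(exc)) from exc

    # ---- stage: coverage gate ---------------------------------------------
    try:
        passing = {
            sid: pool for sid, pool in pools.items()
            if coverage_gate(pool, config.filter)
        }
        counts["sites_in"] = len(pools)
        counts["sites_passing_coverage"] = len(passing)
        counts["sites_failing_coverage"] = len(pools) - len(passing)
        log.info(
            "coverage gate: %d of %d sites pass",
            len(passing), len(pools),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("coverage_gate", str(exc)) from exc

    # ---- stage: per-position F_ST -----------------------------------------
    try:
        records: list[FstRecord] = []
        for sid in sorted(passing):
            ann = ann_by_site.get(sid)
            start = ann.start(config.sim.read_length) if ann is not None else 1
            chrom = ann.chromosome if ann is not None else ""
            snps = pool_to_snp_sites(
                passing[sid], site_id=sid, chromosome=chrom, start_position=start
            )
            records.extend(site_fst_records(snps, estimator=config.estimator))
        df = records_frame(records)
        if ann_by_site:
            df["pair_id"] = [
                f"{ann_by_site[s].chromosome}:{ann_by_site[s].cut_position}"
                for s in df["site_id"]
            ]
            df["side"] = [ann_by_site[s].side for s in df["site_id"]]
        rio.write_fst_tsv(df, outdir / "fst_snps.tsv")
        outputs["fst_snps"] = "fst_snps.tsv"
        counts["snps"] = len(df)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fst", str(exc)) from exc

    agg_rng = stage_rng(config.seed, "aggregation")

    # ---- stage: per-site aggregation + sweep ------------------------------
    try:
        sites1 = site_table(df, 1, config.aggregation, agg_rng) if len(df) else df
        if len(sites1):
            rio.write_fst_tsv(
                sites1.assign(aggregation=config.aggregation), outdir / "fst_sites.tsv"
            )
            outputs["fst_sites"] = "fst_sites.tsv"
        counts["sites_with_snps"] = int(sites1["site_id"].nunique()) if len(sites1) else 0
        sweep = threshold_sweep(
            df, config.thresholds, config.aggregation, config.per_site_mean, agg_rng
        )
        rio.write_table_tsv(sweep, outdir / "sweep.tsv")
        outputs["sweep"] = "sweep.tsv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("sweep", str(exc)) from exc

    # ---- stage: LOESS profiles --------------------------------------------
    try:
        profile_files = {}
        if len(df) and df["chromosome"].iloc[0] != "":
            for n in config.profile_thresholds:
                sites_n = site_table(df, n, config.aggregation, agg_rng)
                for chrom, sub in sites_n.groupby("chromosome"):
                    if len(sub) < 4:
                        log.warning(
                            "skipping profile for %s at n=%d: %d sites", chrom, n, len(sub)
                        )
                        continue
                    prof = loess_profile(
                        sub, chromosome=str(chrom), span=config.span,
                        degree=config.degree, grid_step=config.grid_step,
                    )
                    path = outdir / f"profile_{chrom}_n{n}.bedgraph"
                    rio.write_bedgraph(prof, path)
                    profile_files[f"{chrom}:n={n}"] = path.name
        outputs["profiles"] = profile_files
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("scan", str(exc)) from exc

    # ---- stage: sister diagnostic -----------------------------------------
    try:
        if "pair_id" in df.columns and len(df):
            sides_per_pair = df.groupby("pair_id")["side"].nunique()
            if (sides_per_pair >= 2).any():
                sisters = sister_correlation(
                    df, config.thresholds, config.aggregation, rng=agg_rng
                )
                rio.write_table_tsv(sisters, outdir / "sister.tsv")
                outputs["sister"] = "sister.tsv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diagnose", str(exc)) from exc

    rio.write_json(summary, outdir / "summary.json")
    return summary
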