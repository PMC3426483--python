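"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain TSV with a header line.  Internal coordinates
are 1-based inclusive throughout (genome-browser convention); only the
BEDGRAPH-style profile export converts to 0-based half-open intervals.
Missing data are written as ``.``, never as a sentinel allele.

Formats
-------
stacks TSV
    one row per read base: site_id, individual_id, population_id, read
    (0-based read index), position (1-based within the site), base,
    error_prob.
genotype TSV
    one row per individual x site x position: site_id, individual_id,
    population_id, ploidy, depth, position, call (``T/C`` diploid, ``T``
    haploid, ``.`` missing).
annotations TSV
    site_id, chromosome, cut_position (1-based), side.
population map TSV
    two columns, sample and population (no header).
F_ST TSV
    chromosome, position, site_id, estimator, minor_allele_count, fst_raw,
    fst, aggregation.
BEDGRAPH profile
    chromosome, start (0-based), end (half-open), smoothed F_ST.
VCF (read only)
    genotypes via cyvcf2; diploid ``0/1`` and haploid ``0`` GT calls map to
    two and one contributed genome(s); samples are assigned to populations
    through the population map.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .filters import FilterConfig
from .fst import FstRecord
from .genotyping import ConsensusGenotype, GenotypingConfig, ReadStack
from .scan import ScanProfile
from .simulate import RadSiteAnnotation, SimConfig, SimulatedTruth

log = logging.getLogger(__name__)

MISSING_FIELD = "."


# ---------------------------------------------------------------------------
# read stacks
# ---------------------------------------------------------------------------

def write_stacks_tsv(stacks: Sequence[ReadStack], path: str | Path) -> None:
    """Write read stacks in the documented long tab-delimited format."""
    with open(path, "w") as fh:
        fh.write("site_id\tindividual_id\tpopulation_id\tread\tposition\tbase\terror_prob\n")
        for st in stacks:
            for r in range(st.n_reads):
                for j in range(st.n_positions):
                    fh.write(
                        f"{st.site_id}\t{st.individual_id}\t{st.population_id}\t"
                        f"{r}\t{j + 1}\t{st.bases[r, j]}\t{float(st.error_probs[r, j])!r}\n"
                    )


def read_stacks_tsv(path: str | Path) -> list[ReadStack]:
    """Read stacks written by :func:`write_stacks_tsv` (order preserved)."""
    df = pd.read_csv(path, sep="\t", dtype={"base": str})
    stacks: list[ReadStack] = []
    # preserve file order of (site, individual) groups
    key = df["site_id"].astype(str) + "\x00" + df["individual_id"].astype(str)
    for _, grp in df.groupby(key.to_numpy(), sort=False):
        n_reads = int(grp["read"].max()) + 1 if len(grp) else 0
        n_pos = int(grp["position"].max())
        bases = np.full((n_reads, n_pos), "N", dtype="<U1")
        errs = np.ones((n_reads, n_pos), dtype=float)
        bases[grp["read"], grp["position"] - 1] = grp["base"]
        errs[grp["read"], grp["position"] - 1] = grp["error_prob"]
        first = grp.iloc[0]
        stacks.append(
            ReadStack(
                site_id=str(first["site_id"]),
                individual_id=str(first["individual_id"]),
                population_id=str(first["population_id"]),
                bases=bases,
                error_probs=errs,
            )
        )
    return stacks


# ---------------------------------------------------------------------------
# consensus genotypes
# ---------------------------------------------------------------------------

def write_genotypes_tsv(genotypes: Sequence[ConsensusGenotype], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tindividual_id\tpopulation_id\tploidy\tdepth\tposition\tcall\n")
        for g in genotypes:
            for j, call in enumerate(g.calls):
                text = MISSING_FIELD if call is None else "/".join(call)
                fh.write(
                    f"{g.site_id}\t{g.individual_id}\t{g.population_id}\t"
                    f"{g.ploidy}\t{g.depth}\t{j + 1}\t{text}\n"
                )


def read_genotypes_tsv(path: str | Path) -> list[ConsensusGenotype]:
    df = pd.read_csv(path, sep="\t", dtype={"call": str})
    out: list[ConsensusGenotype] = []
    key = df["site_id"].astype(str) + "\x00" + df["individual_id"].astype(str)
    for _, grp in df.groupby(key.to_numpy(), sort=False):
        grp = grp.sort_values("position")
        n_pos = int(grp["position"].max())
        calls: list[tuple[str, ...] | None] = [None] * n_pos
        for _, row in grp.iterrows():
            text = row["call"]
            if isinstance(text, str) and text != MISSING_FIELD:
                calls[int(row["position"]) - 1] = tuple(text.split("/"))
        first = grp.iloc[0]
        out.append(
            ConsensusGenotype(
                site_id=str(first["site_id"]),
                individual_id=str(first["individual_id"]),
                population_id=str(first["population_id"]),
                ploidy=int(first["ploidy"]),
                calls=calls,
                depth=int(first["depth"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotations, population map
# ---------------------------------------------------------------------------

def write_annotations_tsv(annotations: Sequence[RadSiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tchromosome\tcut_position\tside\n")
        for a in annotations:
            fh.write(f"{a.site_id}\t{a.chromosome}\t{a.cut_position}\t{a.side}\n")


def read_annotations_tsv(path: str | Path) -> list[RadSiteAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        RadSiteAnnotation(
            site_id=str(r.site_id),
            chromosome=str(r.chromosome),
            cut_position=int(r.cut_position),
            side=str(r.side),
        )
        for r in df.itertuples()
    ]


def read_popmap(path: str | Path) -> dict[str, str]:
    """Sample-to-population map: two whitespace-separated columns."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population'")
        mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# genotype matrices (TSV / VCF) -> per-site pools
# ---------------------------------------------------------------------------

def read_genotype_matrix(
    path: str | Path,
    dialect: str = "tsv",
    popmap: Mapping[str, str] | str | Path | None = None,
) -> dict[str, list[ConsensusGenotype]]:
    """Read pre-called genotypes into per-site pools.

    ``dialect="tsv"`` reads the genotype TSV format; ``dialect="vcf"`` reads
    a VCF with GT fields (one pool per record, site_id from the ID column or
    ``chrom:pos``; haploid single-allele GTs contribute one genome).  When a
    population map is given, every sample must appear in it (unknown samples
    raise an error naming the sample); for TSV input the map overrides the
    file's population column.
    """
    if popmap is not None and not isinstance(popmap, Mapping):
        popmap = read_popmap(popmap)
    pools: dict[str, list[ConsensusGenotype]] = {}
    if dialect == "tsv":
        for g in read_genotypes_tsv(path):
            if popmap is not None:
                if g.individual_id not in popmap:
                    raise ValueError(
                        f"sample {g.individual_id!r} absent from the population map"
                    )
                g = dataclasses.replace(g, population_id=popmap[g.individual_id])
            pools.setdefault(g.site_id, []).append(g)
        return pools
    if dialect == "vcf":
        return _read_vcf_pools(path, popmap)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf_pools(
    path: str | Path, popmap: Mapping[str, str] | None
) -> dict[str, list[ConsensusGenotype]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if popmap is None:
        raise ValueError("VCF input requires a sample-to-population map")
    for s in samples:
        if s not in popmap:
            raise ValueError(f"sample {s!r} absent from the population map")
    pools: dict[str, list[ConsensusGenotype]] = {}
    for rec in vcf:
        site_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        alleles = [rec.REF] + list(rec.ALT)
        pool: list[ConsensusGenotype] = []
        for si, s in enumerate(samples):
            gt = rec.genotypes[si]  # [allele0, allele1, ..., phased]
            allele_idx = [a for a in gt[:-1] if a is not None and a >= 0]
            ploidy = len(allele_idx) if allele_idx else (len(gt) - 1 or 1)
            ploidy = 2 if ploidy >= 2 else 1
            if allele_idx:
                call = tuple(sorted(alleles[a] for a in allele_idx[:ploidy]))
                if len(call) < ploidy:
                    call = None
            else:
                call = None
            pool.append(
                ConsensusGenotype(
                    site_id=site_id,
                    individual_id=s,
                    population_id=popmap[s],
                    ploidy=ploidy,
                    calls=[call],
                    depth=0,
                )
            )
        pools[site_id] = pool
    return pools


# ---------------------------------------------------------------------------
# F_ST tables, sweep, profiles
# ---------------------------------------------------------------------------

_FST_COLUMNS = [
    "chromosome", "position", "site_id", "estimator",
    "minor_allele_count", "fst_raw", "fst", "aggregation",
]


def write_fst_tsv(records: Sequence[FstRecord] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "aggregation" not in df.columns:
            df["aggregation"] = "none"
    else:
        df = pd.DataFrame(
            [
                {
                    "chromosome": r.chromosome,
                    "position": r.position,
                    "site_id": r.site_id,
                    "estimator": r.estimator,
                    "minor_allele_count": r.minor_allele_count,
                    "fst_raw": r.fst_raw,
                    "fst": r.fst,
                    "aggregation": r.aggregation,
                }
                for r in records
            ],
            columns=_FST_COLUMNS,
        )
    df.to_csv(path, sep="\t", index=False, columns=_FST_COLUMNS)


def read_fst_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(profile: ScanProfile, path: str | Path) -> None:
    """Export a profile as BEDGRAPH-style TSV (0-based half-open intervals).

    Each evaluation point p (1-based, inclusive) becomes the interval
    [p - 1, p) on the 0-based half-open scale.
    """
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tsmoothed_fst\n")
        for pos, val in zip(profile.eval_positions, profile.smoothed_fst):
            fh.write(f"{profile.chromosome}\t{pos - 1}\t{pos}\t{float(val)!r}\n")


def read_bedgraph(path: str | Path, span: float = 0.4, degree: int = 2) -> ScanProfile:
    df = pd.read_csv(path, sep="\t")
    chroms = df["chromosome"].unique()
    if len(chroms) != 1:
        raise ValueError("profile files hold exactly one chromosome")
    return ScanProfile(
        chromosome=str(chroms[0]),
        eval_positions=df["start"].to_numpy() + 1,
        smoothed_fst=df["smoothed_fst"].to_numpy(),
        span=span,
        degree=degree,
    )


def write_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Composition of all stage configurations plus scan settings and paths.

    ``seed`` overrides ``sim.seed`` so one value controls every stage.
    ``genotypes_path`` switches the pipeline to ingest mode (simulate and
    genotype stages are skipped); ``use_stacks=False`` keeps the simulation
    but genotypes the true genotypes directly, skipping the sequencing
    layer (useful for large desk-scale runs).
    """

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    genotyping: GenotypingConfig = dataclasses.field(default_factory=GenotypingConfig)
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    seed: int = 0
    span: float = 0.4
    degree: int = 2
    grid_step: int = 1000
    n_range: tuple[int, int] = (1, 10)
    estimator: str = "haplotype"
    aggregation: str = "max"
    profile_thresholds: tuple[int, ...] = (1, 4)
    per_site_mean: bool = True
    use_stacks: bool = True
    genotypes_path: str | None = None
    genotypes_dialect: str = "tsv"
    popmap_path: str | None = None
    annotations_path: str | None = None

    def __post_init__(self) -> None:
        self.n_range = tuple(int(v) for v in self.n_range)
        self.profile_thresholds = tuple(int(v) for v in self.profile_thresholds)
        if len(self.n_range) != 2 or self.n_range[0] > self.n_range[1]:
            raise ValueError("n_range must be an (n_low, n_high) pair with low <= high")
        self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    @property
    def thresholds(self) -> range:
        return range(self.n_range[0], self.n_range[1] + 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-friendly: tuples to lists
        def conv(v):
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v
        return conv(d)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        genotyping = GenotypingConfig(**d.pop("genotyping", {}))
        filt = FilterConfig(**d.pop("filter", {}))
        return cls(sim=sim, genotyping=genotyping, filter=filt, **d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
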