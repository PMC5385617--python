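"""End-to-end runs: simulate -> process -> stats, with config files,
a stage MANIFEST for crash-consistent resumption, and a machine-readable
report.

One global seed drives everything; per-stage seeds follow a documented
counter scheme (stage_seed = (seed + stage_index) mod 2**31 with
simulate=1, process=2, stats=3), so each stage is independently
reproducible.  Real-data mode skips simulation and consumes
user-supplied FASTQ, germline FASTA and barcode TSV paths — the tool
never downloads anything.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .germline import (
    GermlineReference,
    InvalidConfiguration,
    build_germline_reference,
    read_reference_fasta,
    write_reference_fasta,
)
from .processing import parse_sample_id, pool_tables, process_run, Scoring
from .stats import (
    cluster_repertoires,
    cohort_overlap_summary,
    compare_overlap_groups,
    gene_usage,
    overlap_profile,
    similarity_matrix,
    vj_restricted_overlap,
)
from .synthetic import (
    SharingModel,
    default_sharing_fractions,
    design_barcodes,
    emit_reads,
    read_barcode_tsv,
    simulate_cohort,
    write_barcode_tsv,
    write_fastq,
)
from .tables import ClonotypeTable, translate_junction

__all__ = ["RunConfig", "run_pipeline", "validate_airr", "stats_stage"]

logger = logging.getLogger("treclineage")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s %(levelname)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

_STAGE_INDEX = {"simulate": 1, "process": 2, "stats": 3}


def stage_seed(base_seed: int, stage: str) -> int:
    return (int(base_seed) + _STAGE_INDEX[stage]) % 2**31


@dataclass
class RunConfig:
    """Full parameterisation of one pipeline run.

    ``sharing`` maps "source->target" strings to theta fractions; None
    selects the default planted lineage model.  Every stage seed derives
    from ``seed``.  The config round-trips losslessly through YAML.
    """

    mode: str = "synthetic"  # or "real"
    outdir: str = "run"
    seed: int = 0
    # simulate
    patients: int = 5
    clone_pool_size: int = 1000
    powerlaw_alpha: float = 2.5
    cells_per_compartment: int = 50_000
    sharing: dict[str, float] | None = None
    error_rate: float = 0.001
    depth_per_clonotype_cell: float = 1.0
    barcode_length: int = 8
    n_v: int = 12
    n_j: int = 4
    # process
    max_mismatch: int = 1
    min_count: int = 1
    productive_only: bool = False
    subsample_depth: int | None = None
    min_score_fraction: float = 0.6
    # stats
    level: str = "clonotype"
    linkage: str = "average"
    restrict_v: str = "TRBV12-4"
    restrict_j: str = "TRBJ1-2"
    # real mode inputs
    fastq: str | None = None
    reference_fasta: str | None = None
    barcodes_tsv: str | None = None

    def sharing_fractions(self) -> dict[tuple[str, str], float]:
        if self.sharing is None:
            return default_sharing_fractions()
        out = {}
        for edge, theta in self.sharing.items():
            src, _, tgt = edge.partition("->")
            out[(src.strip(), tgt.strip())] = float(theta)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfiguration(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# stages


def _manifest_path(outdir: Path) -> Path:
    return outdir / "MANIFEST"


def _completed_stages(outdir: Path) -> list[str]:
    p = _manifest_path(outdir)
    if not p.exists():
        return []
    return [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]

def _mark_complete(outdir: Path, stage: str) -> None:
    with open(_manifest_path(outdir), "a") as fh:
        fh.write(stage + "\n")


def simulate_stage(config: RunConfig, outdir: Path) -> None:
    seed = stage_seed(config.seed, "simulate")
    reference = build_germline_reference(config.n_v, config.n_j, seed=seed)
    model = SharingModel(
        patients=config.patients,
        clone_pool_size=config.clone_pool_size,
        powerlaw_alpha=config.powerlaw_alpha,
        cells_per_compartment=config.cells_per_compartment,
        sharing_fractions=config.sharing_fractions(),
        seed=seed,
    )
    tables = simulate_cohort(model, reference)
    barcodes = design_barcodes(len(tables), length=config.barcode_length, seed=seed)
    barcode_map = dict(zip(tables, barcodes))
    truth_dir = outdir / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, table in tables.items():
        table.to_airr_tsv(truth_dir / f"{sample_id}.airr.tsv")
    write_reference_fasta(reference, outdir / "reference.fasta")
    write_barcode_tsv(barcode_map, outdir / "barcodes.tsv")
    n = write_fastq(
        emit_reads(
            tables,
            reference,
            barcode_map,
            depth_per_clonotype_cell=config.depth_per_clonotype_cell,
            error_rate=config.error_rate,
            seed=seed,
        ),
        outdir / "reads.fastq",
    )
    logger.info("simulate: %d samples, %d reads", len(tables), n)


def process_stage(config: RunConfig, outdir: Path) -> dict:
    seed = stage_seed(config.seed, "process")
    if config.mode == "real":
        fastq = Path(config.fastq)
        reference = read_reference_fasta(config.reference_fasta)
        barcode_map = read_barcode_tsv(config.barcodes_tsv)
    else:
        fastq = outdir / "reads.fastq"
        reference = read_reference_fasta(outdir / "reference.fasta")
        barcode_map = read_barcode_tsv(outdir / "barcodes.tsv")
    tables, report = process_run(
        fastq,
        barcode_map,
        reference,
        max_mismatch=config.max_mismatch,
        min_score_fraction=config.min_score_fraction,
        min_count=config.min_count,
        productive_only=config.productive_only,
        subsample_depth=config.subsample_depth,
        seed=seed,
    )
    proc_dir = outdir / "processed"
    proc_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, table in tables.items():
        table.to_airr_tsv(proc_dir / f"{sample_id}.airr.tsv")
    with open(outdir / "process_report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    logger.info(
        "process: %d reads in, %d undetermined", report["reads_in"], report["undetermined"]
    )
    return report


def stats_stage(
    tables: dict[str, ClonotypeTable],
    outdir: Path,
    level: str = "clonotype",
    linkage: str = "average",
    restrict_v: str | None = "TRBV12-4",
    restrict_j: str | None = "TRBJ1-2",
) -> dict:
    """Compute and persist the repertoire statistics for processed tables.

    Pools per-compartment across patients; writes the similarity matrix
    (TSV), dendrogram (Newick), V-gene usage (TSV), the tumor-Treg
    overlap profile (TSV) and per-patient V-J-restricted overlap with
    cohort mean +/- SEM; returns the headline numbers as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compartments: dict[str, list[ClonotypeTable]] = {}
    for t in tables.values():
        if t.site and t.subset:
            compartments.setdefault(f"{t.site}_{t.subset}", []).append(t)
    pooled = {
        comp: pool_tables(group, sample_id=comp)
        for comp, group in sorted(compartments.items())
        if any(len(t) for t in group)
    }
    headline: dict = {"level": level, "linkage": linkage}

    usage_rows = {}
    for comp, table in pooled.items():
        usage_rows[comp] = gene_usage(table, "V").as_series()
    usage_df = pd.DataFrame(usage_rows).fillna(0.0).sort_index()
    usage_df.to_csv(outdir / "v_usage.tsv", sep="\t")

    if len(pooled) >= 2:
        matrix = similarity_matrix(pooled, level=level)
        matrix.to_dataframe().to_csv(outdir / "similarity.tsv", sep="\t")
        dendrogram = cluster_repertoires(matrix, linkage=linkage)
        (outdir / "dendrogram.nwk").write_text(dendrogram.newick + "\n")
        headline["similarity"] = {
            a: {b: float(matrix.value(a, b)) for b in matrix.labels}
            for a in matrix.labels
        }
        headline["newick"] = dendrogram.newick
        if "TI_Treg" in pooled:
            headline["ti_treg_mh_ranking"] = [
                [lab, val] for lab, val in matrix.off_diagonal_ranking("TI_Treg")
            ]

    if "TI_Treg" in pooled:
        others = {k: v for k, v in pooled.items() if k != "TI_Treg"}
        if others:
            profile = overlap_profile(pooled["TI_Treg"], others)
            profile.to_csv(outdir / "ti_treg_overlap_profile.tsv", sep="\t")

    # per-patient V-J-restricted overlap of TI Tregs against other subsets
    patients = sorted({t.patient for t in tables.values() if t.patient})
    targets = ["TI_naive", "PB_naive", "PB_Treg", "PB_memory"]
    per_patient: dict[str, list] = {tgt: [] for tgt in targets}
    rows = []
    for patient in patients:
        by_comp = {
            f"{t.site}_{t.subset}": t
            for t in tables.values()
            if t.patient == patient
        }
        if "TI_Treg" not in by_comp:
            continue
        for tgt in targets:
            if tgt not in by_comp:
                continue
            res = vj_restricted_overlap(
                by_comp["TI_Treg"], by_comp[tgt], restrict_v, restrict_j
            )
            per_patient[tgt].append(res)
            rows.append(
                {
                    "patient": patient,
                    "target": tgt,
                    "shared_unique": res.shared_unique,
                    "unique_ti_treg": res.unique_a,
                    "unique_target": res.unique_b,
                    "fraction_a": res.fraction_a,
                    "fraction_b": res.fraction_b,
                    "weighted_fraction_a": res.weighted_fraction_a,
                    "weighted_fraction_b": res.weighted_fraction_b,
                    "empty": res.empty,
                }
            )
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "vj_overlap_per_patient.tsv", sep="\t", index=False)
    summary = {}
    for tgt, results in per_patient.items():
        if len(results) >= 2:
            summary[tgt] = cohort_overlap_summary(results)
    if summary:
        headline["vj_overlap_summary"] = summary
    if len(per_patient["PB_naive"]) >= 2 and len(per_patient["PB_Treg"]) >= 2:
        t_stat, p = compare_overlap_groups(
            [r.fraction_a for r in per_patient["PB_naive"]],
            [r.fraction_a for r in per_patient["PB_Treg"]],
        )
        headline["naive_vs_treg_ttest"] = {"t": t_stat, "p_raw": p}
    with open(outdir / "headline.yaml", "w") as fh:
        yaml.safe_dump(headline, fh, sort_keys=True)
    return headline


def _load_processed_tables(outdir: Path) -> dict[str, ClonotypeTable]:
    tables = {}
    for path in sorted((outdir / "processed").glob("*.airr.tsv")):
        sample_id = path.name[: -len(".airr.tsv")]
        tables[sample_id] = ClonotypeTable.from_airr_tsv(path, sample_id=sample_id)
    return tables


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order, resuming from the MANIFEST if present.

    Returns the run report (also written to ``<outdir>/report.yaml``);
    deterministic for a fixed config — the report carries no timestamps.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    done = _completed_stages(outdir)
    stages = (["simulate"] if config.mode == "synthetic" else []) + ["process", "stats"]
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": stages,
    }
    process_report = None
    for stage in stages:
        if stage in done:
            logger.info("%s: already complete, skipping", stage)
            continue
        try:
            if stage == "simulate":
                simulate_stage(config, outdir)
            elif stage == "process":
                process_report = process_stage(config, outdir)
            elif stage == "stats":
                tables = _load_processed_tables(outdir)
                headline = stats_stage(
                    tables,
                    outdir / "stats",
                    level=config.level,
                    linkage=config.linkage,
                    restrict_v=config.restrict_v,
                    restrict_j=config.restrict_j,
                )
                report["stats"] = headline
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        _mark_complete(outdir, stage)
    if process_report is None and (outdir / "process_report.yaml").exists():
        with open(outdir / "process_report.yaml") as fh:
            process_report = yaml.safe_load(fh)
    if "stats" not in report:  # stats already complete: reload persisted headline
        with open(outdir / "stats" / "headline.yaml") as fh:
            report["stats"] = yaml.safe_load(fh)
    report["process"] = process_report
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# AIRR validation


REQUIRED_AIRR = [
    "sequence_id",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "duplicate_count",
]


def validate_airr(path) -> tuple[bool, list[str]]:
    """Check an AIRR Rearrangement TSV; returns (pass, all violations)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    violations: list[str] = []
    for col in REQUIRED_AIRR:
        if col not in df.columns:
            violations.append(f"missing required column {col!r}")
    if violations:
        return False, violations
    for i, row in df.iterrows():
        rid = row["sequence_id"] or f"row {i}"
        try:
            count = int(float(row["duplicate_count"]))
        except ValueError:
            count = -1
        if count < 1:
            violations.append(f"{rid}: duplicate_count >= 1 violated")
        junction = row["junction"]
        if not junction or set(junction) - set("ACGT"):
            violations.append(f"{rid}: junction must be non-empty over ACGT")
            continue
        aa, productive = translate_junction(junction)
        if row["junction_aa"] and row["junction_aa"] != aa:
            violations.append(
                f"{rid}: junction_aa {row['junction_aa']!r} does not match "
                f"translated junction {aa!r}"
            )
        stated = row.get("productive", "")
        if stated in ("T", "F") and (stated == "T") != productive:
            violations.append(f"{rid}: productive flag inconsistent with junction")
    return not violations, violations
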