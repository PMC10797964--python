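"""Shared orchestration of the analysis stages, used by the CLI.

The same path runs either on an in-memory simulation result or on a run
directory of serialized artifacts, so every stage stays independently
invokable on the previous stage's outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import GenomeIndex, MapRecord, annotate_peptides, uniqueness_filter
from .intervals import (
    RegionTrack,
    TranscriptModel,
    read_bed,
    read_refflat,
    region_sizes,
)
from .peptides import (
    DatabaseParams,
    ReadRecord,
    SampleRoles,
    build_count_table,
    build_mmrd_db,
    build_mmrp_db,
    collect_provenance,
    count_sample,
    match_observed,
    read_fastx,
    write_database,
)
from .quantify import (
    CoverageProfile,
    covered_bases,
    peptide_tpm,
    read_bedgraph,
    select_candidates,
    write_candidate_table,
)
from .variants import (
    SampleVariantSet,
    filter_somatic,
    flag_ms_indels,
    read_vcf,
    scan_microsatellites,
)

__all__ = ["PipelineContext", "run_pipeline", "run_from_directory"]

REGION_LABELS = ("coding", "utr5", "utr3", "ncRNA", "intron", "extragenic")


@dataclass
class PipelineContext:
    genome: dict[str, str]
    models: list[TranscriptModel]
    tracks: list[RegionTrack]
    reads: dict[str, list[ReadRecord]]
    somatic_pre: SampleVariantSet  # filtered MMRd pre-injection variants
    coverage: CoverageProfile | None
    observed: pd.DataFrame
    roles: SampleRoles = field(default_factory=SampleRoles)


def context_from_simulation(result) -> PipelineContext:
    loci = scan_microsatellites(result.genome)
    vset = flag_ms_indels(result.filtered["MMRd_pre"], loci)
    return PipelineContext(
        genome=result.genome,
        models=result.models,
        tracks=result.tracks,
        reads=result.reads,
        somatic_pre=vset,
        coverage=result.coverage.get("MMRd_pre"),
        observed=result.observed,
    )


def context_from_directory(rundir: str | Path) -> PipelineContext:
    from Bio import SeqIO

    rundir = Path(rundir)
    genome = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(rundir / "genome.fa", "fasta")
    }
    models = read_refflat(rundir / "transcripts.refflat")
    tracks = [
        RegionTrack(label, read_bed(rundir / "regions" / f"{label}.bed"))
        for label in REGION_LABELS
        if (rundir / "regions" / f"{label}.bed").exists()
    ]
    roles = SampleRoles()
    reads = {
        s: list(read_fastx(rundir / "reads" / f"{s}.fastq", s))
        for s in roles.all_samples
    }
    germ = read_vcf(rundir / "vcf" / "germline.vcf")
    somatic = filter_somatic(read_vcf(rundir / "vcf" / "MMRd_pre.vcf"), germ)
    somatic = flag_ms_indels(somatic, scan_microsatellites(genome))
    cov_path = rundir / "coverage" / "MMRd_pre.bedgraph"
    coverage = read_bedgraph(cov_path) if cov_path.exists() else None
    observed = pd.read_csv(rundir / "observed_peptides.tsv", sep="\t")
    return PipelineContext(genome, models, tracks, reads, somatic, coverage, observed, roles)


def run_pipeline(
    result_or_ctx,
    outdir: str | Path | None = None,
    params: DatabaseParams | None = None,
    top_n: int = 20,
    n_pools: int = 3,
    min_depth: int = 10,
) -> dict:
    """Counting -> databases -> matching -> annotation -> quantification ->
    candidate selection; writes TSV artifacts when ``outdir`` is given."""
    ctx = (
        result_or_ctx
        if isinstance(result_or_ctx, PipelineContext)
        else context_from_simulation(result_or_ctx)
    )
    params = params or DatabaseParams()
    roles = ctx.roles

    counts = {s: count_sample(ctx.reads[s]) for s in roles.all_samples}
    table = build_count_table(counts)
    db_mmrd = build_mmrd_db(table, roles, params)
    db_mmrp = build_mmrp_db(table, roles, params)

    matched = match_observed(
        ctx.observed["peptide"].tolist(), db_mmrd, db_mmrp
    )

    pre_reads = ctx.reads[roles.mmrd_pre]
    provenance = collect_provenance(pre_reads, set(matched.exclusive))
    db_mmrd.provenance = provenance
    reads_by_id = {r.read_id: r.sequence for r in pre_reads}
    index = GenomeIndex(ctx.genome)
    records = annotate_peptides(
        matched.exclusive, provenance, reads_by_id, index,
        ctx.tracks, ctx.models, ctx.somatic_pre,
    )
    unique = uniqueness_filter(records)
    _attach_expression(unique, table, roles, ctx.observed)

    sizes = region_sizes(ctx.tracks)
    region_reads = {lab: 0 for lab in sizes}
    region_maps = {lab: 0 for lab in sizes}
    for r in unique:
        region_reads[r.region] = region_reads.get(r.region, 0) + r.n_reads
        region_maps[r.region] = region_maps.get(r.region, 0) + 1
    tpm = peptide_tpm(region_reads, sizes)
    covered = (
        covered_bases(ctx.coverage, ctx.tracks, min_depth)
        if ctx.coverage is not None
        else {}
    )

    candidates = select_candidates(
        unique,
        pre_sample=roles.mmrd_pre,
        competent_samples=list(roles.mmrd_balbc),
        n_pools=n_pools,
        top_n=top_n,
    )

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_database(db_mmrd, out / "db_MMRd.tsv", out / "db_MMRd.fasta")
        write_database(db_mmrp, out / "db_MMRp.tsv", out / "db_MMRp.fasta")
        _write_annotated(unique, out / "annotated.tsv")
        _write_quant(sizes, covered, region_maps, region_reads, tpm, out / "quantification.tsv")
        write_candidate_table(candidates, out / "candidates.tsv")

    return {
        "table": table,
        "db_mmrd": db_mmrd,
        "db_mmrp": db_mmrp,
        "matched": matched,
        "records": records,
        "unique_records": unique,
        "tpm": tpm,
        "covered": covered,
        "candidates": candidates,
        "db_mmrd_size": len(db_mmrd),
        "db_mmrp_size": len(db_mmrp),
        "n_matched": len(matched.exclusive),
        "n_annotated": len(unique),
        "n_candidates": len(candidates),
    }


def run_from_directory(rundir: str | Path, config=None, top_n: int = 20, n_pools: int = 3):
    ctx = context_from_directory(rundir)
    summary = run_pipeline(ctx, top_n=top_n, n_pools=n_pools)
    return summary["candidates"]


def _attach_expression(
    records: Sequence[MapRecord],
    table: pd.DataFrame,
    roles: SampleRoles,
    observed: pd.DataFrame,
) -> None:
    intensity = (
        observed.set_index("peptide")["ms_intensity"].to_dict()
        if "ms_intensity" in observed.columns
        else {}
    )
    for rec in records:
        if rec.peptide in table.index:
            row = table.loc[rec.peptide]
            rec.rna_counts = {s: int(row[s]) for s in roles.all_samples}
        ms = intensity.get(rec.peptide)
        rec.ms_intensity = None if ms is None or pd.isna(ms) else float(ms)


def _write_annotated(records: Sequence[MapRecord], path: Path) -> None:
    rows = [
        {
            "peptide": r.peptide,
            "coordinates": " ".join(f"{l.chrom}:{l.start}-{l.end}" for l in r.loci),
            "region": r.region,
            "frame": r.frame,
            "canonical": r.canonical,
            "alteration": r.mutation,
            "microsatellite": r.microsatellite,
            "n_reads": r.n_reads,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_quant(sizes, covered, region_maps, region_reads, tpm, path: Path) -> None:
    rows = []
    for lab in sizes:
        bp = covered.get(lab, 0)
        n = region_maps.get(lab, 0)
        rows.append(
            {
                "label": lab,
                "region_bp": sizes[lab],
                "covered_bp_ge_min": bp,
                "n_maps": n,
                "maps_per_mb": n / (bp / 1e6) if bp else float("nan"),
                "supporting_reads": region_reads.get(lab, 0),
                "tpm": tpm[lab],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
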