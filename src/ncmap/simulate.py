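"""Synthetic inputs with planted truth for every pipeline stage.

The generator emits a small multi-chromosome genome with coding / UTR /
intron / ncRNA / extragenic structure and microsatellite runs, per-sample
variant sets with elevated MMR-deficient rates, RNA reads from canonical
and aberrant (UTR, intron, extragenic, antisense, phase-shifted)
transcription, an immune-editing plan that removes reads carrying planted
target peptides from immunocompetent-host samples only, and an
observed-peptide list drawn from the planted truth.

Planted peptide windows are placed only in regions without canonical
background transcription (silent transcripts, introns, extragenic space),
and each window is rejected unless the full 8-11-mer closure of its
supporting read is disjoint from the background k-mer universe and from
every previously accepted window.  In noiseless mode the deficient-arm
database therefore equals the planted closure exactly.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    RegionTrack,
    TranscriptModel,
    assign_region,
    revcomp,
    tracks_from_transcripts,
    write_bed,
    write_genome_sizes,
    write_refflat,
)
from .peptides import ReadRecord, SampleRoles, read_kmers, write_fastq
from .quantify import CoverageProfile, write_bedgraph
from .variants import SampleVariantSet, Variant, write_vcf

__all__ = [
    "SimulationConfig",
    "PlantedWindow",
    "PlantedTruth",
    "SimulationResult",
    "simulate_genome",
    "simulate_variants",
    "simulate_reads",
    "simulate_observed_peptides",
    "simulate_all",
    "write_simulation",
    "WGS_SAMPLES",
]

_BASES = np.array(list("ACGT"))

#: WGS sample names per genotype arm.
WGS_SAMPLES = {
    "MMRp": ["MMRp_pre", "MMRp_NOD_1", "MMRp_BALBc_1", "MMRp_BALBc_2", "MMRp_BALBc_3"],
    "MMRd": ["MMRd_pre", "MMRd_NOD_1", "MMRd_BALBc_1", "MMRd_BALBc_2", "MMRd_BALBc_3"],
}

#: Planted-window categories with their truth region label and frame call.
CATEGORY_TRUTH = {
    "cds_inframe": ("coding", "in-frame"),
    "cds_frameshift": ("coding", "out-of-frame"),
    "utr5": ("utr5", "out-of-frame"),
    "utr3": ("utr3", "out-of-frame"),
    "intron": ("intron", "out-of-frame"),
    "extragenic": ("extragenic", "out-of-frame"),
    "antisense": ("coding", "out-of-frame"),
}

DEFAULT_CATEGORY_WEIGHTS = {
    "cds_inframe": 0.10,
    "cds_frameshift": 0.20,
    "utr5": 0.20,
    "utr3": 0.15,
    "intron": 0.15,
    "extragenic": 0.15,
    "antisense": 0.05,
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults run in minutes on one CPU."""

    seed: int = 0
    # genome
    n_chromosomes: int = 3
    chrom_length: int = 50_000
    n_transcripts: int = 30
    ncrna_fraction: float = 0.1
    expressed_fraction: float = 0.6
    exon_count_range: tuple[int, int] = (1, 3)
    cds_aa_range: tuple[int, int] = (60, 200)
    utr_range: tuple[int, int] = (60, 240)
    intron_range: tuple[int, int] = (150, 500)
    intergenic_range: tuple[int, int] = (300, 1200)
    ms_per_chrom: int = 15
    ms_unit_range: tuple[int, int] = (1, 3)
    ms_repeat_range: tuple[int, int] = (6, 14)
    # variants
    germline_rate_per_mb: float = 100.0
    mmrp_rate_per_mb: float = 60.0
    mmrd_factor: float = 10.0  # deficient/proficient alteration ratio
    rate_overrides: dict = field(default_factory=dict)  # (genotype,label)->rate
    indel_fraction: float = 0.3
    ms_indel_fraction: float = 0.5
    gained_fraction: float = 0.05
    editing_fraction: float = 0.5
    editing_regions: tuple[str, ...] = ("coding", "utr5")
    chaff_per_sample: int = 20  # sub-threshold calls to exercise the filter
    # reads
    read_length: int = 75
    background_depth: float = 10.0
    variant_spike_af: float = 0.0
    error_rate: float = 0.0
    dropout: float = 0.0
    # editing plan
    n_planted: int = 50
    n_planted_mmrp: int = 8
    n_retained: int = 5
    n_support: int = 12
    mutated_fraction: float = 0.2
    category_weights: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))
    # peptide k-mers
    k_min: int = 8
    k_max: int = 11
    # observed list
    observed_decoy_other: int = 5
    observed_decoy_random: int = 5

    def __post_init__(self) -> None:
        if self.mmrd_factor < 1:
            raise ValueError("mmrd_factor must be >= 1")
        for name in ("germline_rate_per_mb", "mmrp_rate_per_mb", "editing_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PlantedWindow:
    """One planted peptide window with its ground truth."""

    peptide: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str
    region: str
    frame: str  # in-frame / out-of-frame
    mutation: str  # WT / SNV
    arm: str  # MMRd / MMRp
    edited: bool
    read_seq: str
    read_start: int = 0  # genomic start of the supporting read's footprint
    closure: list[str] = field(default_factory=list)
    variant_key: tuple | None = None


@dataclass
class PlantedTruth:
    windows: list[PlantedWindow]
    edited_peptides: set[str]  # closure of all edited MMRd windows
    mmrp_edited_peptides: set[str]
    edited_variant_keys: set[tuple]
    expression: pd.DataFrame  # window target peptide x sample support counts


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: dict[str, str]
    genome_sizes: dict[str, int]
    models: list[TranscriptModel]
    expressed: set[str]
    tracks: list[RegionTrack]
    germline: SampleVariantSet
    raw_calls: dict[str, SampleVariantSet]
    filtered: dict[str, SampleVariantSet]
    reads: dict[str, list[ReadRecord]]
    coverage: dict[str, CoverageProfile]
    truth: PlantedTruth
    observed: pd.DataFrame


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[TranscriptModel], set[str]]:
    """Random genome with gene structure and microsatellite runs.

    Returns the genome, transcript models, and the names of the
    background-expressed transcripts (the rest are silent and provide the
    planting space for the editing plan).
    """
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        seq = rng.choice(_BASES, size=config.chrom_length)
        genome[f"chr{i + 1}"] = "".join(seq)
    # overwrite random spots with tandem repeats
    chars = {c: list(s) for c, s in genome.items()}
    for chrom, arr in chars.items():
        for _ in range(config.ms_per_chrom):
            u = int(rng.integers(*config.ms_unit_range, endpoint=True))
            n = int(rng.integers(*config.ms_repeat_range, endpoint=True))
            unit = "".join(rng.choice(_BASES, size=u))
            pos = int(rng.integers(0, config.chrom_length - u * n))
            arr[pos : pos + u * n] = list(unit * n)
    genome = {c: "".join(a) for c, a in chars.items()}

    models: list[TranscriptModel] = []
    chrom_names = sorted(genome)
    cursors = {c: int(rng.integers(200, 800)) for c in chrom_names}
    n_ncrna = max(0, round(config.n_transcripts * config.ncrna_fraction))
    for t in range(config.n_transcripts):
        chrom = chrom_names[t % len(chrom_names)]
        is_ncrna = t < n_ncrna
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
        if is_ncrna:
            exonic = int(rng.integers(300, 900))
            utr5_len = utr3_len = cds_len = 0
        else:
            cds_len = 3 * int(rng.integers(*config.cds_aa_range, endpoint=True))
            utr5_len = int(rng.integers(*config.utr_range, endpoint=True))
            utr3_len = int(rng.integers(*config.utr_range, endpoint=True))
            exonic = utr5_len + cds_len + utr3_len
        # split exonic length into n_exons parts of >= 50 bp
        cuts = sorted(rng.integers(50, exonic - 50, size=n_exons - 1).tolist()) if n_exons > 1 else []
        parts, prev = [], 0
        for c in cuts + [exonic]:
            parts.append(max(50, c - prev))
            prev = c
        start = cursors[chrom]
        exon_starts, exon_ends = [], []
        pos = start
        for j, plen in enumerate(parts):
            exon_starts.append(pos)
            exon_ends.append(pos + plen)
            pos += plen
            if j < len(parts) - 1:
                pos += int(rng.integers(*config.intron_range, endpoint=True))
        tx_end = exon_ends[-1]
        if tx_end >= config.chrom_length - 200:
            continue  # no room left on this chromosome
        if is_ncrna:
            cds_start = cds_end = start
        else:
            # transcript-space CDS bounds -> genomic
            t5 = utr5_len if strand == "+" else utr3_len
            cds_start = _tx_offset_to_genomic_plus(exon_starts, exon_ends, t5)
            cds_end = _tx_offset_to_genomic_plus(
                exon_starts, exon_ends, t5 + cds_len - 1
            ) + 1
        models.append(
            TranscriptModel(
                gene=f"gene{t}", name=f"tx{t}", chrom=chrom, strand=strand,
                tx_start=start, tx_end=tx_end,
                cds_start=cds_start, cds_end=cds_end,
                exon_starts=exon_starts, exon_ends=exon_ends,
            )
        )
        cursors[chrom] = tx_end + int(rng.integers(*config.intergenic_range, endpoint=True))

    coding = [m.name for m in models if not m.is_ncrna]
    n_expr = max(1, round(len(coding) * config.expressed_fraction))
    expressed = set(rng.choice(coding, size=n_expr, replace=False).tolist())
    expressed |= {m.name for m in models if m.is_ncrna}  # ncRNA transcribed
    return genome, models, expressed


def _tx_offset_to_genomic_plus(
    exon_starts: Sequence[int], exon_ends: Sequence[int], offset: int
) -> int:
    """Genomic base of a plus-orientation exonic offset."""
    for s, e in zip(exon_starts, exon_ends):
        if offset < e - s:
            return s + offset
        offset -= e - s
    raise ValueError("offset beyond exonic length")


def _tx_range_to_blocks(
    m: TranscriptModel, t_start: int, t_end: int
) -> list[GenomicInterval]:
    """Genomic blocks of a strand-aware transcript-space range."""
    exons = m.exons if m.strand == "+" else list(reversed(m.exons))
    blocks = []
    off = 0
    for s, e in exons:
        ln = e - s
        lo, hi = max(t_start, off), min(t_end, off + ln)
        if lo < hi:
            if m.strand == "+":
                blocks.append(GenomicInterval(m.chrom, s + lo - off, s + hi - off))
            else:
                blocks.append(GenomicInterval(m.chrom, e - (hi - off), e - (lo - off)))
        off += ln
    blocks.sort(key=lambda b: b.start)
    return blocks


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _rate(config: SimulationConfig, genotype: str, label: str) -> float:
    base = config.rate_overrides.get((genotype, label))
    if base is not None:
        return base
    factor = config.mmrd_factor if genotype == "MMRd" else 1.0
    return config.mmrp_rate_per_mb * factor


def _random_position(
    track: RegionTrack, rng: np.random.Generator, margin: int = 2
) -> tuple[str, int] | None:
    ivs = [iv for iv in track.intervals if len(iv) > 2 * margin]
    if not ivs:
        return None
    weights = np.array([len(iv) for iv in ivs], dtype=float)
    iv = ivs[rng.choice(len(ivs), p=weights / weights.sum())]
    pos = int(rng.integers(iv.start + margin, iv.end - margin))
    return iv.chrom, pos


def _make_variant(
    genome: Mapping[str, str],
    chrom: str,
    pos: int,
    rng: np.random.Generator,
    is_indel: bool,
    total_depth: int | None = None,
    alt_depth: int | None = None,
) -> Variant | None:
    seq = genome[chrom]
    ref_base = seq[pos]
    if ref_base == "N":
        return None
    total = total_depth if total_depth is not None else int(rng.integers(40, 120))
    if alt_depth is None:
        alt = int(rng.integers(max(9, total // 4), max(10, total // 2) + 1))
        alt = min(alt, total)
    else:
        alt = alt_depth
    if not is_indel:
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        return Variant(chrom, pos, ref_base, alt_base, total, alt)
    dlen = int(rng.integers(1, 4))
    if rng.random() < 0.5 and pos + 1 + dlen <= len(seq):  # deletion
        return Variant(chrom, pos, seq[pos : pos + 1 + dlen], ref_base, total, alt)
    ins = "".join(rng.choice(_BASES, size=dlen))
    return Variant(chrom, pos, ref_base, ref_base + ins, total, alt)


def simulate_variants(
    config: SimulationConfig,
    genome: Mapping[str, str],
    tracks: Sequence[RegionTrack],
    rng: np.random.Generator,
) -> tuple[SampleVariantSet, dict[str, SampleVariantSet], dict[str, SampleVariantSet], set[tuple]]:
    """Per-sample variant sets with Poisson-planted per-region rates.

    Returns (germline, raw calls per sample, filtered truth per sample,
    keys of immune-edited variants).  Raw calls include the germline set
    and sub-threshold chaff, so the somatic filter is exercised; the
    editing plan removes a fraction of coding/utr5 variants from the
    immunocompetent-host samples of the deficient genotype only.
    """
    genome_sizes = {c: len(s) for c, s in genome.items()}
    total_mb = sum(genome_sizes.values()) / 1e6

    def _depths_chaff():
        # deliberately failing either threshold
        if rng.random() < 0.5:
            total = int(rng.integers(3, 10))
            return total, min(total, int(rng.integers(1, 9)))
        return int(rng.integers(10, 60)), int(rng.integers(1, 9))

    germ_vars: dict[tuple, Variant] = {}
    n_germ = rng.poisson(config.germline_rate_per_mb * total_mb)
    whole = RegionTrack(
        "genome", [GenomicInterval(c, 0, n) for c, n in genome_sizes.items()]
    )
    for _ in range(n_germ):
        loc = _random_position(whole, rng, margin=5)
        if loc is None:
            continue
        v = _make_variant(genome, *loc, rng=rng, is_indel=rng.random() < 0.1)
        if v is not None:
            germ_vars.setdefault(v.key, v)
    germline = SampleVariantSet("germline", "germline", "pre", 0, list(germ_vars.values()))

    raw: dict[str, SampleVariantSet] = {}
    filtered: dict[str, SampleVariantSet] = {}
    edited_keys: set[tuple] = set()
    track_by_label = {t.label: t for t in tracks}

    for genotype, samples in WGS_SAMPLES.items():
        pre_vars: dict[tuple, Variant] = {}
        for label, track in track_by_label.items():
            lam = _rate(config, genotype, label) * track.total_bp() / 1e6
            for _ in range(rng.poisson(lam)):
                loc = _random_position(track, rng, margin=5)
                if loc is None:
                    continue
                is_indel = rng.random() < config.indel_fraction
                v = _make_variant(genome, *loc, rng=rng, is_indel=is_indel)
                if v is not None and v.key not in germ_vars:
                    pre_vars.setdefault(v.key, v)

        edited_here: set[tuple] = set()
        if genotype == "MMRd" and config.editing_fraction > 0:
            for key, v in pre_vars.items():
                label = assign_region(v.footprint, tracks)
                if label in config.editing_regions and rng.random() < config.editing_fraction:
                    edited_here.add(key)
        edited_keys |= edited_here

        def _gained() -> dict[tuple, Variant]:
            out: dict[tuple, Variant] = {}
            for label, track in track_by_label.items():
                lam = (
                    _rate(config, genotype, label)
                    * config.gained_fraction
                    * track.total_bp()
                    / 1e6
                )
                for _ in range(rng.poisson(lam)):
                    loc = _random_position(track, rng, margin=5)
                    if loc is None:
                        continue
                    v = _make_variant(
                        genome, *loc, rng=rng, is_indel=rng.random() < config.indel_fraction
                    )
                    if v is not None and v.key not in germ_vars and v.key not in pre_vars:
                        out.setdefault(v.key, v)
            return out

        for sample in samples:
            host = "pre" if sample.endswith("_pre") else (
                "NOD-SCID" if "_NOD_" in sample else "BALB/c"
            )
            somatic = dict(pre_vars)
            if host != "pre":
                somatic.update(_gained())
            if host == "BALB/c":
                for key in edited_here:
                    somatic.pop(key, None)
            chaff = []
            for _ in range(config.chaff_per_sample):
                loc = _random_position(whole, rng, margin=5)
                if loc is None:
                    continue
                total, alt = _depths_chaff()
                v = _make_variant(
                    genome, *loc, rng=rng, is_indel=False,
                    total_depth=total, alt_depth=alt,
                )
                if v is not None and v.key not in somatic and v.key not in germ_vars:
                    chaff.append(v)
            rep = int(sample.rsplit("_", 1)[1]) if not sample.endswith("_pre") else 0
            raw[sample] = SampleVariantSet(
                sample, genotype, host, rep,
                list(germ_vars.values()) + list(somatic.values()) + chaff,
            )
            filtered[sample] = SampleVariantSet(
                sample, genotype, host, rep, list(somatic.values())
            )
    return germline, raw, filtered, edited_keys


# ---------------------------------------------------------------------------
# planted peptide windows and reads
# ---------------------------------------------------------------------------

_AA_ONLY = set("ACDEFGHIKLMNPQRSTVWY")


def _translate_window(seq: str) -> str | None:
    from .peptides import frame_translation

    pep = frame_translation(seq, 1)
    if len(pep) * 3 != len(seq) or set(pep) - _AA_ONLY:
        return None
    return pep


def _background_kmers(
    genome: Mapping[str, str],
    models: Sequence[TranscriptModel],
    expressed: set[str],
    k_min: int,
    k_max: int,
) -> set[str]:
    """Six-frame k-mer universe of all background-expressed transcripts.

    Every k-mer of any read sampled from an expressed transcript is a
    k-mer of the mature transcript itself, so this is a superset of the
    background read closure."""
    universe: set[str] = set()
    for m in models:
        if m.name in expressed:
            universe |= set(read_kmers(m.spliced_sequence(genome), k_min, k_max))
    return universe


def _plan_windows(
    config: SimulationConfig,
    genome: Mapping[str, str],
    models: Sequence[TranscriptModel],
    expressed: set[str],
    tracks: Sequence[RegionTrack],
    rng: np.random.Generator,
) -> tuple[list[PlantedWindow], list[Variant]]:
    """Choose the planted windows for both genotype arms.

    Returns the windows (with per-window supporting read sequence and
    closure) and the extra SNVs created for mutated windows."""
    background = _background_kmers(genome, models, expressed, config.k_min, config.k_max)
    taken: set[str] = set()  # union of accepted closures
    occupied: list[GenomicInterval] = []
    silent_coding = [m for m in models if not m.is_ncrna and m.name not in expressed]
    if not silent_coding:
        raise ValueError("no silent coding transcripts available for planting")
    intron_track = next((t for t in tracks if t.label == "intron"), None)
    extr_track = next((t for t in tracks if t.label == "extragenic"), None)

    cats = list(config.category_weights)
    weights = np.array([config.category_weights[c] for c in cats], dtype=float)
    weights /= weights.sum()

    windows: list[PlantedWindow] = []
    extra_snvs: list[Variant] = []

    specs = (
        [("MMRd", True)] * config.n_planted
        + [("MMRd", False)] * config.n_retained
        + [("MMRp", True)] * config.n_planted_mmrp
    )
    for arm, edited in specs:
        placed = False
        for _ in range(500):
            category = str(rng.choice(cats, p=weights))
            w = _try_place_window(
                config, genome, silent_coding, intron_track, extr_track,
                category, rng,
            )
            if w is None:
                continue
            chrom, gs, ge, strand, region, frame = w
            if any(
                o.chrom == chrom and gs < o.end and o.start < ge for o in occupied
            ):
                continue
            k = (ge - gs) // 3
            fl = max(0, (config.read_length - (ge - gs)) // 2)
            rs, re = max(0, gs - fl), min(len(genome[chrom]), ge + fl)
            read_fwd = genome[chrom][rs:re]
            mutation, var_key = "WT", None
            window_fwd = genome[chrom][gs:ge]
            if (
                category in ("cds_inframe", "cds_frameshift", "utr5", "utr3")
                and rng.random() < config.mutated_fraction
            ):
                mut = _mutate_window(genome, chrom, gs, ge, strand, rng)
                if mut is not None:
                    v, window_fwd = mut
                    read_fwd = (
                        read_fwd[: gs - rs] + window_fwd + read_fwd[ge - rs :]
                    )
                    mutation, var_key = "SNV", v.key
                    extra_snv = v
                else:
                    extra_snv = None
            else:
                extra_snv = None
            wseq = window_fwd if strand == "+" else revcomp(window_fwd)
            pep = _translate_window(wseq)
            if pep is None or len(pep) != k:
                continue
            read_seq = read_fwd if strand == "+" else revcomp(read_fwd)
            closure = set(read_kmers(read_seq, config.k_min, config.k_max))
            if pep not in closure:
                continue
            if closure & background or closure & taken:
                continue
            taken |= closure
            occupied.append(GenomicInterval(chrom, rs, re))
            if extra_snv is not None:
                extra_snvs.append(extra_snv)
            windows.append(
                PlantedWindow(
                    peptide=pep, chrom=chrom, start=gs, end=ge, strand=strand,
                    category=category, region=region, frame=frame,
                    mutation=mutation, arm=arm, edited=edited,
                    read_seq=read_seq, read_start=rs, closure=sorted(closure),
                    variant_key=var_key,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a planted window for arm={arm}; "
                "genome too small or too densely transcribed"
            )
    return windows, extra_snvs


def _try_place_window(
    config: SimulationConfig,
    genome: Mapping[str, str],
    silent_coding: Sequence[TranscriptModel],
    intron_track: RegionTrack | None,
    extr_track: RegionTrack | None,
    category: str,
    rng: np.random.Generator,
) -> tuple[str, int, int, str, str, str] | None:
    """One placement attempt; returns (chrom, start, end, strand, region,
    frame) or None."""
    k = int(rng.integers(config.k_min, config.k_max + 1))
    wlen = 3 * k
    region, frame = CATEGORY_TRUTH[category]
    fl = max(0, (config.read_length - wlen) // 2) + 2

    if category in ("cds_inframe", "cds_frameshift", "antisense", "utr5", "utr3"):
        m = silent_coding[int(rng.integers(len(silent_coding)))]
        exonic = m.exonic_length()
        utr5_len = (
            m.genomic_to_transcript(m.cds_start if m.strand == "+" else m.cds_end - 1)
        )
        cds_len = _cds_len(m)
        if category in ("cds_inframe", "cds_frameshift", "antisense"):
            if cds_len < wlen + 6:
                return None
            if category == "cds_inframe":
                phase = 0
            elif category == "cds_frameshift":
                phase = int(rng.integers(1, 3))
            else:
                phase = int(rng.integers(0, 3))
            lo = phase
            hi = cds_len - wlen
            if hi < lo:
                return None
            t = int(rng.integers(lo, hi + 1))
            t -= (t - phase) % 3
            t_start = utr5_len + t
        elif category == "utr5":
            if utr5_len < wlen + 2:
                return None
            t_start = int(rng.integers(0, utr5_len - wlen))
        else:  # utr3
            utr3_len = exonic - utr5_len - _cds_len(m)
            if utr3_len < wlen + 2:
                return None
            t_start = exonic - utr3_len + int(rng.integers(0, utr3_len - wlen))
        blocks = _tx_range_to_blocks(m, t_start, t_start + wlen)
        if len(blocks) != 1:  # keep planted windows exon-contiguous
            return None
        b = blocks[0]
        strand = m.strand
        if category == "antisense":
            strand = "-" if m.strand == "+" else "+"
        return b.chrom, b.start, b.end, strand, region, frame

    track = intron_track if category == "intron" else extr_track
    if track is None:
        return None
    ivs = [iv for iv in track.intervals if len(iv) >= wlen + 2 * fl]
    if not ivs:
        return None
    iv = ivs[int(rng.integers(len(ivs)))]
    gs = int(rng.integers(iv.start + fl, iv.end - fl - wlen + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return iv.chrom, gs, gs + wlen, strand, region, frame


def _cds_len(m: TranscriptModel) -> int:
    return sum(
        max(0, min(e, m.cds_end) - max(s, m.cds_start)) for s, e in m.exons
    )


def _mutate_window(
    genome: Mapping[str, str],
    chrom: str,
    gs: int,
    ge: int,
    strand: str,
    rng: np.random.Generator,
) -> tuple[Variant, str] | None:
    """Create an SNV inside the window; returns (variant, mutated forward
    window sequence) with a stop-free, amino-acid-changing result."""
    window = genome[chrom][gs:ge]
    order = rng.permutation(ge - gs)
    for off in order:
        ref = window[off]
        for alt in rng.permutation([b for b in "ACGT" if b != ref]):
            mutated = window[:off] + alt + window[off + 1 :]
            wseq = mutated if strand == "+" else revcomp(mutated)
            orig = window if strand == "+" else revcomp(window)
            pep = _translate_window(wseq)
            if pep is None or pep == _translate_window(orig):
                continue
            total = int(rng.integers(50, 120))
            alt_depth = int(rng.integers(9, max(10, total // 3)))
            return (
                Variant(chrom, gs + int(off), ref, str(alt), total, alt_depth),
                mutated,
            )
    return None


# ---------------------------------------------------------------------------
# reads and coverage
# ---------------------------------------------------------------------------

def simulate_reads(
    config: SimulationConfig,
    genome: Mapping[str, str],
    models: Sequence[TranscriptModel],
    expressed: set[str],
    windows: Sequence[PlantedWindow],
    rng: np.random.Generator,
    spike_variants: Mapping[str, SampleVariantSet] | None = None,
) -> tuple[dict[str, list[ReadRecord]], dict[str, CoverageProfile]]:
    """Per-sample reads (canonical background + planted aberrant units)
    plus genomic coverage profiles.

    Reads carrying edited peptides are excluded from the designated
    immunocompetent samples: a read is removed when its six-frame k-mer
    closure intersects the arm's edited-peptide set (with a fast substring
    prescreen against the planted window reads)."""
    roles = SampleRoles()
    samples = list(roles.all_samples)
    reads: dict[str, list[ReadRecord]] = {s: [] for s in samples}
    depth_arr = {
        s: {c: np.zeros(len(seq), dtype=np.int32) for c, seq in genome.items()}
        for s in samples
    }
    model_by_name = {m.name: m for m in models}
    spike = spike_variants or {}

    # canonical background transcription, shared by both genotype arms
    for sample in samples:
        snvs_by_chrom: dict[str, dict[int, str]] = {}
        if sample in spike and config.variant_spike_af > 0:
            for v in spike[sample].variants:
                if v.vclass == "SNV":
                    snvs_by_chrom.setdefault(v.chrom, {})[v.pos] = v.alt
        for name in sorted(expressed):
            m = model_by_name[name]
            mrna = m.spliced_sequence(genome)
            L = min(config.read_length, len(mrna))
            n_reads = max(1, int(round(config.background_depth * len(mrna) / L)))
            offsets = rng.integers(0, len(mrna) - L + 1, size=n_reads)
            for i, off in enumerate(offsets):
                if config.dropout > 0 and rng.random() < config.dropout:
                    continue
                # mrna is already in transcript space (5'->3'), so the
                # covered transcript range is [off, off+L) on both strands
                seq = mrna[off : off + L]
                blocks = _tx_range_to_blocks(m, off, off + L)
                if snvs_by_chrom:
                    seq = _apply_spikes(
                        seq, m, blocks, snvs_by_chrom, config.variant_spike_af, rng
                    )
                if config.error_rate > 0:
                    seq = _sequencing_errors(seq, config.error_rate, rng)
                rid = f"{sample}|bg|{name}|{i}"
                reads[sample].append(ReadRecord(rid, seq, sample))
                for b in blocks:
                    depth_arr[sample][b.chrom][b.start : b.end] += 1

    # planted aberrant transcription units
    for w_i, w in enumerate(windows):
        if w.arm == "MMRd":
            targets = [roles.mmrd_pre, roles.mmrd_nod, *roles.mmrd_balbc]
        else:
            targets = [roles.mmrp_pre, roles.mmrp_nod, *roles.mmrp_balbc]
        rs = w.read_start
        re_ = rs + len(w.read_seq)
        for sample in targets:
            for j in range(config.n_support):
                seq = w.read_seq
                if config.error_rate > 0:
                    seq = _sequencing_errors(seq, config.error_rate, rng)
                rid = f"{sample}|pw|{w_i}|{j}"
                reads[sample].append(ReadRecord(rid, seq, sample))
                depth_arr[sample][w.chrom][rs:re_] += 1

    # immune editing: remove reads carrying edited peptides from the
    # immunocompetent samples of each arm
    edited_mmrd = {p for w in windows if w.arm == "MMRd" and w.edited for p in w.closure}
    edited_mmrp = {p for w in windows if w.arm == "MMRp" and w.edited for p in w.closure}
    screen_mmrd = [w.read_seq for w in windows if w.arm == "MMRd" and w.edited]
    screen_mmrp = [w.read_seq for w in windows if w.arm == "MMRp" and w.edited]
    for sample in roles.mmrd_balbc:
        reads[sample] = _apply_editing(
            reads[sample], edited_mmrd, screen_mmrd, config, depth_arr[sample], windows
        )
    for sample in roles.mmrp_balbc:
        reads[sample] = _apply_editing(
            reads[sample], edited_mmrp, screen_mmrp, config, depth_arr[sample], windows
        )

    coverage = {
        s: CoverageProfile(_runs_from_depth(depth_arr[s])) for s in samples
    }
    return reads, coverage


def _apply_editing(
    sample_reads: list[ReadRecord],
    edited_peptides: set[str],
    screen_seqs: list[str],
    config: SimulationConfig,
    depths: dict[str, np.ndarray],
    windows: Sequence[PlantedWindow],
) -> list[ReadRecord]:
    if not edited_peptides:
        return sample_reads
    win_by_idx = {i: w for i, w in enumerate(windows)}
    kept = []
    for r in sample_reads:
        suspicious = any(
            s in r.sequence or revcomp(s) in r.sequence for s in screen_seqs
        )
        if suspicious and (
            set(read_kmers(r.sequence, config.k_min, config.k_max)) & edited_peptides
        ):
            parts = r.read_id.split("|")
            if len(parts) >= 3 and parts[1] == "pw":
                w = win_by_idx[int(parts[2])]
                depths[w.chrom][w.read_start : w.read_start + len(w.read_seq)] -= 1
            continue
        kept.append(r)
    return kept


def _apply_spikes(
    seq: str,
    m: TranscriptModel,
    blocks: Sequence[GenomicInterval],
    snvs_by_chrom: Mapping[str, Mapping[int, str]],
    af: float,
    rng: np.random.Generator,
) -> str:
    snvs = snvs_by_chrom.get(m.chrom)
    if not snvs:
        return seq
    chars = list(seq)
    # transcript-space index of each genomic base in the read
    read_positions: list[int] = []
    for b in blocks:
        read_positions.extend(range(b.start, b.end))
    if m.strand == "-":
        read_positions = read_positions[::-1]
    for i, gpos in enumerate(read_positions):
        alt = snvs.get(gpos)
        if alt is not None and rng.random() < af:
            chars[i] = alt if m.strand == "+" else revcomp(alt)
    return "".join(chars)


def _sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def _runs_from_depth(depths: Mapping[str, np.ndarray]) -> list[tuple[str, int, int, int]]:
    runs = []
    for chrom in sorted(depths):
        arr = depths[chrom]
        if len(arr) == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate(([0], change, [len(arr)]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            runs.append((chrom, int(s), int(e), int(arr[s])))
    return runs


# ---------------------------------------------------------------------------
# observed peptides and orchestration
# ---------------------------------------------------------------------------

def simulate_observed_peptides(
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Observed-peptide list: the planted deficient-arm targets plus decoys
    from the proficient arm and random sequences, with intensities."""
    rows = []
    targets = [w for w in truth.windows if w.arm == "MMRd" and w.edited]
    for w in targets:
        intensity = float(np.round(rng.lognormal(16, 1.5))) if rng.random() < 0.3 else np.nan
        rows.append({"peptide": w.peptide, "ms_intensity": intensity, "source": "target"})
    decoys = [w.peptide for w in truth.windows if w.arm == "MMRp" and w.edited]
    for pep in decoys[: config.observed_decoy_other]:
        rows.append({"peptide": pep, "ms_intensity": np.nan, "source": "decoy_other"})
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(config.observed_decoy_random):
        k = int(rng.integers(config.k_min, config.k_max + 1))
        rows.append(
            {
                "peptide": "".join(rng.choice(aa, size=k)),
                "ms_intensity": np.nan,
                "source": "decoy_random",
            }
        )
    return pd.DataFrame(rows)


def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Run every generator stage under one seed."""
    rng = np.random.default_rng(config.seed)
    genome, models, expressed = simulate_genome(config, rng)
    genome_sizes = {c: len(s) for c, s in genome.items()}
    tracks = tracks_from_transcripts(models, genome_sizes)
    germline, raw, filtered, edited_keys = simulate_variants(
        config, genome, tracks, rng
    )
    windows, extra_snvs = _plan_windows(config, genome, models, expressed, tracks, rng)

    # mutated-window SNVs exist in every MMRd sample (expressed mutations)
    for v in extra_snvs:
        for sample in WGS_SAMPLES["MMRd"]:
            if v.key not in raw[sample].keyset:
                raw[sample].variants.append(v)
            if v.key not in filtered[sample].keyset:
                filtered[sample].variants.append(v)

    reads, coverage = simulate_reads(
        config, genome, models, expressed, windows, rng, spike_variants=filtered
    )

    roles = SampleRoles()
    expr_rows = {}
    for w in windows:
        counts = {}
        for s in roles.all_samples:
            in_arm = s.startswith(w.arm)
            balbc = s in (roles.mmrd_balbc if w.arm == "MMRd" else roles.mmrp_balbc)
            counts[s] = 0 if (not in_arm or (balbc and w.edited)) else config.n_support
        expr_rows[w.peptide] = counts
    expression = pd.DataFrame(expr_rows).T
    expression.index.name = "peptide"

    truth = PlantedTruth(
        windows=windows,
        edited_peptides={
            p for w in windows if w.arm == "MMRd" and w.edited for p in w.closure
        },
        mmrp_edited_peptides={
            p for w in windows if w.arm == "MMRp" and w.edited for p in w.closure
        },
        edited_variant_keys=edited_keys,
        expression=expression,
    )
    observed = simulate_observed_peptides(truth, config, rng)
    return SimulationResult(
        config=config, genome=genome, genome_sizes=genome_sizes,
        models=models, expressed=expressed, tracks=tracks,
        germline=germline, raw_calls=raw, filtered=filtered,
        reads=reads, coverage=coverage, truth=truth, observed=observed,
    )


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Serialize every artifact as plain text (FASTA/refFlat/BED/VCF/FASTQ/
    bedgraph/TSV/JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for chrom in sorted(result.genome):
            fh.write(f">{chrom}\n")
            seq = result.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_genome_sizes(result.genome_sizes, out / "genome.sizes")
    write_refflat(result.models, out / "transcripts.refflat")
    (out / "regions").mkdir(exist_ok=True)
    for t in result.tracks:
        write_bed(t.intervals, out / "regions" / f"{t.label}.bed")
    (out / "vcf").mkdir(exist_ok=True)
    write_vcf(result.germline, out / "vcf" / "germline.vcf", result.genome_sizes)
    for name, vset in result.raw_calls.items():
        write_vcf(vset, out / "vcf" / f"{name}.vcf", result.genome_sizes)
    (out / "reads").mkdir(exist_ok=True)
    for name, rr in result.reads.items():
        write_fastq(rr, out / "reads" / f"{name}.fastq")
    (out / "coverage").mkdir(exist_ok=True)
    for name, prof in result.coverage.items():
        write_bedgraph(prof, out / "coverage" / f"{name}.bedgraph")
    result.observed.to_csv(out / "observed_peptides.tsv", sep="\t", index=False)
    truth = result.truth
    payload = {
        "expressed_transcripts": sorted(result.expressed),
        "edited_variant_keys": sorted(map(list, truth.edited_variant_keys)),
        "edited_peptides": sorted(truth.edited_peptides),
        "mmrp_edited_peptides": sorted(truth.mmrp_edited_peptides),
        "windows": [
            {k: v for k, v in asdict(w).items() if k != "closure"}
            for w in truth.windows
        ],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=list)
    truth.expression.to_csv(out / "planted_expression.tsv", sep="\t")
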