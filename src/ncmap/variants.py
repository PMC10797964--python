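"""Somatic variant filtering, per-region mutational burden, immune-editing
log-ratios, silent/non-silent classification, and microsatellite indels.

Somatic calls are obtained by subtracting germline variants and keeping
positions with total depth >= 10 supported by >= 9 mutated reads (both
thresholds configurable).  Tumor mutational burden (TMB) is variants per
megabase of each labeled region, and immune editing per region is the
natural logarithm of the post/pre TMB ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .intervals import (
    GenomicInterval,
    RegionTrack,
    TranscriptModel,
    assign_region,
    region_sizes,
)

__all__ = [
    "Variant",
    "SampleVariantSet",
    "RegionMutationSummary",
    "MicrosatelliteLocus",
    "filter_somatic",
    "tmb_by_region",
    "editing_logratio",
    "gained_lost",
    "host_delta",
    "coding_effect",
    "scan_microsatellites",
    "flag_ms_indels",
    "read_vcf",
    "write_vcf",
]


@dataclass(frozen=True)
class Variant:
    """A called variant with read support (pos is 0-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int = 0
    alt_depth: int = 0
    microsatellite: bool = False

    def __post_init__(self) -> None:
        if self.alt_depth > self.total_depth:
            raise ValueError("alt_depth exceeds total_depth")
        if not self.ref or not self.alt:
            raise ValueError("empty allele")

    @property
    def vclass(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "INS"
        if len(self.ref) > len(self.alt):
            return "DEL"
        return "MNV"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def footprint(self) -> GenomicInterval:
        """Reference footprint [pos, pos + len(ref))."""
        return GenomicInterval(self.chrom, self.pos, self.pos + len(self.ref))


@dataclass
class SampleVariantSet:
    """Variants of one sample; unique by (chrom, pos, ref, alt)."""

    sample_id: str
    genotype: str = "MMRd"  # {MMRp, MMRd}
    host: str = "pre"  # {pre, NOD-SCID, BALB/c}
    replicate: int = 0
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.sample_id}: duplicate variants")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def keyset(self) -> set[tuple]:
        return {v.key for v in self.variants}


@dataclass
class RegionMutationSummary:
    label: str
    region_bp: int
    n_snv: int = 0
    n_indel: int = 0
    n_silent: int = 0
    n_nonsilent: int = 0
    n_ms_indel: int = 0

    @property
    def n_variants(self) -> int:
        return self.n_snv + self.n_indel

    @property
    def tmb(self) -> float:
        """Variants per megabase of the region."""
        if self.region_bp == 0:
            return float("nan")
        return self.n_variants / (self.region_bp / 1e6)


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A maximal perfect tandem repeat with unit length 1-5 bp."""

    interval: GenomicInterval
    unit: str
    repeat_count: int

    def __post_init__(self) -> None:
        if self.repeat_count * len(self.unit) != len(self.interval):
            raise ValueError("repeat_count * unit length != interval length")


def filter_somatic(
    calls: SampleVariantSet,
    germline: SampleVariantSet,
    min_depth: int = 10,
    min_alt: int = 9,
) -> SampleVariantSet:
    """Subtract germline variants and apply depth/support thresholds."""
    germ = germline.keyset
    kept = [
        v
        for v in calls.variants
        if v.key not in germ and v.total_depth >= min_depth and v.alt_depth >= min_alt
    ]
    return replace(calls, variants=kept)


def tmb_by_region(
    vset: SampleVariantSet,
    tracks: Sequence[RegionTrack],
    models: Sequence[TranscriptModel] | None = None,
    genome: Mapping[str, str] | None = None,
) -> dict[str, RegionMutationSummary]:
    """Per-region mutation summaries with TMB per Mb.

    Each variant is assigned exactly one label via the priority rule applied
    to its reference footprint.  Silent/non-silent classification is filled
    in when transcript models and the genome sequence are supplied.
    """
    sizes = region_sizes(tracks)
    out = {lab: RegionMutationSummary(lab, bp) for lab, bp in sizes.items()}
    for v in vset.variants:
        label = assign_region(v.footprint, tracks)
        summ = out.setdefault(label, RegionMutationSummary(label, 0))
        if v.vclass == "SNV":
            summ.n_snv += 1
        else:
            summ.n_indel += 1
            if v.microsatellite:
                summ.n_ms_indel += 1
        if models is not None and genome is not None:
            effect = coding_effect(v, models, genome)
            if effect == "silent":
                summ.n_silent += 1
            elif effect == "nonsilent":
                summ.n_nonsilent += 1
    return out


def editing_logratio(
    pre: RegionMutationSummary, post: RegionMutationSummary
) -> float:
    """ln(TMB_post / TMB_pre) for one region.

    pre TMB of 0 is undefined (NaN); post TMB of 0 yields -inf, a flagged
    sentinel that callers should render as censored.
    """
    if pre.label != post.label:
        raise ValueError("summaries are for different labels")
    if pre.tmb == 0 or math.isnan(pre.tmb):
        return float("nan")
    if post.tmb == 0:
        return float("-inf")
    return math.log(post.tmb / pre.tmb)


def gained_lost(
    pre_set: SampleVariantSet,
    post_set: SampleVariantSet,
    tracks: Sequence[RegionTrack],
) -> dict[str, dict[str, float]]:
    """Per-label gained/lost alteration rates (per Mb of region size).

    gained = post \\ pre, lost = pre \\ post, each assigned one label by the
    priority rule and normalized by the label's region size.
    """
    sizes = region_sizes(tracks)
    pre_keys = pre_set.keyset
    post_keys = post_set.keyset
    counts = {lab: {"gained": 0, "lost": 0} for lab in sizes}
    for v in post_set.variants:
        if v.key not in pre_keys:
            counts[assign_region(v.footprint, tracks)]["gained"] += 1
    for v in pre_set.variants:
        if v.key not in post_keys:
            counts[assign_region(v.footprint, tracks)]["lost"] += 1
    out = {}
    for lab, c in counts.items():
        mb = sizes.get(lab, 0) / 1e6
        out[lab] = {
            "gained_per_mb": c["gained"] / mb if mb else float("nan"),
            "lost_per_mb": c["lost"] / mb if mb else float("nan"),
        }
    return out


def host_delta(
    per_label_nod: Mapping[str, float], per_label_balbc: Mapping[str, float]
) -> dict[str, float]:
    """Per-label difference immunocompromised minus immunocompetent."""
    return {
        lab: per_label_nod[lab] - per_label_balbc[lab]
        for lab in per_label_nod
        if lab in per_label_balbc
    }


def coding_effect(
    v: Variant,
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> str:
    """Classify a variant as silent, nonsilent, or noncoding.

    An SNV inside an exonic CDS is silent iff the altered codon encodes the
    same amino acid on the transcript strand; CDS indels are nonsilent by
    frameshift/in-frame disruption; everything outside a CDS is noncoding.
    """
    if genome[v.chrom][v.pos : v.pos + len(v.ref)].upper() != v.ref.upper():
        raise ValueError(
            f"ref allele mismatch at {v.chrom}:{v.pos}: "
            f"{genome[v.chrom][v.pos:v.pos + len(v.ref)]!r} != {v.ref!r}"
        )
    for m in models:
        if m.chrom != v.chrom or m.is_ncrna:
            continue
        off = m.cds_offset(v.pos)
        if off is None or off < 0:
            continue
        if v.vclass != "SNV":
            return "nonsilent"
        codon_idx, phase = divmod(off, 3)
        # rebuild the codon from the spliced CDS sequence
        cds = _spliced_cds(m, genome)
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        if len(codon) < 3:
            return "nonsilent"  # truncated terminal codon: treat as altering
        base = v.alt.upper() if m.strand == "+" else str(Seq(v.alt).reverse_complement())
        mutated = codon[:phase] + base + codon[phase + 1 :]
        if str(Seq(codon).translate()) == str(Seq(mutated).translate()):
            return "silent"
        return "nonsilent"
    return "noncoding"


def _spliced_cds(m: TranscriptModel, genome: Mapping[str, str]) -> str:
    parts = []
    for s, e in m.exons:
        cs, ce = max(s, m.cds_start), min(e, m.cds_end)
        if cs < ce:
            parts.append(genome[m.chrom][cs:ce].upper())
    seq = "".join(parts)
    if m.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def scan_microsatellites(
    genome: Mapping[str, str],
    unit_max: int = 5,
    min_repeats: int = 5,
) -> list[MicrosatelliteLocus]:
    """Find maximal perfect tandem repeats with primitive units of 1-5 bp.

    Simplified stand-in for a full microsatellite-instability caller: loci
    are reported per unit length by a greedy left-to-right scan; overlapping
    loci with different unit lengths may both be reported.
    """
    loci: list[MicrosatelliteLocus] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        n = len(seq)
        for u in range(1, unit_max + 1):
            i = 0
            while i + u * min_repeats <= n:
                unit = seq[i : i + u]
                if "N" in unit or _is_periodic(unit):
                    i += 1
                    continue
                j = i + u
                while j + u <= n and seq[j : j + u] == unit:
                    j += u
                count = (j - i) // u
                if count >= min_repeats:
                    loci.append(
                        MicrosatelliteLocus(
                            GenomicInterval(chrom, i, i + count * u), unit, count
                        )
                    )
                    i = i + count * u
                else:
                    i += 1
    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start))
    return loci


def _is_periodic(unit: str) -> bool:
    """True when the unit is itself a repeat of a shorter unit."""
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return True
    return False


def flag_ms_indels(
    vset: SampleVariantSet, loci: Sequence[MicrosatelliteLocus]
) -> SampleVariantSet:
    """Flag indels whose reference footprint overlaps a microsatellite."""
    track = RegionTrack("ms", [l.interval for l in loci])
    flagged = []
    for v in vset.variants:
        hit = (
            v.vclass in ("INS", "DEL")
            and track.overlaps(v.chrom, v.pos, v.pos + len(v.ref))
        )
        flagged.append(replace(v, microsatellite=hit) if hit != v.microsatellite else v)
    return replace(vset, variants=flagged)


# ---------------------------------------------------------------------------
# VCF IO (minimal: CHROM POS REF ALT + DP/AD depths in INFO)
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_id: str | None = None, **meta) -> SampleVariantSet:
    """Read an uncompressed VCF with DP and AD INFO fields."""
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            dp = int(rec.info.get("DP", 0))
            ad = rec.info.get("AD", 0)
            if isinstance(ad, tuple):
                ad = ad[-1]
            for alt in rec.alts or ():
                variants.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,  # VCF is 1-based
                        ref=rec.ref,
                        alt=str(alt),
                        total_depth=dp,
                        alt_depth=int(ad),
                        microsatellite="MS" in rec.info,
                    )
                )
    sid = sample_id or Path(path).stem
    return SampleVariantSet(sample_id=sid, variants=variants, **meta)


def write_vcf(
    vset: SampleVariantSet,
    path: str | Path,
    genome_sizes: Mapping[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ncmap sample={vset.sample_id}\n")
        if genome_sizes:
            for chrom, size in genome_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt depth">\n')
        fh.write('##INFO=<ID=MS,Number=0,Type=Flag,Description="Microsatellite indel">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(vset.variants, key=lambda v: (v.chrom, v.pos)):
            info = f"DP={v.total_depth};AD={v.alt_depth}"
            if v.microsatellite:
                info += ";MS"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )
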