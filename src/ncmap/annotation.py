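"""Back-annotation of matched peptides to genomic loci.

Each matched peptide is traced to its source reads, the encoding nucleotide
segment is located inside each read, and the segment is placed on the
genome with a seed-and-extend matcher scored as
``match + rep_match - mismatch - q_gap_count - t_gap_count`` (rep_match is
always 0 here: no repeat masking).  Per read only the best-scoring
placement(s) are kept; placements within 5 bp are merged into loci carrying
the distinct supporting read ids; peptides mapping to more than one merged
locus are discarded.  Surviving loci get a region label by priority, a
mutation status from the filtered somatic variants, and an in-frame /
out-of-frame call against the canonical transcript models (phase computed
in transcript coordinates).  A peptide is canonical iff it is coding and
in-frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import (
    GenomicInterval,
    RegionTrack,
    TranscriptModel,
    assign_region,
    revcomp,
)
from .peptides import FRAMES, frame_translation
from .variants import SampleVariantSet, Variant

__all__ = [
    "PeptideAlignment",
    "Locus",
    "MapRecord",
    "GenomeIndex",
    "locate_peptide_in_read",
    "align_and_select",
    "merge_loci",
    "uniqueness_filter",
    "annotate_mutation",
    "frame_status",
    "annotate_peptides",
]


class ProvenanceError(ValueError):
    """The peptide cannot be located in the stated read/frame."""


def locate_peptide_in_read(
    peptide: str, read_seq: str, frame: int
) -> tuple[int, int]:
    """Half-open nucleotide range of the peptide on the read's forward
    coordinates.

    For negative frames the peptide is encoded on the reverse complement;
    the returned range is still expressed on the forward strand.
    """
    trans = frame_translation(read_seq, frame)
    aa = trans.find(peptide)
    if aa < 0:
        raise ProvenanceError(
            f"peptide {peptide!r} not found in frame {frame} of read"
        )
    offset = abs(frame) - 1
    s = offset + 3 * aa
    e = s + 3 * len(peptide)
    if frame > 0:
        return s, e
    n = len(read_seq)
    return n - e, n - s


@dataclass
class PeptideAlignment:
    """One placement of a peptide-encoding segment on the genome."""

    peptide: str
    read_id: str
    blocks: list[GenomicInterval]  # 1 block, or 2 for a spliced placement
    strand: str
    match: int
    rep_match: int = 0
    mismatch: int = 0
    q_gap_count: int = 0
    t_gap_count: int = 0

    @property
    def score(self) -> int:
        return (
            self.match + self.rep_match - self.mismatch
            - self.q_gap_count - self.t_gap_count
        )

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0].start, self.blocks[-1].end


class GenomeIndex:
    """Exact k-mer index over the forward strand of a genome."""

    def __init__(self, genome: Mapping[str, str], k: int = 12):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(self.genome):
            seq = self.genome[chrom]
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def align_and_select(
    segment: str,
    index: GenomeIndex,
    peptide: str = "",
    read_id: str = "",
    max_mismatches: int = 2,
    min_score_frac: float = 0.9,
    allow_split: bool = True,
    max_intron: int = 20000,
) -> list[PeptideAlignment]:
    """Best-scoring genomic placements of a nucleotide segment.

    Candidate placements come from exact seed k-mers at both segment ends,
    extended ungapped with up to ``max_mismatches``; when no perfect
    contiguous placement exists and ``allow_split`` is set, a single split
    into two exact blocks (spliced placement, not penalized as a gap) is
    attempted.  Placements scoring below ``min_score_frac * len(segment)``
    land in the unaligned bucket (empty return).  Ties are returned in
    deterministic (chrom, start) order, best first.
    """
    segment = segment.upper()
    n = len(segment)
    k = min(index.k, n)
    candidates: list[PeptideAlignment] = []
    seen: set[tuple] = set()
    for strand, query in (("+", segment), ("-", revcomp(segment))):
        starts: set[tuple[str, int]] = set()
        for seed_off in (0, n - k):
            for chrom, hit in index.seed_hits(query[seed_off : seed_off + k]):
                start = hit - seed_off
                if start >= 0:
                    starts.add((chrom, start))
        for chrom, start in starts:
            ref = index.genome[chrom][start : start + n]
            if len(ref) < n:
                continue
            mm = sum(a != b for a, b in zip(query, ref))
            key = (chrom, start, start + n, strand)
            if mm <= max_mismatches and key not in seen:
                seen.add(key)
                candidates.append(
                    PeptideAlignment(
                        peptide, read_id,
                        [GenomicInterval(chrom, start, start + n, strand)],
                        strand, match=n - mm, mismatch=mm,
                    )
                )
        if allow_split and not any(
            c.strand == strand and c.score == n for c in candidates
        ):
            candidates.extend(
                _split_placements(query, index, strand, peptide, read_id, k, max_intron)
            )
    min_score = min_score_frac * n
    candidates = [c for c in candidates if c.score >= min_score]
    if not candidates:
        return []
    best = max(c.score for c in candidates)
    top = [c for c in candidates if c.score == best]
    top.sort(key=lambda c: (c.chrom, c.span[0], c.strand))
    return top


def _split_placements(
    query: str,
    index: GenomeIndex,
    strand: str,
    peptide: str,
    read_id: str,
    k: int,
    max_intron: int,
) -> list[PeptideAlignment]:
    """Two exact blocks separated by <= max_intron; both blocks must match
    exactly, and the split is not scored as a gap."""
    n = len(query)
    out = []
    for chrom, hit in index.seed_hits(query[:k]):
        seq = index.genome[chrom]
        # maximal exact prefix extension
        m = 0
        while m < n and hit + m < len(seq) and seq[hit + m] == query[m]:
            m += 1
        if m == 0 or m >= n:
            continue
        window = seq[hit + m : hit + m + max_intron + (n - m)]
        gap = window.find(query[m:])
        if gap > 0:
            q2 = hit + m + gap
            out.append(
                PeptideAlignment(
                    peptide, read_id,
                    [
                        GenomicInterval(chrom, hit, hit + m, strand),
                        GenomicInterval(chrom, q2, q2 + (n - m), strand),
                    ],
                    strand, match=n,
                )
            )
    return out


@dataclass
class Locus:
    """A merged genomic locus supported by one or more read placements."""

    chrom: str
    start: int
    end: int
    strand: str
    read_ids: set[str] = field(default_factory=set)
    blocks: list[GenomicInterval] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def merge_loci(
    alignments: Sequence[PeptideAlignment], distance: int = 5
) -> list[Locus]:
    """Merge read placements within ``distance`` bp into loci.

    A spliced placement's two blocks belong to a single locus spanning the
    split.  Carries the distinct read ids per merged locus.
    """
    spans = sorted(
        alignments, key=lambda a: (a.chrom, a.span[0], a.span[1])
    )
    loci: list[Locus] = []
    for a in spans:
        s, e = a.span
        if loci and loci[-1].chrom == a.chrom and s - loci[-1].end <= distance:
            cur = loci[-1]
            cur.end = max(cur.end, e)
            cur.read_ids.add(a.read_id)
            cur.blocks.extend(a.blocks)
        else:
            loci.append(Locus(a.chrom, s, e, a.strand, {a.read_id}, list(a.blocks)))
    return loci


@dataclass
class MapRecord:
    """An annotated MHC-associated peptide."""

    peptide: str
    loci: list[Locus]
    region: str = ""
    frame: str = ""  # {in-frame, out-of-frame}
    mutation: str = "WT"  # {WT, SNV, indel}
    microsatellite: bool = False
    n_reads: int = 0
    rna_counts: dict[str, int] = field(default_factory=dict)
    ms_intensity: float | None = None
    allele_frequency: float | None = None
    unaligned: bool = False

    @property
    def canonical(self) -> str:
        if self.region == "coding" and self.frame == "in-frame":
            return "Canonical"
        return "Non-canonical"


def uniqueness_filter(records: Iterable[MapRecord]) -> list[MapRecord]:
    """Keep only peptides whose best placements merged into a single locus."""
    return [r for r in records if len(r.loci) == 1]


def annotate_mutation(
    record: MapRecord, vset: SampleVariantSet
) -> MapRecord:
    """Set SNV/indel status from filtered somatic variants overlapping the
    peptide loci; indel takes precedence; microsatellite flag propagates."""
    status = "WT"
    ms = False
    af = None
    for locus in record.loci:
        for v in vset.variants:
            if v.chrom != locus.chrom:
                continue
            fp = v.footprint
            if fp.start < locus.end and locus.start < fp.end:
                if v.vclass in ("INS", "DEL"):
                    status = "indel"
                    ms = ms or v.microsatellite
                    af = _variant_af(v)
                elif status != "indel":
                    status = "SNV"
                    af = _variant_af(v)
    record.mutation = status
    record.microsatellite = ms
    record.allele_frequency = af
    return record


def _variant_af(v: Variant) -> float | None:
    if v.total_depth > 0:
        return 100.0 * v.alt_depth / v.total_depth
    return None


def frame_status(
    record_or_locus: MapRecord | Locus,
    models: Sequence[TranscriptModel],
) -> str:
    """in-frame iff the locus lies inside the CDS of a same-strand coding
    transcript with the peptide start at codon phase 0 (phase computed in
    transcript coordinates); everything else is out-of-frame."""
    loci = (
        record_or_locus.loci
        if isinstance(record_or_locus, MapRecord)
        else [record_or_locus]
    )
    for locus in loci:
        for m in models:
            if m.chrom != locus.chrom or m.is_ncrna or m.strand != locus.strand:
                continue
            if not _blocks_in_cds(locus, m):
                continue
            gpos = locus.start if m.strand == "+" else locus.end - 1
            off = m.cds_offset(gpos)
            if off is not None and off >= 0 and off % 3 == 0:
                return "in-frame"
    return "out-of-frame"


def _blocks_in_cds(locus: Locus, m: TranscriptModel) -> bool:
    blocks = locus.blocks or [locus.interval]
    for b in blocks:
        ok = any(
            max(s, m.cds_start) <= b.start and b.end <= min(e, m.cds_end)
            for s, e in m.exons
        )
        if not ok:
            return False
    return True


def annotate_peptides(
    matched: Sequence[str],
    provenance: Mapping[str, set],
    reads_by_id: Mapping[str, str],
    index: GenomeIndex,
    tracks: Sequence[RegionTrack],
    models: Sequence[TranscriptModel],
    vset: SampleVariantSet | None = None,
    merge_distance: int = 5,
    max_reads_per_peptide: int = 50,
    **align_kwargs,
) -> list[MapRecord]:
    """Full annotation path: locate each peptide in its source reads, align
    the encoding segments, merge loci, enforce uniqueness, then assign
    region, frame, and mutation status."""
    out: list[MapRecord] = []
    for pep in matched:
        alignments: list[PeptideAlignment] = []
        entries = sorted(provenance.get(pep, ()))[:max_reads_per_peptide]
        for read_id, frame, _ in entries:
            seq = reads_by_id.get(read_id)
            if seq is None:
                continue
            try:
                s, e = locate_peptide_in_read(pep, seq, frame)
            except ProvenanceError:
                continue
            segment = seq[s:e]
            if frame < 0:
                segment = revcomp(segment)  # encode 5'->3' on the coding strand
            alignments.extend(
                align_and_select(segment, index, pep, read_id, **align_kwargs)
            )
        if not alignments:
            out.append(MapRecord(pep, [], unaligned=True))
            continue
        loci = merge_loci(alignments, merge_distance)
        rec = MapRecord(pep, loci)
        if len(loci) == 1:
            locus = loci[0]
            rec.region = assign_region(locus.interval, tracks)
            rec.frame = frame_status(rec, models)
            rec.n_reads = locus.n_reads
            if vset is not None:
                annotate_mutation(rec, vset)
        out.append(rec)
    return out
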