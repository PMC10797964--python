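"""Interval algebra and construction of the labeled genomic region partition.

All coordinates are 0-based half-open (BED convention). refFlat input is
already 0-based half-open; VCF positions are converted on read.

The genome is partitioned into labeled region tracks (``coding``, ``utr5``,
``utr3``, ``ncRNA``, ``intron``, ``extragenic``) derived from refFlat-style
transcript models.  When a query overlaps several labels, the most specific
one wins, in the priority order ``coding > utr5 > utr3 > ncRNA > intron >
extragenic``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "RegionTrack",
    "TranscriptModel",
    "REGION_PRIORITY",
    "merge_intervals",
    "complement",
    "region_sizes",
    "tracks_from_transcripts",
    "assign_region",
    "read_bed",
    "write_bed",
    "read_refflat",
    "write_refflat",
    "read_genome_sizes",
    "write_genome_sizes",
]

#: Region labels from most to least specific; used for overlap resolution.
#: ncRNA is placed between utr3 and intron (exonic ncRNA is more specific
#: than intron; the source priority list is silent on ncRNA).
REGION_PRIORITY = ("coding", "utr5", "utr3", "ncRNA", "intron", "extragenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class RegionTrack:
    """A labeled set of merged (sorted, non-overlapping) intervals."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    _index: dict | None = field(default=None, repr=False, compare=False)

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def _build_index(self) -> dict:
        # per-chromosome sorted start/end arrays for bisect lookups
        idx: dict[str, tuple[list[int], list[int]]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            idx[chrom] = ([iv.start for iv in ivs], [iv.end for iv in ivs])
        return idx

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) on chrom intersects any interval."""
        if self._index is None:
            self._index = self._build_index()
        entry = self._index.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_right(starts, start)
        # candidate ending after `start` is at i-1 (covers start) or i (next)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the track."""
        if self._index is None:
            self._index = self._build_index()
        entry = self._index.get(chrom)
        if entry is None:
            return 0
        starts, ends = entry
        i = max(bisect.bisect_right(starts, start) - 1, 0)
        bp = 0
        while i < len(starts) and starts[i] < end:
            bp += max(0, min(ends[i], end) - max(starts[i], start))
            i += 1
        return bp


@dataclass
class TranscriptModel:
    """refFlat-style gene model (0-based half-open coordinates)."""

    gene: str
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: list[int]
    exon_ends: list[int]

    def __post_init__(self) -> None:
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(
                f"{self.name}: CDS [{self.cds_start},{self.cds_end}) outside "
                f"transcript span [{self.tx_start},{self.tx_end})"
            )
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.name}: exon start/end lists differ in length")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.name}: exon [{s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.name}: exons unsorted or overlapping")
            prev_end = e

    @property
    def is_ncrna(self) -> bool:
        """A model is non-coding iff cdsEnd - cdsStart = 0."""
        return self.cds_end - self.cds_start == 0

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic base to its strand-aware transcript offset.

        Returns None when ``gpos`` is intronic or outside the span.
        Offset 0 is the 5' end of the mature (spliced) transcript.
        """
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                plus_off = off + (gpos - s)
                if self.strand == "+":
                    return plus_off
                return self.exonic_length() - 1 - plus_off
            off += e - s
        return None

    def cds_offset(self, gpos: int) -> int | None:
        """Strand-aware offset of ``gpos`` from the CDS start, or None.

        Offset 0 is the first base of the start codon; valid only when the
        base lies inside an exonic CDS segment.
        """
        if self.is_ncrna:
            return None
        in_cds = any(
            max(s, self.cds_start) <= gpos < min(e, self.cds_end)
            for s, e in self.exons
        )
        if not in_cds:
            return None
        tpos = self.genomic_to_transcript(gpos)
        anchor = self.cds_start if self.strand == "+" else self.cds_end - 1
        tanchor = self.genomic_to_transcript(anchor)
        if tpos is None or tanchor is None:
            return None
        return tpos - tanchor

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Mature transcript sequence (5'->3' on the transcript strand)."""
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Iterable[GenomicInterval],
    distance: int = 0,
    with_counts: bool = False,
):
    """Merge same-chromosome intervals whose gap is <= ``distance``.

    Mirrors ``bedtools merge -d``: the gap between consecutive sorted
    intervals is ``next.start - prev.end``; bookended intervals (gap 0)
    merge at distance 0.  Output is sorted.  With ``with_counts`` the
    return value is a list of ``(interval, n_merged)`` pairs.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[tuple[GenomicInterval, int]] = []
    for iv in ivs:
        if merged:
            prev, n = merged[-1]
            if prev.chrom == iv.chrom and iv.start - prev.end <= distance:
                if iv.end > prev.end:
                    prev = GenomicInterval(prev.chrom, prev.start, iv.end)
                merged[-1] = (prev, n + 1)
                continue
        merged.append((iv, 1))
    if with_counts:
        return merged
    return [iv for iv, _ in merged]


def complement(
    genome_sizes: Mapping[str, int],
    tracks: Sequence[RegionTrack],
    label: str = "extragenic",
) -> RegionTrack:
    """Genome complement of the union of all track intervals."""
    covered: dict[str, list[GenomicInterval]] = {c: [] for c in genome_sizes}
    for track in tracks:
        for iv in track.intervals:
            if iv.chrom not in genome_sizes:
                raise ValueError(f"chromosome {iv.chrom!r} not in genome sizes")
            if iv.end > genome_sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} beyond "
                    f"chromosome length {genome_sizes[iv.chrom]}"
                )
            covered[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(genome_sizes):
        size = genome_sizes[chrom]
        pos = 0
        for iv in merge_intervals(covered[chrom]):
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < size:
            out.append(GenomicInterval(chrom, pos, size))
    return RegionTrack(label, out)


def region_sizes(tracks: Sequence[RegionTrack]) -> dict[str, int]:
    """Total bp per track label (tracks assumed merged)."""
    return {t.label: t.total_bp() for t in tracks}


def tracks_from_transcripts(
    models: Sequence[TranscriptModel],
    genome_sizes: Mapping[str, int],
    include_ncrna_track: bool = True,
) -> list[RegionTrack]:
    """Derive the labeled region partition from transcript models.

    coding = exonic CDS of coding transcripts; utr5/utr3 = exonic parts
    up/downstream of the CDS respecting strand; intron = transcript span
    minus exons; ncRNA = exons of models with cdsEnd - cdsStart = 0;
    extragenic = complement of everything else.
    """
    raw: dict[str, list[GenomicInterval]] = {
        "coding": [], "utr5": [], "utr3": [], "ncRNA": [], "intron": []
    }
    for m in models:
        prev_end = None
        for s, e in m.exons:
            if prev_end is not None and s > prev_end:
                raw["intron"].append(GenomicInterval(m.chrom, prev_end, s))
            prev_end = e
            if m.is_ncrna:
                raw["ncRNA"].append(GenomicInterval(m.chrom, s, e))
                continue
            cs = max(s, m.cds_start)
            ce = min(e, m.cds_end)
            if cs < ce:
                raw["coding"].append(GenomicInterval(m.chrom, cs, ce))
            left = (s, min(e, m.cds_start))
            right = (max(s, m.cds_end), e)
            left_label = "utr5" if m.strand == "+" else "utr3"
            right_label = "utr3" if m.strand == "+" else "utr5"
            if left[0] < left[1]:
                raw[left_label].append(GenomicInterval(m.chrom, *left))
            if right[0] < right[1]:
                raw[right_label].append(GenomicInterval(m.chrom, *right))
    tracks = [
        RegionTrack(label, merge_intervals(ivs))
        for label, ivs in raw.items()
        if label != "ncRNA" or include_ncrna_track
    ]
    tracks.append(complement(genome_sizes, tracks))
    order = {lab: i for i, lab in enumerate(REGION_PRIORITY)}
    tracks.sort(key=lambda t: order.get(t.label, 99))
    return tracks


def assign_region(
    query: GenomicInterval,
    tracks: Sequence[RegionTrack],
    genome_sizes: Mapping[str, int] | None = None,
) -> str:
    """Label a query interval using the most specific overlapping track.

    Priority: coding > utr5 > utr3 > ncRNA > intron > extragenic.
    A query overlapping no annotated track is extragenic.
    """
    if genome_sizes is not None and query.chrom not in genome_sizes:
        raise ValueError(f"chromosome {query.chrom!r} not in genome")
    by_label = {t.label: t for t in tracks}
    for label in REGION_PRIORITY:
        track = by_label.get(label)
        if track is not None and track.overlaps(query.chrom, query.start, query.end):
            return label
    return "extragenic"


# ---------------------------------------------------------------------------
# IO: BED, refFlat, genome sizes
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    name: str | None = None,
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_refflat(path: str | Path) -> list[TranscriptModel]:
    """Read an 11-column refFlat TSV (comma-terminated exon lists)."""
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
            ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
            models.append(
                TranscriptModel(
                    gene=f[0], name=f[1], chrom=f[2], strand=f[3],
                    tx_start=int(f[4]), tx_end=int(f[5]),
                    cds_start=int(f[6]), cds_end=int(f[7]),
                    exon_starts=starts, exon_ends=ends,
                )
            )
    return models


def write_refflat(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.gene, m.name, m.chrom, m.strand,
                        str(m.tx_start), str(m.tx_end),
                        str(m.cds_start), str(m.cds_end),
                        str(len(m.exon_starts)),
                        ",".join(map(str, m.exon_starts)) + ",",
                        ",".join(map(str, m.exon_ends)) + ",",
                    ]
                )
                + "\n"
            )


def read_genome_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                f = line.split()
                sizes[f[0]] = int(f[1])
    return sizes


def write_genome_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
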