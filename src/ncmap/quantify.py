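"""Expression-level normalization of annotated peptides, the region-level
peptide TPM formula, RNA-level immune-editing fold changes, and the
candidate-selection filters with pooling.

Per region, ``P = (supporting reads * 1e3) / region length`` and
``TPM = P / sum(P) * 1e6``; MAP rates are normalized by the number of bases
covered at >= 10x depth.  RNA fold change is ``ln((post+1)/(pre+1))``.
Candidates must be expressed before injection, absent from the
immunocompetent-host tumors, and derive from atypical translational events;
survivors are ranked by a composite of expression, MS intensity, and allele
frequency and split into pools round-robin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import MapRecord
from .intervals import RegionTrack

__all__ = [
    "CoverageProfile",
    "CandidateMAP",
    "covered_bases",
    "maps_per_mb",
    "peptide_tpm",
    "map_rna_foldchange",
    "select_candidates",
    "read_bedgraph",
    "write_bedgraph",
    "CANDIDATE_COLUMNS",
    "read_candidate_table",
    "write_candidate_table",
]


@dataclass
class CoverageProfile:
    """Bedgraph-like per-base depth runs (sorted, non-overlapping)."""

    runs: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        for chrom, start, end, depth in self.runs:
            if depth < 0 or start >= end:
                raise ValueError(f"bad run {chrom}:{start}-{end} depth {depth}")
            if chrom in prev and start < prev[chrom]:
                raise ValueError("runs overlap or are unsorted")
            prev[chrom] = end


def covered_bases(
    profile: CoverageProfile,
    tracks: Sequence[RegionTrack],
    min_depth: int = 10,
) -> dict[str, int]:
    """Per-label number of bases covered at >= min_depth."""
    out = {t.label: 0 for t in tracks}
    for chrom, start, end, depth in profile.runs:
        if depth < min_depth:
            continue
        for t in tracks:
            out[t.label] += t.overlap_bp(chrom, start, end)
    return out


def maps_per_mb(
    map_counts: Mapping[str, int], covered_bp: Mapping[str, int]
) -> dict[str, float]:
    """MAPs per megabase of covered sequence; 0-covered labels with counts
    are flagged missing (NaN)."""
    out = {}
    for label, count in map_counts.items():
        bp = covered_bp.get(label, 0)
        if bp == 0:
            out[label] = 0.0 if count == 0 else float("nan")
        else:
            out[label] = count / (bp / 1e6)
    return out


def peptide_tpm(
    read_counts: Mapping[str, int], region_lengths: Mapping[str, int]
) -> dict[str, float]:
    """Region-level peptide TPM: P = reads * 1e3 / length; TPM = P/sum(P)*1e6."""
    p = {}
    for label, reads in read_counts.items():
        length = region_lengths.get(label, 0)
        if length <= 0:
            raise ValueError(f"region {label!r} has non-positive length")
        p[label] = reads * 1e3 / length
    total = sum(p.values())
    if total == 0:
        return {label: float("nan") for label in p}
    return {label: v / total * 1e6 for label, v in p.items()}


def map_rna_foldchange(pre_count: int, post_count: int) -> float:
    """Natural-log fold change of supporting RNA read counts, +1 pseudocount
    on both sides."""
    if pre_count < 0 or post_count < 0:
        raise ValueError("counts must be non-negative")
    return math.log((post_count + 1) / (pre_count + 1))


@dataclass
class CandidateMAP:
    """A selected candidate with its filter flags and pool assignment."""

    record: MapRecord
    flag_expressed: bool  # (a) present in pre-injection RNA
    flag_edited: bool  # (b) absent in immunocompetent tumors
    flag_atypical: bool  # (c) non-canonical translational event
    rank_score: float = float("nan")  # (d) composite
    pool: int = 0

    @property
    def selected(self) -> bool:
        return self.flag_expressed and self.flag_edited and self.flag_atypical


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.all(np.isnan(x)):
        return np.zeros_like(x)
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd == 0:
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def select_candidates(
    records: Sequence[MapRecord],
    pre_sample: str,
    competent_samples: Sequence[str],
    n_pools: int = 3,
    top_n: int = 20,
    min_lost_replicates: int | None = None,
) -> list[CandidateMAP]:
    """Apply the candidate filters and pool the top-ranked survivors.

    Hard filters: (a) pre-injection RNA support > 0; (b) zero supporting
    reads in all immunocompetent replicates (or lost in at least
    ``min_lost_replicates`` of them when given); (c) non-canonical.  The
    composite rank (d) sums z-scored log pre-injection expression, z-scored
    log MS intensity where present, and allele frequency for mutated
    records, with equal weights.  Survivors are assigned to ``n_pools``
    pools round-robin by rank.
    """
    cands = []
    for rec in records:
        pre = rec.rna_counts.get(pre_sample, 0)
        ic = [rec.rna_counts.get(s, 0) for s in competent_samples]
        if min_lost_replicates is None:
            edited = all(c == 0 for c in ic)
        else:
            edited = sum(c == 0 for c in ic) >= min_lost_replicates
        cands.append(
            CandidateMAP(
                rec,
                flag_expressed=pre > 0,
                flag_edited=edited,
                flag_atypical=rec.canonical == "Non-canonical",
            )
        )
    survivors = [c for c in cands if c.selected]
    if not survivors:
        return []
    expr = _zscore(
        [math.log1p(c.record.rna_counts.get(pre_sample, 0)) for c in survivors]
    )
    inten = _zscore(
        [
            math.log1p(c.record.ms_intensity)
            if c.record.ms_intensity is not None
            else float("nan")
            for c in survivors
        ]
    )
    af = np.array(
        [
            (c.record.allele_frequency or 0.0) / 100.0
            if c.record.mutation != "WT"
            else 0.0
            for c in survivors
        ]
    )
    for c, e, i, a in zip(survivors, expr, inten, af):
        c.rank_score = float(e + (0.0 if math.isnan(i) else i) + a)
    survivors.sort(key=lambda c: (-c.rank_score, c.record.peptide))
    selected = survivors[:top_n]
    for i, c in enumerate(selected):
        c.pool = (i % n_pools) + 1
    return selected


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> CoverageProfile:
    runs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            runs.append((f[0], int(f[1]), int(f[2]), int(float(f[3]))))
    return CoverageProfile(runs)


def write_bedgraph(profile: CoverageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depth in profile.runs:
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


#: Canonical column order of the annotated candidate table.
CANDIDATE_COLUMNS = [
    "peptide",
    "coordinates",
    "region",
    "n_reads",
    "alteration",
    "canonical",
    "af_percent",
    "ms_replicates",
    "ms_intensity",
    "gene_fpkm",
    "pool",
]


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read an annotated candidate table (TSV, NA for missing values)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in ("peptide", "pool") if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table lacks required columns: {missing}")
    return df


def write_candidate_table(
    candidates: Iterable[CandidateMAP], path: str | Path
) -> None:
    rows = []
    for c in candidates:
        rec = c.record
        coords = " ".join(
            f"{l.chrom}:{l.start}-{l.end}" for l in rec.loci
        )
        rows.append(
            {
                "peptide": rec.peptide,
                "coordinates": coords,
                "region": rec.region,
                "n_reads": rec.n_reads,
                "alteration": rec.mutation,
                "canonical": rec.canonical,
                "af_percent": (
                    round(rec.allele_frequency, 4)
                    if rec.mutation != "WT" and rec.allele_frequency is not None
                    else 100
                ),
                "ms_replicates": 1,
                "ms_intensity": rec.ms_intensity,
                "gene_fpkm": None,
                "pool": c.pool,
            }
        )
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )
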