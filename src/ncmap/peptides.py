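"""Genotype-specific 8-11-mer peptide databases from six-frame translated
RNA-seq reads.

Every read is translated in all six frames (three per strand); maximal
stop-free fragments are cut into k-mers of length 8-11 and counted per
sample.  The MMR-proficient database keeps peptides with >= 10 counts
before injection and in the immunocompromised-host tumor that disappear in
the immunocompetent-host tumor.  The MMR-deficient database additionally
requires loss or strong counter-selection in at least one immunocompetent
replicate, absence from every MMR-proficient sample, and no strong
expansion relative to the proficient counterpart.

Counting unit defaults to occurrences (read x frame x offset x k); set
``count_mode="reads"`` to count distinct reads per peptide instead.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .intervals import revcomp

__all__ = [
    "FRAMES",
    "ReadRecord",
    "PeptideDatabase",
    "DatabaseParams",
    "SampleRoles",
    "MatchResult",
    "six_frame_translate",
    "kmerize",
    "read_kmer_counts",
    "count_sample",
    "build_count_table",
    "lost_or_counterselected",
    "expanded_in_mmrd",
    "build_mmrp_db",
    "build_mmrd_db",
    "match_observed",
    "collect_provenance",
    "read_fastx",
    "write_fastq",
    "write_database",
    "read_database",
]

#: Frame identifiers: +1..+3 translate the forward strand at offsets 0..2,
#: -1..-3 translate the reverse complement at offsets 0..2.
FRAMES = (1, 2, 3, -1, -2, -3)

_CODON_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ReadRecord:
    """One RNA-seq read assigned to a sample."""

    read_id: str
    sequence: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"{self.read_id}: non-ACGTN characters in sequence")


def _translate_offset(seq: str, offset: int) -> list[str]:
    """Maximal peptide fragments at one offset; stops and N-codons split."""
    frags: list[str] = []
    cur: list[str] = []
    for i in range(offset, len(seq) - 2, 3):
        aa = _CODON_AA.get(seq[i : i + 3])
        if aa is None:  # stop codon or codon containing N
            if cur:
                frags.append("".join(cur))
                cur = []
        else:
            cur.append(aa)
    if cur:
        frags.append("".join(cur))
    return frags


def frame_translation(seq: str, frame: int) -> str:
    """Full translation of one frame with '*' for stops, 'X' for N-codons.

    Character i sits at nucleotide offset ``(|frame|-1) + 3*i`` of the
    frame's template strand (the reverse complement for negative frames).
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame}")
    s = seq.upper() if frame > 0 else revcomp(seq.upper())
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(s) - 2, 3):
        codon = s[i : i + 3]
        if codon in _STOPS:
            out.append("*")
        else:
            out.append(_CODON_AA.get(codon, "X"))
    return "".join(out)


def six_frame_translate(read: str | ReadRecord) -> dict[int, list[str]]:
    """Translate in all six frames; fragments are maximal stop-free runs.

    Codons containing N are untranslatable and split fragments, as do stop
    codons; a peptide never spans a stop.
    """
    seq = (read.sequence if isinstance(read, ReadRecord) else read).upper()
    rc = revcomp(seq)
    out: dict[int, list[str]] = {}
    for f in (1, 2, 3):
        out[f] = _translate_offset(seq, f - 1)
        out[-f] = _translate_offset(rc, f - 1)
    return out


def kmerize(
    fragments: Iterable[str], k_min: int = 8, k_max: int = 11
) -> Counter:
    """All substrings of lengths k_min..k_max from each fragment, counted."""
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    counts: Counter = Counter()
    for frag in fragments:
        n = len(frag)
        for k in range(k_min, k_max + 1):
            for i in range(n - k + 1):
                counts[frag[i : i + k]] += 1
    return counts


def read_kmers(seq: str, k_min: int = 8, k_max: int = 11) -> Counter:
    """Six-frame k-mer multiset of a single read."""
    frames = six_frame_translate(seq)
    counts: Counter = Counter()
    for frags in frames.values():
        counts.update(kmerize(frags, k_min, k_max))
    return counts


def read_kmer_counts(seq: str, k_min: int = 8, k_max: int = 11) -> Counter:
    return read_kmers(seq, k_min, k_max)


def count_sample(
    reads: Iterable[ReadRecord | tuple[str, str] | str],
    k_min: int = 8,
    k_max: int = 11,
    count_mode: str = "occurrences",
) -> Counter:
    """Aggregate six-frame k-mer counts over the reads of one sample.

    ``occurrences`` counts every generating (read, frame, offset, k)
    occurrence; ``reads`` counts distinct reads per peptide.
    """
    if count_mode not in ("occurrences", "reads"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    total: Counter = Counter()
    for read in reads:
        if isinstance(read, ReadRecord):
            seq = read.sequence
        elif isinstance(read, tuple):
            seq = read[1]
        else:
            seq = read
        kc = read_kmers(seq, k_min, k_max)
        if count_mode == "reads":
            for pep in kc:
                total[pep] += 1
        else:
            total.update(kc)
    return total


def build_count_table(
    sample_counts: Mapping[str, Counter],
) -> pd.DataFrame:
    """Peptide x sample count matrix (int64, missing = 0)."""
    df = pd.DataFrame(
        {name: pd.Series(c, dtype="int64") for name, c in sample_counts.items()}
    )
    df = df.fillna(0).astype("int64")
    df.index.name = "peptide"
    return df


# ---------------------------------------------------------------------------
# selection formulas
# ---------------------------------------------------------------------------

def lost_or_counterselected(
    counts_pre_selected: int | np.ndarray,
    counts_balbc: int | np.ndarray,
    min_diff: int = 10,
    min_ratio: float = 10.0,
):
    """Lost or strongly counter-selected in an immunocompetent tumor.

    True iff counts_balbc = 0, or (counts_pre - counts_balbc >= min_diff
    and counts_pre / counts_balbc >= min_ratio).
    """
    pre = np.asarray(counts_pre_selected, dtype=float)
    post = np.asarray(counts_balbc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(post > 0, pre / np.where(post > 0, post, 1), np.inf)
    result = (post == 0) | ((pre - post >= min_diff) & (ratio >= min_ratio))
    if np.isscalar(counts_pre_selected) and np.isscalar(counts_balbc):
        return bool(result)
    return result


def expanded_in_mmrd(
    counts_mmrd: int | np.ndarray,
    counts_mmrp: int | np.ndarray,
    min_diff: int = 10,
    min_ratio: float = 10.0,
):
    """Strongly expanded in the MMR-deficient versus proficient counterpart.

    True iff counts_mmrd - counts_mmrp >= min_diff and
    counts_mmrd / counts_mmrp >= min_ratio; division by zero is treated as
    an infinite ratio (the condition holds when the difference holds).
    """
    d = np.asarray(counts_mmrd, dtype=float)
    p = np.asarray(counts_mmrp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, d / np.where(p > 0, p, 1), np.inf)
    result = (d - p >= min_diff) & (ratio >= min_ratio)
    if np.isscalar(counts_mmrd) and np.isscalar(counts_mmrp):
        return bool(result)
    return result


# ---------------------------------------------------------------------------
# database construction
# ---------------------------------------------------------------------------

@dataclass
class DatabaseParams:
    """Thresholds of the selection rules (defaults from the source method)."""

    min_count: int = 10  # count floor before injection and in NOD-SCID
    min_diff: int = 10
    min_ratio: float = 10.0
    min_lost_replicates: int = 1  # "in at least one" immunocompetent tumor
    presence_min: int = 1  # count regarded as "present" for exclusions
    # strict: "disappeared" in the MMRp arm means count == 0; when False the
    # MMRd counter-selection formula is reused symmetrically
    strict_mmrp_disappear: bool = True


@dataclass
class SampleRoles:
    """Column names of the count table by experimental role."""

    mmrd_pre: str = "MMRd_pre"
    mmrd_nod: str = "MMRd_NOD_1"
    mmrd_balbc: tuple[str, ...] = ("MMRd_BALBc_1", "MMRd_BALBc_2", "MMRd_BALBc_3")
    mmrp_pre: str = "MMRp_pre"
    mmrp_nod: str = "MMRp_NOD_1"
    mmrp_balbc: tuple[str, ...] = ("MMRp_BALBc_1",)

    @property
    def mmrp_tumors(self) -> tuple[str, ...]:
        return tuple(self.mmrp_balbc) + (self.mmrp_nod,)

    @property
    def all_samples(self) -> tuple[str, ...]:
        return (
            (self.mmrd_pre, self.mmrd_nod)
            + tuple(self.mmrd_balbc)
            + (self.mmrp_pre, self.mmrp_nod)
            + tuple(self.mmrp_balbc)
        )


@dataclass
class PeptideDatabase:
    """A genotype-specific peptide database with build metadata."""

    genotype: str
    table: pd.DataFrame  # selected rows of the count table
    params: DatabaseParams = field(default_factory=DatabaseParams)
    provenance: dict[str, set] = field(default_factory=dict)

    @property
    def peptides(self) -> set[str]:
        return set(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.table.index


def _require_columns(table: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"count table is missing sample columns: {missing}")


def build_mmrp_db(
    table: pd.DataFrame,
    roles: SampleRoles | None = None,
    params: DatabaseParams | None = None,
) -> PeptideDatabase:
    """MMR-proficient database: >= min_count before injection and in the
    immunocompromised host, disappeared in the immunocompetent host."""
    roles = roles or SampleRoles()
    params = params or DatabaseParams()
    cols = [roles.mmrp_pre, roles.mmrp_nod, *roles.mmrp_balbc]
    _require_columns(table, cols)
    pre = table[roles.mmrp_pre].to_numpy()
    nod = table[roles.mmrp_nod].to_numpy()
    keep = (pre >= params.min_count) & (nod >= params.min_count)
    for col in roles.mmrp_balbc:
        balbc = table[col].to_numpy()
        if params.strict_mmrp_disappear:
            keep &= balbc == 0
        else:
            keep &= lost_or_counterselected(
                pre, balbc, params.min_diff, params.min_ratio
            )
    return PeptideDatabase("MMRp", table.loc[keep, cols].copy(), params)


def build_mmrd_db(
    table: pd.DataFrame,
    roles: SampleRoles | None = None,
    params: DatabaseParams | None = None,
) -> PeptideDatabase:
    """MMR-deficient database per the full selection rule.

    Keep peptides with >= min_count before injection and in the
    immunocompromised host, lost or counter-selected in at least
    ``min_lost_replicates`` immunocompetent replicates, absent from every
    MMR-proficient tumor and from MMR-proficient cells, and not strongly
    expanded relative to the proficient counterpart.  The expansion
    exclusion applies only to peptides detected in proficient cells: with a
    zero proficient count the ratio is infinite and a literal reading would
    empty the database.
    """
    roles = roles or SampleRoles()
    params = params or DatabaseParams()
    if len(roles.mmrd_balbc) < 1:
        raise ValueError("at least one immunocompetent MMRd replicate required")
    _require_columns(table, roles.all_samples)
    pre = table[roles.mmrd_pre].to_numpy()
    nod = table[roles.mmrd_nod].to_numpy()
    keep = (pre >= params.min_count) & (nod >= params.min_count)

    n_lost = np.zeros(len(table), dtype=int)
    for col in roles.mmrd_balbc:
        n_lost += lost_or_counterselected(
            pre, table[col].to_numpy(), params.min_diff, params.min_ratio
        ).astype(int)
    keep &= n_lost >= params.min_lost_replicates

    for col in roles.mmrp_tumors:  # absent from MMRp tumors (both hosts)
        keep &= table[col].to_numpy() < params.presence_min
    mmrp_cells = table[roles.mmrp_pre].to_numpy()
    keep &= mmrp_cells < params.presence_min  # absent from MMRp cells

    expanded = expanded_in_mmrd(pre, mmrp_cells, params.min_diff, params.min_ratio)
    keep &= ~(expanded & (mmrp_cells > 0))

    db = PeptideDatabase("MMRd", table.loc[keep].copy(), params)
    # hard invariant: never intersect the MMRp pre-injection peptide set
    assert not (
        db.table[roles.mmrp_pre] >= params.presence_min
    ).any(), "MMRd database intersects MMRp cell peptides"
    return db


@dataclass
class MatchResult:
    """Outcome of matching observed peptides against the two databases."""

    exclusive: list[str]  # in db_self only
    shared_excluded: list[str]  # in db_self but also in db_other
    unmatched: list[str]  # in neither database
    invalid: list[str]  # malformed residues, skipped


def match_observed(
    observed: Sequence[str],
    db_self: PeptideDatabase,
    db_other: PeptideDatabase | None = None,
) -> MatchResult:
    """Exact-match observed peptides against the genotype's own database,
    excluding any peptide also present in the other genotype's database."""
    exclusive, shared, unmatched, invalid = [], [], [], []
    other = db_other.peptides if db_other is not None else set()
    own = db_self.peptides
    for pep in observed:
        pep = pep.strip().upper()
        if not pep or set(pep) - VALID_RESIDUES:
            invalid.append(pep)
            continue
        if pep in own:
            (shared if pep in other else exclusive).append(pep)
        elif pep in other:
            shared.append(pep)
        else:
            unmatched.append(pep)
    return MatchResult(exclusive, shared, unmatched, invalid)


def collect_provenance(
    reads: Iterable[ReadRecord],
    peptides: set[str],
    k_min: int = 8,
    k_max: int = 11,
) -> dict[str, set[tuple[str, int, int]]]:
    """(read id, frame, aa offset in frame) provenance for a peptide set.

    A second pass over the reads, run only for the (small) set of peptides
    that survive database construction or matching.
    """
    prov: dict[str, set] = {p: set() for p in peptides}
    lengths = sorted({len(p) for p in peptides} & set(range(k_min, k_max + 1)))
    for read in reads:
        for frame in FRAMES:
            trans = frame_translation(read.sequence, frame)
            for k in lengths:
                for i in range(len(trans) - k + 1):
                    pep = trans[i : i + k]
                    if pep in prov:  # windows with '*'/'X' never match
                        prov[pep].add((read.read_id, frame, i))
    return {p: s for p, s in prov.items() if s}


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fastx(path: str | Path, sample_id: str = "") -> Iterator[ReadRecord]:
    """Stream FASTA/FASTQ records (gzip allowed) as ReadRecords."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    stem = path.name.removesuffix(".gz")
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield ReadRecord(rec.id, str(rec.seq).upper(), sample_id)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_database(db: PeptideDatabase, tsv_path: str | Path, fasta_path: str | Path | None = None) -> None:
    """Write the database as TSV (peptide + per-sample counts + provenance
    count) and optionally as a peptide FASTA for MS-search interoperability."""
    out = db.table.copy()
    out["n_provenance"] = [
        len(db.provenance.get(p, ())) for p in out.index
    ]
    out.to_csv(tsv_path, sep="\t")
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for i, pep in enumerate(out.index):
                fh.write(f">{db.genotype}_{i}\n{pep}\n")


def read_database(tsv_path: str | Path, genotype: str = "") -> PeptideDatabase:
    table = pd.read_csv(tsv_path, sep="\t", index_col="peptide")
    table = table.drop(columns=[c for c in ("n_provenance",) if c in table.columns])
    return PeptideDatabase(genotype or "unknown", table)
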