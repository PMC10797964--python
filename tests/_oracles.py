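"""Independent reference implementations used by the acceptance tests.

These deliberately avoid the package's own code paths: translation is done
per codon with Biopython, k-mers by double loop, and alignment by an
exhaustive all-position scan.
"""

from collections import Counter

from Bio.Seq import Seq


def naive_six_frame_kmers(seq: str, k_min: int = 8, k_max: int = 11) -> Counter:
    counts: Counter = Counter()
    seq = seq.upper()
    for template in (seq, str(Seq(seq).reverse_complement())):
        for off in range(3):
            codons = [template[i : i + 3] for i in range(off, len(template) - 2, 3)]
            aa = "".join(
                "*" if set(c) - set("ACGT") else str(Seq(c).translate())
                for c in codons
            )
            for frag in aa.replace("X", "*").split("*"):
                for k in range(k_min, k_max + 1):
                    for i in range(len(frag) - k + 1):
                        counts[frag[i : i + k]] += 1
    return counts


def brute_force_best_placements(segment: str, genome: dict, max_mm: int = 2):
    """Exhaustive ungapped scan over every position and both strands.

    Returns (best score, set of (chrom, start, strand))."""
    best, hits = None, set()
    n = len(segment)
    rc = str(Seq(segment).reverse_complement())
    for strand, query in (("+", segment), ("-", rc)):
        for chrom, seq in genome.items():
            for i in range(len(seq) - n + 1):
                mm = sum(a != b for a, b in zip(query, seq[i : i + n]))
                if mm > max_mm:
                    continue
                score = n - 2 * mm
                if best is None or score > best:
                    best, hits = score, {(chrom, i, strand)}
                elif score == best:
                    hits.add((chrom, i, strand))
    return best, hits
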