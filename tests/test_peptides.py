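from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Seq import Seq

from ncmap.intervals import revcomp
from ncmap.peptides import (
    DatabaseParams,
    PeptideDatabase,
    ReadRecord,
    SampleRoles,
    build_count_table,
    build_mmrd_db,
    build_mmrp_db,
    collect_provenance,
    count_sample,
    expanded_in_mmrd,
    frame_translation,
    kmerize,
    lost_or_counterselected,
    match_observed,
    read_database,
    read_fastx,
    read_kmers,
    six_frame_translate,
    write_database,
    write_fastq,
)


def naive_six_frame_kmers(seq, k_min=8, k_max=11):
    """Independent oracle: Biopython translation per frame, explicit
    stop/X splitting, double-loop k-mer enumeration."""
    counts = Counter()
    seq = seq.upper()
    for template in (seq, str(Seq(seq).reverse_complement())):
        for off in range(3):
            codons = [
                template[i : i + 3] for i in range(off, len(template) - 2, 3)
            ]
            # a codon containing anything but ACGT is untranslatable
            aa = "".join(
                "*" if set(c) - set("ACGT") else str(Seq(c).translate())
                for c in codons
            )
            for frag in aa.replace("X", "*").split("*"):
                for k in range(k_min, k_max + 1):
                    for i in range(len(frag) - k + 1):
                        counts[frag[i : i + k]] += 1
    return counts


class TestSixFrameTranslate:
    def test_forward_frame(self):
        assert six_frame_translate("ATGAAA")[1] == ["MK"]

    def test_reverse_frame(self):
        # revcomp("ATGAAAGGG") = "CCCTTTCAT" -> PFH
        assert six_frame_translate("ATGAAAGGG")[-1] == ["PFH"]

    def test_stop_splits_fragments(self):
        assert six_frame_translate("ATGTAAATG")[1] == ["M", "M"]

    def test_n_codon_splits(self):
        assert six_frame_translate("ATGANAATG")[1] == ["M", "M"]

    def test_all_six_frames_present(self):
        out = six_frame_translate("ATGAAAGGGTTT")
        assert set(out) == {1, 2, 3, -1, -2, -3}

    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    @settings(max_examples=80, deadline=None)
    def test_revcomp_swaps_frames(self, seq):
        fwd = six_frame_translate(seq)
        rev = six_frame_translate(revcomp(seq))
        plus = sorted(f for fr in (1, 2, 3) for f in fwd[fr])
        minus = sorted(f for fr in (-1, -2, -3) for f in rev[fr])
        assert plus == minus


class TestKmerize:
    def test_length_11_fragment(self):
        assert sum(kmerize(["A" * 11]).values()) == 4 + 3 + 2 + 1

    def test_length_7_fragment(self):
        assert kmerize(["A" * 7]) == Counter()

    def test_length_8_fragment(self):
        assert kmerize(["ACDEFGHI"]) == Counter({"ACDEFGHI": 1})

    def test_invalid_k_range(self):
        with pytest.raises(ValueError):
            kmerize([], k_min=9, k_max=8)

    def test_oracle_equivalence_random_reads(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(20, 120))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert read_kmers(seq) == naive_six_frame_kmers(seq)

    def test_oracle_equivalence_with_n(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGTN"), size=80, p=[0.24] * 4 + [0.04]))
            assert read_kmers(seq) == naive_six_frame_kmers(seq)


class TestFrameTranslation:
    def test_markers(self):
        assert frame_translation("ATGTAAANG", 1) == "M*X"

    def test_negative_frame(self):
        assert frame_translation("ATGAAAGGG", -1) == "PFH"

    def test_bad_frame(self):
        with pytest.raises(ValueError):
            frame_translation("ATG", 4)


class TestCountSample:
    def test_count_modes(self):
        # same peptide encoded twice in one read
        seq = "GCTGCAGCTGCAGCAGCGGCAGCTGCAGCTGCAGCAGCGGCAGCT"
        occ = count_sample([seq], count_mode="occurrences")
        dis = count_sample([seq], count_mode="reads")
        assert set(dis.values()) == {1}
        assert max(occ.values()) > 1

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            count_sample([], count_mode="banana")


def make_table(rows):
    roles = SampleRoles()
    df = pd.DataFrame(rows, columns=list(roles.all_samples))
    df.index = [f"PEPTIDE{i:03d}" for i in range(len(df))]
    df.index.name = "peptide"
    return df, roles


class TestLostOrCounterselected:
    # truth table from the printed formula
    @pytest.mark.parametrize(
        "pre,balbc,expected",
        [
            (10, 0, True),  # first disjunct
            (50, 4, True),  # 46 >= 10 and 12.5 >= 10
            (50, 10, False),  # diff 40 but ratio 5 < 10
            (19, 1, True),  # diff 18, ratio 19
        ],
    )
    def test_cases(self, pre, balbc, expected):
        assert lost_or_counterselected(pre, balbc) is expected

    def test_boundary_diff_and_ratio(self):
        # diff exactly 10 and ratio exactly 10 both satisfy the formula
        assert lost_or_counterselected(20, 2) is True  # diff 18, ratio 10
        assert lost_or_counterselected(11, 1) is True  # diff 10, ratio 11
        assert lost_or_counterselected(10, 1) is False  # diff 9
        assert lost_or_counterselected(100, 10) is True  # diff 90, ratio 10

    def test_vectorized(self):
        out = lost_or_counterselected(
            np.array([10, 50, 50]), np.array([0, 4, 10])
        )
        assert out.tolist() == [True, True, False]


class TestExpandedInMmrd:
    @pytest.mark.parametrize(
        "mmrd,mmrp,expected",
        [
            (30, 2, True),  # 28 >= 10, 15 >= 10
            (30, 20, False),  # ratio 1.5
            (10, 0, True),  # diff 10, ratio inf
            (9, 0, False),  # diff 9
            (20, 2, True),  # diff 18, ratio 10 (boundary)
        ],
    )
    def test_cases(self, mmrd, mmrp, expected):
        assert expanded_in_mmrd(mmrd, mmrp) is expected


class TestBuildMmrpDb:
    def test_rule(self):
        rows = [
            # mmrd_pre, mmrd_nod, mmrd_b1..3, mmrp_pre, mmrp_nod, mmrp_b1
            [0, 0, 0, 0, 0, 10, 10, 0],  # selected
            [0, 0, 0, 0, 0, 9, 50, 0],  # pre < 10
            [0, 0, 0, 0, 0, 50, 50, 1],  # did not disappear
        ]
        table, roles = make_table(rows)
        db = build_mmrp_db(table, roles)
        assert db.peptides == {"PEPTIDE000"}

    def test_missing_column_raises(self):
        table, roles = make_table([[0] * 8])
        with pytest.raises(KeyError):
            build_mmrp_db(table.drop(columns=["MMRp_pre"]), roles)

    def test_relaxed_disappearance(self):
        rows = [[0, 0, 0, 0, 0, 50, 50, 4]]  # counter-selected, not zero
        table, roles = make_table(rows)
        strict = build_mmrp_db(table, roles)
        relaxed = build_mmrp_db(
            table, roles, DatabaseParams(strict_mmrp_disappear=False)
        )
        assert len(strict) == 0
        assert len(relaxed) == 1


class TestBuildMmrdDb:
    def test_lost_in_one_of_three(self):
        rows = [[20, 20, 0, 20, 20, 0, 0, 0]]  # lost in replicate 1 only
        table, roles = make_table(rows)
        assert len(build_mmrd_db(table, roles)) == 1

    def test_present_in_mmrp_cells_excluded(self):
        rows = [[20, 20, 0, 0, 0, 5, 0, 0]]
        table, roles = make_table(rows)
        assert len(build_mmrd_db(table, roles)) == 0

    def test_present_in_mmrp_tumor_excluded(self):
        rows = [[20, 20, 0, 0, 0, 0, 3, 0]]
        table, roles = make_table(rows)
        assert len(build_mmrd_db(table, roles)) == 0

    def test_count_floor(self):
        rows = [[9, 20, 0, 0, 0, 0, 0, 0], [20, 9, 0, 0, 0, 0, 0, 0]]
        table, roles = make_table(rows)
        assert len(build_mmrd_db(table, roles)) == 0

    def test_not_lost_anywhere_excluded(self):
        rows = [[20, 20, 20, 20, 20, 0, 0, 0]]
        table, roles = make_table(rows)
        assert len(build_mmrd_db(table, roles)) == 0

    def test_monotone_in_count_floor(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 40, size=(300, 8)).tolist()
        table, roles = make_table(rows)
        prev_d = prev_p = None
        for floor in (10, 15, 20, 30):
            params = DatabaseParams(min_count=floor)
            d = build_mmrd_db(table, roles, params).peptides
            p = build_mmrp_db(table, roles, params).peptides
            if prev_d is not None:
                assert d <= prev_d
                assert p <= prev_p
            prev_d, prev_p = d, p

    def test_never_intersects_mmrp_cells(self):
        rng = np.random.default_rng(13)
        rows = rng.integers(0, 30, size=(500, 8)).tolist()
        table, roles = make_table(rows)
        db = build_mmrd_db(table, roles)
        assert (table.loc[list(db.peptides), "MMRp_pre"] == 0).all()

    def test_no_balbc_replicates_raises(self):
        table, roles = make_table([[0] * 8])
        roles_bad = SampleRoles(mmrd_balbc=())
        with pytest.raises(ValueError):
            build_mmrd_db(table, roles_bad)


class TestMatchObserved:
    def _dbs(self):
        t1, roles = make_table([[20, 20, 0, 0, 0, 0, 0, 0]])
        t1.index = ["LKIAWLREICL"]
        t2, _ = make_table([[0, 0, 0, 0, 0, 20, 20, 0]])
        t2.index = ["AAAAAAAA"]
        return PeptideDatabase("MMRd", t1), PeptideDatabase("MMRp", t2)

    def test_exclusive_retained(self):
        db_d, db_p = self._dbs()
        out = match_observed(["LKIAWLREICL"], db_d, db_p)
        assert out.exclusive == ["LKIAWLREICL"]

    def test_shared_excluded(self):
        db_d, db_p = self._dbs()
        out = match_observed(["AAAAAAAA"], db_d, db_p)
        assert out.exclusive == []
        assert out.shared_excluded == ["AAAAAAAA"]

    def test_unmatched(self):
        db_d, db_p = self._dbs()
        out = match_observed(["CCCCCCCC"], db_d, db_p)
        assert out.unmatched == ["CCCCCCCC"]

    def test_invalid_residues_skipped(self):
        db_d, db_p = self._dbs()
        out = match_observed(["LKIAWLRE1CL"], db_d, db_p)
        assert out.invalid == ["LKIAWLRE1CL"]
        assert out.exclusive == []


class TestProvenance:
    def test_offsets_verifiable(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=90))
        peps = set(read_kmers(seq)) | {"WWWWWWWW"}
        reads = [ReadRecord("r1", seq, "s")]
        prov = collect_provenance(reads, peps)
        assert "WWWWWWWW" not in prov
        assert prov  # every counted peptide has provenance
        for pep, entries in prov.items():
            for read_id, frame, aa_off in entries:
                trans = frame_translation(seq, frame)
                assert trans[aa_off : aa_off + len(pep)] == pep


class TestIO:
    def test_fastq_roundtrip(self, tmp_path):
        reads = [ReadRecord("a", "ACGTACGT", "s"), ReadRecord("b", "GGGGCCCC", "s")]
        path = tmp_path / "x.fastq"
        write_fastq(reads, path)
        back = list(read_fastx(path, "s"))
        assert back == reads

    def test_database_roundtrip(self, tmp_path):
        table, roles = make_table([[20, 20, 0, 0, 0, 0, 0, 0]])
        db = build_mmrd_db(table, roles)
        write_database(db, tmp_path / "db.tsv", tmp_path / "db.fasta")
        back = read_database(tmp_path / "db.tsv", "MMRd")
        assert back.peptides == db.peptides
        fasta = (tmp_path / "db.fasta").read_text()
        assert fasta.startswith(">MMRd_0")
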