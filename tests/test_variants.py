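import math

import numpy as np
import pytest
from Bio.Seq import Seq

from ncmap.intervals import (
    GenomicInterval,
    RegionTrack,
    TranscriptModel,
    tracks_from_transcripts,
)
from ncmap.variants import (
    RegionMutationSummary,
    SampleVariantSet,
    Variant,
    coding_effect,
    editing_logratio,
    filter_somatic,
    flag_ms_indels,
    gained_lost,
    host_delta,
    read_vcf,
    scan_microsatellites,
    tmb_by_region,
    write_vcf,
)


def v(chrom, pos, ref, alt, dp=50, ad=20):
    return Variant(chrom, pos, ref, alt, dp, ad)


def vset(variants, sample="s"):
    return SampleVariantSet(sample, variants=variants)


class TestVariant:
    def test_vclass(self):
        assert v("chr1", 0, "A", "T").vclass == "SNV"
        assert v("chr1", 0, "A", "AT").vclass == "INS"
        assert v("chr1", 0, "AT", "A").vclass == "DEL"

    def test_alt_depth_exceeds_total_raises(self):
        with pytest.raises(ValueError):
            Variant("chr1", 0, "A", "T", total_depth=5, alt_depth=6)

    def test_duplicate_variants_raise(self):
        with pytest.raises(ValueError):
            vset([v("chr1", 0, "A", "T"), v("chr1", 0, "A", "T")])


class TestFilterSomatic:
    def test_at_thresholds_kept(self):
        calls = vset([v("chr1", 5, "A", "T", dp=10, ad=9)])
        out = filter_somatic(calls, vset([], "g"))
        assert len(out) == 1

    def test_below_depth_dropped(self):
        calls = vset([v("chr1", 5, "A", "T", dp=9, ad=9)])
        assert len(filter_somatic(calls, vset([], "g"))) == 0

    def test_below_alt_dropped(self):
        calls = vset([v("chr1", 5, "A", "T", dp=30, ad=8)])
        assert len(filter_somatic(calls, vset([], "g"))) == 0

    def test_germline_subtracted(self):
        shared = v("chr1", 5, "A", "T", dp=50, ad=30)
        calls = vset([shared, v("chr1", 9, "C", "G", dp=50, ad=30)])
        out = filter_somatic(calls, vset([v("chr1", 5, "A", "T", dp=99, ad=50)], "g"))
        assert [x.pos for x in out.variants] == [9]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        calls = vset(
            [
                Variant("chr1", int(p), "A", "T", int(dp), int(min(dp, ad)))
                for p, dp, ad in zip(
                    range(100),
                    rng.integers(1, 40, 100),
                    rng.integers(0, 40, 100),
                )
            ]
        )
        germ = vset([], "g")
        prev = None
        for min_depth, min_alt in [(5, 3), (10, 9), (20, 15)]:
            kept = {x.key for x in filter_somatic(calls, germ, min_depth, min_alt).variants}
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestTmbByRegion:
    def test_arithmetic(self):
        tracks = [RegionTrack("coding", [GenomicInterval("chr1", 0, 2_000_000)])]
        vs = vset([v("chr1", i * 10, "A", "T") for i in range(5)])
        summ = tmb_by_region(vs, tracks)["coding"]
        assert summ.tmb == pytest.approx(2.5)

    def test_zero_variants(self):
        tracks = [RegionTrack("coding", [GenomicInterval("chr1", 0, 1_000_000)])]
        assert tmb_by_region(vset([]), tracks)["coding"].tmb == 0

    def test_each_variant_counted_once(self, small_sim):
        tracks = small_sim.tracks
        vs = small_sim.filtered["MMRd_pre"]
        summaries = tmb_by_region(vs, tracks)
        assert sum(s.n_variants for s in summaries.values()) == len(vs)


class TestEditingLogratio:
    def test_identity(self):
        a = RegionMutationSummary("x", 1_000_000, n_snv=5)
        assert editing_logratio(a, a) == 0

    def test_ln2(self):
        pre = RegionMutationSummary("x", 1_000_000, n_snv=1)
        post = RegionMutationSummary("x", 1_000_000, n_snv=2)
        assert editing_logratio(pre, post) == pytest.approx(math.log(2))

    def test_zero_post_is_neg_inf(self):
        pre = RegionMutationSummary("x", 1_000_000, n_snv=5)
        post = RegionMutationSummary("x", 1_000_000)
        assert editing_logratio(pre, post) == float("-inf")

    def test_zero_pre_is_nan(self):
        pre = RegionMutationSummary("x", 1_000_000)
        post = RegionMutationSummary("x", 1_000_000, n_snv=5)
        assert math.isnan(editing_logratio(pre, post))

    def test_label_mismatch_raises(self):
        with pytest.raises(ValueError):
            editing_logratio(
                RegionMutationSummary("a", 1, n_snv=1),
                RegionMutationSummary("b", 1, n_snv=1),
            )


class TestGainedLost:
    def test_identical_sets(self):
        tracks = [RegionTrack("coding", [GenomicInterval("chr1", 0, 1_000_000)])]
        a = vset([v("chr1", 5, "A", "T")])
        out = gained_lost(a, a, tracks)
        assert out["coding"] == {"gained_per_mb": 0.0, "lost_per_mb": 0.0}

    def test_single_lost_per_mb(self):
        tracks = [RegionTrack("coding", [GenomicInterval("chr1", 0, 1_000_000)])]
        pre = vset([v("chr1", 5, "A", "T")])
        post = vset([], "post")
        assert gained_lost(pre, post, tracks)["coding"]["lost_per_mb"] == 1.0

    def test_planted_removal_direction(self):
        tracks = [RegionTrack("coding", [GenomicInterval("chr1", 0, 1_000_000)])]
        pre = vset([v("chr1", i, "A", "T") for i in range(40)])
        nod = vset(pre.variants[:], "nod")
        balbc = vset(pre.variants[20:], "balbc")  # 20 coding variants removed
        lost_nod = gained_lost(pre, nod, tracks)["coding"]["lost_per_mb"]
        lost_balbc = gained_lost(pre, balbc, tracks)["coding"]["lost_per_mb"]
        assert lost_balbc > lost_nod
        delta = host_delta({"coding": -lost_nod}, {"coding": -lost_balbc})
        assert delta["coding"] > 0  # editing signal


class TestCodingEffect:
    @pytest.fixture()
    def setup(self):
        # chr1: CDS 0-12 on + strand: ATG CTT AAA GGG
        genome = {"chr1": "ATGCTTAAAGGGTTTTTTTT"}
        m = TranscriptModel(
            gene="g", name="t", chrom="chr1", strand="+",
            tx_start=0, tx_end=20, cds_start=0, cds_end=12,
            exon_starts=[0], exon_ends=[20],
        )
        return genome, [m]

    def test_silent_third_position(self, setup):
        genome, models = setup
        # CTT -> CTC, both Leu
        assert coding_effect(v("chr1", 5, "T", "C"), models, genome) == "silent"

    def test_nonsilent(self, setup):
        genome, models = setup
        # ATG -> ATA (Met -> Ile)
        assert coding_effect(v("chr1", 2, "G", "A"), models, genome) == "nonsilent"

    def test_cds_indel_nonsilent(self, setup):
        genome, models = setup
        assert coding_effect(v("chr1", 4, "TT", "T"), models, genome) == "nonsilent"

    def test_noncoding(self, setup):
        genome, models = setup
        assert coding_effect(v("chr1", 15, "T", "C"), models, genome) == "noncoding"

    def test_ref_mismatch_raises(self, setup):
        genome, models = setup
        with pytest.raises(ValueError):
            coding_effect(v("chr1", 0, "C", "T"), models, genome)

    def test_agrees_with_bruteforce_oracle(self):
        # 10 random transcripts; oracle rebuilds both CDS translations fully
        rng = np.random.default_rng(5)
        bases = "ACGT"
        for _ in range(10):
            cds_len = 3 * int(rng.integers(5, 20))
            utr = int(rng.integers(0, 10))
            seq = "".join(rng.choice(list(bases), size=cds_len + 2 * utr + 6))
            strand = "+" if rng.random() < 0.5 else "-"
            genome = {"chr1": seq}
            m = TranscriptModel(
                gene="g", name="t", chrom="chr1", strand=strand,
                tx_start=0, tx_end=len(seq),
                cds_start=utr, cds_end=utr + cds_len,
                exon_starts=[0], exon_ends=[len(seq)],
            )
            for _ in range(30):
                pos = int(rng.integers(utr, utr + cds_len))
                ref = seq[pos]
                alt = rng.choice([b for b in bases if b != ref])
                got = coding_effect(v("chr1", pos, ref, str(alt)), [m], genome)
                mutated = seq[:pos] + str(alt) + seq[pos + 1 :]
                def protein(s):
                    cds = s[utr : utr + cds_len]
                    if strand == "-":
                        cds = str(Seq(cds).reverse_complement())
                    return str(Seq(cds).translate())
                expected = "silent" if protein(seq) == protein(mutated) else "nonsilent"
                assert got == expected


class TestMicrosatellites:
    def test_mononucleotide_run(self):
        loci = scan_microsatellites({"chr1": "AAAAAAAAAA"}, min_repeats=5)
        assert len(loci) == 1
        assert loci[0].unit == "A"
        assert loci[0].repeat_count == 10

    def test_dinucleotide_run(self):
        loci = scan_microsatellites({"chr1": "ACACACACAC"}, min_repeats=5)
        assert [(l.unit, l.repeat_count) for l in loci] == [("AC", 5)]

    def test_below_min_repeats_ignored(self):
        assert scan_microsatellites({"chr1": "ACACACAT"}, min_repeats=5) == []

    def test_non_periodic_units_only(self):
        # a poly-A run must not be reported again as unit "AA"
        loci = scan_microsatellites({"chr1": "GG" + "A" * 12 + "GG"}, min_repeats=5)
        assert len(loci) == 1

    def test_flagging(self):
        genome = {"chr1": "GGGG" + "AT" * 8 + "GGGG"}
        loci = scan_microsatellites(genome, min_repeats=5)
        inside = v("chr1", 6, "TA", "T")
        outside = v("chr1", 1, "GG", "G")
        out = flag_ms_indels(vset([inside, outside]), loci)
        flags = {x.pos: x.microsatellite for x in out.variants}
        assert flags[6] is True
        assert flags[1] is False

    def test_snv_never_flagged(self):
        genome = {"chr1": "A" * 20}
        loci = scan_microsatellites(genome, min_repeats=5)
        out = flag_ms_indels(vset([v("chr1", 5, "A", "T")]), loci)
        assert out.variants[0].microsatellite is False


class TestVcfIO:
    def test_roundtrip(self, tmp_path):
        variants = [
            v("chr1", 5, "A", "T", dp=33, ad=12),
            Variant("chr1", 9, "CT", "C", 40, 15, microsatellite=True),
        ]
        path = tmp_path / "x.vcf"
        write_vcf(vset(variants), path, {"chr1": 100})
        back = read_vcf(path, sample_id="s")
        assert back.keyset == {x.key for x in variants}
        by_key = {x.key: x for x in back.variants}
        assert by_key[("chr1", 5, "A", "T")].total_depth == 33
        assert by_key[("chr1", 9, "CT", "C")].microsatellite is True
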