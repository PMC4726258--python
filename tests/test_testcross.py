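"""TC-site classification, MAF filtering and observation strings."""

from collections import Counter

import numpy as np
import pytest

from lowmap.io_formats import Genotype, PhasedBlock, SampleCall, \
    VariantRecord
from lowmap.testcross import (MafWindow, SYM_M, SYM_N, SYM_S,
                              build_observation_strings,
                              classify_testcross_sites, site_maf)

P = ("P1", "P2")


def call(gt, depth=20, mq_ok=True):
    return SampleCall(gt, depth, mq_ok)


def record(pos, p1, p2, qual=99.0, scaffold="scf1", ref="A", alt="G",
           passes=True):
    return VariantRecord(scaffold, pos, ref, alt, qual, (p1, p2),
                         passes_quality=passes)


BLOCKS = {
    "P1": [PhasedBlock("P1", "b1", "scf1",
                       [(100, "A", "G"), (200, "G", "A"), (300, "A", "G")])],
    "P2": [PhasedBlock("P2", "c1", "scf1", [(150, "G", "A"), (250, "A", "G")])],
}


class TestClassification:
    def test_het_by_hom_site_with_alt_segregating(self):
        recs = [record(100, call(Genotype.HET), call(Genotype.HOM_REF))]
        sites, counts = classify_testcross_sites(recs, P, BLOCKS)
        (s,) = sites
        assert (s.parent_id, s.seg_allele, s.const_allele) == ("P1", "G", "A")
        # phase-0 allele at 100 is A (= const), so alt segregates from phase 1
        assert s.seg_phase == 1
        assert counts["sites_emitted"] == 1

    def test_hom_alt_parent_makes_ref_segregate(self):
        recs = [record(100, call(Genotype.HET), call(Genotype.HOM_ALT))]
        ((s,), _) = classify_testcross_sites(recs, P, BLOCKS)
        assert (s.seg_allele, s.const_allele, s.seg_phase) == ("A", "G", 0)

    def test_intercross_excluded(self):
        recs = [record(100, call(Genotype.HET), call(Genotype.HET))]
        sites, counts = classify_testcross_sites(recs, P, BLOCKS)
        assert not sites and counts["excluded_intercross"] == 1

    def test_monomorphic_and_hom_hom_excluded(self):
        recs = [record(100, call(Genotype.HOM_ALT), call(Genotype.HOM_ALT)),
                record(200, call(Genotype.HOM_ALT), call(Genotype.HOM_REF))]
        sites, counts = classify_testcross_sites(recs, P, BLOCKS)
        assert not sites
        assert counts["excluded_monomorphic"] == 1
        assert counts["excluded_hom_hom"] == 1

    def test_unphased_het_site_excluded(self):
        recs = [record(999, call(Genotype.HET), call(Genotype.HOM_REF))]
        sites, counts = classify_testcross_sites(recs, P, BLOCKS)
        assert not sites and counts["excluded_unphased"] == 1

    def test_quality_gates(self):
        recs = [record(100, call(Genotype.HET), call(Genotype.HOM_REF),
                       passes=False),
                record(200, call(Genotype.HET, mq_ok=False),
                       call(Genotype.HOM_REF)),
                record(300, call(Genotype.HET),
                       call(Genotype.HOM_REF, depth=3))]
        sites, counts = classify_testcross_sites(recs, P, BLOCKS)
        assert not sites
        assert counts["excluded_low_quality"] == 1
        assert counts["excluded_low_mq"] == 1
        assert counts["excluded_hom_unconfident"] == 1

    def test_counts_conserved(self):
        recs = [record(100, call(Genotype.HET), call(Genotype.HOM_REF)),
                record(150, call(Genotype.HOM_REF), call(Genotype.HET),
                       ref="G", alt="A"),
                record(200, call(Genotype.HET), call(Genotype.HET)),
                record(999, call(Genotype.HET), call(Genotype.HOM_REF))]
        sites, counts = classify_testcross_sites(recs, P, BLOCKS)
        excluded = sum(v for k, v in counts.items()
                       if k.startswith("excluded_"))
        assert counts["sites_in"] == counts["sites_emitted"] + excluded
        assert counts["sites_emitted"] == len(sites) == 2

    def test_each_site_in_one_group(self):
        recs = [record(p, call(Genotype.HET), call(Genotype.HOM_REF),
                       ref=r, alt=a)
                for p, r, a in [(100, "A", "G"), (200, "G", "A"),
                                (300, "A", "G")]]
        sites, _ = classify_testcross_sites(recs, P, BLOCKS)
        keys = [(s.parent_id, s.block_id, s.seg_phase, s.position)
                for s in sites]
        assert len(keys) == len(set(keys))


class TestSiteMaf:
    def test_documented_allele_count_convention(self):
        # 40 het carriers, 120 hom-const, 3 missing: 40 segregating copies
        # out of 320 called alleles
        calls = ([call(Genotype.HET, 1)] * 40
                 + [call(Genotype.HOM_REF, 1)] * 120
                 + [call(Genotype.MISSING, 0)] * 3)
        assert site_maf(calls, seg_allele_is_alt=True) \
            == pytest.approx(40 / 320)

    def test_expected_quarter_under_one_to_one_segregation(self):
        # half the progeny are het carriers -> seg allele frequency 0.25
        calls = [call(Genotype.HET, 9)] * 81 + [call(Genotype.HOM_REF, 9)] * 82
        assert site_maf(calls, seg_allele_is_alt=True) \
            == pytest.approx(81 / 326, abs=1e-12)

    def test_monomorphic_is_zero(self):
        calls = [call(Genotype.HOM_ALT, 3)] * 10
        assert site_maf(calls, seg_allele_is_alt=True) == 0.0

    def test_balanced_alleles_give_half(self):
        calls = [call(Genotype.HOM_ALT, 3)] * 5 \
            + [call(Genotype.HOM_REF, 3)] * 5
        assert site_maf(calls, seg_allele_is_alt=True) == 0.5

    def test_all_missing_undefined(self):
        assert site_maf([call(Genotype.MISSING, 0)] * 4, True) is None


def _progeny_record(pos, genotypes, depths, ref="A", alt="G"):
    calls = tuple(SampleCall(g, d) for g, d in zip(genotypes, depths))
    return VariantRecord("scf1", pos, ref, alt, 60.0, calls)


def _tc_fixture():
    """Three phase-1 sites of one block over four individuals."""
    recs = [record(p, call(Genotype.HET), call(Genotype.HOM_REF),
                   ref="A", alt="G")
            for p in (100, 300)] + \
           [record(200, call(Genotype.HET), call(Genotype.HOM_REF),
                   ref="G", alt="A")]
    blocks = {"P1": [PhasedBlock("P1", "b1", "scf1",
                                 [(100, "A", "G"), (200, "G", "A"),
                                  (300, "A", "G")])],
              "P2": []}
    sites, _ = classify_testcross_sites(recs, P, blocks)
    return sites


class TestObservationStrings:
    def test_symbols_follow_call_content(self):
        sites = _tc_fixture()
        G = Genotype
        progeny = [
            _progeny_record(100, [G.HET, G.HOM_REF, G.MISSING, G.HOM_ALT],
                            [2, 1, 0, 1]),
            _progeny_record(200, [G.HOM_ALT, G.HOM_REF, G.HET, G.HET],
                            [1, 2, 3, 2], ref="G", alt="A"),
            _progeny_record(300, [G.HOM_REF, G.HOM_REF, G.HET, G.HET],
                            [1, 1, 2, 2]),
        ]
        result = build_observation_strings(sites, progeny,
                                           ["i1", "i2", "i3", "i4"],
                                           maf=None)
        by_phase = {om.phase_type: om for om in result.matrices}
        # sites at 100/300 segregate from phase 1 (seg allele G = alt);
        # site 200 has ref G so its seg allele A = alt -> also phase 1
        om = by_phase[1]
        assert om.positions.tolist() == [100, 200, 300]
        i1 = om.symbols[0].tolist()
        # het -> S, hom toward seg -> S, depth-1 const-only -> N
        assert i1 == [SYM_S, SYM_S, SYM_N]
        assert om.symbols[2].tolist() == [SYM_M, SYM_S, SYM_S]

    def test_site_outside_maf_window_removed_everywhere(self):
        sites = _tc_fixture()
        G = Genotype
        n = 40
        # site 100: only one carrier among 40 -> MAF 1/80 = 0.0125 < 0.075
        gts_100 = [G.HET] + [G.HOM_REF] * (n - 1)
        gts_200 = [G.HET] * (n // 2) + [G.HOM_ALT] * (n // 2)
        gts_300 = [G.HET] * (n // 2) + [G.HOM_REF] * (n // 2)
        progeny = [
            _progeny_record(100, gts_100, [1] * n),
            _progeny_record(200, gts_200, [1] * n, ref="G", alt="A"),
            _progeny_record(300, gts_300, [1] * n),
        ]
        inds = [f"i{k}" for k in range(n)]
        result = build_observation_strings(sites, progeny, inds, MafWindow())
        om = result.matrices[0]
        assert om.positions.tolist() == [200, 300]
        assert result.counts["sites_maf_filtered"] == 1
        maf_100 = result.site_mafs[("scf1", 100)]
        assert maf_100 == pytest.approx(1 / 80)

    def test_disabling_maf_filter_never_shortens_strings(self):
        sites = _tc_fixture()
        G = Genotype
        n = 40
        progeny = [
            _progeny_record(100, [G.HET] + [G.HOM_REF] * (n - 1), [1] * n),
            _progeny_record(200, [G.HET] * 20 + [G.HOM_ALT] * 20, [1] * n,
                            ref="G", alt="A"),
            _progeny_record(300, [G.HET] * 20 + [G.HOM_REF] * 20, [1] * n),
        ]
        inds = [f"i{k}" for k in range(n)]
        with_filter = build_observation_strings(sites, list(progeny), inds,
                                                MafWindow())
        without = build_observation_strings(sites, list(progeny), inds,
                                            maf=None)
        len_with = {om.phase_type: om.n_sites for om in with_filter.matrices}
        len_without = {om.phase_type: om.n_sites for om in without.matrices}
        for phase, L in len_with.items():
            assert len_without[phase] >= L

    def test_all_missing_strings_still_emitted(self):
        sites = _tc_fixture()
        G = Genotype
        progeny = [_progeny_record(100, [G.HET, G.MISSING], [1, 0]),
                   _progeny_record(200, [G.HET, G.MISSING], [1, 0],
                                   ref="G", alt="A"),
                   _progeny_record(300, [G.HET, G.MISSING], [1, 0])]
        result = build_observation_strings(sites, progeny, ["i1", "i2"],
                                           maf=None)
        om = result.matrices[0]
        assert (om.symbols[1] == SYM_M).all()
        strings = list(om.strings())
        assert strings[1].symbols == "MMM"
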