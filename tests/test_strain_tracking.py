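"""Pileup parsing, consensus SNP calls, breadth gating and sharing calls."""

import numpy as np
import pytest

from gyntransloc import (
    MarkerIndex,
    MarkerInfo,
    MarkerSNPProfile,
    call_snps,
    cohort_strain_summary,
    identical_snps,
    marker_breadth,
    parse_pileup,
    simulate_marker_snps,
    simulate_pileup,
    strain_sharing,
)
from gyntransloc.strain_tracking import StrainError, _parse_base_column


@pytest.fixture
def index():
    return MarkerIndex({
        "m1": MarkerInfo("spX", 100),
        "m2": MarkerInfo("spX", 100),
        "m3": MarkerInfo("spY", 100),
    })


class TestParsePileup:
    def test_all_reference_line(self, index):
        recs = parse_pileup("m1\t10\tA\t8\t....,,..\tIIIIIIII", index)
        rec = recs[("m1", 10)]
        assert (rec.depth, rec.ref_count, rec.alt_counts) == (8, 8, {})

    def test_alt_majority_line(self, index):
        recs = parse_pileup("m1\t7\tA\t10\tGGGGGGGGG.\tIIIIIIIIII", index)
        rec = recs[("m1", 7)]
        assert rec.alt_counts == {"G": 9} and rec.ref_count == 1

    def test_read_start_token_consumed(self):
        ref, alts = _parse_base_column("^].", 1)
        assert ref == 1 and alts == {}

    def test_indel_runs_and_deletions_skipped(self):
        ref, alts = _parse_base_column(".+2AC,-1T*G$", 1)
        assert ref == 2  # '.' and ','
        assert alts == {"G": 1}  # indel bases and '*' are not alleles

    def test_malformed_indel_reports_line(self, index):
        with pytest.raises(StrainError, match="line 1.*indel"):
            parse_pileup("m1\t5\tA\t3\t.+X..\tIII", index)

    def test_unknown_marker_errors(self, index):
        with pytest.raises(StrainError, match="absent from index"):
            parse_pileup("zz\t5\tA\t1\t.\tI", index)

    def test_position_outside_marker(self, index):
        with pytest.raises(StrainError, match="outside"):
            parse_pileup("m1\t101\tA\t1\t.\tI", index)


class TestCallSnps:
    def rec(self, index, bases, depth, pos=5):
        return parse_pileup(f"m1\t{pos}\tA\t{depth}\t{bases}\t{'I' * depth}",
                            index)

    def test_ninety_percent_alt_called(self, index):
        prof = call_snps(self.rec(index, "GGGGGGGGG.", 10))
        assert prof.snps == {("m1", 5, "G")}

    def test_depth_gate(self, index):
        prof = call_snps(self.rec(index, "GGG", 3))
        assert prof.snps == set()
        assert 5 in prof.covered["m1"]  # still covered

    def test_half_alt_not_called(self, index):
        prof = call_snps(self.rec(index, "GGGGG.....", 10))
        assert prof.snps == set()

    def test_majority_threshold_validated(self, index):
        with pytest.raises(StrainError, match="0.5"):
            call_snps(self.rec(index, "GGGG", 4), min_alt_frac=0.4)


class TestMarkerBreadth:
    def prof(self, n_covered):
        return MarkerSNPProfile("s", {"m1": set(range(1, n_covered + 1))}, set())

    def test_boundary_is_strict(self, index):
        assert marker_breadth(self.prof(41), "m1", index) == 0.41
        assert marker_breadth(self.prof(40), "m1", index) == 0.40
        assert marker_breadth(MarkerSNPProfile("s", {}, set()), "m1", index) == 0.0


def profile(sample_id, snps, covered=None):
    markers = {m for m, _, _ in snps} | set(covered or {})
    cov = {m: set(range(1, 101)) for m in markers}
    if covered:
        cov.update({m: set(ps) for m, ps in covered.items()})
    return MarkerSNPProfile(sample_id, cov, set(snps))


class TestIdenticalSnps:
    def test_exact_match_required(self, index):
        pa = profile("a", {("m1", 5, "G")})
        pb = profile("b", {("m1", 5, "G")})
        assert identical_snps(pa, pb, index)["spX"] == {("m1", 5, "G")}
        pc = profile("c", {("m1", 5, "T")})
        assert identical_snps(pa, pc, index)["spX"] == set()

    def test_low_breadth_marker_excluded(self, index):
        pa = profile("a", {("m1", 5, "G")},
                     covered={"m1": range(1, 40)})  # breadth 0.39
        pb = profile("b", {("m1", 5, "G")})
        out = identical_snps(pa, pb, index)
        assert "spX" not in out or out["spX"] == set()

    def test_symmetric(self, index):
        rng = np.random.default_rng(0)
        snps_a = {("m1", int(p), "G") for p in rng.choice(100, 5) + 1}
        snps_b = {("m1", int(p), "G") for p in rng.choice(100, 5) + 1}
        pa, pb = profile("a", snps_a), profile("b", snps_b)
        assert identical_snps(pa, pb, index) == identical_snps(pb, pa, index)

    def test_monotone_in_breadth_min(self, index):
        pa = profile("a", {("m1", 5, "G"), ("m2", 7, "T")},
                     covered={"m2": range(1, 51)})  # m2 breadth 0.5
        pb = profile("b", {("m1", 5, "G"), ("m2", 7, "T")})
        strict = identical_snps(pa, pb, index, breadth_min=0.6)
        loose = identical_snps(pa, pb, index, breadth_min=0.4)
        assert strict.get("spX", set()) <= loose["spX"]


class TestStrainSharing:
    def call_for(self, s_u, s_v, index, **kw):
        calls = strain_sharing(profile("u", s_u), profile("v", s_v),
                               index, **kw)
        return {c.species: c for c in calls}["spX"]

    def test_contained_with_extras_is_vagina_to_uterus(self, index):
        a, b, c = ("m1", 5, "G"), ("m1", 9, "T"), ("m1", 20, "C")
        call = self.call_for({a, b}, {a, b, c}, index)
        assert call.same_strain and call.direction == "vagina_to_uterus"
        assert call.containment_u_in_v == 1.0

    def test_equal_sets_undetermined(self, index):
        a, b = ("m1", 5, "G"), ("m1", 9, "T")
        call = self.call_for({a, b}, {a, b}, index)
        assert call.same_strain and call.direction == "undetermined"

    def test_partial_overlap_not_shared(self, index):
        a, d = ("m1", 5, "G"), ("m1", 30, "A")
        b = ("m1", 9, "T")
        call = self.call_for({a, d}, {a, b}, index)
        assert call.containment_u_in_v == 0.5
        assert not call.same_strain and call.direction == "none"

    def test_reverse_direction(self, index):
        a, b, c = ("m1", 5, "G"), ("m1", 9, "T"), ("m1", 20, "C")
        call = self.call_for({a, b, c}, {a, b}, index)
        assert call.direction == "uterus_to_vagina"

    def test_empty_both_sides_distinct_status(self, index):
        cov = {"m1": range(1, 101)}
        calls = strain_sharing(profile("u", set(), covered=cov),
                               profile("v", set(), covered=cov), index)
        call = {c.species: c for c in calls}["spX"]
        assert call.status == "undetermined_by_absence"
        assert not call.same_strain

    def test_relaxed_containment(self, index):
        s_u = {("m1", p, "G") for p in (5, 9, 20, 30, 40)}
        s_v = set(list(s_u)[:4]) | {("m1", 50, "T")}
        strict = self.call_for(s_u, s_v, index, containment_min=1.0)
        relaxed = self.call_for(s_u, s_v, index, containment_min=0.8)
        assert not strict.same_strain and relaxed.same_strain


class TestEndToEnd:
    def test_noiseless_round_trip_recovers_planted_truth(self):
        species = [f"sp{i}" for i in range(6)]
        pu, pv, truth, idx = simulate_marker_snps(species, seed=1)
        cu = call_snps(parse_pileup(
            simulate_pileup(pu, idx, 30, 0.0, seed=2), idx), sample_id="u")
        cv = call_snps(parse_pileup(
            simulate_pileup(pv, idx, 30, 0.0, seed=3), idx), sample_id="v")
        assert cu.snps == pu.snps and cv.snps == pv.snps
        calls = strain_sharing(cu, cv, idx, subject_id="S1")
        for c in calls:
            planted = c.species in truth.transferred_species
            assert c.same_strain == planted
            if planted:
                assert c.direction == "vagina_to_uterus"

    def test_summary_matches_planted_ratio(self):
        species = [f"sp{i}" for i in range(6)]
        pu, pv, truth, idx = simulate_marker_snps(species, seed=4)
        calls = strain_sharing(pu, pv, idx, subject_id="S1")
        summary = cohort_strain_summary(calls)
        assert summary["fraction_shared"] == pytest.approx(
            len(truth.transferred_species) / len(species))
        assert summary["fraction_vagina_to_uterus"] == 1.0

    def test_empty_call_list_errors(self):
        with pytest.raises(StrainError):
            cohort_strain_summary([])
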