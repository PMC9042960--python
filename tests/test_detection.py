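"""Heteroplasmy filtering, ancestral inference and event detection."""

import io

import pytest

from mitorate.detection import (
    FilterDecision,
    SampleProfile,
    detect_mutation_events,
    filter_heteroplasmy,
    heteroplasmy_prevalence,
    infer_ancestral_profile,
    read_variant_table,
)
from mitorate.genome import MutationCall, parse_mutation_label
from mitorate.pedigree import Individual, MaternalLineage, Pedigree, maternal_lineages


def call(label, maf=None):
    parsed = parse_mutation_label(label)
    return MutationCall(parsed.position, parsed.ref, parsed.observed, maf=maf)


def profile(sample_id, *calls):
    return SampleProfile(sample_id=sample_id, calls=tuple(calls))


class TestFilter:
    def test_below_threshold_censored(self):
        assert filter_heteroplasmy(call("A16280R", maf=0.12)) is FilterDecision.CENSOR

    def test_at_and_above_threshold_kept(self):
        assert filter_heteroplasmy(call("T9012Y", maf=0.45)) is FilterDecision.KEEP
        assert filter_heteroplasmy(call("T9012Y", maf=0.20)) is FilterDecision.KEEP

    def test_homoplasmic_always_kept(self):
        assert filter_heteroplasmy(call("A8817G")) is FilterDecision.KEEP

    def test_missing_maf_policies(self):
        het = call("T146Y")
        with pytest.raises(ValueError, match="minor-allele"):
            filter_heteroplasmy(het)
        with pytest.warns(UserWarning):
            assert filter_heteroplasmy(het, missing_maf="lenient") is FilterDecision.KEEP


class TestAncestralInference:
    def test_shared_fixed_variant_is_ancestral(self):
        shared = call("T16189C")
        profiles = [profile(f"S{i}", shared) for i in range(3)]
        assert infer_ancestral_profile(profiles) == {shared}

    def test_variant_in_subset_is_candidate(self):
        shared = call("A73G")
        extra = call("C16320Y", maf=0.4)
        profiles = [
            profile("S1", shared, extra),
            profile("S2", shared, extra),
            profile("S3", shared),
        ]
        assert infer_ancestral_profile(profiles) == {shared}

    def test_single_member_lineage_has_no_candidates(self):
        only = profile("S1", call("A8817G"), call("T146Y", maf=0.5))
        # all homoplasmic calls of a single profile are ancestral
        assert infer_ancestral_profile([only]) == {call("A8817G")}

    def test_empty_lineage_rejected(self):
        with pytest.raises(ValueError):
            infer_ancestral_profile([])


def three_sibling_lineage():
    ped = Pedigree(
        [
            Individual("F", sex="female"),
            Individual("S1", mother_id="F", sex="female", sequenced=True),
            Individual("S2", mother_id="F", sex="female", sequenced=True),
            Individual("S3", mother_id="F", sex="male", sequenced=True),
        ]
    )
    (lineage,) = maternal_lineages(ped)
    return lineage


class TestEventDetection:
    def test_single_heteroplasmic_event(self):
        lineage = three_sibling_lineage()
        profiles = [
            profile("S1", call("T146Y", maf=0.30)),
            profile("S2"),
            profile("S3"),
        ]
        (event,) = detect_mutation_events(lineage, profiles)
        assert event.call.label == "T146Y"
        assert event.heteroplasmic
        assert event.carrier_ids == {"S1"}
        assert "HVII" in event.regions and "control" in event.regions

    def test_masked_position_yields_no_event(self):
        lineage = three_sibling_lineage()
        profiles = [
            profile("S1", call("C16193T")),
            profile("S2"),
            profile("S3"),
        ]
        assert detect_mutation_events(lineage, profiles) == []

    def test_single_origin_parsimony_merges_carriers(self):
        lineage = three_sibling_lineage()
        shared = call("A2833R", maf=0.4)
        profiles = [profile("S1", shared), profile("S2", shared), profile("S3")]
        (event,) = detect_mutation_events(lineage, profiles)
        assert event.carrier_ids == {"S1", "S2"}

    def test_variant_fixed_in_all_members_is_ancestral(self):
        lineage = three_sibling_lineage()
        shared = call("A8817G")
        profiles = [profile(s, shared) for s in ("S1", "S2", "S3")]
        assert detect_mutation_events(lineage, profiles) == []

    def test_censored_calls_logged(self):
        lineage = three_sibling_lineage()
        profiles = [
            profile("S1", call("A16280R", maf=0.12)),
            profile("S2"),
            profile("S3"),
        ]
        log = []
        events = detect_mutation_events(lineage, profiles, censored_log=log)
        assert events == []
        assert log == [("S1", call("A16280R", maf=0.12))]

    def test_missing_member_profile_rejected(self):
        lineage = three_sibling_lineage()
        with pytest.raises(ValueError, match="missing profile"):
            detect_mutation_events(lineage, [profile("S1")])

    def test_extraneous_profile_warned_and_ignored(self):
        lineage = three_sibling_lineage()
        profiles = [profile(s) for s in ("S1", "S2", "S3", "OUTSIDER")]
        with pytest.warns(UserWarning, match="non-members"):
            assert detect_mutation_events(lineage, profiles) == []

    def test_order_and_duplication_invariance(self):
        lineage = three_sibling_lineage()
        profiles = [
            profile("S1", call("T146Y", maf=0.3)),
            profile("S2", call("A8817G")),
            profile("S3"),
        ]
        forward = detect_mutation_events(lineage, profiles)
        backward = detect_mutation_events(lineage, list(reversed(profiles)))
        assert forward == backward

    @pytest.mark.parametrize("lo,hi", [(0.05, 0.20), (0.20, 0.36), (0.36, 1.0)])
    def test_event_count_monotone_in_threshold(self, study, lo, hi):
        def total(threshold):
            return sum(
                len(
                    detect_mutation_events(
                        lineage, study["profiles"], threshold=threshold
                    )
                )
                for lineage in study["lineages"]
            )

        assert total(lo) >= total(hi)


class TestStudyFixtureEvents:
    def test_nine_events_two_homoplasmic_seven_heteroplasmic(self, study):
        events = study["events"]
        assert len(events) == 9
        assert sum(not e.heteroplasmic for e in events) == 2
        assert sum(e.heteroplasmic for e in events) == 7
        assert {e.call.label for e in events} == {
            "A8470R", "A16280R", "T9012Y", "T146Y", "A2833R",
            "A8817G", "A16247G", "C16344Y", "C16320Y",
        }

    def test_three_below_threshold_mixtures_censored(self, study):
        mafs = sorted(c.maf for _, c in study["censored"])
        assert mafs == [0.12, 0.15, 0.15]
        assert {c.label for _, c in study["censored"]} == {
            "A16280R", "T9012Y", "C16320Y"
        }

    def test_prevalence_matches_study(self, study):
        prev = study["prevalence"]
        assert len(prev.het_positions) == 7
        assert (prev.n_het_individuals, prev.n_individuals) == (13, 225)
        assert round(prev.frac_individuals * 100, 2) == 5.78
        assert (prev.n_het_lineages, prev.n_lineages) == (6, 45)
        assert round(prev.frac_lineages * 100, 1) == 13.3
        assert prev.n_coding_het_lineages == 3
        assert round(prev.frac_coding_lineages * 100, 1) == 6.7


def test_variant_table_round_trip(tmp_path):
    text = (
        "sample_id\tpos\tref\tobs\tmaf\tdepth\tconfirmed\n"
        "S1\t8470\tA\tR\t0.35\t370\t1\n"
        "S1\t73\tA\tG\t\t\t\n"
        "S2\t146\tT\tY\t0.12\t\t0\n"
    )
    profiles = read_variant_table(io.StringIO(text))
    assert set(profiles) == {"S1", "S2"}
    s1 = profiles["S1"]
    assert s1.call_at(8470).maf == 0.35
    assert s1.call_at(8470).confirmed is True
    assert s1.call_at(73).maf is None
    assert profiles["S2"].call_at(146).confirmed is False


def test_duplicate_position_in_profile_rejected():
    with pytest.raises(ValueError, match="multiple calls"):
        profile("S1", call("A8817G"), call("A8817G"))


def test_vcf_reader_maps_het_genotypes_to_iupac(tmp_path):
    vcf = (
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chrM,length=16569>\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "chrM\t73\t.\tA\tG\t.\tPASS\t.\tGT:AF\t1/1:1.0\t0/1:0.35\n"
        "chrM\t8470\t.\tA\tG\t.\tPASS\t.\tGT:AF\t0/0:0.0\t0/1:0.12\n"
        "chrM\t100\t.\tA\tGT\t.\tPASS\t.\tGT:AF\t1/1:1.0\t0/0:0.0\n"  # indel: skipped
    )
    path = tmp_path / "calls.vcf"
    path.write_text(vcf)
    from mitorate.detection import read_vcf

    profiles = read_vcf(path)
    assert profiles["S1"].call_at(73).observed == "G"
    s2_73 = profiles["S2"].call_at(73)
    assert s2_73.observed == "R" and s2_73.maf == pytest.approx(0.35, abs=1e-6)
    assert profiles["S2"].call_at(8470).maf == pytest.approx(0.12, abs=1e-6)
    assert profiles["S1"].call_at(100) is None
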