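"""Pedigree reading, maternal-lineage extraction, transmission counting."""

import io

import numpy as np
import pytest

from mitorate.pedigree import (
    Individual,
    Pedigree,
    count_transmissions,
    maternal_lineages,
    read_pedigree,
)


def ped_from_text(text):
    return read_pedigree(io.StringIO(text))


class TestReading:
    def test_simple_chain(self):
        ped = ped_from_text(
            "id\tmother\tfather\tsex\tsequenced\n"
            "A\t0\t0\tfemale\t1\n"
            "B\tA\t0\tfemale\t1\n"
            "C\tB\t0\tmale\t1\n"
        )
        assert len(ped) == 3
        assert ped["C"].mother_id == "B"
        (lineage,) = maternal_lineages(ped)
        assert count_transmissions(lineage) == 2

    def test_ped_dialect_columns(self):
        ped = ped_from_text(
            "FID\tIID\tPAT\tMAT\tSEX\tsequenced\n"
            "f1\tA\t0\t0\t2\t1\n"
            "f1\tB\t0\tA\t1\t1\n"
        )
        assert ped["B"].mother_id == "A"
        assert ped["A"].sex == "female"

    def test_comments_and_whitespace_delimiters(self):
        ped = ped_from_text(
            "# a comment line\n"
            "id mother father sex sequenced\n"
            "A 0 0 female 0\n"
            "B A 0 male 1\n"
        )
        assert ped["B"].sequenced and not ped["A"].sequenced

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ped_from_text(
                "id\tmother\tfather\tsex\tsequenced\n"
                "A\t0\t0\tfemale\t1\nA\t0\t0\tmale\t0\n"
            )

    def test_dangling_mother_rejected(self):
        with pytest.raises(ValueError, match="not in pedigree"):
            ped_from_text(
                "id\tmother\tfather\tsex\tsequenced\nB\tZ\t0\tfemale\t1\n"
            )

    def test_self_parent_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            ped_from_text(
                "id\tmother\tfather\tsex\tsequenced\nA\tA\t0\tfemale\t1\n"
            )

    def test_male_mother_rejected(self):
        with pytest.raises(ValueError, match="male"):
            ped_from_text(
                "id\tmother\tfather\tsex\tsequenced\n"
                "A\t0\t0\tmale\t0\nB\tA\t0\tfemale\t1\n"
            )


class TestLineageExtraction:
    def test_founder_with_two_sequenced_daughters(self):
        ped = Pedigree(
            [
                Individual("F", sex="female"),
                Individual("D1", mother_id="F", sex="female", sequenced=True),
                Individual("D2", mother_id="F", sex="female", sequenced=True),
            ]
        )
        (lineage,) = maternal_lineages(ped)
        assert lineage.member_ids == {"D1", "D2"}
        assert lineage.n_transmissions == 2

    def test_two_unconnected_founders_give_two_lineages(self):
        ped = Pedigree(
            [
                Individual("F1", sex="female"),
                Individual("C1", mother_id="F1", sex="male", sequenced=True),
                Individual("F2", sex="female"),
                Individual("C2", mother_id="F2", sex="female", sequenced=True),
            ]
        )
        assert len(maternal_lineages(ped)) == 2

    def test_sons_children_are_not_lineage_members(self):
        # a sequenced son's children descend through their own mother
        ped = Pedigree(
            [
                Individual("F", sex="female"),
                Individual("S", mother_id="F", sex="male", sequenced=True),
                Individual("W", sex="female"),
                Individual("G", mother_id="W", father_id="S", sex="female", sequenced=True),
            ]
        )
        by_founder = {l.founder_id: l for l in maternal_lineages(ped)}
        assert by_founder["F"].member_ids == {"S"}
        assert by_founder["W"].member_ids == {"G"}

    def test_unsequenced_intermediate_counted_once(self):
        ped = Pedigree(
            [
                Individual("F", sex="female"),
                Individual("D", mother_id="F", sex="female", sequenced=False),
                Individual("G1", mother_id="D", sex="female", sequenced=True),
                Individual("G2", mother_id="D", sex="female", sequenced=True),
            ]
        )
        (lineage,) = maternal_lineages(ped)
        assert lineage.edges == {("F", "D"), ("D", "G1"), ("D", "G2")}
        assert count_transmissions(lineage) == 3

    def test_sequenced_founder_contributes_member_but_no_edge(self):
        ped = Pedigree(
            [
                Individual("F", sex="female", sequenced=True),
                Individual("D", mother_id="F", sex="female", sequenced=True),
            ]
        )
        (lineage,) = maternal_lineages(ped)
        assert lineage.member_ids == {"F", "D"}
        assert lineage.n_transmissions == 1

    def test_absent_requested_founder_rejected(self):
        ped = Pedigree([Individual("F", sex="female", sequenced=True)])
        with pytest.raises(KeyError):
            maternal_lineages(ped, founders=["nope"])

    def test_lineages_without_sequenced_members_dropped(self):
        ped = Pedigree(
            [
                Individual("F", sex="female"),
                Individual("D", mother_id="F", sex="female"),
            ]
        )
        assert maternal_lineages(ped) == []


def random_matriline_forest(rng, n_founders=3, n_extra=25):
    """Random matrilineal forest with random sequencing flags."""
    individuals = [
        Individual(f"F{i}", sex="female", sequenced=bool(rng.random() < 0.3))
        for i in range(n_founders)
    ]
    ids = [i.id for i in individuals]
    females = list(ids)
    for k in range(n_extra):
        mother = females[rng.integers(len(females))]
        female = bool(rng.random() < 0.6)
        ind = Individual(
            f"X{k}",
            mother_id=mother,
            sex="female" if female else "male",
            sequenced=bool(rng.random() < 0.5),
        )
        individuals.append(ind)
        if female:
            females.append(ind.id)
    return Pedigree(individuals)


def brute_force_transmissions(ped, lineage):
    """Independent oracle: nodes below the founder whose subtree holds a
    sequenced member each contribute exactly their incoming edge."""
    count = 0
    for node in ped.matrilineal_descendants(lineage.founder_id):
        subtree = ped.matrilineal_descendants(node) | {node}
        if any(ped[m].sequenced for m in subtree):
            count += 1
    return count


class TestTransmissionCounting:
    @pytest.mark.parametrize("seed", range(20))
    def test_edge_union_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_matriline_forest(rng)
        for lineage in maternal_lineages(ped):
            assert count_transmissions(lineage) == brute_force_transmissions(
                ped, lineage
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_adding_a_member_adds_at_least_one_edge(self, seed):
        rng = np.random.default_rng(100 + seed)
        ped = random_matriline_forest(rng)
        for lineage in maternal_lineages(ped):
            unsequenced = [
                d
                for d in ped.matrilineal_descendants(lineage.founder_id)
                if not ped[d].sequenced
            ]
            if not unsequenced:
                continue
            target = unsequenced[0]
            boosted = Pedigree(
                [
                    Individual(i.id, i.mother_id, i.father_id, i.sex,
                               i.sequenced or i.id == target)
                    for i in ped.individuals.values()
                ]
            )
            new = {l.founder_id: l for l in maternal_lineages(boosted)}
            assert new[lineage.founder_id].n_transmissions >= lineage.n_transmissions
            assert target in new[lineage.founder_id].member_ids


def test_study_fixture_totals(study):
    lineages = study["lineages"]
    assert len(lineages) == 45
    assert sum(l.n_transmissions for l in lineages) == 345
    assert sum(len(l.member_ids) for l in lineages) == 225
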