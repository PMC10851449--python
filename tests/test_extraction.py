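"""Pair construction from UMLS and OMOP, with generator and brute-force oracles."""

import pytest

from medmap import vocab_io as vio
from medmap.extraction import (
    MappedPair,
    crosscheck_with_meddra,
    extract_omop_direct,
    extract_omop_indirect,
    extract_umls_pairs,
    merge_pair_sets,
    rel_cui_concordance,
)
from medmap.synthetic import SimConfig, generate_fixture
from medmap.vocab_io import Atom, OMOPConcept, OMOPRelationship, Relationship


def _atom(cui, sab, tty, code, string="a term"):
    return Atom(cui, "ENG", sab, tty, code, string)


def brute_force_umls_pairs(atoms):
    """Independent oracle: double loop over all (MDR, ICD) atom pairs."""
    version = {"ICD9CM": 9, "ICD10CM": 10}
    keys = set()
    for m in atoms:
        if m.sab != "MDR" or m.tty not in ("PT", "LLT"):
            continue
        for i in atoms:
            if i.sab in version and i.cui == m.cui:
                keys.add((m.code, m.tty, i.code, version[i.sab]))
    return keys


class TestUMLSExtraction:
    def test_single_cui_single_pair(self):
        atoms = [_atom("C1", "MDR", "PT", "10000000"),
                 _atom("C1", "ICD9CM", "PT", "001.00")]
        pairs = extract_umls_pairs(atoms)
        assert len(pairs) == 1
        (p,) = pairs
        assert p.icd_version == 9 and p.cui == "C1" and p.provenance == {"UMLS"}

    def test_two_by_two_cross_product(self):
        atoms = [
            _atom("C1", "MDR", "PT", "10000000"),
            _atom("C1", "MDR", "LLT", "80000000"),
            _atom("C1", "ICD9CM", "PT", "001.00"),
            _atom("C1", "ICD10CM", "PT", "A01.0"),
        ]
        keys = {p.key for p in extract_umls_pairs(atoms)}
        assert keys == {
            ("10000000", "PT", "001.00", 9),
            ("10000000", "PT", "A01.0", 10),
            ("80000000", "LLT", "001.00", 9),
            ("80000000", "LLT", "A01.0", 10),
        }

    def test_non_pt_llt_meddra_atoms_ignored(self):
        atoms = [_atom("C1", "MDR", "HT", "20000000"),
                 _atom("C1", "ICD9CM", "PT", "001.00")]
        assert extract_umls_pairs(atoms) == set()

    def test_order_independence_and_idempotence(self):
        atoms = [
            _atom("C1", "MDR", "PT", "10000000"),
            _atom("C1", "ICD9CM", "PT", "001.00"),
            _atom("C2", "MDR", "LLT", "80000001"),
            _atom("C2", "ICD10CM", "PT", "B02.1"),
        ]
        forward = extract_umls_pairs(atoms)
        assert extract_umls_pairs(list(reversed(atoms))) == forward
        assert extract_umls_pairs(atoms + atoms) == forward

    def test_same_code_different_strings_one_pair(self):
        atoms = [
            _atom("C1", "MDR", "PT", "10000000", "gastric ulcer"),
            _atom("C1", "ICD9CM", "PT", "001.00", "ulcer of stomach"),
            _atom("C1", "ICD9CM", "PT", "001.00", "stomach ulcer nos"),
        ]
        assert len(extract_umls_pairs(atoms)) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_exactly_the_planted_pairs(self, tmp_path, seed):
        cfg = SimConfig(n_soc=3, n_pt_per_soc=6, seed=seed)
        truth = generate_fixture(cfg, tmp_path)
        atoms = vio.read_mrconso(tmp_path / "MRCONSO.RRF")
        extracted = {p.key for p in extract_umls_pairs(atoms)}
        assert extracted == truth.planted_umls_pairs
        assert extracted == brute_force_umls_pairs(atoms)

    def test_every_umls_pair_shares_a_cui_by_reverse_lookup(self, fixture_dir):
        d, _, _ = fixture_dir
        atoms = vio.read_mrconso(d / "MRCONSO.RRF")
        by_code = {}
        for a in atoms:
            by_code.setdefault((a.sab, a.code), set()).add(a.cui)
        for p in extract_umls_pairs(atoms):
            icd_sab = "ICD9CM" if p.icd_version == 9 else "ICD10CM"
            assert p.cui in by_code[("MDR", p.meddra_code)]
            assert p.cui in by_code[(icd_sab, p.icd_code)]


class TestOMOPExtraction:
    def _concepts(self):
        return [
            OMOPConcept(1, "pt term", "MedDRA", "PT", "10000000"),
            OMOPConcept(2, "icd term", "ICD10CM", "4-char billing code", "A01.0"),
            OMOPConcept(3, "snomed a", "SNOMED", "Clinical Finding", "400001"),
            OMOPConcept(4, "snomed b", "SNOMED", "Clinical Finding", "400002"),
        ]

    def test_direct_single_row(self):
        pairs = extract_omop_direct(
            self._concepts(), [OMOPRelationship(1, 2, "MedDRA - ICD10CM eq")]
        )
        assert {p.key for p in pairs} == {("10000000", "PT", "A01.0", 10)}
        assert next(iter(pairs)).provenance == {"OMOP_DIRECT"}

    def test_snomed_to_snomed_row_contributes_nothing(self):
        pairs = extract_omop_direct(
            self._concepts(), [OMOPRelationship(3, 4, "MedDRA - ICD10CM eq")]
        )
        assert pairs == set()

    def test_configured_id_absent_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning, match="absent"):
            pairs = extract_omop_direct(
                self._concepts(),
                [OMOPRelationship(1, 2, "MedDRA - ICD10CM eq")],
                relationship_ids={"Nonexistent rel"},
            )
        assert pairs == set()

    def test_indirect_single_chain(self):
        rels = [
            OMOPRelationship(1, 3, "MedDRA - SNOMED eq"),
            OMOPRelationship(2, 3, "Maps to"),  # ICD -> SNOMED direction
        ]
        pairs = extract_omop_indirect(self._concepts(), rels)
        assert {p.key for p in pairs} == {("10000000", "PT", "A01.0", 10)}

    def test_indirect_no_icd_attached(self):
        pairs = extract_omop_indirect(
            self._concepts(), [OMOPRelationship(1, 3, "MedDRA - SNOMED eq")]
        )
        assert pairs == set()

    def test_indirect_branching_three_icd(self):
        concepts = self._concepts() + [
            OMOPConcept(5, "icd b", "ICD9CM", "4-char billing code", "002.00"),
            OMOPConcept(6, "icd c", "ICD10CM", "4-char billing code", "B02.0"),
        ]
        rels = [
            OMOPRelationship(1, 3, "MedDRA - SNOMED eq"),
            OMOPRelationship(2, 3, "Maps to"),
            OMOPRelationship(5, 3, "Maps to"),
            OMOPRelationship(3, 6, "Maps to"),  # reverse direction accepted
        ]
        keys = {p.key for p in extract_omop_indirect(concepts, rels)}
        assert keys == {
            ("10000000", "PT", "A01.0", 10),
            ("10000000", "PT", "002.00", 9),
            ("10000000", "PT", "B02.0", 10),
        }

    @pytest.mark.parametrize("seed", range(20))
    def test_fixture_recovery_both_routes(self, tmp_path, seed):
        cfg = SimConfig(n_soc=3, n_pt_per_soc=6, frac_omop_direct=0.4,
                        frac_omop_indirect=0.3, seed=seed)
        truth = generate_fixture(cfg, tmp_path)
        concepts, rels = vio.read_omop_tables(
            tmp_path / "CONCEPT.csv", tmp_path / "CONCEPT_RELATIONSHIP.csv"
        )
        assert {p.key for p in extract_omop_direct(concepts, rels)} == truth.planted_omop_direct
        assert {p.key for p in extract_omop_indirect(concepts, rels)} == truth.planted_omop_indirect


class TestMerge:
    def _pair(self, source, icd="001.00", cui=None):
        return MappedPair("10000000", "PT", "x", icd, 9, "y",
                          frozenset({source}), cui)

    def test_same_pair_from_two_routes_merges_provenance(self):
        merged = merge_pair_sets([
            {self._pair("UMLS", cui="C1")}, {self._pair("OMOP_DIRECT")}
        ])
        assert len(merged) == 1
        (p,) = merged
        assert p.provenance == {"UMLS", "OMOP_DIRECT"} and p.cui == "C1"

    def test_disjoint_sets_add_up(self):
        a = {self._pair("UMLS", icd=f"00{i}.00", cui="C1") for i in range(3)}
        b = {self._pair("OMOP_DIRECT", icd=f"10{i}.00") for i in range(4)}
        assert len(merge_pair_sets([a, b])) == 7

    @pytest.mark.parametrize("seed", range(5))
    def test_union_never_exceeds_sum(self, tmp_path, seed):
        cfg = SimConfig(n_soc=2, n_pt_per_soc=8, frac_omop_direct=0.5, seed=seed)
        generate_fixture(cfg, tmp_path)
        atoms = vio.read_mrconso(tmp_path / "MRCONSO.RRF")
        concepts, rels = vio.read_omop_tables(
            tmp_path / "CONCEPT.csv", tmp_path / "CONCEPT_RELATIONSHIP.csv"
        )
        sets = [extract_umls_pairs(atoms), extract_omop_direct(concepts, rels),
                extract_omop_indirect(concepts, rels)]
        assert len(merge_pair_sets(sets)) <= sum(len(s) for s in sets)


class TestRelConcordance:
    def test_hand_counted_fraction(self):
        rels = [
            Relationship("C1", "C1", "RQ"),
            Relationship("C1", "C2", "RQ", "classified_as"),
            Relationship("C2", "C3", "RQ", "classified_as"),
            Relationship("C3", "C4", "RQ", "mapped_to"),
        ]
        (rq,) = rel_cui_concordance(rels, rel_labels=["RQ"])
        assert rq.n_total == 4 and rq.n_same_cui == 1
        assert rq.fraction_same_cui == 0.25
        assert rq.rela_breakdown == {"classified_as": 2, "mapped_to": 1}

    def test_empty_label_flagged_undefined(self):
        (sy,) = rel_cui_concordance([], rel_labels=["SY"])
        assert sy.n_total == 0 and not sy.defined and sy.fraction_same_cui is None

    def test_all_self_concordant(self):
        rels = [Relationship(f"C{i}", f"C{i}", "SY") for i in range(5)]
        (sy,) = rel_cui_concordance(rels, rel_labels=["SY"])
        assert sy.fraction_same_cui == 1.0


class TestCrosscheck:
    def _hierarchy(self):
        h = vio.MedDRAHierarchy(
            llt_to_pt={"100": "100"},
            pt_to_socs={"100": [("Cardiac disorders", True)]},
            pt_strings={"100": "Gastric  Ulcer"},
            llt_strings={"100": "Gastric  Ulcer"},
        )
        return h

    def test_case_and_whitespace_insensitive_retention(self):
        p = MappedPair("100", "PT", "gastric ulcer", "001.00", 9, "x",
                       frozenset({"UMLS"}), "C1")
        assert crosscheck_with_meddra({p}, self._hierarchy()) == {p}

    def test_unknown_string_dropped(self):
        p = MappedPair("100", "PT", "obsolete term", "001.00", 9, "x",
                       frozenset({"UMLS"}), "C1")
        assert crosscheck_with_meddra({p}, self._hierarchy()) == set()

    def test_official_code_attached_when_source_code_differs(self):
        p = MappedPair("999", "PT", "gastric ulcer", "001.00", 9, "x",
                       frozenset({"UMLS"}), "C1")
        (out,) = crosscheck_with_meddra({p}, self._hierarchy())
        assert out.meddra_code == "100"

    def test_planted_obsolete_strings_all_dropped(self, fixture_dir):
        d, _, _ = fixture_dir
        hierarchy = vio.read_meddra_hierarchy(d / "llt.asc", d / "pt.asc")
        atoms = vio.read_mrconso(d / "MRCONSO.RRF")
        pairs = extract_umls_pairs(atoms)
        # plant k pairs with strings absent from the release
        import dataclasses
        obsolete = {
            dataclasses.replace(p, meddra_string=f"retired term {i}",
                                meddra_code=f"99{i:06d}")
            for i, p in enumerate(sorted(pairs, key=lambda p: p.key)[:3])
        }
        kept = crosscheck_with_meddra(pairs | obsolete, hierarchy)
        assert kept == crosscheck_with_meddra(pairs, hierarchy)
        assert len((pairs | obsolete) - kept) >= 3
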