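import math

import numpy as np
import pytest

from peppinet.dataset_builder import (
    Atom,
    Residue,
    build_dataset,
    filter_nonstandard,
    filter_pairs_nonstandard,
    label_complex,
    parse_structure,
    residue_contact,
    sample_negatives,
)
from peppinet.sequence_io import PairExample, SequenceRecord
from peppinet.synthetic import (
    ComplexPlan,
    PlannedContact,
    default_structure_suite,
    gen_toy_structures,
)


def _res(number, *atoms):
    return Residue("GLY", number, atoms=tuple(Atom(n, c) for n, c in atoms))


class TestResidueContact:
    def test_calpha_within_threshold(self):
        a = _res(1, ("CA", (0.0, 0.0, 0.0)))
        b = _res(2, ("CA", (0.0, 0.0, 4.0)))
        v = residue_contact(a, b)
        assert v.verdict == "interacting" and v.basis == "calpha"
        assert v.distance == pytest.approx(4.0)

    def test_exact_boundary_is_non_binding(self):
        a = _res(1, ("CA", (0.0, 0.0, 0.0)))
        b = _res(2, ("CA", (0.0, 0.0, 5.0)))
        assert residue_contact(a, b).verdict == "non_binding"

    def test_nearest_atom_fallback(self):
        a = _res(1, ("CA", (0.0, 0.0, 0.0)), ("CB", (1.0, 0.0, 0.0)))
        b = _res(2, ("CB", (4.0, 0.0, 0.0)))  # no Calpha
        v = residue_contact(a, b)
        assert v.basis == "nearest_atom"
        assert v.distance == pytest.approx(3.0)
        assert v.verdict == "interacting"

    def test_missing_coordinates_non_binding(self):
        a = _res(1, ("CA", (0.0, 0.0, 0.0)))
        b = Residue("GLY", 2, atoms=())
        v = residue_contact(a, b)
        assert v.verdict == "non_binding" and v.basis == "missing_coordinates"

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = _res(1, ("CA", tuple(rng.uniform(-5, 5, 3))))
            b = _res(2, ("CB", tuple(rng.uniform(-5, 5, 3))))
            va, vb = residue_contact(a, b), residue_contact(b, a)
            assert va.verdict == vb.verdict and va.basis == vb.basis


class TestParseAndLabel:
    def test_toy_file_chain_counts(self, tmp_path):
        plans = [ComplexPlan("c1", 4, 9, (PlannedContact(1, 2, 4.0),))]
        (path,), _ = gen_toy_structures(plans, tmp_path)
        s = parse_structure(path)
        assert [c.chain_id for c in s.chains] == ["A", "B"]
        assert (len(s.chains[0]), len(s.chains[1])) == (4, 9)

    def test_altloc_resolved_to_single_atom(self, tmp_path):
        plans = [ComplexPlan("c2", 3, 6, with_altloc=True)]
        (path,), _ = gen_toy_structures(plans, tmp_path)
        s = parse_structure(path)
        first = s.chains[0].residues[0]
        assert len(first.atoms) == 1  # highest-occupancy altloc kept
        assert first.atoms[0].coord == (0.0, 0.0, 0.0)

    def test_coordinates_round_trip_against_plan(self, tmp_path):
        plans = [ComplexPlan("c3", 5, 8, (PlannedContact(2, 4, 4.25),))]
        (path,), _ = gen_toy_structures(plans, tmp_path)
        s = parse_structure(path)
        ca_pep = s.chains[0].residues[2].calpha
        ca_prot = next(r for r in s.chains[1].residues if r.number == 5).calpha
        d = math.dist(ca_pep.coord, ca_prot.coord)
        assert d == pytest.approx(4.25, abs=1e-3)

    def test_label_complex_positive_and_negative(self, tmp_path):
        plans = [
            ComplexPlan("pos", 4, 9, (PlannedContact(1, 2, 4.0),)),
            ComplexPlan("neg", 4, 9, (PlannedContact(1, 2, 8.0),)),
        ]
        paths, _ = gen_toy_structures(plans, tmp_path)
        res_pos = label_complex(parse_structure(paths[0]))
        res_neg = label_complex(parse_structure(paths[1]))
        assert len(res_pos.positives) == 1
        assert res_pos.positives[0].peptide_id == "pos_A"
        assert res_neg.positives == ()

    def test_rejection_reasons(self, tmp_path):
        plans = [ComplexPlan("long", 30, 40)]
        (path,), _ = gen_toy_structures(plans, tmp_path)
        out = label_complex(parse_structure(path), peptide_max_len=10)
        assert out.rejection_reason is not None
        assert "length" in out.rejection_reason


class TestFiltersAndNegatives:
    def test_nonstandard_filter_boundary(self):
        drop = SequenceRecord("d", "XXX" + "A" * 7, "peptide")  # 30%
        keep_edge = SequenceRecord("e", "XX" + "A" * 8, "peptide")  # exactly 20%
        keep = SequenceRecord("k", "A" * 10, "peptide")
        kept = filter_nonstandard([drop, keep_edge, keep])
        assert [r.id for r in kept] == ["e", "k"]

    def test_pair_filter_drops_on_either_member(self):
        records = [
            SequenceRecord("p1", "XXXAAAAAAA", "peptide"),
            SequenceRecord("q1", "M" * 30, "protein"),
            SequenceRecord("p2", "AAAA", "peptide"),
        ]
        pairs = [PairExample("p1", "q1", 1), PairExample("p2", "q1", 1)]
        assert filter_pairs_nonstandard(pairs, records) == [pairs[1]]

    def test_sample_negatives_contract(self):
        peptides = [SequenceRecord(f"p{i}", "AAAA", "peptide") for i in range(6)]
        proteins = [SequenceRecord(f"q{i}", "M" * 20, "protein") for i in range(6)]
        positives = [PairExample(f"p{i}", f"q{i}", 1) for i in range(6)]
        neg = sample_negatives(positives, peptides, proteins, seed=5)
        assert len(neg) == len(positives)
        assert all(n.label == 0 for n in neg)
        pos_set = {(p.peptide_id, p.protein_id) for p in positives}
        neg_set = {(n.peptide_id, n.protein_id) for n in neg}
        assert not pos_set & neg_set and len(neg_set) == len(neg)
        assert neg == sample_negatives(positives, peptides, proteins, seed=5)
        with pytest.raises(ValueError):
            sample_negatives(positives, peptides[:1], proteins[:1], seed=5, n=5)


def test_full_suite_matches_truth_table(tmp_path):
    """End-to-end: builder verdicts on the generated suite equal the plan."""
    plans = default_structure_suite()
    paths, truths = gen_toy_structures(plans, tmp_path)
    structures = {p.stem: parse_structure(p) for p in paths}
    for t in truths:
        s = structures[t.complex_id]
        pep = s.chains[0]
        prot = s.chains[1]
        res_a = next(r for r in pep.residues if r.number == t.pep_pos + 1)
        res_b = next(
            (r for r in prot.residues if r.number == t.prot_pos + 1), None
        )
        if res_b is None:  # unresolved residue: no coordinates in the file
            assert t.kind == "missing_coords" and not t.expect_interacting
            continue
        v = residue_contact(res_a, res_b)
        assert (v.verdict == "interacting") == t.expect_interacting, t
        assert v.basis == t.expect_basis


def test_build_dataset_positive_count_equals_planted(tmp_path):
    """Positives surviving the non-standard filter match the plan exactly."""
    plans = default_structure_suite()
    paths, truths = gen_toy_structures(plans, tmp_path)
    records, pairs = build_dataset(paths, seed=11)
    positives = [p for p in pairs if p.label == 1]
    negatives = [p for p in pairs if p.label == 0]
    interacting_complexes = {t.complex_id for t in truths if t.expect_interacting}
    filtered = {"cplx_filtered"}  # 30% non-standard peptide
    assert {p.source for p in positives} == interacting_complexes - filtered
    assert len(negatives) == len(positives)
    ids = {r.id for r in records}
    for p in pairs:
        assert p.peptide_id in ids and p.protein_id in ids
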