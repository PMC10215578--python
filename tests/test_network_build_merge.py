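"""KGML reading, database building, overlaps, merging and the gate."""

import logging

import pytest

from gemcurate.fixtures import FixtureSpec, corrupt, generate_truth_network, write_fixture
from gemcurate.mass_balance import balance
from gemcurate.metabolite_id import MatchConfig
from gemcurate.model import MetaboliteEntity, ReactionEntity
from gemcurate.network_build_merge import (
    build_database,
    find_overlaps,
    merge,
    merge_with_gate,
    read_kgml,
)
from gemcurate.network_build_merge import (
    test_stoichiometric_consistency as stoichiometric_consistency,  # noqa: renamed so pytest does not collect it
)
from conftest import networks_equal, toy_network


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(seed=8, n_reactions=30, duplicate_rate=0.1)
    truth, corrupted, catalogs, truth_map = write_fixture(out, spec)
    return out, spec, truth, corrupted, catalogs, truth_map


class TestKgml:
    def test_pathway_files_parse(self, fixture_dir):
        out, spec, truth, *_ = fixture_dir
        reactions = read_kgml(out / "pathways" / "path1.xml")
        assert reactions
        for kr in reactions:
            assert kr.reaction_id in truth.reactions
            assert kr.ec_numbers == truth.reactions[kr.reaction_id].ec_numbers

    def test_unknown_compound_entry_skipped(self, tmp_path, caplog):
        bad = tmp_path / "bad.xml"
        bad.write_text(
            '<?xml version="1.0"?><pathway name="path:x" org="x" number="1" title="x">'
            '<entry id="1" name="cpd:C1" type="compound"/>'
            '<reaction id="9" name="rn:R1" type="irreversible">'
            '<substrate id="1" name="cpd:C1"/><product id="2" name="cpd:GHOST"/>'
            "</reaction></pathway>"
        )
        with caplog.at_level(logging.WARNING):
            assert read_kgml(bad) == []
        assert "unknown compound" in caplog.text


class TestBuildDatabase:
    def test_shared_reactions_appear_once(self, fixture_dir):
        out, spec, truth, corrupted, catalogs, _ = fixture_dir
        files = sorted((out / "pathways").glob("*.xml"))
        db = build_database(files, catalogs.metabolites, catalogs.associations,
                            catalogs.locations)
        # the generator plants the first two internal reactions in all maps
        kgml_ids = set()
        for f in files:
            kgml_ids |= {kr.reaction_id for kr in read_kgml(f)}
        base_ids = {rid for rid in db.reactions if "__" not in rid}
        assert base_ids == kgml_ids  # each once, despite sharing

    def test_empty_pathway_list_gives_empty_network(self, fixture_dir):
        _, _, _, _, catalogs, _ = fixture_dir
        db = build_database([], catalogs.metabolites, catalogs.associations,
                            catalogs.locations)
        assert not db.reactions and not db.metabolites

    def test_metabolites_enriched_and_reactions_balanced(self, fixture_dir):
        out, spec, truth, corrupted, catalogs, _ = fixture_dir
        files = sorted((out / "pathways").glob("*.xml"))
        db = build_database(files, catalogs.metabolites, catalogs.associations,
                            catalogs.locations)
        assert all(
            "PubChem" in m.xrefs
            for m in db.metabolites.values()
            if m.compartment_id == "c" and "KEGG" in m.xrefs
        )
        for r in db.reactions.values():
            if r.is_boundary:
                continue
            out_b = balance(r, db)
            # everything fixable was fixed at build time; what remains is
            # classified unbalanceable (the planted coupled half-reactions)
            assert out_b.status in ("already_balanced", "unbalanceable"), r.id
            if out_b.status == "unbalanceable":
                assert out_b.reason != "none"

    def test_isoenzyme_compartment_copies_with_local_gprs(self, fixture_dir):
        out, spec, truth, corrupted, catalogs, _ = fixture_dir
        files = sorted((out / "pathways").glob("*.xml"))
        db = build_database(files, catalogs.metabolites, catalogs.associations,
                            catalogs.locations)
        copies = [rid for rid in db.reactions if "__m" in rid]
        assert copies  # the fixture plants mitochondrial isoenzymes
        for rid in copies:
            r = db.reactions[rid]
            assert all(
                db.metabolites[m].compartment_id == "m"
                for m, _, _ in r.participants()
            )


class TestOverlapsAndMerge:
    def test_identical_networks_pair_everything(self, fixture_dir):
        _, _, truth, *_ = fixture_dir
        ov = find_overlaps(truth, truth)
        assert ov.counts["metabolites"] == len(truth.metabolites)
        assert ov.counts["reactions"] == len(truth.reactions)
        assert ov.counts["genes"] == len(truth.genes)

    def test_disjoint_networks_empty_report(self):
        a = toy_network({"a": "C2H4"})
        b = toy_network({"zz": "N2"})
        ov = find_overlaps(a, b)
        assert ov.counts == {"metabolites": 0, "reactions": 0, "genes": 0}

    def test_planted_synonym_metabolites_paired(self, fixture_dir):
        _, _, truth, *_ = fixture_dir
        b = toy_network({})
        planted = []
        for mid in sorted(truth.metabolites)[:5]:
            met = truth.metabolites[mid]
            if met.compartment_id != "c" or not met.synonyms:
                continue
            b.add_metabolite(
                MetaboliteEntity(f"other_{mid}", met.synonyms[0], "c",
                                 met.composition, [], {})
            )
            planted.append((mid, f"other_{mid}"))
        assert planted
        ov = find_overlaps(truth, b)
        got = {(a_, b_) for a_, b_, _ in ov.metabolite_pairs}
        assert set(planted) <= got

    def test_merge_size_identity(self, fixture_dir):
        _, spec, truth, corrupted, catalogs, _ = fixture_dir
        ov = find_overlaps(truth, corrupted)
        merged = merge(truth, corrupted, ov)
        for cls, a_len, b_len in [
            ("metabolites", len(truth.metabolites), len(corrupted.metabolites)),
            ("reactions", len(truth.reactions), len(corrupted.reactions)),
            ("genes", len(truth.genes), len(corrupted.genes)),
        ]:
            assert len(getattr(merged, cls)) == a_len + b_len - ov.counts[cls]

    def test_merge_with_itself_is_identity_up_to_annotation_unions(self, fixture_dir):
        _, _, truth, *_ = fixture_dir
        merged = merge(truth, truth, find_overlaps(truth, truth))
        assert set(merged.metabolites) == set(truth.metabolites)
        assert set(merged.reactions) == set(truth.reactions)
        assert set(merged.genes) == set(truth.genes)

    def test_disjoint_merge_sizes_add(self):
        a = toy_network({"a": "C2H4", "b": "CH2"})
        a.add_reaction(ReactionEntity("r1", substrates={"a": 1}, products={"b": 2}))
        b = toy_network({"x": "N2", "y": "N"})
        b.add_reaction(ReactionEntity("r2", substrates={"x": 1}, products={"y": 2}))
        merged = merge(a, b, find_overlaps(a, b))
        assert len(merged.metabolites) == 4 and len(merged.reactions) == 2


class TestConsistency:
    def test_balanced_fixture_consistent_with_positive_witness(self, fixture_dir):
        _, _, truth, *_ = fixture_dir
        res = stoichiometric_consistency(truth)
        assert res.consistent
        assert all(v >= 1.0 - 1e-9 for v in res.witness_masses.values())

    def test_mass_balanced_networks_always_pass(self):
        """Cross-module property: atomic masses witness any network whose
        internal reactions pass the balance check."""
        for seed in (1, 2):
            net, _ = generate_truth_network(
                FixtureSpec(seed=seed, n_reactions=20, include_coupled=False)
            )
            for r in net.reactions.values():
                if not r.is_boundary:
                    assert balance(r, net, allow_additions=False).status == "already_balanced"
            assert stoichiometric_consistency(net).consistent

    def test_leak_reaction_inconsistent(self):
        n = toy_network({"a": "C2H4", "b": "CH2"})
        n.add_reaction(ReactionEntity("r", substrates={"a": 1}, products={"b": 2}))
        n.add_reaction(ReactionEntity("leak", substrates={"a": 1}, products={}))
        res = stoichiometric_consistency(n)
        assert not res.consistent and "a" in res.inconsistent_metabolites

    def test_autocatalytic_reaction_inconsistent(self):
        n = toy_network({"a": "C2H4"})
        n.add_reaction(ReactionEntity("auto", substrates={"a": 1}, products={"a": 2}))
        res = stoichiometric_consistency(n)
        assert not res.consistent and "a" in res.inconsistent_metabolites

    def test_boundary_reactions_excluded(self):
        n = toy_network({"a": "C2H4"})
        n.add_reaction(ReactionEntity("ex", substrates={"a": 1}, products={},
                                      kind="exchange"))
        assert stoichiometric_consistency(n).consistent


class TestGate:
    def test_balanced_inputs_nothing_quarantined(self, fixture_dir):
        _, _, truth, *_ = fixture_dir
        b = toy_network({"q1": "C3H6", "q2": "CH2"})
        b.add_reaction(ReactionEntity("rq", substrates={"q1": 1}, products={"q2": 3}))
        gated, report = merge_with_gate(truth, b)
        assert report["quarantined"] == [] and report["final_consistent"]

    def test_planted_leak_quarantined_exactly(self, fixture_dir):
        _, _, truth, *_ = fixture_dir
        b = toy_network({"q1": "C3H6", "q2": "CH2"})
        b.add_reaction(ReactionEntity("rq", substrates={"q1": 1}, products={"q2": 3}))
        b.add_reaction(ReactionEntity("rleak", substrates={"q1": 1}, products={}))
        gated, report = merge_with_gate(truth, b)
        assert report["quarantined"] == ["rleak"]
        assert "rleak" not in gated.reactions and "rq" in gated.reactions
        assert stoichiometric_consistency(gated).consistent

    def test_repeated_merge_adds_nothing(self, fixture_dir):
        _, _, truth, *_ = fixture_dir
        b = toy_network({"q1": "C3H6", "q2": "CH2"})
        b.add_reaction(ReactionEntity("rq", substrates={"q1": 1}, products={"q2": 3}))
        once, _ = merge_with_gate(truth, b)
        twice, report2 = merge_with_gate(once, b)
        assert set(twice.reactions) == set(once.reactions)
        assert set(twice.metabolites) == set(once.metabolites)
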