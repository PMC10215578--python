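"""LCS similarity, formula neutralization, identification and enrichment."""

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from gemcurate.fixtures import FixtureSpec, corrupt, generate_truth_network, _typo
from gemcurate.formula import ElementComposition, parse_formula
from gemcurate.metabolite_id import (
    CatalogEntry,
    MatchConfig,
    enrich_annotations,
    identify_metabolite,
    lcs_length,
    neutralize_formula,
    similarity_score,
)
from gemcurate.model import MetaboliteEntity


def brute_lcs(a: str, b: str) -> int:
    """Cubic brute force over all substring pairs (oracle)."""
    best = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            if a[i:j] in b:
                best = max(best, j - i)
    return best


class TestLcs:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("glucose", "glucose", 7),
            ("", "anything", 0),
            ("D-glucose", "glucose 6-phosphate", 7),
            ("abc", "xyz", 0),
        ],
    )
    def test_examples_match_brute_force(self, a, b, expected):
        assert lcs_length(a, b) == expected == brute_lcs(a, b)

    @given(st.text(alphabet="abcde-", max_size=25), st.text(alphabet="abcde-", max_size=25))
    @settings(max_examples=300, derandomize=True)
    def test_agrees_with_brute_force_and_symmetric(self, a, b):
        got = lcs_length(a, b)
        assert got == brute_lcs(a, b)
        assert got == lcs_length(b, a)


class TestSimilarity:
    def test_identity_is_one(self):
        assert similarity_score("ATP", "ATP") == 1.0

    def test_one_substitution(self):
        assert similarity_score("ATP", "GTP") == pytest.approx(2 / 3)

    def test_no_common_run_is_zero(self):
        assert similarity_score("Water", "H2O") == 0.0

    def test_both_empty_defined_zero(self):
        assert similarity_score("", "") == 0.0

    def test_normalization_folds_case_and_whitespace(self):
        assert similarity_score("  D-Glucose ", "d-glucose") == 1.0

    @given(st.text(max_size=30), st.text(max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_symmetry_identity(self, a, b):
        s = similarity_score(a, b)
        assert 0.0 <= s <= 1.0
        assert s == similarity_score(b, a)
        norm = lambda t: " ".join(t.split()).casefold()
        if norm(a) == norm(b) and norm(a):
            assert s == 1.0
        elif s == 1.0:
            assert norm(a) == norm(b)


class TestNeutralize:
    def test_anion_gains_hydrogen(self):
        c = ElementComposition({"C": Fraction(3), "H": Fraction(3), "O": Fraction(3)}, -1)
        n = neutralize_formula(c)
        assert dict(n.counts) == {"C": 3, "H": 4, "O": 3} and n.charge == 0

    def test_neutral_unchanged_and_idempotent(self):
        c = parse_formula("C6H12O6")
        assert neutralize_formula(c) == c
        anion = parse_formula("C3H3O3-")
        assert neutralize_formula(neutralize_formula(anion)) == neutralize_formula(anion)

    def test_cation_without_hydrogens_clamps(self):
        c = ElementComposition({}, 1)
        n = neutralize_formula(c)
        assert n.charge == 0 and "H" not in n.counts


CATALOG = [
    CatalogEntry("CAT1", ("D-glucose", "dextrose"), parse_formula("C6H12O6"),
                 {"KEGG": "C00031", "ChEBI": "CHEBI:17634"}),
    CatalogEntry("CAT2", ("water", "H2O"), parse_formula("H2O"), {"KEGG": "C00001"}),
    CatalogEntry("CAT3", ("pyruvate",), parse_formula("C3H3O3-"), {"KEGG": "C00022"}),
]


def met(name, formula="", mid="q", xrefs=None):
    return MetaboliteEntity(mid, name, "c", parse_formula(formula), [], xrefs or {})


class TestIdentify:
    def test_exact_synonym_scores_one_on_name_basis(self):
        m = identify_metabolite(met("dextrose"), CATALOG)
        assert m.catalog_id == "CAT1" and m.score == 1.0 and m.basis == "name"

    def test_single_typo_still_identified_at_default_threshold(self):
        m = identify_metabolite(met("D-glucosa", "C6H12O6"), CATALOG)
        assert m.catalog_id == "CAT1"

    def test_nonsense_name_without_formula_unmatched(self):
        m = identify_metabolite(met("zzzzqqqq"), CATALOG)
        assert not m.matched and m.catalog_id is None

    def test_formula_fallback_after_name_miss(self):
        # neutral form of pyruvate anion matches CAT3's neutralized formula
        m = identify_metabolite(met("mystery acid", "C3H4O3"), CATALOG)
        assert m.catalog_id == "CAT3" and m.basis == "formula"

    def test_threshold_monotonicity(self):
        queries = [met("D-glucos"), met("watr"), met("pyr"), met("xyz")]
        matched = {}
        for t in (0.1, 0.6, 0.8):
            cfg = MatchConfig(threshold=t, use_formula=False)
            matched[t] = {
                q.name for q in queries
                if identify_metabolite(q, CATALOG, cfg).matched
            }
        assert matched[0.8] <= matched[0.6] <= matched[0.1]


class TestRobustnessAcrossThresholds:
    def test_correct_match_sets_overlap_across_thresholds(self):
        """Corrupted 200-name corpus: identification is threshold-robust.

        The corpus uses compound-style names (length >= 8, like real
        database names) with unique neutralized formulas: isomers sharing
        a formula are inherently ambiguous for any string-based fallback
        and are excluded from the robustness analog.
        """
        from collections import Counter

        from gemcurate.formula import format_formula

        net, catalogs = generate_truth_network(FixtureSpec(seed=13, n_reactions=150))
        fkey = lambda e: format_formula(neutralize_formula(e.composition))
        fcounts = Counter(fkey(e) for e in catalogs.metabolites)
        entries = [
            e for e in catalogs.metabolites
            if len(e.names[0]) >= 8 and fcounts[fkey(e)] == 1
        ][:200]
        assert len(entries) == 200
        rng = random.Random(99)
        queries = []
        for e in entries:
            queries.append(
                (e.catalog_id, met(_typo(rng, e.names[0]), mid=e.catalog_id))
            )
        for q, entry in zip(queries, entries):
            q[1].composition = entry.composition
        correct = {}
        for t in (0.1, 0.6, 0.7, 0.8, 0.82):
            cfg = MatchConfig(threshold=t)
            correct[t] = {
                cid for cid, q in queries
                if identify_metabolite(q, entries, cfg).catalog_id == cid
            }
        thresholds = sorted(correct)
        for i, t1 in enumerate(thresholds):
            for t2 in thresholds[i + 1 :]:
                a, b = correct[t1], correct[t2]
                overlap = len(a & b) / max(1, len(a | b))
                assert overlap >= 0.99, (t1, t2, overlap)


class TestEnrichment:
    def test_missing_xrefs_added(self, small_fixture):
        _, truth, catalogs, _, _ = small_fixture
        # truth model metabolites carry only KEGG (+ sometimes ChEBI);
        # catalog has PubChem for all
        missing = sum(
            1 for m in truth.metabolites.values()
            if "PubChem" not in m.xrefs and m.xrefs.get("KEGG")
        )
        assert missing > 0
        enriched, report = enrich_annotations(truth, catalogs.metabolites)
        assert report.added.get("PubChem", 0) >= missing * 0.9
        assert all(
            "PubChem" in m.xrefs
            for m in enriched.metabolites.values()
            if "KEGG" in m.xrefs and m.compartment_id == "c"
        )

    def test_wrong_xref_corrected_to_catalog_value(self, small_fixture):
        _, truth, catalogs, corrupted, truth_map = small_fixture
        enriched, report = enrich_annotations(corrupted, catalogs.metabolites)
        by_cat = {e.catalog_id: e for e in catalogs.metabolites}
        for entry in truth_map:
            if entry["kind"] != "wrong_xref" or not entry["recoverable"]:
                continue
            fixed = enriched.metabolites[entry["metabolite"]]
            assert fixed.xrefs[entry["source"]] == entry["correct"]
        assert report.corrected.get("KEGG", 0) >= sum(
            1 for e in truth_map
            if e["kind"] == "wrong_xref" and e["recoverable"]
        )

    def test_already_annotated_network_unchanged(self):
        from gemcurate.model import Compartment, MetabolicNetwork

        n = MetabolicNetwork()
        n.add_compartment(Compartment("c"))
        n.add_metabolite(
            MetaboliteEntity("glc", "D-glucose", "c", parse_formula("C6H12O6"),
                             [], {"KEGG": "C00031", "ChEBI": "CHEBI:17634"})
        )
        enriched, report = enrich_annotations(n, CATALOG)
        assert not report.added and not report.corrected
        assert enriched.metabolites["glc"].xrefs == n.metabolites["glc"].xrefs
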