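import pytest

from gemcurate.fixtures import FixtureSpec, corrupt, generate_truth_network
from gemcurate.formula import parse_formula
from gemcurate.model import (
    Compartment,
    MetaboliteEntity,
    MetabolicNetwork,
    ReactionEntity,
)


def toy_network(compositions: dict[str, str], compartment: str = "c") -> MetabolicNetwork:
    """Minimal single-compartment network from id -> formula strings."""
    n = MetabolicNetwork("toy")
    n.add_compartment(Compartment(compartment, "cytosol", "GO:0005829"))
    for mid, formula in compositions.items():
        n.add_metabolite(
            MetaboliteEntity(mid, mid, compartment, parse_formula(formula))
        )
    return n


@pytest.fixture
def make_toy_network():
    return toy_network


@pytest.fixture(scope="session")
def small_fixture():
    """Seeded 30-reaction fixture with all corruption classes enabled."""
    spec = FixtureSpec(seed=5, n_reactions=30, duplicate_rate=0.1)
    truth, catalogs = generate_truth_network(spec)
    corrupted, truth_map = corrupt(truth, catalogs, spec)
    return spec, truth, catalogs, corrupted, truth_map


def networks_equal(a: MetabolicNetwork, b: MetabolicNetwork) -> bool:
    """Structural equality up to ordering (used for round-trip checks)."""
    if set(a.compartments) != set(b.compartments):
        return False
    for cid, ca in a.compartments.items():
        cb = b.compartments[cid]
        if (ca.name, ca.go_term) != (cb.name, cb.go_term):
            return False
    if set(a.metabolites) != set(b.metabolites):
        return False
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        if (
            ma.name != mb.name
            or ma.compartment_id != mb.compartment_id
            or ma.composition != mb.composition
            or sorted(ma.synonyms) != sorted(mb.synonyms)
            or ma.xrefs != mb.xrefs
        ):
            return False
    if set(a.genes) != set(b.genes):
        return False
    for gid, ga in a.genes.items():
        gb = b.genes[gid]
        if ga.symbol != gb.symbol or ga.xrefs != gb.xrefs:
            return False
    if set(a.reactions) != set(b.reactions):
        return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        gpr_a = ra.gpr.to_string() if ra.gpr else None
        gpr_b = rb.gpr.to_string() if rb.gpr else None
        if (
            ra.name != rb.name
            or ra.substrates != rb.substrates
            or ra.products != rb.products
            or ra.reversible != rb.reversible
            or ra.ec_numbers != rb.ec_numbers
            or ra.kind != rb.kind
            or gpr_a != gpr_b
            or ra.xrefs != rb.xrefs
        ):
            return False
    return True


@pytest.fixture
def assert_networks_equal():
    def check(a, b):
        assert networks_equal(a, b)

    return check
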