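"""Shared fixtures: hand-built genealogies and small cached simulations."""

import pytest
import tskit

from fstrat.genealogy import GenealogySequence, PopulationAssignment
from fstrat import simstudy


def build_two_leaf(tmrca=100.0, L=1e6):
    """Two haploid samples coalescing at ``tmrca``."""
    t = tskit.TableCollection(sequence_length=L)
    a = t.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0)
    b = t.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0)
    r = t.nodes.add_row(time=tmrca)
    t.edges.add_row(0, L, r, a)
    t.edges.add_row(0, L, r, b)
    return GenealogySequence(t.tree_sequence(), ["s1", "s2"])


def build_balanced_four(L=1e6, with_mutations=True):
    """((s1,s2),(s3,s4)): cherries at 50 and 60, root at 100 generations."""
    t = tskit.TableCollection(sequence_length=L)
    for _ in range(4):
        t.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0)
    u = t.nodes.add_row(time=50.0)
    v = t.nodes.add_row(time=60.0)
    r = t.nodes.add_row(time=100.0)
    for child, parent in [(0, u), (1, u), (2, v), (3, v), (u, r), (v, r)]:
        t.edges.add_row(0, L, parent, child)
    if with_mutations:
        for pos, node in [(1000, 0), (250000, u), (700000, v), (999000, 3)]:
            site = t.sites.add_row(position=pos, ancestral_state="A")
            t.mutations.add_row(site=site, node=node, derived_state="G")
    t.sort()
    return GenealogySequence(t.tree_sequence(), ["s1", "s2", "s3", "s4"])


@pytest.fixture
def two_leaf():
    return build_two_leaf()


@pytest.fixture
def balanced_four():
    return build_balanced_four()


@pytest.fixture
def two_pop_assignment():
    return PopulationAssignment({"s1": "A", "s2": "B"})


@pytest.fixture(scope="session")
def f4ratio_sim():
    """One 20-Mb two-way-admixture replicate (alpha = 0.3, split 500)."""
    cfg = simstudy.build_scenario("f4ratio", sequence_length=20e6)
    g = simstudy.simulate(cfg, 424242)
    return cfg, g, simstudy.scenario_assignment(g)


@pytest.fixture(scope="session")
def f4ratio_outgroups_sim():
    """As f4ratio but with two extra outgroup populations for qpAdm/qpWave."""
    cfg = simstudy.build_scenario(
        "f4ratio", sequence_length=20e6, extra_outgroups=2
    )
    g = simstudy.simulate(cfg, 515151)
    return cfg, g, simstudy.scenario_assignment(g)


@pytest.fixture(scope="session")
def f4ratio_tiny_sim():
    """A 2-Mb replicate, small enough for per-tree reference computations."""
    cfg = simstudy.build_scenario("f4ratio", sequence_length=2e6)
    g = simstudy.simulate(cfg, 616161)
    return cfg, g, simstudy.scenario_assignment(g)


@pytest.fixture(scope="session")
def panmictic_sim():
    cfg = simstudy.build_scenario("panmictic", sequence_length=2e6)
    g = simstudy.simulate(cfg, 77)
    return cfg, g
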