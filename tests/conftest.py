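import pytest

from ervkit import classify, simulate


@pytest.fixture(scope="session")
def base_template():
    return simulate.make_template(seed=1)


@pytest.fixture(scope="session")
def subgroup_templates(base_template):
    return simulate.make_subgroup_templates(base_template, seed=2)


@pytest.fixture(scope="session")
def pbs_library():
    return simulate.load_pbs_library()


@pytest.fixture(scope="session")
def sim_result():
    """Default two-species simulation shared by classification/phylo tests."""
    return simulate.make_genome(seed=5)


@pytest.fixture(scope="session")
def sim_references(sim_result):
    return classify.References.from_template(sim_result.templates["base"])


@pytest.fixture(scope="session")
def sim_candidates(sim_result, sim_references):
    return {
        sp: classify.scan_genome(sim_result.genomes[sp], sim_references, contig=sp)
        for sp in sim_result.params.species
    }


def best_overlap_call(calls, start, end):
    """The classified candidate overlapping [start, end) the most."""
    best, best_ov = None, 0
    for cl in calls:
        iv = cl.locus.interval
        ov = min(iv.end, end) - max(iv.start, start)
        if ov > best_ov:
            best_ov, best = ov, cl
    return best
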