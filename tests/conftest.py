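import numpy as np
import pytest

import piscisel as ps
from piscisel.site_model_inference import SiteClassModel
from piscisel.synthetic_evolution import SimulationSpec, simulate_alignment

TEN_TAXON_NEWICK = (
    "((a:0.12,b:0.09):0.08,(c:0.11,(d:0.07,e:0.05):0.06):0.04,"
    "((f:0.10,g:0.08):0.05,(h:0.06,(i:0.04,j:0.05):0.07):0.06):0.09);"
)

SIX_TAXON_NEWICK = (
    "((a:0.15,b:0.10):0.08,(c:0.12,d:0.09):0.05,(e:0.11,f:0.07):0.06);"
)


@pytest.fixture(scope="session")
def ten_taxon_tree():
    return ps.read_newick_string(TEN_TAXON_NEWICK)


@pytest.fixture(scope="session")
def six_taxon_tree():
    return ps.read_newick_string(SIX_TAXON_NEWICK)


@pytest.fixture(scope="session")
def fixture_bundle():
    return ps.make_piscidin_like_fixture(seed=20100302)


@pytest.fixture(scope="session")
def equal_pi():
    return np.full(ps.N_CODONS, 1.0 / ps.N_CODONS)


def random_tree_newick(names, rng, lo=0.02, hi=0.4):
    """Random unrooted binary topology by random coalescent-style joins."""
    subs = [f"{n}:{rng.uniform(lo, hi):.6f}" for n in names]
    while len(subs) > 3:
        i, j = sorted(rng.choice(len(subs), 2, replace=False))
        merged = f"({subs[i]},{subs[j]}):{rng.uniform(lo, hi):.6f}"
        subs = [s for k, s in enumerate(subs) if k not in (i, j)] + [merged]
    if len(subs) == 2:  # fewer than 4 taxa
        return f"({subs[0]},{subs[1]});"
    return f"({subs[0]},{subs[1]},{subs[2]});"


def simulate_m0(tree, omega, n_codons, seed, kappa=2.0):
    model = SiteClassModel("M0", [1.0], [omega])
    spec = SimulationSpec(tree, model, n_codons, seed=seed, kappa=kappa)
    return simulate_alignment(spec)
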