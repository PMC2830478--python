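"""Forward simulation of codon alignments under site-class models.

Sites evolve independently: each site draws an omega class from the
mixture, a root codon from the equilibrium distribution pi, and then
walks down the tree, with each branch applying the class's transition
matrix P(t) = exp(Q_class t) (common mixture scaling, so branch lengths
mean expected substitutions per codon averaged over classes). Stop
codons can never be emitted because the generator has no flux into
them.

Reproducibility: one integer seed drives everything; each site gets its
own child stream (numpy SeedSequence spawn keyed by site index), so the
sequence of draws at site j never depends on how many taxa or later
sites exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_engine import (
    N_CODONS,
    PhyloTree,
    SENSE_CODONS,
    SpectralPropagator,
    build_class_matrices,
)
from .sequence_io import CodonAlignment, annotate_regions, read_newick_string
from .site_model_inference import SiteClassModel


@dataclass
class SimulationSpec:
    tree: PhyloTree
    model: SiteClassModel
    n_codons: int
    seed: int
    kappa: float = 2.0
    pi: np.ndarray | None = None        # default: equal sense-codon freqs
    #: optional per-site class override (indices into the model's classes);
    #: None draws classes from the model's proportions
    site_classes: np.ndarray | None = None

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        if self.pi is None:
            self.pi = np.full(N_CODONS, 1.0 / N_CODONS)


@dataclass
class SimulatedAlignment:
    alignment: CodonAlignment
    site_classes: np.ndarray            # truth: class index per site
    class_omegas: np.ndarray

    @property
    def site_omegas(self) -> np.ndarray:
        return self.class_omegas[self.site_classes]


def simulate_alignment(spec: SimulationSpec) -> SimulatedAlignment:
    """Evolve an alignment under ``spec``; deterministic given the seed."""
    tree = spec.tree
    model = spec.model
    pi = np.asarray(spec.pi, dtype=float)
    mats = build_class_matrices(
        spec.kappa, model.class_omegas, model.class_proportions, pi
    )
    props = [SpectralPropagator(q, pi) for q in mats]
    # per-branch, per-class transition matrices (cumulative for sampling)
    edge_nodes = [i for i in range(tree.n_nodes) if tree.parent[i] >= 0]
    cum_p = {
        (k, i): np.cumsum(props[k](tree.edge_length[i]), axis=1)
        for k in range(len(mats))
        for i in edge_nodes
    }
    cum_pi = np.cumsum(pi)

    root = int(np.flatnonzero(tree.parent < 0)[0])
    # children in deterministic (index) order for a reproducible traversal
    order = []

    def preorder(i):
        order.append(i)
        for c in sorted(tree.children.get(i, [])):
            preorder(c)

    preorder(root)

    master = np.random.SeedSequence(spec.seed)
    class_rng = np.random.default_rng(master.spawn(1)[0])
    if spec.site_classes is not None:
        site_classes = np.asarray(spec.site_classes, dtype=int)
        if site_classes.shape != (spec.n_codons,):
            raise ValueError("site_classes must have one entry per codon")
    else:
        site_classes = class_rng.choice(
            len(model.class_omegas), size=spec.n_codons,
            p=model.class_proportions,
        )

    n_leaves = tree.n_leaves
    out = np.empty((n_leaves, spec.n_codons), dtype=int)
    for j in range(spec.n_codons):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, j))
        )
        k = int(site_classes[j])
        state = {root: int(np.searchsorted(cum_pi, rng.random(), side="right"))}
        for node in order[1:]:
            row = cum_p[(k, node)][state[tree.parent[node]]]
            state[node] = int(np.searchsorted(row, rng.random() * row[-1],
                                              side="right"))
        for leaf in range(n_leaves):
            out[leaf, j] = state[leaf]

    rows = [[SENSE_CODONS[c] for c in out[i]] for i in range(n_leaves)]
    aln = CodonAlignment(list(tree.leaf_names), rows)
    return SimulatedAlignment(aln, site_classes, model.class_omegas)


# ---------------------------------------------------------------------------
# Piscidin-like study fixture (synthetic)
# ---------------------------------------------------------------------------

#: 10-taxon piscidin-shaped tree: one long-branch basal lineage (cod-like),
#: a divergent pair, and a shallower perciform-like clade; lengths in
#: expected substitutions per codon, scaled so all-pairs Nei-Gojobori
#: averages land in the divergence regime the study reports
#: (mean dS near 1, mean dN near 0.28)
FIXTURE_TREE = (
    "((cod_like:1.925,(seahorse_like:1.12,croaker_like:1.05):0.525):0.35,"
    "((seabass_like:0.21,(whitebass_like:0.105,stripedbass_like:0.105):0.175):0.245,"
    "(mandarinfish_like:0.42,((grouperA_like:0.175,grouperB_like:0.14):0.14,"
    "grouperC_like:0.21):0.21):0.175):0.28);"
)

#: discrete 3-class mixture used as simulation truth (strong purifying,
#: weak purifying, positively selected)
FIXTURE_OMEGAS = (0.05, 0.29, 2.25)
FIXTURE_PROPORTIONS = (0.22, 0.59, 0.19)
FIXTURE_KAPPA = 2.0
FIXTURE_N_CODONS = 46
FIXTURE_SIGNAL_CODONS = 22          # codons 1-22 = signal, 23-46 = mature


@dataclass
class FixtureBundle:
    alignment: CodonAlignment
    tree: PhyloTree
    regions: list[tuple[str, int, int]]
    truth: SimulatedAlignment
    seed: int

    def write(self, out_dir) -> dict[str, Path]:
        """Write alignment FASTA + tree Newick + a region/seed config,
        byte-reproducible for a given seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": out / "alignment.fasta",
            "tree": out / "tree.nwk",
            "config": out / "config.yaml",
        }
        self.alignment.to_fasta(paths["alignment"])
        from .sequence_io import write_newick

        write_newick(self.tree, paths["tree"])
        region_lines = "\n".join(
            f"  - [{label}, {start}, {end}]" for label, start, end in self.regions
        )
        paths["config"].write_text(
            "alignment: alignment.fasta\n"
            "tree: tree.nwk\n"
            f"regions:\n{region_lines}\n"
            f"seed: {self.seed}\n"
        )
        return paths


def make_piscidin_like_fixture(seed: int) -> FixtureBundle:
    """Synthetic stand-in for the piscidin study data (10 taxa, 46 codons,
    22-codon signal region).

    Signal-region sites are forced into the two purifying classes;
    mature-region sites draw from the full 3-class mixture, so the mature
    region accumulates more nonsynonymous change by construction. The
    class values and proportions are the discrete-mixture truth above.
    """
    tree = read_newick_string(FIXTURE_TREE)
    model = SiteClassModel(
        "M3", np.array(FIXTURE_PROPORTIONS), np.array(FIXTURE_OMEGAS)
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(0,)))
    p = np.asarray(FIXTURE_PROPORTIONS)
    low = p[:2] / p[:2].sum()
    site_classes = np.empty(FIXTURE_N_CODONS, dtype=int)
    site_classes[:FIXTURE_SIGNAL_CODONS] = rng.choice(
        2, size=FIXTURE_SIGNAL_CODONS, p=low
    )
    site_classes[FIXTURE_SIGNAL_CODONS:] = rng.choice(
        3, size=FIXTURE_N_CODONS - FIXTURE_SIGNAL_CODONS, p=p
    )
    spec = SimulationSpec(
        tree=tree,
        model=model,
        n_codons=FIXTURE_N_CODONS,
        seed=seed,
        kappa=FIXTURE_KAPPA,
        site_classes=site_classes,
    )
    sim = simulate_alignment(spec)
    regions = [
        ("signal", 1, FIXTURE_SIGNAL_CODONS),
        ("mature", FIXTURE_SIGNAL_CODONS + 1, FIXTURE_N_CODONS),
    ]
    aln = annotate_regions(sim.alignment, regions)
    sim = SimulatedAlignment(aln, sim.site_classes, sim.class_omegas)
    return FixtureBundle(aln, tree, regions, sim, seed)
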