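"""Codon substitution model numerics.

Goldman-Yang style codon model: a 61x61 reversible rate matrix over the
sense codons of the standard genetic code, parameterized by the
transition/transversion rate ratio kappa, the nonsynonymous/synonymous
rate ratio omega (dN/dS), and the equilibrium codon frequencies pi.
On top of it: equilibrium-frequency estimators (equal, F1x4, F3x4),
transition probabilities P(t) = exp(Qt) via spectral decomposition of
the reversible generator, and Felsenstein pruning log-likelihoods for
site-class mixtures on an unrooted tree.

Branch lengths are measured in expected substitutions per codon: every
model (or model mixture) is rescaled so that one unit of branch length
produces one expected codon substitution at equilibrium, the same unit
CODEML uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

NUCLEOTIDES = "TCAG"
_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_standard = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons of the standard code, in TCAG order (CODEML's order)
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if (a + b + c) not in _standard.stop_codons
)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61
CODON_AA: tuple[str, ...] = tuple(_standard.forward_table[c] for c in SENSE_CODONS)

GAP_CODON = "---"


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def _single_step_pairs():
    """All ordered sense-codon pairs differing at exactly one position."""
    rows, cols, is_ts, is_syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rows.append(i)
            cols.append(j)
            is_ts.append(_is_transition(ci[k], cj[k]))
            is_syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.asarray(rows),
        np.asarray(cols),
        np.asarray(is_ts, dtype=bool),
        np.asarray(is_syn, dtype=bool),
    )


_ROWS, _COLS, _IS_TS, _IS_SYN = _single_step_pairs()


# ---------------------------------------------------------------------------
# Equilibrium frequencies
# ---------------------------------------------------------------------------

def estimate_frequencies(aln, scheme: str = "F3x4") -> np.ndarray:
    """Estimate equilibrium sense-codon frequencies from an alignment.

    scheme:
      * ``equal`` — 1/61 for every sense codon;
      * ``F1x4`` — products of the overall nucleotide frequencies,
        stop codons removed and the vector renormalized;
      * ``F3x4`` — products of codon-position-specific nucleotide
        frequencies, stops removed, renormalized.
    """
    if scheme == "equal":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    if scheme not in ("F1x4", "F3x4"):
        raise ValueError(f"unknown frequency scheme {scheme!r}")

    counts = np.zeros((3, 4))
    for row in aln.columns:
        for codon in row:
            if codon == GAP_CODON:
                continue
            for pos, nuc in enumerate(codon):
                counts[pos, _NUC_INDEX[nuc]] += 1

    if counts.sum() == 0:
        logger.warning("empty alignment; falling back to equal codon frequencies")
        return np.full(N_CODONS, 1.0 / N_CODONS)

    if scheme == "F1x4":
        nuc_freq = counts.sum(axis=0)
        nuc_freq = nuc_freq / nuc_freq.sum()
        pos_freq = np.vstack([nuc_freq] * 3)
    else:
        pos_freq = counts / counts.sum(axis=1, keepdims=True)

    pi = np.array(
        [
            pos_freq[0, _NUC_INDEX[c[0]]]
            * pos_freq[1, _NUC_INDEX[c[1]]]
            * pos_freq[2, _NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        logger.warning("degenerate base composition; falling back to equal frequencies")
        return np.full(N_CODONS, 1.0 / N_CODONS)
    return pi / total


# ---------------------------------------------------------------------------
# Rate matrix
# ---------------------------------------------------------------------------

def _unscaled_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                          syn_rate: float = 1.0) -> np.ndarray:
    """GY94 generator before rescaling.

    q_ij = pi_j * (kappa if transition) * (omega if nonsynonymous), for
    codons one nucleotide apart; 0 for multi-step changes. ``syn_rate``
    multiplies synonymous entries (used by the REL-style model where the
    synonymous rate itself varies across sites).
    """
    q = np.zeros((N_CODONS, N_CODONS))
    rate = np.where(_IS_TS, kappa, 1.0) * np.where(_IS_SYN, syn_rate, omega)
    q[_ROWS, _COLS] = rate * pi[_COLS]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def expected_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time: -sum_i pi_i q_ii."""
    return float(-(pi * np.diag(q)).sum())


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                     scale: bool = True) -> np.ndarray:
    """Goldman-Yang codon rate matrix, scaled to one expected substitution
    per codon per unit branch length (so branch lengths are in CODEML units).
    """
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be non-negative")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be a length-61 probability vector")
    q = _unscaled_rate_matrix(kappa, omega, pi)
    if scale:
        mu = expected_rate(q, pi)
        if mu > 0:
            q = q / mu
    return q


def build_class_matrices(kappa: float, omegas, weights, pi,
                         syn_rates=None) -> list[np.ndarray]:
    """Rate matrices for a site-class mixture, under one common scale.

    All class matrices are divided by the weighted mean substitution rate,
    so a branch length of 1 is one expected substitution per codon averaged
    over site classes (matching CODEML's treatment of site models).
    """
    pi = np.asarray(pi, dtype=float)
    if syn_rates is None:
        syn_rates = [1.0] * len(omegas)
    mats = [
        _unscaled_rate_matrix(kappa, w, pi, syn_rate=s)
        for w, s in zip(omegas, syn_rates)
    ]
    mean_rate = sum(
        p * expected_rate(q, pi) for p, q in zip(weights, mats)
    )
    if mean_rate <= 0:
        mean_rate = 1.0
    return [q / mean_rate for q in mats]


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

class SpectralPropagator:
    """P(t) = exp(Qt) via eigendecomposition of the pi-symmetrized generator.

    For a reversible Q with stationary distribution pi, B = D Q D^{-1}
    with D = diag(sqrt(pi)) is symmetric, so exp(Qt) = D^{-1} U e^{Lt} U' D
    with a real orthogonal U. Codons with pi = 0 are held fixed (P[i,i]=1);
    they receive no flux under GY94 anyway.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        self._support = np.flatnonzero(pi > 0)
        s = self._support
        sq = np.sqrt(pi[s])
        b = (sq[:, None] * q[np.ix_(s, s)]) / sq[None, :]
        b = 0.5 * (b + b.T)  # clean residual asymmetry
        lam, u = np.linalg.eigh(b)
        self._lam = lam
        self._left = u / sq[:, None]      # D^{-1} U
        self._right = (u * sq[:, None]).T  # U' D

    def __call__(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        s = self._support
        core = (self._left * np.exp(self._lam * t)) @ self._right
        p = np.eye(N_CODONS)
        p[np.ix_(s, s)] = np.clip(core, 0.0, None)
        # renormalize away eigen round-off
        p[s] /= p[s].sum(axis=1, keepdims=True)
        return p


def transition_probabilities(q: np.ndarray, t: float,
                             pi: np.ndarray | None = None) -> np.ndarray:
    """exp(Qt). With ``pi`` given, uses the stable reversible spectral form;
    otherwise falls back to scipy's scaling-and-squaring expm."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if pi is not None:
        return SpectralPropagator(q, pi)(t)
    from scipy.linalg import expm

    return expm(q * t)


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree with named leaves and branch lengths (subs/codon).

    Stored rooted at an arbitrary internal node for pruning; the likelihood
    of a reversible model does not depend on that choice. ``parent[i]`` is
    the parent of node i (-1 for the root), ``edge_length[i]`` the length of
    the edge above node i; nodes 0..n_leaves-1 are the leaves in
    ``leaf_names`` order; ``postorder`` excludes the root.
    """

    leaf_names: list[str]
    parent: np.ndarray
    edge_length: np.ndarray
    postorder: list[int]
    newick: str = ""
    children: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def edge_nodes(self) -> list[int]:
        """Nodes carrying a free branch length (all but the root)."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    def with_edge_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        el = self.edge_length.copy()
        el[self.edge_nodes()] = lengths
        return PhyloTree(self.leaf_names, self.parent, el, self.postorder,
                         self.newick, self.children)

    def total_length(self) -> float:
        return float(self.edge_length[self.edge_nodes()].sum())

    @classmethod
    def from_dendropy(cls, tree) -> "PhyloTree":
        tree = tree.clone(depth=1)
        tree.deroot()  # collapse any rooting; seed node becomes basal polytomy
        seed = tree.seed_node
        leaves = [lf for lf in tree.leaf_node_iter()]
        leaf_names = [lf.taxon.label for lf in leaves]
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("duplicate leaf labels in tree")
        index = {id(lf): i for i, lf in enumerate(leaves)}
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        for k, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + k
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        edge_length = np.zeros(n)
        children: dict[int, list[int]] = {}
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd is not seed:
                parent[i] = index[id(nd.parent_node)]
                bl = nd.edge.length
                edge_length[i] = 0.0 if bl is None else float(bl)
                if edge_length[i] < 0:
                    raise ValueError("negative branch length")
            children[i] = [index[id(c)] for c in nd.child_nodes()]
        post = []

        def walk(i):
            for c in children.get(i, []):
                walk(c)
            post.append(i)

        root = index[id(seed)]
        walk(root)
        post.remove(root)
        post.append(root)
        post = post[:-1]
        newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
        return cls(leaf_names, parent, edge_length, post, newick, children)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

class TreeLikelihood:
    """Felsenstein pruning for site-class mixtures on a codon alignment.

    Gap codons and any codon with ambiguity are missing data (all-ones
    partial likelihood). Per-node rescaling keeps partials in range for
    long alignments.
    """

    def __init__(self, aln, tree: PhyloTree):
        order = {t: i for i, t in enumerate(aln.taxa)}
        missing_leaf = set(tree.leaf_names) - set(aln.taxa)
        extra = set(aln.taxa) - set(tree.leaf_names)
        if missing_leaf or extra:
            raise ValueError(
                f"tree/alignment taxon mismatch: tree-only={sorted(missing_leaf)}, "
                f"alignment-only={sorted(extra)}"
            )
        self.tree = tree
        self.n_sites = aln.n_codons
        # leaf partials as codon indices (-1 = missing)
        states = np.full((tree.n_leaves, self.n_sites), -1, dtype=int)
        for li, name in enumerate(tree.leaf_names):
            row = aln.columns[order[name]]
            for s, codon in enumerate(row):
                if codon == GAP_CODON:
                    continue
                idx = CODON_INDEX.get(codon)
                if idx is None:
                    if any(ch not in "ACGT" for ch in codon):
                        continue  # ambiguity -> missing
                    raise ValueError(f"stop codon {codon!r} in analyzed alignment")
                states[li, s] = idx
        self.leaf_states = states
        # compress to unique site patterns
        pat, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = pat.T  # (n_leaves, n_patterns)
        self.pattern_counts = counts.astype(float)
        self.pattern_of_site = inverse
        self.n_patterns = pat.shape[0]

    # -- core ---------------------------------------------------------------

    def _class_pattern_likelihoods(self, mats, pi, edge_lengths=None):
        """Per-pattern likelihood under each class matrix.

        Returns (n_classes, n_patterns) array of likelihoods on the linear
        scale times exp(log_scale); log_scale is returned separately as
        (n_classes, n_patterns).
        """
        tree = self.tree
        if edge_lengths is None:
            el = tree.edge_length
        else:
            el = tree.edge_length.copy()
            el[tree.edge_nodes()] = edge_lengths
        n_classes = len(mats)
        props = [SpectralPropagator(q, pi) for q in mats]
        npat = self.n_patterns
        lik = np.empty((n_classes, npat))
        logscale = np.zeros((n_classes, npat))
        eye = np.eye(N_CODONS)
        for k in range(n_classes):
            partial = {}
            scale_k = np.zeros(npat)
            pmats = {i: props[k](el[i]) for i in range(tree.n_nodes)
                     if tree.parent[i] >= 0}
            for node in tree.postorder + [self._root()]:
                kids = tree.children.get(node, [])
                if not kids:  # leaf
                    st = self.patterns[node]
                    part = np.ones((npat, N_CODONS))
                    obs = st >= 0
                    part[obs] = eye[st[obs]]
                    partial[node] = part
                    continue
                part = np.ones((npat, N_CODONS))
                for c in kids:
                    part *= partial.pop(c) @ pmats[c].T
                mx = part.max(axis=1)
                mx[mx == 0] = 1.0
                part /= mx[:, None]
                scale_k += np.log(mx)
                partial[node] = part
            root = self._root()
            lik[k] = partial[root] @ pi
            logscale[k] = scale_k
        return lik, logscale

    def _root(self) -> int:
        return int(np.flatnonzero(self.tree.parent < 0)[0])

    def site_class_likelihoods(self, mats, pi, edge_lengths=None):
        """(n_classes, n_sites) per-site class likelihoods as (lik, logscale)."""
        lik, logscale = self._class_pattern_likelihoods(mats, pi, edge_lengths)
        idx = self.pattern_of_site
        return lik[:, idx], logscale[:, idx]

    def site_log_likelihoods(self, mats, weights, pi, edge_lengths=None):
        """Per-site log-likelihood of the mixture sum_k p_k L_k(site)."""
        lik, logscale = self._class_pattern_likelihoods(mats, pi, edge_lengths)
        w = np.asarray(weights, dtype=float)[:, None]
        m = logscale.max(axis=0)
        mix = (w * lik * np.exp(logscale - m)).sum(axis=0)
        with np.errstate(divide="ignore"):
            per_pattern = np.log(mix) + m
        return per_pattern[self.pattern_of_site]

    def log_likelihood(self, mats, weights, pi, edge_lengths=None) -> float:
        lik, logscale = self._class_pattern_likelihoods(mats, pi, edge_lengths)
        w = np.asarray(weights, dtype=float)[:, None]
        m = logscale.max(axis=0)
        mix = (w * lik * np.exp(logscale - m)).sum(axis=0)
        with np.errstate(divide="ignore"):
            per_pattern = np.log(mix) + m
        return float((per_pattern * self.pattern_counts).sum())


def site_log_likelihood(aln, tree: PhyloTree, kappa: float, pi,
                        class_omegas, class_weights,
                        site: int | None = None):
    """Per-site mixture log-likelihoods on an alignment (convenience wrapper).

    With ``site`` given (0-based), returns that site's value alone.
    """
    mats = build_class_matrices(kappa, class_omegas, class_weights, pi)
    tl = TreeLikelihood(aln, tree)
    vals = tl.site_log_likelihoods(mats, class_weights, pi)
    if site is not None:
        return float(vals[site])
    return vals
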