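"""Pairwise Nei-Gojobori dN/dS, cumulative substitution profiles, and
signal-vs-mature region contrasts.

Site counting follows the classical Nei-Gojobori (1986) / SNAP
conventions: at each codon position the synonymous fraction is taken
over the single-base changes that do not create a stop codon, so
s + n = 3 for every sense codon; observed differences at multi-hit
codons are averaged over all minimal mutational pathways that avoid
stop codons; proportions are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .codon_engine import CODON_AA, CODON_INDEX, GAP_CODON, STOP_CODONS

logger = logging.getLogger(__name__)

_AA = {c: CODON_AA[i] for c, i in CODON_INDEX.items()}


# ---------------------------------------------------------------------------
# Site and difference counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the synonymous fraction is computed among the single-base
    changes that do not create a stop; s is the sum over the 3 positions and
    n = 3 - s.
    """
    if codon not in CODON_INDEX:
        raise ValueError(f"{codon!r} is not an unambiguous sense codon")
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if _AA[alt] == _AA[codon]:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal mutational pathways that avoid stop codons.

    If every ordering of the substitutions passes through a stop codon
    (possible only for 3-fold differences), pathways through stops are
    admitted as a fallback.
    """
    for c in (codon_a, codon_b):
        if c not in CODON_INDEX:
            raise ValueError(f"{c!r} is not an unambiguous sense codon")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = non = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if (cur in STOP_CODONS or nxt in STOP_CODONS
                    or _AA[cur] != _AA[nxt]):
                non += 1.0
            else:
                syn += 1.0
            cur = nxt
        return syn, non

    results = [r for order in itertools.permutations(diff)
               if (r := walk(order, False)) is not None]
    if not results:
        results = [walk(order, True) for order in itertools.permutations(diff)]
    syn = sum(r[0] for r in results) / len(results)
    non = sum(r[1] for r in results) / len(results)
    return syn, non


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN (flagged) at saturation p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Pairwise comparison
# ---------------------------------------------------------------------------

@dataclass
class PairwiseDivergence:
    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons_compared: int
    cumulative_Sd: np.ndarray   # running sums along the alignment
    cumulative_Nd: np.ndarray

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else float("nan")

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else float("nan")

    @property
    def dS(self) -> float:
        return jukes_cantor(self.pS) if self.S > 0 else float("nan")

    @property
    def dN(self) -> float:
        return jukes_cantor(self.pN) if self.N > 0 else float("nan")

    @property
    def omega(self) -> float:
        ds = self.dS
        if not np.isfinite(ds) or ds == 0:
            return float("nan")
        return self.dN / ds


def ng_pairwise(row_i, row_j, pair=("seq_i", "seq_j")) -> PairwiseDivergence:
    """Nei-Gojobori comparison of two aligned codon rows.

    Codon pairs where either member is (or overlaps) a gap are skipped
    entirely; site counts S and N are averaged over the two sequences.
    """
    if len(row_i) != len(row_j):
        raise ValueError("aligned rows must have equal codon counts")
    S = N = 0.0
    n_compared = 0
    L = len(row_i)
    cum_sd = np.zeros(L)
    cum_nd = np.zeros(L)
    sd = nd = 0.0
    for k, (a, b) in enumerate(zip(row_i, row_j)):
        if a == GAP_CODON or b == GAP_CODON:
            cum_sd[k] = sd
            cum_nd[k] = nd
            continue
        sa, na = ng_site_counts(a)
        sb, nb = ng_site_counts(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds_, dn_ = ng_codon_differences(a, b)
        sd += ds_
        nd += dn_
        n_compared += 1
        cum_sd[k] = sd
        cum_nd[k] = nd
    if n_compared == 0:
        raise ValueError(f"no comparable codons for pair {pair}")
    return PairwiseDivergence(tuple(pair), S, N, sd, nd, n_compared,
                              cum_sd, cum_nd)


def all_pairs(aln) -> list[PairwiseDivergence]:
    """Nei-Gojobori comparison for every unordered taxon pair."""
    out = []
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            out.append(
                ng_pairwise(aln.columns[i], aln.columns[j],
                            (aln.taxa[i], aln.taxa[j]))
            )
    return out


def average_divergence(pairs, ratio_of_means: bool = True):
    """Average dN, dS and omega over pairs, excluding saturated (NaN) ones.

    ``ratio_of_means=True`` (default) reports omega = mean(dN)/mean(dS);
    the alternative is the mean of the per-pair ratios.
    """
    dn = np.array([p.dN for p in pairs])
    ds = np.array([p.dS for p in pairs])
    ok = np.isfinite(dn) & np.isfinite(ds)
    if not ok.all():
        logger.warning("%d saturated pair(s) excluded from averages",
                       int((~ok).sum()))
    if not ok.any():
        return float("nan"), float("nan"), float("nan")
    mean_dn = float(dn[ok].mean())
    mean_ds = float(ds[ok].mean())
    if ratio_of_means:
        omega = mean_dn / mean_ds if mean_ds > 0 else float("nan")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = dn[ok] / ds[ok]
        ratios = ratios[np.isfinite(ratios)]
        omega = float(ratios.mean()) if ratios.size else float("nan")
    return mean_dn, mean_ds, omega


def cumulative_profile(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Position-wise average over pairs of the running Sd and Nd sums."""
    if not pairs:
        raise ValueError("at least one pair required")
    sd = np.mean([p.cumulative_Sd for p in pairs], axis=0)
    nd = np.mean([p.cumulative_Nd for p in pairs], axis=0)
    return sd, nd


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(differences, exact_max_n: int = 25
                         ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties receive average ranks. The exact
    null distribution (enumeration over sign assignments, computed by
    dynamic programming over doubled ranks) is used for n <= exact_max_n;
    beyond that, the normal approximation with tie correction and
    continuity correction. Returns (W+, p).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, w_plus)
        return w_plus, p
    mu = n * (n + 1) / 4
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / 48
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    return w_plus, float(min(1.0, 2 * stats.norm.sf(abs(z))))


def _exact_two_sided_p(ranks, w_plus: float) -> float:
    """Exact two-sided p via the distribution of W+ over all 2^n sign
    assignments; ranks are doubled so average ranks become integers."""
    r2 = np.rint(2 * np.asarray(ranks)).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[:w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# Region contrasts
# ---------------------------------------------------------------------------

@dataclass
class RegionContrast:
    region_a: str
    region_b: str
    statistic: str              # "dN" or "dS"
    values_a: np.ndarray        # per-pair region-restricted distances
    values_b: np.ndarray
    ratio_of_means: float       # mean_a / mean_b
    mean_of_ratios: float
    wilcoxon_stat: float
    p_value: float

    @property
    def percent_excess(self) -> float:
        """How much higher region_a is than region_b, in percent."""
        return 100.0 * (self.ratio_of_means - 1.0)


def region_contrast(aln, region_a: str, region_b: str,
                    statistic: str = "dN") -> RegionContrast:
    """Compare a per-pair distance (dN or dS) between two annotated regions
    with a paired two-sided Wilcoxon signed-rank test."""
    if statistic not in ("dN", "dS"):
        raise ValueError("statistic must be 'dN' or 'dS'")
    sites_a = aln.region_sites(region_a)
    sites_b = aln.region_sites(region_b)
    if not sites_a or not sites_b:
        raise ValueError(
            f"regions {region_a!r}/{region_b!r} must both contain codons"
        )
    sub_a = aln.subset_sites(sites_a)
    sub_b = aln.subset_sites(sites_b)
    va = np.array([getattr(p, statistic) for p in all_pairs(sub_a)])
    vb = np.array([getattr(p, statistic) for p in all_pairs(sub_b)])
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < len(va):
        logger.warning("%d pair(s) saturated in a region; excluded",
                       int((~ok).sum()))
    va, vb = va[ok], vb[ok]
    if va.size < 6:
        logger.warning("only %d usable pairs; Wilcoxon test is weak", va.size)
    stat, p = wilcoxon_signed_rank(va - vb)
    mean_a, mean_b = va.mean(), vb.mean()
    rom = mean_a / mean_b if mean_b > 0 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = va / vb
    ratios = ratios[np.isfinite(ratios)]
    mor = float(ratios.mean()) if ratios.size else float("nan")
    return RegionContrast(region_a, region_b, statistic, va, vb,
                          float(rom), mor, stat, float(p))
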