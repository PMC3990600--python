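"""Pairwise linkage disequilibrium and proxy-SNP search.

The central statistic is r² = D² / (p_A(1−p_A) p_B(1−p_B)) with
D = p_AB − p_A·p_B, i.e. the squared allelic correlation between two
biallelic sites.  For phased panels the joint haplotype frequency p_AB is
counted directly; for unphased panels it is estimated by two-locus
expectation–maximization over the double-heterozygote phase ambiguity.

r² values are rounded to 6 decimals before any threshold comparison so that
proxy-set membership is deterministic under floating-point noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import HaplotypePanel, ValidationError, Variant

__all__ = [
    "HaplotypeCounts",
    "LDResult",
    "ProxySet",
    "MonomorphicSiteError",
    "InsufficientDataError",
    "LeadNotGenotypedError",
    "DEFAULT_WINDOW_BP",
    "haplotype_r2",
    "em_haplotype_freqs",
    "find_proxies",
    "merge_panels",
]

logger = logging.getLogger(__name__)

#: Search window on each side of a lead SNP (bp).  Matches the historical
#: default of web-based proxy-search tools; configurable per call.
DEFAULT_WINDOW_BP = 250_000

#: Decimal places r² is rounded to before comparing against a threshold.
R2_DECIMALS = 6


class MonomorphicSiteError(ValueError):
    """LD is undefined when either site is monomorphic."""


class InsufficientDataError(ValueError):
    """No informative individuals remain after dropping missing genotypes."""


class LeadNotGenotypedError(KeyError):
    """The queried lead SNP is absent from the reference panel."""


@dataclass(frozen=True)
class HaplotypeCounts:
    """Two-locus haplotype frequency summary behind an r² value."""

    n: int
    p_a: float
    p_b: float
    p_ab: float

    @property
    def d(self) -> float:
        """Disequilibrium coefficient D = p_AB − p_A·p_B."""
        return self.p_ab - self.p_a * self.p_b

    @property
    def r2(self) -> float:
        denom = self.p_a * (1 - self.p_a) * self.p_b * (1 - self.p_b)
        if denom <= 0:
            raise MonomorphicSiteError("r² undefined for a monomorphic site")
        return self.d**2 / denom


@dataclass(frozen=True)
class LDResult:
    rsid_a: str
    rsid_b: str
    r2: float
    panel_name: str = ""


@dataclass
class ProxySet:
    """All panel variants in LD with one lead at one r² threshold."""

    lead: Variant
    threshold: float
    members: list[LDResult] = field(default_factory=list)
    panel_name: str = ""

    @property
    def member_rsids(self) -> set[str]:
        return {m.rsid_b for m in self.members}


# ---------------------------------------------------------------------------
# r² from phased haplotypes
# ---------------------------------------------------------------------------


def haplotype_counts(col_a: np.ndarray, col_b: np.ndarray) -> HaplotypeCounts:
    """Direct gamete counting on two phased 0/1 columns."""
    col_a = np.asarray(col_a)
    col_b = np.asarray(col_b)
    if col_a.shape != col_b.shape:
        raise ValidationError("allele columns must have the same length")
    n = col_a.size
    return HaplotypeCounts(
        n=n,
        p_a=float(col_a.mean()),
        p_b=float(col_b.mean()),
        p_ab=float((col_a & col_b).mean()),
    )


def haplotype_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared allelic correlation between two phased 0/1 allele columns.

    Symmetric in its arguments and invariant to swapping the allele labels
    at either site.  Raises :class:`MonomorphicSiteError` when either column
    is monomorphic (the caller treats such sites as non-proxies).
    """
    return haplotype_counts(col_a, col_b).r2


# ---------------------------------------------------------------------------
# r² from unphased genotypes: two-locus EM
# ---------------------------------------------------------------------------


def em_haplotype_freqs(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
    return_history: bool = False,
):
    """Maximum-likelihood two-locus haplotype frequencies from unphased genotypes.

    Genotypes are alt-allele dosages in {0,1,2}; values outside that range
    are treated as missing and dropped pairwise.  Only double heterozygotes
    are phase-ambiguous: their two resolutions (AB/ab vs Ab/aB) are weighted
    each E-step by the current haplotype-frequency estimates.  Initialization
    is at linkage equilibrium (p_AB = p_A·p_B); iteration stops when the
    largest haplotype-frequency change falls below ``tol``.
    """
    ga = np.asarray(genotypes_a, dtype=float)
    gb = np.asarray(genotypes_b, dtype=float)
    if ga.shape != gb.shape:
        raise ValidationError("genotype vectors must have the same length")
    keep = np.isin(ga, (0, 1, 2)) & np.isin(gb, (0, 1, 2))
    ga, gb = ga[keep], gb[keep]
    n_ind = ga.size
    if n_ind == 0:
        raise InsufficientDataError("no individuals with genotypes at both sites")

    n_chrom = 2 * n_ind
    p_a = ga.sum() / n_chrom
    p_b = gb.sum() / n_chrom

    dh = (ga == 1) & (gb == 1)  # double heterozygotes: phase unknown
    n_dh = int(dh.sum())
    # Outside the double-het case the gamete pairing is forced and an
    # individual with dosages (a, b) contributes max(0, a + b - 2) AB gametes
    # (e.g. (2,1) -> AB + Ab, (2,2) -> 2 AB, (1,0) -> none).
    known_ab = float(np.maximum(0, ga[~dh] + gb[~dh] - 2).sum())

    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    p_ab = min(max(p_a * p_b, lo), hi)  # independence initialization
    history = [p_ab]
    for _ in range(max_iter):
        # E-step: expected fraction of double-het gametes in cis phase (AB/ab).
        f_ab = p_ab
        f_a_b = p_a - f_ab            # A at site 1, b at site 2
        f_b_a = p_b - f_ab            # a at site 1, B at site 2
        f_00 = 1 - p_a - p_b + f_ab
        cis = max(f_ab, 0.0) * max(f_00, 0.0)
        trans = max(f_a_b, 0.0) * max(f_b_a, 0.0)
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        # M-step: cis resolution contributes one AB gamete per double het.
        new_p_ab = min(max((known_ab + n_dh * w) / n_chrom, lo), hi)
        converged = abs(new_p_ab - p_ab) < tol
        p_ab = new_p_ab
        history.append(p_ab)
        if converged:
            break
    counts = HaplotypeCounts(n=n_chrom, p_a=float(p_a), p_b=float(p_b), p_ab=float(p_ab))
    if return_history:
        return counts, history
    return counts


def em_log_likelihood(counts: HaplotypeCounts, genotypes_a, genotypes_b) -> float:
    """Multinomial log-likelihood of unphased genotype pairs under haplotype freqs."""
    ga = np.asarray(genotypes_a, dtype=int)
    gb = np.asarray(genotypes_b, dtype=int)
    f_ab = counts.p_ab
    f_a_b = counts.p_a - f_ab
    f_b_a = counts.p_b - f_ab
    f_00 = 1 - counts.p_a - counts.p_b + f_ab
    freqs = {(1, 1): f_ab, (1, 0): f_a_b, (0, 1): f_b_a, (0, 0): f_00}
    ll = 0.0
    for a_dos, b_dos in zip(ga, gb):
        prob = 0.0
        # sum over gamete pairs (g1, g2) consistent with the genotype pair
        for a1 in (0, 1):
            for b1 in (0, 1):
                a2, b2 = a_dos - a1, b_dos - b1
                if a2 in (0, 1) and b2 in (0, 1):
                    prob += max(freqs[(a1, b1)], 0.0) * max(freqs[(a2, b2)], 0.0)
        ll += np.log(max(prob, 1e-300))
    return float(ll)


# ---------------------------------------------------------------------------
# Proxy search
# ---------------------------------------------------------------------------


def _pair_r2(panel: HaplotypePanel, rsid_a: str, rsid_b: str) -> float:
    if panel.phased:
        return haplotype_r2(panel.column(rsid_a), panel.column(rsid_b))
    counts = em_haplotype_freqs(panel.genotypes(rsid_a), panel.genotypes(rsid_b))
    return counts.r2


def find_proxies(
    lead: Variant,
    panel: HaplotypePanel,
    threshold: float,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> ProxySet:
    """All panel variants within ±``window_bp`` of ``lead`` with r² ≥ ``threshold``.

    The lead itself is always returned as a member with r² = 1 (self-proxy
    rule).  Monomorphic partner sites are skipped (r² undefined).  Raises
    :class:`LeadNotGenotypedError` when the lead is absent from the panel;
    the pipeline records such leads as untestable rather than failing.
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    if lead.rsid not in panel:
        raise LeadNotGenotypedError(lead.rsid)
    members = [LDResult(lead.rsid, lead.rsid, 1.0, panel.panel_name)]
    lead_col = panel.column(lead.rsid)
    if lead_col.min() == lead_col.max():
        # monomorphic lead: LD with partners is undefined; self-proxy only
        return ProxySet(lead=lead, threshold=threshold, members=members, panel_name=panel.panel_name)
    thr = round(threshold, R2_DECIMALS)
    for variant in panel.variants:
        if variant.rsid == lead.rsid or variant.chrom != lead.chrom:
            continue
        if abs(variant.pos0 - lead.pos0) > window_bp:
            continue
        try:
            r2 = _pair_r2(panel, lead.rsid, variant.rsid)
        except MonomorphicSiteError:
            logger.debug("skipping monomorphic partner %s", variant.rsid)
            continue
        if round(r2, R2_DECIMALS) >= thr:
            members.append(LDResult(lead.rsid, variant.rsid, r2, panel.panel_name))
    return ProxySet(lead=lead, threshold=threshold, members=members, panel_name=panel.panel_name)


def merge_panels(proxy_sets: list[ProxySet]) -> dict:
    """Union of per-panel proxy sets for one lead, overlaps removed.

    Returns ``{"lead", "threshold", "union_rsids", "per_panel_counts",
    "union_count", "best_r2"}`` where ``best_r2`` maps each member rsID to
    its maximum r² across panels.
    """
    if not proxy_sets:
        raise ValidationError("no proxy sets to merge")
    lead = proxy_sets[0].lead
    threshold = proxy_sets[0].threshold
    for ps in proxy_sets[1:]:
        if ps.lead.rsid != lead.rsid or ps.threshold != threshold:
            raise ValidationError("merge_panels requires a shared lead and threshold")
    union: set[str] = set()
    best_r2: dict[str, float] = {}
    per_panel_counts: dict[str, int] = {}
    for ps in proxy_sets:
        rsids = ps.member_rsids
        per_panel_counts[ps.panel_name] = len(rsids)
        union |= rsids
        for m in ps.members:
            best_r2[m.rsid_b] = max(best_r2.get(m.rsid_b, 0.0), m.r2)
    return {
        "lead": lead,
        "threshold": threshold,
        "union_rsids": union,
        "per_panel_counts": per_panel_counts,
        "union_count": len(union),
        "best_r2": best_r2,
    }
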