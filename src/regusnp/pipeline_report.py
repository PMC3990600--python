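"""End-to-end orchestration: LD expansion -> evidence -> categories -> reports.

The proxy universe is built at the loosest requested r² threshold (the
conventional 0.80 working list); tighter thresholds appear only as
annotations (per-member r² bins and per-threshold panel counts).  Lead SNPs
are always part of the universe, as their own proxies where genotyped and
as untested entries otherwise.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import pandas as pd

from .evidence_collector import EvidenceBundle, collect_evidence
from .io_formats import AnnotationTrack, EQTLRecord, HaplotypePanel, ValidationError, Variant
from .ld_engine import DEFAULT_WINDOW_BP, LeadNotGenotypedError, R2_DECIMALS, find_proxies
from .regulome_classifier import RegulomeCategory, classify, is_likely_regulatory

__all__ = [
    "FunctionalHit",
    "StudySummary",
    "run_pipeline",
    "threshold_count_table",
    "functional_detail_table",
    "ld_map_table",
    "TOTAL_ROW_LABEL",
]

logger = logging.getLogger(__name__)

TOTAL_ROW_LABEL = "TOTAL (overlaps removed)"

_BIN_ORDER = {"ge80": 0, "ge90": 1, "eq100": 2}


def _r2_bin(r2: float) -> str:
    r2 = round(r2, R2_DECIMALS)
    if r2 >= 1.0:
        return "eq100"
    if r2 >= 0.9:
        return "ge90"
    return "ge80"


@dataclass
class FunctionalHit:
    """One putative regulatory variant (category better than 3)."""

    variant: Variant
    category: RegulomeCategory
    eqtl_genes: list[str]
    motifs: list[str]
    bound_proteins: list[str]
    lead_links: list[tuple[str, str]]  # (lead rsID, highest attained r² bin)
    is_reported_gwas: bool

    def __post_init__(self) -> None:
        if not is_likely_regulatory(self.category):
            raise ValidationError(
                f"{self.variant.rsid}: category {self.category} is not score < 3"
            )


@dataclass
class StudySummary:
    """Headline tallies of one pipeline run (identities checked on build)."""

    n_examined: int
    n_no_data: int
    n_scored_1_6: int
    n_functional: int
    per_category_counts: dict[str, int]
    n_functional_reported_gwas: int
    n_functional_gw_significant: int
    n_functional_proxy_only: int
    per_locus: dict[str, tuple[int, int]]  # locus -> (tested, functional)
    per_panel_threshold_counts: dict[str, dict[float, int]]
    union_threshold_counts: dict[float, int]
    untested_leads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_examined == self.n_no_data + self.n_scored_1_6
        functional_labels = ("1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c")
        assert self.n_functional == sum(
            self.per_category_counts.get(lbl, 0) for lbl in functional_labels
        )
        assert self.n_functional == (
            self.n_functional_reported_gwas + self.n_functional_proxy_only
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["per_locus"] = {k: list(v) for k, v in self.per_locus.items()}
        out["per_panel_threshold_counts"] = {
            panel: {str(t): c for t, c in counts.items()}
            for panel, counts in self.per_panel_threshold_counts.items()
        }
        out["union_threshold_counts"] = {
            str(t): c for t, c in self.union_threshold_counts.items()
        }
        return out


def run_pipeline(
    leads: list[Variant],
    panels: dict[str, HaplotypePanel],
    tracks: dict[str, AnnotationTrack],
    eqtls: list[EQTLRecord],
    thresholds: tuple[float, ...] = (0.80, 0.90, 1.0),
    window_bp: int = DEFAULT_WINDOW_BP,
) -> tuple[StudySummary, list[FunctionalHit]]:
    """Expand leads into the proxy universe, annotate, classify, tally."""
    if not leads:
        raise ValidationError("empty lead list")
    loosest = min(thresholds)

    # --- LD expansion at the loosest threshold -----------------------------
    # member r² per (lead, panel): rsid -> r²
    proxy_r2: dict[tuple[str, str], dict[str, float]] = {}
    untested: dict[str, int] = {}
    for lead in leads:
        genotyped_anywhere = False
        for panel_name, panel in panels.items():
            try:
                ps = find_proxies(lead, panel, loosest, window_bp)
            except LeadNotGenotypedError:
                continue
            genotyped_anywhere = True
            proxy_r2[(lead.rsid, panel_name)] = {m.rsid_b: m.r2 for m in ps.members}
        if not genotyped_anywhere:
            untested[lead.rsid] = 1
            logger.warning("lead %s absent from every panel; recorded as untested", lead.rsid)

    # --- the universe: union of proxies, overlaps removed, leads included ---
    lead_by_rsid = {v.rsid: v for v in leads}
    universe: dict[str, Variant] = dict(lead_by_rsid)
    best_links: dict[str, dict[str, float]] = {v.rsid: {} for v in leads}
    for (lead_rsid, panel_name), members in proxy_r2.items():
        panel = panels[panel_name]
        for rsid, r2 in members.items():
            if rsid not in universe:
                idx = panel._index[rsid]
                universe[rsid] = panel.variants[idx]
            links = best_links.setdefault(rsid, {})
            links[lead_rsid] = max(links.get(lead_rsid, 0.0), r2)

    # proxies inherit the locus of (the first of) their linked leads unless
    # they carry their own label
    for rsid, variant in universe.items():
        if not variant.locus and best_links.get(rsid):
            lead_rsid = sorted(best_links[rsid])[0]
            universe[rsid] = dataclasses.replace(
                variant, locus=lead_by_rsid[lead_rsid].locus
            )

    # --- evidence + classification -----------------------------------------
    categories: dict[str, RegulomeCategory] = {}
    bundles: dict[str, EvidenceBundle] = {}
    for rsid, variant in universe.items():
        bundle = collect_evidence(variant, tracks, eqtls)
        bundles[rsid] = bundle
        categories[rsid] = classify(bundle)

    hits: list[FunctionalHit] = []
    for rsid in sorted(universe):
        cat = categories[rsid]
        if not is_likely_regulatory(cat):
            continue
        variant = universe[rsid]
        bundle = bundles[rsid]
        links = [
            (lead_rsid, _r2_bin(r2))
            for lead_rsid, r2 in sorted(best_links.get(rsid, {}).items())
        ]
        genes: list[str] = []
        for gene, _cell in bundle.eqtl_targets:
            if gene not in genes:
                genes.append(gene)
        hits.append(
            FunctionalHit(
                variant=variant,
                category=cat,
                eqtl_genes=genes,
                motifs=sorted({m for m, _ in bundle.motif_hits}),
                bound_proteins=sorted(bundle.tf_bindings),
                lead_links=links,
                is_reported_gwas=variant.is_lead,
            )
        )
    hits.sort(key=lambda h: (h.category.rank, h.variant.chrom, h.variant.pos0, h.variant.rsid))

    # --- tallies ------------------------------------------------------------
    n_examined = len(universe)
    n_no_data = sum(1 for c in categories.values() if not c.is_scored)
    per_category: dict[str, int] = {}
    for cat in categories.values():
        per_category[cat.label] = per_category.get(cat.label, 0) + 1

    n_functional = len(hits)
    n_reported = sum(1 for h in hits if h.is_reported_gwas)
    n_gw = sum(
        1 for h in hits if h.variant.assoc_class == "gw_significant_risk"
    )

    per_locus: dict[str, list[int]] = {}
    for rsid, variant in universe.items():
        loci = {
            lead_by_rsid[lead_rsid].locus for lead_rsid in best_links.get(rsid, {})
        } or {variant.locus}
        functional = is_likely_regulatory(categories[rsid])
        for locus in loci:
            entry = per_locus.setdefault(locus, [0, 0])
            entry[0] += 1
            if functional:
                entry[1] += 1

    per_panel_thr: dict[str, dict[float, int]] = {}
    union_thr: dict[float, set] = {t: set() for t in thresholds}
    for panel_name in panels:
        counts: dict[float, int] = {}
        for t in thresholds:
            members = {
                rsid
                for (lead_rsid, pname), mem in proxy_r2.items()
                if pname == panel_name
                for rsid, r2 in mem.items()
                if round(r2, R2_DECIMALS) >= round(t, R2_DECIMALS)
            }
            counts[t] = len(members)
            union_thr[t] |= members
        per_panel_thr[panel_name] = counts

    summary = StudySummary(
        n_examined=n_examined,
        n_no_data=n_no_data,
        n_scored_1_6=n_examined - n_no_data,
        n_functional=n_functional,
        per_category_counts=per_category,
        n_functional_reported_gwas=n_reported,
        n_functional_gw_significant=n_gw,
        n_functional_proxy_only=n_functional - n_reported,
        per_locus={k: (v[0], v[1]) for k, v in per_locus.items()},
        per_panel_threshold_counts=per_panel_thr,
        union_threshold_counts={t: len(s) for t, s in union_thr.items()},
        untested_leads=sorted(untested),
    )
    return summary, hits


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def threshold_count_table(summary: StudySummary) -> pd.DataFrame:
    """Per-panel proxy counts at each threshold, plus the overlap-free union."""
    thresholds = sorted(summary.union_threshold_counts)
    cols = [f"{t:.2f}" for t in thresholds]
    rows = {}
    for panel, counts in summary.per_panel_threshold_counts.items():
        rows[panel] = [counts[t] for t in thresholds]
    rows[TOTAL_ROW_LABEL] = [summary.union_threshold_counts[t] for t in thresholds]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def functional_detail_table(
    hits: list[FunctionalHit],
    position_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per functional variant (the score-<3 detail report)."""
    position_classes = position_classes or {}
    ordered = sorted(
        hits, key=lambda h: (h.category.rank, h.variant.chrom, h.variant.pos0, h.variant.rsid)
    )
    records = []
    for h in ordered:
        v = h.variant
        records.append(
            {
                "coordinate": f"{v.chrom}:{v.pos0}",
                "rsid": v.rsid,
                "score": h.category.label,
                "locus": v.locus,
                "position_class": position_classes.get(v.rsid, ""),
                "eqtl_genes": "|".join(h.eqtl_genes),
                "motifs": "|".join(h.motifs),
                "bound_proteins": "|".join(h.bound_proteins),
                "is_reported_gwas": h.is_reported_gwas,
            }
        )
    columns = [
        "coordinate", "rsid", "score", "locus", "position_class",
        "eqtl_genes", "motifs", "bound_proteins", "is_reported_gwas",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


def ld_map_table(hits: list[FunctionalHit]) -> pd.DataFrame:
    """Lead ↔ functional-proxy pairs with the highest attained r² bin.

    A functional lead appears as its own proxy (self row).  A proxy in LD
    with several leads contributes one row per lead.
    """
    records = []
    for h in hits:
        for lead_rsid, r2_bin in h.lead_links:
            records.append(
                {
                    "lead_rsid": lead_rsid,
                    "proxy_rsid": h.variant.rsid,
                    "proxy_locus": h.variant.locus,
                    "score": h.category.label,
                    "r2_bin": r2_bin,
                    "is_self": lead_rsid == h.variant.rsid,
                }
            )
    df = pd.DataFrame.from_records(
        records,
        columns=["lead_rsid", "proxy_rsid", "proxy_locus", "score", "r2_bin", "is_self"],
    )
    return df.sort_values(
        ["lead_rsid", "score", "proxy_rsid"], kind="stable"
    ).reset_index(drop=True)
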