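"""RegulomeDB-style category hierarchy.

Categories form a total order from 1a (strongest regulatory evidence) down
through 6, with NO_DATA beyond 6 for variants absent from every evidence
source.  A variant is classified into the best (lowest-rank) category whose
requirements its evidence bundle satisfies; the category-1 block combines
expression linkage (eQTL) with binding evidence, the category-2 block is
binding evidence without expression linkage ("likely to affect binding"),
and 3a and worse are progressively weaker.

The study-level filter ``is_likely_regulatory`` keeps categories better
than 3 (1a–2c), the conventional "score < 3" cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

from .evidence_collector import EvidenceBundle

__all__ = [
    "RegulomeCategory",
    "CATEGORY_LABELS",
    "classify",
    "is_likely_regulatory",
    "category_truth_table",
]

#: best-to-worst order; NO_DATA is distinct from 6 and excluded from
#: "scored 1-6" tallies.
CATEGORY_LABELS = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c",
    "3a", "3b",
    "4", "5", "6",
    "NO_DATA",
)

_RANK = {label: rank for rank, label in enumerate(CATEGORY_LABELS, start=1)}


@total_ordering
@dataclass(frozen=True)
class RegulomeCategory:
    label: str

    def __post_init__(self) -> None:
        if self.label not in _RANK:
            raise ValueError(f"unknown category label {self.label!r}")

    @property
    def rank(self) -> int:
        return _RANK[self.label]

    @property
    def is_scored(self) -> bool:
        """True for 1a-6, False for NO_DATA."""
        return self.label != "NO_DATA"

    def __lt__(self, other: "RegulomeCategory") -> bool:
        return self.rank < other.rank

    def __str__(self) -> str:
        return self.label


def classify(ev: EvidenceBundle) -> RegulomeCategory:
    """Map an evidence bundle to its best attainable category.

    Requirements are tested best-first.  Notation: E = eQTL, T = TF binding,
    M = any motif hit, mm = matched TF motif, F = any DNase footprint,
    mf = matched DNase footprint, P = DNase peak.
    """
    e = ev.has_eqtl
    t = ev.has_tf_binding
    m = ev.has_motif
    mm = ev.matched_motif
    f = ev.has_footprint
    mf = ev.matched_footprint
    p = ev.dnase_peak

    if e and t and mm and mf and p:
        return RegulomeCategory("1a")
    if e and t and m and f and p:
        return RegulomeCategory("1b")
    if e and t and mm and p:
        return RegulomeCategory("1c")
    if e and t and m and p:
        return RegulomeCategory("1d")
    if e and t and mm:
        return RegulomeCategory("1e")
    if e and (t or p):  # the slash rule: eQTL plus either binding or peak
        return RegulomeCategory("1f")
    if t and mm and mf and p:
        return RegulomeCategory("2a")
    if t and m and f and p:
        return RegulomeCategory("2b")
    if t and mm and p:
        return RegulomeCategory("2c")
    if t and m and p:
        return RegulomeCategory("3a")
    if t and mm:
        return RegulomeCategory("3b")
    if t and p:
        return RegulomeCategory("4")
    if t or p:
        return RegulomeCategory("5")
    if m:
        return RegulomeCategory("6")
    return RegulomeCategory("NO_DATA")


def is_likely_regulatory(cat: RegulomeCategory) -> bool:
    """The "score < 3" filter: categories 1a-2c."""
    return cat.rank < _RANK["3a"]


# ---------------------------------------------------------------------------
# Exhaustive enumeration over the evidence-flag lattice (test oracle)
# ---------------------------------------------------------------------------

FLAG_NAMES = ("eqtl", "tf", "motif", "matched_motif", "footprint", "matched_footprint", "peak")


def _consistent(flags: tuple[bool, ...]) -> bool:
    e, t, m, mm, f, mf, p = flags
    if mm and not (m and t):
        return False
    if mf and not (f and mm):
        return False
    return True


def bundle_from_flags(flags: tuple[bool, ...]) -> EvidenceBundle:
    """Build a minimal concrete bundle realizing one consistent flag combination."""
    e, t, m, mm, f, mf, p = flags
    bundle = EvidenceBundle()
    if e:
        bundle.eqtl_targets.append(("GENE1", "cells"))
    if t:
        bundle.tf_bindings.add("TFBOUND")
    if m:
        # matched motif's TF coincides with the bound TF; unmatched uses another
        bundle.motif_hits.add(("MOTIF_X", "TFBOUND" if mm else "TFOTHER"))
    if f:
        # matched footprint reuses the matched motif's ID; unmatched uses another
        bundle.dnase_footprint_hits.add(("MOTIF_X" if mf else "MOTIF_Y", "TFANY"))
    bundle.dnase_peak = p
    return bundle


def category_truth_table() -> dict[tuple[bool, ...], RegulomeCategory]:
    """classify() outcome for every consistent evidence-flag combination.

    Keys are (eqtl, tf, motif, matched_motif, footprint, matched_footprint,
    peak) tuples.  Used to establish totality and monotonicity of the
    hierarchy by exhaustive enumeration.
    """
    table = {}
    for i in range(2 ** len(FLAG_NAMES)):
        flags = tuple(bool((i >> j) & 1) for j in range(len(FLAG_NAMES)))
        if not _consistent(flags):
            continue
        bundle = bundle_from_flags(flags)
        # sanity: the concrete bundle must realize exactly the requested flags
        realized = (
            bundle.has_eqtl,
            bundle.has_tf_binding,
            bundle.has_motif,
            bundle.matched_motif,
            bundle.has_footprint,
            bundle.matched_footprint,
            bundle.dnase_peak,
        )
        assert realized == flags, (realized, flags)
        table[flags] = classify(bundle)
    return table
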