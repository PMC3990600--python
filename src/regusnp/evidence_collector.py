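"""Per-variant regulatory evidence assembly.

For each variant this module gathers the seven evidence ingredients that the
category hierarchy consumes: eQTL target genes, ChIP-evidenced TF binding,
motif instances, DNase peaks and DNase footprints, plus the two derived
"matched" flags:

* ``matched_motif`` — some motif instance covering the variant is annotated
  with a TF that also has ChIP binding evidence at the variant;
* ``matched_footprint`` — some DNase footprint at the variant carries the
  motif of such a matched motif instance.

A variant overlaps an interval iff ``start0 <= pos0 < end0``.  TF names are
compared case-insensitively with punctuation stripped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io_formats import AnnotationTrack, EQTLRecord, Variant

__all__ = ["EvidenceBundle", "collect_evidence", "normalize_tf_name", "PAYLOAD_SEP"]

#: separator between motif ID and TF name inside a BED name column
PAYLOAD_SEP = ";"

_PUNCT = re.compile(r"[^0-9a-z]+")


def normalize_tf_name(name: str) -> str:
    """Case-insensitive, punctuation-stripped TF-name key."""
    return _PUNCT.sub("", name.lower())


@dataclass
class EvidenceBundle:
    """Everything known about one variant's regulatory context."""

    eqtl_targets: list[tuple[str, str]] = field(default_factory=list)  # (gene, cell type)
    tf_bindings: set[str] = field(default_factory=set)
    motif_hits: set[tuple[str, str]] = field(default_factory=set)  # (motif ID, TF name)
    dnase_peak: bool = False
    dnase_footprint_hits: set[tuple[str, str]] = field(default_factory=set)

    @property
    def has_eqtl(self) -> bool:
        return bool(self.eqtl_targets)

    @property
    def has_tf_binding(self) -> bool:
        return bool(self.tf_bindings)

    @property
    def has_motif(self) -> bool:
        return bool(self.motif_hits)

    @property
    def has_footprint(self) -> bool:
        return bool(self.dnase_footprint_hits)

    @property
    def matched_motif(self) -> bool:
        bound = {normalize_tf_name(t) for t in self.tf_bindings}
        return any(normalize_tf_name(tf) in bound for _, tf in self.motif_hits)

    @property
    def matched_footprint(self) -> bool:
        bound = {normalize_tf_name(t) for t in self.tf_bindings}
        matched_ids = {
            motif_id for motif_id, tf in self.motif_hits if normalize_tf_name(tf) in bound
        }
        return any(motif_id in matched_ids for motif_id, _ in self.dnase_footprint_hits)

    @property
    def is_empty(self) -> bool:
        return not (
            self.has_eqtl
            or self.has_tf_binding
            or self.has_motif
            or self.dnase_peak
            or self.has_footprint
        )


def _split_payload(payload: str) -> tuple[str, str]:
    """BED name -> (motif ID, TF name); a bare name serves as both."""
    if PAYLOAD_SEP in payload:
        motif_id, tf = payload.split(PAYLOAD_SEP, 1)
        return motif_id, tf
    return payload, payload


def collect_evidence(
    variant: Variant,
    tracks: dict[str, AnnotationTrack],
    eqtls: list[EQTLRecord],
) -> EvidenceBundle:
    """Assemble the evidence bundle for one variant.

    ``tracks`` maps track kind (``tf_peak``, ``motif_instance``,
    ``dnase_peak``, ``dnase_footprint``) to its annotation track; absent
    kinds simply contribute no evidence.  eQTL records are matched by rsID
    when present, else by (chrom, pos0).
    """
    bundle = EvidenceBundle()

    for rec in eqtls:
        if rec.rsid and rec.rsid == variant.rsid:
            bundle.eqtl_targets.append((rec.target_gene, rec.cell_type))
        elif not rec.rsid and rec.chrom == variant.chrom and rec.pos0 == variant.pos0:
            bundle.eqtl_targets.append((rec.target_gene, rec.cell_type))

    track = tracks.get("tf_peak")
    if track is not None:
        bundle.tf_bindings = set(track.query(variant.chrom, variant.pos0))

    track = tracks.get("motif_instance")
    if track is not None:
        bundle.motif_hits = {
            _split_payload(p) for p in track.query(variant.chrom, variant.pos0)
        }

    track = tracks.get("dnase_peak")
    if track is not None:
        bundle.dnase_peak = bool(track.query(variant.chrom, variant.pos0))

    track = tracks.get("dnase_footprint")
    if track is not None:
        bundle.dnase_footprint_hits = {
            _split_payload(p) for p in track.query(variant.chrom, variant.pos0)
        }

    return bundle
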