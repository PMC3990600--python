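"""Readers, writers and the core data model.

All genomic coordinates inside the package are 0-based, half-open.  VCF
input (1-based) is converted on read; BED input is taken as-is.  Chromosome
labels are normalized to the ``chrN`` form on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Variant",
    "HaplotypePanel",
    "AnnotationTrack",
    "EQTLRecord",
    "ASSOC_CLASSES",
    "TRACK_KINDS",
    "FormatError",
    "ValidationError",
    "EmptyPanelError",
    "normalize_chrom",
    "read_lead_snps",
    "write_lead_snps",
    "read_vcf_panel",
    "write_vcf_panel",
    "read_bed_track",
    "write_bed_track",
    "read_eqtl_table",
    "write_eqtl_table",
]

ASSOC_CLASSES = ("gw_significant_risk", "suggestive_risk_or_aao", "proxy_only")

#: BED track kinds.  tf_peak / motif_instance / dnase_footprint carry a payload
#: name in column 4; dnase_peak is a plain BED3 interval.
TRACK_KINDS = ("tf_peak", "motif_instance", "dnase_peak", "dnase_footprint")

_PAYLOAD_KINDS = frozenset({"tf_peak", "motif_instance", "dnase_footprint"})


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


class ValidationError(ValueError):
    """Well-formed input that violates a semantic invariant."""


class EmptyPanelError(ValidationError):
    """A VCF region query returned no usable records."""


def normalize_chrom(chrom: str) -> str:
    """Return ``chrom`` in ``chrN`` form (``11`` -> ``chr11``, ``chrX`` kept)."""
    chrom = str(chrom).strip()
    if not chrom.lower().startswith("chr"):
        chrom = "chr" + chrom
    return "chr" + chrom[3:]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with study annotations.

    ``pos0`` is the 0-based coordinate of the variant base.  ``assoc_class``
    distinguishes genome-wide significant leads, suggestive leads, and plain
    LD proxies.
    """

    rsid: str
    chrom: str
    pos0: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    locus: str = ""
    assoc_class: str = "proxy_only"

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if self.pos0 < 0:
            raise ValidationError(f"{self.rsid}: pos0 must be >= 0, got {self.pos0}")
        if self.assoc_class not in ASSOC_CLASSES:
            raise ValidationError(
                f"{self.rsid}: unknown assoc_class {self.assoc_class!r}"
            )

    @property
    def is_lead(self) -> bool:
        return self.assoc_class != "proxy_only"


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix: one row per chromosome copy, one column per variant.

    ``phased`` is False when the source VCF contained any unphased genotype
    rows, in which case downstream LD estimation must go through the EM
    (genotype) pathway rather than direct haplotype counting.
    """

    variants: list[Variant]
    haplotypes: np.ndarray
    panel_name: str = "panel"
    phased: bool = True

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValidationError("haplotypes must be a 2-D matrix")
        n_rows, n_cols = self.haplotypes.shape
        if n_cols != len(self.variants):
            raise ValidationError(
                f"{n_cols} matrix columns != {len(self.variants)} variants"
            )
        if n_rows % 2 != 0:
            raise ValidationError("row count must be even (diploid source)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValidationError("matrix entries must be in {0, 1}")
        self._index = {v.rsid: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValidationError("duplicate rsIDs in panel")

    @property
    def n_chromosomes(self) -> int:
        return self.haplotypes.shape[0]

    def column(self, rsid: str) -> np.ndarray:
        return self.haplotypes[:, self._index[rsid]]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def genotypes(self, rsid: str) -> np.ndarray:
        """Per-individual 0/1/2 alt-allele dosages."""
        col = self.column(rsid)
        return col.reshape(-1, 2).sum(axis=1)

    def maf(self, rsid: str) -> float:
        p = float(self.column(rsid).mean())
        return min(p, 1.0 - p)


@dataclass
class AnnotationTrack:
    """A point-queryable set of genomic intervals of one evidence kind.

    Intervals are 0-based half-open; payload is the TF / motif name where the
    kind requires one.  Overlapping intervals are all retained (no merging).
    """

    kind: str
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValidationError(f"unknown track kind {self.kind!r}")
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, payload in self.intervals:
            self._validate(chrom, start, end, payload)
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, payload)

    def _validate(self, chrom: str, start: int, end: int, payload: str) -> None:
        if start >= end:
            raise ValidationError(
                f"{self.kind} interval {chrom}:{start}-{end}: start must be < end"
            )
        if self.kind in _PAYLOAD_KINDS and not payload:
            raise FormatError(f"{self.kind} interval {chrom}:{start}-{end} lacks a name")

    def add(self, chrom: str, start: int, end: int, payload: str = "") -> None:
        self._validate(chrom, start, end, payload)
        self.intervals.append((chrom, start, end, payload))
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, payload)

    def query(self, chrom: str, pos0: int) -> list[str]:
        """Payloads of all intervals with start0 <= pos0 < end0."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos0)]

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class EQTLRecord:
    """One variant -> target-gene expression association."""

    rsid: str
    target_gene: str
    cell_type: str = ""
    chrom: str = ""
    pos0: int = -1

    def __post_init__(self) -> None:
        if not self.target_gene:
            raise ValidationError("eQTL record lacks a target gene")


# ---------------------------------------------------------------------------
# Lead-SNP tables
# ---------------------------------------------------------------------------

_LEAD_COLUMNS = ["rsid", "chrom", "pos0", "locus", "assoc_class"]


def read_lead_snps(path: str | Path) -> list[Variant]:
    """Read a lead-SNP TSV (columns rsid, chrom, pos0, locus, assoc_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _LEAD_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"lead-SNP table {path} is missing column {col!r}")
    dups = df["rsid"][df["rsid"].duplicated()]
    if len(dups):
        raise ValidationError(f"duplicate rsIDs in lead table: {sorted(set(dups))}")
    variants = []
    for row in df.itertuples(index=False):
        variants.append(
            Variant(
                rsid=row.rsid,
                chrom=normalize_chrom(row.chrom),
                pos0=int(row.pos0),
                locus=row.locus,
                assoc_class=row.assoc_class,
            )
        )
    return variants


def write_lead_snps(variants: Iterable[Variant], path: str | Path) -> None:
    df = pd.DataFrame(
        [(v.rsid, v.chrom, v.pos0, v.locus, v.assoc_class) for v in variants],
        columns=_LEAD_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# VCF haplotype panels
# ---------------------------------------------------------------------------


def read_vcf_panel(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    panel_name: str | None = None,
) -> HaplotypePanel:
    """Load a (preferably phased) VCF into a haplotype matrix.

    Multi-allelic records are split into one biallelic column per alternate
    allele, with ``:altN`` suffixed rsIDs to keep identifiers unique.  If any
    record carries an unphased genotype the panel is flagged ``phased=False``
    so LD estimation falls back to the EM genotype pathway.

    ``region`` is (chrom, start0, end0) in the package's 0-based half-open
    convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    phased = True
    ploidy_seen: set[int] = set()

    if region is not None:
        chrom0, start0, end0 = region
        chrom0 = normalize_chrom(chrom0)
        records = [
            rec
            for rec in vcf
            if normalize_chrom(rec.CHROM) == chrom0 and start0 <= rec.POS - 1 < end0
        ]
    else:
        records = list(vcf)

    for rec in records:
        gts = rec.genotype.array()  # (n_samples, ploidy+1); last col = phase flag
        ploidy = gts.shape[1] - 1
        ploidy_seen.add(ploidy)
        if len(ploidy_seen) > 1:
            raise ValidationError(f"mixed ploidy in {path}")
        alleles = gts[:, :ploidy]
        if (alleles < 0).any():
            raise ValidationError(f"missing genotypes at {rec.ID or rec.POS}")
        if not gts[:, ploidy].all():
            phased = False
        rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            rsid = rid if len(rec.ALT) == 1 else f"{rid}:alt{alt_idx}"
            variants.append(
                Variant(
                    rsid=rsid,
                    chrom=normalize_chrom(rec.CHROM),
                    pos0=rec.POS - 1,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                )
            )
            columns.append((alleles == alt_idx).astype(np.int8).ravel(order="C"))

    if not variants:
        raise EmptyPanelError(f"no VCF records in requested region of {path}")
    matrix = np.stack(columns, axis=1)
    name = panel_name or Path(path).stem
    return HaplotypePanel(variants=variants, haplotypes=matrix, panel_name=name, phased=phased)


def write_vcf_panel(panel: HaplotypePanel, path: str | Path) -> None:
    """Emit a minimal phased VCF 4.2 for a panel (round-trips through read_vcf_panel)."""
    n_samples = panel.n_chromosomes // 2
    sample_names = [f"S{i:04d}" for i in range(n_samples)]
    chroms = []
    for v in panel.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names))
    order = sorted(range(len(panel.variants)), key=lambda i: (chroms.index(panel.variants[i].chrom), panel.variants[i].pos0))
    for i in order:
        v = panel.variants[i]
        col = panel.haplotypes[:, i]
        gts = "\t".join(f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(n_samples))
        lines.append(
            f"{v.chrom}\t{v.pos0 + 1}\t{v.rsid}\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# BED annotation tracks
# ---------------------------------------------------------------------------

#: payload fields inside a BED name column are ';'-separated (motif_id;tf_name)


def read_bed_track(path: str | Path, kind: str) -> AnnotationTrack:
    """Read a BED3/BED4 file into an :class:`AnnotationTrack` of the given kind."""
    track = AnnotationTrack(kind=kind)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
            payload = fields[3] if len(fields) > 3 else ""
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if kind in _PAYLOAD_KINDS and not payload:
                raise FormatError(f"{path}:{lineno}: {kind} requires a name in column 4")
            track.add(chrom, start, end, payload)
    return track


def write_bed_track(track: AnnotationTrack, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom, start, end, payload in sorted(track.intervals):
            if track.kind in _PAYLOAD_KINDS:
                fh.write(f"{chrom}\t{start}\t{end}\t{payload}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# eQTL tables
# ---------------------------------------------------------------------------

_EQTL_COLUMNS = ["rsid", "target_gene", "cell_type"]


def read_eqtl_table(path: str | Path) -> list[EQTLRecord]:
    """Read an eQTL TSV (rsid, target_gene, cell_type); one record per row."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in _EQTL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"eQTL table {path} is missing column {col!r}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if not row.target_gene:
            raise ValidationError(f"{path}:{lineno}: eQTL row lacks a gene symbol")
        records.append(
            EQTLRecord(rsid=row.rsid, target_gene=row.target_gene, cell_type=row.cell_type)
        )
    return records


def write_eqtl_table(records: Sequence[EQTLRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.rsid, r.target_gene, r.cell_type) for r in records], columns=_EQTL_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
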