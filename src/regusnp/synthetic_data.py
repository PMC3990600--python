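"""Synthetic inputs with known ground truth.

Three generators live here:

* :func:`simulate_panel` — LD-block-structured haplotype panels with
  controllable within-block r², built by planting each site's joint
  haplotype frequency with a latent block founder column (no coalescent
  machinery; direct control of r²).
* :func:`plant_evidence` — annotation tracks and eQTL rows constructed so
  that evidence collection followed by classification recovers a requested
  category label exactly, including withholding evidence that would promote
  the variant to a better category.
* :func:`study_fixture` — the packaged fixture encoding a published survey
  of regulatory variants at late-onset Alzheimer's disease GWAS loci:
  44 lead SNPs, two reference-panel LD structures whose per-threshold proxy
  counts reproduce the survey's panel table, and planted evidence
  reproducing every reported functional SNP's category and payloads.

Fixture provenance notes: the 34 functional SNPs, their categories, eQTL
genes, motifs and bound proteins, the 13 identifiable lead SNPs and the
lead↔proxy r² bins are transcribed from the published report tables.
DNase peak / footprint flags are not printed there and are back-derived
from each row's category (e.g. a 2b row implies footprint and peak present,
eQTL absent).  Everything else — the remaining 31 lead SNPs (rs99xxxxxx
identifiers), panel haplotypes, padding variants and their category
distribution — is synthetic, constructed only to realize the survey's
printed totals (614 examined / 220 no-data / 394 scored, panel counts
612/466/189, 122/85/62, unions 614/472/191).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evidence_collector import EvidenceBundle, collect_evidence, normalize_tf_name
from .io_formats import (
    AnnotationTrack,
    EQTLRecord,
    HaplotypePanel,
    ValidationError,
    Variant,
)
from .regulome_classifier import classify

__all__ = [
    "LDBlockSpec",
    "PlantSpec",
    "FeasibilityError",
    "simulate_panel",
    "plant_evidence",
    "StudyFixture",
    "study_fixture",
    "CATEGORY_RECIPES",
]


class FeasibilityError(ValueError):
    """Requested (r², allele frequency) combination violates the Lewontin bound."""


# ---------------------------------------------------------------------------
# LD-block panel simulation
# ---------------------------------------------------------------------------


@dataclass
class LDBlockSpec:
    """Recipe for a haplotype panel made of independent LD blocks.

    ``blocks`` is a list of (variant count, target pairwise r² within the
    block, (freq_lo, freq_hi)) tuples.  Sites within a block are noisy
    copies of a latent founder column, giving pairwise r² close to the
    target; founders of different blocks are independent, so inter-block
    r² is near zero.
    """

    n_chromosomes: int = 2000
    blocks: list[tuple[int, float, tuple[float, float]]] = field(default_factory=list)
    seed: int = 0
    chrom: str = "chr1"
    start_pos: int = 1_000_000
    spacing_bp: int = 2_000

    def __post_init__(self) -> None:
        if self.n_chromosomes % 2 or self.n_chromosomes < 100:
            raise ValidationError("n_chromosomes must be even and >= 100")
        for _, r2, _ in self.blocks:
            if not (0 <= r2 <= 1):
                raise ValidationError(f"target r² must be in [0, 1], got {r2}")


def _planted_column(
    z: np.ndarray, p: float, corr: float, rng: np.random.Generator
) -> np.ndarray:
    """A 0/1 column with frequency ~p and correlation ~corr with founder z."""
    n = z.size
    q = z.mean()
    d = corr * np.sqrt(p * (1 - p) * q * (1 - q))
    d_max = min(p, q) - p * q
    d_min = max(0.0, p + q - 1.0) - p * q
    if d > d_max + 1e-12 or d < d_min - 1e-12:
        raise FeasibilityError(
            f"target correlation {corr:.4f} at frequencies p={p:.3f}, q={q:.3f} "
            f"requires D={d:.4f} outside the Lewontin bound [{d_min:.4f}, {d_max:.4f}]"
        )
    n1 = int(round(n * p))
    n11 = int(round(n * (p * q + d)))
    ones = np.flatnonzero(z == 1)
    zeros = np.flatnonzero(z == 0)
    n11 = min(n11, ones.size, n1)
    n10 = min(n1 - n11, zeros.size)
    col = np.zeros(n, dtype=np.int8)
    col[rng.choice(ones, size=n11, replace=False)] = 1
    col[rng.choice(zeros, size=n10, replace=False)] = 1
    return col


def _feasible_freq(q: float, corr: float, f_lo: float, f_hi: float, n: int,
                   rng: np.random.Generator, max_tries: int = 200) -> float:
    """Sample a site frequency from [f_lo, f_hi] compatible with the requested
    founder correlation; high correlations restrict p to a band around q."""
    for _ in range(max_tries):
        p = float(rng.uniform(f_lo, f_hi))
        p = min(max(p, 1.0 / n), 1 - 1.0 / n)
        d = corr * np.sqrt(p * (1 - p) * q * (1 - q))
        if d <= min(p, q) - p * q + 1e-12:
            return p
    raise FeasibilityError(
        f"no frequency in [{f_lo}, {f_hi}] supports correlation {corr:.4f} with a "
        f"founder at frequency {q:.3f}: the required D exceeds the Lewontin bound "
        f"D_max = min(p, q) - pq throughout the range"
    )


def simulate_panel(spec: LDBlockSpec, panel_name: str = "simulated") -> HaplotypePanel:
    """Draw a haplotype panel realizing ``spec``; deterministic under its seed."""
    rng = np.random.default_rng(spec.seed)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    n = spec.n_chromosomes
    pos = spec.start_pos
    for bi, (n_var, target_r2, (f_lo, f_hi)) in enumerate(spec.blocks):
        q = float(rng.uniform(f_lo, f_hi))
        q = min(max(q, 1.0 / n), 1 - 1.0 / n)
        n_q = int(round(n * q))
        z = np.zeros(n, dtype=np.int8)
        z[rng.choice(n, size=n_q, replace=False)] = 1
        perfect = target_r2 >= 1.0 - 1e-9
        # pairwise r² between two planted sites is (corr with founder)^4
        corr = 1.0 if perfect else target_r2**0.25
        for vi in range(n_var):
            if perfect:
                col = z.copy() if vi % 2 == 0 else (1 - z).astype(np.int8)
            else:
                p = _feasible_freq(q, corr, f_lo, f_hi, n, rng)
                col = _planted_column(z, p, corr, rng)
            variants.append(
                Variant(rsid=f"rs_sim_b{bi}_{vi}", chrom=spec.chrom, pos0=pos)
            )
            columns.append(col)
            pos += spec.spacing_bp
    if not variants:
        raise ValidationError("spec contains no blocks")
    return HaplotypePanel(
        variants=variants,
        haplotypes=np.stack(columns, axis=1),
        panel_name=panel_name,
    )


# ---------------------------------------------------------------------------
# Evidence planting
# ---------------------------------------------------------------------------

#: flag recipe per category label:
#: (eqtl, tf, motif, matched_motif, footprint, matched_footprint, peak).
#: Each recipe is the minimal consistent bundle classifying to its label.
CATEGORY_RECIPES: dict[str, tuple[bool, bool, bool, bool, bool, bool, bool]] = {
    "1a": (True, True, True, True, True, True, True),
    "1b": (True, True, True, False, True, False, True),
    "1c": (True, True, True, True, False, False, True),
    "1d": (True, True, True, False, False, False, True),
    "1e": (True, True, True, True, False, False, False),
    "1f": (True, True, False, False, False, False, False),
    "2a": (False, True, True, True, True, True, True),
    "2b": (False, True, True, False, True, False, True),
    "2c": (False, True, True, True, False, False, True),
    "3a": (False, True, True, False, False, False, True),
    "3b": (False, True, True, True, False, False, False),
    "4": (False, True, False, False, False, False, True),
    "5": (False, True, False, False, False, False, False),
    "6": (False, False, True, False, False, False, False),
    "NO_DATA": (False, False, False, False, False, False, False),
}

# evidence interval half-widths (bp) around a planted variant
_TF_HALF = 35
_MOTIF_HALF = 10
_FP_HALF = 5
_PEAK_HALF = 60

#: default payload-name pools (vocabulary of the encoded report tables)
_TF_POOL = ("CTCF", "POLR2A", "JUN", "GATA2", "USF1", "RAD21", "FOXA1", "STAT1", "EP300", "RFX3")
_MOTIF_POOL = ("TCF11:MafG", "Nkx2-5", "Pax-3", "Oct-1", "Irx-3", "HEN1", "E47", "DMRT3", "Glis2", "Zfp740")
_GENE_POOL = ("MS4A4A", "C1QTNF4", "GATS", "PILRB", "TRIM4", "NMB", "DPYSL2", "MYBPC3", "SPI1")


@dataclass
class PlantSpec:
    """Per-variant target category labels plus payload-name pools."""

    targets: dict[str, str]  # rsid -> category label
    tf_pool: tuple[str, ...] = _TF_POOL
    motif_pool: tuple[str, ...] = _MOTIF_POOL
    gene_pool: tuple[str, ...] = _GENE_POOL
    cell_type: str = "monocytes"
    seed: int = 0

    def __post_init__(self) -> None:
        bad = {label for label in self.targets.values() if label not in CATEGORY_RECIPES}
        if bad:
            raise ValidationError(f"unachievable target labels: {sorted(bad)}")


def _empty_tracks() -> dict[str, AnnotationTrack]:
    return {
        "tf_peak": AnnotationTrack(kind="tf_peak"),
        "motif_instance": AnnotationTrack(kind="motif_instance"),
        "dnase_peak": AnnotationTrack(kind="dnase_peak"),
        "dnase_footprint": AnnotationTrack(kind="dnase_footprint"),
    }


def _plant_flags(
    variant: Variant,
    flags: tuple[bool, bool, bool, bool, bool, bool, bool],
    tracks: dict[str, AnnotationTrack],
    eqtls: list[EQTLRecord],
    tf_name: str,
    motif_id: str,
    gene: str,
    cell_type: str,
) -> None:
    """Materialize one flag recipe as intervals/records at the variant."""
    e, t, m, mm, f, mf, p = flags
    chrom, pos = variant.chrom, variant.pos0
    if e:
        eqtls.append(EQTLRecord(rsid=variant.rsid, target_gene=gene, cell_type=cell_type))
    if t:
        tracks["tf_peak"].add(chrom, pos - _TF_HALF, pos + _TF_HALF + 1, tf_name)
    if m:
        # an unmatched motif gets a decoy TF guaranteed absent from bindings
        motif_tf = tf_name if mm else f"{motif_id}-decoy"
        tracks["motif_instance"].add(
            chrom, pos - _MOTIF_HALF, pos + _MOTIF_HALF + 1, f"{motif_id};{motif_tf}"
        )
    if f:
        fp_motif = motif_id if mf else f"{motif_id}-fpx"
        tracks["dnase_footprint"].add(
            chrom, pos - _FP_HALF, pos + _FP_HALF + 1, f"{fp_motif};{tf_name}"
        )
    if p:
        tracks["dnase_peak"].add(chrom, pos - _PEAK_HALF, pos + _PEAK_HALF + 1, "")


def plant_evidence(
    variants: list[Variant], spec: PlantSpec
) -> tuple[dict[str, AnnotationTrack], list[EQTLRecord]]:
    """Generate tracks/eQTLs so each variant classifies to its target label.

    Variants should be spaced more than ~130 bp apart (twice the widest
    planted interval); closer spacing can leak evidence between neighbours.
    """
    rng = np.random.default_rng(spec.seed)
    tracks = _empty_tracks()
    eqtls: list[EQTLRecord] = []
    for variant in variants:
        label = spec.targets.get(variant.rsid, "NO_DATA")
        flags = CATEGORY_RECIPES[label]
        _plant_flags(
            variant,
            flags,
            tracks,
            eqtls,
            tf_name=str(rng.choice(spec.tf_pool)),
            motif_id=str(rng.choice(spec.motif_pool)),
            gene=str(rng.choice(spec.gene_pool)),
            cell_type=spec.cell_type,
        )
    return tracks, eqtls


# ---------------------------------------------------------------------------
# The packaged study fixture
# ---------------------------------------------------------------------------

# Functional-SNP table transcription: one entry per reported score-<3 row.
# Fields: rsid, chrom, pos0, score, printed locus, position class,
# eQTL target genes, motif names, bound proteins.  Payload strings are kept
# verbatim (including idiosyncratic spellings).
_T3 = [
    ("rs667897", "chr11", 59936978, "1b", "MS4A region", "intergenic",
     ["MS4A4A"], ["TCF11:MafG", "NFE2L2"],
     ["SMARCC2", "STAT1", "JUN", "MXI1", "YY1", "CEBPB", "GTF2F1", "FOXA1", "FOS",
      "USF1", "STAT3", "BRCA1", "EP300", "POLR2A", "ELK4", "PRDM1", "RFX5", "GATA2",
      "TRIM28", "SETDB1", "JUND"]),
    ("rs7103835", "chr11", 47461692, "1f", "RAPSN", "intron 4", ["C1QTNF4"], [], []),
    ("rs6485758", "chr11", 47530023, "1f", "CELF1", "intron 1", ["C1QTNF4"], [], []),
    ("rs11039290", "chr11", 47572278, "1f", "CELF1", "intron 1", ["C1QTNF4"],
     ["Glis2", "Mtf1"], []),
    ("rs2293576", "chr11", 47434985, "1f", "SLC39A13", "exon 5",
     ["C1QTNF4", "MYBPC3", "SPI1"], [], ["RAD21"]),
    ("rs7933019", "chr11", 47509136, "1f", "CELF1", "intron 2", ["C1QTNF4"], [], []),
    ("rs2280231", "chr11", 47600437, "1f", "NDUFS3", "5' UTR", ["C1QTNF4"], [],
     ["BCLAF1", "CHD2", "CREBBP", "CTBP2", "E2F1", "E2F4", "EFL1", "ELK4", "EP300",
      "ERG", "ETS1", "EWSR1", "FLI1", "GABPA", "GATA1", "GTF2F1", "HNF4A", "IRF1",
      "IRF4", "JUNB", "JUND", "MYC", "NFKB1", "NR2C2", "PAX5", "POLR2A", "SIX5",
      "SMARCB1", "SMARCC1", "SP1", "STAT1", "TAF1", "TBP", "TCF4", "TRIM28", "USF1",
      "WRNIP1", "ZBTB7A", "ZEB1"]),
    ("rs7120548", "chr11", 47662931, "1f", "MTCH2", "intron 1",
     ["C1QTNF4", "MYBPC3", "SPI1"], [], []),
    ("rs7114011", "chr11", 47811308, "1f", "NUP160", "intron 29",
     ["C1QTNF4", "MYBPC3", "SPI1"], ["AP-3", "Oct-1", "Irx-3"], []),
    ("rs1476679", "chr7", 100004445, "1f", "ZCWPW1", "intron 11",
     ["GATS", "PILRB", "TRIM4"], [], ["RFX3", "CTCF"]),
    ("rs17057043", "chr8", 27220309, "1f", "PTK2B", "intron 5",
     ["DPYSL2", "PTK2B"], ["N-Myc", "RBP-Jkappa"], ["IRF1"]),
    ("rs1303615", "chr11", 59885119, "1f", "MS4A region", "intergenic",
     ["MS4A4A"], [], []),
    ("rs617135", "chr11", 59936756, "1f", "MS4A region", "intergenic",
     ["MS4A4A"], [], ["POLR2A", "MAX", "SMARCC2"]),
    ("rs11230180", "chr11", 59961485, "1f", "MS4A region", "intergenic",
     ["MS4A4A"], [], ["JUNB", "NKB1"]),
    ("rs2123314", "chr11", 59966294, "1f", "MS4A region", "intergenic",
     ["MS4A4A"], [], []),
    ("rs2081547", "chr11", 59989429, "1f", "MS4A4E", "intron 2",
     ["MS4A4A"], [], ["CEBPB", "JUN", "JUND"]),
    ("rs655231", "chr11", 60013856, "1f", "MS4A region", "intergenic",
     ["MS4A4A"], [], ["RFX3"]),
    ("rs12917429", "chr15", 85425096, "1f", "SLC28A1", "intergenic", ["NMB"], [], []),
    ("rs12909280", "chr15", 85429355, "1f", "SLC28A1", "intron 1", ["NMB"], [], ["RFX3"]),
    ("rs636317", "chr11", 60019149, "2a", "MS4A region", "intergenic", [],
     ["TAL1", "CTCF"],
     ["CTCF", "RAD21", "FOXA1", "SMC3", "BCLAF1", "YY1", "POU2F2", "ZNF143"]),
    ("rs636341", "chr11", 60019160, "2a", "MS4A region", "intergenic", [],
     ["CTCF", "STAT1:STAT1", "C/EBPbeta"],
     ["CTCF", "RAD21", "FOXA1", "SMC3", "BCLAF1", "YY1", "POU2F2", "ZNF143"]),
    ("rs1237999", "chr11", 85815029, "2a", "PICALM region", "intergenic", [],
     ["AP-1", "Jundm2"], ["JUN", "JUNB", "JUND", "FOS"]),
    ("rs3764650", "chr19", 1046519, "2a", "ABCA7", "intron 13", [],
     ["TBX22", "TBX18", "TBX15", "HNF4alpha1", "COUPTF", "HNF4", "COUP-TF = HNF-4",
      "NR2F1"],
     ["SP1", "HNF4A", "HNF4G", "BHLHE40", "USF1", "USF2"]),
    ("rs17429217", "chr12", 117295332, "2b", "HRK/RNFT2 region", "intergenic", [],
     ["HNF4 = COUP", "Hnf4a"], ["EBF1"]),
    ("rs4715019", "chr6", 47447040, "2b", "CD2AP", "intron 1", [],
     ["Irx-3", "Sox15", "HoxB5", "Zfp105", "Hoxa3", "DIx1", "Hoxb8", "Irx6",
      "Hoxa6", "Hoxb6", "Hoxb5"],
     ["POLR2A"]),
    ("rs1532278", "chr8", 27466314, "2b", "CLU", "intron 3", [], ["Nkx2-5"],
     ["NANOG", "TAF1", "USF1", "MAX", "USF2", "GATA2"]),
    ("rs7933202", "chr11", 59936925, "2b", "MS4A region", "intergenic", [],
     ["DMRT3"],
     ["POLR2A", "SMARCC2", "STAT1", "JUN", "YY1", "CEBPB", "GTF2F1", "FOS", "USF1",
      "STAT3", "EP300", "ELK4", "MXI1", "FOXA1", "BRCA1", "PRDM1", "GATA2",
      "TRIM28", "SETDB1", "JUND"]),
    ("rs542126", "chr11", 85811237, "2b", "PICALM region", "intergenic", [],
     ["E47"], ["HNF4A", "RXRA", "POLR3A", "USF2", "USF1"]),
    ("rs4147911", "chr19", 1047686, "2b", "ABCA7", "intron 16", [], ["HEN1"],
     ["IKZF1"]),
    ("rs6024870", "chr20", 54997567, "2b", "CASS4", "intron 2", [], ["Pax-3"],
     ["TCF4", "CTCF", "FOS", "RAD21"]),
    ("rs11689287", "chr2", 127888336, "2b", "BIN1 region", "intergenic", [],
     ["FOXL1", "Oct-1", "Six6", "FOXP1", "Tbp"], ["CTCF"]),
    ("rs812651", "chr3", 64918621, "2b", "ADAMTS9-AS2", "intron 4", [],
     ["RBP-Jkappa"], ["HNF4A", "SETDB1"]),
    ("rs73223431", "chr8", 27219986, "2b", "PTK2B", "intron 5", [],
     ["TRUE", "TBX15", "TBX18", "TBX22", "T", "Brachyury"],
     ["MYC", "GATA1", "CDX2", "POLR2A", "JUN", "NKFB1", "HNF4A", "GATA2"]),
    ("rs867230", "chr8", 27468502, "2b", "CLU", "intron 1", [], ["MEF-2", "Zfp740"],
     ["GATA1", "GABPA"]),
]

# Lead SNPs identifiable from the report's LD table: (rsid, chrom, pos0,
# lead locus, assoc class).  Positions of the four functional leads are
# printed; the other positions are synthetic cluster centres chosen to keep
# every known proxy inside the default search window.
_KNOWN_LEADS = [
    ("rs3764650", "chr19", 1046519, "ABCA7", "gw_significant_risk"),
    ("rs17429217", "chr12", 117295332, "HRK/RNFT2", "suggestive_risk_or_aao"),
    ("rs704454", "chr3", 64920000, "ADAMTS9", "suggestive_risk_or_aao"),
    ("rs7274581", "chr20", 55000000, "CASS4", "gw_significant_risk"),
    ("rs1476679", "chr7", 100004445, "ZCWPW1", "gw_significant_risk"),
    ("rs9296559", "chr6", 47440000, "CD2AP", "gw_significant_risk"),
    ("rs9349407", "chr6", 47450000, "CD2AP", "gw_significant_risk"),
    ("rs10838725", "chr11", 47620000, "CELF1", "gw_significant_risk"),
    ("rs28834970", "chr8", 27195000, "PTK2B", "gw_significant_risk"),
    ("rs1532278", "chr8", 27466314, "CLU", "gw_significant_risk"),
    ("rs561655", "chr11", 85813000, "PICALM", "gw_significant_risk"),
    ("rs3743162", "chr15", 85427000, "ZNF592/ALPK3/SLC28A1", "suggestive_risk_or_aao"),
    ("rs7561528", "chr2", 127890000, "BIN1", "gw_significant_risk"),
]

# lead ↔ functional-proxy LD bins from the report's LD table
# (1 = r² in [0.80, 0.90), 2 = [0.90, 1.0), 3 = 1.0).
_T4_LINKS = [
    ("rs3764650", "rs3764650", 3), ("rs3764650", "rs4147911", 2),
    ("rs17429217", "rs17429217", 3),
    ("rs704454", "rs812651", 2),
    ("rs7274581", "rs6024870", 1),
    ("rs1476679", "rs1476679", 3),
    ("rs9296559", "rs4715019", 3), ("rs9349407", "rs4715019", 3),
    ("rs10838725", "rs2293576", 1), ("rs10838725", "rs7933019", 2),
    ("rs10838725", "rs2280231", 2), ("rs10838725", "rs7120548", 1),
    ("rs10838725", "rs7114011", 2), ("rs10838725", "rs11039290", 2),
    ("rs10838725", "rs6485758", 2), ("rs10838725", "rs7103835", 1),
    ("rs28834970", "rs17057043", 1), ("rs28834970", "rs73223431", 1),
    ("rs1532278", "rs1532278", 3), ("rs1532278", "rs867230", 1),
    ("rs561655", "rs1237999", 1), ("rs561655", "rs542126", 1),
    ("rs3743162", "rs12917429", 3), ("rs3743162", "rs12909280", 3),
    ("rs7561528", "rs11689287", 2),
]

#: synthetic lead for the MS4A region (its rsID is not identifiable from the
#: report, which lists no MS4A rows in its LD table); the 10 MS4A functional
#: SNPs are linked to it at the loosest bin.
_MS4A_LEAD = ("rs99000001", "chr11", 59950000, "MS4A region", "gw_significant_risk")
_MS4A_FUNCTIONAL = [
    "rs667897", "rs1303615", "rs617135", "rs11230180", "rs2123314",
    "rs2081547", "rs655231", "rs636317", "rs636341", "rs7933202",
]

# additional synthetic leads: (locus, assoc class, count) — fills the roster
# of 28 genome-wide significant + 16 suggestive leads named in the survey.
_SYNTH_LEAD_LOCI = [
    ("MS4A region", "gw_significant_risk", 1),   # second MS4A lead
    ("PICALM", "gw_significant_risk", 1),
    ("BIN1", "gw_significant_risk", 1),
    ("CD33", "gw_significant_risk", 1),
    ("EPHA1", "gw_significant_risk", 2),
    ("CR1", "gw_significant_risk", 2),
    ("HLA-DRB5/HLA-DRB1", "gw_significant_risk", 1),
    ("SORL1", "gw_significant_risk", 2),
    ("SLC24A4/RIN3", "gw_significant_risk", 1),
    ("DSG2", "gw_significant_risk", 1),
    ("INPP5D", "gw_significant_risk", 1),
    ("MEF2C", "gw_significant_risk", 1),
    ("NME8", "gw_significant_risk", 1),
    ("FERMT2", "gw_significant_risk", 1),
    ("DCHS", "suggestive_risk_or_aao", 1),
    ("KCNV2/VLDLR", "suggestive_risk_or_aao", 1),
    ("LEMD2/MLN/MIR1275", "suggestive_risk_or_aao", 1),
    ("LOC390958/Sec11C", "suggestive_risk_or_aao", 1),
    ("PSMD1/HTR2B/ARMC9", "suggestive_risk_or_aao", 1),
    ("NRXN3", "suggestive_risk_or_aao", 1),
    ("PPP1R3B", "suggestive_risk_or_aao", 1),
    ("MMP3/MMP12", "suggestive_risk_or_aao", 1),
    ("FLJ37543", "suggestive_risk_or_aao", 1),
    ("PCDH7", "suggestive_risk_or_aao", 1),
    ("LOC440390", "suggestive_risk_or_aao", 1),
    ("MAPRE1P2", "suggestive_risk_or_aao", 1),
    ("PP1R2P5", "suggestive_risk_or_aao", 1),
]

# per-(lead-locus) tested counts from the survey's results text (they
# include the locus' lead SNPs and functional SNPs).
_LOCUS_TESTED = {
    "MS4A region": 157, "ZCWPW1": 8, "CLU": 10, "ABCA7": 7, "CELF1": 25,
    "PTK2B": 6, "CASS4": 11, "PICALM": 93, "CD2AP": 69, "BIN1": 6,
    "ADAMTS9": 6, "ZNF592/ALPK3/SLC28A1": 7, "HRK/RNFT2": 1,
}

# survey totals and panel table (loosest -> tightest threshold)
FIXTURE_TOTALS = {
    "n_examined": 614,
    "n_no_data": 220,
    "n_scored_1_6": 394,
    "panel_counts": {"1000Genomes": (612, 466, 189), "HapMap3": (122, 85, 62)},
    "union_counts": (614, 472, 191),
}

#: synthetic per-category padding distribution for the 359 scored,
#: non-functional, non-lead-rs10838725 variants (the survey's supplement
#: with the real distribution is not machine-readable).
PADDING_CATEGORIES = {"6": 150, "5": 120, "4": 40, "3a": 25, "3b": 24}

# joint (1000Genomes bin, HapMap3 bin) occupancy matrix realizing the panel
# table; bins: 0 = absent, 1 = [0.8, 0.9), 2 = [0.9, 1.0), 3 = 1.0.
_PANEL_CELLS = [
    ((3, 3), 60), ((3, 0), 129), ((2, 2), 19), ((2, 1), 30), ((2, 0), 228),
    ((1, 2), 4), ((1, 1), 7), ((1, 0), 135), ((0, 3), 2),
]

_PANEL_N_CHROM = 120
# ones-to-zeros flips from a 60/60 lead column realizing each r² bin:
# 0 flips -> r² = 1, 2 -> 0.9355, 4 -> 0.875
_FLIPS_PER_BIN = {3: 0, 2: 2, 1: 4}


@dataclass
class StudyFixture:
    """Everything the pipeline needs, with known expected outcomes."""

    leads: list[Variant]
    panels: dict[str, HaplotypePanel]
    tracks: dict[str, AnnotationTrack]
    eqtls: list[EQTLRecord]
    expected_scores: dict[str, str]  # rsid -> category label (all 614)
    functional_rsids: list[str]  # the 34 reported score-<3 rsIDs
    lead_links: list[tuple[str, str, int]]  # (lead, proxy, bin 1/2/3)
    position_classes: dict[str, str]
    variants: list[Variant]  # full 614-variant universe


def _fixture_leads() -> list[Variant]:
    leads = [
        Variant(rsid=r, chrom=c, pos0=p, locus=loc, assoc_class=a)
        for r, c, p, loc, a in _KNOWN_LEADS
    ]
    leads.append(Variant(rsid=_MS4A_LEAD[0], chrom=_MS4A_LEAD[1], pos0=_MS4A_LEAD[2],
                         locus=_MS4A_LEAD[3], assoc_class=_MS4A_LEAD[4]))
    # synthetic leads on spread-out cluster centres
    anchor = {v.locus: v for v in leads}
    next_id = 99000002
    chrom_cycle = 0
    for locus, assoc, count in _SYNTH_LEAD_LOCI:
        for k in range(count):
            if locus in anchor:
                base = anchor[locus]
                chrom, pos = base.chrom, base.pos0 + 3000 * (k + 1)
            else:
                chrom_cycle += 1
                chrom = f"chr{(chrom_cycle % 22) + 1}"
                pos = 150_000_000 + chrom_cycle * 1_000_000 + k * 3000
            lead = Variant(rsid=f"rs{next_id}", chrom=chrom, pos0=pos,
                           locus=locus, assoc_class=assoc)
            next_id += 1
            leads.append(lead)
            if locus not in anchor:
                anchor[locus] = lead
    assert len(leads) == 44
    return leads


def _padding_positions(center: int, count: int, occupied: set[tuple[str, int]],
                       chrom: str) -> list[int]:
    """Deterministic comb of positions around a cluster centre, skipping
    slots within 200 bp of anything already placed."""
    out: list[int] = []
    k = 1
    while len(out) < count:
        offset = ((k + 1) // 2) * 1600 * (1 if k % 2 else -1)
        pos = center + offset
        k += 1
        if pos < 0:
            continue
        if any((chrom, q) in occupied for q in range(pos - 200, pos + 201)):
            continue
        out.append(pos)
        occupied.add((chrom, pos))
    return out


def study_fixture(seed: int = 2014) -> StudyFixture:
    """Materialize the packaged survey fixture.

    Deterministic given ``seed`` (which only controls payload-name draws,
    padding-category shuffling and haplotype patterns — never the counts).
    """
    rng = np.random.default_rng(seed)
    leads = _fixture_leads()
    lead_by_rsid = {v.rsid: v for v in leads}
    lead_locus_anchor: dict[str, Variant] = {}
    for v in leads:
        lead_locus_anchor.setdefault(v.locus, v)

    occupied: set[tuple[str, int]] = set()
    for v in leads:
        occupied.add((v.chrom, v.pos0))
    for rsid, chrom, pos0, *_ in _T3:
        occupied.add((chrom, pos0))

    # --- assemble the 614-variant universe, locus by locus -----------------
    variants: list[Variant] = list(leads)
    functional_proxies: list[Variant] = []
    for rsid, chrom, pos0, score, locus, pos_class, eq, mo, pr in _T3:
        if rsid in lead_by_rsid:
            continue  # the four functional leads are already in the roster
        functional_proxies.append(
            Variant(rsid=rsid, chrom=chrom, pos0=pos0, locus=locus)
        )
    variants.extend(functional_proxies)

    # locus membership of every variant (by lead locus, for proxy wiring)
    locus_of: dict[str, str] = {v.rsid: v.locus for v in leads}
    link_map = list(_T4_LINKS) + [(_MS4A_LEAD[0], r, 1) for r in _MS4A_FUNCTIONAL]
    for lead_rsid, proxy_rsid, _bin in link_map:
        locus_of.setdefault(proxy_rsid, lead_by_rsid[lead_rsid].locus)

    # padding counts per locus: named loci hit their printed tested totals;
    # the remainder is spread round-robin over the other lead clusters.
    locus_members: dict[str, list[str]] = {}
    for rsid, locus in locus_of.items():
        locus_members.setdefault(locus, []).append(rsid)
    named_total = sum(_LOCUS_TESTED.values())
    other_loci = sorted(set(locus_of[v.rsid] for v in leads) - set(_LOCUS_TESTED))
    remainder = FIXTURE_TOTALS["n_examined"] - named_total - sum(
        len(locus_members[loc]) for loc in other_loci
    )
    padding_per_locus = {
        loc: _LOCUS_TESTED[loc] - len(locus_members[loc]) for loc in _LOCUS_TESTED
    }
    for i in range(remainder):
        loc = other_loci[i % len(other_loci)]
        padding_per_locus[loc] = padding_per_locus.get(loc, 0) + 1

    next_pad = 1
    padding_variants: list[Variant] = []
    for loc in list(_LOCUS_TESTED) + other_loci:
        count = padding_per_locus.get(loc, 0)
        if count <= 0:
            continue
        anchor = lead_locus_anchor[loc]
        for pos in _padding_positions(anchor.pos0, count, occupied, anchor.chrom):
            v = Variant(rsid=f"rs98{next_pad:06d}", chrom=anchor.chrom, pos0=pos,
                        locus=loc)
            next_pad += 1
            padding_variants.append(v)
            locus_of[v.rsid] = loc
            locus_members.setdefault(loc, []).append(v.rsid)
    variants.extend(padding_variants)
    assert len(variants) == FIXTURE_TOTALS["n_examined"], len(variants)

    # --- category labels ---------------------------------------------------
    expected_scores: dict[str, str] = {row[0]: row[3] for row in _T3}
    expected_scores["rs10838725"] = "6"  # the survey prints the CELF1 lead as 6
    unlabeled = [v.rsid for v in variants if v.rsid not in expected_scores]
    label_pool = ["NO_DATA"] * FIXTURE_TOTALS["n_no_data"]
    for label, count in PADDING_CATEGORIES.items():
        label_pool.extend([label] * count)
    assert len(label_pool) == len(unlabeled)
    rng.shuffle(label_pool)
    expected_scores.update(dict(zip(unlabeled, label_pool)))

    # --- plant evidence ----------------------------------------------------
    tracks = _empty_tracks()
    eqtls: list[EQTLRecord] = []
    by_rsid = {v.rsid: v for v in variants}
    for rsid, chrom, pos0, score, locus, pos_class, eq_genes, motifs, proteins in _T3:
        _plant_t3_row(by_rsid[rsid], score, eq_genes, motifs, proteins, tracks, eqtls)
    pad_rng = np.random.default_rng(seed + 1)
    for rsid in ["rs10838725"] + unlabeled:
        label = expected_scores[rsid]
        if label == "NO_DATA":
            continue
        _plant_flags(
            by_rsid[rsid], CATEGORY_RECIPES[label], tracks, eqtls,
            tf_name=str(pad_rng.choice(_TF_POOL)),
            motif_id=str(pad_rng.choice(_MOTIF_POOL)),
            gene=str(pad_rng.choice(_GENE_POOL)),
            cell_type="monocytes",
        )

    # --- panel bins and haplotype panels -----------------------------------
    bins: dict[str, tuple[int, int]] = {}
    star_bin = {}
    for lead_rsid, proxy_rsid, b in link_map:
        if proxy_rsid not in lead_by_rsid:
            star_bin[proxy_rsid] = max(star_bin.get(proxy_rsid, 0), b)
    for v in leads:
        bins[v.rsid] = (3, 3)
    for rsid, b in star_bin.items():
        bins[rsid] = (b, 0)  # functional proxies live in the 1000 Genomes panel
    cell_slots: list[tuple[int, int]] = []
    used = {
        cell: sum(1 for b in bins.values() if b == cell)
        for cell in {c for c, _ in _PANEL_CELLS}
    }
    for cell, count in _PANEL_CELLS:
        cell_slots.extend([cell] * (count - used.get(cell, 0)))
    free = [v.rsid for v in variants if v.rsid not in bins]
    assert len(free) == len(cell_slots), (len(free), len(cell_slots))
    bins.update(dict(zip(free, cell_slots)))

    panels = {
        "1000Genomes": _build_panel("1000Genomes", 0, variants, leads, locus_of,
                                    bins, lead_locus_anchor, seed),
        "HapMap3": _build_panel("HapMap3", 1, variants, leads, locus_of, bins,
                                lead_locus_anchor, seed),
    }

    position_classes = {row[0]: row[5] for row in _T3}
    fixture = StudyFixture(
        leads=leads,
        panels=panels,
        tracks=tracks,
        eqtls=eqtls,
        expected_scores=expected_scores,
        functional_rsids=[row[0] for row in _T3],
        lead_links=link_map,
        position_classes=position_classes,
        variants=variants,
    )
    _self_check(fixture)
    return fixture


def _plant_t3_row(variant, score, eq_genes, motifs, proteins, tracks, eqtls) -> None:
    """Plant one transcribed functional row: printed payloads verbatim, with
    the unprinted peak/footprint flags back-derived from the category."""
    chrom, pos = variant.chrom, variant.pos0
    for gene in eq_genes:
        cell = "monocytes" if gene == "MS4A4A" else "unspecified"
        eqtls.append(EQTLRecord(rsid=variant.rsid, target_gene=gene, cell_type=cell))
    for protein in proteins:
        tracks["tf_peak"].add(chrom, pos - _TF_HALF, pos + _TF_HALF + 1, protein)
    matched = score in ("1a", "1c", "1e", "2a", "2c", "3b")
    bound_norm = {normalize_tf_name(p) for p in proteins}
    first_motif_id = motifs[0] if motifs else None
    for motif in motifs:
        if matched:
            hit = next((p for p in proteins if normalize_tf_name(p) == normalize_tf_name(motif)), None)
            tf = hit or (proteins[0] if proteins else motif)
        else:
            tf = motif  # natural payload; never matches this row's proteins
            assert normalize_tf_name(tf) not in bound_norm, (variant.rsid, tf)
        tracks["motif_instance"].add(chrom, pos - _MOTIF_HALF, pos + _MOTIF_HALF + 1,
                                     f"{motif};{tf}")
    needs_footprint = score in ("1a", "1b", "2a", "2b")
    needs_peak = score in ("1a", "1b", "1c", "1d", "2a", "2b", "2c", "3a", "4")
    if score == "1f" and not proteins:
        needs_peak = True  # 1f via the peak side of the disjunction
    if needs_footprint:
        fp_tf = proteins[0] if proteins else first_motif_id
        tracks["dnase_footprint"].add(chrom, pos - _FP_HALF, pos + _FP_HALF + 1,
                                      f"{first_motif_id};{fp_tf}")
    if needs_peak:
        tracks["dnase_peak"].add(chrom, pos - _PEAK_HALF, pos + _PEAK_HALF + 1, "")


def _build_panel(name, panel_idx, variants, leads, locus_of, bins,
                 lead_locus_anchor, seed) -> HaplotypePanel:
    """One reference panel: per-locus founder columns plus bin-controlled flips."""
    n = _PANEL_N_CHROM
    member_vars: list[Variant] = []
    columns: list[np.ndarray] = []
    loci = sorted({locus_of[v.rsid] for v in variants})
    base_cols: dict[str, np.ndarray] = {}
    for li, locus in enumerate(loci):
        col = np.zeros(n, dtype=np.int8)
        lrng = np.random.default_rng((seed, panel_idx, li))
        col[lrng.choice(n, size=n // 2, replace=False)] = 1
        base_cols[locus] = col
    for vi, v in enumerate(variants):
        b = bins[v.rsid][panel_idx]
        if b == 0:
            continue
        base = base_cols[locus_of[v.rsid]]
        flips = _FLIPS_PER_BIN[b]
        col = base.copy()
        if flips:
            vrng = np.random.default_rng((seed, panel_idx, 10_000 + vi))
            ones = np.flatnonzero(col == 1)
            col[vrng.choice(ones, size=flips, replace=False)] = 0
        member_vars.append(v)
        columns.append(col)
    return HaplotypePanel(
        variants=member_vars,
        haplotypes=np.stack(columns, axis=1),
        panel_name=name,
    )


def _self_check(fx: StudyFixture) -> None:
    """Internal consistency: planted evidence classifies to the recorded label."""
    for rsid in fx.functional_rsids + ["rs10838725"]:
        v = next(x for x in fx.variants if x.rsid == rsid)
        got = classify(collect_evidence(v, fx.tracks, fx.eqtls)).label
        if got != fx.expected_scores[rsid]:
            raise AssertionError(
                f"fixture self-check: {rsid} classifies as {got}, "
                f"expected {fx.expected_scores[rsid]}"
            )
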