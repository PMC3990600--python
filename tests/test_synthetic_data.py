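"""Synthetic generators: LD-block panels, evidence planting, the study fixture."""

import itertools

import numpy as np
import pytest

from regusnp.evidence_collector import collect_evidence
from regusnp.io_formats import Variant
from regusnp.ld_engine import haplotype_r2
from regusnp.regulome_classifier import CATEGORY_LABELS, classify
from regusnp.synthetic_data import (
    CATEGORY_RECIPES,
    FIXTURE_TOTALS,
    FeasibilityError,
    LDBlockSpec,
    PlantSpec,
    plant_evidence,
    simulate_panel,
    study_fixture,
)


# ------------------------------------------------------------ simulate_panel


class TestSimulatePanel:
    def test_perfect_ld_block_columns_identical_or_complementary(self):
        spec = LDBlockSpec(n_chromosomes=200, blocks=[(5, 1.0, (0.3, 0.5))], seed=1)
        panel = simulate_panel(spec)
        base = panel.haplotypes[:, 0]
        for j in range(1, 5):
            col = panel.haplotypes[:, j]
            assert np.array_equal(col, base) or np.array_equal(col, 1 - base)
            assert haplotype_r2(base, col) == pytest.approx(1.0)

    def test_target_r2_recovered_within_tolerance_at_n2000(self):
        spec = LDBlockSpec(n_chromosomes=2000, blocks=[(8, 0.85, (0.3, 0.5))], seed=7)
        panel = simulate_panel(spec)
        r2s = [
            haplotype_r2(panel.haplotypes[:, i], panel.haplotypes[:, j])
            for i, j in itertools.combinations(range(8), 2)
        ]
        assert all(abs(r2 - 0.85) <= 0.05 for r2 in r2s)

    def test_inter_block_r2_near_zero(self):
        spec = LDBlockSpec(
            n_chromosomes=2000,
            blocks=[(6, 0.9, (0.3, 0.5)), (6, 0.9, (0.3, 0.5))],
            seed=3,
        )
        panel = simulate_panel(spec)
        cross = [
            haplotype_r2(panel.haplotypes[:, i], panel.haplotypes[:, 6 + j])
            for i in range(6)
            for j in range(6)
        ]
        assert np.median(cross) < 0.05

    def test_reproducible_under_seed(self):
        spec = LDBlockSpec(n_chromosomes=200, blocks=[(4, 0.8, (0.2, 0.5))], seed=42)
        p1 = simulate_panel(spec)
        p2 = simulate_panel(spec)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)

    def test_infeasible_combination_cites_lewontin_bound(self):
        # r² near 1 between sites forced to very different frequencies
        spec = LDBlockSpec(n_chromosomes=200, blocks=[(40, 0.99, (0.05, 0.95))], seed=0)
        with pytest.raises(FeasibilityError, match="Lewontin"):
            simulate_panel(spec)

    def test_spec_validation(self):
        with pytest.raises(Exception):
            LDBlockSpec(n_chromosomes=99, blocks=[(2, 0.5, (0.2, 0.5))])
        with pytest.raises(Exception):
            LDBlockSpec(n_chromosomes=200, blocks=[(2, 1.5, (0.2, 0.5))])


# ------------------------------------------------------------ plant_evidence


def _spaced_variants(labels, chrom="chr5", start=1_000_000, step=1_000):
    return [
        Variant(rsid=f"rsP{i}", chrom=chrom, pos0=start + i * step)
        for i in range(len(labels))
    ]


class TestPlantEvidence:
    def test_all_fifteen_labels_round_trip(self):
        labels = list(CATEGORY_LABELS)
        variants = _spaced_variants(labels)
        spec = PlantSpec(targets=dict(zip([v.rsid for v in variants], labels)), seed=1)
        tracks, eqtls = plant_evidence(variants, spec)
        for v, label in zip(variants, labels):
            assert classify(collect_evidence(v, tracks, eqtls)).label == label

    def test_no_data_target_generates_nothing(self):
        v = Variant(rsid="rsN", chrom="chr5", pos0=100)
        tracks, eqtls = plant_evidence([v], PlantSpec(targets={"rsN": "NO_DATA"}))
        assert all(len(t) == 0 for t in tracks.values()) and eqtls == []

    def test_thousand_random_specs_full_recovery(self):
        """Plant -> collect -> classify recovers every random target label."""
        rng = np.random.default_rng(2024)
        labels = [str(rng.choice(CATEGORY_LABELS)) for _ in range(1000)]
        variants = _spaced_variants(labels)
        spec = PlantSpec(
            targets=dict(zip([v.rsid for v in variants], labels)), seed=99
        )
        tracks, eqtls = plant_evidence(variants, spec)
        recovered = [
            classify(collect_evidence(v, tracks, eqtls)).label for v in variants
        ]
        assert recovered == labels

    def test_unachievable_label_rejected(self):
        with pytest.raises(Exception):
            PlantSpec(targets={"rs1": "0x"})

    def test_recipes_cover_all_labels(self):
        assert set(CATEGORY_RECIPES) == set(CATEGORY_LABELS)


# ------------------------------------------------------------- study fixture


class TestStudyFixture:
    def test_lead_roster_size_and_composition(self, fixture):
        assert len(fixture.leads) == 44
        gw = [v for v in fixture.leads if v.assoc_class == "gw_significant_risk"]
        sugg = [v for v in fixture.leads if v.assoc_class == "suggestive_risk_or_aao"]
        assert (len(gw), len(sugg)) == (28, 16)

    def test_universe_and_score_totals(self, fixture):
        assert len(fixture.variants) == FIXTURE_TOTALS["n_examined"]
        labels = list(fixture.expected_scores.values())
        assert labels.count("NO_DATA") == FIXTURE_TOTALS["n_no_data"]
        assert len(labels) - labels.count("NO_DATA") == FIXTURE_TOTALS["n_scored_1_6"]

    def test_every_linked_proxy_is_a_functional_row(self, fixture):
        functional = set(fixture.functional_rsids)
        for _lead, proxy, _bin in fixture.lead_links:
            assert proxy in functional

    def test_reported_gwas_functional_rows_are_leads(self, fixture):
        lead_rsids = {v.rsid for v in fixture.leads}
        reported = [r for r in fixture.functional_rsids if r in lead_rsids]
        assert sorted(reported) == sorted(
            ["rs1476679", "rs3764650", "rs1532278", "rs17429217"]
        )

    def test_celf1_block_eqtl_targets(self, fixture):
        """Eight functional SNPs linked to the CELF1 lead, all eQTLs for C1QTNF4."""
        proxies = [p for l, p, _ in fixture.lead_links if l == "rs10838725"]
        assert len(proxies) == 8
        for rsid in proxies:
            genes = {e.target_gene for e in fixture.eqtls if e.rsid == rsid}
            assert "C1QTNF4" in genes

    def test_planted_evidence_reproduces_printed_scores(self, fixture):
        by_rsid = {v.rsid: v for v in fixture.variants}
        for rsid in fixture.functional_rsids:
            got = classify(
                collect_evidence(by_rsid[rsid], fixture.tracks, fixture.eqtls)
            )
            assert got.label == fixture.expected_scores[rsid], rsid

    def test_deterministic_under_seed(self):
        fx1 = study_fixture(seed=5)
        fx2 = study_fixture(seed=5)
        assert fx1.expected_scores == fx2.expected_scores
        assert np.array_equal(
            fx1.panels["HapMap3"].haplotypes, fx2.panels["HapMap3"].haplotypes
        )

    def test_counts_invariant_to_seed(self):
        fx = study_fixture(seed=123)
        assert len(fx.variants) == FIXTURE_TOTALS["n_examined"]
        labels = list(fx.expected_scores.values())
        assert labels.count("NO_DATA") == FIXTURE_TOTALS["n_no_data"]
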