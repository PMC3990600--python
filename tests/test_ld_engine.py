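"""r² computation, two-locus EM, and proxy search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regusnp.io_formats import HaplotypePanel, ValidationError, Variant
from regusnp.ld_engine import (
    HaplotypeCounts,
    LeadNotGenotypedError,
    MonomorphicSiteError,
    em_haplotype_freqs,
    em_log_likelihood,
    find_proxies,
    haplotype_r2,
    merge_panels,
)


# ------------------------------------------------------------- haplotype_r2


class TestHaplotypeR2:
    def test_identical_columns_give_one(self):
        col = np.array([1, 1, 0, 0, 1, 0])
        assert haplotype_r2(col, col) == pytest.approx(1.0)

    def test_hand_counted_two_by_two_table(self):
        # 3x(1,1), 1x(1,0), 1x(0,1), 3x(0,0): p_A=p_B=0.5, p_AB=0.375,
        # D=0.125, r² = 0.125² / 0.5⁴ = 0.25
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        b = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        assert haplotype_r2(a, b) == pytest.approx(0.25)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 50)
        a[:2] = [0, 1]
        assert haplotype_r2(a, 1 - a) == pytest.approx(1.0)
        b = rng.integers(0, 2, 50)
        b[:2] = [0, 1]
        assert haplotype_r2(a, b) == pytest.approx(haplotype_r2(1 - a, b))
        assert haplotype_r2(a, b) == pytest.approx(haplotype_r2(b, a))

    def test_monomorphic_site_raises(self):
        with pytest.raises(MonomorphicSiteError):
            haplotype_r2(np.ones(10, dtype=int), np.array([0, 1] * 5))

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_equals_pearson_correlation_squared(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200)) * 2
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        if a.min() == a.max() or b.min() == b.max():
            return
        expected = np.corrcoef(a, b)[0, 1] ** 2
        assert haplotype_r2(a, b) == pytest.approx(expected, abs=1e-12)


def test_haplotype_counts_d_bounds():
    c = HaplotypeCounts(n=100, p_a=0.4, p_b=0.6, p_ab=0.3)
    assert c.d == pytest.approx(0.3 - 0.24)
    assert max(0, c.p_a + c.p_b - 1) <= c.p_ab <= min(c.p_a, c.p_b)


# ---------------------------------------------------------------------- EM


def _simulate_genotypes(p_a, p_b, p_ab, n_ind, seed):
    """Draw unphased genotypes from specified two-locus haplotype frequencies."""
    rng = np.random.default_rng(seed)
    freqs = [p_ab, p_a - p_ab, p_b - p_ab, 1 - p_a - p_b + p_ab]
    haps = [(1, 1), (1, 0), (0, 1), (0, 0)]
    draws = rng.choice(4, size=2 * n_ind, p=freqs)
    alleles = np.array([haps[i] for i in draws])
    ga = alleles[0::2, 0] + alleles[1::2, 0]
    gb = alleles[0::2, 1] + alleles[1::2, 1]
    return ga, gb


def _grid_search_p_ab(ga, gb):
    """Independent oracle: vectorized likelihood maximization over p_AB."""
    n2 = 2 * ga.size
    p_a, p_b = ga.sum() / n2, gb.sum() / n2
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)

    combos, counts = np.unique(np.stack([ga, gb], axis=1), axis=0, return_counts=True)

    def loglik(grid):
        f = {
            (1, 1): grid,
            (1, 0): p_a - grid,
            (0, 1): p_b - grid,
            (0, 0): 1 - p_a - p_b + grid,
        }
        ll = np.zeros_like(grid)
        for (a_dos, b_dos), count in zip(map(tuple, combos), counts):
            prob = np.zeros_like(grid)
            for a1 in (0, 1):
                for b1 in (0, 1):
                    a2, b2 = a_dos - a1, b_dos - b1
                    if a2 in (0, 1) and b2 in (0, 1):
                        prob += np.clip(f[(a1, b1)], 0, 1) * np.clip(f[(a2, b2)], 0, 1)
            ll += count * np.log(np.maximum(prob, 1e-300))
        return ll

    grid = np.linspace(lo, hi, 2001)
    best = grid[np.argmax(loglik(grid))]
    step = (hi - lo) / 2000 if hi > lo else 0.0
    if step:
        fine = np.linspace(max(lo, best - 2 * step), min(hi, best + 2 * step), 2001)
        best = fine[np.argmax(loglik(fine))]
    return best


class TestEmHaplotypeFreqs:
    def test_no_double_heterozygotes_equals_direct_counting(self):
        ga = np.array([2, 2, 0, 0, 1, 1])
        gb = np.array([2, 0, 2, 0, 0, 2])
        counts = em_haplotype_freqs(ga, gb)
        # direct gamete count: AB gametes = 2 + 0 + 0 + 0 + 0 + 1 = 3 of 12
        assert counts.p_ab == pytest.approx(3 / 12, abs=1e-9)

    def test_all_double_heterozygous_symmetric_fixed_point(self):
        ga = np.ones(20, dtype=int)
        gb = np.ones(20, dtype=int)
        counts = em_haplotype_freqs(ga, gb)
        assert counts.p_ab == pytest.approx(0.25)
        assert counts.p_a == pytest.approx(0.5)

    def test_missing_dropped_pairwise_and_all_missing_raises(self):
        ga = np.array([2, -1, 1])
        gb = np.array([2, 2, -1])
        counts = em_haplotype_freqs(ga, gb)
        assert counts.n == 2
        with pytest.raises(Exception):
            em_haplotype_freqs(np.array([-1, -1]), np.array([1, 2]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_likelihood_maximizer(self, seed):
        rng = np.random.default_rng(seed)
        p_a, p_b = rng.uniform(0.2, 0.8, 2)
        lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
        p_ab = rng.uniform(lo, hi)
        ga, gb = _simulate_genotypes(p_a, p_b, p_ab, n_ind=20, seed=seed + 100)
        if ga.min() == ga.max() or gb.min() == gb.max():
            return
        counts = em_haplotype_freqs(ga, gb, tol=1e-12)
        assert counts.p_ab == pytest.approx(_grid_search_p_ab(ga, gb), abs=1e-4)

    def test_log_likelihood_nondecreasing_over_iterations(self):
        ga, gb = _simulate_genotypes(0.5, 0.5, 0.4, n_ind=50, seed=11)
        counts, history = em_haplotype_freqs(ga, gb, return_history=True)
        lls = [
            em_log_likelihood(
                HaplotypeCounts(n=counts.n, p_a=counts.p_a, p_b=counts.p_b, p_ab=p),
                ga, gb,
            )
            for p in history
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


# -------------------------------------------------------------- find_proxies


def _panel_from_columns(cols, positions, chrom="chr1", name="p"):
    variants = [
        Variant(rsid=f"rs{i}", chrom=chrom, pos0=pos) for i, pos in enumerate(positions)
    ]
    return HaplotypePanel(
        variants=variants, haplotypes=np.stack(cols, axis=1), panel_name=name
    )


def _planted_pair(r2_target=0.85, n=2000):
    """Two columns with exact haplotype counts giving r² = r2_target at p=0.5."""
    d = np.sqrt(r2_target * 0.5**4)
    n11 = int(round(n * (0.25 + d)))
    n10 = n // 2 - n11
    a = np.array([1] * (n // 2) + [0] * (n // 2))
    b = np.array([1] * n11 + [0] * n10 + [1] * n10 + [0] * (n // 2 - n10))
    return a, b


class TestFindProxies:
    def test_self_proxy_always_member(self):
        a = np.array([1, 0] * 30)
        c = np.array([1] * 60)  # monomorphic partner: skipped
        panel = _panel_from_columns([a, c], [100, 200])
        ps = find_proxies(panel.variants[0], panel, threshold=0.8)
        assert ps.member_rsids == {"rs0"}
        assert ps.members[0].r2 == 1.0

    def test_planted_pair_in_at_080_out_at_090(self):
        a, b = _planted_pair(0.85)
        realized = haplotype_r2(a, b)
        assert 0.80 <= realized < 0.90
        panel = _panel_from_columns([a, b], [100, 500])
        lead = panel.variants[0]
        assert find_proxies(lead, panel, 0.80).member_rsids == {"rs0", "rs1"}
        assert find_proxies(lead, panel, 0.90).member_rsids == {"rs0"}

    def test_window_excludes_distant_variants(self):
        a, b = _planted_pair(0.95)
        panel = _panel_from_columns([a, b], [100, 600_000])
        lead = panel.variants[0]
        assert find_proxies(lead, panel, 0.8, window_bp=250_000).member_rsids == {"rs0"}

    def test_absent_lead_raises_signal(self):
        a = np.array([1, 0] * 10)
        panel = _panel_from_columns([a], [100])
        outsider = Variant(rsid="rsX", chrom="chr1", pos0=150)
        with pytest.raises(LeadNotGenotypedError):
            find_proxies(outsider, panel, 0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_nesting(self, seed):
        from regusnp.synthetic_data import LDBlockSpec, simulate_panel

        spec = LDBlockSpec(
            n_chromosomes=400,
            blocks=[(12, 0.9, (0.3, 0.5))],
            seed=seed,
        )
        panel = simulate_panel(spec)
        lead = panel.variants[0]
        sets = {
            t: find_proxies(lead, panel, t).member_rsids for t in (0.8, 0.9, 1.0)
        }
        assert sets[1.0] <= sets[0.9] <= sets[0.8]


# -------------------------------------------------------------- merge_panels


class TestMergePanels:
    def _ps(self, lead, rsids, panel, threshold=0.8):
        from regusnp.ld_engine import LDResult, ProxySet

        members = [LDResult(lead.rsid, r, 0.9, panel) for r in rsids]
        return ProxySet(lead=lead, threshold=threshold, members=members, panel_name=panel)

    def test_union_removes_overlap(self):
        lead = Variant(rsid="rsL", chrom="chr1", pos0=10)
        merged = merge_panels(
            [self._ps(lead, ["A", "B"], "p1"), self._ps(lead, ["B", "C"], "p2")]
        )
        assert merged["union_rsids"] == {"A", "B", "C"}
        assert merged["union_count"] == 3
        assert merged["per_panel_counts"] == {"p1": 2, "p2": 2}

    def test_identical_panels_idempotent(self):
        lead = Variant(rsid="rsL", chrom="chr1", pos0=10)
        merged = merge_panels([self._ps(lead, ["A"], "p1"), self._ps(lead, ["A"], "p2")])
        assert merged["union_count"] == 1

    def test_mismatched_lead_or_threshold_rejected(self):
        lead1 = Variant(rsid="rsL", chrom="chr1", pos0=10)
        lead2 = Variant(rsid="rsM", chrom="chr1", pos0=20)
        with pytest.raises(ValidationError):
            merge_panels([self._ps(lead1, ["A"], "p1"), self._ps(lead2, ["A"], "p2")])
        with pytest.raises(ValidationError):
            merge_panels(
                [self._ps(lead1, ["A"], "p1"), self._ps(lead1, ["A"], "p2", 0.9)]
            )
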