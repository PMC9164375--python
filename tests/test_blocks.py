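"""D' confidence intervals, block finding, candidates and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from linevar.config import AnalysisConfig
from linevar.ldblocks import (
    HaplotypeBlock,
    LdClass,
    classify_pair,
    dprime_ci,
    em_haplotype_freqs,
    enrichment_score,
    enrichment_table,
    find_blocks,
    fst_enrichment,
    genotype_table,
    select_candidate,
    _geno_cell_probs,
)


def brute_force_blocks(classes, positions, cfg=None):
    """Exhaustive enumeration of intervals satisfying the informative-pair rule,
    resolved longest-first with leftmost tie-break (independent oracle)."""
    cfg = cfg or AnalysisConfig()
    m = len(positions)
    candidates = []
    for a in range(m):
        for b in range(a + 1, m):
            n_inf = n_strong = 0
            for i, j in itertools.combinations(range(a, b + 1), 2):
                if positions[j] - positions[i] > cfg.pair_span:
                    continue
                if classes[i, j] != 0:
                    n_inf += 1
                    n_strong += classes[i, j] == 1
            if n_inf > 0 and n_strong / n_inf >= cfg.informative_fraction:
                candidates.append((positions[b] - positions[a], a, b))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken = set()
    blocks = []
    for span, a, b in candidates:
        if any(i in taken for i in range(a, b + 1)):
            continue
        taken.update(range(a, b + 1))
        blocks.append((a, b))
    return sorted(blocks)


class TestDprimeCi:
    def test_complete_ld_phased_is_strong_ld(self):
        d, lo, hi = dprime_ci(haplotype_counts=np.array([50.0, 0, 0, 50]))
        assert d == pytest.approx(1.0)
        assert lo > 0.7 and hi == 1.0
        assert classify_pair(lo, hi) is LdClass.STRONG_LD

    def test_independent_pair_shows_strong_recombination(self):
        rng = np.random.default_rng(9)
        g1 = rng.binomial(2, 0.5, 1000)
        g2 = rng.binomial(2, 0.5, 1000)
        d, lo, hi = dprime_ci(g1, g2)
        assert d < 0.2
        assert hi < 0.7

    def test_symmetric_in_locus_order_and_allele_labels(self):
        rng = np.random.default_rng(10)
        g1 = rng.binomial(2, 0.3, 300)
        g2 = np.clip(g1 + rng.integers(-1, 2, 300), 0, 2)
        a = dprime_ci(g1, g2)
        b = dprime_ci(g2, g1)
        c = dprime_ci(2 - g1, g2)
        assert a == pytest.approx(b, abs=1e-9)
        assert a == pytest.approx(c, abs=1e-9)

    def test_monomorphic_member_rejected(self):
        with pytest.raises(ValueError):
            dprime_ci(np.zeros(100), np.ones(100))

    def test_em_matches_exhaustive_grid_mle(self):
        """EM haplotype frequencies equal the grid-search ML solution over the
        single free haplotype frequency, to 1e-6."""
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(11)
        for _ in range(10):
            g1 = rng.binomial(2, rng.uniform(0.2, 0.8), 400)
            g2 = rng.binomial(2, rng.uniform(0.2, 0.8), 400)
            tab = genotype_table(g1, g2)
            f = em_haplotype_freqs(tab)
            pa, pb = f[2] + f[3], f[1] + f[3]

            def negll(f11):
                d = f11 - pa * pb
                fr = np.clip(
                    np.array(
                        [(1 - pa) * (1 - pb) + d, (1 - pa) * pb - d, pa * (1 - pb) - d, f11]
                    ),
                    1e-12,
                    None,
                )
                return -float((tab * np.log(_geno_cell_probs(fr))).sum())

            lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
            grid = np.linspace(lo, hi, 2001)
            best = grid[np.argmin([negll(v) for v in grid])]
            step = (hi - lo) / 2000
            res = minimize_scalar(
                negll, bounds=(max(lo, best - step), min(hi, best + step)), method="bounded",
                options={"xatol": 1e-12},
            )
            assert f[3] == pytest.approx(res.x, abs=1e-6)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (0.75, 0.95, LdClass.STRONG_LD),
            (0.71, 0.90, LdClass.STRONG_LD),
            (0.1, 0.6, LdClass.STRONG_RECOMBINATION),
            (0.5, 0.8, LdClass.UNINFORMATIVE),
            (0.70, 0.95, LdClass.UNINFORMATIVE),  # lower bound must exceed 0.7
            (0.0, 0.7, LdClass.UNINFORMATIVE),  # upper bound not below 0.7
        ],
    )
    def test_threshold_rules(self, lo, hi, expected):
        assert classify_pair(lo, hi) is expected

    def test_classification_is_a_partition(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            lo = rng.uniform(0, 1)
            hi = rng.uniform(lo, 1)
            assert classify_pair(lo, hi) in list(LdClass)


class TestFindBlocks:
    def test_all_strong_pairs_one_block(self):
        m = 5
        classes = np.ones((m, m), dtype=np.int8)
        np.fill_diagonal(classes, 0)
        pos = np.arange(m) * 1000 + 1
        blocks = find_blocks(classes, pos)
        assert len(blocks) == 1
        assert blocks[0].member_indices == list(range(5))
        assert blocks[0].fraction_strong_ld == 1.0

    def test_recombination_gap_separates_two_blocks(self):
        m = 6
        classes = np.zeros((m, m), dtype=np.int8)
        for grp in (range(0, 3), range(3, 6)):
            for i, j in itertools.combinations(grp, 2):
                classes[i, j] = classes[j, i] = 1
        for i in range(3):
            for j in range(3, 6):
                classes[i, j] = classes[j, i] = -1
        pos = np.arange(m) * 1000 + 1
        blocks = find_blocks(classes, pos)
        assert [b.member_indices for b in blocks] == [[0, 1, 2], [3, 4, 5]]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            m = int(rng.integers(2, 13))
            upper = rng.choice([1, -1, 0], size=(m, m), p=[0.45, 0.25, 0.3])
            classes = np.triu(upper, 1)
            classes = (classes + classes.T).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 8_000_000, 1000), size=m, replace=False))
            got = sorted(
                (b.member_indices[0], b.member_indices[-1]) for b in find_blocks(classes, pos)
            )
            assert got == brute_force_blocks(classes, pos)

    def test_single_variant_chromosome_empty(self):
        assert find_blocks(np.zeros((1, 1), dtype=np.int8), np.array([100])) == []


def _members(rows):
    return pd.DataFrame(rows, columns=["variant_id", "pos", "category", "p_value", "significant"])


class TestSelectCandidate:
    BLOCK = HaplotypeBlock("1", 100, 5000, [0, 1], 1, 1.0)

    def test_severity_beats_p_value(self):
        members = _members(
            [("v1", 100, "missense", 1e-7, True), ("v2", 200, "intergenic", 1e-12, True)]
        )
        cand = select_candidate(self.BLOCK, members)
        assert cand.variant_id == "v1"
        assert cand.selection_reason == "severity"

    def test_p_value_breaks_category_tie(self):
        members = _members(
            [("v1", 100, "synonymous", 1e-8, True), ("v2", 200, "synonymous", 1e-9, True)]
        )
        cand = select_candidate(self.BLOCK, members)
        assert cand.variant_id == "v2"
        assert cand.selection_reason == "p-value tie-break"

    def test_single_significant_member_selected(self):
        members = _members(
            [("v1", 100, "intronic", 1e-8, True), ("v2", 200, "missense", 0.5, False)]
        )
        assert select_candidate(self.BLOCK, members).variant_id == "v1"

    def test_no_significant_member_yields_none(self):
        members = _members([("v1", 100, "missense", 0.5, False)])
        assert select_candidate(self.BLOCK, members) is None


class TestEnrichmentScore:
    def test_equal_odds_is_zero(self):
        assert enrichment_score(10, 90, 100, 900) == 0.0

    def test_closed_form(self):
        assert enrichment_score(20, 80, 100, 900) == pytest.approx(np.log(2.25))

    def test_category_equal_to_total_is_zero(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            s, ns = int(rng.integers(1, 1000)), int(rng.integers(1, 1000))
            assert enrichment_score(s, ns, s, ns) == 0.0

    def test_zero_count_sentinels(self):
        assert enrichment_score(0, 50, 100, 900) == -np.inf
        assert enrichment_score(50, 0, 100, 900) == np.inf

    def test_table_counts_partition_totals(self):
        rng = np.random.default_rng(15)
        cats = pd.Series(rng.choice(["a", "b", "c"], 500))
        sig = pd.Series(rng.random(500) < 0.1)
        table = enrichment_table(cats, sig)
        assert table["n_sign"].sum() == sig.sum()
        assert (table["n_sign"] + table["n_not_sign"]).sum() == 500


class TestFstEnrichment:
    def test_identical_distributions_zero(self):
        x = np.array([0.1, 0.2, 0.3])
        assert fst_enrichment(x, x) == 0.0

    def test_log_ratio_of_medians(self):
        assert fst_enrichment(np.array([0.15]), np.array([0.05])) == pytest.approx(np.log(3))

    def test_single_candidate_at_category_median(self):
        assert fst_enrichment(np.array([0.2]), np.array([0.1, 0.2, 0.3])) == 0.0

    def test_empty_candidates_absent(self):
        assert fst_enrichment(np.array([]), np.array([0.1])) is None
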