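"""Differential-expression machinery: size factors, dispersion, the Wald
test (including a permutation-oracle cross-check), BH adjustment, DEG
calling and the Venn partition."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from stressgcn.deg import (
    ALPHA_MIN,
    bh_adjust,
    call_degs,
    estimate_dispersion,
    estimate_size_factors,
    venn_partition,
)
from stressgcn.deg import test_gene as wald_test_gene  # alias: avoid pytest collection

from conftest import make_experiment


def bh_oracle(p):
    """Hand-coded Benjamini-Hochberg step-up, independent of the package."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted


class TestSizeFactors:
    def test_identical_samples(self):
        counts = np.tile(np.array([[5], [10], [20]]), (1, 2))
        assert np.allclose(estimate_size_factors(counts), [1.0, 1.0])

    def test_exact_doubling(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 100, size=50)
        counts = np.column_stack([a, 2 * a])
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_bruteforce_median_of_ratios(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 300, size=(200, 6)) + rng.integers(0, 2, size=(200, 6))
        counts[:5] += 1  # guarantee some all-positive genes
        sf = estimate_size_factors(counts)
        # brute force: per-sample median of counts / geometric mean
        with np.errstate(divide="ignore"):
            logc = np.log(counts.astype(float))
        ok = np.isfinite(logc).all(axis=1)
        geo = np.exp(logc[ok].mean(axis=1))
        ratios = counts[ok] / geo[:, None]
        expected = np.median(ratios, axis=0)
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(sf, expected, rtol=1e-12)

    def test_fallback_when_no_all_positive_gene(self, caplog):
        counts = np.array([[0, 5], [7, 0]])
        with caplog.at_level("WARNING"):
            sf = estimate_size_factors(counts)
        assert np.allclose(np.exp(np.mean(np.log(sf))), 1.0)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 200, size=(100, 4))
        base = estimate_size_factors(counts)
        scaled = counts.copy().astype(float)
        scaled[:, 1] *= 3
        out = estimate_size_factors(scaled)
        # ratio to other samples changes by exactly 3 (up to global rescale)
        assert np.allclose(out[1] / out[0], 3 * base[1] / base[0])


class TestDispersion:
    def test_poisson_gene_at_floor(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(100, size=(1, 60))
        disp = estimate_dispersion(counts, np.ones(60))
        assert disp[0] <= 0.01

    def test_constant_gene_at_floor(self):
        counts = np.full((1, 10), 42)
        disp = estimate_dispersion(counts, np.ones(10))
        assert disp[0] == ALPHA_MIN

    def test_recovers_known_alpha(self):
        rng = np.random.default_rng(4)
        alpha, n = 0.2, 50
        mu = 200.0
        lam = rng.gamma(1 / alpha, alpha * mu, size=(300, n))
        counts = rng.poisson(lam)
        disp = estimate_dispersion(counts, np.ones(n))
        assert 0.1 <= np.median(disp) <= 0.3

    def test_arm_effect_removed_before_pooling(self):
        rng = np.random.default_rng(5)
        n = 30
        arms = np.array(["m"] * n + ["t"] * n)
        # strong arm shift, Poisson within arm
        counts = np.concatenate(
            [rng.poisson(50, size=(1, n)), rng.poisson(400, size=(1, n))], axis=1
        )
        disp = estimate_dispersion(counts, np.ones(2 * n), arms)
        assert disp[0] < 0.05  # arm difference must not masquerade as dispersion


class TestWaldTest:
    def test_identical_arms_null(self):
        x = np.array([10.0, 12.0, 9.0])
        lfc, p = wald_test_gene(x, x, np.ones(3), np.ones(3), 0.1)
        assert lfc == 0.0
        assert p == pytest.approx(1.0)

    def test_all_zero_convention(self):
        z = np.zeros(3)
        assert wald_test_gene(z, z, np.ones(3), np.ones(3), 0.1) == (0.0, 1.0)

    def test_matches_permutation_oracle_on_null_genes(self):
        """Wald p-values track an exact permutation test on NB null data:
        rank agreement and matching rejection rates."""
        rng = np.random.default_rng(5)
        n, alpha, n_genes = 5, 0.1, 100
        mu = 2 ** rng.uniform(3, 9, n_genes)
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], size=(n_genes, 2 * n))
        counts = rng.poisson(lam)
        sf = estimate_size_factors(counts)
        arms = np.array(["m"] * n + ["t"] * n)
        disp = estimate_dispersion(counts, sf, arms)
        combos = list(itertools.combinations(range(2 * n), n))
        p_wald = np.empty(n_genes)
        p_perm = np.empty(n_genes)
        for g in range(n_genes):
            _lfc, p_wald[g] = wald_test_gene(
                counts[g, n:], counts[g, :n], sf[n:], sf[:n], disp[g]
            )
            y = counts[g] / sf
            observed = abs(y[n:].mean() - y[:n].mean())
            hits = 0
            for combo in combos:
                mask = np.zeros(2 * n, bool)
                mask[list(combo)] = True
                hits += abs(y[mask].mean() - y[~mask].mean()) >= observed - 1e-12
            p_perm[g] = hits / len(combos)
        assert spearmanr(p_wald, p_perm).statistic > 0.9
        assert abs((p_wald < 0.05).mean() - (p_perm < 0.05).mean()) <= 0.03


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    def test_matches_oracle_and_is_monotone(self, p):
        got = bh_adjust(p)
        assert np.allclose(got, bh_oracle(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(got[order]) >= -1e-12)


class TestCallDegs:
    def test_is_deg_matches_threshold_rule(self, small_experiment):
        exp, _ann, _truth = small_experiment
        table = call_degs(exp, exp.conditions[0], log2fc_cutoff=1.0, fdr_cutoff=0.05)
        t = table.table
        expected = (t["log2fc"].abs() > 1.0) & (t["fdr"] < 0.05)
        assert (t["is_deg"] == expected).all()
        assert (t.loc[t["is_deg"], "fdr"] < 0.05).all()

    def test_boundary_gene_excluded(self, small_experiment):
        """|log2fc| below the cutoff is never a DEG however small its FDR."""
        exp, _ann, _truth = small_experiment
        table = call_degs(exp, exp.conditions[0]).table
        sub = table[(table["log2fc"].abs() <= 1.0)]
        assert not sub["is_deg"].any()

    def test_missing_mock_named(self):
        counts = np.ones((5, 4), dtype=int)
        exp = make_experiment(counts)
        exp.samples["arm"] = "treated"
        with pytest.raises(ValueError, match="mock"):
            call_degs(exp, "c1")

    def test_fdr_is_bh_of_pvalues_within_comparison(self, small_experiment):
        exp, _ann, _truth = small_experiment
        t = call_degs(exp, exp.conditions[0]).table
        for _tp, sub in t.groupby("time_point"):
            assert np.allclose(sub["fdr"], bh_oracle(sub["p_value"].to_numpy()))

    def test_row_permutation_invariance(self, small_experiment):
        exp, _ann, _truth = small_experiment
        rng = np.random.default_rng(0)
        perm = rng.permutation(exp.counts.index)
        from stressgcn.synthetic_data import CountExperiment

        exp_p = CountExperiment(
            counts=exp.counts.loc[perm],
            samples=exp.samples,
            gene_lengths=exp.gene_lengths,
        )
        a = call_degs(exp, exp.conditions[0]).table.set_index(["gene_id", "time_point"])
        b = call_degs(exp_p, exp.conditions[0]).table.set_index(["gene_id", "time_point"])
        b = b.loc[a.index]
        assert np.allclose(a["log2fc"], b["log2fc"])
        assert (a["is_deg"] == b["is_deg"]).all()


class TestVennPartition:
    def test_two_set_example(self):
        part = venn_partition({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        assert part.cells[frozenset({"A"})] == 1
        assert part.cells[frozenset({"B"})] == 1
        assert part.cells[frozenset({"A", "B"})] == 1
        assert part.universe_size == 3

    def test_disjoint_sets(self):
        part = venn_partition({"A": {"g1"}, "B": {"g2"}})
        assert part.cells[frozenset({"A", "B"})] == 0
        assert part.total() == 2

    def test_matches_bruteforce_membership(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(1000)]
        sets = {
            c: {g for g in genes if rng.random() < 0.3} for c in ("A", "B", "C", "D")
        }
        part = venn_partition(sets)
        union = set().union(*sets.values())
        assert part.total() == len(union)
        for subset, count in part.cells.items():
            expected = sum(
                1
                for g in union
                if {c for c in sets if g in sets[c]} == set(subset)
            )
            assert count == expected

    def test_guards(self):
        with pytest.raises(ValueError, match=">= 2"):
            venn_partition({"A": set()})
        nine = {f"c{i}": set() for i in range(9)}
        with pytest.raises(ValueError, match="8-set"):
            venn_partition(nine)
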