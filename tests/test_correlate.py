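import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tmesig import (
    ExpressionMatrix,
    SampleAnnotation,
    bh_adjust,
    entity_panel,
    group_mean_test,
    pearson_r,
    spearman_r,
    split_signature_by_direction,
    simulate_cohort,
    compute_entity_z,
    select_high_expressers,
    run_consensus,
)
from tmesig.consensus import RFConfig
from tmesig.dichotomize import HIGH, REST, DichotomyLabels


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)) * math.sqrt(sum((b - my) ** 2 for b in y))
    return num / den


def mid_ranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2 * v + 1 for v in x]
        r, p = pearson_r(x, y)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_hand_computed_half(self):
        r, _ = pearson_r([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_matches_naive_reference_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.3 * x
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, _ = pearson_r(x, y)
            assert abs(r - naive_pearson(list(x), list(y))) <= 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_r([1, 2], [3, 4])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = [0.5, 1.0, 2.0, 7.0]
        rho, _ = spearman_r(x, [math.exp(v) for v in x])
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        rho, _ = spearman_r([1, 2, 3, 4], [9, 7, 5, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        x, y = [1, 2, 3, 4], [1, 1, 3, 4]
        rho, _ = spearman_r(x, y)
        assert rho == pytest.approx(naive_pearson(mid_ranks(x), mid_ranks(y)))

    def test_matches_rank_pearson_on_random_fixtures(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            x = list(rng.integers(0, 6, n).astype(float))  # many ties
            y = list(rng.integers(0, 6, n).astype(float))
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, _ = spearman_r(x, y)
            assert abs(rho - naive_pearson(mid_ranks(x), mid_ranks(y))) <= 1e-12


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        # sorted p=[.01,.02,.03], m=3: q_i = min over j>=i of p_j*m/j
        # = [.03, .03, .03]
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_second_hand_computed_vector(self):
        # p = [.005, .04, .03]: sorted [.005,.03,.04] -> q = [.015,.04,.04]
        got = dict(zip([0.005, 0.04, 0.03], bh_adjust([0.005, 0.04, 0.03])))
        assert got[0.005] == pytest.approx(0.015)
        assert got[0.03] == pytest.approx(0.04)
        assert got[0.04] == pytest.approx(0.04)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_never_below_raw_p_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1.0, 50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-4, 1, 20)
        perm = rng.permutation(20)
        q1 = bh_adjust(p)
        q2 = bh_adjust(p[perm])
        np.testing.assert_allclose(q1[perm], q2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


@pytest.fixture(scope="module")
def planted():
    from tmesig.simulate import SimConfig

    cfg = SimConfig(n_entities=3, samples_per_entity=120, n_genes=60,
                    module_size=8, loading=0.8, noise_sd=0.5,
                    entity_shift_sd=0.5, seed=31)
    return cfg, *simulate_cohort(cfg)


class TestEntityPanel:
    def test_row_count_and_order(self, planted):
        cfg, expr, ann, truth = planted
        panel = sorted(truth.module_gene_ids)[:4]
        rows = entity_panel(expr, ann, cfg.target_gene_id, panel)
        assert len(rows) == 3 * 4
        assert [(r.entity, r.gene) for r in rows] == sorted(
            [(e, g) for e in ann.entity_names for g in panel]
        )

    def test_planted_genes_positive_noise_centered(self, planted):
        cfg, expr, ann, truth = planted
        module = sorted(truth.module_gene_ids)[:5]
        noise = [g for g in expr.gene_ids
                 if g not in truth.module_gene_ids and g != cfg.target_gene_id][:10]
        rows = entity_panel(expr, ann, cfg.target_gene_id, module + noise)
        module_r = [r.r for r in rows if r.gene in module]
        noise_r = [r.r for r in rows if r.gene in noise]
        assert min(module_r) > 0.3
        assert abs(np.mean(noise_r)) < 0.1

    def test_self_correlation_is_one(self, planted):
        cfg, expr, ann, _ = planted
        rows = entity_panel(expr, ann, cfg.target_gene_id, [cfg.target_gene_id])
        assert all(r.r == pytest.approx(1.0) for r in rows)

    def test_entity_specific_correlation_survives_bh(self):
        # correlation planted only in entity A
        rng = np.random.default_rng(4)
        nA, nB = 80, 80
        xA = rng.normal(size=nA)
        target = np.concatenate([np.exp2(xA), np.exp2(rng.normal(size=nB))])
        partner = np.concatenate(
            [np.exp2(xA + rng.normal(0, 0.3, nA)), np.exp2(rng.normal(size=nB))]
        )
        samples = [f"s{i}" for i in range(nA + nB)]
        expr = ExpressionMatrix(["T", "P"], samples, np.vstack([target, partner]))
        ann = SampleAnnotation({s: ("A" if i < nA else "B") for i, s in enumerate(samples)})
        rows = entity_panel(expr, ann, "T", ["P"], log2p1=True)
        by_ent = {r.entity: r for r in rows}
        assert by_ent["A"].q < 0.05
        assert by_ent["B"].q > 0.05

    def test_small_entity_flagged(self, tiny_matrix):
        ann = SampleAnnotation(
            {s: ("A" if i < 2 else "B") for i, s in enumerate(tiny_matrix.sample_ids)}
        )
        rows = entity_panel(tiny_matrix, ann, "g0", ["g1"])
        flags = {r.entity: r.flag for r in rows}
        assert flags["A"] == "too_few_samples"
        assert flags["B"] == ""

    def test_absent_gene_rejected(self, planted):
        cfg, expr, ann, _ = planted
        with pytest.raises(KeyError):
            entity_panel(expr, ann, cfg.target_gene_id, ["missing_gene"])


class TestGroupMeanTest:
    def _labels(self, n_high, n_rest):
        d = {f"h{i}": HIGH for i in range(n_high)}
        d.update({f"r{i}": REST for i in range(n_rest)})
        return DichotomyLabels(pd.Series(d))

    def test_identical_groups(self):
        labels = self._labels(5, 5)
        vals = pd.Series({s: 3.0 for s in labels.sample_ids})
        row = group_mean_test(vals, labels)
        assert row.mean_high == row.mean_low == 3.0
        assert row.p == pytest.approx(1.0)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(6)
        labels = self._labels(200, 200)
        vals = {}
        for s in labels.sample_ids:
            base = rng.normal(0, 1)
            vals[s] = base + (10 if s.startswith("h") else 0)
        row = group_mean_test(pd.Series(vals), labels)
        assert row.p < 1e-10
        assert row.mean_high > row.mean_low + 9

    @pytest.mark.parametrize("test", ["mannwhitney", "welch", "kruskal"])
    def test_all_tests_run(self, test):
        rng = np.random.default_rng(7)
        labels = self._labels(20, 30)
        vals = pd.Series({s: float(v) for s, v in
                          zip(labels.sample_ids, rng.lognormal(0, 1, 50))})
        row = group_mean_test(vals, labels, test=test)
        assert 0 < row.p <= 1
        assert row.sd_high >= 0 and row.sd_low >= 0

    def test_kruskal_equals_mannwhitney_two_sided(self):
        # for two groups without ties these agree asymptotically; check p ordering sanity
        rng = np.random.default_rng(12)
        labels = self._labels(50, 60)
        vals = pd.Series({s: float(v) for s, v in
                          zip(labels.sample_ids, rng.normal(0, 1, 110))})
        p_k = group_mean_test(vals, labels, test="kruskal").p
        p_m = group_mean_test(vals, labels, test="mannwhitney").p
        assert p_k == pytest.approx(p_m, rel=0.05)

    def test_tiny_group_flagged(self):
        labels = self._labels(1, 5)
        vals = pd.Series({s: float(i) for i, s in enumerate(labels.sample_ids)})
        row = group_mean_test(vals, labels)
        assert row.flag == "group_too_small"
        assert math.isnan(row.sd_high)

    def test_empty_group_rejected(self):
        labels = self._labels(3, 3)
        vals = pd.Series({s: 1.0 for s in labels.sample_ids})
        only_high = DichotomyLabels(pd.Series({s: HIGH for s in labels.sample_ids}))
        with pytest.raises(ValueError, match="non-empty"):
            group_mean_test(vals, only_high)


@pytest.fixture(scope="module")
def sig_setup():
    from tmesig.simulate import SimConfig

    cfg = SimConfig(n_entities=2, samples_per_entity=150, n_genes=120,
                    module_size=15, loading=0.8, noise_sd=0.5,
                    entity_shift_sd=0.3, seed=19)
    expr, ann, truth = simulate_cohort(cfg)
    z = compute_entity_z(expr, ann, cfg.target_gene_id)
    labels = select_high_expressers(z)
    sig, _ = run_consensus(expr, labels, RFConfig(n_models=5, n_trees=50, top_k=40),
                           target_gene=cfg.target_gene_id)
    return cfg, expr, labels, truth, sig


class TestSplitSignature:
    def test_partition_is_exhaustive_and_disjoint(self, sig_setup):
        _, expr, labels, _, sig = sig_setup
        up, down = split_signature_by_direction(sig, expr, labels)
        assert set(up) | set(down) == set(sig.gene_ids)
        assert not set(up) & set(down)

    def test_planted_genes_classified_up(self, sig_setup):
        _, expr, labels, truth, sig = sig_setup
        up, _ = split_signature_by_direction(sig, expr, labels)
        planted_in_sig = truth.module_gene_ids & set(sig.gene_ids)
        assert planted_in_sig  # sanity: signature found some module genes
        assert planted_in_sig <= set(up)

    def test_mean_equal_gene_goes_down(self, sig_setup):
        # constant gene: means equal, fails the strict inequality
        _, expr, labels, _, sig = sig_setup
        constant = pd.Series({s: 5.0 for s in labels.sample_ids})
        row = group_mean_test(constant, labels)
        assert not (row.mean_high > row.mean_low and row.p < 0.05)
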