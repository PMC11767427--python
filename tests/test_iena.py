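"""Reference-anchored single-sample networks and the sCI warning index."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest

import osteowarn as ow
from osteowarn.iena import (
    ReferenceStats,
    build_reference,
    detect_critical_stage,
    detect_modules,
    loo_zscores,
    sci,
    select_top_edges,
    shpcc,
    shpcc_matrix,
    spcc,
    zscores,
)
from tests.conftest import make_cohort


def _toy_reference():
    mets = ["A", "B", "C", "D", "E"]
    mu = pd.Series([10.0, 20.0, 30.0, 40.0, 50.0], index=mets)
    sigma = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=mets)
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(mu.values + sigma.values * rng.standard_normal((6, 5)),
                        index=[f"R{i}" for i in range(6)], columns=mets)
    return ReferenceStats(mu, sigma, vals)


class TestBuildReference:
    def test_mean_and_sample_sd(self):
        x = np.column_stack([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        x = np.vstack([x, [[10, 7], [11, 7], [12, 7]]])  # non-reference rows
        cohort = make_cohort(x, ["control"] * 3 + ["osteopenia", "osteopenia",
                                                   "osteoporosis"])
        ref = build_reference(cohort)
        assert ref.mu["M000"] == pytest.approx(2.0)
        assert ref.sigma["M000"] == pytest.approx(1.0)  # ddof=1

    def test_constant_metabolite_dropped(self):
        x = np.column_stack([[1.0, 2.0, 3.0, 1.5], [7.0, 7.0, 7.0, 7.0]])
        cohort = make_cohort(x, ["control"] * 3 + ["osteopenia"])
        ref = build_reference(cohort)
        assert ref.dropped == ["M001"]
        assert list(ref.metabolite_ids) == ["M000"]

    def test_reference_uses_control_samples_only(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=(9, 4))
        stages = ["control"] * 3 + ["osteopenia"] * 3 + ["osteoporosis"] * 3
        ref1 = build_reference(make_cohort(x, stages))
        x2 = x.copy()
        x2[3:] *= 100.0  # perturb non-reference rows only
        ref2 = build_reference(make_cohort(x2, stages))
        pd.testing.assert_series_equal(ref1.mu, ref2.mu)
        pd.testing.assert_series_equal(ref1.sigma, ref2.sigma)

    def test_too_few_reference_samples_is_error(self):
        cohort = make_cohort(np.ones((3, 2)) + np.eye(3, 2),
                             ["control", "control", "osteopenia"])
        with pytest.raises(ValueError, match=">= 3"):
            build_reference(cohort)


class TestSpcc:
    def test_zero_at_reference_mean(self):
        ref = _toy_reference()
        sample = ref.mu.copy()
        for pair in itertools.combinations(ref.metabolite_ids, 2):
            assert spcc(sample, ref, pair) == 0.0

    def test_product_of_z_scores(self):
        ref = _toy_reference()
        sample = ref.mu + ref.sigma * pd.Series([2.0, -1.0, 0.0, 1.0, 3.0],
                                                index=ref.metabolite_ids)
        assert spcc(sample, ref, ("A", "B")) == pytest.approx(-2.0)
        assert spcc(sample, ref, ("B", "A")) == pytest.approx(-2.0)

    def test_mean_over_reference_equals_scaled_pearson(self):
        # loop-based oracle for the identity mean_ref(z_x z_y) = (n-1)/n * r
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = 20
            x = rng.lognormal(size=(n + 6, 4))
            cohort = make_cohort(x, ["control"] * n + ["osteopenia"] * 3
                                 + ["osteoporosis"] * 3)
            ref = build_reference(cohort)
            a, b = "M001", "M003"
            acc = 0.0
            for sid in ref.sample_ids:
                acc += spcc(cohort.abundance.loc[sid], ref, (a, b))
            r = np.corrcoef(ref.values[a], ref.values[b])[0, 1]
            assert acc / n == pytest.approx((n - 1) / n * r, abs=1e-10)

    def test_unknown_metabolite_is_error(self):
        ref = _toy_reference()
        with pytest.raises(KeyError):
            spcc(ref.mu, ref, ("A", "Z"))

    def test_affine_rescaling_invariance(self):
        # unit changes of a metabolite leave sPCC unchanged
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=(12, 3))
        stages = ["control"] * 6 + ["osteopenia"] * 3 + ["osteoporosis"] * 3
        cohort = make_cohort(x, stages)
        ref = build_reference(cohort)
        s = cohort.abundance.iloc[-1]
        before = spcc(s, ref, ("M000", "M001"))
        x2 = x.copy()
        x2[:, 0] = x2[:, 0] * 37.5 + 4.0
        cohort2 = make_cohort(x2, stages)
        ref2 = build_reference(cohort2)
        after = spcc(cohort2.abundance.iloc[-1], ref2, ("M000", "M001"))
        assert after == pytest.approx(before, rel=1e-9)


class TestSelectTopEdges:
    def test_top_k_counts(self):
        rng = np.random.default_rng(4)
        cohort = make_cohort(rng.lognormal(size=(12, 4)),
                             ["control"] * 6 + ["osteopenia"] * 3
                             + ["osteoporosis"] * 3)
        ref = build_reference(cohort)
        net = select_top_edges(cohort, ref, rule="top_k", top_k=2)
        assert net.n_edges == 2

    def test_zero_edges_is_error(self):
        rng = np.random.default_rng(4)
        cohort = make_cohort(rng.lognormal(size=(12, 4)),
                             ["control"] * 6 + ["osteopenia"] * 3
                             + ["osteoporosis"] * 3)
        ref = build_reference(cohort)
        with pytest.raises(ValueError):
            select_top_edges(cohort, ref, rule="top_quantile", q=0.001)

    def test_planted_domain_pair_ranks_first(self):
        hits = 0
        for seed in range(50):
            cfg = ow.SimConfig(n_metabolites=12, domain_size=2, n_trend=0,
                               missing_fraction=0.0, seed=seed)
            cohort, truth = ow.generate_cohort(cfg)
            ref = build_reference(cohort)
            net = select_top_edges(cohort, ref, rule="top_k", top_k=1)
            hits += net.edges[0] == tuple(truth.domain_members)
        assert hits >= 45  # >= 90% of 50 seeds

    def test_deterministic_tie_break(self):
        # two identical metabolite pairs -> identical scores; lexicographically
        # smaller pair id first
        rng = np.random.default_rng(5)
        base = rng.lognormal(size=(12, 2))
        x = np.column_stack([base, base])  # M002/M003 duplicate M000/M001
        cohort = make_cohort(x, ["control"] * 6 + ["osteopenia"] * 3
                             + ["osteoporosis"] * 3)
        ref = build_reference(cohort)
        net = select_top_edges(cohort, ref, rule="top_k", top_k=6)
        scores = net.scores.abs().mean(axis=0)
        tied = scores[np.isclose(scores, scores.max())].index.tolist()
        assert tied == sorted(tied)


class TestShpcc:
    @staticmethod
    def _net(seed=6, p=5):
        rng = np.random.default_rng(seed)
        cohort = make_cohort(rng.lognormal(size=(16, p)),
                             ["control"] * 8 + ["osteopenia"] * 4
                             + ["osteoporosis"] * 4)
        ref = build_reference(cohort)
        net = select_top_edges(cohort, ref, rule="top_k",
                               top_k=p * (p - 1) // 2)
        return cohort, ref, net

    def test_symmetric_in_edge_order(self):
        cohort, ref, net = self._net()
        s = cohort.abundance.iloc[-1]
        e1, e2 = net.edges[0], net.edges[1]
        assert shpcc(s, (e1, e2), ref, net) == pytest.approx(
            shpcc(s, (e2, e1), ref, net))

    def test_finite_at_reference_mean(self):
        cohort, ref, net = self._net()
        sample = ref.mu.copy()
        v = shpcc(sample, (net.edges[0], net.edges[1]), ref, net)
        assert np.isfinite(v)
        # edge scores are 0, so Z_e = -mean/sd for both edges
        z1 = -net.ref_edge_mean.iloc[0] / net.ref_edge_sd.iloc[0]
        z2 = -net.ref_edge_mean.iloc[1] / net.ref_edge_sd.iloc[1]
        assert v == pytest.approx(z1 * z2)

    def test_vectorized_equals_nested_loop_oracle(self):
        for seed in range(10):
            cohort, ref, net = self._net(seed=seed)
            e1, e2 = net.edges[0], net.edges[2]
            lab = (f"{e1[0]}|{e1[1]}", f"{e2[0]}|{e2[1]}")
            vec = shpcc_matrix(net, [lab])

            # scalar oracle from raw metabolite values
            mu, sg = ref.mu, ref.sigma
            def edge_score(row, e):
                return ((row[e[0]] - mu[e[0]]) / sg[e[0]]
                        * (row[e[1]] - mu[e[1]]) / sg[e[1]])
            for e, lbl in ((e1, lab[0]), (e2, lab[1])):
                ref_scores = [edge_score(ref.values.loc[r], e) for r in ref.sample_ids]
                m = float(np.mean(ref_scores))
                sd = float(np.std(ref_scores, ddof=1))
                assert m == pytest.approx(net.ref_edge_mean[lbl], abs=1e-10)
                assert sd == pytest.approx(net.ref_edge_sd[lbl], abs=1e-10)
            for sid in cohort.sample_ids:
                row = cohort.abundance.loc[sid]
                z = []
                for e, lbl in ((e1, lab[0]), (e2, lab[1])):
                    z.append((edge_score(row, e) - net.ref_edge_mean[lbl])
                             / net.ref_edge_sd[lbl])
                assert vec.loc[sid].iloc[0] == pytest.approx(z[0] * z[1], abs=1e-10)


class TestDetectModules:
    @staticmethod
    def _planted_blocks(seed=0, n=100, block=5, rho=0.8, noise=20):
        rng = np.random.default_rng(seed)
        cols = []
        truth = []
        for b in range(2):
            f = rng.standard_normal(n)
            blockvals = (np.sqrt(rho) * f[:, None]
                         + np.sqrt(1 - rho) * rng.standard_normal((n, block)))
            cols.append(blockvals)
            truth += [b + 1] * block
        cols.append(rng.standard_normal((n, noise)))
        truth += [0] * noise
        x = np.exp(np.hstack(cols) * 0.3)
        stages = (["control"] * (n // 3) + ["osteopenia"] * (n // 3)
                  + ["osteoporosis"] * (n - 2 * (n // 3)))
        return make_cohort(x, stages), np.asarray(truth)

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        cohort, truth = self._planted_blocks()
        modules = detect_modules(cohort)
        labels = np.zeros(len(truth), dtype=int)
        cols = list(cohort.metabolite_ids)
        for k, mod in enumerate(modules, start=1):
            for m in mod:
                labels[cols.index(m)] = k
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_independent_metabolites_yield_no_primary_module(self, caplog):
        fallbacks = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cohort = make_cohort(np.exp(0.3 * rng.standard_normal((100, 25))),
                                 ["control"] * 34 + ["osteopenia"] * 33
                                 + ["osteoporosis"] * 33)
            with caplog.at_level(logging.WARNING, logger="osteowarn.iena"):
                caplog.clear()
                detect_modules(cohort)
                fallbacks += any("falling back" in r.message for r in caplog.records)
        assert fallbacks >= 18  # >= 90% of seeds

    def test_invariant_to_column_order(self):
        cohort, _ = self._planted_blocks(seed=3)
        modules = detect_modules(cohort)
        rev = ow.Cohort(cohort.abundance[list(cohort.metabolite_ids[::-1])],
                        cohort.metadata)
        modules_rev = detect_modules(rev)
        assert {frozenset(m) for m in modules} == {frozenset(m) for m in modules_rev}


class TestSci:
    def test_zero_at_reference_mean(self):
        ref = _toy_reference()
        v, comp = sci(ref.mu.copy(), ["A", "B", "C"], ref)
        assert v == 0.0
        assert comp["ssd_in"] == 0.0

    def test_hand_computed_worked_example(self):
        # z = (2, -1, 1, 1, -1); module {A,B,C}, outside {D,E}
        # sPCC_in = (2*1 + 2*1 + 1*1)/3 = 5/3
        # sPCC_out = (2+1+1)*(1+1)/6   = 4/3
        # sSD_in = (|2*1| + |-1*2| + |1*3|)/3 = 7/3
        # sCI = (5/3)/(4/3) * 7/3 = 35/12
        ref = _toy_reference()
        sample = ref.mu + ref.sigma * pd.Series([2.0, -1.0, 1.0, 1.0, -1.0],
                                                index=ref.metabolite_ids)
        v, comp = sci(sample, ["A", "B", "C"], ref)
        assert comp["spcc_in"] == pytest.approx(5 / 3, abs=1e-10)
        assert comp["spcc_out"] == pytest.approx(4 / 3, abs=1e-10)
        assert comp["ssd_in"] == pytest.approx(7 / 3, abs=1e-10)
        assert v == pytest.approx(35 / 12, abs=1e-10)
        assert not comp["floored"]

    def test_decoupled_module_is_floored_not_nan(self):
        ref = _toy_reference()
        # outside metabolites exactly at their reference means
        sample = ref.mu + ref.sigma * pd.Series([2.0, -1.0, 1.0, 0.0, 0.0],
                                                index=ref.metabolite_ids)
        v, comp = sci(sample, ["A", "B", "C"], ref)
        assert comp["floored"]
        assert np.isfinite(v)

    def test_module_smaller_than_two_is_error(self):
        ref = _toy_reference()
        with pytest.raises(ValueError):
            sci(ref.mu.copy(), ["A"], ref)

    def test_monotone_in_common_deviation_scale(self):
        ref = _toy_reference()
        base = pd.Series([1.0, -0.5, 0.8, 0.7, -0.9], index=ref.metabolite_ids)
        prev = -1.0
        for c in (1.0, 1.5, 2.0, 4.0):
            dev = base.copy()
            dev[["A", "B", "C"]] *= c
            v, _ = sci(ref.mu + ref.sigma * dev, ["A", "B", "C"], ref)
            assert v > prev
            prev = v

    def test_vectorized_equals_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, p = rng.integers(8, 11), rng.integers(5, 9)
            x = rng.lognormal(size=(n, int(p)))
            stages = (["control"] * 5 + ["osteopenia"] * 2
                      + ["osteoporosis"] * (n - 7))
            cohort = make_cohort(x, stages)
            ref = build_reference(cohort)
            mets = list(ref.metabolite_ids)
            module = mets[:3]
            sample = cohort.abundance.iloc[-1]
            v, comp = sci(sample, module, ref)

            z = {m: (sample[m] - ref.mu[m]) / ref.sigma[m] for m in mets}
            inp = [abs(z[a] * z[b]) for a, b in itertools.combinations(module, 2)]
            outp = [abs(z[a] * z[b]) for a in module for b in mets if b not in module]
            ssd = np.mean([abs(sample[m] - ref.mu[m]) for m in module])
            expect = (np.mean(inp) / max(np.mean(outp), 1e-8)) * ssd
            assert v == pytest.approx(expect, abs=1e-10)


class TestDetectCriticalStage:
    def test_planted_dnb_names_middle_stage(self, filtered_cohort):
        cohort, truth = filtered_cohort
        domain = detect_critical_stage(cohort)
        assert domain.critical_stage == "osteopenia"
        a, b = set(domain.members), set(truth.domain_members)
        assert len(a & b) / len(a | b) >= 0.5
        assert domain.stage_means["osteopenia"] > domain.stage_means["control"]

    def test_loo_scores_for_reference_samples(self, filtered_cohort):
        # reference-stage z-scores come from leave-one-out statistics
        cohort, _ = filtered_cohort
        ref = build_reference(cohort)
        z_loo, _ = loo_zscores(ref)
        z_plain = zscores(ref.values, ref)
        # LOO deviations are strictly larger in magnitude on average
        assert z_loo.abs().mean().mean() > z_plain.abs().mean().mean()

    def test_missing_stage_is_error(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.lognormal(size=(10, 4)),
                             ["control"] * 5 + ["osteopenia"] * 5)
        with pytest.raises(ValueError, match="osteoporosis"):
            detect_critical_stage(cohort)

    def test_sci_nonnegative_everywhere(self, filtered_cohort):
        cohort, _ = filtered_cohort
        domain = detect_critical_stage(cohort)
        assert (domain.sci_per_sample >= 0).all()
        assert np.isfinite(domain.sci_per_sample).all()
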