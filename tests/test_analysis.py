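"""Analysis layer: pairwise MA, NMA, Wald test, direct/indirect separation,
Q decomposition, ranking and shrinkage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rpnma.analysis import (cox_trial_estimates, fit_nma, fit_pairwise_ma,
                            network_design_estimates, q_decomposition,
                            rank_treatments, separate_direct_indirect,
                            shrinkage_intervals, wald_global_nonph)
from rpnma.ipd import Design, IPDDataset, NetworkSpec, ValidationError
from rpnma.model import ModelSpec
from rpnma.sampler import MCMCSettings, run_mcmc
from rpnma.simulate import SimSpec, TrialPlan, WeibullBaseline, simulate_network


class TestPairwiseMA:
    def test_mixed_designs_rejected(self, loop_data):
        data, _ = loop_data
        with pytest.raises(ValidationError):
            fit_pairwise_ma(data)

    def test_single_trial_ma_equals_single_trial_fit(self, two_arm_network,
                                                     fast_settings):
        spec = SimSpec(
            network=two_arm_network,
            trials=(TrialPlan("only", two_arm_network.designs[0], 150,
                              WeibullBaseline(0.15, 1.1)),),
            true_beta=np.array([-0.4]), admin_horizon=10.0, seed=12)
        data, _ = simulate_network(spec)
        fit = fit_pairwise_ma(data, reference="A", settings=fast_settings)
        # an MA of one trial is the single-trial model: its estimate agrees
        # with the frequentist Cox fit of that trial within posterior sd
        from rpnma.diagnostics import cox_fit
        lhr, se, _ = cox_fit(data.trial("only"), reference="A")
        row = fit.summaries.loc["beta[A:B]"]
        assert abs(row["mean"] - lhr) < 2 * max(se, row["sd"])

    def test_known_truth_five_trials(self, two_arm_network):
        spec = SimSpec(
            network=two_arm_network,
            trials=tuple(TrialPlan(f"T{i}", two_arm_network.designs[0], 200,
                                   WeibullBaseline(0.1 + 0.02 * i, 1.0 + 0.05 * i))
                         for i in range(5)),
            true_beta=np.array([-0.3]), admin_horizon=10.0,
            dropout_rate=0.02, seed=33)
        data, _ = simulate_network(spec)
        fit = fit_pairwise_ma(data, reference="A",
                              settings=MCMCSettings(2, 600, 600, seed=2))
        assert fit.summaries.loc["beta[A:B]", "mean"] == pytest.approx(-0.3,
                                                                       abs=0.1)


class TestNMA:
    def test_derived_contrasts_present(self, loop_data, loop_network,
                                       fast_settings):
        data, _ = loop_data
        spec = ModelSpec(network=loop_network)
        fit = fit_nma(data, spec, settings=fast_settings)
        assert "derived[B:C]" in fit.summaries.index

    def test_derived_equals_per_draw_difference(self, loop_data, loop_network,
                                                fast_settings):
        data, _ = loop_data
        spec = ModelSpec(network=loop_network)
        fit = fit_nma(data, spec, settings=fast_settings)
        ch = fit.chains
        diff = ch.get("beta[A:C]") - ch.get("beta[A:B]")
        assert fit.summaries.loc["derived[B:C]", "mean"] == pytest.approx(
            diff.mean(), abs=1e-12)

    def test_disconnected_network_rejected(self, fast_settings):
        net = NetworkSpec(treatments=("A", "B", "C", "D"), reference="A",
                          designs=(Design(("A", "B"), "A"),
                                   Design(("C", "D"), "C")))
        df = pd.DataFrame({
            "trial": ["t1"] * 4 + ["t2"] * 4,
            "treatment": ["A", "A", "B", "B", "C", "C", "D", "D"],
            "time": [1.0, 2.0, 1.5, 2.5] * 2,
            "event": [1] * 8,
        })
        with pytest.raises(ValidationError):
            fit_nma(IPDDataset(df), ModelSpec(network=net),
                    settings=fast_settings)

    def test_uninformed_contrast_returns_prior(self, loop_network):
        """Data containing only the A-vs-B design leave beta[A:C] at its
        N(0, 1000) prior — the no-information limit."""
        spec_sim = SimSpec(
            network=loop_network,
            trials=(TrialPlan("t1", loop_network.designs[0], 100,
                              WeibullBaseline(0.15, 1.1)),
                    TrialPlan("t2", loop_network.designs[0], 100,
                              WeibullBaseline(0.12, 1.0))),
            true_beta=np.array([-0.3, 0.0]), admin_horizon=10.0, seed=5)
        data, _ = simulate_network(spec_sim)
        spec = ModelSpec(network=loop_network)
        chains = run_mcmc(spec, data,
                          settings=MCMCSettings(2, 4000, 4000, seed=8))
        free = chains.get("beta[A:C]").ravel()
        assert 0.6 * np.sqrt(1000) < free.std() < 1.4 * np.sqrt(1000)
        informed = chains.get("beta[A:B]").ravel()
        assert informed.std() < 1.0


class TestWald:
    def test_requires_interactions(self, small_pairwise_data, two_arm_network,
                                   fast_settings):
        data, _ = small_pairwise_data
        chains = run_mcmc(ModelSpec(network=two_arm_network), data,
                          settings=fast_settings)
        with pytest.raises(ValueError):
            wald_global_nonph(chains)

    def test_statistic_matches_direct_solve(self, small_pairwise_data,
                                            two_arm_network, fast_settings):
        data, _ = small_pairwise_data
        chains = run_mcmc(
            ModelSpec(network=two_arm_network, interactions="fixed"),
            data, settings=fast_settings)
        w = wald_global_nonph(chains)
        X = chains.get("beta_int[A:B]").reshape(-1, 1)
        m = X.mean(axis=0)
        V = np.cov(X, rowvar=False).reshape(1, 1)
        expected = float(m @ np.linalg.solve(V, m))
        assert w.statistic == pytest.approx(expected, abs=1e-10)
        assert w.p_value == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-12)

    def test_include_variance_adds_df(self, small_pairwise_data,
                                      two_arm_network, fast_settings):
        data, _ = small_pairwise_data
        chains = run_mcmc(
            ModelSpec(network=two_arm_network, interactions="random-by-trial"),
            data, settings=fast_settings)
        w0 = wald_global_nonph(chains)
        w1 = wald_global_nonph(chains, include_variance=True)
        assert w1.df == w0.df + 1


class TestDirectIndirect:
    def test_no_loop_error(self, small_pairwise_data, two_arm_network,
                           fast_settings):
        data, _ = small_pairwise_data
        spec = ModelSpec(network=two_arm_network)
        with pytest.raises(ValidationError, match="loop"):
            separate_direct_indirect(data, spec, settings=fast_settings)

    def test_loop_not_closed_by_data(self, loop_network, fast_settings):
        spec_sim = SimSpec(
            network=loop_network,
            trials=(TrialPlan("t1", loop_network.designs[0], 60,
                              WeibullBaseline(0.15, 1.1)),
                    TrialPlan("t2", loop_network.designs[1], 60,
                              WeibullBaseline(0.15, 1.1))),
            true_beta=np.array([-0.3, 0.2]), admin_horizon=10.0, seed=2)
        data, _ = simulate_network(spec_sim)
        spec = ModelSpec(network=loop_network,
                         inconsistency=(("A", "B", "C"),))
        with pytest.raises(ValidationError, match="not closed"):
            separate_direct_indirect(data, spec, settings=fast_settings)

    def test_direct_indirect_differ_by_omega(self, loop_data, loop_network):
        data, _ = loop_data
        spec = ModelSpec(network=loop_network,
                         inconsistency=(("A", "B", "C"),))
        tab = separate_direct_indirect(data, spec,
                                       settings=MCMCSettings(2, 500, 500, seed=9))
        om = tab.attrs["omega"]["mean"]
        ab = tab[tab["comparison"] == "A:B"].set_index("source")
        assert (ab.loc["direct", "estimate"] - ab.loc["indirect", "estimate"]
                == pytest.approx(om, abs=1e-9))
        assert set(tab["source"]) == {"direct", "indirect", "network"}
        assert len(tab) == 9


class TestQDecomposition:
    def test_single_design_single_trial_zero(self):
        te = pd.DataFrame({"design": ["A:B"], "trial": ["t1"],
                           "theta": [0.3], "se": [0.1]})
        qd = q_decomposition(te, {"A:B": 0.3})
        assert qd.q_total == pytest.approx(0.0)
        assert qd.q_inc == pytest.approx(0.0)
        assert qd.q_het == pytest.approx(0.0)
        assert qd.df_het == 0 and qd.df_inc == 0

    def test_two_trial_hand_computation(self):
        """Two trials at +/-d with equal variance: the pool is 0, Qhet is
        2 d^2/sigma^2, and Qinc depends only on the network estimate."""
        d, sig, thN = 0.4, 0.2, 0.1
        te = pd.DataFrame({"design": ["A:B", "A:B"], "trial": ["t1", "t2"],
                           "theta": [d, -d], "se": [sig, sig]})
        qd = q_decomposition(te, {"A:B": thN})
        assert qd.per_design.loc[0, "theta_pooled"] == pytest.approx(0.0)
        assert qd.q_het == pytest.approx(2 * d ** 2 / sig ** 2)
        assert qd.q_inc == pytest.approx(thN ** 2 / (sig ** 2 / 2))
        assert qd.q_total == pytest.approx(qd.q_inc + qd.q_het, abs=1e-12)
        assert qd.df_het == 1

    def test_zero_variance_rejected(self):
        te = pd.DataFrame({"design": ["A:B"], "trial": ["t1"],
                           "theta": [0.3], "se": [0.0]})
        with pytest.raises(ValueError):
            q_decomposition(te, {"A:B": 0.0})

    def test_df_accounting_with_loop(self):
        # three designs A:B, A:C, B:C identify q* = 2 basic parameters
        te = pd.DataFrame({
            "design": ["A:B", "A:B", "A:C", "B:C"],
            "trial": ["t1", "t2", "t3", "t4"],
            "theta": [0.1, 0.2, -0.1, 0.05], "se": [0.1] * 4})
        qd = q_decomposition(te, {"A:B": 0.1, "A:C": -0.1, "B:C": 0.0})
        assert qd.df_inc == 3 - 2
        assert qd.df_het == 1
        assert qd.df_total == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_identity_random_inputs(self, seed):
        """Q = Qinc + Qhet exactly under inverse-variance pooling."""
        rng = np.random.default_rng(seed)
        rows = []
        designs = ["A:B", "A:C", "B:C"][: rng.integers(1, 4)]
        for d in designs:
            for i in range(rng.integers(1, 5)):
                rows.append({"design": d, "trial": f"{d}-{i}",
                             "theta": rng.normal(0, 1),
                             "se": rng.uniform(0.05, 2.0)})
        te = pd.DataFrame(rows)
        netest = {d: rng.normal(0, 1) for d in designs}
        qd = q_decomposition(te, netest)
        assert abs(qd.q_total - (qd.q_inc + qd.q_het)) < 1e-10
        assert qd.q_total >= -1e-12 and qd.q_inc >= -1e-12 and qd.q_het >= -1e-12

    def test_cox_feed_pipeline(self, loop_data, loop_network, fast_settings):
        data, _ = loop_data
        te = cox_trial_estimates(data, loop_network)
        assert set(te.columns) == {"design", "trial", "theta", "se"}
        fit = fit_nma(data, ModelSpec(network=loop_network),
                      settings=fast_settings)
        ne = network_design_estimates(fit, loop_network, te["design"].unique())
        qd = q_decomposition(te, ne)
        assert np.isfinite(qd.q_total)
        assert abs(qd.q_total - (qd.q_inc + qd.q_het)) < 1e-10


class TestRanking:
    def test_degenerate_chain_certain_winner(self, loop_data, loop_network,
                                             fast_settings):
        data, _ = loop_data
        chains = run_mcmc(ModelSpec(network=loop_network), data,
                          settings=fast_settings)
        # force B's effect to always be the smallest
        i_ab = chains.names.index("beta[A:B]")
        i_ac = chains.names.index("beta[A:C]")
        chains.draws[:, :, i_ab] = -2.0
        chains.draws[:, :, i_ac] = 1.0
        table = rank_treatments(chains)
        assert table.loc["B", "rank 1"] == pytest.approx(100.0)
        assert table.loc["A", "rank 2"] == pytest.approx(100.0)

    def test_rows_and_columns_sum_to_100(self, loop_data, loop_network,
                                         fast_settings):
        data, _ = loop_data
        chains = run_mcmc(ModelSpec(network=loop_network), data,
                          settings=fast_settings)
        table = rank_treatments(chains)
        np.testing.assert_allclose(table.sum(axis=1), 100.0, atol=1e-9)
        np.testing.assert_allclose(table.sum(axis=0), 100.0, atol=1e-9)

    def test_symmetric_posteriors_near_even_split(self, loop_data,
                                                  loop_network, fast_settings):
        data, _ = loop_data
        chains = run_mcmc(ModelSpec(network=loop_network), data,
                          settings=fast_settings)
        rng = np.random.default_rng(0)
        i_ab = chains.names.index("beta[A:B]")
        i_ac = chains.names.index("beta[A:C]")
        sym = rng.normal(-1.0, 0.3, size=chains.draws.shape[:2])
        chains.draws[:, :, i_ab] = sym
        chains.draws[:, :, i_ac] = rng.normal(-1.0, 0.3,
                                              size=chains.draws.shape[:2])
        table = rank_treatments(chains)
        assert table.loc["B", "rank 1"] == pytest.approx(50.0, abs=5.0)

    def test_tally_matches_brute_force_sort(self, loop_data, loop_network,
                                            fast_settings):
        data, _ = loop_data
        chains = run_mcmc(ModelSpec(network=loop_network), data,
                          settings=fast_settings)
        table = rank_treatments(chains)
        net = loop_network
        base = chains.stacked([f"beta[{l}]" for l in net.contrast_labels()])
        effects = np.column_stack([base @ net.expression(t)
                                   for t in net.treatments])
        counts = np.zeros((3, 3))
        for row in effects:
            for r, idx in enumerate(np.argsort(row, kind="stable")):
                counts[idx, r] += 1
        expected = 100.0 * counts / len(effects)
        np.testing.assert_allclose(table.values, expected, atol=1e-12)

    def test_permutation_equivariance(self, loop_network):
        """Relabelling treatments permutes the rank table rows and nothing
        else (same data, same seed)."""
        spec_sim = SimSpec(
            network=loop_network,
            trials=tuple(TrialPlan(f"T{i}", d, 80, WeibullBaseline(0.15, 1.1))
                         for i, d in enumerate(loop_network.designs)),
            true_beta=np.array([-0.3, 0.2]), admin_horizon=10.0, seed=3)
        data, _ = simulate_network(spec_sim)
        st_ = MCMCSettings(2, 400, 400, seed=17)
        t1 = rank_treatments(run_mcmc(ModelSpec(network=loop_network), data,
                                      settings=st_))
        # swap labels B <-> C everywhere
        swap = {"B": "C", "C": "B", "A": "A"}
        df2 = data.df.copy()
        df2["treatment"] = df2["treatment"].map(swap)
        net2 = NetworkSpec(
            treatments=("A", "C", "B"), reference="A",
            designs=tuple(Design(tuple(swap[t] for t in d.treatments),
                                 swap[d.reference])
                          for d in loop_network.designs),
            loops=(("A", "C", "B"),))
        t2 = rank_treatments(run_mcmc(ModelSpec(network=net2),
                                      IPDDataset(df2), settings=st_))
        # the arm formerly labelled B is now labelled C and vice versa
        np.testing.assert_allclose(t1.loc["B"].values, t2.loc["C"].values,
                                   atol=1e-9)
        np.testing.assert_allclose(t1.loc["C"].values, t2.loc["B"].values,
                                   atol=1e-9)
        np.testing.assert_allclose(t1.loc["A"].values, t2.loc["A"].values,
                                   atol=1e-9)


class TestShrinkage:
    def test_wrong_model_variant_rejected(self, small_pairwise_data,
                                          two_arm_network, fast_settings):
        data, _ = small_pairwise_data
        chains = run_mcmc(ModelSpec(network=two_arm_network), data,
                          settings=fast_settings)
        with pytest.raises(ValueError):
            shrinkage_intervals(chains)

    def test_intervals_symmetric_about_means(self, small_pairwise_data,
                                             two_arm_network, fast_settings):
        data, _ = small_pairwise_data
        chains = run_mcmc(
            ModelSpec(network=two_arm_network, interactions="random-by-trial"),
            data, settings=fast_settings)
        tab = shrinkage_intervals(chains)
        np.testing.assert_allclose(tab["upper"] - tab["mean"],
                                   tab["mean"] - tab["lower"], atol=1e-12)
        assert set(tab["trial"]) == set(data.trial_ids)

    def test_nonph_trial_stands_out(self, two_arm_network):
        """One strongly non-PH trial among PH trials gets the largest
        trial-level interaction deviation."""
        plans = tuple(TrialPlan(f"T{i}", two_arm_network.designs[0], 200,
                                WeibullBaseline(0.12, 1.1)) for i in range(4))
        datasets = []
        for i, plan in enumerate(plans):
            alpha = np.array([0.8]) if i == 0 else np.array([0.0])
            spec_sim = SimSpec(network=two_arm_network, trials=(plan,),
                               true_beta=np.array([0.0]), true_alpha=alpha,
                               admin_horizon=10.0, seed=100 + i)
            d, _ = simulate_network(spec_sim)
            datasets.append(d.df)
        data = IPDDataset(pd.concat(datasets, ignore_index=True))
        chains = run_mcmc(
            ModelSpec(network=two_arm_network, interactions="random-by-trial"),
            data, settings=MCMCSettings(2, 1500, 1500, seed=4))
        tab = shrinkage_intervals(chains).set_index("trial")
        assert tab["mean"].abs().idxmax() == "T0"
        assert tab.loc["T0", "mean"] > 0
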