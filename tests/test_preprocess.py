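import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glycocc import (
    GlycanMatrix,
    combat_fit_adjust,
    log_transform,
    to_proportions,
    total_area_normalize,
)
from glycocc.panel import PEAKS

from conftest import percent_matrix
from helpers_oracles import combat_bruteforce


def raw_matrix(rows):
    rows = np.asarray(rows, dtype=float)
    return GlycanMatrix(
        pd.DataFrame(rows, index=[f"s{i}" for i in range(rows.shape[0])],
                     columns=list(PEAKS)),
        "raw_area",
    )


class TestTotalAreaNormalize:
    def test_forced_arithmetic(self):
        row = np.zeros(24)
        row[:3] = [2.0, 3.0, 5.0]
        out = total_area_normalize(raw_matrix(row[None, :]))
        np.testing.assert_allclose(out.values()[0, :3], [20.0, 30.0, 50.0])
        assert out.values()[0].sum() == pytest.approx(100.0)

    def test_idempotent_on_percent_rows(self):
        rng = np.random.default_rng(1)
        rows = rng.dirichlet(np.ones(24), size=4) * 100
        out = total_area_normalize(raw_matrix(rows))
        np.testing.assert_allclose(out.values(), rows, rtol=1e-12)

    def test_zero_row_total_names_sample(self):
        rows = np.vstack([np.full(24, 2.0), np.zeros(24)])
        with pytest.raises(ValueError, match="s1"):
            total_area_normalize(raw_matrix(rows))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        rows = rng.uniform(0.1, 50.0, size=(2, 24))
        a = total_area_normalize(raw_matrix(rows)).values()
        b = total_area_normalize(raw_matrix(rows * c)).values()
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestLogTransform:
    def test_log_values(self):
        rows = np.full((1, 24), 100.0 / 24)
        rows[0, 0], rows[0, 1] = np.e, np.e ** 2
        rows = 100 * rows / rows.sum()
        m = percent_matrix(rows)
        out, n_zero = log_transform(m)
        assert n_zero == 0
        np.testing.assert_allclose(out.values(), np.log(rows))

    def test_strict_zero_errors_with_coordinates(self):
        rows = np.full((1, 24), 100.0 / 23)
        rows[0, 5] = 0.0
        rows = 100 * rows / rows.sum()
        rows[0, 5] = 0.0
        m = GlycanMatrix(pd.DataFrame(rows, index=["s0"], columns=list(PEAKS)),
                         "proportion")
        with pytest.raises(ValueError, match="GP6"):
            log_transform(m, zero_policy="strict")
        out, n_zero = log_transform(m, zero_policy="pseudo", pseudo=1e-3)
        assert n_zero == 1
        assert out.values()[0, 5] == pytest.approx(np.log(1e-3))


class TestComBat:
    def _simulate(self, seed, n_per_batch=20, n_feat=5, loc_shift=0.5, scale=1.0,
                  sd=0.4):
        rng = np.random.default_rng(seed)
        base = rng.normal(2.0, sd, size=(2 * n_per_batch, n_feat))
        base[n_per_batch:] = (base[n_per_batch:] - 2.0) * scale + 2.0 + loc_shift
        labels = ["b1"] * n_per_batch + ["b2"] * n_per_batch
        m = GlycanMatrix(
            pd.DataFrame(base, index=[f"s{i}" for i in range(2 * n_per_batch)],
                         columns=list(PEAKS[:n_feat])),
            "log",
        )
        return m, labels

    def test_single_batch_identity(self):
        m, _ = self._simulate(0)
        out, model = combat_fit_adjust(m, ["only"] * len(m.data))
        assert model.trivial
        np.testing.assert_array_equal(out.values(), m.values())

    @pytest.mark.parametrize("mode", ["full", "mean_only"])
    def test_matches_bruteforce_oracle(self, mode):
        m, labels = self._simulate(42, loc_shift=0.5, scale=1.3)
        out, model = combat_fit_adjust(m, labels, mode=mode)
        adj, params = combat_bruteforce(m.values(), labels, mode=mode)
        np.testing.assert_allclose(out.values(), adj, atol=1e-6)
        np.testing.assert_allclose(model.grand_mean, params["grand_mean"], atol=1e-6)
        np.testing.assert_allclose(model.pooled_sd ** 2, params["pooled_var"], atol=1e-6)
        for bi, b in enumerate(model.batches):
            for key in ("gamma_hat", "delta_hat_sq", "gamma_star", "delta_sq_star"):
                np.testing.assert_allclose(
                    getattr(model, key)[bi], params["params"][b][key], atol=1e-6,
                    err_msg=f"{key} batch {b}",
                )
            assert model.gamma_bar[bi] == pytest.approx(params["params"][b]["gamma_bar"], abs=1e-6)
            assert model.a_prior[bi] == pytest.approx(params["params"][b]["a_prior"], abs=1e-6)

    def test_removes_planted_location_shift(self):
        # residual batch-mean difference scales with the noise SD; 0.1 log
        # units is the typical per-peak variation the pipeline sees
        m, labels = self._simulate(7, loc_shift=0.5, sd=0.1)
        out, _ = combat_fit_adjust(m, labels)
        adj = out.values()
        half = len(adj) // 2
        diff = np.abs(adj[:half].mean(axis=0) - adj[half:].mean(axis=0))
        assert np.all(diff < 0.05)

    def test_null_adjustment_is_small(self):
        """No true batch effect: adjustment stays within 3 SE of a batch mean."""
        m, labels = self._simulate(123, n_per_batch=200, loc_shift=0.0)
        out, _ = combat_fit_adjust(m, labels)
        delta = np.abs(out.values() - m.values()).mean()
        se_batch_mean = m.values().std() / np.sqrt(200)
        assert delta < 3 * se_batch_mean

    def test_grand_mean_preserved(self):
        m, labels = self._simulate(5, loc_shift=0.4, scale=1.5)
        out, _ = combat_fit_adjust(m, labels)
        np.testing.assert_allclose(
            out.values().mean(axis=0), m.values().mean(axis=0), atol=1e-8
        )

    def test_batch_of_one_and_constant_feature_errors(self):
        m, labels = self._simulate(0, n_per_batch=5)
        labels = ["b1"] * 9 + ["b2"]
        with pytest.raises(ValueError, match="fewer than 2"):
            combat_fit_adjust(m, labels)
        m2, labels2 = self._simulate(0, n_per_batch=5)
        m2.data.iloc[:, 2] = 1.234
        with pytest.raises(ValueError, match="GP3"):
            combat_fit_adjust(m2, labels2)

    def test_f_statistic_suppressed_in_most_replicates(self):
        """Planted location/scale effects: post-adjustment batch F below the
        95% null quantile in >= 90% of 100 seeded replicates."""
        wins = 0
        n_per, n_feat = 20, 5
        crit = stats.f.ppf(0.95, 1, 2 * n_per - 2)
        for seed in range(100):
            m, labels = self._simulate(seed, n_per_batch=n_per, loc_shift=0.4, scale=1.4)
            out, _ = combat_fit_adjust(m, labels)
            adj = out.values()
            a, b = adj[:n_per], adj[n_per:]
            f = (
                n_per * ((a.mean(0) - adj.mean(0)) ** 2 + (b.mean(0) - adj.mean(0)) ** 2)
            ) / (((a - a.mean(0)) ** 2).sum(0) + ((b - b.mean(0)) ** 2).sum(0)) * (2 * n_per - 2)
            if np.all(f < crit):
                wins += 1
        assert wins >= 90


class TestToProportions:
    def test_exp_log_roundtrip_single_batch(self):
        rng = np.random.default_rng(2)
        rows = rng.dirichlet(np.ones(24), size=3) * 100
        m = percent_matrix(rows)
        logged, _ = log_transform(m)
        corrected, _ = combat_fit_adjust(logged, ["b"] * 3)
        back = to_proportions(corrected)
        np.testing.assert_allclose(back.values(), rows, rtol=1e-12)

    def test_elementwise_exp_and_renormalize(self):
        vals = np.zeros((1, 24))
        vals[0, 0], vals[0, 1] = 0.0, 1.0
        m = GlycanMatrix(pd.DataFrame(vals, index=["s0"], columns=list(PEAKS)),
                         "corrected_log")
        out = to_proportions(m)
        assert out.values()[0, 0] == pytest.approx(1.0)
        assert out.values()[0, 1] == pytest.approx(np.e)
        renorm = to_proportions(m, renormalize=True)
        assert renorm.values().sum() == pytest.approx(100.0)
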