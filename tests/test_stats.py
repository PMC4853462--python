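import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from cartbox import (
    AnalysisError,
    DEFAULT_GRID_SPECS,
    EMMMap,
    GridSpec,
    mixed_model_r2,
    pair_points_with_reference,
    roc_grid,
)


def simulate_hierarchical(seed, n_groups=17, n_per=90, beta=0.5, tau00=4.0, sigma2=16.0,
                          cov_var=20.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, np.sqrt(tau00))
        x = rng.normal(0, np.sqrt(cov_var), n_per)
        y = beta * x + b + rng.normal(0, np.sqrt(sigma2), n_per)
        rows.append(pd.DataFrame({"group": g, "outcome": y, "covariate": x}))
    return pd.concat(rows, ignore_index=True)


class TestGridSpecs:
    def test_printed_steps_reproduced(self):
        assert DEFAULT_GRID_SPECS["it"].step == pytest.approx(2.5)
        assert DEFAULT_GRID_SPECS["uv"].step == pytest.approx(25.0 / 40.0)
        assert DEFAULT_GRID_SPECS["bv"].step == pytest.approx(0.3)
        assert DEFAULT_GRID_SPECS["lls"].step == pytest.approx(2.0)
        assert DEFAULT_GRID_SPECS["wt"].step == pytest.approx(0.5)

    def test_grid_sizes_and_anchors(self):
        it = DEFAULT_GRID_SPECS["it"]
        assert len(it.cutoffs()) == 40 and it.cutoffs()[0] == 0.0
        assert 5.0 in it.cutoffs() and 97.5 in it.cutoffs()
        uv = DEFAULT_GRID_SPECS["uv"]
        assert len(uv.thresholds()) == 40
        assert 9.375 in uv.thresholds()  # the clinically reported UV cutoff


class TestROCGrid:
    def test_perfectly_separated(self):
        ref = np.concatenate([np.full(50, 80.0), np.full(50, 10.0)])
        pred = np.where(ref >= 50, 1.0, 10.0)
        grid = roc_grid(
            np.column_stack([pred, ref]), GridSpec(0, 25), GridSpec(0, 100)
        )
        i = np.where(grid.ref_cutoffs == 50.0)[0][0]
        assert grid.auc_per_cutoff[i] == pytest.approx(1.0)
        assert grid.best["auc"] == pytest.approx(1.0)
        assert grid.best["sens"] == 1.0 and grid.best["spec"] == 1.0

    def test_null_auc_half(self):
        """Independent predictor: per-cutoff AUC sits at 0.5.  The max
        over 40 cutoffs is slightly inflated by selection (extreme
        cutoffs have tiny classes and noisy AUCs), so the null check
        uses well-populated cutoffs."""
        rng = np.random.default_rng(17)
        pred = rng.uniform(0, 25, 2000)
        ref = rng.uniform(0, 100, 2000)  # independent
        grid = roc_grid(np.column_stack([pred, ref]), GridSpec(0, 25), GridSpec(0, 100))
        mid = (grid.ref_cutoffs >= 20) & (grid.ref_cutoffs <= 80)
        assert np.nanmean(grid.auc_per_cutoff[mid]) == pytest.approx(0.5, abs=0.05)
        assert grid.best["auc"] < 0.62  # max-of-40 selection bound

    def test_auc_matches_concordance_oracle(self):
        """Per-cutoff trapezoid AUC agrees with the Mann-Whitney
        pairwise concordance up to grid discretization."""
        rng = np.random.default_rng(5)
        ref = rng.uniform(0, 100, 200)
        pred = 20 - 0.15 * ref + rng.normal(0, 2, 200)
        grid = roc_grid(np.column_stack([pred, ref]), GridSpec(0, 25), GridSpec(0, 100))
        for i, cut in enumerate(grid.ref_cutoffs):
            if not np.isfinite(grid.auc_per_cutoff[i]):
                continue
            pos = ref >= cut
            if pos.sum() < 2 or (~pos).sum() < 2:
                continue
            u = mannwhitneyu(pred[~pos], pred[pos]).statistic
            auc_oracle = u / (pos.sum() * (~pos).sum())
            assert abs(grid.auc_per_cutoff[i] - auc_oracle) < 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        ref = rng.uniform(0, 100, 300)
        pred = 15 - 0.1 * ref + rng.normal(0, 2, 300)
        g1 = roc_grid(np.column_stack([pred, ref]), GridSpec(0, 25), GridSpec(0, 100))
        pred2 = np.exp(pred / 10.0)  # strictly monotone transform
        g2 = roc_grid(
            np.column_stack([pred2, ref]), GridSpec(pred2.min(), pred2.max()), GridSpec(0, 100)
        )
        ok = np.isfinite(g1.auc_per_cutoff) & np.isfinite(g2.auc_per_cutoff)
        assert np.max(np.abs(g1.auc_per_cutoff[ok] - g2.auc_per_cutoff[ok])) <= 0.02

    def test_sens_spec_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(0, 100, 400)
        pred = rng.uniform(0, 25, 400)
        grid = roc_grid(np.column_stack([pred, ref]), GridSpec(0, 25), GridSpec(0, 100))
        for i in range(len(grid.ref_cutoffs)):
            row_s = grid.sens[i]
            row_p = grid.spec[i]
            if not np.all(np.isfinite(row_s)):
                continue
            assert np.all(np.diff(row_s) >= -1e-12)  # more positives as t grows
            assert np.all(np.diff(row_p) <= 1e-12)

    def test_direction_configurable(self):
        ref = np.concatenate([np.full(30, 80.0), np.full(30, 10.0)])
        pred = np.where(ref >= 50, 10.0, 1.0)  # high pred = diseased
        grid = roc_grid(
            np.column_stack([pred, ref]),
            GridSpec(0, 25),
            GridSpec(0, 100),
            direction="pred_ge_is_positive",
        )
        assert grid.best["auc"] == pytest.approx(1.0)

    def test_degenerate_rows_missing(self):
        ref = np.concatenate([np.full(10, 30.0), np.full(10, 70.0)])
        pairs = np.column_stack([np.linspace(1, 10, 20), ref])
        grid = roc_grid(pairs, GridSpec(0, 25), GridSpec(0, 100))
        assert np.isnan(grid.auc_per_cutoff[0])  # cutoff 0: no negatives
        i50 = np.where(grid.ref_cutoffs == 50.0)[0][0]
        assert np.isfinite(grid.auc_per_cutoff[i50])


class TestPairPoints:
    def test_vertex_value_paired(self, cyl_mesh):
        mesh = cyl_mesh.with_channel("it", np.full(cyl_mesh.n_vertices, 40.0))
        emm = EMMMap(
            ids=np.array([1]),
            positions=mesh.vertices[[7]],
            uv=np.array([6.5]),
            bv=np.array([1.0]),
            lls=np.array([5.0]),
            included=np.array([True]),
        )
        pairs, dropped = pair_points_with_reference(emm, mesh, "it", predictor="uv")
        assert pairs.tolist() == [[6.5, 40.0]]
        assert dropped == 0

    def test_all_excluded_errors(self, cyl_mesh):
        mesh = cyl_mesh.with_channel("it", np.zeros(cyl_mesh.n_vertices))
        emm = EMMMap(
            ids=np.array([1]),
            positions=np.zeros((1, 3)),
            uv=np.array([1.0]),
            bv=np.array([1.0]),
            lls=np.array([0.0]),
            included=np.array([False]),
        )
        with pytest.raises(AnalysisError):
            pair_points_with_reference(emm, mesh, "it")

    def test_conservation(self, cyl_mesh):
        rng = np.random.default_rng(9)
        n = 30
        it = np.full(cyl_mesh.n_vertices, 20.0)
        it[:40] = np.nan  # missing channel values near the base
        mesh = cyl_mesh.with_channel("it", it)
        emm = EMMMap(
            ids=np.arange(n),
            positions=cyl_mesh.vertices[rng.choice(cyl_mesh.n_vertices, n, replace=False)],
            uv=rng.uniform(0, 20, n),
            bv=rng.uniform(0, 5, n),
            lls=rng.uniform(-10, 30, n),
            included=np.ones(n, dtype=bool),
        )
        pairs, dropped = pair_points_with_reference(emm, mesh, "it")
        assert len(pairs) + dropped == emm.n_included


class TestMixedModelR2:
    def test_zero_covariate_r2_zero(self):
        df = simulate_hierarchical(0)
        df["covariate"] = 0.0
        res = mixed_model_r2(df)
        assert abs(res.r2) < 0.01

    def test_generative_fraction_recovered(self):
        # var explained by the fixed effect: beta^2 var(x) / total
        r2s = [mixed_model_r2(simulate_hierarchical(seed)).r2 for seed in range(5)]
        assert np.mean(r2s) == pytest.approx(5.0 / 25.0, abs=0.04)

    def test_matches_grid_search_oracle(self):
        """ML variance components on a 3-group toy set match a direct
        likelihood maximization over (mu, sigma2, tau00)."""
        rng = np.random.default_rng(12)
        rows = []
        for g, off in enumerate((-2.0, 0.5, 1.5)):
            y = off + rng.normal(0, 2.0, 30)
            rows.append(pd.DataFrame({"group": g, "outcome": y, "covariate": 0.0}))
        df = pd.concat(rows, ignore_index=True)
        res = mixed_model_r2(df, covariate_in_full=False)

        groups = [df.loc[df.group == g, "outcome"].to_numpy() for g in range(3)]

        def nll(mu, s2, t00):
            total = 0.0
            for y in groups:
                n = len(y)
                # compound symmetry: log-det and quadratic form in O(n)
                r = y - mu
                denom = s2 + n * t00
                logdet = (n - 1) * np.log(s2) + np.log(denom)
                quad = r @ r / s2 - t00 * r.sum() ** 2 / (s2 * denom)
                total += 0.5 * (logdet + quad + n * np.log(2 * np.pi))
            return total

        # nested grid refinement around the ML solution
        mu0, s20, t000 = df.outcome.mean(), df.outcome.var(), 1.0
        best = (mu0, s20, t000)
        width = np.array([2.0, 4.0, 4.0])
        for _ in range(12):
            mus = np.linspace(best[0] - width[0], best[0] + width[0], 11)
            s2s = np.linspace(max(best[1] - width[1], 0.05), best[1] + width[1], 11)
            t0s = np.linspace(max(best[2] - width[2], 0.0), best[2] + width[2], 11)
            vals = [(nll(m, s, t), (m, s, t)) for m in mus for s in s2s for t in t0s]
            best = min(vals)[1]
            width = width / 3.0
        assert res.sigma2_null == pytest.approx(best[1], abs=1e-3)
        assert res.tau00_null == pytest.approx(best[2], abs=1e-3)

    def test_r2_monotone_in_effect_size(self):
        betas = [0.0, 0.2, 0.4, 0.6, 0.8]
        r2s = [mixed_model_r2(simulate_hierarchical(3, beta=b)).r2 for b in betas]
        from scipy.stats import spearmanr

        assert spearmanr(betas, r2s).statistic > 0.9

    def test_too_few_groups(self):
        df = simulate_hierarchical(1, n_groups=2)
        with pytest.raises(AnalysisError):
            mixed_model_r2(df)
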