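import numpy as np
import pandas as pd
import pytest
from scipy import stats

from germscan.io import A, B, GenotypeMatrix
from germscan.phenotype import (
    anova_association,
    association_grid,
    bin_trait_values,
    blup_accession_values,
    shannon_weaver_diversity,
    trait_summary,
)


def _pheno(values_by_acc: dict[str, list[float]], trait="TKW") -> pd.DataFrame:
    rows = []
    for acc, vals in values_by_acc.items():
        for e, v in enumerate(vals):
            rows.append((acc, trait, f"env{e + 1}", v))
    return pd.DataFrame(rows, columns=["accession_id", "trait", "environment", "value"])


def _values(mapping: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"accession_id": list(mapping), "value": list(mapping.values()),
         "raw_mean": list(mapping.values()), "n_env": 1}
    )


class TestBlup:
    def test_no_residual_variance_returns_means(self):
        pheno = _pheno({"a": [10.0, 10.0], "b": [12.0, 12.0], "c": [14.0, 14.0]})
        out = blup_accession_values(pheno, "TKW").set_index("accession_id")
        assert out.loc["a", "value"] == pytest.approx(10.0)
        assert out.loc["c", "value"] == pytest.approx(14.0)

    def test_no_genetic_variance_collapses_to_grand_mean(self):
        rng = np.random.default_rng(2)
        # all accessions share one expectation; between-accession MS falls at
        # or below within MS so the MoM genetic component clamps to zero
        pheno = _pheno({f"a{i}": list(10 + rng.normal(0, 0.5, 3)) for i in range(40)})
        out = blup_accession_values(pheno, "TKW")
        spread_raw = out["raw_mean"].std()
        spread_blup = out["value"].std()
        assert spread_blup < spread_raw  # strong shrinkage
        # grand mean preserved
        assert out["value"].mean() == pytest.approx(out["raw_mean"].mean())

    def test_shrinkage_never_expands(self):
        rng = np.random.default_rng(3)
        pheno = _pheno(
            {f"a{i}": list(rng.normal(rng.normal(50, 2), 1, 3)) for i in range(50)}
        )
        out = blup_accession_values(pheno, "TKW")
        mu = out["value"].mean()
        assert (np.abs(out["value"] - mu) <= np.abs(out["raw_mean"] - mu) + 1e-9).all()

    def test_environment_offsets_removed(self):
        # accession effect 0 everywhere; env2 shifted by +5 for every
        # accession: the shift must not leak into accession values
        pheno = _pheno({"a": [10.0, 15.0], "b": [10.0, 15.0], "c": [10.0, 15.0]})
        out = blup_accession_values(pheno, "TKW")
        assert np.allclose(out["value"], 12.5)

    def test_unknown_trait_raises(self):
        with pytest.raises(ValueError, match="HD"):
            blup_accession_values(_pheno({"a": [1.0]}), "HD")

    def test_mse_not_worse_than_raw_mean(self):
        # generative check: sigma2_g = 4, sigma2_e = 1, 3 environments
        rng = np.random.default_rng(17)
        n_acc, n_env = 200, 3
        g_true = rng.normal(0, 2.0, n_acc)
        env = rng.normal(0, 1.0, n_env)
        rows = []
        for i in range(n_acc):
            for e in range(n_env):
                rows.append(
                    (f"a{i:03d}", "TKW", f"env{e}", 50 + g_true[i] + env[e]
                     + rng.normal(0, 1.0))
                )
        pheno = pd.DataFrame(rows, columns=["accession_id", "trait", "environment", "value"])
        out = blup_accession_values(pheno, "TKW").sort_values("accession_id")
        truth = 50 + g_true
        mse_blup = np.mean((out["value"].to_numpy() - truth) ** 2)
        mse_raw = np.mean((out["raw_mean"].to_numpy() - truth) ** 2)
        assert mse_blup <= mse_raw + 1e-9


class TestTraitSummary:
    META = pd.DataFrame(
        {"accession_id": [f"a{i}" for i in range(6)],
         "subgroup": ["CL"] * 3 + ["MCC"] * 3}
    )

    def test_identical_groups_p_one(self):
        vals = _values({f"a{i}": [1.0, 2.0, 3.0][i % 3] for i in range(6)})
        out = trait_summary(vals, self.META, compare=("CL", "MCC"))
        assert out["p_diff"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out.subgroup == "CL", "mean"].iloc[0] == pytest.approx(
            out.loc[out.subgroup == "MCC", "mean"].iloc[0]
        )

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(1)
        n = 100
        meta = pd.DataFrame(
            {"accession_id": [f"x{i}" for i in range(2 * n)],
             "subgroup": ["CL"] * n + ["MCC"] * n}
        )
        vals = _values(
            {f"x{i}": v for i, v in enumerate(
                np.concatenate([rng.normal(0, 1, n), rng.normal(5, 1, n)])
            )}
        )
        out = trait_summary(vals, meta, compare=("CL", "MCC"))
        assert out["p_diff"].iloc[0] < 1e-10

    def test_single_accession_group_skips_test(self):
        meta = pd.DataFrame(
            {"accession_id": ["a0", "a1", "a2"], "subgroup": ["CL", "MCC", "MCC"]}
        )
        vals = _values({"a0": 1.0, "a1": 2.0, "a2": 3.0})
        with pytest.warns(UserWarning, match="skipped"):
            out = trait_summary(vals, meta, compare=("CL", "MCC"))
        assert out["p_diff"].isna().all()
        assert set(out["n"]) == {1, 2}


class TestBinning:
    def test_boundary_conventions(self):
        vals = _values({"mid": 0.0, "low": -3.0, "high": 3.0, "edge": 2.0})
        binning = bin_trait_values(vals, "TKW", mean=0.0, sd=1.0)
        cls = binning.class_index
        assert cls["mid"] == 6      # [X, X+0.5s) belongs upward
        assert cls["low"] == 1      # open lower tail
        assert cls["high"] == 10    # open upper tail
        assert cls["edge"] == 10    # boundary value joins the upper class

    def test_zero_spread_all_class_six(self):
        vals = _values({f"a{i}": 5.0 for i in range(4)})
        with pytest.warns(UserWarning, match="class 6"):
            binning = bin_trait_values(vals, "TKW")
        assert (binning.class_index == 6).all()

    def test_partition_property(self):
        rng = np.random.default_rng(12)
        vals = _values({f"a{i}": v for i, v in enumerate(rng.normal(0, 1, 500))})
        binning = bin_trait_values(vals, "TKW")
        assert len(binning.class_index) == 500
        assert binning.class_index.between(1, 10).all()

    def test_uniform_sample_fills_middle_classes(self):
        rng = np.random.default_rng(30)
        draw = rng.uniform(-2, 2, 4000)
        vals = _values({f"a{i}": v for i, v in enumerate(draw)})
        binning = bin_trait_values(vals, "TKW", mean=0.0, sd=1.0)
        counts = binning.class_index.value_counts()
        mids = counts.reindex(range(2, 10), fill_value=0)
        assert (mids > 0).all()
        assert mids.max() / mids.min() < 1.3  # approximately equal occupancy


class TestShannon:
    def test_single_class_zero(self):
        vals = _values({f"a{i}": 5.0 for i in range(10)})
        with pytest.warns(UserWarning):
            binning = bin_trait_values(vals, "TKW")
        sd = shannon_weaver_diversity(binning)
        assert sd.H == 0.0

    def test_uniform_ten_classes_ln10(self):
        # one accession exactly in each class
        centers = [-2.25] + list(np.arange(-1.75, 2.0, 0.5)) + [2.25]
        vals = _values({f"a{i}": c for i, c in enumerate(centers)})
        binning = bin_trait_values(vals, "TKW", mean=0.0, sd=1.0)
        assert sorted(binning.class_index) == list(range(1, 11))
        sd = shannon_weaver_diversity(binning)
        assert sd.H == pytest.approx(np.log(10), abs=1e-12)

    def test_two_even_classes_ln2(self):
        vals = _values({"a": 0.1, "b": 0.1, "c": 3.0, "d": 3.0})
        binning = bin_trait_values(vals, "TKW", mean=0.0, sd=1.0)
        sd = shannon_weaver_diversity(binning)
        assert sd.H == pytest.approx(np.log(2), abs=1e-12)

    def test_empty_classes_do_not_change_h(self):
        vals = _values({"a": 0.1, "b": 3.0})
        binning = bin_trait_values(vals, "TKW", mean=0.0, sd=1.0)
        sd = shannon_weaver_diversity(binning)
        assert sd.H == pytest.approx(np.log(2), abs=1e-12)
        assert sd.class_proportions.sum() == pytest.approx(1.0)

    def test_population_filter(self):
        meta = pd.DataFrame(
            {"accession_id": ["a", "b", "c"], "subgroup": ["CL", "CL", "MCC"]}
        )
        vals = _values({"a": 0.1, "b": 3.0, "c": 0.1})
        binning = bin_trait_values(vals, "TKW", mean=0.0, sd=1.0)
        sd_cl = shannon_weaver_diversity(binning, meta, population="CL")
        sd_mcc = shannon_weaver_diversity(binning, meta, population="MCC")
        assert sd_cl.H == pytest.approx(np.log(2))
        assert sd_mcc.H == 0.0


class TestAnovaAssociation:
    def _panel(self, calls):
        g = GenotypeMatrix(
            [f"a{i}" for i in range(len(calls))], ["L1"],
            np.array(calls, dtype=np.int8).reshape(-1, 1),
        )
        return g

    def test_hand_computed_example(self):
        # groups {1,2,3} vs {4,5,6}: SSB=13.5, SSW=4, F=13.5, R2=27/35
        g = self._panel([A, A, A, B, B, B])
        vals = _values({f"a{i}": float(i + 1) for i in range(6)})
        res = anova_association(vals, g, "L1", "TKW")
        assert res.F == pytest.approx(13.5)
        assert res.p_value == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-12)
        assert res.p_value == pytest.approx(0.0213, abs=2e-4)
        assert res.r_squared == pytest.approx(13.5 / 17.5)
        assert res.significant

    def test_equal_group_means_null(self):
        g = self._panel([A, A, B, B])
        vals = _values({"a0": 1.0, "a1": 3.0, "a2": 1.0, "a3": 3.0})
        res = anova_association(vals, g, "L1", "TKW")
        assert res.F == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_monomorphic_locus_skipped(self):
        g = self._panel([A, A, A, A])
        vals = _values({f"a{i}": float(i) for i in range(4)})
        assert anova_association(vals, g, "L1", "TKW") is None

    def test_het_excluded_by_default(self):
        from germscan.io import HET

        g = self._panel([A, A, HET, B, B])
        vals = _values({"a0": 1.0, "a1": 2.0, "a2": 100.0, "a3": 4.0, "a4": 5.0})
        res = anova_association(vals, g, "L1", "TKW")
        assert res.n == 4  # HET accession left out

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(77)
        n = 60
        pvals = []
        for _ in range(300):
            calls = np.where(rng.random(n) < 0.5, A, B)
            g = self._panel(list(calls))
            vals = _values({f"a{i}": v for i, v in enumerate(rng.normal(0, 1, n))})
            res = anova_association(vals, g, "L1", "TKW")
            if res is not None:
                pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_association_grid_shape_and_cells(self, rng):
        n = 40
        calls = rng.integers(0, 2, size=(n, 3)).astype(np.int8)
        g = GenotypeMatrix(
            [f"a{i}" for i in range(n)], ["L1", "L2", "L3"], calls
        )
        rows = []
        for i in range(n):
            for e in range(2):
                rows.append((f"a{i}", "TKW", f"env{e}", float(rng.normal(40, 2))))
                rows.append((f"a{i}", "PH", f"env{e}", float(rng.normal(100, 5))))
        pheno = pd.DataFrame(rows, columns=["accession_id", "trait", "environment", "value"])
        grid = association_grid(pheno, g)
        assert grid.shape == (3, 2)
        assert set(grid.columns) == {"TKW", "PH"}
        assert (grid.stack() >= 0).all()
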