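import subprocess

import numpy as np
import pandas as pd
import pytest

from crossage import harmonize, synthetic
from crossage.harmonize import (
    CorrectionPlan,
    CorrectionStep,
    apply_plan,
    combat_eb,
    pvca,
    search_order,
    zscore_within,
)


def _frame(values, genes=None, cols=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


class TestZscoreWithin:
    def test_single_group_standardization(self):
        X = _frame([[1, 2, 3]])
        groups = pd.Series(["a"] * 3, index=X.columns)
        out = zscore_within(X, groups)
        assert np.allclose(out.to_numpy(), [[-1.2247, 0.0, 1.2247]], atol=1e-4)

    def test_constant_gene_maps_to_zero(self):
        X = _frame([[5, 5, 5]])
        out = zscore_within(X, pd.Series(["a"] * 3, index=X.columns))
        assert np.array_equal(out.to_numpy(), [[0.0, 0.0, 0.0]])

    def test_per_group_means_zero(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.normal(size=(10, 8)) + np.r_[np.zeros(4), np.full(4, 5.0)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=X.columns)
        out = zscore_within(X, groups)
        for g in ("a", "b"):
            assert np.allclose(out.loc[:, groups == g].mean(axis=1), 0.0, atol=1e-12)

    def test_singleton_group_rejected_naming_group(self):
        X = _frame([[1, 2, 3]])
        with pytest.raises(ValueError, match="'b'"):
            zscore_within(X, pd.Series(["a", "a", "b"], index=X.columns))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = _frame(rng.normal(size=(20, 10)))
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=X.columns)
        once = zscore_within(X, groups)
        twice = zscore_within(once, groups)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)


class TestCombat:
    @pytest.fixture()
    def batched(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.normal(0, 1, (60, 24)) + rng.normal(0, 2, size=(60, 1)))
        batch = pd.Series(["a"] * 12 + ["b"] * 12, index=X.columns)
        return X, batch

    def test_single_batch_identity_with_warning(self):
        X = _frame(np.random.default_rng(0).normal(size=(5, 6)))
        with pytest.warns(UserWarning, match="single batch"):
            out = combat_eb(X, pd.Series(["a"] * 6, index=X.columns))
        assert np.allclose(out.to_numpy(), X.to_numpy())

    def test_identical_distributions_near_identity(self, batched):
        X, batch = batched
        out = combat_eb(X, batch)
        # no systematic batch difference: adjustment only removes sampling
        # noise in the batch means, output stays close to the input
        assert np.corrcoef(out.to_numpy().ravel(), X.to_numpy().ravel())[0, 1] > 0.98

    def test_offset_batch_gap_shrinks(self):
        # null gene set with a pure batch offset; the residual gap is the
        # shrunk sampling noise of the batch means
        rng = np.random.default_rng(7)
        X = _frame(rng.normal(size=(200, 40)))
        batch = pd.Series(["a"] * 20 + ["b"] * 20, index=X.columns)
        delta = 2.0
        X.loc[:, batch == "b"] += delta
        out = combat_eb(X, batch)
        gap = (
            out.loc[:, batch == "a"].mean(axis=1) - out.loc[:, batch == "b"].mean(axis=1)
        ).abs().mean()
        assert gap < 0.1 * delta

    def test_small_batch_rejected(self):
        X = _frame(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError, match="fewer than 2"):
            combat_eb(X, pd.Series(["a", "a", "a", "b"], index=X.columns))

    def test_matches_bioconductor_sva(self, batched):
        """Independent oracle: sva::ComBat (parametric priors) via Rscript."""
        X, batch = batched
        X = X.copy()
        rng = np.random.default_rng(5)
        X.loc[:, batch == "b"] += rng.normal(1.0, 0.5, size=(len(X), 1))
        X.loc[:, batch == "b"] *= 1.4
        ours = combat_eb(X, batch)
        import tempfile
        with tempfile.TemporaryDirectory() as td:
            X.to_csv(f"{td}/x.tsv", sep="\t")
            script = (
                'suppressMessages(library(sva))\n'
                f'x <- as.matrix(read.delim("{td}/x.tsv", row.names=1))\n'
                'batch <- c(rep("a",12), rep("b",12))\n'
                'out <- ComBat(dat=x, batch=batch, par.prior=TRUE)\n'
                f'write.table(out, "{td}/out.tsv", sep="\\t", quote=FALSE)\n'
            )
            with open(f"{td}/s.R", "w") as fh:
                fh.write(script)
            subprocess.run(["Rscript", f"{td}/s.R"], check=True, capture_output=True)
            ref = pd.read_csv(f"{td}/out.tsv", sep="\t").to_numpy()
        assert np.abs(ours.to_numpy() - ref).max() < 1e-4

    def test_idempotent_up_to_tolerance(self):
        rng = np.random.default_rng(7)
        X = _frame(rng.normal(size=(200, 60)))
        batch = pd.Series(["a"] * 30 + ["b"] * 30, index=X.columns)
        X.loc[:, batch == "b"] += 1.5
        once = combat_eb(X, batch)
        twice = combat_eb(once, batch)
        rms = np.sqrt(((once.to_numpy() - twice.to_numpy()) ** 2).mean())
        assert rms < 0.05


class TestApplyPlan:
    def test_empty_plan_identity(self, tiny_cohort):
        plan = CorrectionPlan(())
        out = apply_plan(tiny_cohort.expression, tiny_cohort.samples, plan)
        assert out.equals(tiny_cohort.expression)

    def test_single_zscore_step_equivalence(self, tiny_cohort):
        plan = CorrectionPlan.from_pairs([("organ", "zscore")])
        out = apply_plan(tiny_cohort.expression, tiny_cohort.samples, plan)
        direct = zscore_within(tiny_cohort.expression, tiny_cohort.samples["organ"])
        assert np.allclose(out.to_numpy(), direct.to_numpy())

    def test_correction_raises_age_fraction(self):
        design = synthetic.CohortDesign(
            organs=["o1", "o2", "o3"], strains=["s1", "s2"], sexes=["f", "m"],
            ages=[3, 6, 12, 18, 24], replicates_per_cell=2, seed=11,
        )
        structure = synthetic.default_planted_structure(
            n_genes=150, n_per_archetype=8, n_regulators=0,
            variance_fractions={"organ": 0.6, "strain": 0.2, "sex": 0.02,
                                "age": 0.05, "residual": 0.13},
        )
        cohort = synthetic.generate_cohort(design, structure)
        factors = ["organ", "strain", "sex", "age"]
        raw = pvca(cohort.expression, cohort.samples, factors)
        plan = CorrectionPlan.from_pairs(
            [("organ", "combat"), ("strain", "combat"), ("sex", "zscore")]
        )
        corrected = apply_plan(cohort.expression, cohort.samples, plan)
        post = pvca(corrected, cohort.samples, factors)
        assert post.fractions["age"] > raw.fractions["age"]

    def test_small_stratum_rejected_with_name(self, tiny_cohort):
        # nesting organ then age leaves 3-sample strata; z-scoring age
        # levels inside them yields singleton groups
        plan = CorrectionPlan.from_pairs([("organ", "zscore"), ("age", "zscore")])
        samples = tiny_cohort.samples.copy()
        samples.loc[samples.index[0], "age_months"] = 99
        with pytest.raises(ValueError, match="stratum"):
            apply_plan(tiny_cohort.expression, samples, plan)

    def test_repeated_covariate_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            CorrectionPlan.from_pairs([("organ", "zscore"), ("organ", "combat")])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            CorrectionStep("organ", "quantile")


class TestPVCA:
    def test_saturated_factor(self):
        rng = np.random.default_rng(0)
        organs = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        samples = pd.DataFrame({"organ": organs, "age_months": [3] * 15 + [24] * 15},
                               index=[f"s{i}" for i in range(30)])
        effects = rng.normal(size=(50, 3))
        codes = pd.Categorical(samples["organ"]).codes
        X = pd.DataFrame(effects[:, codes], index=[f"g{i}" for i in range(50)],
                         columns=samples.index)
        res = pvca(X, samples, ["organ"])
        assert res.fractions["organ"] >= 0.99

    def test_pure_noise_mostly_residual(self):
        rng = np.random.default_rng(1)
        samples = pd.DataFrame(
            {"organ": ["a", "b"] * 100, "age_months": [3, 6, 12, 18] * 50},
            index=[f"s{i}" for i in range(200)],
        )
        X = pd.DataFrame(rng.normal(size=(200, 200)), columns=samples.index)
        res = pvca(X, samples, ["organ", "age"])
        assert res.fractions["residual"] >= 0.9

    def test_planted_recovery(self):
        design = synthetic.CohortDesign(
            organs=["o1", "o2", "o3", "o4"], strains=["s1", "s2"], sexes=["f", "m"],
            ages=[3, 6, 12, 18, 24], replicates_per_cell=2, seed=1,
        )
        target = {"organ": 0.6, "strain": 0.1, "age": 0.1, "residual": 0.2}
        structure = synthetic.PlantedStructure(n_genes=500, variance_fractions=target)
        cohort = synthetic.generate_cohort(design, structure)
        res = pvca(cohort.expression, cohort.samples,
                   ["organ", "strain", "sex", "age"], cum_var_threshold=0.99)
        for f, v in target.items():
            assert res.fractions[f] == pytest.approx(v, abs=0.05)

    def test_sample_permutation_invariance(self, tiny_cohort):
        factors = ["organ", "age"]
        res = pvca(tiny_cohort.expression, tiny_cohort.samples, factors)
        rng = np.random.default_rng(0)
        perm = rng.permutation(tiny_cohort.expression.columns)
        res_p = pvca(tiny_cohort.expression[perm], tiny_cohort.samples.loc[perm], factors)
        for f in res.fractions:
            assert res.fractions[f] == pytest.approx(res_p.fractions[f], abs=1e-8)

    def test_fractions_nonnegative_sum_one(self, tiny_cohort):
        res = pvca(tiny_cohort.expression, tiny_cohort.samples, ["organ", "age"])
        assert all(v >= 0 for v in res.fractions.values())
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_level_factor_zero_with_warning(self, tiny_cohort):
        with pytest.warns(UserWarning, match="single level"):
            res = pvca(tiny_cohort.expression, tiny_cohort.samples, ["sex", "organ"])
        assert res.fractions["sex"] == 0.0

    def test_correcting_factor_does_not_raise_its_fraction(self, tiny_cohort):
        factors = ["organ", "age"]
        before = pvca(tiny_cohort.expression, tiny_cohort.samples, factors)
        plan = CorrectionPlan.from_pairs([("organ", "zscore")])
        after = pvca(apply_plan(tiny_cohort.expression, tiny_cohort.samples, plan),
                     tiny_cohort.samples, factors)
        assert after.fractions["organ"] <= before.fractions["organ"] + 0.02


@pytest.fixture(scope="module")
def small():
    design = synthetic.CohortDesign(
        organs=["o1", "o2"], strains=["s1", "s2"], sexes=["f", "m"],
        ages=[3, 24], replicates_per_cell=2, seed=2,
    )
    structure = synthetic.PlantedStructure(
        n_genes=40,
        variance_fractions={"organ": 0.4, "strain": 0.2, "sex": 0.1,
                            "age": 0.1, "residual": 0.2},
    )
    return synthetic.generate_cohort(design, structure)


class TestSearchOrder:

    def test_single_covariate_single_method(self, small):
        ranked = search_order(small.expression, small.samples, ["organ"], ("zscore",))
        assert len(ranked) == 1
        assert ranked[0][0].describe() == "zscore(organ)"

    def test_enumeration_count(self, small):
        ranked = search_order(small.expression, small.samples,
                              ["organ", "strain", "sex"], ("zscore", "combat"))
        assert len(ranked) == 48  # 3! permutations x 2^3 method assignments

    def test_ranked_by_age_fraction_descending(self, small):
        ranked = search_order(small.expression, small.samples,
                              ["organ", "strain"], ("zscore",))
        fracs = [r.fractions["age"] for _, r in ranked]
        assert fracs == sorted(fracs, reverse=True)

    def test_too_many_covariates_rejected(self, small):
        with pytest.raises(ValueError, match="at most 4"):
            search_order(small.expression, small.samples,
                         ["organ", "strain", "sex", "age", "replicate"])
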