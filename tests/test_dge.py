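"""Differential expression: size factors, Wald calibration, BH, exclusion logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sexpanel.config import DEGThresholds
from sexpanel.dge import (
    ConfoundedDesignError,
    DEGSet,
    bh_adjust,
    estimate_size_factors,
    exclude_shared_degs,
    filter_degs,
    nb_wald_test,
)
from sexpanel.sim import BatchSpec, PlantedTruth, SimConfig, simulate_cohorts


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=list("xyz"))
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_gets_double_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=list("xyz"))
        sf = estimate_size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_invariant_to_gene_order(self, toy_counts):
        sf1 = estimate_size_factors(toy_counts)
        sf2 = estimate_size_factors(toy_counts.iloc[::-1])
        assert np.allclose(sf1, sf2)

    def test_no_all_positive_gene_suggests_fallback(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="poscounts"):
            estimate_size_factors(counts)
        sf = estimate_size_factors(counts, method="poscounts")
        assert (sf > 0).all()


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.04] * 5), 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_invariant_and_idempotent(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps, kind="stable")
        assert np.allclose(np.sort(adj), np.sort(bh_adjust(np.asarray(ps)[order])))
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


class TestFilterDegs:
    def test_boundary_cases(self):
        result = pd.DataFrame(
            {
                "log2fc": [1.01, 2.0, -1.0, -1.5],
                "padj": [0.049, 0.05, 0.01, 0.02],
            },
            index=["in_up", "padj_at_limit", "lfc_at_limit", "in_down"],
        )
        degs = filter_degs(result, DEGThresholds())
        assert degs.directions == {"in_up": 1, "in_down": -1}


class TestExclusion:
    def test_same_direction_removed_opposite_retained(self):
        target = DEGSet({"a": 1, "b": 1, "c": -1}, contrast="male-dev")
        other = DEGSet({"a": 1, "b": -1}, contrast="female-dev")
        out = exclude_shared_degs(target, other)
        assert out.directions == {"b": 1, "c": -1}

    def test_empty_other_is_identity(self):
        target = DEGSet({"a": 1, "b": -1})
        out = exclude_shared_degs(target, DEGSet())
        assert out.directions == target.directions

    @settings(max_examples=30, deadline=None)
    @given(
        st.dictionaries(st.sampled_from("abcdefgh"), st.sampled_from([1, -1]), max_size=8),
        st.dictionaries(st.sampled_from("abcdefgh"), st.sampled_from([1, -1]), max_size=8),
    )
    def test_result_is_subset_without_shared_direction(self, t, o):
        out = exclude_shared_degs(DEGSet(t), DEGSet(o))
        assert set(out.directions) <= set(t)
        for g, d in out.directions.items():
            assert o.get(g) != d


def _sim_two_groups(n_genes, n_per_group, truth=None, seed=0, **kw):
    cfg = SimConfig(
        n_genes=n_genes,
        batch_specs=(
            BatchSpec("b1", {("male", "tumor"): n_per_group, ("male", "non-tumor"): n_per_group}),
        ),
        planted=truth or PlantedTruth(),
        batch_effect_sigma=0.0,
        seed=seed,
        **kw,
    )
    return simulate_cohorts(cfg)


class TestNbWald:
    def test_planted_log2fc_estimates(self):
        truth = PlantedTruth(
            male_specific={f"g{i:05d}": (3.0 if i % 2 == 0 else -3.0) for i in range(30)}
        )
        sim = _sim_two_groups(800, 60, truth, seed=13)
        res = nb_wald_test(sim.counts["b1"], sim.metadata["status"], positive="tumor")
        est = res.loc[list(truth.male_specific), "log2fc"]
        err = np.abs(est - pd.Series(truth.male_specific))
        assert (err <= 0.3).mean() >= 0.9

    def test_batch_covariate_absorbs_global_batch_shift(self):
        # doubling all counts of one batch, condition balanced within batches,
        # must not inflate condition false positives relative to no batch at all
        cfg = SimConfig(
            n_genes=800,
            batch_specs=(
                BatchSpec("b1", {("male", "tumor"): 30, ("male", "non-tumor"): 30}),
                BatchSpec("b2", {("male", "tumor"): 30, ("male", "non-tumor"): 30}),
            ),
            planted=PlantedTruth(),
            batch_effect_sigma=0.0,
            seed=17,
        )
        sim = simulate_cohorts(cfg)
        counts = pd.concat([sim.counts["b1"], sim.counts["b2"] * 2], axis=1)
        res = nb_wald_test(
            counts, sim.metadata["status"], sim.metadata["batch"], positive="tumor"
        )
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_confounded_design_rejected(self, two_group_sim):
        sim = two_group_sim
        with pytest.raises(ConfoundedDesignError):
            nb_wald_test(
                sim.counts["b1"],
                sim.metadata["status"],
                sim.metadata["status"],  # batch identical to condition
                positive="tumor",
            )

    def test_all_zero_genes_excluded_and_reported(self, two_group_sim):
        counts = two_group_sim.counts["b1"].copy()
        counts.loc["g00399"] = 0
        res = nb_wald_test(counts, two_group_sim.metadata["status"], positive="tumor")
        assert "g00399" not in res.index
        assert "g00399" in res.attrs["excluded"]

    def test_padj_dominates_pvalue(self, two_group_sim):
        res = nb_wald_test(
            two_group_sim.counts["b1"], two_group_sim.metadata["status"], positive="tumor"
        )
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()
        assert res["pvalue"].between(0, 1).all()

    def test_agrees_with_deseq2_reference_on_small_fixture(self, two_group_sim):
        """Independent oracle: a published NB Wald implementation on the same
        counts should produce near-identical fold changes and concordant p-values."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        sim = two_group_sim
        counts = sim.counts["b1"]
        mine = nb_wald_test(counts, sim.metadata["status"], positive="tumor")
        meta = sim.metadata.loc[counts.columns, ["status"]].copy()
        meta["status"] = meta["status"].str.replace("-", "_")
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~status", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["status", "tumor", "non_tumor"], quiet=True)
        ds.summary()
        ref = ds.results_df
        both = mine.join(ref[["log2FoldChange", "pvalue"]], rsuffix="_ref").dropna()
        assert (both["log2fc"] - both["log2FoldChange"]).abs().median() < 0.05
        from scipy.stats import spearmanr

        assert spearmanr(both["pvalue"], both["pvalue_ref"]).statistic > 0.95


def test_task_pools_recover_planted_classes():
    """Male/female pools keep their own class plus opposite-direction genes and
    exclude shared same-direction genes; contamination stays low."""
    truth = PlantedTruth.default(
        n_male=20, n_female=20, n_shared_same=15, n_shared_opposite=10, n_dimorphic=10,
        lfc=2.5, dimorphic_lfc=1.6,
    )
    cfg = SimConfig(
        n_genes=800,
        batch_specs=(
            BatchSpec(
                "b1",
                {
                    ("male", "tumor"): 50,
                    ("male", "non-tumor"): 50,
                    ("female", "tumor"): 50,
                    ("female", "non-tumor"): 50,
                },
            ),
        ),
        planted=truth,
        batch_effect_sigma=0.0,
        seed=23,
    )
    sim = simulate_cohorts(cfg)
    meta = sim.metadata
    pools = {}
    for sex in ("male", "female"):
        ids = meta.index[meta["sex"] == sex]
        res = nb_wald_test(
            sim.counts["b1"].loc[:, ids], meta.loc[ids, "status"], positive="tumor"
        )
        pools[sex] = filter_degs(res)
    male_pool = exclude_shared_degs(pools["male"], pools["female"])
    female_pool = exclude_shared_degs(pools["female"], pools["male"])

    assert len(set(truth.male_specific) & male_pool.genes()) >= 0.8 * len(truth.male_specific)
    assert len(set(truth.female_specific) & female_pool.genes()) >= 0.8 * len(truth.female_specific)
    # shared same-direction genes never survive into the sex-specific pools
    assert not set(truth.shared_same) & male_pool.genes()
    assert not set(truth.shared_same) & female_pool.genes()
    # opposite-direction genes are deliberately retained
    assert len(set(truth.shared_opposite) & male_pool.genes()) >= 0.8 * len(truth.shared_opposite)
    # genes with no true effect in this contrast stay rare
    class_of = sim.truth_table()["class"]
    for pool in (male_pool, female_pool):
        contaminants = [
            g for g in pool.genes() if class_of.loc[g] in ("null", "shared_same")
        ]
        assert len(contaminants) <= 0.1 * len(pool)
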