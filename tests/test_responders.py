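"""Responder identification: filters, data-derived null, BH, end-to-end calls."""

import numpy as np
import pandas as pd
import pytest

from hrsip.io import CountMatrix, SampleMeta
from hrsip.responders import (
    ComparisonSpec,
    aggregate_responders,
    bh_adjust,
    comparisons_from_meta,
    detect_responders,
    lfc_null_threshold,
    sparsity_filter,
)
from hrsip.simulate import SimConfig, simulate_gradient_pair


def seed7_comparison():
    cfg = SimConfig(n_otus=100, n_labeled=10, depth=30_000, max_shift=0.03, seed=7)
    m, meta, truth = simulate_gradient_pair(cfg, day=3, substrate="13C-cellulose")
    spec = ComparisonSpec("13C-cellulose", 3, "13C-cellulose_d3", "control_d3")
    return m, meta, truth, spec


class TestSparsityFilter:
    def table(self, n_present, n_total):
        row = [1] * n_present + [0] * (n_total - n_present)
        return pd.DataFrame([row], index=["o"], columns=[f"f{i}" for i in range(n_total)])

    def test_boundary_inclusive(self):
        assert sparsity_filter(self.table(9, 20)).loc["o"]  # exactly 45%

    def test_below_threshold_dropped(self):
        assert not sparsity_filter(self.table(8, 20)).loc["o"]

    def test_ubiquitous_kept(self):
        assert sparsity_filter(self.table(20, 20)).loc["o"]

    def test_empty_fraction_set_rejected(self):
        with pytest.raises(ValueError):
            sparsity_filter(pd.DataFrame(index=["o"]))


class TestLfcNullThreshold:
    def test_constant_values(self):
        assert lfc_null_threshold([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_mean_plus_sample_sd(self):
        assert lfc_null_threshold([0.0, 1.0, 2.0]) == pytest.approx(2.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        lfcs = rng.normal(size=20)
        assert lfc_null_threshold(lfcs + 1.7) == pytest.approx(lfc_null_threshold(lfcs) + 1.7)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            lfc_null_threshold([1.0])


class TestBhAdjust:
    def test_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.04, 0.5])
        assert out == pytest.approx([0.04, 0.04, 0.0533333, 0.5], abs=1e-6)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestDetectResponders:
    def test_simulated_recovery_seed7(self):
        # ground-truth recovery under the narrow-profile study conditions;
        # expected counts frozen from the simulator oracle at this seed
        m, meta, truth, spec = seed7_comparison()
        res = detect_responders(m, meta, spec)
        labeled = set(truth.index[truth["labeled"]])
        called = set(res.loc[res["responder"], "otu_id"])
        assert len(called & labeled) >= 8
        assert len(called - labeled) <= 2

    def test_identical_gradients_give_zero_responders(self, gradient_meta):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 200, size=(40, 10))
        data = pd.DataFrame(
            np.hstack([block, block]),
            index=[f"OTU.{i}" for i in range(40)],
            columns=list(gradient_meta.data.index),
        )
        m = CountMatrix(data)
        spec = ComparisonSpec("13C-xylose", 1, "xyl_d1", "ctl_d1")
        res = detect_responders(m, meta=gradient_meta, spec=spec)
        assert not res["responder"].any()

    def test_responder_implies_lfc_above_threshold(self):
        m, meta, truth, spec = seed7_comparison()
        res = detect_responders(m, meta, spec)
        hits = res[res["responder"]]
        others = res[res["passed_sparsity"] & ~res["responder"]]
        assert hits["lfc"].min() > others["lfc"].median()
        assert (hits["wald_p"] < 0.5).all()  # one-sided: rejects only above threshold

    def test_sample_order_invariance(self):
        m, meta, truth, spec = seed7_comparison()
        res1 = detect_responders(m, meta, spec)
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.sample_ids)
        m2 = CountMatrix(m.data.loc[:, perm])
        meta2 = SampleMeta(meta.data.loc[perm])
        res2 = detect_responders(m2, meta2, spec)
        assert set(res1.loc[res1["responder"], "otu_id"]) == set(
            res2.loc[res2["responder"], "otu_id"]
        )

    def test_depth_doubling_leaves_lfc_invariant(self):
        # size-factor absorption: with the dispersion held fixed, doubling
        # every count leaves each OTU's treatment LFC unchanged
        from hrsip.density import select_heavy
        from hrsip.nb import estimate_dispersion, estimate_size_factors, fit_nb_glm

        m, meta, truth, spec = seed7_comparison()
        heavy = select_heavy(meta.data)
        sub = m.select_samples(heavy)
        labeled = [1.0 if meta.data.loc[s, "treatment"] != "control" else 0.0 for s in heavy]
        design = np.column_stack([np.ones(len(heavy)), labeled])
        sf1 = estimate_size_factors(sub)
        sub2 = CountMatrix(sub.data * 2)
        sf2 = estimate_size_factors(sub2)
        assert np.allclose(sf1, sf2, atol=1e-10)  # factors absorb the rescaling
        for otu in sub.otu_ids[:30]:
            if sub.data.loc[otu].groupby(np.array(labeled)).sum().min() == 0:
                continue  # unpenalized LFC undefined for a separated group
            lfc1 = fit_nb_glm(
                sub.data.loc[otu].to_numpy(), design, sf1.to_numpy(), 0.0, ridge_var=1e8
            ).coef[1]
            lfc2 = fit_nb_glm(
                sub2.data.loc[otu].to_numpy(), design, sf2.to_numpy(), 0.0, ridge_var=1e8
            ).coef[1]
            assert abs(lfc1 - lfc2) < 0.01

    def test_sensitivity_monotone_in_shift(self):
        hits = []
        for shift in (0.005, 0.015, 0.030):
            cfg = SimConfig(n_otus=100, n_labeled=10, depth=30_000, max_shift=shift, seed=21)
            m, meta, truth = simulate_gradient_pair(cfg, day=3, substrate="13C-cellulose")
            spec = ComparisonSpec("13C-cellulose", 3, "13C-cellulose_d3", "control_d3")
            res = detect_responders(m, meta, spec)
            labeled = set(truth.index[truth["labeled"]])
            called = set(res.loc[res["responder"], "otu_id"])
            hits.append(len(called & labeled))
        assert hits == sorted(hits)

    def test_mismatched_day_rejected(self):
        m, meta, truth, _ = seed7_comparison()
        spec = ComparisonSpec("13C-cellulose", 7, "13C-cellulose_d3", "control_d3")
        with pytest.raises(ValueError):
            detect_responders(m, meta, spec)


class TestAggregation:
    def results(self, rows):
        return pd.DataFrame(rows, columns=["otu_id", "substrate", "day", "responder"])

    def test_shared_and_exclusive_sets(self):
        rows = [
            ("a", "13C-xylose", 1, True),
            ("b", "13C-xylose", 3, True),
            ("b", "13C-cellulose", 14, True),
            ("c", "13C-cellulose", 14, True),
        ]
        summary = aggregate_responders(self.results(rows))
        assert summary["shared"] == {"b"}
        assert summary["exclusive"]["13C-xylose"] == {"a"}
        assert summary["exclusive"]["13C-cellulose"] == {"c"}

    def test_first_day_of_response(self):
        rows = [("a", "13C-xylose", 7, True), ("a", "13C-xylose", 3, True)]
        summary = aggregate_responders(self.results(rows))
        assert summary["first_day"]["13C-xylose"]["a"] == 3

    def test_empty_input(self):
        summary = aggregate_responders(self.results([]))
        assert summary["per_substrate"] == {} and summary["shared"] == set()

    def test_comparisons_derived_from_metadata(self, gradient_meta):
        specs = comparisons_from_meta(gradient_meta)
        assert len(specs) == 1
        assert specs[0].substrate == "13C-xylose"
        assert specs[0].control_gradient_id == "ctl_d1"
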