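"""Aggregation: bias/MSE conventions, selection rates, prevalence groups."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rarepen as rp
from rarepen.estimators_base import FitResult
from rarepen.evaluation import prevalence_groups


def _fit(p, coefs=None, selected=None, method="ml"):
    coefs = np.zeros(p) if coefs is None else np.asarray(coefs, float)
    selected = (coefs != 0) if selected is None else np.asarray(selected, bool)
    return FitResult(method=method, intercept=0.0, coefficients=coefs,
                     selected=selected)


def _records(spec, selections, method="ml"):
    """One record per row of boolean `selections` (replicate x variable)."""
    out = []
    for i, sel in enumerate(selections):
        rec = rp.ReplicateRecord(replicate_id=i, truth=spec)
        rec.fits[method] = _fit(spec.n_exposures, selected=sel,
                                coefs=np.asarray(sel, float), method=method)
        out.append(rec)
    return out


class TestBiasAndMse:
    def test_bias_is_estimate_minus_truth(self):
        assert rp.bias(1.2, 1.0) == pytest.approx(0.2)
        assert rp.bias(0.0, -1.0) == pytest.approx(1.0)

    def test_unselected_relevant_variable_contributes_unit_bias(self):
        # effective estimate is 0, so bias is exactly -beta = +/-1
        fit = _fit(3, coefs=[0.7, 0.0, -2.0], selected=[True, False, False])
        eff = fit.effective_estimates()
        assert eff.tolist() == [0.7, 0.0, 0.0]
        assert rp.bias(eff[2], -1.0) == pytest.approx(1.0)

    def test_mse_trivial_cases(self):
        assert rp.mse([1.0, 1.0], 1.0) == 0.0
        assert rp.mse([0.0, 2.0], 1.0) == 1.0

    @given(st.lists(st.floats(-3, 3), min_size=2, max_size=30),
           st.floats(-1, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mse_equals_variance_plus_squared_bias(self, ests, truth):
        ests = np.asarray(ests)
        lhs = rp.mse(ests, truth)
        rhs = ests.var() + (ests.mean() - truth) ** 2
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)

    def test_mse_requires_replicates(self):
        with pytest.raises(ValueError):
            rp.mse([], 1.0)


class TestSelectionRate:
    def test_all_and_none(self):
        spec = rp.ExposureSpec.default()
        recs = _records(spec, np.ones((4, 50), bool))
        assert rp.selection_rate(recs, "ml", range(50)) == 100.0
        recs = _records(spec, np.zeros((4, 50), bool))
        assert rp.selection_rate(recs, "ml", range(50)) == 0.0

    def test_partial_count(self):
        spec = rp.ExposureSpec.default()
        sel = np.zeros((100, 50), bool)
        sel[:54, 25] = True  # 54 of 100 replicates select x26
        recs = _records(spec, sel)
        assert rp.selection_rate(recs, "ml", [25]) == pytest.approx(54.0)

    def test_unknown_method_or_variable_errors(self):
        spec = rp.ExposureSpec.default()
        recs = _records(spec, np.zeros((2, 50), bool))
        with pytest.raises(KeyError):
            rp.selection_rate(recs, "nope", [0])
        with pytest.raises(KeyError):
            rp.selection_rate(recs, "ml", [99])


class TestPrevalenceGroups:
    def test_partition_into_five_groups_of_nine(self):
        spec = rp.ExposureSpec.default()
        groups = prevalence_groups(spec)
        assert len(groups) == 5
        allidx = np.concatenate([idx for _, idx in groups])
        assert len(allidx) == 45
        assert set(allidx.tolist()) == set(spec.irrelevant_indices.tolist())
        assert all(len(idx) == 9 for _, idx in groups)

    def test_group_boundaries_match_the_log_grid(self):
        spec = rp.ExposureSpec.default()
        groups = prevalence_groups(spec)
        # most prevalent group is x2..x10 (0.9%-3%); rarest is x41..x49
        assert groups[-1][1].tolist() == list(range(1, 10))
        assert groups[0][1].tolist() == list(range(40, 49))

    def test_indivisible_count_rejected(self):
        spec = rp.ExposureSpec(rp.make_prevalence_grid(12, 0.3, 0.01),
                               (0, 11), (-1, 1))
        with pytest.raises(ValueError):
            prevalence_groups(spec, n_groups=4)


class TestSummaryTables:
    def _full_records(self, n_reps=6, seed=0):
        spec = rp.ExposureSpec.default()
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n_reps):
            rec = rp.ReplicateRecord(replicate_id=i, truth=spec)
            for m in ("ml", "lasso"):
                coefs = rng.normal(scale=0.5, size=50)
                sel = rng.random(50) < 0.4
                rec.fits[m] = _fit(50, coefs=coefs, selected=sel, method=m)
            recs.append(rec)
        return spec, recs

    def test_shapes_and_ranges(self):
        spec, recs = self._full_records()
        t = rp.build_summary_tables(recs)
        assert t.selection_relevant.shape == (2, 5)
        assert t.selection_irrelevant.shape == (2, 5)
        assert t.mean_bias.shape == (2, 50)
        assert ((t.selection_relevant.values >= 0)
                & (t.selection_relevant.values <= 100)).all()

    def test_mse_at_least_squared_bias(self):
        spec, recs = self._full_records(seed=3)
        t = rp.build_summary_tables(recs)
        assert np.all(t.mse.values >= t.mean_bias.values ** 2 - 1e-12)

    def test_never_selecting_method_has_zero_rates(self):
        spec = rp.ExposureSpec.default()
        recs = _records(spec, np.zeros((3, 50), bool))
        t = rp.build_summary_tables(recs)
        assert (t.selection_relevant.values == 0).all()
        assert (t.selection_irrelevant.values == 0).all()

    def test_incomplete_replicates_rejected_with_cells(self):
        spec, recs = self._full_records()
        del recs[2].fits["lasso"]
        with pytest.raises(ValueError, match="missing"):
            rp.build_summary_tables(recs)
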