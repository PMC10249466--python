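import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmrnet import (
    DoseResponseSeries,
    VariableGroup,
    align_dataset,
    derive_response_features,
    derive_response_group,
)
from tmrnet.exceptions import (
    AlignmentError,
    InsufficientDataError,
    ValidationError,
)
from .conftest import make_group


class TestAlignment:
    def test_identical_sample_sets_keep_all_samples(self):
        a = make_group("a", "measured", np.arange(6).reshape(3, 2), ["m2", "m1", "m3"])
        b = make_group("b", "measured", np.arange(9).reshape(3, 3), ["m1", "m3", "m2"])
        ds = align_dataset([a, b])
        assert ds.sample_index == ["m1", "m2", "m3"]
        for g in ds.groups:
            assert g.samples == ["m1", "m2", "m3"]

    def test_partial_overlap_keeps_intersection(self):
        a = make_group("a", "measured", np.arange(6).reshape(3, 2), ["m1", "m2", "m3"])
        b = make_group("b", "measured", np.arange(6).reshape(3, 2), ["m2", "m3", "m4"])
        ds = align_dataset([a, b])
        assert ds.sample_index == ["m2", "m3"]

    def test_permuted_groups_align_to_identical_row_order(self, rng):
        universe = [f"s{i:02d}" for i in range(30)]
        groups = []
        for k in range(5):
            perm = rng.permutation(30)
            samples = [universe[i] for i in perm]
            groups.append(
                make_group(f"g{k}", "measured", rng.normal(size=(30, 3)), samples)
            )
        ds = align_dataset(groups)
        # oracle: direct per-sample lookup into the original tables
        for g_orig, g_al in zip(groups, ds.groups):
            for s in ds.sample_index:
                np.testing.assert_array_equal(
                    g_al.data.loc[s].to_numpy(), g_orig.data.loc[s].to_numpy()
                )
        orders = [g.samples for g in ds.groups]
        assert all(o == orders[0] for o in orders)

    def test_alignment_is_idempotent(self, rng):
        a = make_group("a", "measured", rng.normal(size=(4, 2)), ["m1", "m2", "m3", "m4"])
        b = make_group("b", "measured", rng.normal(size=(3, 2)), ["m2", "m4", "m1"])
        once = align_dataset([a, b])
        twice = align_dataset(once.groups)
        assert twice.sample_index == once.sample_index
        for g1, g2 in zip(once.groups, twice.groups):
            pd.testing.assert_frame_equal(g1.data, g2.data)

    def test_disjoint_groups_named_in_error(self):
        a = make_group("first", "measured", np.zeros((2, 1)), ["m1", "m2"])
        b = make_group("second", "measured", np.zeros((2, 1)), ["m3", "m4"])
        with pytest.raises(AlignmentError, match="first.*second"):
            align_dataset([a, b])

    def test_duplicate_group_names_rejected(self):
        a = make_group("dup", "measured", np.zeros((2, 1)), ["m1", "m2"])
        b = make_group("dup", "measured", np.zeros((2, 1)), ["m1", "m2"])
        with pytest.raises(ValidationError, match="dup"):
            align_dataset([a, b])

    def test_missing_values_drop_samples_before_intersection(self):
        a = make_group("a", "measured", [[1.0, 2.0], [np.nan, 3.0], [4.0, 5.0]],
                       ["m1", "m2", "m3"])
        b = make_group("b", "measured", np.ones((3, 1)), ["m1", "m2", "m3"])
        ds = align_dataset([a, b])
        assert ds.sample_index == ["m1", "m3"]


class TestVariableGroup:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValidationError):
            make_group("a", "measured", np.zeros((2, 1)), ["m1", "m1"])

    def test_bad_role_rejected(self):
        with pytest.raises(ValidationError):
            make_group("a", "covariate", np.zeros((2, 1)))


class TestDoseResponseFeatures:
    def test_exact_line(self):
        series = DoseResponseSeries([0, 10, 20], [3, 5, 7], "H")
        baseline, slope = derive_response_features(series)
        assert baseline == pytest.approx(3.0)
        assert slope == pytest.approx(0.2)

    def test_flat_series_has_zero_slope(self):
        series = DoseResponseSeries([0, 1, 2, 3], [4, 4, 4, 4], "G")
        _, slope = derive_response_features(series)
        assert slope == pytest.approx(0.0, abs=1e-14)

    def test_noisy_slope_matches_normal_equations(self, rng):
        doses = np.array([0, 3.125, 12.5, 25, 50.0])
        resp = 2.0 + 0.3 * doses + rng.normal(size=5)
        _, slope = derive_response_features(DoseResponseSeries(doses, resp, "Ers"))
        # closed-form normal-equations oracle
        a = np.array([[len(doses), doses.sum()], [doses.sum(), (doses**2).sum()]])
        rhs = np.array([resp.sum(), doses @ resp])
        slope_oracle = np.linalg.solve(a, rhs)[1]
        assert slope == pytest.approx(slope_oracle, abs=1e-10)

    @given(a=st.floats(-5, 5), b=st.floats(-2, 2))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_series_recovered_exactly(self, a, b):
        doses = np.array([0, 3.125, 12.5, 25, 50.0])
        series = DoseResponseSeries(doses, a + b * doses, "H")
        baseline, slope = derive_response_features(series)
        assert baseline == pytest.approx(a, abs=1e-9)
        assert slope == pytest.approx(b, abs=1e-9)

    def test_log_dose_scale_drops_zero_dose(self):
        doses = np.array([0.0, 1.0, 10.0, 100.0])
        resp = 1.0 + 2.0 * np.log(np.maximum(doses, 1e-300))
        resp[0] = 5.0  # baseline value at dose 0 is independent of the fit
        baseline, slope = derive_response_features(
            DoseResponseSeries(doses, resp, "Rn"), dose_scale="log"
        )
        assert baseline == pytest.approx(5.0)
        assert slope == pytest.approx(2.0, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            derive_response_features(DoseResponseSeries([0.0], [1.0], "H"))

    def test_non_finite_response_rejected(self):
        with pytest.raises(ValidationError):
            derive_response_features(DoseResponseSeries([0, 1], [1.0, np.nan], "H"))

    def test_doses_must_increase(self):
        with pytest.raises(ValidationError):
            DoseResponseSeries([0, 0, 1], [1, 2, 3], "H")


class TestDeriveResponseGroup:
    def test_series_columns_become_baseline_and_slope(self):
        doses = [0.0, 3.125, 12.5, 25.0, 50.0]
        data = {f"H@{d:g}": [10 + 0.5 * d, 12 + 0.25 * d] for d in doses}
        group = VariableGroup(
            "lung_function", "response",
            pd.DataFrame(data, index=["m1", "m2"]), {"dose_response": True},
        )
        derived = derive_response_group(group)
        assert derived.variables == ["H_baseline", "H_slope"]
        np.testing.assert_allclose(derived.data["H_baseline"], [10, 12])
        np.testing.assert_allclose(derived.data["H_slope"], [0.5, 0.25], atol=1e-12)
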