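import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmrnet import alr_transform, select_top_taxa, to_relative_abundance
from tmrnet.exceptions import DegenerateDataError, ParameterError, ValidationError
from .conftest import make_group


def taxa_group(values, variables=None, units=None):
    g = make_group("16S", "measured", values, variables=variables,
                   meta={"compositional": True})
    if units:
        g.meta["units"] = units
    return g


class TestRelativeAbundance:
    def test_direct_division(self):
        rel = to_relative_abundance(taxa_group([[5, 5, 10]]))
        np.testing.assert_allclose(rel.values[0], [0.25, 0.25, 0.5])

    def test_single_taxon_normalizes_to_unity(self):
        rel = to_relative_abundance(taxa_group([[7.0]]))
        assert rel.values[0, 0] == pytest.approx(1.0)

    def test_rows_sum_to_one_seeded(self, rng):
        counts = rng.integers(0, 500, size=(6, 8)).astype(float) + 1
        rel = to_relative_abundance(taxa_group(counts))
        # oracle: explicit per-row division
        for i in range(6):
            np.testing.assert_allclose(rel.values[i], counts[i] / counts[i].sum(),
                                       atol=1e-12)
        np.testing.assert_allclose(rel.values.sum(axis=1), 1.0, atol=1e-12)

    def test_idempotent(self, rng):
        counts = rng.integers(1, 100, size=(4, 5)).astype(float)
        once = to_relative_abundance(taxa_group(counts))
        twice = to_relative_abundance(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-15)

    def test_all_zero_row_names_sample(self):
        g = taxa_group([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(DegenerateDataError, match="m2"):
            to_relative_abundance(g)

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            to_relative_abundance(taxa_group([[1.0, -0.5]]))


class TestTopTaxa:
    def test_n_at_least_taxa_is_identity_plus_zero_remainder(self, rng):
        rel = to_relative_abundance(taxa_group(rng.random((3, 4)) + 0.1))
        out = select_top_taxa(rel, n=10)
        assert out.variables[:-1] == rel.variables
        assert out.variables[-1] == "Remainder"
        np.testing.assert_allclose(out.data["Remainder"], 0.0)

    def test_hand_ranked_selection(self):
        rel = taxa_group(
            [[0.4, 0.3, 0.2, 0.1]] * 3, variables=["t1", "t2", "t3", "t4"],
            units="relative_abundance",
        )
        out = select_top_taxa(rel, n=2)
        assert out.variables == ["t1", "t2", "Remainder"]
        np.testing.assert_allclose(out.data["Remainder"], 0.3)

    def test_selection_matches_exhaustive_ranking(self, rng):
        rel = to_relative_abundance(taxa_group(rng.random((8, 12)) + 0.01))
        out = select_top_taxa(rel, n=10)
        means = rel.data.mean().sort_values(ascending=False)
        expected = set(means.index[:10])
        assert set(out.variables) - {"Remainder"} == expected

    def test_per_sample_totals_preserved(self, rng):
        rel = to_relative_abundance(taxa_group(rng.random((5, 9)) + 0.01))
        out = select_top_taxa(rel, n=4)
        np.testing.assert_allclose(out.values.sum(axis=1), rel.values.sum(axis=1),
                                   atol=1e-12)

    def test_invalid_n_rejected(self, rng):
        rel = to_relative_abundance(taxa_group(rng.random((3, 4)) + 0.1))
        with pytest.raises(ParameterError):
            select_top_taxa(rel, n=0)


class TestALR:
    def test_uniform_row_is_zero(self):
        g = taxa_group([[0.25, 0.25, 0.25, 0.25]], units="relative_abundance")
        out = alr_transform(g, reference="v4", pseudocount=0.0)
        np.testing.assert_allclose(out.values[0], [0.0, 0.0, 0.0], atol=1e-15)

    def test_two_to_one_ratio(self):
        g = taxa_group([[0.5, 0.25, 0.25]], units="relative_abundance")
        out = alr_transform(g, reference="v3", pseudocount=0.0)
        np.testing.assert_allclose(out.values[0], [np.log(2), 0.0], atol=1e-12)

    def test_matches_elementwise_formula_with_zeros(self, rng):
        vals = rng.random((6, 5))
        vals[vals < 0.2] = 0.0
        vals[:, -1] += 0.3  # keep reference positive-ish (pseudocount covers zeros anyway)
        g = taxa_group(vals, units="relative_abundance")
        pc = 1e-6
        out = alr_transform(g, reference="v5", pseudocount=pc)
        expected = np.log(vals[:, :4] + pc) - np.log(vals[:, [4]] + pc)
        assert np.all(np.isfinite(out.values))
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_matches_reference_library(self, rng):
        from skbio.stats.composition import alr as skbio_alr

        comp = rng.dirichlet(np.ones(5), size=6)
        g = taxa_group(comp, variables=list("abcde"), units="relative_abundance")
        out = alr_transform(g, reference="e", pseudocount=0.0)
        np.testing.assert_allclose(out.values, skbio_alr(comp, 4), atol=1e-12)

    def test_output_drops_reference_column(self, rng):
        g = taxa_group(rng.random((4, 6)) + 0.05, units="relative_abundance")
        out = alr_transform(g, reference="v2")
        assert "v2" not in out.variables
        assert out.n_variables == 5
        assert out.meta["alr_reference"] == "v2"

    def test_default_reference_is_remainder_when_present(self, rng):
        rel = to_relative_abundance(taxa_group(rng.random((5, 8)) + 0.01))
        top = select_top_taxa(rel, n=4)
        out = alr_transform(top)
        assert out.meta["alr_reference"] == "Remainder"

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance_at_zero_pseudocount(self, c):
        row = np.array([[0.2, 0.3, 0.1, 0.4]])
        base = alr_transform(taxa_group(row, units="relative_abundance"),
                             reference="v4", pseudocount=0.0)
        scaled = alr_transform(taxa_group(c * row, units="relative_abundance"),
                               reference="v4", pseudocount=0.0)
        np.testing.assert_allclose(base.values, scaled.values, atol=1e-9)

    def test_unknown_reference_rejected(self, rng):
        g = taxa_group(rng.random((3, 4)) + 0.1, units="relative_abundance")
        with pytest.raises(ParameterError, match="nope"):
            alr_transform(g, reference="nope")

    def test_zero_pseudocount_requires_positive_table(self):
        g = taxa_group([[0.0, 0.5, 0.5]], units="relative_abundance")
        with pytest.raises(ParameterError):
            alr_transform(g, reference="v3", pseudocount=0.0)
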