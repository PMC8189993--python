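"""Divergence transform, eigendecomposition, polar summaries, group tests."""

import numpy as np
import pandas as pd
import pytest

import chelamorph as cm
from chelamorph.ordination import (
    DivergenceMatrix, _compass, polar_table,
)


class TestLbfTransform:
    def test_identical_distributions_give_zero(self):
        assert cm.lbf(185.87, 185.87, 10.93, 185.87, 10.93) == 0.0

    def test_value_at_species_mean(self):
        """At its own species mean, far from the reference, the divergence is
        dominated by the reference distance term (frozen hand computation)."""
        v = cm.lbf(185.87, 185.87, 10.93, 216.42, 2.995)
        assert v == pytest.approx(-50.73, abs=0.01)

    def test_value_at_reference_mean(self):
        v = cm.lbf(216.42, 185.87, 10.93, 216.42, 2.995)
        assert v == pytest.approx(5.20, abs=0.01)

    def test_zero_sd_is_an_error(self):
        with pytest.raises(ValueError):
            cm.lbf(1.0, 1.0, 0.0, 1.0, 1.0)

    def test_zero_whenever_parameters_coincide(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mu, sd, x = rng.uniform(10, 300), rng.uniform(0.5, 30), rng.uniform(10, 300)
            assert cm.lbf(x, mu, sd, mu, sd) == pytest.approx(0.0, abs=1e-12)


class TestDivergenceMatrix:
    def test_reference_rows_are_exactly_zero_before_standardisation(
            self, reference, cohort):
        typ_ind, trow = cm.build_typical_reference(cohort)
        full = pd.concat([cohort, typ_ind], ignore_index=True)
        summ = pd.concat([cm.summarize_cohort(cohort), trow.to_frame().T],
                         ignore_index=True)
        mat = cm.build_divergence_matrix(full, summ)
        ref_rows = mat.raw_lbf[(mat.row_species == "Typical").to_numpy()]
        assert np.allclose(ref_rows.to_numpy(), 0.0)

    def test_shape_contract(self, reference, cohort):
        typ_ind, trow = cm.build_typical_reference(cohort)
        full = pd.concat([cohort, typ_ind], ignore_index=True)
        summ = pd.concat([cm.summarize_cohort(cohort), trow.to_frame().T],
                         ignore_index=True)
        mat = cm.build_divergence_matrix(full, summ)
        assert mat.data.shape == (48 * 20, 6 + 48)
        assert len(mat.indicator_cols) == 48
        no_ind = cm.build_divergence_matrix(full, summ, with_indicators=False)
        assert no_ind.data.shape == (48 * 20, 6)

    def test_species_far_below_reference_codes_negative(self, reference):
        """When a species mean is many reference-SDs from the typical mean,
        the distance term dominates and its lbf column mean is negative."""
        sub = reference[reference.species_code.isin(["KL", "Typical"])]
        cohort = cm.simulate_cohort(cm.CohortSpec(summaries=sub, seed=5))
        mat = cm.build_divergence_matrix(cohort, sub, with_indicators=False)
        assert mat.raw_lbf.lbf_IL.mean() < 0

    def test_standardised_columns(self, ordination_model, reference, cohort):
        typ_ind, trow = cm.build_typical_reference(cohort)
        full = pd.concat([cohort, typ_ind], ignore_index=True)
        summ = pd.concat([cm.summarize_cohort(cohort), trow.to_frame().T],
                         ignore_index=True)
        mat = cm.build_divergence_matrix(full, summ)
        assert np.allclose(mat.data.mean(), 0, atol=1e-10)
        assert np.allclose(mat.data.std(ddof=1), 1, atol=1e-10)


def _toy_matrix(data: pd.DataFrame) -> DivergenceMatrix:
    means = data.mean()
    sds = data.std(ddof=1)
    std = (data - means) / sds
    return DivergenceMatrix(
        data=std, raw_lbf=data,
        row_species=pd.Series(["X"] * len(data)),
        measure_cols=list(data.columns), indicator_cols=[],
        col_means=means, col_sds=sds)


class TestDecompose:
    def test_independent_columns_give_unit_eigenvalues(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.standard_normal((4000, 4)),
                            columns=["lbf_IL", "lbf_L2M", "lbf_CHI", "lbf_CLI"])
        model = cm.decompose(_toy_matrix(data))
        assert np.allclose(model.eigenvalues, 1.0, atol=0.2)
        assert model.eigenvalues.sum() == pytest.approx(4.0, abs=1e-9)

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        data = pd.DataFrame({"lbf_IL": x, "lbf_CLI": 2 * x + 3})
        model = cm.decompose(_toy_matrix(data))
        assert model.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-9)

    def test_eigenvalue_sum_equals_trace(self, ordination_model):
        assert ordination_model.eigenvalues.sum() == pytest.approx(54, rel=1e-9)
        assert (ordination_model.eigenvalues >= 0).all()
        assert (np.diff(ordination_model.eigenvalues) <= 1e-9).all()

    def test_component1_loadings_share_sign_with_strong_chelal_weights(
            self, ordination_model):
        l1 = ordination_model.loadings.PC1[ordination_model.measure_cols]
        assert (np.sign(l1) == np.sign(l1.iloc[0])).all()
        chelal = l1.drop("lbf_IL").abs()
        assert (chelal > abs(l1["lbf_IL"])).all()

    def test_component2_contrasts_size_against_heights(self, ordination_model):
        l2 = ordination_model.loadings.PC2
        assert l2["lbf_IL"] <= 0
        assert l2["lbf_L1U"] > 0

    def test_row_permutation_invariance(self, reference, cohort):
        typ_ind, trow = cm.build_typical_reference(cohort)
        full = pd.concat([cohort, typ_ind], ignore_index=True)
        summ = pd.concat([cm.summarize_cohort(cohort), trow.to_frame().T],
                         ignore_index=True)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(full))
        m1 = cm.decompose(cm.build_divergence_matrix(full, summ))
        m2 = cm.decompose(cm.build_divergence_matrix(
            full.iloc[perm].reset_index(drop=True), summ))
        assert np.allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-9)
        # compare only the leading, well-separated components: the indicator
        # eigenvalues are nearly degenerate, so their eigenvectors are not
        # unique up to row permutation
        s1 = m1.scores.iloc[perm].reset_index(drop=True)
        for pc in ("PC1", "PC2"):
            assert np.allclose(s1[pc], m2.scores[pc], atol=1e-8)


class TestPolar:
    @pytest.mark.parametrize("s1,s2,angle", [
        (0.0, 1.0, 0.0),     # North
        (1.0, 0.0, 90.0),    # East
        (0.0, -1.0, 180.0),  # South
        (-1.0, 0.0, 270.0),  # West
    ])
    def test_compass_convention(self, s1, s2, angle):
        assert _compass(s1, s2) == pytest.approx(angle)

    def test_typical_sits_at_the_origin(self, ordination_model):
        p = cm.polar_summary(ordination_model, "Typical")
        assert p.distance == pytest.approx(0.0, abs=1e-9)
        assert not p.angle_defined
        pt = polar_table(ordination_model).set_index("species_code")
        assert pt.distance.idxmin() == "Typical"
        assert pt.loc["Typical", "distance"] < 0.1 * pt.drop("Typical").distance.median()

    def test_unknown_species_is_an_error(self, ordination_model):
        with pytest.raises(KeyError):
            cm.polar_summary(ordination_model, "nope")


class TestGroupContrast:
    def test_identical_groups_by_relabelling_are_null(self, ordination_model,
                                                      metadata):
        """Two groups whose polar points are identical multisets: distance
        p = 1 and angle randomization p ~ 1."""
        scores = ordination_model.scores
        dup = scores[scores.species_code.isin(["Ca4", "KL", "D5", "R1"])].copy()
        dup["species_code"] = dup.species_code + "_twin"
        twin_scores = pd.concat([scores, dup], ignore_index=True)
        from chelamorph.ordination import OrdinationModel
        twin = OrdinationModel(
            eigenvalues=ordination_model.eigenvalues,
            loadings=ordination_model.loadings,
            scores=twin_scores,
            measure_cols=ordination_model.measure_cols)
        res = cm.group_contrast(twin, ["Ca4", "KL", "D5", "R1"],
                                ["Ca4_twin", "KL_twin", "D5_twin", "R1_twin"],
                                n_permutations=99, seed=0)
        assert res["distance_welch"]["p"] == pytest.approx(1.0)
        assert res["angle_mww"].p_randomization > 0.5

    def test_singleton_group_is_an_error(self, ordination_model):
        with pytest.raises(ValueError):
            cm.group_contrast(ordination_model, ["Ca4"], ["KL", "D5"])

    def test_overlapping_groups_are_an_error(self, ordination_model):
        with pytest.raises(ValueError):
            cm.group_contrast(ordination_model, ["Ca4", "KL"], ["KL", "D5"])
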