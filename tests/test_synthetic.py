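"""Generators: determinism, degenerate cases and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from ccapipe import synthetic
from ccapipe.synthetic import (
    ExpressionCohortSpec,
    IFFieldSpec,
    KnockdownPlateSpec,
    PlacementError,
    TMACohortSpec,
)


class TestTMACohort:
    def test_fixed_seed_is_bit_identical(self):
        spec = TMACohortSpec(n_tumors=20, seed=5)
        obs1, truth1 = synthetic.generate_tma_cohort(spec)
        obs2, truth2 = synthetic.generate_tma_cohort(TMACohortSpec(n_tumors=20, seed=5))
        pd.testing.assert_frame_equal(obs1, obs2)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_structure_two_cores_and_code_ranges(self):
        obs, truth = synthetic.generate_tma_cohort(TMACohortSpec(n_tumors=30, seed=1))
        sizes = obs.groupby(["tumor_id", "marker", "compartment"]).size()
        assert (sizes == 2).all()
        assert obs["quantity"].isin(range(5)).all()
        assert obs["intensity"].isin(range(4)).all()

    def test_zero_positivity_gives_all_negative(self):
        spec = TMACohortSpec(
            n_tumors=25,
            marker_compartment_positivity={("YAP", "nuclear"): 0.0, ("TAZ", "nuclear"): 0.0},
            seed=2,
        )
        obs, truth = synthetic.generate_tma_cohort(spec)
        assert (obs["quantity"] == 0).all() and (obs["intensity"] == 0).all()
        assert not truth["true_positive"].any()

    def test_full_concordance_duplicates_core_codes(self):
        spec = TMACohortSpec(n_tumors=40, core_concordance=1.0, seed=3)
        obs, _ = synthetic.generate_tma_cohort(spec)
        wide = obs.pivot(
            index=["tumor_id", "marker", "compartment"],
            columns="core_id",
            values=["quantity", "intensity"],
        )
        assert (wide[("quantity", 1)] == wide[("quantity", 2)]).all()
        assert (wide[("intensity", 1)] == wide[("intensity", 2)]).all()

    def test_positivity_rate_recovers_spec_probability(self):
        """Mean observed positive fraction over 200 seeds within 3 SE of
        the planted rate (binomial sampling oracle)."""
        p, n = 0.395, 152
        fractions = []
        for seed in range(200):
            spec = TMACohortSpec(
                n_tumors=n,
                marker_compartment_positivity={("YAP", "nuclear"): p},
                seed=seed,
            )
            _, truth = synthetic.generate_tma_cohort(spec)
            fractions.append(truth["true_positive"].mean())
        se = np.sqrt(p * (1 - p) / (n * 200))
        assert abs(np.mean(fractions) - p) < 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            TMACohortSpec(marker_compartment_positivity={("YAP", "nuclear"): 1.2})
        with pytest.raises(ValueError):
            TMACohortSpec(grade_probs={"G1": 0.5, "G2": 0.4})


class TestIFField:
    def test_equal_intensities_give_unit_true_ratio(self):
        spec = IFFieldSpec(noise_sd=0.0, nuclear_intensity=150, cytoplasmic_intensity=150, seed=1)
        field = synthetic.generate_if_field(spec)
        assert field.true_ratio == 1.0

    def test_noiseless_mask_means_are_exact(self, noiseless_field):
        stain = noiseless_field.channels[1]
        mean_nuc = stain[noiseless_field.nuclear_mask].mean()
        mean_cyt = stain[noiseless_field.cytoplasm_mask].mean()
        assert mean_nuc / mean_cyt == pytest.approx(2.0)
        assert noiseless_field.true_ratio == 2.0

    def test_masks_disjoint(self, noiseless_field):
        assert not (noiseless_field.nuclear_mask & noiseless_field.cytoplasm_mask).any()

    def test_empty_field(self):
        field = synthetic.generate_if_field(IFFieldSpec(n_cells=0, seed=0))
        assert not field.nuclear_mask.any() and not field.cytoplasm_mask.any()
        assert field.n_cells == 0

    def test_infeasible_density_raises_placement_error(self):
        spec = IFFieldSpec(width=64, height=64, n_cells=50, max_attempts_per_cell=20, seed=0)
        with pytest.raises(PlacementError, match="dense"):
            synthetic.generate_if_field(spec)

    def test_fixed_seed_is_bit_identical(self):
        f1 = synthetic.generate_if_field(IFFieldSpec(seed=9))
        f2 = synthetic.generate_if_field(IFFieldSpec(seed=9))
        np.testing.assert_array_equal(f1.channels, f2.channels)

    def test_geometry_constraint_enforced(self):
        with pytest.raises(ValueError):
            IFFieldSpec(nucleus_radius=(6, 12), cell_radius=(10, 11))


class TestExpressionCohort:
    def test_planted_cluster_size_matches_fraction(self, small_expression_cohort):
        spec, matrix, annotations, survival = small_expression_cohort
        assert annotations["planted_cin"].sum() == round(spec.cin_fraction * spec.n_tumors)

    def test_default_spec_plants_26_of_104(self):
        spec = ExpressionCohortSpec()
        assert round(spec.cin_fraction * spec.n_tumors) == 26

    def test_signature_genes_shifted_in_planted_cluster(self, small_expression_cohort):
        spec, matrix, annotations, _ = small_expression_cohort
        cpm = matrix / matrix.sum(axis=0) * 1e6
        log2cpm = np.log2(cpm + 1)
        cin = annotations.loc[annotations["planted_cin"], "sample_id"]
        rest = annotations.loc[~annotations["planted_cin"], "sample_id"]
        shift = log2cpm[cin].mean(axis=1) - log2cpm[rest].mean(axis=1)
        sig = list(spec.signature)
        bg = [g for g in matrix.index if g not in spec.signature]
        # CPM is compositional: the library-size term cancels in the
        # signature-vs-background contrast, which recovers the planted effect
        contrast = shift[sig].mean() - shift[bg].mean()
        assert contrast == pytest.approx(spec.effect_log2fc, rel=0.1)

    def test_survival_records_complete_and_censored(self, small_expression_cohort):
        spec, _, _, survival = small_expression_cohort
        assert len(survival) == spec.n_tumors
        assert (survival["time"] <= spec.censor_time).all()
        assert (survival["time"] > 0).all()

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ExpressionCohortSpec(signature=())

    def test_signature_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            ExpressionCohortSpec(genes=("A", "B"), signature=("C",))

    def test_fixed_seed_is_bit_identical(self):
        spec = ExpressionCohortSpec(n_tumors=10, n_normals=2, seed=4)
        m1, a1, s1 = synthetic.generate_expression_cohort(spec)
        m2, a2, s2 = synthetic.generate_expression_cohort(spec)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(s1, s2)


class TestKnockdownPlate:
    def test_quarter_fraction_raises_ct_by_two_cycles(self):
        spec = KnockdownPlateSpec(
            target_genes=("YAP",),
            knockdown_fraction={("YAP", "scrambled"): 1.0, ("YAP", "siYAP"): 0.25},
            conditions=("scrambled", "siYAP"),
            ct_noise_sd=0.0,
            seed=0,
        )
        plate = synthetic.generate_knockdown_plate(spec)
        ct = plate.groupby(["condition", "gene"])["ct"].mean()
        assert ct[("siYAP", "YAP")] - ct[("scrambled", "YAP")] == pytest.approx(2.0)

    def test_reference_gene_condition_independent_at_zero_noise(self):
        spec = KnockdownPlateSpec(ct_noise_sd=0.0, seed=0)
        plate = synthetic.generate_knockdown_plate(spec)
        ref = plate[plate["gene"] == spec.reference_gene]
        assert ref["ct"].nunique() == 1

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="residual fraction"):
            KnockdownPlateSpec(knockdown_fraction={("YAP", "siYAP"): 0.0})

    def test_scrambled_fraction_must_be_one(self):
        with pytest.raises(ValueError, match="scrambled"):
            KnockdownPlateSpec(knockdown_fraction={("YAP", "scrambled"): 0.5})

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate_n"):
            KnockdownPlateSpec(replicate_n=1)


class TestDensityCohort:
    def test_shape_and_determinism(self):
        df1 = synthetic.generate_density_cohort(n_fields=50, seed=8)
        df2 = synthetic.generate_density_cohort(n_fields=50, seed=8)
        pd.testing.assert_frame_equal(df1, df2)
        assert len(df1) == 50 and (df1["nc_ratio"] > 0).all()

    def test_planted_negative_trend(self):
        df = synthetic.generate_density_cohort(n_fields=400, noise_sd=0.05, seed=1)
        assert np.corrcoef(df["nucleus_count"], df["nc_ratio"])[0, 1] < -0.9
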