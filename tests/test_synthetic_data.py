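import numpy as np
import pytest

from esm_abeta.connectome import bilateral_pairs
from esm_abeta.positivity import CompositeDefinition, composite_value
from esm_abeta.regional_probability import build_evd, roi_probabilities
from esm_abeta.synthetic_data import (
    DKT_BASE_NAMES,
    make_synthetic_connectome,
    simulate_cohort,
    simulate_controls,
    simulate_longitudinal,
    simulate_pet_image,
)


class TestSyntheticConnectome:
    def test_default_atlas_contract(self, dkt_connectome):
        C = dkt_connectome
        assert C.n_regions == 78
        assert len(bilateral_pairs(C.region_labels)) == 39
        assert np.allclose(C.weights, C.weights.T)
        assert np.all(np.diag(C.weights) == 0)
        assert C.weights.min() >= 0 and C.weights.max() <= 1

    def test_mirror_symmetry(self, dkt_connectome):
        w = dkt_connectome.weights
        half = 39
        assert np.allclose(w[:half, :half], w[half:, half:])
        assert np.allclose(w[:half, half:], w[half:, :half].T)

    def test_same_seed_identical(self):
        a = make_synthetic_connectome(seed=3)
        b = make_synthetic_connectome(seed=3)
        assert np.array_equal(a.weights, b.weights)

    def test_distance_decay_shapes_weights(self, dkt_connectome):
        # nearby homotopic midline pairs connect more strongly than the
        # overall average of present edges
        w = dkt_connectome.weights
        i = dkt_connectome.index_of("L_posterior_cingulate")
        j = dkt_connectome.index_of("R_posterior_cingulate")
        present = w[w > 0]
        assert w[i, j] > np.median(present)

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_connectome(n_regions=7)

    def test_requested_density_approximate(self):
        C = make_synthetic_connectome(seed=0, density=0.2)
        iu = np.triu_indices(78, 1)
        got = np.mean(C.weights[iu] > 0)
        assert got == pytest.approx(0.2, abs=0.02)


class TestSimulateCohort:
    def test_outputs_schema_and_truth_alignment(self, noisy_cohort):
        patterns, covars, truth = noisy_cohort
        assert patterns.values.shape == (20, 78)
        assert patterns.values.min() >= 0 and patterns.values.max() <= 1
        assert list(covars["subject_id"]) == patterns.subject_ids
        assert list(truth.table["subject_id"]) == patterns.subject_ids
        assert set(truth.table["true_subgroup"]) <= {"DMN", "Striatum", "Other"}

    def test_same_seed_bit_identical(self, dkt_connectome):
        a = simulate_cohort(dkt_connectome, 5, seed=42)
        b = simulate_cohort(dkt_connectome, 5, seed=42)
        assert np.array_equal(a[0].values, b[0].values)
        assert a[1].equals(b[1])

    def test_empty_cohort_schema_valid(self, dkt_connectome):
        patterns, covars, truth = simulate_cohort(dkt_connectome, 0, seed=0)
        assert patterns.values.shape == (0, 78)
        assert len(covars) == 0

    def test_false_positive_class_has_nonspecific_subcortical_signal(
        self, dkt_connectome
    ):
        patterns, covars, truth = simulate_cohort(
            dkt_connectome, 10, fp_fraction=1.0, noise_sd=0.0, seed=1
        )
        labels = patterns.region_labels
        pall_thal = [i for i, l in enumerate(labels)
                     if l.endswith("pallidum") or l.endswith("thalamus")]
        cortical = [i for i, l in enumerate(labels)
                    if l.endswith("precuneus") or l.endswith("superior_frontal")]
        assert patterns.values[:, pall_thal].mean() > 0.2
        assert patterns.values[:, cortical].mean() < 0.05
        assert (truth.table["true_subgroup"] == "Other").all()

    def test_fp_cohort_fails_dual_positivity(self, dkt_connectome):
        from esm_abeta.positivity import PositivityThresholds, ThresholdMethod, classify_positivity

        patterns, covars, _ = simulate_cohort(
            dkt_connectome, 12, fp_fraction=1.0, seed=2
        )
        comp = CompositeDefinition()
        thresholds = PositivityThresholds(
            suvr_cutoff=0.81, probability_cutoff=0.05,
            method=ThresholdMethod.FIXED,
        )
        labels = patterns.region_labels
        flags = [
            classify_positivity(
                covars["composite_suvr"].iloc[i],
                composite_value(patterns.values[i], labels, comp),
                thresholds,
            )
            for i in range(12)
        ]
        assert not any(flags)

    def test_invalid_mixing_rejected(self, dkt_connectome):
        with pytest.raises(ValueError):
            simulate_cohort(dkt_connectome, 5, mixing=(0.5, 0.2, 0.1))

    def test_striatum_class_is_younger_on_average(self, dkt_connectome):
        patterns, covars, truth = simulate_cohort(
            dkt_connectome, 60, mixing=(0.5, 0.5, 0.0), seed=8,
            striatum_age_shift=10.0,
        )
        merged = covars.merge(truth.table, on="subject_id")
        dmn_age = merged.loc[merged.true_subgroup == "DMN", "age"].mean()
        str_age = merged.loc[merged.true_subgroup == "Striatum", "age"].mean()
        assert dmn_age - str_age > 3.0

    def test_mixing_proportions_recovered_at_scale(self, dkt_connectome):
        """Class draws follow the requested mixture within binomial error."""
        _, _, truth = simulate_cohort(
            dkt_connectome, 200, mixing=(0.60, 0.15, 0.25), seed=7
        )
        counts = truth.table["true_subgroup"].value_counts(normalize=True)
        assert counts["DMN"] == pytest.approx(0.60, abs=0.10)
        assert counts["Striatum"] == pytest.approx(0.15, abs=0.08)
        assert counts["Other"] == pytest.approx(0.25, abs=0.09)


class TestControls:
    def test_controls_low_cortical_elevated_pallidum_thalamus(self, dkt_connectome):
        ctl = simulate_controls(dkt_connectome, 15, seed=3)
        labels = ctl.region_labels
        pall_thal = [i for i, l in enumerate(labels)
                     if l.endswith("pallidum") or l.endswith("thalamus")]
        rest = [i for i in range(78) if i not in pall_thal]
        assert ctl.values[:, pall_thal].mean() > ctl.values[:, rest].mean() + 0.1


class TestLongitudinal:
    def test_zero_followup_reproduces_baseline(self, dkt_connectome, reduced_grid):
        patterns, covars, truth = simulate_cohort(
            dkt_connectome, 6, mixing=(0.7, 0.3, 0.0), noise_sd=0.0, seed=4,
        )
        t2 = simulate_longitudinal(
            dkt_connectome, covars, truth, followup_years=0.0,
            grid=reduced_grid, noise_sd=0.0, seed=0,
        )
        assert np.allclose(t2.values, patterns.values, atol=1e-12)

    def test_growth_without_clearance_like_dynamics(self, dkt_connectome,
                                                     reduced_grid):
        patterns, covars, truth = simulate_cohort(
            dkt_connectome, 6, mixing=(1.0, 0.0, 0.0), noise_sd=0.0, seed=4,
        )
        t2 = simulate_longitudinal(
            dkt_connectome, covars, truth, followup_years=4.0,
            grid=reduced_grid, noise_sd=0.0, seed=0,
        )
        comp = CompositeDefinition()
        labels = patterns.region_labels
        for i in range(6):
            c1 = composite_value(patterns.values[i], labels, comp)
            c2 = composite_value(t2.values[i], labels, comp)
            # production dominates clearance in the draw pools
            assert c2 >= c1 - 1e-6

    def test_scripted_transition_lands_in_expected_cell(self, dkt_connectome,
                                                        reduced_grid):
        from esm_abeta.epicentre_analysis import sweep_epicentres_cohort

        patterns, covars, truth = simulate_cohort(
            dkt_connectome, 4, mixing=(0.0, 1.0, 0.0), noise_sd=0.0, seed=5,
        )
        sid = patterns.subject_ids[0]
        t2 = simulate_longitudinal(
            dkt_connectome, covars, truth, followup_years=4.0,
            transition_script={sid: "posterior_cingulate"},
            grid=reduced_grid, noise_sd=0.0, seed=0,
        )
        a2 = sweep_epicentres_cohort(
            t2.values[:1], dkt_connectome,
            covars["age"].to_numpy()[:1] + 4.0, grid=reduced_grid,
        )
        assert a2[0].subgroup == "DMN"


class TestPetImage:
    def test_deterministic_and_labelled(self):
        a = simulate_pet_image((6, 6, 6), {1: 1.0, 2: 2.0}, seed=1)
        b = simulate_pet_image((6, 6, 6), {1: 1.0, 2: 2.0}, seed=1)
        assert np.array_equal(a.values, b.values)
        assert set(np.unique(a.voxel_labels)) <= {0, 1, 2, 99}

    def test_noiseless_means_give_step_probabilities(self):
        img = simulate_pet_image(
            (8, 8, 8), {1: 0.5, 2: 5.0}, reference_params=(1.0, 0.1),
            noise_sd=0.0, seed=2,
        )
        ref = img.region_values(99)
        evd = build_evd(ref, "max", n_boot=500, seed=0)
        probs = roi_probabilities(img, evd)
        assert probs["roi_01"] == 0.0  # below the reference band
        assert probs["roi_02"] == 1.0  # far above every extreme

    def test_reference_label_collision_rejected(self):
        with pytest.raises(ValueError):
            simulate_pet_image((4, 4, 4), {99: 1.0})
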