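"""Generator contracts: ground truth fidelity, determinism, error models."""

import numpy as np
import pandas as pd
import pytest

import adipomorph as am
from adipomorph.synthetic_data import FAGroupParams, CtGroupParams, GTTGroupSpec


class TestGenerateBatImage:
    def test_single_noiseless_disc_has_faithful_truth(self, single_disc):
        spec, image, truth, table = single_disc
        assert truth.n_labels == 1
        measured = table.loc[0, "equiv_diameter_um"]
        assert abs(measured - 20.0) <= spec.pixel_size_um
        assert image.pixels.dtype == np.uint8
        # droplets are brighter than background in the raw image
        disc = truth.labels == 1
        assert image.pixels[disc].mean() > image.pixels[~disc].mean()

    def test_seed_contract_changes_centroids_not_counts(self):
        base = dict(n_small=3, n_large=1, noise_sd=0.0)
        _, t1, tab1 = am.generate_bat_image(am.ImageSpec(seed=1, **base))
        _, t2, tab2 = am.generate_bat_image(am.ImageSpec(seed=2, **base))
        assert t1.n_labels == t2.n_labels == 4
        assert not np.allclose(tab1["center_row"], tab2["center_row"])

    def test_same_seed_is_deterministic(self):
        spec = am.ImageSpec(n_small=4, n_large=1, seed=11)
        img1, tr1, tab1 = am.generate_bat_image(spec)
        img2, tr2, tab2 = am.generate_bat_image(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(tr1.labels, tr2.labels)
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_infeasible_packing_raises_placement_error(self):
        # 150 small + 5 large droplets cannot fit a 512×512 px field at
        # 0.249 μm/px once the min-gap exclusion zones are accounted for:
        # exhaustive rejection sampling must fail.
        spec = am.ImageSpec(
            n_small=150,
            n_large=5,
            small_diam_dist=am.DiameterDist(5.0, 0.1, 4.0, 6.0),
            large_diam_dist=am.DiameterDist(30.0, 0.1, 25.0, 40.0),
            min_gap_px=8,
            max_retries=2000,
            seed=0,
        )
        with pytest.raises(am.PlacementError):
            am.generate_bat_image(spec)

    def test_truth_conservation_measured_vs_recorded_diameter(self):
        _, truth, table = am.generate_bat_image(am.ImageSpec(n_small=10, n_large=3, seed=5))
        for _, row in table.iterrows():
            area = int((truth.labels == row["label"]).sum())
            measured = 2.0 * np.sqrt(area / np.pi) * truth.pixel_size_um
            assert abs(measured - row["diameter_um"]) <= truth.pixel_size_um

    def test_truth_discs_never_overlap(self):
        _, truth, table = am.generate_bat_image(am.ImageSpec(n_small=20, n_large=4, seed=9))
        # one id per pixel is structural; total area must equal sum of parts
        assert (truth.labels > 0).sum() == table["area_px"].sum()


class TestSimulateScaleDetections:
    def test_clean_model_splits_by_size_class(self, clean_field):
        _, _, _, small, large = clean_field
        assert small.n_labels == 5
        assert large.n_labels == 2

    def test_clean_detections_reproduce_truth_footprints(self, clean_field):
        _, truth, table, small, large = clean_field
        for lm, cls in ((small, "small"), (large, "large")):
            truth_mask = np.isin(truth.labels, table.loc[table["size_class"] == cls, "label"])
            assert np.array_equal(lm.labels > 0, truth_mask)

    def test_fragmentation_emits_fragments_inside_footprint(self):
        _, truth, table = am.generate_bat_image(am.ImageSpec(n_small=0, n_large=1, seed=2))
        err = am.DetectionErrorModel(fragment_rate=1.0, fragment_k=3, seed=4)
        small, large = am.simulate_scale_detections(truth, table, err)
        assert small.n_labels == 3
        assert large.n_labels == 1
        footprint = truth.labels == 1
        assert np.all(footprint[small.labels > 0])
        assert (small.labels > 0).sum() < footprint.sum()  # strictly inside

    def test_merge_emits_single_label_covering_both(self):
        _, truth, table = am.generate_bat_image(am.ImageSpec(n_small=2, n_large=0, seed=6))
        err = am.DetectionErrorModel(merge_rate=1.0, seed=1)
        small, _ = am.simulate_scale_detections(truth, table, err)
        assert small.n_labels == 1
        assert np.array_equal(small.labels > 0, truth.labels > 0)

    def test_deterministic_given_seed(self, clean_field):
        _, truth, table, _, _ = clean_field
        err = am.DetectionErrorModel(miss_rate_small_at_small_scale=0.3, boundary_jitter_px=1, seed=8)
        a = am.simulate_scale_detections(truth, table, err)
        b = am.simulate_scale_detections(truth, table, err)
        assert np.array_equal(a[0].labels, b[0].labels)
        assert np.array_equal(a[1].labels, b[1].labels)


class TestGenerateFaTables:
    def test_noise_off_recovers_exact_group_means(self):
        params = FAGroupParams(concentration=None, effect_multipliers={}, seed=0)
        table = am.generate_fa_tables(params)
        idx = am.compute_indices(table)
        # lipogenic index = C16:0 / C18:2n-6 = 24/20 for every sample
        assert np.allclose(idx["lipogenic_index"], 24.0 / 20.0)

    def test_equal_palmitate_linoleate_means_give_unit_lipogenic_index(self):
        mean = {"C16:0": 25.0, "C18:2n-6": 25.0, "C18:1n-9": 50.0}
        params = FAGroupParams(
            groups=[("Ctrl", "NaCl", 3)], mean_mol_percent=mean,
            effect_multipliers={}, concentration=None, seed=0,
        )
        idx = am.compute_indices(am.generate_fa_tables(params))
        assert np.allclose(idx["lipogenic_index"], 1.0)

    def test_multiplier_effect_matches_hand_renormalized_means(self):
        # independently renormalize the 8-species mean vector by hand
        params = FAGroupParams(
            concentration=None,
            effect_multipliers={("KO", "CL"): {"C16:1n-7": 2.0}},
            seed=0,
        )
        base = dict(params.mean_mol_percent)
        doubled = {sp: v * (2.0 if sp == "C16:1n-7" else 1.0) for sp, v in base.items()}
        total = sum(doubled.values())
        expected = (doubled["C16:1n-7"] / total * 100) / (doubled["C16:0"] / total * 100)
        idx = am.compute_indices(am.generate_fa_tables(params))
        ko_cl = idx[(idx["group"] == "KO:CL")]
        ctrl = idx[(idx["group"] == "Ctrl:NaCl")]
        assert np.allclose(ko_cl["scd1_ratio"], expected)
        assert np.allclose(ko_cl["scd1_ratio"].mean() / ctrl["scd1_ratio"].mean(),
                           expected / (base["C16:1n-7"] / base["C16:0"]))

    def test_seed_contract_same_expectation_different_samples(self):
        p1 = FAGroupParams(concentration=50.0, seed=1)
        p2 = FAGroupParams(concentration=50.0, seed=2)
        t1, t2 = am.generate_fa_tables(p1), am.generate_fa_tables(p2)
        assert not np.allclose(t1["quantity"], t2["quantity"])
        # expectations are seed-free
        assert p1.expected_mol_percent(("Ctrl", "NaCl")) == p2.expected_mol_percent(("Ctrl", "NaCl"))

    def test_mean_vector_not_summing_to_100_raises(self):
        with pytest.raises(am.ValidationError):
            FAGroupParams(mean_mol_percent={"C16:0": 50.0, "C18:0": 49.0})


class TestCtAndGtt:
    def test_zero_shift_zero_sd_gives_exact_delta_ct(self):
        params = CtGroupParams(genes={"Ucp1": 26.0, "36B4": 18.0}, replicate_sd=0.0)
        rq = am.relative_expression(am.generate_ct_table(params), "Ucp1")
        assert np.allclose(rq["rq"], 2.0 ** -(26.0 - 18.0))

    def test_plus_one_ct_shift_halves_expression(self):
        base = CtGroupParams(genes={"Ucp1": 26.0, "36B4": 18.0}, replicate_sd=0.0)
        shifted = CtGroupParams(
            genes={"Ucp1": 26.0, "36B4": 18.0}, replicate_sd=0.0,
            group_shifts={("KO", "CL"): {"Ucp1": 1.0}},
        )
        rq0 = am.relative_expression(am.generate_ct_table(base), "Ucp1")
        rq1 = am.relative_expression(am.generate_ct_table(shifted), "Ucp1")
        merged = rq0.merge(rq1, on="sample", suffixes=("_base", "_shift"))
        ko_cl = merged["group_base"] == "KO:CL"
        assert np.allclose(merged.loc[ko_cl, "rq_shift"], merged.loc[ko_cl, "rq_base"] / 2.0)
        assert np.allclose(merged.loc[~ko_cl, "rq_shift"], merged.loc[~ko_cl, "rq_base"])

    def test_base_ct_outside_plausible_range_rejected(self):
        with pytest.raises(am.ValidationError):
            CtGroupParams(genes={"Ucp1": 45.0, "36B4": 18.0})

    def test_flat_gtt_auc_is_rectangle(self):
        gtt = am.generate_gtt([GTTGroupSpec("Ctrl", 3, mean_glucose=(100.0,) * 6, sd=0.0)], seed=0)
        auc = am.gtt_auc_table(gtt)
        assert np.allclose(auc["auc"], 100.0 * 120.0)

    def test_gtt_values_positive_and_deterministic(self):
        g = [GTTGroupSpec("KO", 5, sd=40.0)]
        t1 = am.generate_gtt(g, seed=3)
        t2 = am.generate_gtt(g, seed=3)
        assert (t1["glucose_mg_dl"] > 0).all()
        pd.testing.assert_frame_equal(t1, t2)
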