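import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from condenscan import cells, foci, simkit


def _cell_scene(cyto=2.0, bg=1.0, shape=(40, 40)):
    img = np.full(shape, bg)
    mask_img = np.zeros(shape, dtype=np.int32)
    mask_img[10:30, 10:30] = 1
    img[10:30, 10:30] = cyto
    return img, cells.CellMask(mask_img, 0.1)


class TestNormalizePixels:
    def test_linear_map(self):
        norm, deg = foci.normalize_pixels([2.0, 4.0, 6.0])
        assert not deg
        assert np.allclose(norm, [0.0, 0.5, 1.0])

    def test_constant_cell_flagged_degenerate(self):
        _, deg = foci.normalize_pixels([3.0, 3.0, 3.0])
        assert deg

    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_affine_invariance(self, a, b):
        vals = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        base, _ = foci.normalize_pixels(vals)
        scaled, _ = foci.normalize_pixels(a * vals + b)
        assert np.allclose(base, scaled, atol=1e-9)


class TestDetectFoci:
    def test_bright_round_blob_detected(self):
        img, mask = _cell_scene()
        img[14:18, 14:18] = 10.0
        out = foci.detect_foci(img, mask, foci.FocusParams(blur_sigma=0))
        assert len(out) == 1
        assert out[0].area_px >= 16

    def test_small_speck_rejected_by_min_area(self):
        img, mask = _cell_scene()
        img[15, 15] = 10.0
        img[15, 16] = 10.0
        img[16, 15] = 10.0   # 3-px speck < min_area 4
        out = foci.detect_foci(img, mask,
                               foci.FocusParams(blur_sigma=0, min_area=4))
        assert out == []

    def test_elongated_streak_rejected_by_eccentricity(self):
        img, mask = _cell_scene()
        img[15, 12:28] = 10.0
        img[16, 12:28] = 10.0   # 2×16 streak, eccentricity ≈ 0.99
        out = foci.detect_foci(img, mask,
                               foci.FocusParams(blur_sigma=0,
                                                eccentricity_max=0.75))
        assert out == []

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            foci.FocusParams(intensity_threshold=1.5)
        with pytest.raises(ValueError):
            foci.FocusParams(min_area=0)

    def test_detection_roc_on_generated_cells(self):
        """≥95% recall on cells with a focus, ≤5% false-positive cells."""
        n = 100
        pop = simkit.simulate_cell_population(
            n, rng=11, concentration_uM=40.0, focus_fraction=0.5,
            focus_excess_molecules=30000)
        hits = misses = false_pos = 0
        for stack, gt, row in zip(pop.stacks, pop.masks,
                                  pop.truth.itertuples()):
            mask = cells.CellMask(gt, pop.pixel_size)
            found = len(foci.detect_foci(stack.data, mask)) > 0
            if row.has_focus:
                hits += found
                misses += not found
            else:
                false_pos += found
        n_focus = pop.truth.has_focus.sum()
        assert hits >= 0.95 * n_focus
        assert false_pos <= 0.05 * (n - n_focus)


class TestCondensationCoefficients:
    def test_linear_ramp_exact_fractions(self):
        img, mask = _cell_scene()
        region = mask.labels == 1
        # 400 px linear ramp: fraction strictly below q is exactly q
        img[region] = 1.0 + np.arange(400) / 399.0
        table = foci.condensation_coefficients(img, mask)
        assert table.loc[0, "frac_below_0.3"] == pytest.approx(0.30, abs=0.0026)
        assert table.loc[0, "frac_below_0.5"] == pytest.approx(0.50, abs=0.0026)
        assert table.loc[0, "frac_below_0.7"] == pytest.approx(0.70, abs=0.0026)

    def test_single_bright_pixel_delta_case(self):
        img, mask = _cell_scene()
        img[15, 15] = 100.0
        table = foci.condensation_coefficients(img, mask)
        n = int(table.loc[0, "n_pixels"])
        assert table.loc[0, "frac_below_0.3"] == pytest.approx((n - 1) / n)

    def test_fractions_monotone_in_threshold(self, rng):
        img, mask = _cell_scene()
        region = mask.labels == 1
        img[region] = rng.gamma(2.0, 3.0, region.sum())
        t = foci.condensation_coefficients(img, mask)
        assert t.loc[0, "frac_below_0.3"] <= t.loc[0, "frac_below_0.5"] \
            <= t.loc[0, "frac_below_0.7"]

    def test_control_self_normalization_is_unity(self):
        tables = []
        for seed in range(6):
            img, mask = _cell_scene()
            region = mask.labels == 1
            img[region] = np.random.default_rng(seed).normal(10, 2, region.sum())
            tables.append(foci.condensation_coefficients(img, mask))
        control = pd.concat(tables, ignore_index=True)
        rel = foci.condensation_coefficients(img, mask,
                                             control_fractions=control)
        # a control cell evaluated against the pooled control stays near 1
        assert rel["relative_0.5"].iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_degenerate_cell_excluded(self):
        img, mask = _cell_scene()
        table = foci.condensation_coefficients(img, mask)
        assert len(table) == 0  # constant cell (all pixels equal) dropped


class TestPartitionRatio:
    def test_block_arithmetic_oracle(self):
        img, mask = _cell_scene(cyto=2.0, bg=1.0)
        img[14:18, 14:18] = 10.0
        f = foci.detect_foci(img, mask, foci.FocusParams(blur_sigma=0))
        r = foci.partition_ratio(img, mask, 1, f, background=1.0)
        assert r == pytest.approx(9.0)

    def test_no_enrichment_gives_unity(self):
        img, mask = _cell_scene(cyto=5.0, bg=1.0)
        fake = [foci.Focus(cell_label=1, centroid_px=(15, 15), area_px=16,
                           eccentricity=0.0, mean_intensity=4.0,
                           total_intensity=64.0,
                           pixels=np.array([[r, c] for r in range(14, 18)
                                            for c in range(14, 18)]))]
        r = foci.partition_ratio(img, mask, 1, fake, background=1.0)
        assert r == pytest.approx(1.0)

    def test_multi_focus_average_rule(self):
        """Two foci with bg-corrected means 9 and 5 over cytoplasm 1 → 7."""
        img, mask = _cell_scene(cyto=2.0, bg=1.0)
        img[12:15, 12:15] = 10.0
        img[22:25, 22:25] = 6.0
        f = foci.detect_foci(img, mask, foci.FocusParams(
            blur_sigma=0, intensity_threshold=0.4))
        assert len(f) == 2
        r = foci.partition_ratio(img, mask, 1, f, background=1.0)
        assert r == pytest.approx(7.0)

    def test_no_focus_returns_none(self):
        img, mask = _cell_scene()
        assert foci.partition_ratio(img, mask, 1, []) is None


class TestPercentWithFocus:
    def test_counting(self):
        pop = simkit.simulate_cell_population(
            10, rng=5, concentration_uM=40.0, focus_fraction=0.0)
        imgs = [s.data for s in pop.stacks]
        masks = [cells.CellMask(m, pop.pixel_size) for m in pop.masks]
        t = foci.percent_with_focus(imgs, masks)
        assert (t["percent"] == 0.0).all()

    def test_zero_cells_is_error(self):
        img = np.zeros((20, 20))
        mask = cells.CellMask(np.zeros((20, 20), dtype=np.int32), 0.1)
        with pytest.raises(ValueError):
            foci.percent_with_focus([img], [mask])

    def test_titration_series_monotone(self):
        percents = []
        for i, p in enumerate([0.0, 0.4, 0.8]):
            pop = simkit.simulate_cell_population(
                40, rng=20 + i, concentration_uM=40.0, focus_fraction=p,
                focus_excess_molecules=30000)
            masks = [cells.CellMask(m, pop.pixel_size) for m in pop.masks]
            t = foci.percent_with_focus([s.data for s in pop.stacks], masks)
            total = t.n_with_focus.sum()
            percents.append(100 * total / t.n_cells.sum())
        assert percents[0] <= percents[1] <= percents[2]
        assert percents[2] > 60


class TestFrapNormalize:
    def test_anchors_exact(self):
        mov = simkit.simulate_frap_series(0.5, rng=1)
        c = foci.frap_normalize(mov.stack, mov.bleach_roi, mov.bleach_frame,
                                background_roi=mov.background_roi)
        assert c.values[mov.bleach_frame - 1] == 1.0
        assert c.values[mov.bleach_frame] == 0.0

    def test_no_exchange_stays_flat(self):
        mov = simkit.simulate_frap_series(0.0, rng=2)
        c = foci.frap_normalize(mov.stack, mov.bleach_roi, mov.bleach_frame,
                                background_roi=mov.background_roi)
        assert abs(c.recovery_fraction) <= 0.05

    def test_full_exchange_recovers_to_one(self):
        mov = simkit.simulate_frap_series(1.0, recovery_rate=0.6, rng=3)
        c = foci.frap_normalize(mov.stack, mov.bleach_roi, mov.bleach_frame,
                                background_roi=mov.background_roi)
        assert c.recovery_fraction == pytest.approx(1.0, abs=0.08)

    def test_requires_pre_bleach_frame(self):
        mov = simkit.simulate_frap_series(0.5, rng=4)
        with pytest.raises(ValueError):
            foci.frap_normalize(mov.stack, mov.bleach_roi, 0)
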