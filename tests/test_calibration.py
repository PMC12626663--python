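import numpy as np
import pytest

from autofluor.calibration import (CalibrationModel, calibrate_block,
                                   despike_and_smooth, fit_calibration)
from autofluor.errors import UncalibratableChannelError, ValidationError
from autofluor.model import DataBlock, ReferenceSet
from autofluor.synthetic import (generate_cohort, illumination_field,
                                 render_reference_set, response_matrix)
from tests.conftest import small_two_group_config


class TestDespikeAndSmooth:
    def test_constant_image_is_fixed_point(self):
        img = np.full((20, 20), 7.0)
        np.testing.assert_allclose(despike_and_smooth(img), img)

    def test_isolated_defects_restored_by_median(self):
        img = np.full((15, 15), 100.0)
        img[4, 4] = 0.0        # dead pixel
        img[10, 7] = 65535.0   # saturated pixel
        out = despike_and_smooth(img, sigma=0.0)
        np.testing.assert_allclose(out, 100.0)

    def test_variance_reduced_on_poisson_noise(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(100.0, (64, 64)).astype(float)
        out = despike_and_smooth(img)
        assert out.var() < img.var()

    def test_output_nonnegative_and_shape_preserved(self):
        rng = np.random.default_rng(1)
        img = rng.poisson(3.0, (32, 48)).astype(float)
        out = despike_and_smooth(img)
        assert out.shape == img.shape
        assert (out >= 0).all()


def _flat_refs(table, water_level, excess, ref_values, shape=(32, 32)):
    water = {cid: np.full(shape, float(water_level)) for cid in table.channel_ids}
    calib = {cid: np.full(shape, float(water_level + excess)) for cid in table.channel_ids}
    return ReferenceSet(background_images=water, calibration_images=calib,
                        reference_values={cid: ref_values for cid in table.channel_ids})


class TestFitCalibration:
    def test_flat_case_unit_field_and_scale(self, table4):
        refs = _flat_refs(table4, water_level=20, excess=50, ref_values=8.0)
        model = fit_calibration(refs, table4)
        cid = table4.channel_ids[0]
        np.testing.assert_allclose(model.flat_field[cid], 1.0)
        assert model.scale[cid] == pytest.approx(8.0 / 50.0)

    def test_doubling_excess_halves_scale(self, table4):
        m1 = fit_calibration(_flat_refs(table4, 20, 50, 8.0), table4)
        m2 = fit_calibration(_flat_refs(table4, 20, 100, 8.0), table4)
        cid = table4.channel_ids[0]
        assert m2.scale[cid] == pytest.approx(m1.scale[cid] / 2)

    def test_nonpositive_excess_names_channel(self, table4):
        refs = _flat_refs(table4, water_level=50, excess=0, ref_values=8.0)
        with pytest.raises(UncalibratableChannelError, match=table4.channel_ids[0]):
            fit_calibration(refs, table4)

    def test_flat_field_recovers_synthetic_illumination(self, table34):
        cfg = small_two_group_config()
        refs = render_reference_set(cfg, table34, np.random.default_rng(7))
        model = fit_calibration(refs, table34)
        true_field = illumination_field(cfg.field_shape, cfg.illumination_gradient)
        # brightest channels carry enough photons for a precise estimate
        bright = sorted(refs.reference_values, key=refs.reference_values.get,
                        reverse=True)[:5]
        for cid in bright:
            rho = np.corrcoef(model.flat_field[cid].ravel(), true_field.ravel())[0, 1]
            assert rho > 0.99

    def test_model_round_trip(self, tmp_path, table4):
        model = fit_calibration(_flat_refs(table4, 20, 50, 8.0), table4)
        model.save(tmp_path / "model")
        back = CalibrationModel.load(tmp_path / "model")
        cid = table4.channel_ids[0]
        assert back.scale[cid] == pytest.approx(model.scale[cid])
        np.testing.assert_allclose(back.flat_field[cid], model.flat_field[cid])


def _block_from_images(table, images, group="A"):
    bf = np.zeros(next(iter(images.values())).shape)
    return DataBlock("s", "p", group, images, bf, table)


class TestCalibrateBlock:
    def test_calibration_frame_maps_to_reference_value(self, table4):
        # a block equal to the calibration frame must land on R_c on average
        refs = _flat_refs(table4, water_level=20, excess=50, ref_values=8.0)
        model = fit_calibration(refs, table4)
        block = _block_from_images(table4, {cid: np.full((32, 32), 70.0)
                                            for cid in table4.channel_ids})
        out = calibrate_block(block, model)
        for cid in table4.channel_ids:
            assert out.channel_images[cid].mean() == pytest.approx(8.0, rel=1e-6)

    def test_water_frame_maps_to_zero(self, table4):
        refs = _flat_refs(table4, 20, 50, 8.0)
        model = fit_calibration(refs, table4)
        block = _block_from_images(table4, {cid: np.full((32, 32), 20.0)
                                            for cid in table4.channel_ids})
        out = calibrate_block(block, model)
        for cid in table4.channel_ids:
            np.testing.assert_allclose(out.channel_images[cid], 0.0, atol=1e-9)

    def test_double_calibration_rejected(self, table4):
        refs = _flat_refs(table4, 20, 50, 8.0)
        model = fit_calibration(refs, table4)
        block = _block_from_images(table4, {cid: np.full((32, 32), 70.0)
                                            for cid in table4.channel_ids})
        out = calibrate_block(block, model)
        with pytest.raises(ValidationError, match="already calibrated"):
            calibrate_block(out, model)

    def test_linearity_above_background(self, table4):
        # the subtract/divide/scale chain is affine-linear; affine test
        # images pass the (median) despike step unchanged in the interior,
        # so linearity holds there exactly
        refs = _flat_refs(table4, 20, 50, 8.0)
        model = fit_calibration(refs, table4)
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        a = {cid: 40 + 0.9 * xx + 0.4 * yy for cid in table4.channel_ids}
        b = {cid: 90 - 0.7 * xx + 0.2 * yy for cid in table4.channel_ids}
        alpha = 0.3
        mix = {cid: alpha * a[cid] + (1 - alpha) * b[cid] for cid in table4.channel_ids}
        ca = calibrate_block(_block_from_images(table4, a), model)
        cb = calibrate_block(_block_from_images(table4, b), model)
        cm = calibrate_block(_block_from_images(table4, mix), model)
        cid = table4.channel_ids[0]
        interior = np.s_[3:-3, 3:-3]
        np.testing.assert_allclose(
            cm.channel_images[cid][interior],
            (alpha * ca.channel_images[cid]
             + (1 - alpha) * cb.channel_images[cid])[interior],
            rtol=1e-5)

    def test_nonnegative_output(self, mini_cohort):
        model = fit_calibration(mini_cohort.reference, mini_cohort.channel_table)
        out = calibrate_block(mini_cohort.blocks[0], model)
        for img in out.channel_images.values():
            assert (img >= 0).all()

    def test_calibrated_spectra_match_ground_truth(self, mini_cohort):
        # cosine similarity between calibrated cell-mean spectra and the
        # true mixed fluorophore spectra
        cohort = mini_cohort
        cfg = cohort.config
        model = fit_calibration(cohort.reference, cohort.channel_table)
        resp = response_matrix(cfg.fluorophores, cohort.channel_table)
        gt = cohort.ground_truth.cells.set_index("cell_id")
        cos = []
        for block in cohort.blocks[:2]:
            cal = calibrate_block(block, model)
            stack = cal.image_stack()
            label = cohort.label_images[block.sample_id]
            for k in range(int(label.max())):
                inside = label == k + 1
                measured = stack[:, inside].mean(axis=1)
                ab = gt.loc[f"{block.patient_id}_c{k + 1:02d}",
                            [f"abundance_{f.name}" for f in cfg.fluorophores]].to_numpy(float)
                true = ab @ resp
                cos.append(measured @ true
                           / np.linalg.norm(measured) / np.linalg.norm(true))
        assert min(cos) > 0.98


def test_illumination_invariance_of_cell_means(table34):
    """Two identical cells at field center vs corner agree within 5% after
    flat-field correction but differ by the full gradient without it."""
    cfg = small_two_group_config(abundance_cv=0.0, patient_effect_sd=0.0,
                                 texture_sd=0.0, dead_pixel_rate=0.0,
                                 saturated_pixel_rate=0.0)
    shape = cfg.field_shape
    illum = illumination_field(shape, cfg.illumination_gradient)
    resp = response_matrix(cfg.fluorophores, table34)
    ab = np.array([130.0, 55.0])
    spectrum = ab @ resp
    rng = np.random.default_rng(9)

    from skimage.draw import ellipse
    label = np.zeros(shape, dtype=np.uint16)
    rr, cc = ellipse(48, 48, 10, 8, shape=shape)   # center
    label[rr, cc] = 1
    rr, cc = ellipse(12, 12, 10, 8, shape=shape)   # corner
    label[rr, cc] = 2
    images = {}
    for ci, cid in enumerate(table34.channel_ids):
        signal = np.where(label > 0, spectrum[ci], 0.0)
        images[cid] = rng.poisson(illum * (cfg.background_level + signal)
                                  ).astype(np.uint16)
    block = DataBlock("s", "p", "A", images, np.zeros(shape), table34)

    refs = render_reference_set(cfg, table34, np.random.default_rng(10))
    model = fit_calibration(refs, table34)
    cal = calibrate_block(block, model)

    bright = max(refs.reference_values, key=refs.reference_values.get)
    raw = block.channel_images[bright].astype(float)
    corrected = cal.channel_images[bright]
    raw_center = raw[label == 1].mean() - cfg.background_level
    raw_corner = raw[label == 2].mean() - cfg.background_level
    cal_center = corrected[label == 1].mean()
    cal_corner = corrected[label == 2].mean()
    assert abs(raw_center - raw_corner) / max(raw_center, raw_corner) > 0.15
    assert abs(cal_center - cal_corner) / max(cal_center, cal_corner) < 0.05
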