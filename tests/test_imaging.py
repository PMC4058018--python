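"""Counting algorithm: thresholds, shape filters, measurement, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from cmcount import (
    CellObject,
    CountConfig,
    SceneSpec,
    ThresholdPair,
    classify_object,
    count_slide,
    isodata_threshold,
    make_fov,
    make_slide,
    measure_cell,
    nuclear_mask,
    select_thresholds,
    shape_metrics,
)
from cmcount.imaging import DegenerateHistogramError, ThresholdError
from cmcount.io import FOVImage, SlideImageSet


def brute_force_intermeans(hist):
    """Independent oracle: scan all 256 candidates for the fixed point
    t == round((mean_below(t) + mean_above(t)) / 2), below = bins <= t."""
    hist = np.asarray(hist, dtype=float)
    bins = np.arange(256)
    fixed = []
    for t in range(255):
        below = hist[: t + 1]
        above = hist[t + 1 :]
        if below.sum() == 0 or above.sum() == 0:
            continue
        mb = (below * bins[: t + 1]).sum() / below.sum()
        ma = (above * bins[t + 1 :]).sum() / above.sum()
        if t == int(np.floor((mb + ma) / 2.0 + 0.5)):
            fixed.append(t)
    return fixed


class TestIsodata:
    def test_symmetric_two_level_histogram(self):
        hist = np.zeros(256)
        hist[50] = hist[200] = 1000
        assert isodata_threshold(hist) == 125

    def test_single_valued_histogram_raises(self):
        hist = np.zeros(256)
        hist[40] = 500
        with pytest.raises(DegenerateHistogramError):
            isodata_threshold(hist)

    def test_matches_brute_force_on_random_bimodal_histograms(self):
        """The iterative threshold is always an intermeans fixed point."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            hist = np.zeros(256)
            m1, m2 = sorted(rng.integers(5, 250, size=2))
            s1, s2 = rng.uniform(2, 20, size=2)
            for m, s, n in ((m1, s1, 3000), (m2, s2, 1500)):
                vals = np.clip(np.rint(rng.normal(m, s, n)), 0, 255).astype(int)
                hist += np.bincount(vals, minlength=256)
            t = isodata_threshold(hist)
            fixed = brute_force_intermeans(hist)
            if fixed:
                assert t in fixed
            else:  # rounding can leave no exact fixed point; accept |t - next(t)| <= 1
                bins = np.arange(256)
                below, above = hist[: t + 1], hist[t + 1 :]
                mb = (below * bins[: t + 1]).sum() / below.sum()
                ma = (above * bins[t + 1 :]).sum() / above.sum()
                assert abs(t - (mb + ma) / 2.0) <= 1.0


class TestShapeMetrics:
    def test_disk_is_nearly_circular(self):
        img = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 20)
        img[rr, cc] = True
        area, perim, aspect, circ = shape_metrics(img)
        assert circ >= 0.9
        assert aspect <= 1.1

    def test_square_circularity_approaches_pi_over_4(self):
        img = np.zeros((220, 220), bool)
        img[10:210, 10:210] = True
        *_, circ = shape_metrics(img)
        assert circ == pytest.approx(np.pi / 4, abs=0.03)

    def test_ellipse_aspect_ratio(self):
        img = np.zeros((96, 96), bool)
        rr, cc = draw_ellipse(48, 48, 20, 10)
        img[rr, cc] = True
        _, _, aspect, _ = shape_metrics(img)
        assert aspect == pytest.approx(2.0, abs=0.1)

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError):
            shape_metrics(np.zeros((10, 10), bool))


class TestNuclearMask:
    def test_counts_sharp_nuclei(self, config):
        fov, _ = make_fov(SceneSpec(n_cmc=5, seed=1))
        nuclei, mask = nuclear_mask(fov.channels["dapi"], config)
        assert len(nuclei) == 5

    def test_anuclear_debris_not_counted(self, config):
        fov, _ = make_fov(SceneSpec(n_cmc=5, n_debris=10, seed=2))
        nuclei, _ = nuclear_mask(fov.channels["dapi"], config)
        assert len(nuclei) == 5

    def test_fuzzy_margins_filtered_out(self, config):
        fov, _ = make_fov(SceneSpec(n_cmc=6, margin_sharpness=0.2, seed=5))
        nuclei, _ = nuclear_mask(fov.channels["dapi"], config)
        assert nuclei == []

    def test_blank_image_yields_empty_list(self, config):
        nuclei, mask = nuclear_mask(np.zeros((128, 128), np.uint8), config)
        assert nuclei == []
        assert not mask.any()

    def test_noise_only_image_yields_nothing(self, config):
        rng = np.random.default_rng(0)
        noise = np.clip(rng.normal(8, 3, (256, 256)), 0, 255).astype(np.uint8)
        nuclei, _ = nuclear_mask(noise, config)
        assert nuclei == []


@pytest.fixture(scope="module")
def measured(config):
    def run(pattern, seed=3):
        fov, _ = make_fov(SceneSpec(n_cmc=5, pattern=pattern, seed=seed))
        nuclei, mask = nuclear_mask(fov.channels["dapi"], config)
        from skimage import measure as skmeasure

        labels = skmeasure.label(mask, connectivity=2)
        return [
            measure_cell(fov, n, mask, labels, config.annulus_width)
            for n in nuclei
        ]

    return run


class TestMeasureCell:
    def test_uniform_green_has_low_cv(self, measured, config):
        for cell in measured("uniform"):
            assert cell.green_cv < config.green_cv_punctate
            assert cell.green_mean > 100

    def test_punctate_green_has_high_cv(self, measured, config):
        for cell in measured("punctate"):
            assert cell.green_cv > config.green_cv_punctate

    def test_background_annulus_mean_near_background(self, config):
        spec = SceneSpec(n_leuko=5, seed=6)
        fov, _ = make_fov(spec)
        nuclei, mask = nuclear_mask(fov.channels["dapi"], config)
        for nuc in nuclei:
            cell = measure_cell(fov, nuc, mask, None, config.annulus_width)
            # leukocytes carry no green: the annulus sees pure background
            n_px = 300  # annulus holds a few hundred pixels
            assert cell.green_mean == pytest.approx(
                spec.background_mean, abs=3 * spec.background_sd / np.sqrt(n_px) + 0.6
            )


class TestSelectThresholds:
    def _cells(self, greens, reds):
        return [
            CellObject(nucleus=None, green_mean=g, red_mean=r,
                       green_nuclear_mean=0.0, green_cv=0.0)
            for g, r in zip(greens, reds)
        ]

    def test_explicit_passthrough(self):
        t = select_thresholds([], mode="explicit", explicit=(30, 40))
        assert (t.t_red, t.t_green) == (30, 40)

    def test_bimodal_green_threshold_between_modes(self):
        greens = [20.0] * 50 + [180.0] * 20
        reds = [10.0] * 70
        cells = self._cells(greens, reds)
        tp = select_thresholds(cells, mode="patient")
        tc = select_thresholds(cells, mode="control")
        base = tp.t_green / 1.25
        assert 20 < base < 180
        assert tp.t_green > tc.t_green
        assert tp.t_green == pytest.approx(base * 1.25)
        assert tc.t_green == pytest.approx(base / 1.25)

    def test_too_few_cells_suggests_explicit(self):
        with pytest.raises(ThresholdError, match="explicit"):
            select_thresholds(self._cells([5] * 4, [5] * 4), mode="patient")

    def test_negative_slide_threshold_clears_every_cell(self, config):
        """Patient-mode bias pushes t_green above all-background green means."""
        slide, _ = make_slide(SceneSpec(n_leuko=300, seed=8), n_fov=4)
        res = count_slide(slide, config)
        assert (res.cells["green_mean"] <= res.thresholds.t_green).all()
        assert res.slide_count.n_cmc_slide == 0


@pytest.fixture(scope="module")
def nucleus(config):
    """A real segmented nucleus to attach to hand-built cells."""
    fov, _ = make_fov(SceneSpec(n_cmc=1, seed=9))
    nuclei, _ = nuclear_mask(fov.channels["dapi"], config)
    return nuclei[0]


@pytest.fixture(scope="module")
def thresholds():
    return ThresholdPair(t_red=30, t_green=40)


class TestClassifyObject:
    def _cell(self, nucleus, green, red, nuclear_green=0.0, cv=0.1, border=False):
        return CellObject(nucleus=nucleus, green_mean=green, red_mean=red,
                          green_nuclear_mean=nuclear_green, green_cv=cv,
                          border=border)

    def test_green_only_nucleated_cell_is_cmc(self, nucleus, thresholds):
        cell = self._cell(nucleus, green=150, red=5)
        assert classify_object(cell, thresholds) == "cmc"

    def test_green_and_red_is_dual_not_cmc(self, nucleus, thresholds):
        cell = self._cell(nucleus, green=150, red=120)
        assert classify_object(cell, thresholds) == "dual"

    def test_green_without_nucleus_is_debris(self, thresholds):
        cell = self._cell(None, green=150, red=5)
        assert classify_object(cell, thresholds) == "debris"

    def test_red_only_is_leukocyte(self, nucleus, thresholds):
        assert classify_object(self._cell(nucleus, 5, 150), thresholds) == "leukocyte"

    def test_unstained_cell_is_null(self, nucleus, thresholds):
        assert classify_object(self._cell(nucleus, 5, 5), thresholds) == "null"

    def test_border_cell_excluded(self, nucleus, thresholds):
        cell = self._cell(nucleus, 150, 5, border=True)
        assert classify_object(cell, thresholds) == "border"

    def test_nuclear_predominant_green_rejected_for_melan_a(self, nucleus, thresholds):
        cell = self._cell(nucleus, green=100, red=5, nuclear_green=150)
        assert classify_object(cell, thresholds, marker="MelanA") == "null"
        assert classify_object(cell, thresholds, marker="S100B") == "cmc"

    @given(
        green=st.floats(0, 255), red=st.floats(0, 255),
        t1=st.floats(0, 255), t2=st.floats(0, 255),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_in_thresholds(self, nucleus, green, red, t1, t2):
        """Raising t_green never turns a non-CMC into a CMC; raising t_red
        never turns a non-leukocyte into a leukocyte."""
        lo_g, hi_g = sorted([t1, t2])
        cell = self._cell(nucleus, green, red)
        lo = classify_object(cell, ThresholdPair(t_red=30, t_green=lo_g))
        hi = classify_object(cell, ThresholdPair(t_red=30, t_green=hi_g))
        assert not (lo != "cmc" and hi == "cmc")
        lo_r, hi_r = sorted([t1, t2])
        lo = classify_object(cell, ThresholdPair(t_red=lo_r, t_green=40))
        hi = classify_object(cell, ThresholdPair(t_red=hi_r, t_green=40))
        assert not (lo != "leukocyte" and hi == "leukocyte")


class TestCountSlide:
    def test_mixed_slide_tallies_match_ground_truth(self, mixed_slide, config):
        slide, truth = mixed_slide
        res = count_slide(slide, config)
        true_counts = truth["true_class"].value_counts()
        sc = res.slide_count
        assert abs(sc.n_cmc_slide - true_counts["cmc"]) <= 0.1 * true_counts["cmc"]
        assert abs(sc.n_dual - true_counts["dual"]) <= 0.2 * true_counts["dual"]
        assert sc.n_leuko_slide == pytest.approx(true_counts["leukocyte"], rel=0.05)

    def test_four_class_partition_is_exact(self, mixed_slide, config):
        """green+red+yellow+null equals all accepted nucleated objects."""
        slide, _ = mixed_slide
        res = count_slide(slide, config)
        sc = res.slide_count
        accepted = (res.cells["class_label"] != "border").sum()
        assert sc.n_cmc_slide + sc.n_leuko_slide + sc.n_dual + sc.n_null == accepted
        assert accepted + sc.n_border == len(res.cells)

    def test_all_leukocyte_slide_has_zero_cmc(self, config):
        slide, _ = make_slide(SceneSpec(n_leuko=400, seed=13), n_fov=4)
        res = count_slide(slide, config)
        assert res.slide_count.n_cmc_slide == 0

    def test_empty_slide_all_zero(self, config):
        blank = FOVImage(channels={
            "dapi": np.zeros((128, 128), np.uint8),
            "cd45": np.zeros((128, 128), np.uint8),
            "marker": np.zeros((128, 128), np.uint8),
        })
        res = count_slide(SlideImageSet([blank]), config)
        sc = res.slide_count
        assert (sc.n_cmc_slide, sc.n_leuko_slide, sc.n_dual, sc.n_null,
                sc.n_debris) == (0, 0, 0, 0, 0)

    def test_overlays_written(self, tmp_path, config):
        slide, _ = make_slide(SceneSpec(n_cmc=3, n_leuko=10, seed=2), n_fov=2)
        count_slide(slide, config.replace(t_red=30.0, t_green=40.0),
                    out_dir=tmp_path)
        assert len(list(tmp_path.glob("overlay_fov*.png"))) == 2
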