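"""ROI measurement, bleaching factor, relative fluorescence, fixed-mode ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lexykit.photocycle import StateTrace
from lexykit.quantify import (QuantError, bleaching_factor, measure_roi,
                              measure_stack, quantify_fixed, read_measurements,
                              relative_fluorescence, write_measurements)
from lexykit.scene import AcquisitionPlan, ScenePlan, render_timelapse
from lexykit.segmentation import derive_rois, segment_nuclei

FLAT_TRACE = StateTrace(times=np.array([0.0, 1000.0]), u=np.zeros(2),
                        N=np.full(2, 0.75), C=np.full(2, 0.25))


def _measurement_row(cell_id, t_index, roi_type, area, rid, time_min=None):
    return {"cell_id": cell_id, "t_index": t_index,
            "time_min": float(t_index if time_min is None else time_min),
            "roi_type": roi_type, "area_um2": area, "raw_int_den": rid}


def _simple_table(n_frames, nuc_dens, cyt_dens, bg_dens, allcells_dens):
    """Constant-density measurement table over n_frames."""
    rows = []
    for m in range(n_frames):
        rows.append(_measurement_row(1, m, "nucleus", 10.0, 10.0 * nuc_dens[m]))
        rows.append(_measurement_row(1, m, "cytoplasm", 20.0, 20.0 * cyt_dens[m]))
        rows.append(_measurement_row(0, m, "BG", 50.0, 50.0 * bg_dens[m]))
        rows.append(_measurement_row(0, m, "AllCells", 30.0, 30.0 * allcells_dens[m]))
    return pd.DataFrame(rows)


def test_measure_roi_area_and_density():
    img = np.zeros((6, 6))
    mask = np.zeros((6, 6), dtype=bool)
    mask[0, :5] = True
    mask[1, :5] = True
    img[mask] = 5.0
    m = measure_roi(img, mask, pixel_size_um=1.0)
    assert m.area_um2 == 10.0
    assert m.raw_int_den == 50.0
    single = np.zeros((4, 4), dtype=bool)
    single[2, 2] = True
    m1 = measure_roi(img[:4, :4] * 0, single, pixel_size_um=0.5)
    assert m1.area_um2 == 0.25
    assert m1.raw_int_den == 0.0
    with pytest.raises(QuantError):
        measure_roi(img, np.zeros((6, 6), dtype=bool), 1.0)


def test_measured_density_matches_ground_truth_noise_free():
    scene = ScenePlan.grid(n_cells=4, seed=1)
    acq = AcquisitionPlan((0.0,), noise=False, bleach_reporter=1.0,
                          bleach_marker=1.0)
    reporter, _, truth = render_timelapse(scene, FLAT_TRACE, acq)
    mask = truth.label_mask == 1
    m = measure_roi(reporter[0], mask, scene.pixel_size_um)
    expected = (truth.nuc_mean[0, 0] + scene.background) / scene.pixel_size_um ** 2
    assert m.density == pytest.approx(expected, rel=1e-6)


def test_bleaching_factor_identity_and_worked_example():
    assert bleaching_factor((1, 200.0), (1, 10.0), (1, 200.0), (1, 10.0)) == 1.0
    # densities 200 -> 110 with BG 10: (110-10)/(200-10)
    factor = bleaching_factor((1.0, 110.0), (1.0, 10.0), (1.0, 200.0), (1.0, 10.0))
    assert factor == pytest.approx(100.0 / 190.0, abs=1e-12)
    with pytest.raises(QuantError):
        bleaching_factor((1, 100.0), (1, 10.0), (1, 10.0), (1, 10.0))


def test_bleaching_factor_tracks_survival_on_render():
    """Noise-free render with per-frame survival b: the whole-field bleaching
    factor at frame m equals b^m within 1e-6."""
    b = 0.98
    scene = ScenePlan.grid(n_cells=5, seed=2)
    acq = AcquisitionPlan(tuple(float(i) for i in range(6)), noise=False,
                          bleach_reporter=b, bleach_marker=1.0)
    reporter, marker, _ = render_timelapse(scene, FLAT_TRACE, acq)
    rois = derive_rois(segment_nuclei(marker[0]))
    df = measure_stack(reporter, rois, scene.pixel_size_um)
    traces = relative_fluorescence(df)
    bleach = traces.groupby("time_min")["bleach_factor"].first().to_numpy()
    assert np.allclose(bleach, b ** np.arange(6), rtol=1e-6)


def test_relative_fluorescence_identical_frames():
    """All frames identical, no bleaching: relative nucleus is 1 everywhere
    and relative cytoplasm is the t0 density quotient."""
    n = 6
    tab = _simple_table(n, [40.0] * n, [20.0] * n, [10.0] * n, [25.0] * n)
    out = relative_fluorescence(tab)
    assert np.allclose(out["rel_nuc"], 1.0)
    assert np.allclose(out["rel_cyt"], (20.0 - 10.0) / (40.0 - 10.0))
    assert np.allclose(out["bleach_factor"], 1.0)
    assert np.allclose(out["nc_ratio"], 3.0)


def test_corrected_mode_flattens_bleached_constant_signal():
    """A constant-concentration control under bleaching is flat at 1 in
    'corrected' mode."""
    b = 0.98
    scene = ScenePlan.grid(n_cells=5, seed=2)
    acq = AcquisitionPlan(tuple(float(i) for i in range(8)), noise=False,
                          bleach_reporter=b, bleach_marker=1.0)
    reporter, marker, _ = render_timelapse(scene, FLAT_TRACE, acq)
    rois = derive_rois(segment_nuclei(marker[0]))
    df = measure_stack(reporter, rois, scene.pixel_size_um)
    out = relative_fluorescence(df, mode="corrected")
    assert np.allclose(out["rel_nuc"], 1.0, atol=1e-6)


def test_bleach_cancels_in_nc_ratio_between_modes():
    """The N/C ratio is identical to 1e-9 between 'as-printed' and
    'corrected' bleaching modes: the factor multiplies both compartments."""
    rng = np.random.default_rng(0)
    n = 8
    tab = _simple_table(n, 40 + rng.random(n), 20 + rng.random(n),
                        10 + 0.1 * rng.random(n), 25 + rng.random(n))
    printed = relative_fluorescence(tab, mode="as-printed")
    corrected = relative_fluorescence(tab, mode="corrected")
    assert np.allclose(printed["nc_ratio"], corrected["nc_ratio"], atol=1e-9)
    assert np.allclose(printed["nc_ratio_rel"], corrected["nc_ratio_rel"], atol=1e-9)


@given(scale=st.floats(min_value=0.1, max_value=50.0))
def test_scale_invariance(scale):
    """Multiplying every pixel by a constant leaves every trace output
    unchanged."""
    n = 6
    tab = _simple_table(n, [40, 39, 37, 36, 35, 34], [20] * n, [10] * n,
                        [25, 24.5, 24, 23.5, 23, 22.5])
    base = relative_fluorescence(tab)
    scaled_tab = tab.copy()
    scaled_tab["raw_int_den"] *= scale
    scaled = relative_fluorescence(scaled_tab)
    for col in ("bleach_factor", "rel_nuc", "rel_cyt", "nc_ratio", "nc_ratio_rel"):
        assert np.allclose(base[col], scaled[col], rtol=1e-9)


def test_t0_normalization_exact(induction_run):
    """Relative nuclear fluorescence and relative ratio are exactly 1 at t0
    for every quantified cell."""
    t0_rows = induction_run.traces.groupby("cell_id").first()
    assert np.all(t0_rows["rel_nuc"] == 1.0)
    assert np.all(t0_rows["nc_ratio_rel"] == 1.0)
    assert np.all(t0_rows["bleach_factor"] == 1.0)


def test_pipeline_ratio_tracks_ground_truth(induction_run):
    """Mean per-frame quantified N/C ratio stays within 5% of the generating
    trace's ratio through the full noisy pipeline."""
    traces = induction_run.traces[induction_run.traces["valid"]]
    mean_ratio = traces.groupby("time_min")["nc_ratio"].mean()
    truth_ratio = induction_run.truth.ratio[0]
    times = induction_run.truth.frame_times_min
    for t, truth_val in zip(times, truth_ratio):
        assert mean_ratio.loc[t] == pytest.approx(truth_val, rel=0.05)


def test_negative_background_subtraction_invalidates_timepoint():
    n = 6
    nuc = [40.0] * n
    nuc[3] = 5.0  # below background
    tab = _simple_table(n, nuc, [20.0] * n, [10.0] * n, [25.0] * n)
    out = relative_fluorescence(tab)
    assert not out.loc[out["time_min"] == 3.0, "valid"].iloc[0]
    assert out.loc[out["time_min"] == 3.0, "rel_nuc"].isna().all()


def test_table_round_trip_equivalence(tmp_path, induction_run):
    """Quantifying from an exported ROI CSV equals quantifying in memory."""
    scene = ScenePlan.grid(n_cells=4, seed=5)
    acq = AcquisitionPlan(tuple(float(i) for i in range(4)))
    reporter, marker, _ = render_timelapse(scene, FLAT_TRACE, acq)
    rois = derive_rois(segment_nuclei(marker[0]))
    df = measure_stack(reporter, rois, scene.pixel_size_um)
    path = tmp_path / "measurements.csv"
    write_measurements(df, path)
    df2 = read_measurements(path)
    a = relative_fluorescence(df)
    b = relative_fluorescence(df2)
    for col in ("bleach_factor", "rel_nuc", "rel_cyt", "nc_ratio"):
        assert np.allclose(a[col], b[col], atol=1e-9)


def test_quantify_fixed_arithmetic():
    """Identical planes with N density 4, C density 2, BG 1 give ratio 3."""
    rows = []
    for z in range(3):
        rows.append(_measurement_row(1, z, "nucleus", 10.0, 40.0))
        rows.append(_measurement_row(1, z, "cytoplasm", 10.0, 20.0))
        rows.append(_measurement_row(0, z, "BG", 10.0, 10.0))
        rows.append(_measurement_row(0, z, "AllCells", 10.0, 30.0))
    ratios = quantify_fixed(pd.DataFrame(rows), z_center=1)
    assert ratios.loc[1] == pytest.approx(3.0)


def test_quantify_fixed_requires_three_planes():
    rows = [_measurement_row(1, 0, "nucleus", 10.0, 40.0)]
    with pytest.raises(QuantError):
        quantify_fixed(pd.DataFrame(rows), z_center=0)


def test_quantify_fixed_excludes_mitotic_and_background_level_cells():
    rows = []
    for z in range(3):
        for cid, nuc in ((1, 40.0), (2, 40.0), (3, 8.0)):
            rows.append(_measurement_row(cid, z, "nucleus", 10.0, nuc))
            rows.append(_measurement_row(cid, z, "cytoplasm", 10.0,
                                         20.0 if cid != 3 else 9.0))
        rows.append(_measurement_row(0, z, "BG", 10.0, 10.0))
    with pytest.warns(UserWarning):
        ratios = quantify_fixed(pd.DataFrame(rows), z_center=1, mitotic={2: True})
    assert list(ratios.index) == [1]
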