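"""Image rendering and quantification: ROI sums, ring diameter, spindle clock."""

import numpy as np
import pytest

from cytokinetics.quantify import (NeckROI, detect_spindle_breakage,
                                   intensity_diameter_relation,
                                   measure_ring_diameter, measure_roi_intensity,
                                   score_constriction_symmetry)
from cytokinetics.render import (Movie, SceneConfig, read_movie, render_movie,
                                 write_movie)
from cytokinetics.simulate import (ConstrictionParams, simulate_constriction,
                                   simulate_ring_cell)

ROI = NeckROI(32, 32, 12, 12)


@pytest.fixture(scope="module")
def ring_movie_noiseless():
    trace = np.linspace(20, 120, 91)
    return trace, render_movie(SceneConfig(), trace,
                               diameter=np.full(91, 1.0), noise=False)


@pytest.fixture(scope="module")
def noisy_constriction_movie():
    d_true, truth = simulate_constriction(ConstrictionParams(noise_sd=0.0), seed=3)
    trace = np.where(d_true > 0, 100.0, 0.0)
    movie = render_movie(SceneConfig(seed=3), trace, diameter=d_true)
    return d_true, truth, movie


# -- ROI intensity --------------------------------------------------------------


def test_rendered_flux_proportional_to_trace(ring_movie_noiseless):
    trace, movie = ring_movie_noiseless
    meas = measure_roi_intensity(movie, "GFP", ROI)
    ratio = meas / trace
    assert (ratio.max() - ratio.min()) / ratio.mean() < 0.01


def test_uniform_image_gives_zero_roi_sum():
    mov = Movie({"GFP": np.full((3, 64, 64), 7.5)}, pixel_size=0.1, frame_interval=1.0)
    assert np.all(measure_roi_intensity(mov, "GFP", ROI) == 0.0)


def test_missing_channel_raises(ring_movie_noiseless):
    with pytest.raises(KeyError):
        measure_roi_intensity(ring_movie_noiseless[1], "mCherry", ROI)


def test_roi_filling_frame_raises(ring_movie_noiseless):
    with pytest.raises(ValueError, match="margin"):
        measure_roi_intensity(ring_movie_noiseless[1], "GFP", NeckROI(32, 32, 31, 31))


def test_background_invariance_and_scale_equivariance(ring_movie_noiseless):
    trace, movie = ring_movie_noiseless
    base = measure_roi_intensity(movie, "GFP", ROI)
    shifted = Movie({"GFP": movie.channels["GFP"] + 37.0}, movie.pixel_size,
                    movie.frame_interval)
    np.testing.assert_allclose(measure_roi_intensity(shifted, "GFP", ROI),
                               base, rtol=1e-9)
    scaled = Movie({"GFP": movie.channels["GFP"] * 2.5}, movie.pixel_size,
                   movie.frame_interval)
    np.testing.assert_allclose(measure_roi_intensity(scaled, "GFP", ROI),
                               2.5 * base, rtol=1e-9)
    # diameter and breakage frame are scale-invariant
    r0 = measure_ring_diameter(movie.channels["GFP"][45], ROI, 0.1)
    r1 = measure_ring_diameter(2.5 * movie.channels["GFP"][45], ROI, 0.1)
    assert r1.diameter == pytest.approx(r0.diameter, abs=1e-6)


# -- ring diameter --------------------------------------------------------------


def test_ring_diameter_noiseless_exact(ring_movie_noiseless):
    _, movie = ring_movie_noiseless
    r = measure_ring_diameter(movie.channels["GFP"][45], ROI, movie.pixel_size)
    assert r.resolved
    assert r.diameter == pytest.approx(1.0, abs=0.02)


def test_coincident_puncta_flagged_below_resolution():
    mov = render_movie(SceneConfig(), np.full(5, 100.0),
                       diameter=np.zeros(5), noise=False)
    r = measure_ring_diameter(mov.channels["GFP"][2], ROI, 0.1)
    assert not r.resolved
    assert r.flag == "below_resolution"


def test_background_only_profile_flagged_no_ring():
    rng = np.random.default_rng(0)
    frame = rng.poisson(100.0, size=(64, 64)).astype(float)
    r = measure_ring_diameter(frame, ROI, 0.1)
    assert r.flag == "no_ring"


def test_diameter_unbiased_for_well_separated_puncta():
    """Separations of at least 3 PSF sigmas recover within 0.05 μm, noise off."""
    for diam in (0.45, 0.6, 0.8, 1.0, 1.4):
        mov = render_movie(SceneConfig(), np.full(3, 100.0),
                           diameter=np.full(3, diam), noise=False)
        r = measure_ring_diameter(mov.channels["GFP"][1], ROI, 0.1)
        assert r.resolved
        assert r.diameter == pytest.approx(diam, abs=0.05)


def test_noisy_diameter_series_tracks_truth(noisy_constriction_movie):
    d_true, truth, movie = noisy_constriction_movie
    est = np.array([
        (r.diameter if r.resolved else 0.0)
        for r in (measure_ring_diameter(movie.channels["GFP"][k], ROI, 0.1)
                  for k in range(91))])
    rmse = float(np.sqrt(np.mean((est - d_true) ** 2)))
    assert rmse < 0.1


def test_ring_diameter_exceeding_field_raises():
    with pytest.raises(ValueError, match="field of view"):
        render_movie(SceneConfig(), np.full(3, 100.0),
                     diameter=np.full(3, 7.0), noise=False)


# -- spindle breakage -----------------------------------------------------------


def test_spindle_component_count_switches_at_breakage():
    from skimage.measure import label
    mov = render_movie(SceneConfig(), np.full(91, 50.0), breakage_time=0.0,
                       noise=False)
    stack = mov.channels["spindle"]
    def n_comp(frame):
        bg = np.median(frame)
        return int(label(frame > bg + 0.5 * (frame.max() - bg)).max())
    assert n_comp(stack[40]) == 1
    assert n_comp(stack[45]) in (0, 2)


def test_breakage_detection_noiseless_exact():
    mov = render_movie(SceneConfig(), np.full(91, 50.0), breakage_time=0.0,
                       noise=False)
    assert detect_spindle_breakage(mov) == 45


def test_breakage_abrupt_disappearance_detected_at_k():
    mov = render_movie(SceneConfig(), np.full(91, 50.0), breakage_time=0.0,
                       noise=False)
    stack = mov.channels["spindle"].copy()
    stack[40:] = 100.0  # spindle vanishes abruptly at frame 40, before breaking
    cut = Movie({"spindle": stack}, mov.pixel_size, mov.frame_interval, mov.t_start)
    assert detect_spindle_breakage(cut) == 40


def test_spindle_never_breaking_raises():
    mov = render_movie(SceneConfig(), np.full(60, 50.0), breakage_time=30.0,
                       noise=False)
    with pytest.raises(ValueError, match="never breaks"):
        detect_spindle_breakage(mov)


def test_no_anaphase_spindle_raises():
    mov = Movie({"spindle": np.random.default_rng(0).poisson(100, (20, 64, 64)).astype(float)},
                pixel_size=0.1, frame_interval=1.0)
    with pytest.raises(ValueError, match="no anaphase spindle"):
        detect_spindle_breakage(mov)


# -- intensity–diameter relation -------------------------------------------------


def test_relation_exact_for_noiseless_coupling(byid):
    tr, truth = simulate_ring_cell(byid["Myo1"], ConstrictionParams(noise_sd=0.0),
                                   jitter_sd=0.0, noise_cv=0.0, seed=2)
    t = tr.times - tr.t0
    win = (t >= truth["onset_min"]) & (t <= truth["end_min"])
    r, slope, _ = intensity_diameter_relation(tr.intensity[win], tr.diameter[win])
    assert r == pytest.approx(1.0, abs=1e-6)
    assert slope > 0


def test_relation_pooled_cells_strongly_correlated(byid):
    """Intensity tracks ring length across cells at default noise."""
    xs, ys = [], []
    for i in range(30):
        tr, truth = simulate_ring_cell(byid["Myo1"], seed=100 + i)
        t = tr.times - tr.t0
        win = (t >= truth["onset_min"]) & (t <= truth["end_min"])
        xs.append(tr.intensity[win])
        ys.append(tr.diameter[win])
    r, _, _ = intensity_diameter_relation(np.concatenate(xs), np.concatenate(ys))
    assert r > 0.9


def test_relation_constant_diameter_errors():
    with pytest.raises(ValueError, match="zero variance"):
        intensity_diameter_relation(np.arange(10.0), np.full(10, 1.0))
    with pytest.raises(ValueError, match="fewer than 5"):
        intensity_diameter_relation(np.arange(3.0), np.arange(3.0))


# -- constriction symmetry --------------------------------------------------------


def test_symmetric_convergence_scores_zero():
    pos = [(-0.5 + 0.05 * k, 0.5 - 0.05 * k) for k in range(10)]
    idx, cls = score_constriction_symmetry(pos)
    assert idx == pytest.approx(0.0, abs=1e-12)
    assert cls == "symmetric"


def test_one_sided_sweep_scores_one():
    pos = [(-0.5, 0.5 - 0.1 * k) for k in range(10)]  # one punctum fixed
    idx, cls = score_constriction_symmetry(pos)
    assert idx == pytest.approx(0.9, abs=1e-9)  # -> 1 as the sweep completes
    assert cls == "asymmetric"
    full = pos + [-0.5]  # midpoint when puncta finally coincide at -0.5
    idx_full, _ = score_constriction_symmetry(full)
    assert idx_full == pytest.approx(1.0)


def test_rendered_asymmetry_parameter_recovered():
    d = np.clip(np.linspace(1.0, 0.0, 91), 0.0, None)
    mov = render_movie(SceneConfig(seed=5), np.full(91, 100.0), diameter=d,
                       asymmetry=0.5, noise=False)
    pos = []
    for k in range(91):
        r = measure_ring_diameter(mov.channels["GFP"][k], ROI, 0.1)
        pos.append(r.positions if r.resolved
                   else (r.center if r.flag == "below_resolution" else None))
    idx, cls = score_constriction_symmetry(pos)
    assert idx == pytest.approx(0.5, abs=0.1)
    assert cls == "asymmetric"


def test_symmetry_needs_three_resolved_frames():
    with pytest.raises(ValueError):
        score_constriction_symmetry([(-0.5, 0.5), None, 0.1])


# -- movie I/O -------------------------------------------------------------------


def test_movie_roundtrip_through_tiff(tmp_path):
    mov = render_movie(SceneConfig(seed=9), np.full(10, 80.0),
                       diameter=np.full(10, 0.9))
    sidecar = write_movie(mov, tmp_path, "cell0")
    back = read_movie(sidecar)
    assert back.pixel_size == mov.pixel_size
    assert set(back.channels) == set(mov.channels)
    np.testing.assert_allclose(back.channels["GFP"], mov.channels["GFP"],
                               rtol=1e-6)
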