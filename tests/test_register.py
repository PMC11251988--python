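import numpy as np
import pytest

from srtmsi import (
    LandmarkPairs,
    PipelineConfig,
    SimilarityTransform2D,
    assemble_multimodal,
    fit_similarity,
    pair_modalities,
    suggest_distance_cutoff,
)
from srtmsi.register import PairMap, apply_transform
from srtmsi.srt import normalize_logcpm

from conftest import make_raster, make_section


def brute_force_pairing(msi_xy, spot_xy, cfg):
    """All-pairs oracle: full distance matrix, cutoff, per-pixel argmin with
    lowest-index tie-breaking."""
    rows = []
    unpaired = []
    for i, p in enumerate(msi_xy):
        d = np.linalg.norm(spot_xy - p, axis=1)
        ok = np.flatnonzero(d <= cfg.max_pair_dist_px)
        if ok.size == 0:
            unpaired.append(i)
            continue
        dmin = d[ok].min()
        j = int(ok[d[ok] == dmin].min())
        rows.append((i, j, float(dmin)))
    return rows, unpaired


def test_fit_similarity_identity():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [3.0, 7.0]])
    t = fit_similarity(LandmarkPairs(pts, pts))
    assert t.scale == pytest.approx(1.0)
    assert t.rotation_rad == pytest.approx(0.0)
    np.testing.assert_allclose(t.translation, [0.0, 0.0], atol=1e-12)


def test_fit_similarity_recovers_known_transform():
    truth = SimilarityTransform2D(scale=2.0, rotation_rad=np.pi / 2,
                                  translation=(10.0, -5.0))
    src = np.array([[0.0, 0.0], [5.0, 1.0], [-3.0, 4.0], [2.0, -6.0]])
    t = fit_similarity(LandmarkPairs(src, truth.apply(src)))
    assert t.scale == pytest.approx(2.0, abs=1e-8)
    assert t.rotation_rad == pytest.approx(np.pi / 2, abs=1e-8)
    np.testing.assert_allclose(t.translation, [10.0, -5.0], atol=1e-8)


def test_fit_similarity_beats_random_transforms():
    """Fitted residual RMS is minimal against 1,000 random transforms."""
    rng = np.random.default_rng(0)
    src = rng.uniform(-50, 50, size=(6, 2))
    dst = SimilarityTransform2D(1.7, 0.4, (12.0, 3.0)).apply(src)
    dst += rng.normal(0, 2.0, dst.shape)
    fitted = fit_similarity(LandmarkPairs(src, dst))
    rms_fit = np.sqrt(((fitted.apply(src) - dst) ** 2).sum(axis=1).mean())
    for _ in range(1000):
        t = SimilarityTransform2D(
            scale=rng.uniform(0.5, 3.0),
            rotation_rad=rng.uniform(-np.pi, np.pi),
            translation=tuple(rng.uniform(-30, 30, 2)),
        )
        rms = np.sqrt(((t.apply(src) - dst) ** 2).sum(axis=1).mean())
        assert rms_fit <= rms + 1e-12


def test_fit_similarity_matches_skimage():
    from skimage.transform import SimilarityTransform as SkTransform

    rng = np.random.default_rng(1)
    src = rng.uniform(-100, 100, size=(8, 2))
    dst = SimilarityTransform2D(0.8, -1.1, (5.0, 40.0)).apply(src)
    dst += rng.normal(0, 1.0, dst.shape)
    ours = fit_similarity(LandmarkPairs(src, dst))
    sk = SkTransform.from_estimate(src, dst)
    np.testing.assert_allclose(ours.apply(src), sk(src), atol=1e-8)


def test_fit_similarity_degenerate_sources_error():
    pts = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ValueError):
        LandmarkPairs(pts, pts)  # duplicated source points
    near = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-15]])
    with pytest.raises(ValueError, match="degenerate"):
        fit_similarity(LandmarkPairs(near, near))


def test_transform_inverse_round_trip():
    t = SimilarityTransform2D(scale=1.4, rotation_rad=0.7, translation=(3.0, -9.0))
    pts = np.random.default_rng(2).uniform(-100, 100, size=(20, 2))
    np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)


def test_apply_transform_translation():
    raster = make_raster(np.ones((2, 3)), pixel_xy=[(0, 0), (1, 0), (0, 1)])
    t = SimilarityTransform2D(translation=(5.0, 5.0))
    np.testing.assert_allclose(
        apply_transform(t, raster), raster.pixel_xy + 5.0
    )
    ident = SimilarityTransform2D()
    np.testing.assert_allclose(apply_transform(ident, raster), raster.pixel_xy)


def test_pair_modalities_hand_geometry(cfg):
    pairs = pair_modalities(
        np.array([[0.0, 0.0]]), np.array([[3.0, 4.0], [30.0, 40.0]]), cfg
    )
    assert len(pairs) == 1
    assert pairs.spot_index[0] == 0
    assert pairs.distance_px[0] == pytest.approx(5.0)


def test_pair_modalities_default_config_is_k5_cutoff35(cfg):
    assert cfg.knn_k == 5
    assert cfg.max_pair_dist_px == 35.0


def test_pair_modalities_zero_cutoff_reports_all_unpaired():
    cfg = PipelineConfig(max_pair_dist_px=1e-9)
    msi = np.array([[0.3, 0.3], [5.2, 1.1]])
    spots = np.array([[1.0, 1.0], [4.0, 4.0]])
    pairs = pair_modalities(msi, spots, cfg)
    assert len(pairs) == 0
    np.testing.assert_array_equal(pairs.unpaired_msi_pixels, [0, 1])


def test_pair_modalities_spot_reuse_allowed(cfg):
    msi = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    spots = np.array([[0.5, 0.5]])
    pairs = pair_modalities(msi, spots, cfg)
    assert len(pairs) == 3
    assert set(pairs.spot_index) == {0}


def test_pair_modalities_empty_spots_error(cfg):
    with pytest.raises(ValueError, match="empty"):
        pair_modalities(np.array([[0.0, 0.0]]), np.empty((0, 2)), cfg)


def test_pair_modalities_matches_brute_force_oracle():
    """kNN search equals the all-pairs oracle on random instances; with
    k=5 the closest in-cutoff spot is always among the 5 nearest."""
    rng = np.random.default_rng(42)
    cfg = PipelineConfig(max_pair_dist_px=8.0)
    for _ in range(30):
        n_msi = rng.integers(5, 200)
        n_spot = rng.integers(5, 200)
        msi = rng.uniform(0, 100, size=(n_msi, 2))
        spots = rng.uniform(0, 100, size=(n_spot, 2))
        pairs = pair_modalities(msi, spots, cfg)
        rows, unpaired = brute_force_pairing(msi, spots, cfg)
        assert list(pairs.msi_pixel_index) == [r[0] for r in rows]
        assert list(pairs.spot_index) == [r[1] for r in rows]
        np.testing.assert_allclose(pairs.distance_px, [r[2] for r in rows])
        assert list(pairs.unpaired_msi_pixels) == unpaired


def test_pairmap_invariants_enforced():
    with pytest.raises(ValueError, match="unique"):
        PairMap(np.array([0, 0]), np.array([1, 2]), np.array([1.0, 1.0]),
                np.array([]), 35.0)
    with pytest.raises(ValueError, match="distance"):
        PairMap(np.array([0]), np.array([1]), np.array([99.0]), np.array([]), 35.0)


def test_assemble_multimodal_duplicates_spots(cfg):
    section = make_section(np.arange(12).reshape(3, 4))
    normed = normalize_logcpm(section)
    raster = make_raster(np.arange(10).reshape(2, 5) + 1.0,
                         pixel_xy=[(i, 0.0) for i in range(5)])
    pairs = PairMap(np.array([0, 2, 4]), np.array([1, 1, 3]),
                    np.array([0.0, 1.0, 2.0]), np.array([1, 3]), 35.0)
    mm = assemble_multimodal(section, normed, raster, pairs)
    assert mm.n_obs == 3
    assert len(set(mm.obs_barcodes)) == 2
    np.testing.assert_array_equal(mm.obs_msi_pixel, [0, 2, 4])
    np.testing.assert_array_equal(mm.gene_counts, section.counts[:, [1, 1, 3]])
    np.testing.assert_array_equal(mm.peak_intensities, raster.intensities[:, [0, 2, 4]])
    assert (mm.pair_distance_px <= cfg.max_pair_dist_px).all()


def test_assemble_multimodal_empty_pairs_error():
    section = make_section(np.ones((2, 2), int))
    raster = make_raster(np.ones((2, 2)))
    empty = PairMap(np.array([], int), np.array([], int), np.array([]),
                    np.array([0, 1]), 35.0)
    with pytest.raises(ValueError, match="empty"):
        assemble_multimodal(section, normalize_logcpm(section), raster, empty)


def test_assemble_multimodal_out_of_range_error():
    section = make_section(np.ones((2, 2), int))
    raster = make_raster(np.ones((2, 2)))
    bad = PairMap(np.array([0]), np.array([5]), np.array([0.0]), np.array([]), 35.0)
    with pytest.raises(IndexError):
        assemble_multimodal(section, normalize_logcpm(section), raster, bad)


def test_suggest_cutoff_bimodal_lands_between_modes():
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(3)
    d = np.abs(np.r_[rng.normal(10, 2, 500), rng.normal(80, 5, 200)])
    t = suggest_distance_cutoff(d)
    assert 20 < t < 70
    # both the plateau midpoint and skimage's (lowest-plateau) Otsu value
    # must induce the same separation of the two modes
    t_sk = threshold_otsu(d, nbins=64)
    assert t_sk <= t
    np.testing.assert_array_equal(d <= t, d <= t_sk)


def test_suggest_cutoff_scale_equivariant():
    rng = np.random.default_rng(4)
    d = np.abs(np.r_[rng.normal(10, 2, 500), rng.normal(80, 5, 200)])
    t = suggest_distance_cutoff(d)
    assert suggest_distance_cutoff(3.0 * d) == pytest.approx(3.0 * t, rel=1e-9)


def test_suggest_cutoff_constant_warns():
    with pytest.warns(UserWarning, match="identical"):
        t = suggest_distance_cutoff(np.full(60, 7.0))
    assert t == 7.0


def test_suggest_cutoff_needs_fifty_distances():
    with pytest.raises(ValueError, match="50"):
        suggest_distance_cutoff(np.arange(49, dtype=float))


def test_end_to_end_pairing_accuracy(default_synthetic):
    """Fitted transform maps pixels within 2 px RMS of truth and >=95% of
    tissue pixels pair to the spot nearest their true position."""
    from srtmsi import generate_landmarks

    scfg, srt, raster, truth = default_synthetic
    t = fit_similarity(generate_landmarks(scfg, truth))
    mapped = t.apply(raster.pixel_xy)
    err = np.linalg.norm(mapped - truth.pixel_xy_common, axis=1)
    assert np.sqrt((err ** 2).mean()) <= 2.0
    tissue = ~truth.offtissue
    cfg = PipelineConfig()
    pairs = pair_modalities(mapped[tissue], srt.spot_xy, cfg)
    agree = truth.nearest_spot[tissue][pairs.msi_pixel_index] == pairs.spot_index
    assert agree.mean() >= 0.95
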