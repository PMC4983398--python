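import numpy as np
import pytest

import octlbp as ol
from octlbp.lbp import LBPMapSet
from octlbp.represent import K_SWEEP, descriptor_length


def _mapset_2d(d=4, H=16, W=16, P=8, R=1, seed=0) -> LBPMapSet:
    rng = np.random.default_rng(seed)
    return ol.lbp_maps_per_slice(rng.random((d, H, W)), ol.LBPParams(P, R))


def _mapset_3d(d=9, H=9, W=9, P=8, R=1, seed=0) -> LBPMapSet:
    rng = np.random.default_rng(seed)
    return ol.lbp_top_maps(rng.random((d, H, W)), ol.LBPParams(P, R))


# ----------------------------------------------------------- partition ----


def test_global_lbp_yields_one_element_per_slice():
    maps = _mapset_2d(d=6)
    el = ol.partition(maps, ol.MappingSpec("global"))
    assert el.histograms.shape == (6, 10)
    # every histogram counts exactly the valid coded pixels of its slice
    assert (el.histograms.sum(axis=1) == 14 * 14).all()


def test_global_lbptop_yields_single_three_plane_element():
    maps = _mapset_3d()
    el = ol.partition(maps, ol.MappingSpec("global"))
    assert el.histograms.shape == (1, 30)
    valid = maps.masks["xz"].sum()
    assert el.histograms[0, :10].sum() == valid


def test_local_lbp_grid_counts_and_sums():
    """m=7 patches over a 14x14 valid region: 2x2 = 4 cells per slice, each
    histogram summing to 49."""
    maps = _mapset_2d(d=3, H=16, W=16)  # valid region 14x14 for R=1
    el = ol.partition(maps, ol.MappingSpec("local", m=7))
    assert el.histograms.shape == (3 * 4, 10)
    assert (el.histograms.sum(axis=1) == 49).all()


def test_local_lbp_drops_incomplete_border_cells():
    maps = _mapset_2d(d=1, H=18, W=23)  # valid 16x21 -> 2x3 cells of 7
    el = ol.partition(maps, ol.MappingSpec("local", m=7))
    assert el.n_elements == 2 * 3


def test_local_lbptop_subvolume_histograms():
    maps = _mapset_3d(d=9, H=9, W=9)  # valid 7x7x7 -> one m=7 cell
    el = ol.partition(maps, ol.MappingSpec("local", m=7))
    assert el.histograms.shape == (1, 30)
    # each plane block counts that subvolume's voxels once
    assert (el.histograms.reshape(1, 3, 10).sum(axis=2) == 343).all()


def test_local_mode_rejects_oversized_element():
    maps = _mapset_2d(d=1, H=10, W=10)
    with pytest.raises(ValueError, match="exceeds"):
        ol.partition(maps, ol.MappingSpec("local", m=9))


def test_partition_agrees_with_manual_patch_histogram():
    maps = _mapset_2d(d=1, H=16, W=16)
    el = ol.partition(maps, ol.MappingSpec("local", m=7))
    codes = maps.planes["xz"][0]
    manual = np.bincount(codes[1:8, 1:8].ravel(), minlength=10)
    assert np.array_equal(el.histograms[0], manual)


@pytest.mark.parametrize("P", [8, 16, 24])
@pytest.mark.parametrize("feature", ["lbp", "lbptop"])
@pytest.mark.parametrize("mode", ["global", "local"])
def test_descriptor_lengths_for_all_combinations(P, feature, mode):
    """Concatenated descriptor sizes must follow d*(P+2), 1*3(P+2),
    (N*d)*(P+2) and N'*3(P+2) for the four (feature, mapping) cases."""
    R = {8: 1, 16: 2, 24: 3}[P]
    d, H, W = 16, 24, 24
    rng = np.random.default_rng(P)
    vox = rng.random((d, H, W))
    params = ol.LBPParams(P, R)
    maps = (
        ol.lbp_maps_per_slice(vox, params)
        if feature == "lbp"
        else ol.lbp_top_maps(vox, params)
    )
    spec = ol.MappingSpec(mode, m=7)
    el = ol.partition(maps, spec)
    if mode == "global":
        n_expected = d if feature == "lbp" else 1
        assert el.n_elements == n_expected
        assert el.histograms.size == descriptor_length(feature, mode, P, d=d)
    else:
        n_grid = (H - 2 * R) // 7 * ((W - 2 * R) // 7)
        if feature == "lbp":
            assert el.n_elements == d * n_grid
        else:
            assert el.n_elements == ((d - 2 * R) // 7) * n_grid
        assert el.histograms.size == descriptor_length(
            feature, mode, P, n_elements=el.n_elements
        )


# ----------------------------------------------------------- low level ----


def test_lowlevel_descriptor_lengths():
    el = ol.partition(_mapset_2d(d=5), ol.MappingSpec("global"))
    assert ol.lowlevel_descriptor(el).shape == (50,)
    el3 = ol.partition(_mapset_3d(P=16, R=2, d=12, H=12, W=12),
                       ol.MappingSpec("global"))
    assert ol.lowlevel_descriptor(el3).shape == (54,)


def test_lowlevel_normalization_per_block():
    el = ol.partition(_mapset_2d(d=4), ol.MappingSpec("global"))
    desc = ol.lowlevel_descriptor(el, normalize=True)
    assert np.allclose(desc.reshape(4, 10).sum(axis=1), 1.0)


def test_lowlevel_rejects_local_mapping():
    el = ol.partition(_mapset_2d(), ol.MappingSpec("local", m=7))
    with pytest.raises(ValueError, match="global"):
        ol.lowlevel_descriptor(el)


# ------------------------------------------------------------ codebook ----


def test_codebook_recovers_separated_cloud_means():
    rng = np.random.default_rng(0)
    cloud1 = rng.normal(0.0, 0.05, size=(50, 6))
    cloud2 = rng.normal(5.0, 0.05, size=(50, 6))
    X = np.concatenate([cloud1, cloud2])
    cb = ol.build_codebook(X, k=2, build="kmeans", seed=1)
    means = sorted([cloud1.mean(axis=0), cloud2.mean(axis=0)], key=lambda m: m[0])
    words = cb.words[np.argsort(cb.words[:, 0])]
    assert np.allclose(words, means, atol=0.05)


@pytest.mark.parametrize("build", ["kmeans", "kmeans_pp_init_only", "random"])
def test_codebook_deterministic_under_seed(build):
    rng = np.random.default_rng(2)
    X = rng.random((80, 10))
    cb1 = ol.build_codebook(X, k=5, build=build, seed=9)
    cb2 = ol.build_codebook(X, k=5, build=build, seed=9)
    assert np.array_equal(cb1.words, cb2.words)


def test_codebook_rejects_fewer_samples_than_words():
    with pytest.raises(ValueError):
        ol.build_codebook(np.zeros((3, 4)), k=5)


def test_codebook_accepts_word_count_sweep_values():
    rng = np.random.default_rng(3)
    X = rng.random((1100, 4))
    for k in K_SWEEP:
        cb = ol.build_codebook(X, k=k, build="kmeans_pp_init_only", seed=0)
        assert cb.k == k


# ----------------------------------------------------------------- BoW ----


def test_bow_counts_sum_to_element_count():
    el = ol.partition(_mapset_2d(d=3), ol.MappingSpec("local", m=7))
    cb = ol.build_codebook(el.histograms, k=4, seed=0)
    bow = ol.encode_bow(el, cb)
    assert bow.sum() == el.n_elements
    assert ol.encode_bow(el, cb, normalize=True).sum() == pytest.approx(1.0)


def test_bow_one_hot_when_elements_equal_a_word():
    words = np.eye(5) * 10
    cb = ol.Codebook(words=words, build="random", seed=0)
    elements = np.tile(words[2], (7, 1))
    bow = ol.encode_bow(elements, cb)
    assert np.array_equal(bow, [0, 0, 7, 0, 0])


def test_bow_matches_bruteforce_nearest_word():
    rng = np.random.default_rng(4)
    elements = rng.random((40, 6))
    cb = ol.Codebook(words=rng.random((9, 6)), build="random", seed=0)
    bow = ol.encode_bow(elements, cb)
    ref = np.zeros(9)
    for e in elements:
        dists = [np.sqrt(((e - w) ** 2).sum()) for w in cb.words]
        ref[int(np.argmin(dists))] += 1
    assert np.array_equal(bow, ref)


def test_bow_ties_break_to_lowest_word_index():
    cb = ol.Codebook(words=np.array([[1.0, 0.0], [0.0, 1.0]]), build="random", seed=0)
    bow = ol.encode_bow(np.array([[0.5, 0.5]]), cb)  # equidistant
    assert np.array_equal(bow, [1, 0])


def test_bow_rejects_dimension_mismatch():
    cb = ol.Codebook(words=np.zeros((3, 5)), build="random", seed=0)
    with pytest.raises(ValueError, match="length"):
        ol.encode_bow(np.zeros((2, 4)), cb)


def test_bow_invariant_to_element_permutation():
    rng = np.random.default_rng(5)
    elements = rng.random((30, 6))
    cb = ol.Codebook(words=rng.random((4, 6)), build="random", seed=0)
    b1 = ol.encode_bow(elements, cb)
    b2 = ol.encode_bow(elements[rng.permutation(30)], cb)
    assert np.array_equal(b1, b2)
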