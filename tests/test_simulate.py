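import numpy as np
import pytest

from gmherit import (DeformationSpec, STANDARD_HD_MAGNITUDE, Treatment,
                     analyze_dataset, centroid_size, default_allometry_slopes,
                     default_mean_shape, gpa_align, hd_offset,
                     simulate_dataset, tangent_pca)


# ----------------------------------------------------------------- deformations

def test_treatment_table_resolution():
    t = {name: Treatment.from_name(name) for name in Treatment.names()}
    std = STANDARD_HD_MAGNITUDE
    assert (t["T1"].spec.hd_type, t["T1"].spec.nd_multiplier) == ("HD1", 1.0)
    assert t["T2"].spec.hd_magnitude == 2 * std          # double effect
    assert t["T3"].spec.nd_multiplier == 2.0             # double noise
    assert t["T4"].spec.hd_magnitude == 0.5 * std        # half effect
    assert (t["T5o"].spec.hd_type, t["T5o"].spec.orientation) == ("HD5", "orthogonal")
    assert (t["T5p"].spec.hd_type, t["T5p"].spec.orientation) == ("HD5", "parallel")
    assert t["T6o"].spec.hd_type == "HD6"
    assert t["T6p"].spec.orientation == "parallel"
    with pytest.raises(ValueError):
        Treatment.from_name("T9")


def test_hd2_offset_is_double_hd1():
    t1 = Treatment.from_name("T1").spec
    t2 = Treatment.from_name("T2").spec
    for p in (1, 2):
        np.testing.assert_allclose(hd_offset(t2, p, 2), 2 * hd_offset(t1, p, 2))


def test_orthogonal_displacements_perpendicular():
    spec = Treatment.from_name("T5o").spec
    off = hd_offset(spec, 3, 3)
    i, j = spec.hd_targets[0] - 1, spec.hd_targets[1] - 1
    assert off[i] @ off[j] == pytest.approx(0.0)
    assert np.linalg.norm(off[i]) > 0 and np.linalg.norm(off[j]) > 0


def test_reference_patriline_has_zero_offset():
    spec = Treatment.from_name("T5p").spec
    np.testing.assert_array_equal(hd_offset(spec, 1, 5), 0.0)


def test_offsets_zero_off_target_and_gradient():
    spec = Treatment.from_name("T5p").spec
    mf = 5
    mask = np.ones(spec.k, dtype=bool)
    mask[[t - 1 for t in spec.hd_targets]] = False
    mags = []
    for p in range(1, mf + 1):
        off = hd_offset(spec, p, mf)
        np.testing.assert_array_equal(off[mask], 0.0)
        mags.append(np.linalg.norm(off[spec.hd_targets[0] - 1]))
    expected = spec.hd_magnitude * (np.arange(mf)) / (mf - 1)
    np.testing.assert_allclose(mags, expected)


def test_hd6_inflates_with_mating_frequency():
    hd5 = Treatment.from_name("T5p").spec
    hd6 = Treatment.from_name("T6p").spec
    for mf, factor in [(3, 1.0), (5, 1.1), (10, 1.35), (20, 1.85)]:
        a = hd_offset(hd5, mf, mf)
        b = hd_offset(hd6, mf, mf)
        np.testing.assert_allclose(b, factor * a, rtol=1e-12)


def test_hd_offset_preconditions():
    spec = Treatment.from_name("T1").spec
    with pytest.raises(ValueError):
        hd_offset(spec, 1, 1)
    with pytest.raises(ValueError):
        hd_offset(spec, 3, 2)


def test_spec_validation():
    with pytest.raises(ValueError, match="HD"):
        DeformationSpec(hd_type="HD4")
    with pytest.raises(ValueError, match="magnitude"):
        DeformationSpec(hd_magnitude=-0.1)
    with pytest.raises(ValueError, match="distinct"):
        DeformationSpec(hd_targets=(9, 9))
    with pytest.raises(ValueError, match="orientation"):
        DeformationSpec(orientation="diagonal")


# ----------------------------------------------------------------- the fixture

def test_default_template_is_unit_size_and_centered():
    mean = default_mean_shape()
    assert mean.shape == (14, 2)
    np.testing.assert_allclose(mean.mean(axis=0), 0.0, atol=1e-12)
    assert centroid_size(mean) == pytest.approx(1.0)


def test_default_slopes_avoid_targets_and_similarity_directions():
    mean = default_mean_shape()
    v = default_allometry_slopes().reshape(14, 2)
    np.testing.assert_array_equal(v[[8, 9]], 0.0)  # heritable targets untouched
    flat = v.reshape(-1)
    for direction in (
        np.column_stack([np.ones(14), np.zeros(14)]).reshape(-1),
        np.column_stack([np.zeros(14), np.ones(14)]).reshape(-1),
        mean.reshape(-1),
        np.column_stack([-mean[:, 1], mean[:, 0]]).reshape(-1),
    ):
        assert abs(flat @ direction) < 1e-10


# --------------------------------------------------------------------- datasets

def test_deterministic_limit_is_pure_allometry():
    t = Treatment.from_name("T1", noise_sd=0.0)
    t = t.with_magnitude(0.0)
    ds = simulate_dataset(t, n=10, mating_frequency=2, seed=3)
    spec = t.spec
    slopes = spec.ad_slopes.reshape(spec.k, 2)
    expected = spec.mean_shape[None] + slopes[None] * (ds.sizes - 1.0)[:, None, None]
    np.testing.assert_allclose(ds.shapes, expected, atol=1e-15)
    # raw coordinates are the shape scaled by the drawn size
    for c, s, sh in zip(ds.configs, ds.sizes, ds.shapes):
        np.testing.assert_allclose(c.landmarks, s * sh, atol=1e-15)


def test_patriline_mean_difference_equals_hd_displacement():
    # T1, 2 patrilines, no noise: shape-space group-mean difference at the
    # target landmarks is exactly the standard displacement
    t = Treatment.from_name("T1", noise_sd=0.0)
    ds = simulate_dataset(t, n=50, mating_frequency=2, seed=11)
    g1 = ds.shapes[ds.patriline_indices == 1]
    g2 = ds.shapes[ds.patriline_indices == 2]
    diff = g2.mean(axis=0) - g1.mean(axis=0)
    np.testing.assert_allclose(diff[8], [0.0, STANDARD_HD_MAGNITUDE], atol=1e-12)
    np.testing.assert_allclose(diff[9], [0.0, STANDARD_HD_MAGNITUDE], atol=1e-12)


def test_seed_reproducibility_and_divergence():
    t = Treatment.from_name("T1")
    a = simulate_dataset(t, n=20, mating_frequency=2, seed=5)
    b = simulate_dataset(t, n=20, mating_frequency=2, seed=5)
    c = simulate_dataset(t, n=20, mating_frequency=2, seed=6)
    for x, y in zip(a.configs, b.configs):
        np.testing.assert_array_equal(x.landmarks, y.landmarks)
    np.testing.assert_array_equal(a.sizes, b.sizes)
    assert not np.allclose(a.configs[0].landmarks, c.configs[0].landmarks)


def test_toggling_hd_does_not_shift_noise_stream():
    base = Treatment.from_name("T1")
    a = simulate_dataset(base, n=12, mating_frequency=2, seed=9)
    b = simulate_dataset(base.with_magnitude(0.0), n=12, mating_frequency=2, seed=9)
    np.testing.assert_array_equal(a.sizes, b.sizes)
    # reference patriline untouched by HD: identical raw coordinates
    ref = a.patriline_indices == 1
    np.testing.assert_array_equal(
        np.stack([c.landmarks for c in a.configs])[ref],
        np.stack([c.landmarks for c in b.configs])[ref])


def test_patriline_blocks_near_equal():
    t = Treatment.from_name("T5p")
    ds = simulate_dataset(t, n=100, mating_frequency=3, seed=1)
    counts = np.bincount(ds.patriline_indices)[1:]
    assert counts.tolist() == [34, 33, 33]
    assert ds.pedigree.patrilines == ["P1", "P2", "P3"]
    assert len(ds.pedigree) == 100


def test_noise_sd_recovered_within_three_percent():
    # ND-only dataset: no allometry, no heritable signal, unit sizes
    sd = np.linspace(0.002, 0.006, 14)
    spec = DeformationSpec(ad_slopes=np.zeros(28), size_log_sigma=0.0,
                           nd_sd=sd, hd_magnitude=0.0)
    t = Treatment("ND-only", spec)
    ds = simulate_dataset(t, n=5000, mating_frequency=2, seed=21)
    dev = ds.shapes - spec.mean_shape[None]
    est = dev.std(axis=0, ddof=1)  # (k, 2) per-landmark, per-axis SD
    np.testing.assert_allclose(est, np.repeat(sd, 2).reshape(14, 2), rtol=0.03)


def test_truth_record_roundtrip():
    t = Treatment.from_name("T6o")
    ds = simulate_dataset(t, n=30, mating_frequency=5, seed=17)
    truth = ds.truth()
    assert truth["treatment"] == "T6o"
    assert truth["hd_type"] == "HD6"
    assert truth["mating_frequency"] == 5
    assert truth["seed"] == 17


# ------------------------------------------------------------ pipeline geometry

def test_allometry_dominates_pc1_and_heritable_signal_separates_on_pc2():
    t = Treatment.from_name("T1", noise_sd=0.002)
    ds = simulate_dataset(t, n=100, mating_frequency=2, seed=23)
    shapes = gpa_align(ds.configs)
    pca = tangent_pca(shapes)
    # PC1 carries the allometric signal
    assert pca.variance_fractions[0] > 0.5
    assert abs(np.corrcoef(pca.score(1), shapes.centroid_sizes)[0, 1]) > 0.95
    # patrilines separate on PC2
    pc2 = pca.score(2)
    g1 = pc2[ds.patriline_indices == 1]
    g2 = pc2[ds.patriline_indices == 2]
    gap = abs(g1.mean() - g2.mean())
    pooled = np.sqrt((g1.var(ddof=1) + g2.var(ddof=1)) / 2)
    assert gap > 2 * pooled


def test_full_recovery_on_one_replicate():
    t = Treatment.from_name("T5p", noise_sd=0.002)
    ds = simulate_dataset(t, n=100, mating_frequency=3, seed=29)
    fits = analyze_dataset(ds)
    assert fits[1].significant and fits[1].h2 > 0.0
    assert not fits[0].significant


def test_fit_allometry_recovers_generating_slopes():
    # exact recovery holds in the tangent regime (small slope norm); at the
    # default norm the unit-size normalization adds a small curvature term
    from gmherit import DeformationSpec, fit_allometry
    for norm, tol in [(1e-4, 1e-6), (0.04, 5e-4)]:
        slopes = default_allometry_slopes(norm=norm)
        spec = DeformationSpec(ad_slopes=slopes, nd_sd=0.0, hd_magnitude=0.0)
        ds = simulate_dataset(Treatment("AD-only", spec), n=200,
                              mating_frequency=2, seed=5)
        allom = fit_allometry(gpa_align(ds.configs))
        assert np.max(np.abs(allom.slopes - slopes)) < tol
        assert abs(allom.cac @ (slopes / np.linalg.norm(slopes))) > 0.9998
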