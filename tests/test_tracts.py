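import numpy as np
import pandas as pd
import pytest

from ieegface.simulate import SyntheticStreamlineSet, simulate_tract_endpoints
from ieegface import tracts as tr


def _line(a, b, n=10):
    frac = np.linspace(0, 1, n)[:, None]
    return np.asarray(a, float) + frac * (np.asarray(b, float) - np.asarray(a, float))


def _set(streamlines, name="t", subj="s0"):
    return SyntheticStreamlineSet(name, subj, streamlines)


GRID = tr.VoxelGrid(origin=(-10.0, -10.0, -10.0), shape=(60, 24, 24))


# ----------------------------------------------------------------- cleaning

def test_identical_streamlines_none_removed():
    s = _set([_line((0, 0, 0), (20, 0, 0))] * 10)
    out = tr.clean_streamline_outliers(s)
    assert len(out.streamlines) == 10


def test_extreme_length_outlier_removed():
    base = [_line((0, 0, 0), (20, 0, 0)) + 0.01 * i for i in range(100)]
    long_one = _line((0, 0, 0), (200, 0, 0))
    out = tr.clean_streamline_outliers(_set(base + [long_one]))
    assert len(out.streamlines) == 100
    assert not any(np.allclose(s, long_one) for s in out.streamlines)


def test_cleaning_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    sl = [_line(rng.normal(0, 3, 3), rng.normal((20, 0, 0), 3))
          for _ in range(50)]
    out = tr.clean_streamline_outliers(_set(sl), n_sd=1.0)

    # independent brute-force transcription of the rule
    lengths = np.array([np.sum(np.sqrt(np.sum(np.diff(s, axis=0) ** 2, 1)))
                        for s in sl])
    cents = np.array([s.mean(axis=0) for s in sl])
    d = np.sqrt(np.sum((cents - cents.mean(0)) ** 2, 1))
    keep = ((d - d.mean()) <= 1.0 * d.std()) & \
           (np.abs(lengths - lengths.mean()) <= 1.0 * lengths.std())
    expected = [s for s, k in zip(sl, keep) if k]
    assert len(out.streamlines) == len(expected)
    for a, b in zip(out.streamlines, expected):
        np.testing.assert_array_equal(a, b)


def test_cleaning_degenerate_inputs():
    with pytest.raises(ValueError):
        tr.clean_streamline_outliers(_set([_line((0, 0, 0), (1, 0, 0))]))


# -------------------------------------------------------------- reorientation

def test_reorient_aligned_identity_and_single():
    sl = [_line((0, 0, 0), (20, 0, 0)) + 0.1 * i for i in range(5)]
    out = tr.reorient_streamlines(_set(sl))
    for a, b in zip(out.streamlines, sl):
        np.testing.assert_array_equal(a, b)
    single = tr.reorient_streamlines(_set([sl[0]]))
    np.testing.assert_array_equal(single.streamlines[0], sl[0])


def test_reorient_half_reversed_endpoints_cohere():
    rng = np.random.default_rng(1)
    sl = []
    for i in range(40):
        s = _line((0, 0, 0), (20, 0, 0)) + rng.normal(0, 0.5, 3)
        sl.append(s[::-1] if i % 2 else s)
    out = tr.reorient_streamlines(_set(sl))
    firsts = np.array([s[0] for s in out.streamlines])
    lasts = np.array([s[-1] for s in out.streamlines])
    # brute-force pairing oracle: every 'first' node nearer its own
    # collection centroid than the other one
    c0, c1 = firsts.mean(0), lasts.mean(0)
    assert np.all(np.linalg.norm(firsts - c0, axis=1)
                  < np.linalg.norm(firsts - c1, axis=1))
    assert np.all(np.linalg.norm(lasts - c1, axis=1)
                  < np.linalg.norm(lasts - c0, axis=1))


# ------------------------------------------------------------- density maps

def test_density_counts_preserved_with_and_without_smoothing():
    sets = simulate_tract_endpoints(1, [("t", (0.5, 0.5, 0.5),
                                         (30.5, 0.5, 0.5))],
                                    scatter_sd=1.0, rng_seed=0,
                                    n_streamlines=37)
    s = tr.reorient_streamlines(sets[0])
    raw = tr.endpoint_density_map(s, "first", GRID, smoothing_radius_mm=0)
    assert raw.data.sum() == pytest.approx(37)
    sm = tr.endpoint_density_map(s, "first", GRID, smoothing_radius_mm=3)
    assert sm.data.sum() == pytest.approx(37, abs=1e-9)


def test_smoothing_footprint_matches_geometric_oracle():
    """A single endpoint spreads exactly to voxels within 3 mm."""
    s = _set([_line((10.2, 0.7, 0.3), (30.0, 0.0, 0.0))])
    vol = tr.endpoint_density_map(s, "first", GRID, smoothing_radius_mm=3)
    nz = np.argwhere(vol.data > 0)
    center = GRID.voxel_of((10.2, 0.7, 0.3))
    dist = np.linalg.norm(nz - center, axis=1)
    assert np.all(dist <= 3.0)
    expected = sum(1 for i in range(-3, 4) for j in range(-3, 4)
                   for k in range(-3, 4) if i * i + j * j + k * k <= 9)
    assert len(nz) == expected


def test_density_invariant_to_streamline_order():
    rng = np.random.default_rng(5)
    sl = [_line(rng.normal(0, 1, 3), rng.normal((20, 0, 0), 1))
          for _ in range(20)]
    a = tr.endpoint_density_map(_set(sl), "first", GRID)
    b = tr.endpoint_density_map(_set(sl[::-1]), "first", GRID)
    np.testing.assert_allclose(a.data, b.data, atol=1e-12)


def test_density_errors():
    with pytest.raises(ValueError):
        tr.endpoint_density_map(_set([_line((0, 0, 0), (1, 0, 0))]), "middle",
                                GRID)
    far = _set([_line((500, 0, 0), (520, 0, 0))])
    with pytest.raises(ValueError, match="cover"):
        tr.endpoint_density_map(far, "first", GRID)


# -------------------------------------------------------------- group masks

def _volume_with_peak(count=5.0):
    s = _set([_line((0.5, 0.5, 0.5), (30.5, 0.5, 0.5))] * int(count))
    return tr.endpoint_density_map(s, "first", GRID, smoothing_radius_mm=0)


def test_group_mask_counts_subjects():
    vols = [_volume_with_peak() for _ in range(10)]
    mask = tr.group_endpoint_mask(vols)
    assert mask.counts.max() == 10
    assert mask.n_subjects == 10


def test_group_mask_threshold_is_strict():
    """A voxel exactly at the threshold is excluded (strict >)."""
    vol = _volume_with_peak(count=1.0)
    vol.data[vol.data > 0] = 0.01  # normalized density exactly 0.01
    mask = tr.group_endpoint_mask([vol], density_threshold=0.01,
                                  normalized=False)
    assert mask.counts.max() == 0


def test_group_mask_disjoint_subjects():
    v1 = _volume_with_peak()
    s2 = _set([_line((40.5, 0.5, 0.5), (20.5, 10.5, 0.5))] * 5)
    v2 = tr.endpoint_density_map(s2, "first", GRID, smoothing_radius_mm=0)
    mask = tr.group_endpoint_mask([v1, v2])
    assert mask.counts.max() == 1


def test_group_mask_grid_mismatch():
    other = tr.VoxelGrid(origin=(0.0, 0.0, 0.0), shape=(10, 10, 10))
    v1 = _volume_with_peak()
    v2 = tr.EndpointDensityVolume(np.zeros(other.shape), other, "t", "s1",
                                  "first")
    with pytest.raises(ValueError):
        tr.group_endpoint_mask([v1, v2])


# ------------------------------------------------------------------ overlap

def _mask_at(points, n_support, tract="t"):
    counts = np.zeros(GRID.shape)
    for p in points:
        v = GRID.voxel_of(p)
        counts[tuple(v)] = n_support
    return tr.GroupEndpointMask(counts=counts, grid=GRID, tract_name=tract,
                                n_subjects=n_support)


def test_overlap_proportions_and_dropped_columns():
    sites = pd.DataFrame([
        {"roi": "IOC", "response_class": "Face1", "x": 0.5, "y": 0.5, "z": 0.5},
        {"roi": "IOC", "response_class": "Face1", "x": 20.5, "y": 0.5, "z": 0.5},
        {"roi": "STC", "response_class": "Face2_only", "x": 0.5, "y": 0.5,
         "z": 0.5},
    ])
    masks = {"hit": _mask_at([(0.5, 0.5, 0.5)], 150),
             "miss": _mask_at([(40.5, 10.5, 10.5)], 150)}
    out = tr.compute_overlap(sites, masks)
    tbl = out.table.set_index(["roi", "response_class"])
    assert tbl.loc[("IOC", "Face1"), "hit"] == pytest.approx(0.5)
    assert tbl.loc[("STC", "Face2_only"), "hit"] == pytest.approx(1.0)
    assert out.dropped_columns == ["miss"]
    assert "miss" not in out.table.columns


def test_overlap_insufficient_subject_support_zero():
    """Masks supported by 99 subjects yield zero overlap regardless of
    geometry."""
    sites = pd.DataFrame([{"roi": "IOC", "response_class": "Face1",
                           "x": 0.5, "y": 0.5, "z": 0.5}])
    masks = {"t": _mask_at([(0.5, 0.5, 0.5)], 99)}
    out = tr.compute_overlap(sites, masks)
    assert out.dropped_columns == ["t"]


def test_overlap_site_outside_grid_warns():
    sites = pd.DataFrame([{"roi": "IOC", "response_class": "Face1",
                           "x": 500.0, "y": 0.5, "z": 0.5}])
    masks = {"t": _mask_at([(0.5, 0.5, 0.5)], 150)}
    with pytest.warns(UserWarning, match="outside"):
        out = tr.compute_overlap(sites, masks)
    assert out.dropped_columns == ["t"]


def test_overlap_monotone_in_validity_threshold():
    rng = np.random.default_rng(9)
    counts = rng.integers(0, 200, size=GRID.shape).astype(float)
    mask = tr.GroupEndpointMask(counts=counts, grid=GRID, tract_name="t",
                                n_subjects=200)
    sites = pd.DataFrame([{"roi": "IOC", "response_class": "Face1",
                           "x": float(x) + 0.5, "y": 0.5, "z": 0.5}
                          for x in range(20)])
    vals = [tr.compute_overlap(sites, {"t": mask}, validity_threshold=v)
            .table.get("t", pd.Series([0.0])).iloc[0]
            for v in (50, 100, 150, 190)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


# ----------------------------------------------------------- end-to-end

def test_constructed_tract_targets_ioc_cluster():
    """A tract terminating at the IOC electrode cluster scores highest on
    the IOC row."""
    ioc_xyz = (30.5, 0.5, 0.5)
    stc_xyz = (45.5, 10.5, 10.5)
    sets = simulate_tract_endpoints(
        120, [("to_ioc", (0.5, 0.5, 0.5), ioc_xyz)], scatter_sd=1.0,
        rng_seed=4, n_streamlines=30)
    masks = tr.subject_density_maps(sets, grid=GRID, collection="last")
    sites = pd.DataFrame(
        [{"roi": "IOC", "response_class": "Face1",
          "x": ioc_xyz[0] + dx, "y": ioc_xyz[1], "z": ioc_xyz[2]}
         for dx in (-1.0, 0.0, 1.0)] +
        [{"roi": "STC", "response_class": "Face1",
          "x": stc_xyz[0] + dx, "y": stc_xyz[1], "z": stc_xyz[2]}
         for dx in (-1.0, 0.0, 1.0)])
    out = tr.compute_overlap(sites, masks, validity_threshold=100)
    tbl = out.table.set_index("roi")
    assert tbl.loc["IOC", "to_ioc"] > tbl.loc["STC", "to_ioc"]
    assert tbl.loc["IOC", "to_ioc"] == pytest.approx(1.0)
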