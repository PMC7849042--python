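"""features module: structure, geometric/intensity oracles, GLCM brute-force
oracle, measure selection and correlation pruning."""

import numpy as np
import pytest
from skimage import morphology

from mscpheno.features import (
    ALL_FEATURES,
    FIRST_ORDER_FEATURES,
    SECOND_ORDER_FEATURES,
    SHAPE_FEATURES,
    SIZE_FEATURES,
    CellRecord,
    correlation_filter,
    extract_cell_record,
    extract_records,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glcm_offsets,
    glcm_statistics,
    quantize,
    select_best_measure,
    shape_features,
    size_features,
)


def _variants(shape, rng=None):
    rng = rng or np.random.default_rng(6)
    return {
        "gray": rng.random(shape),
        "preprocessed": rng.random(shape),
        "reconstructed": rng.random(shape),
    }


# ------------------------------------------------------------- structure


def test_exactly_thirty_named_features():
    assert len(ALL_FEATURES) == 30
    assert len(SIZE_FEATURES) == 6
    assert len(SHAPE_FEATURES) == 6
    assert len(FIRST_ORDER_FEATURES) == 9
    assert len(SECOND_ORDER_FEATURES) == 9
    assert len(set(ALL_FEATURES)) == 30


def test_measure_multiplicity_per_feature():
    mask = np.zeros((40, 40), bool)
    mask[10:30, 10:30] = True
    rec = extract_cell_record(mask, _variants((40, 40)), "img", 1)
    assert set(rec.raw_measures) == set(ALL_FEATURES)
    for f in SIZE_FEATURES + SHAPE_FEATURES:
        assert len(rec.raw_measures[f]) == 1  # purely geometric
    for f in FIRST_ORDER_FEATURES:
        assert len(rec.raw_measures[f]) == 3  # one per image rendition
    for f in SECOND_ORDER_FEATURES:
        assert len(rec.raw_measures[f]) == 72  # 24 orientations x 3 renditions


def test_glcm_offsets_schemes():
    a24 = glcm_offsets("angles24")
    assert len(a24) == 24
    assert a24[0] == ("a000", (0, 1))
    assert a24[6] == ("a090", (-1, 0))
    a83 = glcm_offsets("angles8x3dist")
    assert len(a83) == 24
    with pytest.raises(ValueError):
        glcm_offsets("nope")


def test_extract_cell_record_requires_all_variants():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    with pytest.raises(ValueError):
        extract_cell_record(mask, {"gray": np.zeros((20, 20))}, "img", 1)


def test_extract_records_skips_tiny_masks():
    labels = np.zeros((30, 30), np.int32)
    labels[5:15, 5:15] = 1
    labels[20:22, 20:22] = 2  # 4 px < 5
    recs = extract_records(labels, _variants((30, 30)), "img")
    assert [r.cell_id for r in recs] == [1]


# ------------------------------------------------------------- size/shape


def test_size_features_disk_oracle():
    r = 25
    mask = np.pad(morphology.disk(r), 4).astype(bool)
    s = size_features(mask, pixels_per_micron=1.0)
    assert s["area"] == pytest.approx(np.pi * r**2, rel=0.05)
    assert s["perimeter"] == pytest.approx(2 * np.pi * r, rel=0.05)
    assert s["width"] == 2 * r + 1
    assert s["height"] == 2 * r + 1
    assert s["major_axis"] == pytest.approx(2 * r, rel=0.05)


def test_size_features_micron_scaling():
    mask = np.zeros((40, 40), bool)
    mask[10:30, 10:30] = True
    s1 = size_features(mask, pixels_per_micron=1.0)
    s2 = size_features(mask, pixels_per_micron=2.0)
    assert s2["area"] == pytest.approx(s1["area"] / 4.0)
    assert s2["perimeter"] == pytest.approx(s1["perimeter"] / 2.0)


def test_shape_features_disk_and_bar():
    disk = np.pad(morphology.disk(15), 2).astype(bool)
    s = shape_features(disk)
    assert s["circularity"] > 0.9
    assert s["ellipticity"] < 0.1
    assert s["elongation"] == pytest.approx(1.0, abs=0.05)
    assert s["solidity"] > 0.95
    bar = np.zeros((40, 60), bool)
    bar[18:22, 2:58] = True
    s = shape_features(bar)
    assert s["ellipticity"] > 0.9
    assert s["elongation"] > 5
    assert s["compactness"] > 1.0 / 0.5  # far from a disk


# ------------------------------------------------------------- first order


def test_first_order_oracle_values():
    mask = np.ones((1, 5), bool)
    img = np.array([[0.1, 0.2, 0.3, 0.4, 0.5]])
    fo = first_order_features(mask, img)
    assert fo["mean_intensity"] == pytest.approx(0.3)
    assert fo["median"] == pytest.approx(0.3)
    assert fo["std"] == pytest.approx(np.std(img))
    assert fo["variance"] == pytest.approx(np.var(img))
    assert fo["intensity_profile"] == pytest.approx(
        np.quantile(img, 0.9) - np.quantile(img, 0.1)
    )
    assert fo["balance"] == pytest.approx(0.0)  # symmetric -> mean == median


def test_first_order_constant_region():
    mask = np.ones((3, 3), bool)
    img = np.full((3, 3), 0.25)
    fo = first_order_features(mask, img)
    assert fo["std"] == 0.0
    assert fo["skewness"] == 0.0
    assert fo["kurtosis"] == 0.0
    assert fo["balance"] == 0.0
    assert fo["mode"] == pytest.approx(0.25, abs=1 / 255)


def test_first_order_mode():
    mask = np.ones((1, 6), bool)
    img = np.array([[0.2, 0.2, 0.2, 0.8, 0.9, 1.0]])
    fo = first_order_features(mask, img)
    assert fo["mode"] == pytest.approx(np.round(0.2 * 255) / 255)


# ------------------------------------------------------------- GLCM


def _brute_force_glcm(quantized, offset, levels):
    """Oracle: enumerate every pixel pair explicitly."""
    dr, dc = offset
    h, w = quantized.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = quantized[r, c], quantized[r2, c2]
                if a >= 0 and b >= 0:
                    counts[a, b] += 1
                    counts[b, a] += 1
    total = counts.sum()
    return counts / total if total else counts


def test_glcm_matrix_equals_brute_force_all_24_orientations():
    rng = np.random.default_rng(7)
    levels = 8
    for trial in range(3):
        img = rng.random((5, 5))
        mask = rng.random((5, 5)) > 0.2
        mask[2, 2] = True  # never fully empty
        q = quantize(img, mask, levels)
        for key, offset in glcm_offsets("angles24"):
            got = glcm_matrix(q, offset, levels)
            want = _brute_force_glcm(q, offset, levels)
            assert np.allclose(got, want), (trial, key)


def test_glcm_matrix_symmetric_and_normalised():
    rng = np.random.default_rng(8)
    img = rng.random((9, 9))
    mask = np.ones((9, 9), bool)
    q = quantize(img, mask, 16)
    p = glcm_matrix(q, (0, 1), 16)
    assert np.allclose(p, p.T)
    assert p.sum() == pytest.approx(1.0)


def test_glcm_statistics_hand_oracle():
    # two-level matrix with known marginals
    p = np.array([[0.4, 0.1], [0.1, 0.4]])
    st = glcm_statistics(p)
    # mu = 0.5, sigma^2 = 0.25; E[(i-mu)(j-mu)] = 0.25*(0.4+0.4) - 0.25*(0.2)
    assert st["glcm_energy"] == pytest.approx(0.16 + 0.01 + 0.01 + 0.16)
    assert st["glcm_inertia"] == pytest.approx(0.2)  # sum (i-j)^2 p
    assert st["glcm_dissimilarity"] == pytest.approx(0.2)
    assert st["glcm_max_probability"] == pytest.approx(0.4)
    assert st["glcm_homogeneity"] == pytest.approx(0.8 + 0.2 / 2)
    assert st["glcm_entropy"] == pytest.approx(
        -(2 * 0.4 * np.log2(0.4) + 2 * 0.1 * np.log2(0.1))
    )
    # mu=0.5, sigma=0.5: covariance = 0.25*(0.4+0.4) - 0.25*(0.1+0.1) = 0.15
    assert st["glcm_correlation"] == pytest.approx(0.15 / 0.25)


def test_glcm_constant_region_degenerate():
    mask = np.ones((6, 6), bool)
    img = np.full((6, 6), 0.5)
    st = glcm_features(mask, img, (0, 1), levels=8)
    assert st["glcm_correlation"] == 1.0  # zero variance convention
    assert st["glcm_energy"] == pytest.approx(1.0)
    assert st["glcm_inertia"] == 0.0


def test_quantize_bounds_and_mask():
    rng = np.random.default_rng(9)
    img = rng.random((10, 10))
    mask = np.zeros((10, 10), bool)
    mask[2:8, 2:8] = True
    q = quantize(img, mask, 32)
    assert (q[~mask] == -1).all()
    inside = q[mask]
    assert inside.min() >= 0 and inside.max() <= 31
    # extremes of the masked range hit the first and last level
    assert inside.min() == 0 and inside.max() == 31


# ------------------------------------------------------------- selection


def _toy_records(n=40, seed=10):
    """Records with a known best measure: 'geom' separates, others are noise."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        sr = i % 2 == 1
        raw = {}
        for f in ALL_FEATURES:
            raw[f] = {
                "geom": (2.0 if sr else 0.0) + rng.normal(0, 0.1),
                "noise": rng.normal(0, 1),
            }
        records.append(
            CellRecord(
                image_id="t",
                cell_id=i + 1,
                raw_measures=raw,
                phenotype="SR" if sr else "RS",
            )
        )
    return records


def test_select_best_measure_picks_separating_measure():
    records = _toy_records()
    sel = select_best_measure(records)
    assert all(sel.chosen[f] == "geom" for f in ALL_FEATURES)
    assert all(sel.auc[f] > 0.95 for f in ALL_FEATURES)


def test_select_best_measure_folds_auc():
    # inverted separation still counts: AUC folded as max(auc, 1-auc)
    records = _toy_records()
    for r in records:
        for f in ALL_FEATURES:
            r.raw_measures[f]["geom"] *= -1.0
    sel = select_best_measure(records)
    assert all(sel.auc[f] > 0.95 for f in ALL_FEATURES)


def test_select_best_measure_requires_both_classes():
    records = _toy_records()
    for r in records:
        r.phenotype = "RS"
    with pytest.raises(ValueError):
        select_best_measure(records)


def test_correlation_filter_prunes_duplicates():
    records = _toy_records()
    sel = select_best_measure(records)
    # all 'geom' measures are near-identical -> heavy pruning
    out = correlation_filter(sel, records, max_corr=0.8)
    assert len(out.retained) < len(ALL_FEATURES)
    # retained features are pairwise below the correlation cutoff
    vals = {
        f: np.array([r.raw_measures[f][out.chosen[f]] for r in records])
        for f in out.retained
    }
    for i, f in enumerate(out.retained):
        for g in out.retained[i + 1 :]:
            assert abs(np.corrcoef(vals[f], vals[g])[0, 1]) <= 0.8 + 1e-9


def test_selection_vector_roundtrip():
    records = _toy_records()
    sel = correlation_filter(select_best_measure(records), records)
    v = sel.vector(records[0])
    assert v.shape == (len(sel.retained),)
    from mscpheno.features import FeatureSelection

    back = FeatureSelection.from_dict(sel.to_dict())
    assert np.array_equal(back.vector(records[0]), v)
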