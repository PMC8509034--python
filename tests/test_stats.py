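"""Normalisation, group averaging, difference profiles and per-segment tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import plf
from plf.errors import CompositeScaleError
from plf.segmentation import SampleKey, SegmentCountMatrix
from plf.stats import NormalizedSegmentMatrix, star_annotation


def _matrix(counts, groups=None, region="r", acc="P1"):
    counts = np.asarray(counts)
    n_samples, n_segments = counts.shape
    if groups is None:
        groups = ["young"] * (n_samples // 2) + ["aged"] * (n_samples - n_samples // 2)
    samples = [SampleKey(f"s{i}", g) for i, g in enumerate(groups)]
    segments = plf.segment_boundaries(n_segments * 50, 50)
    return SegmentCountMatrix(
        accession=acc, region=region, segments=segments, samples=samples,
        counts=counts,
    )


def _normalized(values, groups, acc="P1", region="r"):
    values = np.asarray(values, dtype=float)
    samples = [SampleKey(f"s{i}", g) for i, g in enumerate(groups)]
    segments = plf.segment_boundaries(values.shape[1] * 50, 50)
    return NormalizedSegmentMatrix(
        accession=acc, region=region, segments=segments, samples=samples,
        values=values, median_total=float(values.sum(axis=1).mean()),
    )


# ----------------------------------------------------------------- normalisation


def test_normalize_scales_every_row_to_the_median_total():
    # row totals [10, 20, 30, 40] -> median anchor 25, factors [2.5, 1.25, 25/30, 0.625]
    counts = np.array([[10, 0], [10, 10], [20, 10], [30, 10]])
    nm = plf.normalize_matrix(_matrix(counts))
    assert nm.median_total == 25
    np.testing.assert_allclose(nm.values.sum(axis=1), 25, rtol=1e-12)
    np.testing.assert_allclose(nm.values[0], [25, 0])
    np.testing.assert_allclose(nm.values[3], [18.75, 6.25])


def test_normalize_identity_when_totals_already_equal():
    counts = np.array([[5, 5], [4, 6], [9, 1], [2, 8]])
    nm = plf.normalize_matrix(_matrix(counts))
    np.testing.assert_array_equal(nm.values, counts.astype(float))


def test_normalize_drops_zero_total_rows_from_matrix_and_median():
    counts = np.array([[0, 0], [8, 4], [9, 9]])
    nm = plf.normalize_matrix(_matrix(counts, ["young", "young", "aged"]))
    assert nm.median_total == 15  # median over the positive totals {12, 18}
    assert [s.sample_id for s in nm.samples] == ["s1", "s2"]
    assert [s.sample_id for s in nm.dropped_samples] == ["s0"]


def test_normalize_all_zero_protein_reported_undetected():
    nm = plf.normalize_matrix(_matrix(np.zeros((3, 2), dtype=int)))
    assert nm.samples == [] and nm.values.shape == (0, 2)
    assert math.isnan(nm.median_total)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(data=st.data())
def test_normalization_conservation_and_abundance_invariance(data):
    """Every retained row sums to the anchor (rel. tol. 1e-9), and scaling a
    raw row by any positive constant changes the normalized matrix only by
    the common anchor ratio — so the fingerprint, and every group statistic
    computed from it, is independent of whole-protein abundance."""
    n_samples = data.draw(st.integers(2, 8))
    n_segments = data.draw(st.integers(1, 12))
    counts = np.array(
        [
            [data.draw(st.integers(0, 50)) for _ in range(n_segments)]
            for _ in range(n_samples)
        ]
    )
    nm = plf.normalize_matrix(_matrix(counts))
    if nm.values.size:
        np.testing.assert_allclose(
            nm.values.sum(axis=1), nm.median_total, rtol=1e-9
        )
    # abundance invariance on an arbitrary positive-total row
    totals = counts.sum(axis=1)
    if (totals > 0).any():
        i = int(np.flatnonzero(totals > 0)[0])
        c = data.draw(st.floats(0.1, 20.0, allow_nan=False))
        scaled = counts.astype(float).copy()
        scaled[i] *= c
        nm2 = plf.normalize_matrix(_matrix(scaled))
        np.testing.assert_allclose(
            nm2.values * (nm.median_total / nm2.median_total),
            nm.values, rtol=1e-9,
        )


# --------------------------------------------------------------- group averaging


def test_group_average_mean_and_sample_sd():
    nm = _normalized([[2, 0], [4, 0], [6, 0], [1, 1], [1, 1], [1, 1]],
                     ["young"] * 3 + ["aged"] * 3)
    s = plf.group_average(nm)
    assert s.mean_young[0] == 4 and s.sd_young[0] == 2
    assert s.mean_aged[0] == 1 and s.sd_aged[0] == 0


def test_group_average_one_group_only_is_excluded():
    nm = _normalized([[2, 0], [4, 0]], ["aged", "aged"])
    assert plf.group_average(nm) is None


def test_group_average_single_sample_group_flagged_untestable():
    nm = _normalized([[2, 0], [4, 0], [3, 1]], ["young", "young", "aged"])
    s = plf.group_average(nm)
    assert not s.testable
    assert np.isnan(s.sd_aged).all()
    # the difference profile is still computable
    prof = plf.difference_profile(s)
    assert prof.values.shape == (2,)


# ------------------------------------------------------------ difference profile


def _summary(mean_young, mean_aged, protein_length, nominal=50):
    segs = plf.segment_boundaries(protein_length, nominal)
    z = np.zeros(len(segs))
    return plf.stats.GroupSummary(
        accession="P1", region="r", segments=segs, n_young=3, n_aged=3,
        mean_young=np.asarray(mean_young, float),
        mean_aged=np.asarray(mean_aged, float),
        sd_young=z, sd_aged=z,
    )


def test_difference_profile_sign_and_scale():
    s = _summary([3, 1], [5, 1], 100)
    prof = plf.difference_profile(s)
    np.testing.assert_allclose(prof.values, [0.04, 0.0])  # positive = higher in aged


def test_difference_profile_tail_modes():
    # 66-residue protein: tail segment is 16 residues long
    s = _summary([0, 0], [1, 1], 66)
    actual = plf.difference_profile(s, "actual", 50)
    strict = plf.difference_profile(s, "nominal", 50)
    assert actual.values[1] == pytest.approx(1 / 16)
    assert strict.values[1] == pytest.approx(1 / 50)
    assert actual.values[0] == strict.values[0] == pytest.approx(1 / 50)


# -------------------------------------------------------------------- testing


def _pooled_t_oracle(young, aged):
    """Independently coded closed-form pooled two-sample t, two-sided."""
    young, aged = np.asarray(young, float), np.asarray(aged, float)
    n1, n2 = len(young), len(aged)
    sp2 = ((n1 - 1) * young.var(ddof=1) + (n2 - 1) * aged.var(ddof=1)) / (n1 + n2 - 2)
    t = (aged.mean() - young.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2 * sps.t.sf(abs(t), n1 + n2 - 2), t


def test_raw_p_matches_closed_form_pooled_t_oracle():
    nm = _normalized([[1], [2], [3], [4], [5], [6]], ["young"] * 3 + ["aged"] * 3)
    (res,) = plf.test_segments(nm)
    p_expected, t_expected = _pooled_t_oracle([1, 2, 3], [4, 5, 6])
    assert t_expected == pytest.approx(3 / math.sqrt(2 / 3), abs=1e-12)
    assert res.raw_p == pytest.approx(p_expected, abs=1e-10)
    assert res.raw_p == pytest.approx(0.021312, abs=5e-7)


def test_identical_groups_give_p_one_no_stars():
    nm = _normalized([[2, 1], [2, 2], [2, 3], [2, 1], [2, 2], [2, 3]],
                     ["young"] * 3 + ["aged"] * 3)
    res = plf.test_segments(nm)
    degenerate = next(r for r in res if r.segment.index == 1)
    assert degenerate.raw_p == 1.0 and degenerate.stars == ""


def test_all_zero_segments_excluded_from_bonferroni_family():
    vals = np.array(
        [[1, 0, 5], [2, 0, 6], [3, 0, 7], [4, 0, 1], [5, 0, 2], [6, 0, 3]], float
    )
    nm = _normalized(vals, ["young"] * 3 + ["aged"] * 3)
    res = plf.test_segments(nm)
    assert [r.segment.index for r in res] == [1, 3]  # m = 2, not 3
    for r in res:
        assert r.corrected_p == pytest.approx(min(1.0, r.raw_p * 2))


def test_bonferroni_capping_and_star_thresholds_exhaustively():
    ps = np.concatenate(
        [np.logspace(-6, 0, 200), [0.001, 0.01, 0.05, 1.0, 0.0009]]
    )
    for m in (1, 2, 5, 28, 100):
        for p in ps:
            corrected = min(1.0, p * m)
            stars = star_annotation(corrected)
            if corrected <= 0.001:
                assert stars == "***"
            elif corrected <= 0.01:
                assert stars == "**"
            elif corrected <= 0.05:
                assert stars == "*"
            else:
                assert stars == ""
    assert min(1.0, 0.0009 * 28) == pytest.approx(0.0252)
    assert star_annotation(0.0252) == "*"


def test_corrected_p_monotone_in_family_size():
    for p in (1e-5, 1e-3, 0.02, 0.3):
        corrected = [min(1.0, p * m) for m in range(1, 60)]
        assert corrected == sorted(corrected)


def test_group_label_symmetry():
    """Swapping young and aged negates the difference profile and leaves
    every p-value unchanged."""
    rng = np.random.default_rng(3)
    vals = rng.gamma(5, 3, size=(6, 8))
    groups = ["young"] * 3 + ["aged"] * 3
    swapped = ["aged"] * 3 + ["young"] * 3
    nm, nm_sw = _normalized(vals, groups), _normalized(vals, swapped)
    res, res_sw = plf.test_segments(nm), plf.test_segments(nm_sw)
    assert [r.raw_p for r in res] == [r.raw_p for r in res_sw]
    p = plf.difference_profile(plf.group_average(nm))
    p_sw = plf.difference_profile(plf.group_average(nm_sw))
    np.testing.assert_array_equal(p.values, -p_sw.values)


def test_flag_significant_proteins_threshold():
    seg = plf.segment_boundaries(50, 50)[0]

    def _res(acc, corrected):
        return plf.SegmentTestResult(
            accession=acc, region="r", segment=seg, mean_young=0, mean_aged=0,
            sd_young=0, sd_aged=0, raw_p=corrected, corrected_p=corrected,
            stars=star_annotation(corrected),
        )

    flagged = plf.flag_significant_proteins(
        [_res("A", 0.04), _res("B", 0.07), _res("B", 0.051)]
    )
    assert flagged == {"A"}


# ------------------------------------------------------------------- composite


def test_composite_scale_maps_each_region_to_unit_interval():
    scaled = plf.composite_scale(
        {"posterior": np.array([0.02, -0.04]), "anterior": np.array([0.0, 0.0])}
    )
    np.testing.assert_allclose(scaled["posterior"], [0.5, -1.0])
    np.testing.assert_array_equal(scaled["anterior"], [0.0, 0.0])


def test_composite_scale_requires_two_regions():
    with pytest.raises(CompositeScaleError):
        plf.composite_scale({"posterior": np.array([0.1])})
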