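"""Segment tiling, peptide-to-segment mapping and count aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plf
from plf.errors import DesignError, SegmentationError
from plf.segmentation import SampleKey


@pytest.mark.parametrize(
    "length,nominal,expected",
    [
        (120, 50, [(1, 50), (51, 100), (101, 120)]),
        (50, 50, [(1, 50)]),
        (101, 50, [(1, 50), (51, 100), (101, 101)]),
        (1, 50, [(1, 1)]),
        (7, 3, [(1, 3), (4, 6), (7, 7)]),
    ],
)
def test_segment_boundaries_tile_the_protein(length, nominal, expected):
    segs = plf.segment_boundaries(length, nominal)
    assert [(s.start, s.end) for s in segs] == expected
    assert [s.index for s in segs] == list(range(1, len(expected) + 1))


def test_segment_boundaries_rejects_nonpositive():
    with pytest.raises(SegmentationError):
        plf.segment_boundaries(0, 50)
    with pytest.raises(SegmentationError):
        plf.segment_boundaries(100, 0)


@pytest.mark.parametrize(
    "start,end,expected",
    [
        (48, 55, {1, 2}),  # spanning peptides count in both segments
        (50, 50, {1}),  # a boundary residue belongs to one segment
        (49, 120, {1, 2, 3}),  # long peptides count in every overlapped segment
        (1, 1, {1}),
        (101, 120, {3}),
    ],
)
def test_map_peptide_to_segments(start, end, expected):
    assert plf.map_peptide_to_segments(start, end, 120, 50) == expected


def test_map_rejects_out_of_range():
    with pytest.raises(SegmentationError):
        plf.map_peptide_to_segments(100, 130, 120, 50)


def _brute_force_segments(start, end, protein_length, nominal):
    """Per-residue membership oracle: mark each residue's segment, take the
    set over the peptide's residues."""
    residue_segment = {
        r: (r - 1) // nominal + 1 for r in range(1, protein_length + 1)
    }
    return {residue_segment[r] for r in range(start, end + 1)}


@settings(max_examples=300, deadline=None, derandomize=True)
@given(data=st.data())
def test_mapping_agrees_with_residue_membership_oracle(data):
    length = data.draw(st.integers(1, 3000))
    nominal = data.draw(st.integers(1, 120))
    start = data.draw(st.integers(1, length))
    end = data.draw(st.integers(start, min(length, start + 80)))
    assert plf.map_peptide_to_segments(start, end, length, nominal) == \
        _brute_force_segments(start, end, length, nominal)


# -------------------------------------------------------------- count aggregation


def _loc(acc, seq, start, count, sample="s1", group="young", region="r"):
    return plf.LocatedPeptide(
        sample_id=sample, group=group, region=region, accession=acc,
        peptide_seq=seq, spectral_count=count, start=start,
        end=start + len(seq) - 1,
    )


@pytest.fixture
def protein_120():
    return {"P1": plf.ProteinEntry("P1", "A" * 120)}


def test_spanning_peptide_counted_in_both_segments(protein_120):
    # one peptide, count 3, spanning segments 1 and 2: both columns get the
    # full count, so the grid total (6) exceeds the raw count (3) on purpose
    peps = [_loc("P1", "A" * 8, 48, 3)]
    (m,) = plf.build_segment_counts(peps, protein_120).values()
    assert m.counts.tolist() == [[3, 3, 0]]
    assert m.counts.sum() == 6


def test_declared_sample_without_peptides_gets_zero_row(protein_120):
    peps = [_loc("P1", "AAAA", 1, 2, sample="s1")]
    design = {"r": [SampleKey("s1", "young"), SampleKey("s2", "aged")]}
    (m,) = plf.build_segment_counts(peps, protein_120, design=design).values()
    assert m.counts.shape == (2, 3)
    assert m.counts[1].tolist() == [0, 0, 0]


def test_counts_are_additive_within_a_segment(protein_120):
    peps = [_loc("P1", "AAAA", 1, 2), _loc("P1", "AAAA", 10, 5)]
    (m,) = plf.build_segment_counts(peps, protein_120).values()
    assert m.counts[0, 0] == 7


def test_inconsistent_sample_metadata_rejected(protein_120):
    peps = [
        _loc("P1", "AAAA", 1, 2, sample="s1", group="young"),
        _loc("P1", "AAAA", 1, 2, sample="s1", group="aged"),
    ]
    with pytest.raises(DesignError):
        plf.build_segment_counts(peps, protein_120)


def test_each_region_is_an_independent_matrix(protein_120):
    peps = [
        _loc("P1", "AAAA", 1, 2, region="posterior"),
        _loc("P1", "AAAA", 60, 4, region="anterior"),
    ]
    mats = plf.build_segment_counts(peps, protein_120)
    assert set(mats) == {("P1", "posterior"), ("P1", "anterior")}
    assert mats[("P1", "posterior")].counts[0].tolist() == [2, 0, 0]
    assert mats[("P1", "anterior")].counts[0].tolist() == [0, 4, 0]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(data=st.data())
def test_grid_total_equals_counts_times_segments_overlapped(data):
    """Sum of the grid = sum over peptides of count x (#segments overlapped);
    peptides shorter than the nominal size overlap at most two segments."""
    length = data.draw(st.integers(30, 400))
    prots = {"P1": plf.ProteinEntry("P1", "A" * length)}
    nominal = 50
    n = data.draw(st.integers(1, 15))
    peps = []
    expected = 0
    total_counts = 0
    for _ in range(n):
        start = data.draw(st.integers(1, length))
        plen = data.draw(st.integers(1, min(nominal - 1, length - start + 1)))
        count = data.draw(st.integers(0, 9))
        peps.append(_loc("P1", "A" * plen, start, count))
        k = len(plf.map_peptide_to_segments(start, start + plen - 1, length, nominal))
        assert k <= 2
        expected += count * k
        total_counts += count
    (m,) = plf.build_segment_counts(peps, prots, nominal_size=nominal).values()
    assert m.counts.sum() == expected
    assert m.counts.sum() <= 2 * total_counts
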