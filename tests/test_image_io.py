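"""MetaImage round-trips, coordinate geometry, merging and consensus."""

import numpy as np
import pytest

from ldcnet.image_io import (
    Candidate,
    CTVolume,
    GeometryError,
    MetaImageError,
    NoduleAnnotation,
    WorldPoint,
    consensus_filter,
    merge_annotations,
    read_candidates_csv,
    read_metaimage,
    world_to_voxel,
    voxel_to_world,
    write_candidates_csv,
    write_metaimage,
)


def make_annotation(x, y, z, d, series="s1", readers=1):
    return NoduleAnnotation(
        series_id=series,
        center=WorldPoint(float(x), float(y), float(z)),
        diameter_mm=float(d),
        reader_count=readers,
    )


class TestMetaImage:
    def test_round_trip_bit_exact(self, small_volume, tmp_path):
        path = tmp_path / "vol.mhd"
        write_metaimage(small_volume, path)
        back = read_metaimage(path)
        np.testing.assert_array_equal(back.voxels, small_volume.voxels)
        assert back.voxels.dtype == small_volume.voxels.dtype
        np.testing.assert_allclose(back.origin_mm, small_volume.origin_mm)
        np.testing.assert_allclose(back.spacing_mm, small_volume.spacing_mm)
        np.testing.assert_allclose(back.direction, small_volume.direction)

    def test_float_volume_round_trip(self, tmp_path, rng):
        vol = CTVolume(
            voxels=rng.normal(size=(3, 5, 6)).astype(np.float32),
            origin_mm=[0, 0, 0],
            spacing_mm=[1, 1, 1],
        )
        write_metaimage(vol, tmp_path / "f.mhd")
        back = read_metaimage(tmp_path / "f.mhd")
        np.testing.assert_array_equal(back.voxels, vol.voxels)

    def test_header_spacing_parsed(self, small_volume, tmp_path):
        write_metaimage(small_volume, tmp_path / "v.mhd")
        header = (tmp_path / "v.mhd").read_text()
        assert "ElementSpacing" in header
        back = read_metaimage(tmp_path / "v.mhd")
        assert tuple(back.spacing_mm) == (0.7, 0.7, 2.5)

    def test_truncated_raw_is_size_mismatch_error(self, small_volume, tmp_path):
        write_metaimage(small_volume, tmp_path / "v.mhd")
        raw = tmp_path / "v.raw"
        raw.write_bytes(raw.read_bytes()[:-32])  # drop one 4x4 slice
        with pytest.raises(MetaImageError, match="DimSize"):
            read_metaimage(tmp_path / "v.mhd")

    def test_missing_header_field(self, small_volume, tmp_path):
        write_metaimage(small_volume, tmp_path / "v.mhd")
        text = (tmp_path / "v.mhd").read_text()
        cleaned = "\n".join(
            line for line in text.splitlines() if not line.startswith("DimSize")
        )
        (tmp_path / "v.mhd").write_text(cleaned)
        with pytest.raises(MetaImageError, match="DimSize"):
            read_metaimage(tmp_path / "v.mhd")

    def test_missing_file(self, tmp_path):
        with pytest.raises(MetaImageError, match="not found"):
            read_metaimage(tmp_path / "absent.mhd")


class TestVolumeInvariants:
    def test_spacing_must_be_positive(self):
        with pytest.raises(ValueError, match="spacing"):
            CTVolume(np.zeros((2, 2, 2)), [0, 0, 0], [1, -1, 1])

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            CTVolume(np.zeros((0, 2, 2)), [0, 0, 0], [1, 1, 1])

    def test_direction_rows_unit_norm(self):
        with pytest.raises(ValueError, match="unit-norm"):
            CTVolume(np.zeros((2, 2, 2)), [0, 0, 0], [1, 1, 1], direction=2 * np.eye(3))


class TestWorldToVoxel:
    def test_origin_maps_to_zero(self, small_volume):
        p = WorldPoint(*small_volume.origin_mm)
        assert world_to_voxel(small_volume, p) == (0, 0, 0)

    def test_origin_plus_spacing(self, small_volume):
        p = WorldPoint(*(small_volume.origin_mm + small_volume.spacing_mm))
        assert world_to_voxel(small_volume, p) == (1, 1, 1)

    def test_hand_computed_case(self, small_volume):
        # (-86+100)/0.7 = 20, (-93+100)/0.7 = 10, (-40+50)/2.5 = 4
        index = world_to_voxel(small_volume, WorldPoint(-86.0, -93.0, -40.0))
        assert index == (4, 10, 20)

    def test_round_trip_with_voxel_to_world(self, small_volume):
        for idx in [(0, 0, 0), (3, 2, 1), (1, 3, 2)]:
            assert world_to_voxel(small_volume, voxel_to_world(small_volume, idx)) == idx

    def test_singular_direction_raises(self, small_volume):
        vol = CTVolume(
            small_volume.voxels,
            small_volume.origin_mm,
            small_volume.spacing_mm,
            direction=np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1]], dtype=float),
        )
        with pytest.raises(GeometryError):
            world_to_voxel(vol, WorldPoint(0, 0, 0))

    def test_nonfinite_point_rejected(self):
        with pytest.raises(ValueError):
            WorldPoint(np.nan, 0, 0)


def brute_force_merge(anns):
    """Independent oracle: transitive closure over all original pairs, then
    component-wise averaging."""
    n = len(anns)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(anns[i].center.as_array() - anns[j].center.as_array())
            if d < (anns[i].diameter_mm + anns[j].diameter_mm) / 2:
                parent[find(j)] = find(i)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in sorted(comps.values(), key=min):
        pts = np.mean([anns[i].center.as_array() for i in members], axis=0)
        diam = float(np.mean([anns[i].diameter_mm for i in members]))
        out.append((tuple(np.round(pts, 9)), round(diam, 9), len(members)))
    return out


class TestMergeAnnotations:
    def test_two_close_marks_merge_to_midpoint(self):
        a = make_annotation(0, 0, 0, 4)
        b = make_annotation(3, 0, 0, 4)  # 3 mm apart < 2 + 2
        merged = merge_annotations([a, b])
        assert len(merged) == 1
        assert merged[0].center == WorldPoint(1.5, 0, 0)
        assert merged[0].diameter_mm == 4
        assert merged[0].reader_count == 2

    def test_distant_marks_unchanged(self):
        a = make_annotation(0, 0, 0, 4)
        b = make_annotation(10, 0, 0, 4)
        merged = merge_annotations([a, b])
        assert len(merged) == 2
        assert merged[0].center == a.center

    def test_boundary_distance_does_not_merge(self):
        # centres exactly sum-of-radii apart: strictly-less-than comparison
        a = make_annotation(0, 0, 0, 4)
        b = make_annotation(4, 0, 0, 4)
        assert len(merge_annotations([a, b])) == 2

    def test_chain_merges_transitively(self):
        a = make_annotation(0, 0, 0, 4)
        b = make_annotation(3, 0, 0, 4)
        c = make_annotation(6, 0, 0, 4)  # close to b, far from a
        merged = merge_annotations([a, b, c])
        assert len(merged) == 1
        assert merged[0].reader_count == 3
        assert merged[0].center == WorldPoint(3, 0, 0)

    def test_mixed_series_rejected(self):
        a = make_annotation(0, 0, 0, 4, series="s1")
        b = make_annotation(1, 0, 0, 4, series="s2")
        with pytest.raises(ValueError, match="series"):
            merge_annotations([a, b])

    def test_matches_brute_force_closure_oracle(self):
        # 200 seeded random toy sets of up to 6 marks each
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 7))
            anns = [
                make_annotation(*rng.uniform(-30, 30, size=3), rng.uniform(3, 10))
                for _ in range(n)
            ]
            merged = merge_annotations(anns)
            expected = brute_force_merge(anns)
            got = [
                (tuple(np.round(m.center.as_array(), 9)), round(m.diameter_mm, 9),
                 m.reader_count)
                for m in merged
            ]
            assert got == expected

    def test_idempotent_and_conserves_readers(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(1, 7))
            anns = [
                make_annotation(*rng.uniform(-20, 20, size=3), rng.uniform(3, 8))
                for _ in range(n)
            ]
            merged = merge_annotations(anns)
            assert len(merged) <= len(anns)
            assert sum(m.reader_count for m in merged) == len(anns)
            again = merge_annotations(merged)
            assert [m.center for m in again] == [m.center for m in merged]
            assert [m.diameter_mm for m in again] == [m.diameter_mm for m in merged]


class TestConsensusFilter:
    def test_keeps_at_least_min_readers(self):
        anns = [make_annotation(i, 0, 0, 4, readers=i + 1) for i in range(4)]
        assert len(consensus_filter(anns, 3)) == 2
        assert consensus_filter(anns, 1) == anns

    def test_monotone_in_threshold(self, rng):
        anns = [
            make_annotation(i * 20, 0, 0, 4, readers=int(rng.integers(1, 5)))
            for i in range(12)
        ]
        merged = merge_annotations(anns)
        sizes = [len(consensus_filter(merged, k)) for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_brute_force_filter(self, rng):
        anns = [
            make_annotation(i * 20, 0, 0, 4, readers=int(rng.integers(1, 5)))
            for i in range(20)
        ]
        for k in (1, 2, 3, 4):
            assert consensus_filter(anns, k) == [a for a in anns if a.reader_count >= k]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            consensus_filter([], 0)


class TestCandidatesCsv:
    def test_three_row_fixture(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "seriesuid,coordX,coordY,coordZ,class\n"
            "s1,1.0,2.0,3.0,1\ns1,4.0,5.0,6.0,0\ns2,7.0,8.0,9.0,0\n"
        )
        cands = read_candidates_csv(path)
        assert [c.label for c in cands] == [1, 0, 0]
        assert cands[0].center == WorldPoint(1.0, 2.0, 3.0)

    def test_empty_with_header(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("seriesuid,coordX,coordY,coordZ,class\n")
        assert read_candidates_csv(path) == []

    def test_nonbinary_class_names_row(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "seriesuid,coordX,coordY,coordZ,class\ns1,1,2,3,1\ns1,4,5,6,2\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_candidates_csv(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("seriesuid,coordX,coordY,coordZ\ns1,1,2,3\n")
        with pytest.raises(ValueError, match="class"):
            read_candidates_csv(path)

    def test_write_read_round_trip(self, tmp_path):
        cands = [
            Candidate("s1", WorldPoint(1.5, -2.25, 3.0), 1),
            Candidate("s1", WorldPoint(0.0, 0.5, -9.75), 0),
        ]
        write_candidates_csv(cands, tmp_path / "c.csv")
        assert read_candidates_csv(tmp_path / "c.csv") == cands
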