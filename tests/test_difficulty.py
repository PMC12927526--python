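"""Morphology primitives and the DCI/EFI difficulty indices.

Fast paths are checked against the coordinate-set and flood-fill oracles from
conftest, plus analytic constructions (abutting cubes, dumbbells, thin sheets)
whose index values follow directly from the definitions.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitometrics import (
    InstanceVolume,
    StructuringElement,
    compute_dci,
    compute_efi,
    count_components,
    difficulty_report,
    dilate_mask,
    erode_mask,
    export_difficulty_scatter,
)
from conftest import (
    bfs_components,
    dci_oracle,
    dilate_oracle,
    efi_oracle,
    erode_oracle,
    random_volume,
)


def _vol(labels):
    return InstanceVolume(labels=np.asarray(labels, dtype=np.int64))


def _two_cubes(gap_voxels: int):
    """Two 3x3x3 cubes along x separated by `gap_voxels` background voxels."""
    labels = np.zeros((9, 9, 16), dtype=np.int64)
    labels[3:6, 3:6, 2:5] = 1
    start = 5 + gap_voxels
    labels[3:6, 3:6, start : start + 3] = 2
    return _vol(labels)


def _dumbbell_volume():
    """Two 5x5x5 cubes joined by a 1x1x3 bar: the canonical thin-neck object."""
    labels = np.zeros((9, 9, 17), dtype=np.int64)
    labels[2:7, 2:7, 2:7] = 1
    labels[2:7, 2:7, 10:15] = 1
    labels[4, 4, 7:10] = 1
    return _vol(labels)


class TestStructuringElement:
    def test_radius_one_is_3x3x3_box(self):
        assert StructuringElement(1).footprint().shape == (3, 3, 3)
        assert StructuringElement(1).footprint().all()

    @pytest.mark.parametrize("radius", [0, -1, 1.5])
    def test_invalid_radius_rejected(self, radius):
        with pytest.raises(ValueError):
            StructuringElement(radius)

    def test_anisotropic_footprint_shrinks_coarse_axis(self):
        fp = StructuringElement.anisotropic_footprint(1, (30.0, 8.0, 8.0))
        assert fp.shape == (1, 3, 3)


class TestMorphologyPrimitives:
    def test_center_voxel_dilates_to_27_box(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        out = dilate_mask(mask)
        assert out.sum() == 27
        assert out[1:4, 1:4, 1:4].all()

    def test_corner_voxel_dilation_clips_to_8(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = True
        assert dilate_mask(mask).sum() == 8

    def test_solid_cube_erodes_to_center(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        out = erode_mask(mask)
        assert out.sum() == 1 and out[3, 3, 3]

    def test_one_voxel_sheet_erodes_to_empty(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, :, :] = True
        assert not erode_mask(mask).any()

    def test_border_voxels_erode_away(self):
        # outside-volume is background, so a full volume erodes to its interior
        mask = np.ones((5, 5, 5), dtype=bool)
        out = erode_mask(mask)
        assert out.sum() == 27 and out[1:4, 1:4, 1:4].all()

    @pytest.mark.parametrize("seed", range(10))
    def test_dilation_matches_coordinate_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16, 16)) < 0.15
        np.testing.assert_array_equal(dilate_mask(mask), dilate_oracle(mask))

    @pytest.mark.parametrize("seed", range(10))
    def test_erosion_matches_coordinate_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16, 16)) < 0.6
        np.testing.assert_array_equal(erode_mask(mask), erode_oracle(mask))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_dilation_superset_erosion_subset(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12, 12)) < 0.4
        assert (dilate_mask(mask) | mask).sum() == dilate_mask(mask).sum()
        assert (erode_mask(mask) & mask).sum() == erode_mask(mask).sum()


class TestCountComponents:
    def test_diagonal_voxels_connectivity_dependence(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert count_components(mask, 26) == 1
        assert count_components(mask, 6) == 2

    def test_empty_mask_has_zero_components(self):
        assert count_components(np.zeros((3, 3, 3), dtype=bool)) == 0

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            count_components(np.ones((2, 2, 2), dtype=bool), connectivity=4)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16, 16)) < 0.2
        assert count_components(mask, connectivity) == bfs_components(mask, connectivity)


class TestDCI:
    def test_abutting_cubes_collide_both_ways(self):
        vol = _two_cubes(gap_voxels=0)
        assert compute_dci(vol, 1) == 1
        assert compute_dci(vol, 2) == 1

    def test_one_voxel_gap_no_collision_at_radius_1(self):
        # one background voxel between cubes: Chebyshev distance 2 > radius 1,
        # so the dilated mask reaches the gap but not the neighbor
        vol = _two_cubes(gap_voxels=1)
        assert compute_dci(vol, 1) == 0
        assert compute_dci(vol, 2) == 0

    def test_larger_radius_bridges_the_gap(self):
        vol = _two_cubes(gap_voxels=1)
        assert compute_dci(vol, 1, StructuringElement(2)) == 1

    def test_absent_instance_raises(self):
        with pytest.raises(KeyError):
            compute_dci(_two_cubes(0), 9)

    def test_monotone_in_radius(self):
        vol = random_volume(42)
        for i in vol.instance_ids():
            d1 = compute_dci(vol, int(i), StructuringElement(1))
            d2 = compute_dci(vol, int(i), StructuringElement(2))
            assert d2 >= d1


class TestEFI:
    def test_solid_ball_is_not_fragile(self):
        zz, yy, xx = np.ogrid[:11, :11, :11]
        ball = ((zz - 5) ** 2 + (yy - 5) ** 2 + (xx - 5) ** 2 <= 16).astype(np.int64)
        assert compute_efi(_vol(ball), 1) == 0

    def test_dumbbell_neck_breaks_into_one_extra_fragment(self):
        assert compute_efi(_dumbbell_volume(), 1) == 1

    def test_thin_cross_erodes_to_empty_and_scores_zero(self):
        labels = np.zeros((9, 9, 9), dtype=np.int64)
        labels[4, 4, :] = 1
        labels[4, :, 4] = 1
        labels[:, 4, 4] = 1
        assert compute_efi(_vol(labels), 1) == 0

    def test_thicker_neck_survives_erosion(self):
        # 3x3 neck cross-section survives a radius-1 erosion: EFI drops to 0
        labels = np.zeros((11, 11, 17), dtype=np.int64)
        labels[3:8, 3:8, 2:7] = 1
        labels[3:8, 3:8, 10:15] = 1
        labels[4:7, 4:7, 7:10] = 1
        assert compute_efi(_vol(labels), 1) == 0

    def test_absent_instance_raises(self):
        with pytest.raises(KeyError):
            compute_efi(_dumbbell_volume(), 2)


class TestOracleEquivalence:
    """Bounding-box fast path == whole-volume brute force on random volumes."""

    @pytest.mark.parametrize("seed", range(25))
    def test_dci_and_efi_match_oracles(self, seed):
        vol = random_volume(seed, shape=(18, 18, 18))
        for i in map(int, vol.instance_ids()):
            assert compute_dci(vol, i) == dci_oracle(vol.labels, i)
            assert compute_efi(vol, i) == efi_oracle(vol.labels, i)


class TestDifficultyReportInvariants:
    def test_isolated_ball_report(self):
        zz, yy, xx = np.ogrid[:11, :11, :11]
        ball = ((zz - 5) ** 2 + (yy - 5) ** 2 + (xx - 5) ** 2 <= 16).astype(np.int64)
        rep = difficulty_report(_vol(ball))
        assert [(r.dci, r.efi) for r in rep.records] == [(0, 0)]
        assert rep.mean_dci == 0.0 and rep.mean_efi == 0.0

    def test_mixed_volume_means_are_hand_computed(self):
        # two abutting cubes (dci 1 each, efi 0) + isolated dumbbell (dci 0, efi 1)
        labels = np.zeros((11, 11, 34), dtype=np.int64)
        labels[3:6, 3:6, 2:5] = 1
        labels[3:6, 3:6, 5:8] = 2
        d = _dumbbell_volume().labels
        labels[1:10, 1:10, 15:32][d > 0] = 3
        rep = difficulty_report(_vol(labels))
        assert rep.mean_dci == pytest.approx(2 / 3)
        assert rep.mean_efi == pytest.approx(1 / 3)

    def test_empty_volume_has_absent_means(self):
        rep = difficulty_report(_vol(np.zeros((4, 4, 4))))
        assert rep.records == [] and rep.mean_dci is None and rep.mean_efi is None

    def test_label_permutation_leaves_index_multiset_unchanged(self):
        vol = random_volume(7)
        ids = vol.instance_ids()
        perm = {int(i): int(j) for i, j in zip(ids, np.roll(ids, 1))}
        lut = np.zeros(int(ids.max()) + 1, dtype=np.int64)
        for old, new in perm.items():
            lut[old] = new
        permuted = InstanceVolume(labels=lut[vol.labels], spacing=vol.spacing)
        orig = difficulty_report(vol)
        after = difficulty_report(permuted)
        key = lambda rep: sorted((r.voxel_count, r.dci, r.efi) for r in rep.records)  # noqa: E731
        assert key(orig) == key(after)

    def test_translation_invariance(self):
        # rigid shift via np.roll, with content confined away from borders so
        # nothing wraps or touches the volume boundary before/after
        vol = random_volume(13, shape=(16, 16, 16))
        inner = np.zeros_like(vol.labels)
        inner[2:12, 2:12, 2:12] = vol.labels[2:12, 2:12, 2:12]
        vol_inner = InstanceVolume(labels=inner)
        rolled = InstanceVolume(labels=np.roll(inner, (2, 1, 2), axis=(0, 1, 2)))
        a = difficulty_report(vol_inner)
        b = difficulty_report(rolled)
        assert [(r.instance_id, r.dci, r.efi) for r in a.records] == [
            (r.instance_id, r.dci, r.efi) for r in b.records
        ]

    def test_dumbbell_efi_non_increasing_with_neck_thickness(self):
        def dumbbell_with_neck(w):
            labels = np.zeros((11, 11, 17), dtype=np.int64)
            labels[3:8, 3:8, 2:7] = 1
            labels[3:8, 3:8, 10:15] = 1
            lo, hi = 5 - w // 2, 5 + w // 2 + 1
            labels[lo:hi, lo:hi, 7:10] = 1
            return compute_efi(_vol(labels), 1)

        efis = [dumbbell_with_neck(w) for w in (1, 3, 5)]
        assert efis[0] == 1 and efis == sorted(efis, reverse=True)


class TestScatterExport:
    def test_rows_match_records_and_parse_back(self, tmp_path):
        import pandas as pd

        rep = difficulty_report(random_volume(3))
        path = tmp_path / "scatter.csv"
        export_difficulty_scatter([rep], path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["dataset", "instance_id", "voxel_count", "dci", "efi"]
        assert len(df) == len(rep.records)
        got = list(df[["instance_id", "voxel_count", "dci", "efi"]].itertuples(index=False, name=None))
        want = [(r.instance_id, r.voxel_count, r.dci, r.efi) for r in rep.records]
        assert got == want

    def test_empty_report_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        export_difficulty_scatter([], path)
        assert path.read_text().strip() == "dataset,instance_id,voxel_count,dci,efi"
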