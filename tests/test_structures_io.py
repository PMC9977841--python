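"""Domain types, XYZ/manifest round-trips, interpolation, and bond-change
classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tsgeo.io import (XYZParseError, load_dataset, read_reaction_xyz,
                      write_reaction_xyz, write_structure_xyz)
from tsgeo.structures import (BondChange, Reaction, Structure, classify_pairs,
                              interpolate, strict_pairs)
from tsgeo.synthetic import SyntheticConfig, generate, write_dataset


def make_reaction(xr, xp, numbers=None, ts=None):
    numbers = numbers if numbers is not None else [6] * len(xr)
    return Reaction(
        reactant=Structure(numbers, xr, label="reactant"),
        product=Structure(numbers, xp, label="product"),
        ts_ref=None if ts is None else Structure(numbers, ts, label="ts"),
        reaction_id="test",
    )


class TestStructure:
    def test_distance_matrix_symmetric_hollow_nonnegative(self):
        rng = np.random.default_rng(0)
        s = Structure([1, 6, 7, 8], rng.normal(size=(4, 3)))
        d = s.distance_matrix()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all(d >= 0)

    @pytest.mark.parametrize("bad", [
        dict(atomic_numbers=[], coordinates=np.zeros((0, 3))),
        dict(atomic_numbers=[0], coordinates=np.zeros((1, 3))),
        dict(atomic_numbers=[6], coordinates=np.array([[np.nan, 0, 0]])),
        dict(atomic_numbers=[6, 6], coordinates=np.zeros((1, 3))),
    ])
    def test_invalid_structures_rejected(self, bad):
        with pytest.raises(ValueError):
            Structure(**bad)


class TestReaction:
    def test_mismatched_elements_rejected(self):
        with pytest.raises(ValueError):
            Reaction(
                reactant=Structure([1, 6], np.zeros((2, 3))),
                product=Structure([6, 1], np.zeros((2, 3))),
            )

    def test_reverse_swaps_endpoints_and_keeps_ts(self):
        rng = np.random.default_rng(1)
        r = make_reaction(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)),
                          ts=rng.normal(size=(3, 3)))
        rev = r.reverse()
        assert np.allclose(rev.reactant.coordinates, r.product.coordinates)
        assert np.allclose(rev.product.coordinates, r.reactant.coordinates)
        assert np.allclose(rev.ts_ref.coordinates, r.ts_ref.coordinates)
        back = rev.reverse()
        assert np.allclose(back.reactant.coordinates, r.reactant.coordinates)


class TestInterpolate:
    def test_endpoints_and_midpoint(self):
        xr = np.array([[0.0, 0, 0]])
        xp = np.array([[2.0, 0, 0]])
        r = make_reaction(xr, xp)
        assert np.allclose(interpolate(r, 0.0).coordinates, xr)
        assert np.allclose(interpolate(r, 1.0).coordinates, xp)
        assert np.allclose(interpolate(r, 0.5).coordinates, [[1.0, 0, 0]])
        assert interpolate(r, 0.5).label == "interpolated"

    def test_fraction_out_of_range(self):
        r = make_reaction(np.zeros((1, 3)), np.ones((1, 3)))
        with pytest.raises(ValueError):
            interpolate(r, 1.5)

    def test_equivariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(2)
        xr, xp = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        a = interpolate(make_reaction(xr, xp), 0.3).coordinates
        b = interpolate(make_reaction(xr @ rot.T + t, xp @ rot.T + t), 0.3).coordinates
        assert np.allclose(a @ rot.T + t, b, atol=1e-12)

    def test_alignment_removes_arbitrary_product_pose(self):
        rng = np.random.default_rng(4)
        xr = rng.normal(size=(5, 3))
        rot = Rotation.random(random_state=5).as_matrix()
        r = make_reaction(xr, xr @ rot.T + 3.0)
        mid = interpolate(r, 0.5, align=True)
        # product is a rigid copy of the reactant: aligned midpoint == reactant shape
        d_mid = mid.distance_matrix()
        d_r = r.reactant.distance_matrix()
        assert np.allclose(d_mid, d_r, atol=1e-8)


class TestClassifyPairs:
    def test_examples_and_count(self):
        # bonded means distance < 156.6 pm
        xr = np.array([[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]])
        xp = np.array([[0.0, 0, 0], [3.0, 0, 0], [3.0, 0, 1.0]])
        r = make_reaction(xr, xp)
        cats = classify_pairs(r)
        assert len(cats) == 3
        lookup = dict(zip(map(tuple, strict_pairs(3)), cats))
        assert lookup[(1, 0)] == BondChange.BREAKAGE     # 100 pm -> 300 pm
        assert lookup[(2, 1)] == BondChange.FORMATION    # 400 pm -> 100 pm
        assert lookup[(2, 0)] == BondChange.NONE_NONE

    def test_reversal_swaps_formation_and_breakage(self, small_dataset):
        for r in small_dataset:
            fwd = classify_pairs(r)
            bwd = classify_pairs(r.reverse())
            swap = {BondChange.FORMATION: BondChange.BREAKAGE,
                    BondChange.BREAKAGE: BondChange.FORMATION}
            assert [swap.get(c, c) for c in fwd] == bwd

    def test_both_above_threshold_is_none_none(self):
        xr = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        r = make_reaction(xr, xr)
        assert classify_pairs(r) == [BondChange.NONE_NONE]


class TestXYZ:
    def test_write_read_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        s = Structure([1, 6, 7, 8, 6, 1], rng.normal(size=(6, 3)) * 3)
        path = tmp_path / "s.xyz"
        write_structure_xyz(s, str(path))
        from tsgeo.io import read_xyz_frames

        frames = read_xyz_frames(str(path))
        assert len(frames) == 1
        got, _ = frames[0]
        assert np.max(np.abs(got.coordinates - s.coordinates)) <= 1e-6
        assert np.array_equal(got.atomic_numbers, s.atomic_numbers)

    def test_single_atom_roundtrip(self, tmp_path):
        s = Structure([1], np.array([[0.1, -0.2, 0.3]]))
        path = tmp_path / "one.xyz"
        write_structure_xyz(s, str(path))
        from tsgeo.io import read_xyz_frames

        got, _ = read_xyz_frames(str(path))[0]
        assert got.n_atoms == 1

    def test_nonfinite_coordinates_rejected_before_write(self):
        with pytest.raises(ValueError):
            Structure([6], np.array([[np.inf, 0, 0]]))

    def test_reaction_roundtrip_with_properties(self, tmp_path, small_dataset):
        r = small_dataset[0]
        path = tmp_path / "rxn.xyz"
        write_reaction_xyz(r, str(path))
        got = read_reaction_xyz(str(path), {"id": r.reaction_id, "frames": "RTP"})
        assert got.ts_ref is not None
        assert np.max(np.abs(got.ts_ref.coordinates - r.ts_ref.coordinates)) <= 1e-6
        assert got.properties["reactant"]["E"] == pytest.approx(
            r.properties["reactant"]["E"], rel=1e-8)

    def test_two_frame_file_has_no_ts(self, tmp_path):
        rng = np.random.default_rng(7)
        r = make_reaction(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        path = tmp_path / "rp.xyz"
        write_reaction_xyz(r, str(path))
        got = read_reaction_xyz(str(path), {"frames": "RP"})
        assert got.ts_ref is None

    def test_frame_count_mismatch_with_manifest(self, tmp_path, small_dataset):
        path = tmp_path / "rxn.xyz"
        write_reaction_xyz(small_dataset[0], str(path))  # 3 frames
        with pytest.raises(XYZParseError):
            read_reaction_xyz(str(path), {"frames": "RP"})

    def test_inconsistent_element_order_rejected(self, tmp_path):
        content = "2\nframe1\nH 0 0 0\nC 1 0 0\n2\nframe2\nC 0 0 0\nH 1 0 0\n"
        path = tmp_path / "bad.xyz"
        path.write_text(content)
        with pytest.raises(ValueError):
            read_reaction_xyz(str(path))

    def test_malformed_line_reports_position(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\nc\nH 0 0 0\nC 1 zero 0\n")
        with pytest.raises(XYZParseError, match=r":4"):
            read_reaction_xyz(str(path))


def test_dataset_roundtrip_through_manifest(tmp_path):
    reactions = generate(SyntheticConfig(n_reactions=3, n_atoms_range=(3, 5), seed=9))
    manifest = write_dataset(reactions, str(tmp_path / "data"))
    loaded = load_dataset(manifest)
    assert len(loaded) == 3
    for a, b in zip(reactions, loaded):
        assert a.reaction_id == b.reaction_id
        assert np.max(np.abs(a.ts_ref.coordinates - b.ts_ref.coordinates)) <= 1e-6
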