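"""Voxel-model I/O, conductivity lookup, and surface extraction."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmscoilopt import model_io as mio

from conftest import voxel_sphere


# ---------------------------------------------------------------------------
# file round trips and world convention
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["nii.gz", "nii", "raw"])
def test_round_trip_preserves_labels(tmp_path, fmt):
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 4, size=(9, 7, 11)).astype(np.uint8)
    names = {1: "Skin", 2: "Bone", 3: "Grey matter"}
    m = mio.VoxelModel(labels=labels, spacing=1.5,
                       origin=mio.default_origin(labels.shape, 1.5),
                       label_names=names)
    path = tmp_path / f"vol.{fmt}"
    mio.save_voxel_model(m, path)
    back = mio.load_voxel_model(path)
    np.testing.assert_array_equal(back.labels, m.labels)
    assert back.spacing == pytest.approx(m.spacing)
    np.testing.assert_allclose(back.origin, m.origin, atol=1e-6)
    assert back.label_names == names


def test_bottom_center_origin_convention():
    # 100^3 grid at 1 mm, bottom slice centered -> corner at (-50, -50, 0)
    origin = mio.default_origin((100, 100, 100), 1.0)
    np.testing.assert_allclose(origin, [-50.0, -50.0, 0.0])


def test_anisotropic_spacing_rejected(tmp_path):
    import nibabel as nib
    img = nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.uint8), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 2.0))
    nib.save(img, str(tmp_path / "aniso.nii"))
    with pytest.raises(mio.ModelFormatError, match="cubic"):
        mio.load_voxel_model(tmp_path / "aniso.nii")


def test_unknown_label_rejected(tmp_path):
    labels = np.zeros((4, 4, 4), dtype=np.uint8)
    labels[1, 1, 1] = 7
    m = mio.VoxelModel(labels=labels, spacing=1.0,
                       origin=np.zeros(3), label_names={7: "Grey matter"})
    path = mio.save_voxel_model(m, tmp_path / "v.nii")
    # drop the sidecar so label 7 has no name
    (tmp_path / "v.labels.json").write_text(json.dumps({}))
    with pytest.raises(mio.UnknownTissueError, match="7"):
        mio.load_voxel_model(path)


def test_all_zero_volume_loads_empty(tmp_path):
    m = mio.VoxelModel(labels=np.zeros((8, 8, 8), dtype=np.uint8),
                       spacing=1.0, origin=mio.default_origin((8, 8, 8), 1.0))
    back = mio.load_voxel_model(mio.save_voxel_model(m, tmp_path / "z.nii.gz"))
    assert not np.any(back.labels)


# ---------------------------------------------------------------------------
# conductivity mapping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tissue,expected", [
    ("Grey matter", 0.104),
    ("Cerebrospinal fluid", 2.00),
    ("Internal air", 0.0),
    ("White matter", 0.0642),
    ("Bone", 0.0203),
])
def test_table_conductivities(tissue, expected):
    table = mio.ConductivityTable.default()
    assert table.conductivity(tissue) == pytest.approx(expected, rel=1e-9)


def test_map_conductivity_lookup_and_errors():
    labels = np.array([[[0, 1], [2, 3]]], dtype=np.uint8)
    m = mio.VoxelModel(labels=labels, spacing=1.0, origin=np.zeros(3),
                       label_names={1: "Grey matter",
                                    2: "Cerebrospinal fluid",
                                    3: "Internal air"})
    sv = mio.map_conductivity(m)
    np.testing.assert_allclose(sv.sigma[0], [[0.0, 0.104], [2.0, 0.0]])

    m.label_names.pop(2)
    with pytest.raises(mio.UnknownTissueError, match="2"):
        mio.map_conductivity(m)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_conductivity_mapping_commutes_with_permutation(seed):
    """Mapping is a pure per-voxel lookup: permute-then-map == map-then-permute."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 3, size=(4, 4, 4)).astype(np.uint8)
    names = {1: "Grey matter", 2: "White matter"}
    perm = rng.permutation(4)
    m = mio.VoxelModel(labels=labels, spacing=1.0, origin=np.zeros(3),
                       label_names=names)
    mp = mio.VoxelModel(labels=labels[perm], spacing=1.0, origin=np.zeros(3),
                        label_names=names)
    np.testing.assert_array_equal(mio.map_conductivity(m).sigma[perm],
                                  mio.map_conductivity(mp).sigma)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def test_scalp_surface_area_of_sphere(sphere40):
    mesh = mio.extract_scalp_surface(sphere40)
    analytic = 4 * np.pi * 40.0 ** 2
    assert mesh.area == pytest.approx(analytic, rel=0.05)
    assert mesh.is_watertight


def test_single_voxel_surface_is_closed_and_centered():
    labels = np.zeros((8, 8, 8), dtype=np.uint8)
    labels[4, 4, 4] = 1
    m = mio.VoxelModel(labels=labels, spacing=1.0,
                       origin=mio.default_origin((8, 8, 8), 1.0),
                       label_names={1: "Skin"})
    mesh = mio.extract_scalp_surface(m)
    assert mesh.is_watertight
    np.testing.assert_allclose(mesh.centroid, m.index_to_world([4, 4, 4]),
                               atol=0.2)


def test_disjoint_blobs_keep_largest_with_warning():
    labels = np.zeros((16, 16, 16), dtype=np.uint8)
    labels[2:10, 2:10, 2:10] = 1          # large blob
    labels[13, 13, 13] = 1                # stray voxel
    m = mio.VoxelModel(labels=labels, spacing=1.0,
                       origin=mio.default_origin((16, 16, 16), 1.0),
                       label_names={1: "Skin"})
    with pytest.warns(UserWarning, match="disjoint"):
        mesh = mio.extract_scalp_surface(m)
    # blob spans world x in [-6, 2]; the stray voxel at x ~ 5.5 is excluded
    assert mesh.vertices[:, 0].max() < 4.0


def test_empty_model_rejected():
    m = mio.VoxelModel(labels=np.zeros((4, 4, 4), dtype=np.uint8),
                       spacing=1.0, origin=np.zeros(3))
    with pytest.raises(ValueError, match="no conducting"):
        mio.extract_scalp_surface(m)


@pytest.mark.parametrize("spacing", [1.0, 2.0])
def test_offset_surface_distance_property(spacing):
    """Every offset-surface vertex sits 10 mm +/- half a voxel off the scalp."""
    model = voxel_sphere(40.0, spacing)
    scalp = mio.extract_scalp_surface(model)
    off = mio.offset_surface(model, 10.0)
    query = mio.SurfaceQuery(scalp)
    verts = off.vertices[::max(1, len(off.vertices) // 400)]
    _, _, d = query.closest(verts)
    assert np.all(np.abs(d - 10.0) <= 0.5 * spacing + 1e-6)
    # concentric spheres: offset of a 40 mm sphere is ~ a 50 mm sphere
    assert off.area == pytest.approx(4 * np.pi * 50.0 ** 2, rel=0.06)
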