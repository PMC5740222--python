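import numpy as np
import pytest

from mpetsim import geometry as geo
from mpetsim import (LabeledMesh, MeshError, domain_volume,
                     generate_shell_mesh, read_mesh, surface_area,
                     write_msh, write_vtk_mesh)


class TestShellGenerator:
    def test_shell_is_watertight_and_labeled(self, shell_mesh):
        shell_mesh.validate(require_two_surfaces=True,
                            require_territories=True)

    def test_surface_areas_approach_analytic(self):
        m = generate_shell_mesh(0.03, 0.07, 1.0, resolution=(8, 4))
        for label, r in (("cortical", 0.07), ("ventricular", 0.03)):
            area = surface_area(m, label)
            assert area == pytest.approx(4 * np.pi * r ** 2, rel=0.02)
        assert domain_volume(m) == pytest.approx(
            4 / 3 * np.pi * (0.07 ** 3 - 0.03 ** 3), rel=0.02)

    def test_territories_partition_cortical_surface(self, shell_mesh):
        total = sum(surface_area(shell_mesh, t) for t in geo.TERRITORIES)
        assert total == pytest.approx(surface_area(shell_mesh, "cortical"),
                                      abs=1e-15)
        for t in geo.TERRITORIES:
            assert surface_area(shell_mesh, t) > 0

    def test_halving_target_h_grows_elements_about_8x(self):
        n1 = generate_shell_mesh(0.03, 0.07, 0.01).n_elements
        n2 = generate_shell_mesh(0.03, 0.07, 0.005).n_elements
        assert 5.0 < n2 / n1 < 12.0

    @pytest.mark.parametrize("ri, ro, h", [
        (0.07, 0.03, 0.01), (0.03, 0.03, 0.01), (0.03, 0.07, 0.1)])
    def test_bad_arguments_rejected(self, ri, ro, h):
        with pytest.raises(ValueError):
            generate_shell_mesh(ri, ro, h)

    def test_deterministic_for_fixed_inputs(self):
        a = generate_shell_mesh(0.03, 0.07, 0.01, seed=1)
        b = generate_shell_mesh(0.03, 0.07, 0.01, seed=1)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.tets, b.tets)
        assert np.array_equal(a.territory, b.territory)


class TestLabeling:
    def test_relabeling_is_idempotent(self, shell_mesh):
        before = shell_mesh.territory.copy()
        geo.label_territories(shell_mesh)
        assert np.array_equal(before, shell_mesh.territory)

    def test_degenerate_band_raises(self, shell_mesh):
        with pytest.raises(geo.LabelingError):
            geo.label_territories(shell_mesh, va_cap_cos=-1.5)
        geo.label_territories(shell_mesh)   # restore

    def test_hemispheres_split_by_sagittal_plane(self, shell_mesh):
        cx = shell_mesh.tet_centroids()[:, 0]
        assert np.array_equal(shell_mesh.hemisphere == geo.HEMI_L, cx < 0)

    def test_unknown_label_is_an_error(self, shell_mesh):
        with pytest.raises(MeshError):
            surface_area(shell_mesh, "SPINAL")


class TestBoxMesh:
    def test_volume_and_validity(self):
        m = geo.generate_box_mesh(2, 3, 4, 1.0, 2.0, 3.0)
        m.validate(require_two_surfaces=False)
        assert domain_volume(m) == pytest.approx(6.0)
        assert m.n_elements == 2 * 3 * 4 * 6

    def test_face_tags_cover_all_faces(self):
        m = geo.generate_box_mesh(2, 2, 2, 1, 1, 1)
        for tag in (geo.XMIN, geo.XMAX, geo.YMIN, geo.YMAX, geo.ZMIN,
                    geo.ZMAX):
            assert surface_area(m, tag) == pytest.approx(1.0)


class TestFileFormats:
    @pytest.mark.parametrize("fmt", ["msh", "vtk"])
    def test_round_trip_preserves_labels(self, coarse_shell, tmp_path, fmt):
        path = tmp_path / f"shell.{fmt}"
        if fmt == "msh":
            write_msh(coarse_shell, path)
        else:
            write_vtk_mesh(coarse_shell, path)
        m = read_mesh(path)
        assert m.n_nodes == coarse_shell.n_nodes
        assert m.n_elements == coarse_shell.n_elements
        assert np.allclose(m.nodes, coarse_shell.nodes)
        assert np.array_equal(np.sort(m.facet_tag),
                              np.sort(coarse_shell.facet_tag))
        assert np.array_equal(m.territory, coarse_shell.territory)
        assert np.array_equal(m.hemisphere, coarse_shell.hemisphere)

    def test_mm_unit_hint_scales_to_metres(self, coarse_shell, tmp_path):
        mm = LabeledMesh(coarse_shell.nodes * 1e3, coarse_shell.tets,
                         coarse_shell.boundary_facets,
                         coarse_shell.facet_tag, coarse_shell.territory,
                         coarse_shell.hemisphere)
        path = tmp_path / "mm.msh"
        write_msh(mm, path)
        m = read_mesh(path, unit_scale=1e-3)
        assert np.allclose(m.nodes, coarse_shell.nodes)

    def test_hexahedral_cells_rejected(self, tmp_path):
        path = tmp_path / "hex.msh"
        path.write_text(
            "$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
            "$Nodes\n8\n1 0 0 0\n2 1 0 0\n3 1 1 0\n4 0 1 0\n"
            "5 0 0 1\n6 1 0 1\n7 1 1 1\n8 0 1 1\n$EndNodes\n"
            "$Elements\n1\n1 5 2 1 1 1 2 3 4 5 6 7 8\n$EndElements\n")
        with pytest.raises(MeshError, match="non-tetrahedral"):
            read_mesh(path)

    def test_untagged_boundary_rejected(self, tmp_path):
        path = tmp_path / "untagged.msh"
        path.write_text(
            "$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
            "$Nodes\n4\n1 0 0 0\n2 1 0 0\n3 0 1 0\n4 0 0 1\n$EndNodes\n"
            "$Elements\n1\n1 4 2 1 0 1 2 3 4\n$EndElements\n")
        with pytest.raises(MeshError, match="tags"):
            read_mesh(path)
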