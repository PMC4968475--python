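import numpy as np
import pytest

from spherewall.geometry import (
    ResolutionError,
    SphereSpec,
    build_reduced_domain,
    build_sphere_mesh,
    graded_sphere_quadrature,
    write_vtk_surface,
)
from spherewall.units import ChannelSpec


@pytest.fixture(scope="module")
def domain():
    return build_reduced_domain(
        SphereSpec(diameter=10e-6, gap=0.069e-6), ChannelSpec(), resolution="medium"
    )


class TestReducedDomain:
    def test_inlet_cross_section(self, domain):
        w, h = domain.outline(-0.5 * domain.length)
        assert w == pytest.approx(80e-6, rel=1e-9)
        assert h == pytest.approx(40e-6, rel=1e-9)

    def test_area_preserved_at_every_station(self, domain):
        assert domain.area_preservation_error(513) < 1e-3

    def test_outline_returns_to_inlet_at_outlet(self, domain):
        w_in, h_in = domain.outline(-0.5 * domain.length)
        w_out, h_out = domain.outline(+0.5 * domain.length)
        assert w_out == pytest.approx(w_in, rel=1e-9)
        assert h_out == pytest.approx(h_in, rel=1e-9)

    def test_bulge_smooth_and_symmetric(self, domain):
        x = np.linspace(-0.5 * domain.length, 0.5 * domain.length, 1001)
        lam = domain.bulge(x)
        assert np.allclose(lam, lam[::-1], rtol=1e-9)

    def test_bulge_continuously_differentiable(self, domain):
        """Second differences of the outline shrink with the sampling
        step (they saturate at a kink, vanish for a C1 profile)."""
        jumps = []
        for n in (501, 2001):
            x = np.linspace(-0.5 * domain.length, 0.5 * domain.length, n)
            dlam = np.gradient(domain.bulge(x), x)
            jumps.append(np.max(np.abs(np.diff(dlam))))
        assert jumps[1] < 0.5 * jumps[0]

    def test_degenerate_no_sphere_is_straight_duct(self):
        dom = build_reduced_domain(
            SphereSpec(diameter=1e-9, gap=1e-9), ChannelSpec(), resolution="coarse"
        )
        lam = dom.bulge(np.linspace(-0.5 * dom.length, 0.5 * dom.length, 101))
        assert np.max(np.abs(lam - 1.0)) < 1e-6

    def test_domain_length_covers_eight_diameters(self, domain):
        assert domain.length >= 8 * domain.sphere.diameter

    def test_unknown_resolution_rejected(self):
        with pytest.raises(ResolutionError):
            build_reduced_domain(
                SphereSpec(diameter=10e-6, gap=1e-6), ChannelSpec(), resolution="ultra"
            )

    def test_gap_layer_grading(self, domain):
        """At least the configured number of volume layers lie in the gap."""
        y = domain.grid["y"]
        assert (y[y <= domain.sphere.gap * (1 + 1e-9)].size - 1) >= 4


class TestSphereMeshes:
    def test_facet_mesh_invariants(self):
        sp = SphereSpec(diameter=10e-6, gap=0.069e-6)
        mesh = build_sphere_mesh(sp, n_target=2000)
        assert mesh.total_area == pytest.approx(np.pi * sp.diameter ** 2, rel=1e-3)
        assert mesh.closed_surface_defect() < 1e-6
        radii = np.linalg.norm(mesh.centroids, axis=1)
        assert np.allclose(radii, sp.radius, rtol=1e-6)

    def test_facet_count_near_target(self):
        sp = SphereSpec(diameter=10e-6, gap=1e-6)
        for n_target in (320, 1280, 5120):
            mesh = build_sphere_mesh(sp, n_target=n_target)
            assert abs(mesh.n_facets - n_target) <= 0.2 * n_target

    def test_too_few_facets_rejected(self):
        with pytest.raises(ResolutionError):
            build_sphere_mesh(SphereSpec(diameter=10e-6, gap=1e-6), n_target=64)

    def test_refinement_improves_area(self):
        """Flat-facet area error decreases monotonically under subdivision."""
        import trimesh

        sp = SphereSpec(diameter=10e-6, gap=1e-6)
        errors = []
        for k in (1, 2, 3):
            m = trimesh.creation.icosphere(subdivisions=k, radius=sp.radius)
            errors.append(abs(m.area / (4 * np.pi * sp.radius ** 2) - 1.0))
        assert errors[0] > errors[1] > errors[2]

    def test_quadrature_grid_exact_area_and_closure(self):
        sp = SphereSpec(diameter=10e-6, gap=0.069e-6)
        mesh = graded_sphere_quadrature(sp, n_theta=24, n_phi=16, grading=4.0)
        assert mesh.total_area == pytest.approx(np.pi * sp.diameter ** 2, rel=1e-12)
        assert mesh.closed_surface_defect() < 1e-12

    def test_contact_geometry_rejected(self):
        with pytest.raises(ValueError):
            SphereSpec(diameter=10e-6, gap=0.0)


def test_vtk_surface_writer(tmp_path):
    mesh = build_sphere_mesh(SphereSpec(diameter=10e-6, gap=1e-6), n_target=320)
    path = tmp_path / "sphere.vtk"
    write_vtk_surface(mesh, str(path))
    text = path.read_text()
    assert text.startswith("# vtk DataFile")
    assert "POLYGONS" in text
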