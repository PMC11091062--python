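"""Shared phantom fixtures: small, noise-free geometries with known truth."""

import numpy as np
import pytest

import vasculomorph as vm


@pytest.fixture(scope="session")
def straight_tube_phantom():
    """Axis-aligned cylinder, radius 60 um (4 vx) at 15 um voxels, 1600 um long."""
    tube = vm.straight_tube((300, 300, 150), (300, 300, 1750), 60.0, name="straight")
    spec = vm.PhantomSpec(shape_vx=(40, 40, 128), voxel_size_um=(15.0, 15.0, 15.0),
                          tubes=[tube])
    vol, truth, gt = vm.rasterize_phantom(spec)
    return spec, vol, truth, gt


@pytest.fixture(scope="session")
def y_phantom():
    """Three straight tubes meeting at one point: 3 segments, 1 branching node."""
    junction = (300.0, 450.0, 900.0)
    tubes = [
        vm.straight_tube((300, 450, 150), junction, 50.0, name="stem"),
        vm.straight_tube(junction, (300, 150, 1500), 50.0, name="arm_up"),
        vm.straight_tube(junction, (300, 750, 1500), 50.0, name="arm_down"),
    ]
    spec = vm.PhantomSpec(shape_vx=(40, 60, 112), voxel_size_um=(15.0, 15.0, 15.0),
                          tubes=tubes)
    vol, truth, gt = vm.rasterize_phantom(spec)
    return spec, vol, truth, gt


@pytest.fixture(scope="session")
def semicircle_phantom():
    """Half-circular arc tube: tortuosity pi/2 in the limit of fine sampling."""
    tube = vm.arc_tube(center=(900.0, 900.0), radius_arc_um=600.0, radius_um=50.0,
                       z_um=300.0, angle_start_deg=0.0, angle_extent_deg=180.0,
                       name="semicircle")
    spec = vm.PhantomSpec(shape_vx=(40, 120, 120), voxel_size_um=(15.0, 15.0, 15.0),
                          tubes=[tube])
    vol, truth, gt = vm.rasterize_phantom(spec)
    return spec, vol, truth, gt


@pytest.fixture(scope="session")
def torus_mask():
    """Solid torus mask: one connected component containing one cycle."""
    zz, yy, xx = np.indices((11, 48, 48))
    r_inplane = np.hypot(yy - 24, xx - 24)
    return ((r_inplane - 15) ** 2 + (zz - 5) ** 2) <= 3.0**2


@pytest.fixture(scope="session")
def half_annulus_phantom():
    """Half-annulus tissue (inner 10 mm, outer 20 mm) with a 1 mm PM band.

    Voxel size 200 um; the analytic PM mask (outer 1 mm) and the in-plane
    radius field are returned alongside for closed-form comparisons.
    """
    vs = (200.0, 200.0, 200.0)
    shape = (10, 125, 225)
    center = (2400.0, 22400.0)
    spec = vm.PhantomSpec(
        shape_vx=shape, voxel_size_um=vs, tubes=[],
        tissue=vm.WedgeParams(center_um=center, inner_radius_um=10_000.0,
                              outer_radius_um=20_000.0, angle_start_deg=0.0,
                              angle_extent_deg=180.0, pm_band_um=1000.0),
    )
    tissue = vm.make_wedge_tissue(spec)
    zz, yy, xx = np.indices(shape)
    rho = np.hypot(yy * vs[1] - center[0], xx * vs[2] - center[1])
    pm = tissue & (rho > 19_000.0)
    return spec, tissue, pm, rho, center


@pytest.fixture(scope="session")
def peripheral_vessel_phantom(half_annulus_phantom):
    """Wedge tissue with vessels dense peripherally, sparse toward the free edge.

    Arc vessels are laid at mid-band radii of the PM band and of each Cooper
    zone with decreasing caliber and angular span, mimicking the centripetal
    perimeniscal supply.
    """
    spec0, tissue, pm, _, center = half_annulus_phantom
    tubes = [
        vm.arc_tube(center, 19_400.0, 260.0, 900.0, 15.0, 150.0, name="pm_a"),
        vm.arc_tube(center, 19_600.0, 260.0, 1300.0, 10.0, 160.0, name="pm_b"),
        vm.arc_tube(center, 17_500.0, 240.0, 1100.0, 30.0, 120.0, name="z1"),
        vm.arc_tube(center, 14_500.0, 200.0, 1100.0, 60.0, 60.0, name="z2"),
        vm.arc_tube(center, 11_500.0, 150.0, 1100.0, 85.0, 12.0, name="z3"),
    ]
    spec = vm.PhantomSpec(shape_vx=spec0.shape_vx, voxel_size_um=spec0.voxel_size_um,
                          tubes=tubes, tissue=spec0.tissue)
    _, vessel_mask, _ = vm.rasterize_phantom(spec)
    from vasculomorph.zonation import circumferential_zones

    zm = circumferential_zones(tissue, spec.voxel_size_um, pm_mask=pm)
    return spec, zm, vessel_mask
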