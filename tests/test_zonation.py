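"""Circumferential thirds, radial sectors and zone-wise vascular metrics."""

import numpy as np
import pandas as pd
import pytest

import vasculomorph as vm
from vasculomorph.zonation import (
    CIRC_LABELS,
    RADIAL_LABELS,
    ZoneMap,
    circumferential_zones,
    radial_sectors,
    zone_contributions,
    zone_morphometry,
)


def _circ_fracs(zm, remainder):
    tot = remainder.sum()
    return {name: (zm.circ == code).sum() / tot
            for code, name in CIRC_LABELS.items() if name.startswith("Z")}


class TestCircumferentialZones:
    def test_half_annulus_thirds_match_closed_form_areas(self, half_annulus_phantom):
        _, tissue, pm, rho, _ = half_annulus_phantom
        zm = circumferential_zones(tissue, (200.0,) * 3, pm_mask=pm)
        remainder = tissue & ~pm
        fracs = _circ_fracs(zm, remainder)
        # equal-thickness shells of the annulus 10 -> 19 mm
        closed = {"Z1": (19**2 - 16**2) / (19**2 - 10**2),
                  "Z2": (16**2 - 13**2) / (19**2 - 10**2),
                  "Z3": (13**2 - 10**2) / (19**2 - 10**2)}
        for name in ("Z1", "Z2", "Z3"):
            assert abs(fracs[name] - closed[name]) < 0.03

    def test_labels_partition_the_tissue(self, half_annulus_phantom):
        _, tissue, pm, _, _ = half_annulus_phantom
        zm = circumferential_zones(tissue, (200.0,) * 3, pm_mask=pm)
        assert np.all((zm.circ > 0) == tissue)       # every tissue voxel labeled
        assert np.all(zm.circ[~tissue] == 0)         # nothing outside labeled

    def test_zone_boundaries_follow_the_radius(self, half_annulus_phantom):
        _, tissue, pm, rho, _ = half_annulus_phantom
        zm = circumferential_zones(tissue, (200.0,) * 3, pm_mask=pm)
        # away from the cut faces, Z1 voxels sit outward of Z3 voxels
        z1 = rho[(zm.circ == 2)]
        z3 = rho[(zm.circ == 4)]
        assert np.median(z1) > np.median(z3)

    def test_pm_band_fallback_agrees_with_explicit_mask_on_annulus(self):
        # the band fallback assumes a star-convex periphery: use a full annulus
        vs = (200.0,) * 3
        center = (12_000.0, 12_000.0)
        spec = vm.PhantomSpec(
            shape_vx=(6, 120, 120), voxel_size_um=vs, tubes=[],
            tissue=vm.WedgeParams(center_um=center, inner_radius_um=5_000.0,
                                  outer_radius_um=11_000.0, angle_extent_deg=360.0),
        )
        tissue = vm.make_wedge_tissue(spec)
        zz, yy, xx = np.indices(spec.shape_vx)
        rho = np.hypot(yy * 200.0 - center[0], xx * 200.0 - center[1])
        pm = tissue & (rho > 10_000.0)
        by_mask = circumferential_zones(tissue, vs, pm_mask=pm)
        by_band = circumferential_zones(tissue, vs, pm_band_um=1000.0)
        agree = (by_mask.circ == by_band.circ)[tissue].mean()
        assert agree > 0.9

    def test_requires_exactly_one_pm_source(self, half_annulus_phantom):
        _, tissue, pm, _, _ = half_annulus_phantom
        with pytest.raises(ValueError, match="exactly one"):
            circumferential_zones(tissue, (200.0,) * 3)
        with pytest.raises(ValueError, match="exactly one"):
            circumferential_zones(tissue, (200.0,) * 3, pm_mask=pm, pm_band_um=500.0)

    def test_thin_degenerate_tissue_still_fully_labeled(self):
        tissue = np.zeros((3, 5, 30), bool)
        tissue[1, 2, 2:28] = True
        pm = np.zeros_like(tissue)
        pm[1, 2, 25:28] = True
        zm = circumferential_zones(tissue, 100.0, pm_mask=pm)
        assert np.all(zm.circ[tissue] > 0)

    def test_zonemap_is_deterministic(self, half_annulus_phantom):
        _, tissue, pm, _, _ = half_annulus_phantom
        a = circumferential_zones(tissue, (200.0,) * 3, pm_mask=pm)
        b = circumferential_zones(tissue, (200.0,) * 3, pm_mask=pm)
        assert np.array_equal(a.circ, b.circ)


class TestRadialSectors:
    def test_half_annulus_sectors_equal_volume_with_arc_center(self, half_annulus_phantom):
        _, tissue, _, _, center = half_annulus_phantom
        zm = radial_sectors(tissue, (200.0,) * 3, sagittal_axis=(0, 0, 1),
                            center_um=center)
        tot = tissue.sum()
        for code in (1, 2, 3, 4):
            frac = (zm.radial == code).sum() / tot
            assert frac == pytest.approx(0.25, abs=0.02)

    def test_sectors_partition_the_tissue(self, half_annulus_phantom):
        _, tissue, _, _, _ = half_annulus_phantom
        zm = radial_sectors(tissue, (200.0,) * 3)
        assert np.all((zm.radial > 0) == tissue)

    def test_rotating_the_axis_by_45_degrees_shifts_sector_labels(
        self, half_annulus_phantom
    ):
        _, tissue, _, _, center = half_annulus_phantom
        base = radial_sectors(tissue, (200.0,) * 3, sagittal_axis=(0, 0, 1),
                              center_um=center)
        c, s = np.cos(np.radians(45)), np.sin(np.radians(45))
        # axis rotated by -45 degrees: every in-plane angle grows by 45,
        # so labels shift one sector (up to exact-boundary voxels)
        rot = radial_sectors(tissue, (200.0,) * 3, sagittal_axis=(0, -s, c),
                             center_um=center)
        inner = tissue & (base.radial == 1)
        moved = rot.radial[inner]
        assert (moved == 2).mean() > 0.95

    def test_medial_flag_mirrors_the_order(self, half_annulus_phantom):
        _, tissue, _, _, center = half_annulus_phantom
        lat = radial_sectors(tissue, (200.0,) * 3, sagittal_axis=(0, 0, 1),
                             center_um=center, side="lateral")
        med = radial_sectors(tissue, (200.0,) * 3, sagittal_axis=(0, 0, 1),
                             center_um=center, side="medial")
        zz, yy, xx = np.indices(tissue.shape)
        theta = np.degrees(np.arctan2(yy * 200.0 - center[0], xx * 200.0 - center[1]))
        off_boundary = tissue & (np.abs(theta % 45.0) > 1e-9)
        mirror = 5 - lat.radial.astype(int)
        # exact mirror everywhere off the 45-degree cut planes (where the
        # half-open binning necessarily breaks the symmetry)
        assert np.array_equal(med.radial[off_boundary], mirror[off_boundary])

    def test_zero_axis_rejected(self, half_annulus_phantom):
        _, tissue, _, _, _ = half_annulus_phantom
        with pytest.raises(ValueError, match="non-zero"):
            radial_sectors(tissue, (200.0,) * 3, sagittal_axis=(1, 0, 0))


class TestZoneContributions:
    def _zonemap_from_counts(self):
        """Tiny synthetic map holding exactly {PM:720, Z1:240, Z2:30, Z3:10}
        vessel voxels."""
        circ = np.zeros((1, 40, 40), np.uint8)
        vessels = np.zeros((1, 40, 40), bool)
        flat_circ = circ.reshape(-1)
        flat_ves = vessels.reshape(-1)
        start = 0
        for code, n in [(1, 720), (2, 240), (3, 30), (4, 10)]:
            flat_circ[start:start + n] = code
            flat_ves[start:start + n] = True
            start += n
        return ZoneMap(circ=circ, radial=None, voxel_size_um=(100.0,) * 3), vessels

    def test_fraction_arithmetic_matches_hand_computation(self):
        zm, vessels = self._zonemap_from_counts()
        table = zone_contributions(zm, vessels).set_index("zone")
        assert table.loc["PM", "fraction"] == pytest.approx(0.72)
        assert table.loc["Z1", "fraction"] == pytest.approx(0.24)
        assert table.loc["Z2", "fraction"] == pytest.approx(0.03)
        assert table.loc["Z3", "fraction"] == pytest.approx(0.01)
        assert table.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exclude_pm_renormalizes(self):
        zm, vessels = self._zonemap_from_counts()
        table = zone_contributions(zm, vessels, exclude_pm=True).set_index("zone")
        assert "PM" not in table.index
        assert table.loc["Z1", "fraction"] == pytest.approx(240 / 280)
        assert table.loc["Z2", "fraction"] == pytest.approx(30 / 280)
        assert table.loc["Z3", "fraction"] == pytest.approx(10 / 280)
        assert table.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_vessels_confined_to_one_zone(self):
        zm, _ = self._zonemap_from_counts()
        vessels = zm.circ == 2
        table = zone_contributions(zm, vessels).set_index("zone")
        assert table.loc["Z1", "fraction"] == pytest.approx(1.0)
        assert table.drop("Z1").fraction.sum() == 0.0

    def test_empty_vessel_mask_warns_and_returns_zeros(self):
        zm, _ = self._zonemap_from_counts()
        with pytest.warns(UserWarning, match="empty"):
            table = zone_contributions(zm, np.zeros_like(zm.circ, bool))
        assert (table.fraction == 0).all()

    def test_peripheral_vessel_phantom_reproduces_pm_dominance(
        self, peripheral_vessel_phantom
    ):
        """Vessels dense in the PM band and sparse inside: PM > Z1 > Z2 > Z3."""
        spec, zm, vessel_mask = peripheral_vessel_phantom
        table = zone_contributions(zm, vessel_mask).set_index("zone")
        f = table.fraction
        assert f["PM"] > f["Z1"] > f["Z2"] > f["Z3"]
        assert f["PM"] > 0.5


class TestZoneMorphometry:
    def test_majority_rule_assigns_straddling_segment(self):
        circ = np.zeros((1, 1, 10), np.uint8)
        circ[0, 0, :6] = 2   # Z1
        circ[0, 0, 6:] = 3   # Z2
        zm = ZoneMap(circ=circ, radial=None, voxel_size_um=(10.0,) * 3)
        from vasculomorph.skeleton import VesselSegment, VesselGraph

        pts = np.array([[0, 0, x * 10.0] for x in range(10)])
        seg = VesselSegment(id=0, node_a=None, node_b=None, points_um=pts,
                            radii_um=np.full(10, 5.0))
        graph = VesselGraph(nodes=[], segments=[seg], voxel_size_um=(10.0,) * 3,
                            shape=(1, 1, 10))
        table = zone_morphometry(zm, graph).set_index("zone")
        assert table.loc["Z1", "n_segments"] == 1
        assert table.loc["Z2", "n_segments"] == 0

    def test_per_zone_totals_sum_to_network_total(self, peripheral_vessel_phantom):
        spec, zm, vessel_mask = peripheral_vessel_phantom
        from vasculomorph.skeleton import build_graph, distance_map, skeletonize

        graph = build_graph(skeletonize(vessel_mask),
                            distance_map(vessel_mask, spec.voxel_size_um))
        table = zone_morphometry(zm, graph)
        total = sum(vm.segment_metrics(s).curved_length_um for s in graph.segments)
        assert table.total_length_mm.sum() * 1000 == pytest.approx(total, rel=1e-9)
        assert table.n_segments.sum() == len(graph.segments)
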