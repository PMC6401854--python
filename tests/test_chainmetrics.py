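"""Geometry descriptors: oracles, invariances and the idealized builder."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from paacs.chainmetrics import (
    PAAC_TEMPLATE,
    Conformer,
    backbone_torsions,
    build_extended_chain,
    chain_from_torsions,
    describe,
    dipole_moment,
    end_to_end,
    radius_of_gyration,
    sasa,
    transoid_fraction,
)
from paacs.exceptions import AnalysisError, DomainError


def _conf(coords, elements=None, **kw):
    coords = np.asarray(coords, dtype=float)
    if elements is None:
        elements = np.array(["C"] * len(coords), dtype=object)
    return Conformer(elements=np.asarray(elements, dtype=object), coords=coords, **kw)


class TestEndToEnd:
    def test_axis_aligned_pair(self):
        c = _conf([[0, 0, 0], [0, 0, 10.0]], backbone=[0, 1])
        assert end_to_end(c) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(30, 3)) * 5
        c = _conf(coords, backbone=np.arange(30))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = c.transformed(rotation=rot, translation=[3.0, -7.0, 11.0])
        assert end_to_end(moved) == pytest.approx(end_to_end(c), abs=1e-10)

    def test_missing_backbone_is_error(self):
        with pytest.raises(AnalysisError):
            end_to_end(_conf([[0, 0, 0], [1, 0, 0]]))


class TestRadiusOfGyration:
    def test_dumbbell_is_half_separation(self):
        c = _conf([[0, 0, 0], [10.0, 0, 0]])
        assert radius_of_gyration(c) == pytest.approx(0.5)

    def test_uniform_cube_analytic(self):
        a = 2.0  # Angstrom edge
        corners = [
            [x, y, z] for x in (0, a) for y in (0, a) for z in (0, a)
        ]
        c = _conf(corners, elements=["H"] * 8)
        assert radius_of_gyration(c) == pytest.approx(a * math.sqrt(3) / 2 / 10)

    def test_mass_weighting_shifts_center(self):
        c = _conf(
            [[0, 0, 0], [10.0, 0, 0]],
            elements=["H", "C"],  # 1.008 vs 12.011 amu
        )
        unweighted = radius_of_gyration(c, mass_weighted=False)
        weighted = radius_of_gyration(c, mass_weighted=True)
        assert weighted < unweighted  # heavy atom pulls the center


class TestDipole:
    def test_unit_charge_pair_conversion_constant(self):
        c = _conf(
            [[0, 0, 0], [1.0, 0, 0]], elements=["H", "H"],
            charges=np.array([1.0, -1.0]),
        )
        assert dipole_moment(c).debye == pytest.approx(4.803, abs=1e-3)

    def test_zero_charges_zero_dipole(self):
        c = _conf([[0, 0, 0], [1.0, 2, 3]], charges=np.zeros(2))
        assert dipole_moment(c).debye == 0.0

    def test_neutral_system_translation_invariant(self, rng):
        coords = rng.normal(size=(12, 3))
        q = rng.normal(size=12)
        q -= q.mean()  # enforce neutrality
        a = dipole_moment(_conf(coords, charges=q))
        b = dipole_moment(_conf(coords + 100.0, charges=q))
        assert a.debye == pytest.approx(b.debye, abs=1e-8)
        assert a.net_charge == pytest.approx(0.0, abs=1e-12)

    def test_charged_system_reports_origin(self):
        c = _conf([[0, 0, 0], [1.0, 0, 0]], charges=np.array([1.0, 1.0]))
        res = dipole_moment(c, origin="center_of_mass")
        assert res.origin == "center_of_mass" and res.net_charge == 2.0

    def test_missing_charges_rejected(self):
        with pytest.raises(DomainError):
            dipole_moment(_conf([[0, 0, 0]]))


class TestSasa:
    def test_single_sphere_analytic(self):
        c = _conf([[0, 0, 0]], radii=np.array([1.5]))
        expected = 4 * math.pi * (1.5 + 1.4) ** 2 / 100  # nm^2
        assert sasa(c, probe_radius=0.14) == pytest.approx(expected, rel=0.01)

    def test_far_separated_atoms_additive(self):
        one = _conf([[0, 0, 0]], radii=np.array([1.7]))
        two = _conf([[0, 0, 0], [100.0, 0, 0]], radii=np.array([1.7, 1.7]))
        assert sasa(two) == pytest.approx(2 * sasa(one), rel=1e-9)

    def test_buried_atom_contributes_nothing(self):
        # small atom caged at the center of a tight octahedron of large atoms
        d = 2.0
        cage = np.array(
            [[d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0], [0, 0, d], [0, 0, -d]]
        )
        big = np.full(6, 2.5)
        cage_only = _conf(cage, radii=big)
        with_center = _conf(
            np.vstack([[0.0, 0.0, 0.0], cage]),
            radii=np.concatenate([[0.8], big]),
        )
        assert sasa(with_center) == pytest.approx(sasa(cage_only), rel=5e-3)

    def test_exact_duplicates_not_double_counted(self):
        one = _conf([[0, 0, 0]], radii=np.array([1.7]))
        dup = _conf([[0, 0, 0], [0, 0, 0]], radii=np.array([1.7, 1.7]))
        assert sasa(dup) == pytest.approx(sasa(one), rel=1e-9)

    def test_convergence_with_point_count(self):
        conf = build_extended_chain(n_units=1)
        coarse = sasa(conf, n_sphere_points=960)
        fine = sasa(conf, n_sphere_points=3840)
        assert abs(coarse - fine) / fine < 0.005

    def test_rotation_invariance(self, rng):
        conf = build_extended_chain(n_units=2)
        rot = Rotation.random(random_state=11).as_matrix()
        moved = conf.transformed(rotation=rot, translation=[1.0, 2.0, 3.0])
        assert sasa(moved) == pytest.approx(sasa(conf), rel=5e-3)


class TestTorsions:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)], 180.0),  # planar trans
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], 0.0),    # planar cis
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], -90.0),  # right angle
        ],
    )
    def test_canonical_quadruples(self, points, expected):
        c = _conf(points, backbone=np.arange(4))
        t = backbone_torsions(c)
        assert t[0] == pytest.approx(expected, abs=1e-9)

    def test_matches_projection_oracle_on_random_quadruples(self, rng):
        """Cross-check against an independent plane-projection construction."""
        for _ in range(50):
            p = rng.normal(size=(4, 3)) * 3
            b2 = p[2] - p[1]
            b2 /= np.linalg.norm(b2)
            v1 = (p[0] - p[1]) - np.dot(p[0] - p[1], b2) * b2
            v2 = (p[3] - p[2]) - np.dot(p[3] - p[2], b2) * b2
            if np.linalg.norm(v1) < 1e-6 or np.linalg.norm(v2) < 1e-6:
                continue
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            mag = math.degrees(math.acos(np.clip(cosang, -1, 1)))
            # IUPAC sign: negative when v2 is counter-clockwise from v1
            # looking down the central bond
            sign = -math.copysign(1.0, np.dot(np.cross(v1, v2), b2))
            t = backbone_torsions(_conf(p, backbone=np.arange(4)))[0]
            assert t == pytest.approx(sign * mag, abs=1e-8)

    def test_collinear_triple_flagged_nan(self):
        c = _conf(
            [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)], backbone=np.arange(4)
        )
        assert np.isnan(backbone_torsions(c)[0])

    def test_transoid_fraction_threshold(self):
        t = np.array([180.0, -179.0, 150.0, -150.0, 120.0, 60.0, np.nan])
        assert transoid_fraction(t, threshold=150.0) == pytest.approx(4 / 6)


def _zigzag_projection_e2e(template, n_units):
    """Independent 2-D turtle construction of the all-trans end-to-end, nm.

    A planar all-trans chain alternates turn direction by the bond-angle
    supplement; summing the bond vectors in the plane gives the exact
    end-to-end displacement.
    """
    p = len(template.elements)
    n_bb = n_units * p
    heading = 0.0
    pos = np.zeros(2)
    first = pos.copy()
    sign = 1.0
    for i in range(1, n_bb):
        length = template.bond_lengths[i % p]
        if i > 1:
            angle = template.bond_angles[i % p]
            heading += sign * math.radians(180.0 - angle)
            sign = -sign
        pos = pos + length * np.array([math.cos(heading), math.sin(heading)])
    return float(np.linalg.norm(pos - first)) / 10.0


class TestBuilder:
    def test_single_unit_layout(self):
        conf = build_extended_chain(n_units=1)
        assert conf.backbone.size == 10
        torsions = backbone_torsions(conf)
        assert torsions.size == 7  # n_backbone - 3 dihedrals
        assert np.allclose(np.abs(torsions), 180.0, atol=1e-6)

    def test_all_trans_chain_is_fully_transoid(self):
        conf = build_extended_chain(n_units=10)
        assert transoid_fraction(backbone_torsions(conf)) == 1.0

    def test_end_to_end_matches_zigzag_projection(self):
        conf = build_extended_chain(n_units=10)
        oracle = _zigzag_projection_e2e(PAAC_TEMPLATE, 10)
        assert end_to_end(conf) == pytest.approx(oracle, rel=0.02)
        assert end_to_end(conf) >= 0.95 * oracle

    def test_doubling_units_doubles_length(self):
        e10 = end_to_end(build_extended_chain(n_units=10))
        e20 = end_to_end(build_extended_chain(n_units=20))
        assert e20 / e10 == pytest.approx(2.0, rel=0.01)

    def test_torsion_specification_honoured(self):
        n_bb = 2 * 10
        torsions = np.linspace(-170, 170, n_bb - 3)
        conf = chain_from_torsions(torsions, n_units=2, side_chain=False)
        assert np.allclose(backbone_torsions(conf), torsions, atol=1e-6)

    def test_wrong_torsion_count_rejected(self):
        with pytest.raises(DomainError):
            chain_from_torsions(np.zeros(5), n_units=2)

    def test_side_chain_pseudo_atoms_attached(self):
        bare = build_extended_chain(n_units=3, side_chain=False)
        dressed = build_extended_chain(n_units=3, side_chain=True)
        assert dressed.n_atoms == bare.n_atoms + 3
        assert dressed.backbone.size == bare.n_atoms


class TestDescribe:
    def test_full_descriptor_bundle(self):
        conf = build_extended_chain(n_units=2)
        ds = describe(conf, n_sphere_points=240)
        d = ds.to_dict()
        assert d["transoid_fraction"] == 1.0
        assert d["rg_nm"] > 0 and d["sasa_nm2"] > 0
        assert "dipole_debye" not in d  # no charges supplied
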