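"""Collective variables: closed-form examples, invariances, gradients, walls."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bemd import (
    CVDefinition, Wall, coordination_number, dihedral_correlation,
    dihedral_similarity_alpha, hbond_count, make_bead_peptide, softmin_distance,
)
from bemd.geometry import DegenerateGeometryError


def _place(*points):
    return np.asarray(points, dtype=float)


class TestCoordinationNumber:
    def test_close_pair_saturates_to_one(self):
        c = _place([0, 0, 0], [1e-4, 0, 0])
        v = coordination_number(c, [0], [1], r0=0.65)
        assert v.value == pytest.approx(1.0, abs=1e-10)

    def test_pair_at_r0_equals_n_over_m(self):
        c = _place([0, 0, 0], [0.65, 0, 0])
        v = coordination_number(c, [0], [1], r0=0.65, n=6, m=12)
        assert v.value == pytest.approx(0.5, abs=1e-9)

    def test_equilateral_triangle_closed_form(self):
        """Three mutual pairs at r = r0/2 give 3*(1-2^-6)/(1-2^-12)."""
        r = 0.325  # r0/2 with r0 = 0.65
        c = _place([0, 0, 0], [r, 0, 0], [r / 2, r * np.sqrt(3) / 2, 0])
        v = coordination_number(c, [0, 1, 2], [0, 1, 2], r0=0.65)
        expected = 3 * (1 - 2.0**-6) / (1 - 2.0**-12)
        assert v.value == pytest.approx(expected, rel=1e-12)

    def test_rejects_nondecaying_exponents(self):
        c = _place([0, 0, 0], [0.4, 0, 0])
        with pytest.raises(ValueError, match="n < m"):
            coordination_number(c, [0], [1], r0=0.65, n=12, m=6)

    def test_rejects_partially_overlapping_groups(self):
        c = _place([0, 0, 0], [0.4, 0, 0], [0.9, 0, 0])
        with pytest.raises(ValueError, match="disjoint or identical"):
            coordination_number(c, [0, 1], [1, 2], r0=0.65)


class TestHbondCount:
    def test_distant_pairs_vanish(self):
        c = _place([0, 0, 0], [1.0, 0, 0])
        v = hbond_count(c, [0], [1], r0=0.25)
        assert v.value < 0.01

    def test_pair_at_r0_is_half(self):
        c = _place([0, 0, 0], [0.25, 0, 0])
        assert hbond_count(c, [0], [1], r0=0.25).value == pytest.approx(0.5, abs=1e-9)

    def test_symmetric_under_role_swap(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 0.6, size=(6, 3))
        a = hbond_count(c, [0, 1, 2], [3, 4, 5], r0=0.25)
        b = hbond_count(c, [3, 4, 5], [0, 1, 2], r0=0.25)
        assert a.value == pytest.approx(b.value, rel=1e-12)


def _psi_chain(angles):
    """Build a 3-D chain whose successive dihedrals equal the given angles."""
    coords = [np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 1.0, 0])]
    for phi in angles:
        # place next atom so the dihedral over the last four equals phi
        a, b, c3 = coords[-3], coords[-2], coords[-1]
        e1 = (c3 - b) / np.linalg.norm(c3 - b)
        ref = (b - a) - np.dot(b - a, e1) * e1
        ref = ref / np.linalg.norm(ref)
        perp = np.cross(e1, ref)
        coords.append(c3 + e1 + np.cos(np.pi - phi) * ref - np.sin(np.pi - phi) * perp)
    return np.asarray(coords)


class TestDihedralCVs:
    def test_similarity_maximal_at_reference(self):
        coords = _psi_chain([-0.82, -0.82, -0.82])
        quads = [[i, i + 1, i + 2, i + 3] for i in range(3)]
        v = dihedral_similarity_alpha(coords, quads, psi_ref=-0.82)
        assert v.value == pytest.approx(3.0, abs=1e-8)

    def test_similarity_zero_at_antireference(self):
        coords = _psi_chain([np.pi - 0.82, np.pi - 0.82])
        quads = [[i, i + 1, i + 2, i + 3] for i in range(2)]
        v = dihedral_similarity_alpha(coords, quads, psi_ref=-0.82)
        assert v.value == pytest.approx(0.0, abs=1e-8)

    def test_similarity_half_at_quarter_offsets(self):
        coords = _psi_chain([-0.82 + np.pi / 2, -0.82 - np.pi / 2])
        quads = [[i, i + 1, i + 2, i + 3] for i in range(2)]
        v = dihedral_similarity_alpha(coords, quads, psi_ref=-0.82)
        assert v.value == pytest.approx(1.0, abs=1e-8)

    def test_correlation_equal_angles_is_n_minus_1(self):
        coords = _psi_chain([0.7, 0.7, 0.7])
        quads = [[i, i + 1, i + 2, i + 3] for i in range(3)]
        assert dihedral_correlation(coords, quads).value == pytest.approx(2.0, abs=1e-8)

    def test_correlation_alternating_by_pi_is_zero(self):
        coords = _psi_chain([0.5, 0.5 + np.pi])
        quads = [[i, i + 1, i + 2, i + 3] for i in range(2)]
        assert dihedral_correlation(coords, quads).value == pytest.approx(0.0, abs=1e-8)

    def test_correlation_hand_computed_sequence(self):
        """Angles (0, pi/3, pi/3): (1+cos(pi/3))/2 + 1 = 1.75."""
        coords = _psi_chain([0.0, np.pi / 3, np.pi / 3])
        quads = [[i, i + 1, i + 2, i + 3] for i in range(3)]
        assert dihedral_correlation(coords, quads).value == pytest.approx(1.75, abs=1e-8)

    def test_collinear_quadruple_rejected(self):
        coords = _place([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            dihedral_similarity_alpha(coords, [[0, 1, 2, 3]])


class TestSoftminDistance:
    def test_single_target_exact(self):
        c = _place([0, 0, 0], [0.37, 0, 0])
        v = softmin_distance(c, 0, [1], beta_s=1.0)
        assert v.value == pytest.approx(0.37, rel=1e-12)

    def test_two_targets_near_hard_minimum(self):
        c = _place([0, 0, 0], [0.4, 0, 0], [4.0, 0, 0])
        v = softmin_distance(c, 0, [1, 2], beta_s=1.0)
        assert abs(v.value - 0.4) / 0.4 < 0.05

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        c = rng.uniform(0.2, 1.5, size=(5, 3))
        a = softmin_distance(c, 0, [1, 2, 3, 4], beta_s=1.5)
        b = softmin_distance(c, 0, [4, 2, 1, 3], beta_s=1.5)
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_coincident_probe_rejected(self):
        c = _place([0, 0, 0], [0, 0, 0])
        with pytest.raises(ValueError, match="singular"):
            softmin_distance(c, 0, [1])


def _model_cvs():
    model = make_bead_peptide(11, holo=True, seed=9)
    defs = [
        CVDefinition("coord", "coordination", sigma=0.7, params={"r0": 0.65},
                     groups={"a": "calpha", "b": "calpha"}),
        CVDefinition("hb", "hbond_count", sigma=0.25, params={"r0": 0.25},
                     groups={"donor": "donor", "acceptor": "acceptor"}),
        CVDefinition("alpha", "dihedral_similarity", sigma=0.25),
        CVDefinition("corr", "dihedral_correlation", sigma=0.25),
        CVDefinition("lig", "softmin_distance", sigma=0.05, params={"beta_s": 2.0},
                     groups={"probe": "ligand_c1", "target": "calpha"}),
    ]
    return model, defs


def test_rotation_translation_invariance_of_all_cv_kinds():
    model, defs = _model_cvs()
    rng = np.random.default_rng(3)
    c = model.coordinates
    for trial in range(5):
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        c2 = c @ rot.T + rng.normal(size=3)
        for cv in defs:
            v1 = cv.evaluate(c, model).value
            v2 = cv.evaluate(c2, model).value
            assert v2 == pytest.approx(v1, abs=1e-10), cv.name


def test_cv_gradients_match_finite_differences():
    """All CV kinds: analytic gradient vs central differences on random frames."""
    model, defs = _model_cvs()
    rng = np.random.default_rng(11)
    h = 1e-6
    for frame in range(10):
        c = model.coordinates + 0.03 * rng.standard_normal(model.coordinates.shape)
        for cv in defs:
            v = cv.evaluate(c, model)
            for _ in range(3):
                i, d = rng.integers(0, c.shape[0]), rng.integers(0, 3)
                cp, cm = c.copy(), c.copy()
                cp[i, d] += h
                cm[i, d] -= h
                num = (cv.evaluate(cp, model).value - cv.evaluate(cm, model).value) / (2 * h)
                assert v.gradient[i, d] == pytest.approx(num, rel=1e-4, abs=1e-7), cv.name


def test_cv_bounds_respected_on_random_frames():
    model, defs = _model_cvs()
    n_dih = len(model.backbone_dihedral_quads())
    n_ca = len(model.group("calpha"))
    rng = np.random.default_rng(4)
    for _ in range(20):
        c = model.coordinates + 0.05 * rng.standard_normal(model.coordinates.shape)
        vals = {cv.name: cv.evaluate(c, model).value for cv in defs}
        assert 0.0 <= vals["alpha"] <= n_dih
        assert 0.0 <= vals["corr"] <= n_dih - 1
        assert 0.0 <= vals["coord"] <= n_ca * (n_ca - 1) / 2
        assert vals["hb"] >= 0.0


class TestWall:
    def test_zero_inside_bounds(self):
        w = Wall(lower=-1.0, upper=1.0, k=100.0)
        assert w.energy_dvds(0.3) == (0.0, 0.0)

    def test_quadratic_beyond_bounds(self):
        w = Wall(lower=-1.0, upper=1.0, k=100.0)
        e, dv = w.energy_dvds(1.5)
        assert e == pytest.approx(100.0 * 0.25)
        assert dv == pytest.approx(100.0)
        e, dv = w.energy_dvds(-1.2)
        assert e == pytest.approx(100.0 * 0.04)
        assert dv == pytest.approx(-40.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Wall(lower=1.0, upper=-1.0)


def test_cv_definition_validation():
    with pytest.raises(ValueError, match="kind"):
        CVDefinition("bad", "not_a_kind", sigma=0.1)
    with pytest.raises(ValueError, match="sigma"):
        CVDefinition("bad", "coordinate", sigma=0.0)
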