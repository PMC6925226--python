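"""Helix vectors, crossing angles, superposition and layer metrics."""

import numpy as np
import pytest

from capsgeom import synthetic as syn
from capsgeom.errors import (
    DegenerateGeometryError,
    HelixTooShortError,
    IncompleteBackboneError,
)
from capsgeom.geometry import (
    centroid_displacement,
    crossing_angle,
    helix_vector,
    layer_metrics,
    relative_domain_motion,
    superpose,
)
from capsgeom.pointgroup import _axis_rotation
from capsgeom.structure import Atom, StructureModel

from conftest import random_rotation


def _transformed(model, rot, shift):
    return model.with_coords(model.coords() @ rot.T + shift)


# -- helix vectors ----------------------------------------------------------


def test_helix_vector_direction_tracks_build_axis():
    """The half-centroid vector follows the helix axis.

    The estimator aliases with the 100-degree twist: residue counts whose
    half-spans are near whole turns (14, 22) track the axis to a fraction
    of a degree, while off-phase counts deviate by a few degrees.  The
    16-residue default marker helix stays within 1.5 degrees.
    """
    z = np.array([0.0, 0.0, 1.0])
    for n, tol in [(14, 0.5), (16, 1.5), (20, 1.0), (22, 0.5)]:
        hv = helix_vector(syn.make_ideal_helix(n))
        dev = np.degrees(np.arccos(min(1.0, float(hv.direction @ z))))
        assert dev < tol, (n, dev)


def test_helix_vector_agrees_with_pca_axis_fit():
    """Independent least-squares axis oracle, honest per-length bounds."""
    for n in (15, 16, 17, 18, 20, 24):
        model = syn.make_ideal_helix(n)
        hv = helix_vector(model)
        x = model.coords() - model.coords().mean(axis=0)
        pca_axis = np.linalg.svd(x)[2][0]
        dev = np.degrees(np.arccos(min(1.0, abs(float(hv.direction @ pca_axis)))))
        assert dev < 3.0, (n, dev)


def test_helix_vector_is_rigid_motion_equivariant():
    rng = np.random.default_rng(11)
    base = syn.make_ideal_helix(16)
    hv0 = helix_vector(base)
    for _ in range(10):
        rot = random_rotation(rng)
        shift = rng.normal(scale=30, size=3)
        hv = helix_vector(_transformed(base, rot, shift))
        assert np.abs(hv.direction - rot @ hv0.direction).max() < 1e-6
        assert np.abs(hv.centroid - (rot @ hv0.centroid + shift)).max() < 1e-6


def test_helix_vector_reversed_residue_order_negates_direction():
    model = syn.make_ideal_helix(16, start_res=1)
    reversed_atoms = [Atom(**{**a.__dict__, "res_seq": 17 - a.res_seq})
                      for a in model.atoms]
    hv = helix_vector(model)
    hv_rev = helix_vector(StructureModel(reversed_atoms))
    assert np.abs(hv_rev.direction + hv.direction).max() < 1e-12


def test_helix_vector_error_conditions():
    with pytest.raises(HelixTooShortError):
        helix_vector(syn.make_ideal_helix(6), (1, 3))
    model = syn.make_ideal_helix(8)
    broken = StructureModel([a for a in model.atoms
                             if not (a.res_seq == 4 and a.name == "CA")])
    with pytest.raises(IncompleteBackboneError, match="4"):
        helix_vector(broken)


# -- crossing angle / displacement ------------------------------------------


def test_crossing_angle_limits_and_constructed_rotation():
    h = helix_vector(syn.make_ideal_helix(16))
    assert crossing_angle(h, h) == pytest.approx(0.0, abs=1e-9)
    model = syn.make_ideal_helix(16)
    perp = np.array([1.0, 0.0, 0.0])
    perp = perp - (perp @ h.direction) * h.direction  # exactly normal to the axis
    flipped = helix_vector(_transformed(model, _axis_rotation(perp, np.pi),
                                        np.zeros(3)))
    assert crossing_angle(h, flipped) == pytest.approx(180.0, abs=1e-6)
    # rotate a copy 65 degrees about an axis perpendicular to the helix
    rot = _axis_rotation(perp, np.radians(65.0))
    other = helix_vector(_transformed(model, rot, np.zeros(3)))
    assert crossing_angle(h, other) == pytest.approx(65.0, abs=1e-6)
    assert crossing_angle(other, h) == crossing_angle(h, other)


def test_displacement_pythagorean_and_symmetry():
    model = syn.make_ideal_helix(16)
    h = helix_vector(model)
    shifted = helix_vector(_transformed(model, np.eye(3), np.array([3.0, 4.0, 0.0])))
    assert centroid_displacement(h, shifted) == pytest.approx(5.0, abs=1e-9)
    assert centroid_displacement(h, h) == 0.0
    assert centroid_displacement(shifted, h) == centroid_displacement(h, shifted)


def test_pair_parameters_invariant_under_common_rigid_motion():
    fixture = syn.make_two_helix_fixture(65.0, 12.0)
    ha = helix_vector(fixture.select(chain_ids=["A"]))
    hb = helix_vector(fixture.select(chain_ids=["B"]))
    rng = np.random.default_rng(23)
    for _ in range(10):
        rot, shift = random_rotation(rng), rng.normal(scale=50, size=3)
        moved = _transformed(fixture, rot, shift)
        ga = helix_vector(moved.select(chain_ids=["A"]))
        gb = helix_vector(moved.select(chain_ids=["B"]))
        assert crossing_angle(ga, gb) == pytest.approx(65.0, abs=1e-6)
        assert centroid_displacement(ga, gb) == pytest.approx(12.0, abs=1e-6)


# -- superposition ----------------------------------------------------------


def test_superpose_identity_and_constructed_transform():
    rng = np.random.default_rng(3)
    fixed = rng.normal(scale=10, size=(40, 3))
    res = superpose(fixed, fixed)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert res.rotation_angle == pytest.approx(0.0, abs=1e-6)
    rot = _axis_rotation((1, 2, 3), np.radians(37.0))
    moving = fixed @ rot.T + np.array([5.0, -4.0, 2.0])
    res = superpose(fixed, moving)
    assert res.rmsd < 1e-9
    assert res.rotation_angle == pytest.approx(37.0, abs=1e-6)
    assert np.abs(res.apply(moving) - fixed).max() < 1e-9


def test_superpose_residual_matches_monte_carlo_expectation():
    """Noise-only residual: rmsd -> sigma * sqrt(3) for large point sets."""
    rng = np.random.default_rng(5)
    sigma, n = 0.3, 500
    fixed = rng.normal(scale=20, size=(n, 3))
    rot = _axis_rotation((0, 1, 1), 1.0)
    rmsds = []
    for _ in range(40):
        moving = fixed @ rot.T + 3.0 + rng.normal(scale=sigma, size=(n, 3))
        rmsds.append(superpose(fixed, moving).rmsd)
    assert np.mean(rmsds) == pytest.approx(sigma * np.sqrt(3.0), rel=0.10)


def test_superpose_beats_random_rigid_transforms():
    rng = np.random.default_rng(9)
    fixed = rng.normal(scale=5, size=(12, 3))
    moving = fixed @ random_rotation(rng).T + rng.normal(size=3) \
        + rng.normal(scale=0.5, size=(12, 3))
    best = superpose(fixed, moving)
    for _ in range(200):
        rot = random_rotation(rng)
        centred = (moving - moving.mean(axis=0)) @ rot.T
        trial = np.sqrt(((centred + fixed.mean(axis=0) - fixed) ** 2).sum() / 12)
        assert best.rmsd <= trial + 1e-12


def test_superpose_agrees_with_biotite_oracle():
    import biotite.structure as struc

    rng = np.random.default_rng(13)
    fixed = rng.normal(scale=8, size=(30, 3))
    moving = fixed @ random_rotation(rng).T + rng.normal(size=3) \
        + rng.normal(scale=0.2, size=(30, 3))
    ours = superpose(fixed, moving)
    fitted, _ = struc.superimpose(fixed, moving)
    rmsd_ref = np.sqrt(((fitted - fixed) ** 2).sum() / len(fixed))
    # biotite works in single precision; agree to its accuracy floor
    assert ours.rmsd == pytest.approx(rmsd_ref, abs=1e-5)
    assert np.abs(ours.apply(moving) - fitted).max() < 1e-4


def test_superpose_degenerate_inputs():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    with pytest.raises(DegenerateGeometryError):
        superpose(line, line)
    with pytest.raises(DegenerateGeometryError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# -- domain motion ----------------------------------------------------------


def test_relative_domain_motion_identity_hinge_and_shift():
    ref = syn.make_toy_monomer("pentamer")
    assert relative_domain_motion(ref, ref) == pytest.approx((0.0, 0.0), abs=1e-9)

    coords = ref.coords()
    ctd_idx = [i for i, a in enumerate(ref.atoms) if a.res_seq >= 154]
    hinge = coords[ctd_idx].mean(axis=0)
    rot = _axis_rotation((0, 1, 0), np.radians(15.0))
    rotated = coords.copy()
    rotated[ctd_idx] = (rotated[ctd_idx] - hinge) @ rot.T + hinge
    angle, _ = relative_domain_motion(ref, ref.with_coords(rotated))
    assert angle == pytest.approx(15.0, abs=0.1)

    shifted = coords.copy()
    shifted[ctd_idx] += np.array([0.0, 0.0, 3.6])
    angle, shift = relative_domain_motion(ref, ref.with_coords(shifted))
    assert shift == pytest.approx(3.6, abs=1e-6)
    assert angle == pytest.approx(0.0, abs=1e-6)


# -- layer metrics ----------------------------------------------------------


def test_layer_metrics_recover_built_ring_geometry():
    """NTD at 86.3 A, CTD 21.6 A beneath: the T=1 layer architecture."""
    ring = syn.make_toy_ring(5, radius=86.3, layer_separation=21.6)
    lm = layer_metrics(ring, centre=np.zeros(3), axis=(0, 0, 1))
    assert lm.ntd_radius == pytest.approx(86.3, abs=1e-6)
    assert lm.ctd_radius == pytest.approx(64.7, abs=1e-6)
    assert lm.vertical_displacement == pytest.approx(21.6, abs=1e-6)


def test_layer_metrics_translation_covariance():
    ring = syn.make_toy_ring(5, radius=86.3, layer_separation=21.6)
    lm0 = layer_metrics(ring, centre=np.zeros(3), axis=(0, 0, 1))
    d = 10.0
    lm = layer_metrics(ring, centre=np.array([0.0, 0.0, d]), axis=(0, 0, 1))
    assert lm.ntd_radius == pytest.approx(lm0.ntd_radius - d, abs=1e-6)
    assert lm.vertical_displacement == pytest.approx(lm0.vertical_displacement,
                                                    abs=1e-9)
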