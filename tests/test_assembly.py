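"""Whole-particle pipeline: rings, interfaces, classification, reports."""

import numpy as np
import pandas as pd
import pytest

from capsgeom import assembly as asm
from capsgeom import synthetic as syn
from capsgeom.errors import RingDetectionError
from capsgeom.geometry import PairGeometry
from capsgeom.structure import StructureModel

from conftest import INTERFACE_COUNTS, RING_FOLDS, random_rotation

KIND_COUNTS = {
    "T1": {"pentamer-pentamer": 30},
    "T3": {"pentamer-hexamer": 60, "hexamer-hexamer": 30},
    "D5": {"pentamer-pentamer": 20, "pentamer-hexamer": 20, "hexamer-hexamer": 5},
    "D6": {"pentamer-pentamer": 12, "pentamer-hexamer": 36, "hexamer-hexamer": 6},
}


def _pairs(records):
    return {frozenset((r.chain_a, r.chain_b)): r for r in records}


# -- particle centre --------------------------------------------------------


def test_particle_centre_symmetry_translation_and_monomer(shells):
    model, _ = shells["T1"]
    assert np.abs(asm.particle_centre(model)).max() < 1e-9
    shifted = model.with_coords(model.coords() + np.array([10.0, 0.0, 0.0]))
    assert np.allclose(asm.particle_centre(shifted), [10.0, 0.0, 0.0], atol=1e-9)
    monomer = syn.make_toy_monomer()
    assert np.allclose(asm.particle_centre(monomer),
                       monomer.coords().mean(axis=0), atol=1e-12)


# -- rings ------------------------------------------------------------------


@pytest.mark.parametrize("cls", syn.SHELL_CLASSES)
def test_ring_detection_census_and_partition(cls, analyzed):
    model, manifest, rings, _ = analyzed[cls]
    folds = [r.fold for r in rings]
    assert (folds.count(5), folds.count(6)) == RING_FOLDS[cls]
    members = [c for r in rings for c in r.chains]
    assert sorted(members) == sorted(model.chain_ids())
    assert sum(folds) == len(model.chain_ids())
    # detected partition matches the manifest's
    want = {frozenset(r["chains"]) for r in manifest.rings}
    got = {frozenset(r.chains) for r in rings}
    assert got == want


def test_ring_detection_reports_broken_components(shells):
    model, _ = shells["T1"]
    kept = model.chain_ids()[1:]  # amputate one chain of one pentamer
    broken = model.select(chain_ids=kept)
    with pytest.raises(RingDetectionError) as err:
        asm.detect_rings(broken)
    assert any(len(c) == 4 for c in err.value.components)


def test_ring_axes_match_manifest(analyzed):
    _, manifest, rings, _ = analyzed["T3"]
    by_chains = {frozenset(r["chains"]): np.asarray(r["axis"]) for r in manifest.rings}
    for ring in rings:
        want = by_chains[frozenset(ring.chains)]
        assert min(np.linalg.norm(ring.axis - want),
                   np.linalg.norm(ring.axis + want)) < 1e-6


# -- interfaces -------------------------------------------------------------


@pytest.mark.parametrize("cls", syn.SHELL_CLASSES)
def test_interface_counts_match_closed_form(cls, analyzed):
    _, _, _, interfaces = analyzed[cls]
    assert len(interfaces) == INTERFACE_COUNTS[cls]
    kinds = {}
    for r in interfaces:
        kinds[r.geometry.kind] = kinds.get(r.geometry.kind, 0) + 1
    assert kinds == KIND_COUNTS[cls]


@pytest.mark.parametrize("cls", syn.SHELL_CLASSES)
def test_noise_free_recovery_is_exact(cls, analyzed):
    """Pipeline re-measurement reproduces the generator manifest exactly."""
    _, manifest, _, interfaces = analyzed[cls]
    truth = {frozenset((i["chain_a"], i["chain_b"])): i
             for i in manifest.interfaces}
    got = _pairs(interfaces)
    assert set(got) == set(truth)
    for key, rec in got.items():
        want = truth[key]
        assert rec.geometry.crossing_angle == pytest.approx(want["angle"], abs=1e-6)
        assert rec.geometry.displacement == pytest.approx(want["displacement"], abs=1e-6)
        assert rec.geometry.kind == want["kind"]
        assert rec.geometry.topology == want["topology"]


@pytest.mark.parametrize("cls", syn.SHELL_CLASSES)
def test_interface_groups_follow_ring_folds(cls, analyzed):
    """Pentamer-involving contacts are group 2, hexamer-hexamer group 3."""
    _, _, _, interfaces = analyzed[cls]
    for rec in interfaces:
        want = 3 if rec.geometry.kind == "hexamer-hexamer" else 2
        assert rec.group == want


def test_classification_boundaries_and_stability():
    def group(angle):
        return asm.classify_interface(PairGeometry(angle, 12.0))[0]

    assert [group(a) for a in (20.0, 65.0, 95.0)] == [1, 2, 3]
    # +-5 degrees around each family centre does not change the label
    for centre, want in [(20.0, 1), (65.0, 2), (95.0, 3)]:
        assert group(centre - 5) == want and group(centre + 5) == want
    # flips happen exactly at the documented midpoint boundaries
    eps = 1e-9
    assert group(42.5 - eps) == 1 and group(42.5) == 2
    assert group(80.0 - eps) == 2 and group(80.0) == 3
    assert asm.classify_interface(PairGeometry(65.0, 12.0))[1] == 0.0


def test_geometry_invariant_under_global_rigid_motion(shells):
    model, manifest = shells["T1"]
    rng = np.random.default_rng(17)
    rot, shift = random_rotation(rng), rng.normal(scale=40, size=3)
    moved = model.with_coords(model.coords() @ rot.T + shift)
    rings = asm.detect_rings(moved)
    interfaces = asm.enumerate_interfaces(moved, rings)
    got = _pairs(interfaces)
    assert len(got) == 30
    for rec in got.values():
        assert rec.geometry.crossing_angle == pytest.approx(65.0, abs=1e-6)
        assert rec.geometry.displacement == pytest.approx(12.0, abs=1e-6)
    for ring in rings:
        assert ring.radius == pytest.approx(86.3, abs=1e-6)


# -- noisy full circle ------------------------------------------------------


@pytest.mark.parametrize("cls", syn.SHELL_CLASSES)
def test_noisy_recovery_within_tolerance(cls, noisy_shells):
    """0.3 A coordinate noise: angles within 2 deg, displacements 0.5 A."""
    model, manifest = noisy_shells[cls]
    rings = asm.detect_rings(model)
    interfaces = asm.enumerate_interfaces(model, rings)
    truth = {frozenset((i["chain_a"], i["chain_b"])): i
             for i in manifest.interfaces}
    got = _pairs(interfaces)
    assert set(got) == set(truth)
    for key, rec in got.items():
        want = truth[key]
        assert abs(rec.geometry.crossing_angle - want["angle"]) < 2.0
        assert abs(rec.geometry.displacement - want["displacement"]) < 0.5
        assert rec.group == (3 if want["kind"] == "hexamer-hexamer" else 2)


# -- radial profile ---------------------------------------------------------


def test_radial_profile_recovers_built_radii(analyzed):
    model, _, rings, _ = analyzed["T3"]
    profile = asm.radial_profile(model, rings)
    pent = profile[profile["fold"] == 5]["radius"]
    hexa = profile[profile["fold"] == 6]["radius"]
    assert np.abs(pent - 143.9).max() < 1e-6
    assert np.abs(hexa - 136.5).max() < 1e-6
    model1, _, rings1, _ = analyzed["T1"]
    r1 = asm.radial_profile(model1, rings1)["radius"]
    assert np.abs(r1 - 86.3).max() < 1e-6


# -- fingerprints -----------------------------------------------------------


def test_fingerprint_states_constructed_pairs():
    ring5 = syn.make_toy_ring(5)
    fp = asm.conformation_fingerprint(ring5.select(chain_ids=["A"]),
                                      ring5.select(chain_ids=["B"]))
    assert fp.state == "pentamer-like"
    assert fp.d_r143_k182mc == pytest.approx(2.9, abs=1e-6)
    assert fp.d_k229_d90 == pytest.approx(2.9, abs=1e-6)

    ring6 = syn.make_toy_ring(6)
    fp6 = asm.conformation_fingerprint(ring6.select(chain_ids=["A"]),
                                       ring6.select(chain_ids=["B"]))
    assert fp6.state == "hexamer-like"
    assert fp6.d_r143_q181sc == pytest.approx(2.9, abs=1e-6)
    assert fp6.d_k229_d90 > 3.5


def test_fingerprint_indeterminate_when_no_pair_bonds():
    ring = syn.make_toy_ring(5)
    coords = ring.coords()
    far = [i for i, a in enumerate(ring.atoms)
           if a.res_seq in (181, 182, 90) and a.chain_id in ("A", "B")]
    coords[far] += np.array([0.0, 0.0, 50.0])
    moved = ring.with_coords(coords)
    fp = asm.conformation_fingerprint(moved.select(chain_ids=["A"]),
                                      moved.select(chain_ids=["B"]))
    assert fp.state == "indeterminate"


def test_ring_fingerprints_follow_ring_fold(analyzed):
    model, _, rings, _ = analyzed["T3"]
    fps = asm.ring_fingerprints(model, rings)
    fold_of = {c: r.fold for r in rings for c in r.chains}
    for fp in fps:
        want = "pentamer-like" if fold_of[fp.chain] == 5 else "hexamer-like"
        assert fp.state == want


# -- reports ----------------------------------------------------------------


def test_report_tables_deterministic_and_sorted(tmp_path, analyzed):
    model, _, rings, interfaces = analyzed["T1"]
    layers = asm.radial_profile(model, rings)
    out1, out2 = tmp_path / "r1", tmp_path / "r2"
    s1 = asm.write_report(out1, rings, interfaces, layers)
    s2 = asm.write_report(out2, rings, interfaces, layers)
    assert s1 == s2
    for name in ("interfaces.csv", "rings.csv", "layers.csv",
                 "fingerprints.csv", "summary.json"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
    table = pd.read_csv(out1 / "interfaces.csv")
    assert len(table) == 30
    key = list(zip(table["ring_a"], table["ring_b"], table["chain_a"]))
    assert key == sorted(key)
    assert s1["n_rings"] == 12 and s1["n_interfaces"] == 30


def test_empty_interface_report_is_header_only(tmp_path):
    df = asm.interfaces_table([])
    assert len(df) == 0 and list(df.columns) == asm.INTERFACE_COLUMNS


def test_unique_interfaces_collapse_symmetry_copies(analyzed):
    _, _, _, interfaces = analyzed["T3"]
    reps = asm.unique_interfaces(interfaces)
    assert {r.geometry.kind for r in reps} == {"pentamer-hexamer",
                                              "hexamer-hexamer"}
    assert len(reps) == 2
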