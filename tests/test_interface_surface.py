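"""Shrake-Rupley surface areas against analytic and independent oracles."""

import math

import numpy as np
import pytest

from conftest import make_frame, random_two_partner_frame
from mdcons.errors import UnknownAtomError
from mdcons.interface_surface import (
    AreaSeries,
    RadiiSet,
    SasaParams,
    area_series,
    atom_sasa,
    interface_area,
    residue_burial,
    sphere_points,
    total_sasa,
)
from mdcons.structure_io import Atom, Frame, ResidueKey, Trajectory

PARAMS = SasaParams()


def test_isolated_atom_matches_analytic_sphere():
    """A lone atom's sampled area equals 4*pi*(r+probe)^2 to within 1%."""
    r = 1.87
    area = atom_sasa(np.zeros((1, 3)), np.array([r]), PARAMS)[0]
    exact = 4 * math.pi * (r + PARAMS.probe_radius) ** 2
    assert area == pytest.approx(exact, rel=0.01)
    assert area == pytest.approx(134.4, abs=0.5)  # carbon-like atom, 1.4 A probe


@pytest.mark.parametrize("d", [0.5, 1.5, 3.0, 4.5])
def test_two_equal_spheres_match_cap_formula(d):
    """Analytic oracle: each sphere of radius R at separation d exposes
    4*pi*R^2 - 2*pi*R*(R - d/2) while the spheres intersect."""
    r = 1.87
    R = r + PARAMS.probe_radius
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    areas = atom_sasa(coords, np.array([r, r]), PARAMS)
    exact = 4 * math.pi * R**2 - 2 * math.pi * R * (R - d / 2)
    assert areas[0] == pytest.approx(exact, rel=0.02)
    assert areas[1] == pytest.approx(exact, rel=0.02)


def test_distant_atoms_do_not_occlude():
    r = 1.87
    R = r + PARAMS.probe_radius
    coords = np.array([[0.0, 0, 0], [2 * R + 0.5, 0, 0]])
    areas = atom_sasa(coords, np.array([r, r]), PARAMS)
    exact = 4 * math.pi * R**2
    np.testing.assert_allclose(areas, exact, rtol=1e-12)


def test_convergence_with_sampling_density():
    r = 1.6
    R = r + 1.4
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    exact = 4 * math.pi * R**2 - 2 * math.pi * R * (R - 1.0)
    errors = []
    for n in (100, 400, 1600):
        params = SasaParams(n_sphere_points=n)
        areas = atom_sasa(coords, np.array([r, r]), params)
        errors.append(abs(areas[0] - exact) / exact)
    assert errors[-1] < errors[0]
    assert errors[-1] < 0.01


def test_sphere_lattice_is_unit_and_deterministic():
    pts = sphere_points(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(pts, sphere_points(960))


def test_cross_check_against_independent_shrake_rupley(rng):
    """Same radii, independent implementation (different point lattice)."""
    import biotite.structure as biotite_struc

    frame = random_two_partner_frame(rng, n_a=8, n_b=8, atoms_per_res=3, box=12.0)
    coords, radii, owners = [], [], []
    for key in sorted(frame.residues):
        for atom in frame.residues[key]:
            coords.append(atom.coords)
            radii.append(PARAMS.radii.radius(key.res_name, atom))
    coords, radii = np.asarray(coords), np.asarray(radii)
    mine = atom_sasa(coords, radii, PARAMS).sum()

    arr = biotite_struc.AtomArray(len(coords))
    arr.coord = coords
    arr.res_id = np.arange(len(coords)) // 3 + 1
    arr.res_name = np.repeat("ALA", len(coords))
    arr.atom_name = np.tile(["CA", "CB", "CG"], len(coords) // 3)
    arr.element = np.repeat("C", len(coords))
    arr.chain_id = np.repeat("A", len(coords))
    theirs = biotite_struc.sasa(
        arr, probe_radius=PARAMS.probe_radius, point_number=960, vdw_radii=radii
    ).sum()
    assert mine == pytest.approx(theirs, rel=0.02)


def test_interface_area_zero_for_separated_partners():
    frame = make_frame([[0, 0, 0], [8, 0, 0]], [[0, 40.0, 0], [8, 40.0, 0]])
    assert interface_area(frame, PARAMS) == pytest.approx(0.0, abs=1e-9)


def test_interface_area_symmetric_under_partner_swap(rng):
    frame = random_two_partner_frame(rng, n_a=6, n_b=6, atoms_per_res=2, box=10.0)
    a = interface_area(frame, PARAMS)
    b = interface_area(frame.swapped(), PARAMS)
    assert a == pytest.approx(b, rel=1e-12)
    assert a > 0


def test_rigid_body_invariance(rng):
    """Global rotation+translation moves the area by < 0.5% (lattice artifact)."""
    frame = random_two_partner_frame(rng, n_a=6, n_b=6, atoms_per_res=2, box=10.0)
    base = interface_area(frame, PARAMS)
    # random rotation via QR decomposition
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.uniform(-20, 20, 3)
    rotated = Frame(
        index=0,
        residues={
            k: [Atom(a.serial, a.name, a.element, q @ a.coords + shift, a.is_heavy)
                for a in atoms]
            for k, atoms in frame.residues.items()
        },
        partner_of=dict(frame.partner_of),
    )
    moved = interface_area(rotated, PARAMS)
    assert moved == pytest.approx(base, rel=0.005)


def test_burial_additivity_identity(rng):
    """Sum of per-residue (free - complex) ASA over both partners equals
    twice the interface area, within sampling tolerance."""
    frame = random_two_partner_frame(rng, n_a=5, n_b=5, atoms_per_res=3, box=9.0)
    report = residue_burial(frame, PARAMS)
    delta = sum(r.asa_free - r.asa_complex for r in report.rows)
    assert delta == pytest.approx(2 * interface_area(frame, PARAMS), rel=1e-9)


def test_burial_bounds_and_remote_residue(rng):
    close = make_frame([[0, 0, 0]], [[4.0, 0, 0], [60.0, 0, 0]])
    report = residue_burial(close, PARAMS)
    rows = report.by_key()
    remote = rows[ResidueKey("B", 2, "")]
    buried = rows[ResidueKey("B", 1, "")]
    assert remote.pct_buried == pytest.approx(0.0, abs=1e-9)
    assert buried.pct_buried > 5.0
    for r in report.rows:
        assert -1e-6 <= r.pct_buried <= 100 + 1e-6
        assert r.asa_complex <= r.asa_free + 1e-6


def test_area_series_constant_and_alternating():
    near = make_frame([[0, 0, 0]], [[4.0, 0, 0]])
    far = make_frame([[0, 0, 0]], [[5.5, 0, 0]], index=1)
    area_near = interface_area(near, PARAMS)
    area_far = interface_area(far, PARAMS)
    assert area_near != pytest.approx(area_far)

    frames = [near, Frame(1, far.residues, far.partner_of),
              Frame(2, near.residues, near.partner_of),
              Frame(3, far.residues, far.partner_of)]
    series = area_series(Trajectory(frames=frames), PARAMS)
    np.testing.assert_allclose(
        series.per_frame_area, [area_near, area_far, area_near, area_far]
    )

    constant = Trajectory(frames=[Frame(i, near.residues, near.partner_of)
                                  for i in range(3)])
    assert area_series(constant, PARAMS).sd == 0.0


def test_single_frame_sd_reported_zero_with_flag():
    series = AreaSeries(per_frame_area=[123.4])
    assert series.sd == 0.0
    assert not series.sd_defined


def test_unknown_element_raises_naming_the_atom():
    frame = make_frame([[0, 0, 0]], [[4.0, 0, 0]])
    key = sorted(frame.residues)[0]
    frame.residues[key][0].element = "ZZ"
    with pytest.raises(UnknownAtomError, match="ZZ"):
        total_sasa(frame, ["A"], PARAMS)


def test_params_validation():
    with pytest.raises(ValueError):
        SasaParams(probe_radius=0.0)
    with pytest.raises(ValueError):
        SasaParams(n_sphere_points=50)


def test_radii_dialect_from_file(tmp_path):
    path = tmp_path / "radii.txt"
    path.write_text("C 1.70\nN 1.55\n")
    custom = RadiiSet.from_file(path)
    atom = Atom(1, "CA", "C", np.zeros(3), True)
    assert custom.radius("ALA", atom) == pytest.approx(1.70)
    assert RadiiSet.chothia().radius("ALA", atom) == pytest.approx(1.87)
    carbonyl = Atom(2, "C", "C", np.zeros(3), True)
    assert RadiiSet.chothia().radius("ALA", carbonyl) == pytest.approx(1.76)
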