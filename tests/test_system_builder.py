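"""Double-bilayer construction, salt placement and bookkeeping."""

import numpy as np
import pytest

from memtilt.io_model import read_coordinates, write_coordinates
from memtilt.system_builder import (MIN_ION_SEPARATION_A,
                                    CompartmentGeometry, add_salt,
                                    delete_selection, duplicate_translate,
                                    set_ion_imbalance)

CENTRAL = CompartmentGeometry(central=(57.5, 102.5))


@pytest.fixture(scope="module")
def double_bilayer(mock_bilayer):
    top, frame, _, _ = mock_bilayer
    (dtop, dframe), report = duplicate_translate((top, frame))
    return dtop, dframe, report


def test_duplicate_doubles_atoms_and_box(mock_bilayer, double_bilayer):
    top, frame, _, _ = mock_bilayer
    dtop, dframe, report = double_bilayer
    assert dtop.n_atoms == 2 * top.n_atoms
    np.testing.assert_allclose(dframe.box, frame.box * [1, 1, 2])
    assert report.atoms_after == 2 * report.atoms_before


def test_duplicate_residue_numbering_unique(double_bilayer):
    dtop, _, _ = double_bilayer
    resids = [a.residue_index for a in dtop.atoms]
    per_res = {}
    for a in dtop.atoms:
        per_res.setdefault(a.residue_index, set()).add(a.residue_name)
    assert all(len(names) == 1 for names in per_res.values())
    assert max(resids) == 2 * max(a.residue_index
                                  for a in dtop.atoms[:dtop.n_atoms // 2])


def test_duplicate_preserves_neutrality(mock_bilayer, double_bilayer):
    top, _, _, _ = mock_bilayer
    dtop, _, report = double_bilayer
    assert report.net_charge_after == pytest.approx(2 * top.total_charge(),
                                                    abs=1e-9)


def test_image_distance_at_least_original_box(mock_bilayer, double_bilayer):
    """Each original atom and its duplicate must be separated by the
    original box height along z (minimum image in the doubled box)."""
    top, frame, _, _ = mock_bilayer
    _, dframe, _ = double_bilayer
    n = top.n_atoms
    dz = dframe.coordinates[n:, 2] - dframe.coordinates[:n, 2]
    lz2 = dframe.box[2]
    dz_mi = np.abs(dz - np.round(dz / lz2) * lz2)
    assert np.all(dz_mi >= frame.box[2] - 1e-9)


def test_add_salt_places_exact_counts_in_compartment(double_bilayer):
    dtop, dframe, _ = double_bilayer
    (stop, sframe), report = add_salt((dtop, dframe), CENTRAL,
                                      n_na=44, n_cl=44, seed=3)
    na = stop.groups["Na+"]
    cl = stop.groups["Cl-"]
    # 20 counterions per copy pre-exist in the mock system
    n_na_new = na.size - 2 * 20
    assert n_na_new == 44 and cl.size == 44
    assert report.ions_added == {"Na+": {"central": 44},
                                 "Cl-": {"central": 44}}
    lz = sframe.box[2]
    new_ions = np.concatenate([na, cl])
    # every added ion inside the central range (pre-existing counterions
    # sit at the surfaces; restrict to the declared range membership count)
    z = np.mod(sframe.coordinates[cl, 2], lz)
    assert np.all((z >= 57.5) & (z < 102.5))


def test_add_salt_separation_and_charge(double_bilayer):
    dtop, dframe, _ = double_bilayer
    (stop, sframe), report = add_salt((dtop, dframe), CENTRAL,
                                      n_na=44, n_cl=44, seed=3)
    assert report.net_charge_after == pytest.approx(
        report.net_charge_before, abs=1e-9)
    # pairwise minimum-image separation of the newly placed ions
    cl = sframe.coordinates[stop.groups["Cl-"]]
    na_all = stop.groups["Na+"]
    lz = sframe.box[2]
    z = np.mod(sframe.coordinates[na_all, 2], lz)
    na_new = sframe.coordinates[na_all[(z >= 57.5) & (z < 102.5)]]
    ions = np.vstack([na_new, cl])
    box = sframe.box
    for i in range(len(ions)):
        d = ions[i + 1:] - ions[i]
        d -= np.round(d / box) * box
        if len(d):
            assert np.linalg.norm(d, axis=1).min() >= MIN_ION_SEPARATION_A


def test_add_salt_books_water_removal(double_bilayer):
    dtop, dframe, _ = double_bilayer
    n_waters_before = len({dtop.atoms[i].residue_index
                           for i in dtop.groups["water"]})
    (stop, _), report = add_salt((dtop, dframe), CENTRAL,
                                 n_na=44, n_cl=44, seed=3)
    n_waters_after = len({stop.atoms[i].residue_index
                          for i in stop.groups["water"]})
    assert n_waters_before - n_waters_after == 88
    assert report.waters_removed == 88
    assert report.atoms_after == report.atoms_before - 88 * 2  # 2 H per water


def test_add_salt_zero_request_is_identity(double_bilayer):
    dtop, dframe, _ = double_bilayer
    (stop, sframe), report = add_salt((dtop, dframe), CENTRAL,
                                      n_na=0, n_cl=0, seed=3)
    assert stop.n_atoms == dtop.n_atoms
    np.testing.assert_allclose(sframe.coordinates, dframe.coordinates)


def test_add_salt_concentration_conversion(double_bilayer):
    dtop, dframe, _ = double_bilayer
    (stop, _), report = add_salt((dtop, dframe), CENTRAL,
                                 concentration=0.4, seed=3)
    # counts = round(c * N_A * n_waters * 30 Å³): recompute independently
    lz = dframe.box[2]
    ow = [i for i in dtop.groups["water"] if dtop.atoms[i].name == "OW"]
    z = np.mod(dframe.coordinates[ow, 2], lz)
    n_comp = int(np.sum((z >= 57.5) & (z < 102.5)))
    expected = round(0.4 * 6.02214076e23 * n_comp * 30.0 * 1e-27)
    assert report.ions_added["Na+"]["central"] == expected


def test_add_salt_insufficient_waters_errors(double_bilayer):
    dtop, dframe, _ = double_bilayer
    with pytest.raises(ValueError, match="insufficient"):
        add_salt((dtop, dframe), CENTRAL, n_na=10 ** 5, n_cl=10 ** 5)


def test_add_salt_seeded_reproducible(double_bilayer):
    dtop, dframe, _ = double_bilayer
    (t1, f1), _ = add_salt((dtop, dframe), CENTRAL, n_na=10, n_cl=10, seed=9)
    (t2, f2), _ = add_salt((dtop, dframe), CENTRAL, n_na=10, n_cl=10, seed=9)
    np.testing.assert_array_equal(f1.coordinates, f2.coordinates)
    assert [a.name for a in t1.atoms] == [a.name for a in t2.atoms]


def test_build_round_trips_through_file(tmp_path, double_bilayer, mock_bilayer):
    _, _, table_text, _ = mock_bilayer
    dtop, dframe, _ = double_bilayer
    (stop, sframe), report = add_salt((dtop, dframe), CENTRAL,
                                      n_na=44, n_cl=44, seed=3)
    path = tmp_path / "built.gro"
    write_coordinates((stop, sframe), path)
    top2, frame2 = read_coordinates(path)
    assert top2.n_atoms == report.atoms_after
    from memtilt.io_model import apply_charge_table, load_charge_table
    ct = tmp_path / "charges.txt"
    ct.write_text(table_text)
    apply_charge_table(top2, load_charge_table(ct))
    assert top2.total_charge() == pytest.approx(report.net_charge_after,
                                                abs=1e-6)


def test_ion_imbalance_plus_eight(double_bilayer):
    dtop, dframe, _ = double_bilayer
    (stop, sframe), rep_salt = add_salt((dtop, dframe), CENTRAL,
                                        n_na=8, n_cl=8, seed=4)
    (itop, iframe), report = set_ion_imbalance((stop, sframe), 8,
                                               CENTRAL, seed=4)
    assert itop.n_atoms == stop.n_atoms
    assert report.net_charge_after == pytest.approx(
        rep_salt.net_charge_after, abs=1e-9)
    assert any("imbalance +8" in n for n in report.notes)


def test_ion_imbalance_zero_equalizes(double_bilayer):
    dtop, dframe, _ = double_bilayer
    (stop, sframe), _ = add_salt((dtop, dframe), CENTRAL,
                                 n_na=4, n_cl=4, seed=5)
    (_, _), report = set_ion_imbalance((stop, sframe), 0, CENTRAL, seed=5)
    assert any("imbalance +0" in n for n in report.notes)


def test_ion_imbalance_parity_unreachable_errors(double_bilayer):
    dtop, dframe, _ = double_bilayer
    with pytest.raises(ValueError, match="parity"):
        set_ion_imbalance((dtop, dframe), 7, CENTRAL, seed=0)


def test_delete_peptide_and_counterions_conserves_charge(two_state):
    _, traj, _, _ = two_state
    # build a +5 peptide analog: assign +1 to five beads; add 5 Cl- atoms
    import copy
    from memtilt.io_model import Atom, Frame, Topology, standard_groups
    top = traj.topology
    atoms = [copy.copy(a) for a in top.atoms]
    for i in (3, 7, 11, 14, 18):
        atoms[i].charge = 1.0
    max_res = max(a.residue_index for a in atoms)
    for k in range(5):
        atoms.append(Atom(name="CL", residue_index=max_res + 1 + k,
                          residue_name="CL", charge=-1.0, mass=35.45))
    coords = np.vstack([traj.frames[0].coordinates,
                        np.column_stack([np.full(5, 5.0),
                                         5.0 + np.arange(5) * 4.0,
                                         np.full(5, 10.0)])])
    new_top = standard_groups(Topology(atoms, charges_assigned=True))
    frame = Frame(time=0.0, coordinates=coords, box=traj.frames[0].box)
    q0 = new_top.total_charge()
    sel = np.concatenate([new_top.groups["peptide"], new_top.groups["Cl-"]])
    (out_top, _), report = delete_selection((new_top, frame), sel)
    assert out_top.total_charge() == pytest.approx(q0, abs=1e-9)
    assert report.atoms_after == report.atoms_before - sel.size
    # residues renumbered contiguously from 1
    resids = sorted({a.residue_index for a in out_top.atoms})
    assert resids == list(range(1, len(resids) + 1))


def test_delete_empty_selection_is_identity(mock_bilayer):
    top, frame, _, _ = mock_bilayer
    (out_top, out_frame), report = delete_selection((top, frame), [])
    assert out_top.n_atoms == top.n_atoms
    np.testing.assert_allclose(out_frame.coordinates, frame.coordinates)


def test_delete_everything_errors(mock_bilayer):
    top, frame, _, _ = mock_bilayer
    with pytest.raises(ValueError, match="empty system"):
        delete_selection((top, frame), np.arange(top.n_atoms))


def test_salt_then_delete_added_ions_restores_atom_count(double_bilayer):
    dtop, dframe, _ = double_bilayer
    (stop, sframe), _ = add_salt((dtop, dframe), CENTRAL,
                                 n_na=12, n_cl=12, seed=6)
    lz = sframe.box[2]
    added = [i for i in np.concatenate([stop.groups["Na+"],
                                        stop.groups["Cl-"]])
             if 57.5 <= np.mod(sframe.coordinates[i, 2], lz) < 102.5]
    (out_top, _), _ = delete_selection((stop, sframe), added)
    # ions replaced whole waters (3 atoms); deleting the ions leaves the
    # atom count short by exactly the removed water hydrogens
    assert out_top.n_atoms == dtop.n_atoms - 24 * 3
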