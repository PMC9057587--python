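"""SASA, disulfide detection, numbering map, and the epitope filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from displaymap.reference import ReferenceConstruct
from displaymap.structure import (
    MAX_ASA_TIEN2013,
    ResidueAnnotation,
    annotate_structure,
    detect_disulfides,
    epitope_set,
    filter_epitope,
    map_numbering,
    parse_structure,
    read_annotation_table,
    relative_sasa,
    shrake_rupley_sasa,
)
from conftest import backbone_residue, cys_chain_pdb, cys_pair_pdb, format_pdb


def single_atom_model(tmp_path, element="C", name="CA", resname="ALA"):
    path = tmp_path / "one.pdb"
    path.write_text(format_pdb([
        dict(name=name, resname=resname, chain="A", resseq=1,
             x=0.0, y=0.0, z=0.0, element=element)]))
    return parse_structure(path)


def two_atom_model(tmp_path, separation):
    path = tmp_path / "two.pdb"
    path.write_text(format_pdb([
        dict(name="C1", resname="UNL", chain="A", resseq=1,
             x=0.0, y=0.0, z=0.0, element="C"),
        dict(name="C2", resname="UNL", chain="A", resseq=2,
             x=separation, y=0.0, z=0.0, element="C"),
    ]))
    return parse_structure(path)


def two_sphere_accessible_area(r1, r2, d):
    """Closed form: accessible area of sphere 1 (radius r1) partly
    occluded by sphere 2 (radius r2) at center distance d < r1 + r2."""
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    return 4 * math.pi * r1**2 - 2 * math.pi * r1 * h1


# ---------------------------------------------------------------- parsing

def test_toy_peptide_parses_with_expected_residues(toy_peptide_pdb):
    model = parse_structure(toy_peptide_pdb)
    residues = model.residues()
    assert [r[2] for r in residues] == ["ALA", "GLY", "SER", "CYS"]
    # ALA 5 atoms, GLY 4, SER 5+OG... SER gets CB+OG=6, CYS CB+SG=6
    assert len(model.atoms) == 5 + 4 + 6 + 6


def test_two_model_file_keeps_first_model(tmp_path, caplog):
    body = format_pdb([dict(name="CA", resname="GLY", chain="A", resseq=1,
                            x=0.0, y=0.0, z=0.0, element="C")]).replace("END\n", "")
    text = ("MODEL        1\n" + body + "ENDMDL\n"
            "MODEL        2\n" + body.replace("   0.000   0.000   0.000",
                                              "   9.000   0.000   0.000")
            + "ENDMDL\nEND\n")
    path = tmp_path / "two_models.pdb"
    path.write_text(text)
    model = parse_structure(path)
    assert len(model.atoms) == 1
    assert model.atoms[0].xyz[0] == 0.0


def test_garbage_file_is_parse_error(tmp_path):
    path = tmp_path / "garbage.pdb"
    path.write_text("this is not a structure\n")
    with pytest.raises(ValueError):
        parse_structure(path)


def test_altloc_highest_occupancy_wins(tmp_path):
    atoms = [
        dict(name="CA", resname="SER", chain="A", resseq=1, altloc="A",
             x=0.0, y=0.0, z=0.0, element="C", occ=0.4),
        dict(name="CA", resname="SER", chain="A", resseq=1, altloc="B",
             x=5.0, y=0.0, z=0.0, element="C", occ=0.6),
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text(format_pdb(atoms))
    model = parse_structure(path)
    assert len(model.atoms) == 1
    assert model.atoms[0].xyz[0] == 5.0


def test_hydrogens_and_waters_dropped(tmp_path):
    atoms = [
        dict(name="CA", resname="GLY", chain="A", resseq=1,
             x=0.0, y=0.0, z=0.0, element="C"),
        dict(name="HA", resname="GLY", chain="A", resseq=1,
             x=1.0, y=0.0, z=0.0, element="H"),
        dict(name="O", resname="HOH", chain="A", resseq=2,
             x=8.0, y=0.0, z=0.0, element="O"),
    ]
    path = tmp_path / "hw.pdb"
    path.write_text(format_pdb(atoms))
    model = parse_structure(path)
    assert len(model.atoms) == 1


# ------------------------------------------------------------------- SASA

def test_isolated_carbon_matches_sphere_area(tmp_path):
    """Lone C atom: SASA = 4 pi (1.7 + 1.4)^2 within 1%."""
    model = single_atom_model(tmp_path)
    sasa = shrake_rupley_sasa(model)
    expected = 4 * math.pi * 3.1**2  # ~120.76 A^2
    assert sasa["sasa"].iloc[0] == pytest.approx(expected, rel=0.01)


def test_distant_atoms_keep_isolated_area(tmp_path):
    model = two_atom_model(tmp_path, separation=10.0)  # > 2 * 3.1
    sasa = shrake_rupley_sasa(model)
    expected = 4 * math.pi * 3.1**2
    assert np.allclose(sasa["sasa"], expected, rtol=0.01)


def test_overlapping_spheres_match_cap_closed_form(tmp_path):
    """Two expanded C spheres at 4 A: spherical-cap closed form, 2%."""
    model = two_atom_model(tmp_path, separation=4.0)
    sasa = shrake_rupley_sasa(model, n_sphere_points=960)
    expected = two_sphere_accessible_area(3.1, 3.1, 4.0)
    assert np.allclose(sasa["sasa"], expected, rtol=0.02)


def test_occlusion_monotonicity(tmp_path, toy_peptide_pdb):
    """Adding an atom never increases any other residue's SASA."""
    model = parse_structure(toy_peptide_pdb)
    base = shrake_rupley_sasa(model).set_index("residue_number")["sasa"]
    import copy
    from displaymap.structure import Atom, StructureModel
    extra = Atom(chain="A", residue_number=99, residue_name="UNL",
                 atom_name="X", element="S", xyz=(3.8, 1.0, 1.0))
    bigger = StructureModel(atoms=model.atoms + [extra])
    after = shrake_rupley_sasa(bigger)
    after = after[after["residue_number"] != 99].set_index("residue_number")["sasa"]
    assert (after <= base + 1e-9).all()


def test_sasa_converged_at_default_point_count(toy_peptide_pdb):
    """Doubling the sphere-point count changes residue SASA by < 1%."""
    model = parse_structure(toy_peptide_pdb)
    a = shrake_rupley_sasa(model, n_sphere_points=960)["sasa"]
    b = shrake_rupley_sasa(model, n_sphere_points=1920)["sasa"]
    assert np.allclose(a, b, rtol=0.01)


def test_sasa_agrees_with_independent_implementation(toy_peptide_pdb):
    """Cross-check against biotite's Shrake-Rupley with the same radii."""
    biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
    import biotite.structure as struc
    arr = biotite_pdb.PDBFile.read(str(toy_peptide_pdb)).get_structure(model=1)
    atom_sasa = struc.sasa(arr, probe_radius=1.4, point_number=2000,
                           vdw_radii="Single")
    theirs = [float(atom_sasa[arr.res_id == rid].sum()) for rid in (1, 2, 3, 4)]
    model = parse_structure(toy_peptide_pdb)
    ours = shrake_rupley_sasa(model, n_sphere_points=2000)["sasa"].tolist()
    assert np.allclose(ours, theirs, rtol=0.02)


# -------------------------------------------------------------------- RSA

def test_zero_sasa_gives_zero_rsa():
    df = pd.DataFrame({"chain": ["A"], "residue_number": [1],
                       "residue_name": ["ALA"], "sasa": [0.0]})
    out = relative_sasa(df)
    assert out["rsa"].iloc[0] == 0.0


def test_extended_triglycine_central_rsa_near_unity(tmp_path):
    """Central Gly of an extended Gly-Gly-Gly: RSA in [0.8, 1.2]."""
    atoms = []
    for i in range(3):
        atoms.extend(backbone_residue("GLY", "A", i + 1, 3.8 * i))
    path = tmp_path / "ggg.pdb"
    path.write_text(format_pdb(atoms))
    model = parse_structure(path)
    out = relative_sasa(shrake_rupley_sasa(model))
    central = out[out["residue_number"] == 2].iloc[0]
    assert 0.8 <= central["rsa"] <= 1.2


def test_unknown_residue_flagged_not_scored():
    df = pd.DataFrame({"chain": ["A"], "residue_number": [1],
                       "residue_name": ["XYZ"], "sasa": [50.0]})
    with pytest.warns(UserWarning, match="max-ASA"):
        out = relative_sasa(df)
    assert np.isnan(out["rsa"].iloc[0])
    assert out["flag"].iloc[0] == "unknown_residue"


# -------------------------------------------------------------- disulfides

def test_bonded_pair_detected(tmp_path):
    model = parse_structure(cys_pair_pdb(tmp_path, 2.05, "bonded.pdb"))
    pairs = detect_disulfides(model)
    assert pairs == {frozenset({("A", 1), ("A", 2)})}


def test_distant_pair_not_detected(tmp_path):
    model = parse_structure(cys_pair_pdb(tmp_path, 4.0, "free.pdb"))
    assert detect_disulfides(model) == set()


def test_three_cys_chain_greedy_matches_brute_force(tmp_path):
    """Greedy nearest-first on the 2.0/2.1/2.2 A triangle: one pair only.

    Brute force enumerates all matchings among the candidate pairs and
    confirms the greedy result is the matching containing the globally
    nearest pair.
    """
    model = parse_structure(cys_chain_pdb(tmp_path))
    pairs = detect_disulfides(model)
    assert pairs == {frozenset({("A", 1), ("A", 2)})}

    sg = {a.residue_number: np.array(a.xyz) for a in model.atoms
          if a.atom_name == "SG"}
    candidates = {
        frozenset({a, b}): float(np.linalg.norm(sg[a] - sg[b]))
        for a, b in itertools.combinations(sg, 2)
        if np.linalg.norm(sg[a] - sg[b]) <= 2.3
    }
    assert len(candidates) == 3  # all three pairs are within the cutoff
    nearest = min(candidates, key=candidates.get)
    matchings = []
    for r in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            members = [m for pair in combo for m in pair]
            if len(members) == len(set(members)):
                matchings.append(set(combo))
    # every maximal matching here is a single pair; greedy picks the nearest
    assert all(len(m) == 1 for m in matchings)
    assert pairs == {frozenset({("A", n) for n in nearest})}


def test_disulfide_pairs_invariant_under_atom_permutation(tmp_path):
    from displaymap.structure import StructureModel
    model = parse_structure(cys_chain_pdb(tmp_path))
    rng = np.random.default_rng(2)
    shuffled = StructureModel(atoms=[model.atoms[i]
                                     for i in rng.permutation(len(model.atoms))])
    assert detect_disulfides(shuffled) == detect_disulfides(model)


# ----------------------------------------------------------- numbering map

def _structure_for(ref: ReferenceConstruct, tmp_path, offset=0, scramble=False,
                   fname="map.pdb"):
    from displaymap.structure import THREE_TO_ONE
    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    rng = np.random.default_rng(5)
    atoms = []
    for i, aa in enumerate(ref.aa_seq):
        if scramble:
            aa = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
        atoms.extend(backbone_residue(one_to_three[aa], "A",
                                      ref.first_residue + i - offset, 3.8 * i,
                                      with_cb=False))
    path = tmp_path / fname
    path.write_text(format_pdb(atoms))
    return path


def test_identity_numbering_maps_all_positions(small_ref, tmp_path):
    model = parse_structure(_structure_for(small_ref, tmp_path))
    nm = map_numbering(small_ref, model, "A")
    assert nm.unmapped == frozenset()
    assert nm.mapping[22] == ("A", 22)
    assert nm.mapping[33] == ("A", 33)


def test_renumbered_structure_offset_recovered(small_ref, tmp_path):
    model = parse_structure(_structure_for(small_ref, tmp_path, offset=-100))
    nm = map_numbering(small_ref, model, "A")
    assert nm.unmapped == frozenset()
    assert nm.mapping[22] == ("A", 122)


def test_scrambled_sequence_fails_numbering(small_ref, tmp_path):
    model = parse_structure(_structure_for(small_ref, tmp_path, scramble=True))
    with pytest.raises(ValueError, match="numbering map failed"):
        map_numbering(small_ref, model, "A")


def test_missing_chain_is_error(small_ref, tmp_path):
    model = parse_structure(_structure_for(small_ref, tmp_path))
    with pytest.raises(ValueError, match="chain"):
        map_numbering(small_ref, model, "B")


# ------------------------------------------------------------------ filter

def make_annotation(rows):
    return ResidueAnnotation(table=pd.DataFrame(
        rows, columns=["position", "rsa", "disulfide"]))


def test_filter_applies_burial_and_disulfide_rules():
    ann = make_annotation([(30, 0.4, False), (50, 0.05, False), (61, 0.3, True)])
    out = filter_epitope({30, 50, 61}, ann)
    assert epitope_set(out) == {30}
    reasons = out.set_index("position")["reason"]
    assert reasons[50] == "buried"
    assert reasons[61] == "disulfide"


def test_filter_empty_called_set():
    ann = make_annotation([(30, 0.4, False)])
    out = filter_epitope(set(), ann)
    assert out.empty
    assert epitope_set(out) == set()


def test_unannotated_position_kept_with_flag():
    ann = make_annotation([(30, 0.4, False)])
    out = filter_epitope({30, 99}, ann)
    row = out.set_index("position").loc[99]
    assert bool(row["kept"]) and row["reason"] == "unfiltered"
    out2 = filter_epitope({30, 99}, ann, drop_unannotated=True)
    assert epitope_set(out2) == {30}


def test_filter_soundness_invariant_holds():
    rng = np.random.default_rng(8)
    positions = list(range(22, 62))
    ann = make_annotation([
        (p, float(rng.uniform(0, 0.6)), bool(rng.random() < 0.2))
        for p in positions
    ])
    out = filter_epitope(set(positions), ann, rsa_min=0.15)
    kept = out[out["kept"]]
    assert not kept["disulfide"].any()
    assert (kept["rsa"] >= 0.15).all()


def test_annotation_table_round_trip(tmp_path, ref):
    from displaymap.simulate import write_annotation
    path = tmp_path / "ann.tsv"
    write_annotation(ref, path, disulfide_positions={38, 45},
                     buried_positions={118}, seed=1)
    ann = read_annotation_table(path)
    rsa, ss = ann.lookup(45)
    assert ss is True
    rsa118, ss118 = ann.lookup(118)
    assert rsa118 == pytest.approx(0.02)
    assert ss118 is False
    assert ann.lookup(9999) is None


def test_annotate_structure_end_to_end(small_ref, tmp_path):
    """Structure-derived annotation: exposed surface, no disulfides."""
    path = _structure_for(small_ref, tmp_path, fname="annot.pdb")
    ann = annotate_structure(small_ref, path, "A")
    assert set(ann.table["position"]) == set(small_ref.native_positions)
    assert not ann.table["disulfide"].any()
    assert (ann.table["rsa"] > 0.15).all()  # extended chain: everything exposed
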