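"""Shared fixtures: small constructs and programmatic coordinate fixtures."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings, HealthCheck

from displaymap.reference import ReferenceConstruct, default_construct

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref() -> ReferenceConstruct:
    """The built-in 111-aa construct numbered 22..132."""
    return default_construct()


@pytest.fixture(scope="session")
def small_ref() -> ReferenceConstruct:
    """A 12-residue construct with first_residue=22.

    Codon 8 is GCT (Ala) so a single G->A change at its second base
    yields GAT (Asp): the canonical worked example for codon calling.
    """
    aa = "MKTVLQWERAYH"
    codons = {
        "M": "ATG", "K": "AAA", "T": "ACA", "V": "GTT", "L": "CTT",
        "Q": "CAA", "W": "TGG", "E": "GAA", "R": "CGT", "A": "GCT",
        "Y": "TAT", "H": "CAT",
    }
    nt = "".join(codons[a] for a in aa)
    return ReferenceConstruct(name="toy", aa_seq=aa, nt_orf=nt, first_residue=22)


def format_pdb(atoms: list[dict]) -> str:
    """Render ATOM records; each dict needs name/resname/chain/resseq/x/y/z/element
    and may override occ/altloc."""
    lines = []
    for i, a in enumerate(atoms, start=1):
        name = a["name"]
        # PDB convention: 1-2 letter element names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            "ATOM  {serial:5d} {name}{altloc:1s}{resname:>3s} {chain:1s}{resseq:4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}".format(
                serial=i, name=name_field, altloc=a.get("altloc", " "),
                resname=a["resname"], chain=a["chain"], resseq=a["resseq"],
                x=a["x"], y=a["y"], z=a["z"], occ=a.get("occ", 1.0), b=0.0,
                element=a["element"],
            )
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def backbone_residue(resname: str, chain: str, resseq: int, x0: float,
                     with_cb: bool = True) -> list[dict]:
    """Crude extended-chain residue: N, CA, C, O (+CB) around CA at (x0, 0, 0)."""
    atoms = [
        dict(name="N", resname=resname, chain=chain, resseq=resseq,
             x=x0 - 1.2, y=0.45, z=0.0, element="N"),
        dict(name="CA", resname=resname, chain=chain, resseq=resseq,
             x=x0, y=0.0, z=0.0, element="C"),
        dict(name="C", resname=resname, chain=chain, resseq=resseq,
             x=x0 + 1.2, y=0.45, z=0.0, element="C"),
        dict(name="O", resname=resname, chain=chain, resseq=resseq,
             x=x0 + 1.25, y=1.68, z=0.0, element="O"),
    ]
    if with_cb and resname != "GLY":
        atoms.append(
            dict(name="CB", resname=resname, chain=chain, resseq=resseq,
                 x=x0, y=-1.0, z=1.1, element="C")
        )
    return atoms


@pytest.fixture()
def toy_peptide_pdb(tmp_path: Path) -> Path:
    """Bundled-style 4-residue peptide fixture (ALA-GLY-SER-CYS)."""
    atoms = []
    for i, resname in enumerate(["ALA", "GLY", "SER", "CYS"]):
        atoms.extend(backbone_residue(resname, "A", i + 1, 3.8 * i))
    # side-chain tips so SER/CYS have their signature atoms
    atoms.append(dict(name="OG", resname="SER", chain="A", resseq=3,
                      x=3.8 * 2, y=-2.0, z=2.0, element="O"))
    atoms.append(dict(name="SG", resname="CYS", chain="A", resseq=4,
                      x=3.8 * 3, y=-2.2, z=2.1, element="S"))
    path = tmp_path / "toy_peptide.pdb"
    path.write_text(format_pdb(atoms))
    return path


def cys_pair_pdb(tmp_path: Path, sg_distance: float, fname: str) -> Path:
    """Two cysteines whose SG atoms sit exactly sg_distance apart."""
    atoms = []
    atoms.extend(backbone_residue("CYS", "A", 1, 0.0))
    atoms.extend(backbone_residue("CYS", "A", 2, 20.0))
    atoms.append(dict(name="SG", resname="CYS", chain="A", resseq=1,
                      x=8.0, y=0.0, z=0.0, element="S"))
    atoms.append(dict(name="SG", resname="CYS", chain="A", resseq=2,
                      x=8.0 + sg_distance, y=0.0, z=0.0, element="S"))
    path = tmp_path / fname
    path.write_text(format_pdb(atoms))
    return path


def cys_chain_pdb(tmp_path: Path) -> Path:
    """Three cysteines, SG-SG distances 2.0 (1-2), 2.1 (2-3), 2.2 (1-3).

    All three pairs are within the 2.3 A cutoff; only a greedy
    nearest-first matching resolves this to the single 2.0 A pair.
    """
    atoms = []
    for i in range(3):
        atoms.extend(backbone_residue("CYS", "A", i + 1, 15.0 * i))
    sg_xy = [(0.0, 0.0), (2.0, 0.0), (1.1075, 1.9009)]
    for i, (x, y) in enumerate(sg_xy):
        atoms.append(dict(name="SG", resname="CYS", chain="A", resseq=i + 1,
                          x=x, y=y - 8.0, z=0.0, element="S"))
    path = tmp_path / "cys_chain.pdb"
    path.write_text(format_pdb(atoms))
    return path
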