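"""Structural annotation and the buried/disulfide exclusion filter.

Called positions are screened against an atomic structure: a residue
that is buried in the protein interior (relative solvent accessibility
below a threshold) or engaged in a disulfide bond cannot be part of an
antibody epitope on the folded antigen, so it is removed from the
candidate set.  Solvent-accessible surface area is computed by
Shrake-Rupley sphere sampling; RSA normalizes by the theoretical
maximum accessible area of each residue type (Tien et al. 2013).  A
precomputed annotation table (position, rsa, disulfide) can be supplied
instead of a structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import gemmi

from displaymap.reference import ReferenceConstruct

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_SPHERE_POINTS = 960
DEFAULT_SG_CUTOFF = 2.3
DEFAULT_RSA_MIN = 0.15

#: van der Waals radii (Angstrom) by element symbol
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}
_DEFAULT_VDW = 1.70

#: Theoretical maximum accessible surface area per residue (Tien et al. 2013)
MAX_ASA_TIEN2013 = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), _DEFAULT_VDW)


@dataclass
class StructureModel:
    """Flat single-model atom list (hydrogens and waters removed)."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("empty structure model")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite atom coordinates")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain, residue_number, residue_name) in first-appearance order."""
        seen: dict[tuple[str, int], tuple[str, int, str]] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.residue_number), (a.chain, a.residue_number, a.residue_name))
        return list(seen.values())


def parse_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a flat atom list.

    Keeps the first model only (warning if more exist), drops hydrogens
    and waters, and resolves alternate locations by highest occupancy,
    breaking ties by alphabetical altloc id.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    if len(st) > 1:
        logger.warning("structure %s has %d models; keeping model 1 only", path, len(st))
    model = st[0]
    best: dict[tuple[str, int, str, str], tuple[float, str, Atom]] = {}
    order: list[tuple[str, int, str, str]] = []
    for chain in model:
        for residue in chain:
            if residue.name in _WATER_NAMES:
                continue
            for atom in residue:
                element = atom.element.name.upper()
                if element == "H" or element == "D":
                    continue
                key = (chain.name, residue.seqid.num, residue.name, atom.name)
                occ = float(atom.occ)
                altloc = atom.altloc or ""
                cand = (
                    occ,
                    altloc,
                    Atom(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=element,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    ),
                )
                if key not in best:
                    best[key] = cand
                    order.append(key)
                else:
                    prev_occ, prev_alt, _ = best[key]
                    if occ > prev_occ or (occ == prev_occ and altloc < prev_alt):
                        best[key] = cand
    atoms = [best[key][2] for key in order]
    if not atoms:
        raise ValueError(f"structure file {path} contains no usable atoms")
    return StructureModel(atoms=atoms)


def _sphere_points(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
) -> pd.DataFrame:
    """Per-residue solvent-accessible surface area by sphere sampling.

    Test points are distributed on each atom's solvent-expanded sphere
    (radius vdW + probe); a point is accessible when it lies outside
    every other atom's expanded sphere.  Atom SASA is the accessible
    fraction of the expanded-sphere area; residue SASA sums its atoms.
    Each atom is sampled under two fixed rotations of the spiral
    lattice, which suppresses lattice aliasing at the occlusion-circle
    boundaries without changing the point budget semantics.

    Returns a DataFrame with columns chain, residue_number,
    residue_name, sasa.
    """
    coords = model.coords
    radii = model.radii + probe_radius
    n_atoms = len(model.atoms)
    unit = _sphere_points(n_sphere_points)
    # neighbor lists from the full pairwise distance matrix; fixtures and
    # single-domain structures are small enough for O(n^2) memory
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    # a fixed (deterministic) rotation of the lattice per atom decorrelates
    # the cap-boundary aliasing of the spiral lattice across atoms, which
    # tightens residue-level convergence at moderate point counts
    rot_rng = np.random.default_rng(1234567)
    atom_sasa = np.empty(n_atoms)
    for i in range(n_atoms):
        units = []
        for _ in range(2):  # two rotated copies of the lattice per atom
            q, r = np.linalg.qr(rot_rng.normal(size=(3, 3)))
            rotation = q * np.sign(np.diag(r))
            units.append(unit @ rotation.T)
        neighbor_mask = (dist[i] < radii[i] + radii) & (np.arange(n_atoms) != i)
        pts = coords[i] + radii[i] * np.concatenate(units)
        if neighbor_mask.any():
            ncoords = coords[neighbor_mask]
            nradii = radii[neighbor_mask]
            d2 = ((pts[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 > nradii**2).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        atom_sasa[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    rows: dict[tuple[str, int], dict] = {}
    for atom, area in zip(model.atoms, atom_sasa):
        key = (atom.chain, atom.residue_number)
        if key not in rows:
            rows[key] = {
                "chain": atom.chain,
                "residue_number": atom.residue_number,
                "residue_name": atom.residue_name,
                "sasa": 0.0,
            }
        rows[key]["sasa"] += float(area)
    return pd.DataFrame(list(rows.values()))


def relative_sasa(
    sasa_df: pd.DataFrame,
    max_asa_table: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Add an ``rsa`` column: SASA over the residue-type maximum.

    Residues absent from the table get NaN RSA and are flagged; they are
    never used to exclude a position.
    """
    table = MAX_ASA_TIEN2013 if max_asa_table is None else max_asa_table
    out = sasa_df.copy()
    rsa = []
    flags = []
    for _, row in out.iterrows():
        max_asa = table.get(row["residue_name"])
        if max_asa is None:
            warnings.warn(
                f"residue {row['residue_name']} not in max-ASA table; RSA undefined",
                stacklevel=2,
            )
            rsa.append(np.nan)
            flags.append("unknown_residue")
        else:
            rsa.append(row["sasa"] / max_asa)
            flags.append("")
    out["rsa"] = rsa
    out["flag"] = flags
    return out


def detect_disulfides(
    model: StructureModel,
    sg_cutoff: float = DEFAULT_SG_CUTOFF,
) -> set[frozenset[tuple[str, int]]]:
    """Cysteine pairs whose SG-SG distance is within the bond cutoff.

    Each SG is assigned to at most one partner, nearest pair first, so
    a chain of close cysteines resolves to a maximal greedy matching.
    Returns unordered pairs of (chain, residue_number).
    """
    sg = [
        a for a in model.atoms
        if a.residue_name == "CYS" and a.atom_name == "SG"
    ]
    candidates = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if (sg[i].chain, sg[i].residue_number) == (sg[j].chain, sg[j].residue_number):
                continue
            d = float(np.linalg.norm(np.array(sg[i].xyz) - np.array(sg[j].xyz)))
            if d <= sg_cutoff:
                candidates.append((d, (sg[i].chain, sg[i].residue_number),
                                   (sg[j].chain, sg[j].residue_number)))
    pairs: set[frozenset[tuple[str, int]]] = set()
    used: set[tuple[str, int]] = set()
    for d, a, b in sorted(candidates, key=lambda t: (t[0], t[1], t[2])):
        if a in used or b in used:
            continue
        pairs.add(frozenset((a, b)))
        used.update((a, b))
    return pairs


@dataclass
class NumberingMap:
    """Construct native position -> structure (chain, residue_number)."""

    mapping: dict[int, tuple[str, int]]
    unmapped: frozenset[int]

    def __post_init__(self) -> None:
        targets = list(self.mapping.values())
        if len(targets) != len(set(targets)):
            raise ValueError("numbering map is not injective")


def map_numbering(
    ref: ReferenceConstruct,
    model: StructureModel,
    chain: str,
    min_identity: float = 0.9,
) -> NumberingMap:
    """Match construct numbering to structure residue numbers.

    If author numbering already equals native numbering (matching amino
    acids), the identity map is returned; otherwise the single ungapped
    offset maximizing sequence identity is used, requiring at least
    ``min_identity`` over the overlap.  Construct positions without a
    matching structure residue are flagged unmapped.
    """
    residues = [
        (rnum, THREE_TO_ONE.get(rname))
        for ch, rnum, rname in model.residues()
        if ch == chain
    ]
    residues = [(n, aa) for n, aa in residues if aa is not None]
    if not residues:
        raise ValueError(f"chain {chain!r} not present or has no standard residues")
    by_num = dict(residues)
    best_offset, best_matches, best_overlap = None, -1, 0
    # candidate offsets: structure_number + offset = native_number
    offsets = {
        native - rnum for native in ref.native_positions for rnum, _ in residues
    }
    for offset in sorted(offsets):
        matches = overlap = 0
        for rnum, aa in residues:
            native = rnum + offset
            idx = native - ref.first_residue
            if 0 <= idx < len(ref.aa_seq):
                overlap += 1
                if ref.aa_seq[idx] == aa:
                    matches += 1
        if matches > best_matches:
            best_offset, best_matches, best_overlap = offset, matches, overlap
    if best_offset is None or best_overlap == 0 or best_matches / best_overlap < min_identity:
        raise ValueError(
            "numbering map failed: no ungapped offset reaches "
            f"{min_identity:.0%} identity with the construct sequence"
        )
    mapping = {}
    for rnum, aa in residues:
        native = rnum + best_offset
        idx = native - ref.first_residue
        if 0 <= idx < len(ref.aa_seq) and ref.aa_seq[idx] == aa:
            mapping[native] = (chain, rnum)
    unmapped = frozenset(set(ref.native_positions) - set(mapping))
    return NumberingMap(mapping=mapping, unmapped=unmapped)


@dataclass
class ResidueAnnotation:
    """Per-native-position structural annotation used by the filter.

    ``table`` columns: position, rsa, disulfide.  Positions missing from
    the table are treated as unannotated (kept, flagged) by the filter.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"position", "rsa", "disulfide"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if self.table["position"].duplicated().any():
            raise ValueError("duplicate positions in annotation table")

    def lookup(self, position: int) -> tuple[float, bool] | None:
        row = self.table[self.table["position"] == position]
        if row.empty:
            return None
        return float(row["rsa"].iloc[0]), bool(row["disulfide"].iloc[0])


def annotate_structure(
    ref: ReferenceConstruct,
    structure_path: str | Path,
    chain: str,
    *,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    sg_cutoff: float = DEFAULT_SG_CUTOFF,
    max_asa_table: dict[str, float] | None = None,
) -> ResidueAnnotation:
    """Compute per-residue RSA and disulfide flags from a structure.

    SASA is evaluated on the full model (all chains occlude), RSA and
    disulfide status are then projected onto construct numbering via the
    chain's numbering map.
    """
    model = parse_structure(structure_path)
    sasa_df = relative_sasa(shrake_rupley_sasa(model, probe_radius, n_sphere_points),
                            max_asa_table)
    bonded = {res for pair in detect_disulfides(model, sg_cutoff) for res in pair}
    numbering = map_numbering(ref, model, chain)
    rows = []
    lookup = sasa_df.set_index(["chain", "residue_number"])
    for native, key in sorted(numbering.mapping.items()):
        rec = lookup.loc[key]
        rows.append(
            {
                "position": native,
                "rsa": float(rec["rsa"]),
                "disulfide": key in bonded,
                "sasa": float(rec["sasa"]),
            }
        )
    return ResidueAnnotation(table=pd.DataFrame(rows))


def read_annotation_table(path: str | Path) -> ResidueAnnotation:
    """Load a precomputed (position, rsa, disulfide) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "disulfide" in df.columns and df["disulfide"].dtype == object:
        df["disulfide"] = df["disulfide"].map(
            {"True": True, "False": False, "true": True, "false": False}
        )
    return ResidueAnnotation(table=df)


def filter_epitope(
    called_positions: set[int],
    annotation: ResidueAnnotation,
    scores: pd.Series | None = None,
    rsa_min: float = DEFAULT_RSA_MIN,
    drop_unannotated: bool = False,
) -> pd.DataFrame:
    """Remove called positions that are buried or disulfide-bonded.

    Returns one row per called position: position, e_log2, rsa,
    disulfide, kept, reason.  Positions without annotation are kept with
    reason ``unfiltered`` (or dropped when ``drop_unannotated``); an NaN
    RSA never excludes a position.  The soundness invariant -- no kept
    position is annotated buried or disulfide-bonded -- is asserted on
    every call.
    """
    rows = []
    for pos in sorted(called_positions):
        ann = annotation.lookup(pos)
        e_val = float(scores.loc[pos]) if scores is not None and pos in scores.index else np.nan
        if ann is None:
            kept, reason, rsa, ss = (not drop_unannotated,
                                     "unfiltered" if not drop_unannotated else "unannotated",
                                     np.nan, False)
        else:
            rsa, ss = ann
            if ss:
                kept, reason = False, "disulfide"
            elif not np.isnan(rsa) and rsa < rsa_min:
                kept, reason = False, "buried"
            else:
                kept, reason = True, ""
        rows.append(
            {"position": pos, "e_log2": e_val, "rsa": rsa, "disulfide": ss,
             "kept": kept, "reason": reason}
        )
    result = pd.DataFrame(
        rows, columns=["position", "e_log2", "rsa", "disulfide", "kept", "reason"]
    )
    if not result.empty:
        kept_rows = result[result["kept"].astype(bool)]
        assert not kept_rows["disulfide"].any(), "filter soundness violated: disulfide kept"
        assert not (kept_rows["rsa"].fillna(1.0) < rsa_min).any(), \
            "filter soundness violated: buried kept"
    return result


def epitope_set(filtered: pd.DataFrame) -> set[int]:
    """Positions surviving the structural filter."""
    return set(filtered.loc[filtered["kept"], "position"])


def write_bfactor_structure(
    structure_path: str | Path,
    chain: str,
    scores: pd.Series,
    numbering: NumberingMap,
    out_path: str | Path,
) -> None:
    """Copy a structure with per-residue enrichment in the B-factor column.

    Handy for coloring the epitope on the 3D structure in a viewer.
    Residues without a score get B = 0.
    """
    st = gemmi.read_structure(str(structure_path))
    by_resnum = {
        key[1]: float(scores.loc[native])
        for native, key in numbering.mapping.items()
        if key[0] == chain and native in scores.index and np.isfinite(scores.loc[native])
    }
    for model in st:
        for ch in model:
            for residue in ch:
                b = by_resnum.get(residue.seqid.num, 0.0) if ch.name == chain else 0.0
                for atom in residue:
                    atom.b_iso = b
    st.write_pdb(str(out_path))
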