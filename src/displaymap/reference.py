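"""Reference antigen construct: amino-acid sequence, ORF, native numbering."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"


def translate_nt(nt: str) -> str:
    """Translate a nucleotide string under the standard genetic code.

    Stop codons are rendered as '*'.  Length must be a multiple of 3.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"ORF length {len(nt)} is not a multiple of 3")
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class ReferenceConstruct:
    """Displayed antigen construct with its native residue numbering.

    ``first_residue`` is the biological number of the first amino acid,
    so position ``i`` (0-based in ``aa_seq``) carries native number
    ``first_residue + i``.  The built-in default is a synthetic IgV-like
    construct spanning residues 22-132, the numbering of the human
    Tim-3 IgV ectodomain.
    """

    name: str
    aa_seq: str
    nt_orf: str
    first_residue: int = 1

    def __post_init__(self) -> None:
        if len(self.nt_orf) != 3 * len(self.aa_seq):
            raise ValueError(
                f"ORF length {len(self.nt_orf)} != 3 x protein length {len(self.aa_seq)}"
            )
        if "*" in self.aa_seq:
            raise ValueError("reference amino-acid sequence contains a stop symbol")
        bad = set(self.nt_orf) - set(NT_ALPHABET)
        if bad:
            raise ValueError(f"ORF contains non-ACGT characters: {sorted(bad)}")
        if translate_nt(self.nt_orf) != self.aa_seq:
            raise ValueError("nt_orf does not translate to aa_seq")

    def __len__(self) -> int:
        return len(self.aa_seq)

    @property
    def orf_length(self) -> int:
        return len(self.nt_orf)

    @property
    def native_positions(self) -> range:
        """Native residue numbers covered by the construct."""
        return range(self.first_residue, self.first_residue + len(self.aa_seq))

    def native_to_index(self, native_position: int) -> int:
        idx = native_position - self.first_residue
        if not 0 <= idx < len(self.aa_seq):
            raise IndexError(
                f"native position {native_position} outside construct "
                f"{self.first_residue}..{self.first_residue + len(self.aa_seq) - 1}"
            )
        return idx

    def index_to_native(self, index: int) -> int:
        if not 0 <= index < len(self.aa_seq):
            raise IndexError(f"index {index} outside construct of length {len(self.aa_seq)}")
        return self.first_residue + index

    def codon(self, index: int) -> str:
        return self.nt_orf[3 * index : 3 * index + 3]

    def to_fasta(self, path: str | Path) -> None:
        """Write paired amino-acid and nucleotide records.

        Record ids are ``<name>|aa|first_residue=<n>`` and ``<name>|nt``,
        round-trippable via :func:`read_reference_fasta`.
        """
        records = [
            SeqRecord(Seq(self.aa_seq), id=f"{self.name}|aa|first_residue={self.first_residue}",
                      description=""),
            SeqRecord(Seq(self.nt_orf), id=f"{self.name}|nt", description=""),
        ]
        SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> ReferenceConstruct:
    """Load a construct written by :meth:`ReferenceConstruct.to_fasta`.

    A FASTA containing only the nucleotide record (id ``<name>|nt`` or a
    bare single nucleotide record) is accepted; the protein sequence is
    then derived by translation and first_residue defaults to 1.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    aa_rec = nt_rec = None
    first_residue = 1
    for rec in records:
        parts = rec.id.split("|")
        if len(parts) >= 2 and parts[1] == "aa":
            aa_rec = rec
            for token in parts[2:]:
                if token.startswith("first_residue="):
                    first_residue = int(token.split("=", 1)[1])
        elif len(parts) >= 2 and parts[1] == "nt":
            nt_rec = rec
    if nt_rec is None:
        if len(records) == 1:
            nt_rec = records[0]
        else:
            raise ValueError(f"no nucleotide record (id '<name>|nt') in {path}")
    name = nt_rec.id.split("|")[0]
    nt = str(nt_rec.seq).upper()
    aa = str(aa_rec.seq).upper() if aa_rec is not None else translate_nt(nt)
    return ReferenceConstruct(name=name, aa_seq=aa, nt_orf=nt, first_residue=first_residue)


# Synthetic 111-residue stand-in for an IgV-domain construct numbered
# 22-132 (the native span of the human Tim-3 IgV ectodomain).  The
# sequence is a fixed, IgV-like random draw -- NOT the real Tim-3
# sequence -- with cysteines at native positions 38 and 45 so the
# synthetic structural annotation can mark a disulfide pair.  The ORF is
# a deterministic reverse translation (one fixed codon per amino acid):
# only the coding relationship matters for simulation.
_IGV_SYNTHETIC_AA = (
    "EGTWPGQGVDEEAVHQCLGALMKCRIGPFESTGSIVLAENAVRVDTRRIALFMIRMVELEEVGNAIYIEFE"
    "VGANEGFTTDNINRPTEDANGQIRKHTIKNYAAAQPWALA"
)

_CODON_CHOICE = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


def default_construct() -> ReferenceConstruct:
    """Built-in synthetic IgV-like construct, 111 aa, numbered 22-132."""
    aa = _IGV_SYNTHETIC_AA
    nt = "".join(_CODON_CHOICE[a] for a in aa)
    return ReferenceConstruct(name="IgV_synthetic", aa_seq=aa, nt_orf=nt, first_residue=22)
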