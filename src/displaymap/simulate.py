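"""Synthetic sort-seq data: mutagenesis, FACS selection, fragment sequencing.

The generator emulates the wet-lab procedure behind display-based
epitope mapping at desk scale: error-prone PCR introduces a low random
load of nucleotide substitutions into the antigen ORF; FACS gating keeps
clones that still display antigen (no stop codons) but have lost
antibody binding; two rounds of gate-and-expand enrich loss-of-binding
clones; tagmentation-style fragment sequencing produces short reads at
random offsets across the ORF.  Every stochastic step takes an explicit
seed, so a whole simulated experiment is reproducible bit for bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from displaymap.reference import ReferenceConstruct, NT_ALPHABET

STOP = "*"


class SelectionExtinguishedError(RuntimeError):
    """Raised when a selection round captures zero clones."""


@dataclass(frozen=True)
class Clone:
    """One library member: nucleotide substitutions on the reference ORF.

    ``aa_substitutions`` is derived from ``nt_substitutions`` by codon
    translation and lists only amino-acid changes (synonymous
    substitutions contribute nothing).  A clone containing a stop codon
    is not displayed on the cell surface (``is_displayed`` False) and
    can never be captured by the antigen-positive gate.
    """

    nt_substitutions: tuple[tuple[int, str, str], ...]
    aa_substitutions: tuple[tuple[int, str, str], ...]
    is_displayed: bool

    @property
    def n_nt_substitutions(self) -> int:
        return len(self.nt_substitutions)

    def mutated_positions(self) -> frozenset[int]:
        """Native positions carrying an amino-acid change."""
        return frozenset(p for p, _, _ in self.aa_substitutions)


def derive_clone(ref: ReferenceConstruct, nt_substitutions: Sequence[tuple[int, str, str]]) -> Clone:
    """Build a :class:`Clone` from nucleotide substitutions.

    Translates every affected codon; stop-gain substitutions set
    ``is_displayed`` to False.
    """
    seen = set()
    for idx, ref_base, _ in nt_substitutions:
        if idx in seen:
            raise ValueError(f"duplicate substitution at ORF index {idx}")
        seen.add(idx)
        if ref.nt_orf[idx] != ref_base:
            raise ValueError(
                f"ref base mismatch at ORF index {idx}: expected {ref.nt_orf[idx]}, got {ref_base}"
            )
    by_codon: dict[int, list[tuple[int, str]]] = {}
    for idx, _, alt in nt_substitutions:
        by_codon.setdefault(idx // 3, []).append((idx % 3, alt))
    aa_subs = []
    displayed = True
    for codon_idx in sorted(by_codon):
        codon = list(ref.codon(codon_idx))
        for within, alt in by_codon[codon_idx]:
            codon[within] = alt
        alt_aa = str(Seq("".join(codon)).translate())
        ref_aa = ref.aa_seq[codon_idx]
        if alt_aa == STOP:
            displayed = False
        if alt_aa != ref_aa:
            aa_subs.append((ref.index_to_native(codon_idx), ref_aa, alt_aa))
    return Clone(
        nt_substitutions=tuple((i, r, a) for i, r, a in nt_substitutions),
        aa_substitutions=tuple(aa_subs),
        is_displayed=displayed,
    )


@dataclass
class CloneLibrary:
    """Multiset of clones: unique genotypes plus multiplicities."""

    ref: ReferenceConstruct
    clones: list[Clone]
    counts: np.ndarray  # int64, same length as clones

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.clones):
            raise ValueError("counts and clones length mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative clone multiplicity")

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    def mutated_orf(self, clone_index: int) -> str:
        """Full ORF sequence of one clone."""
        orf = list(self.ref.nt_orf)
        for idx, _, alt in self.clones[clone_index].nt_substitutions:
            orf[idx] = alt
        return "".join(orf)

    def position_mutation_fraction(self) -> dict[int, float]:
        """True per-position amino-acid mutation frequency in the multiset.

        Oracle quantity used by tests: the fraction of library members
        carrying an amino-acid change at each native position.
        """
        total = self.size
        acc: dict[int, int] = {}
        for clone, n in zip(self.clones, self.counts):
            for pos in clone.mutated_positions():
                acc[pos] = acc.get(pos, 0) + int(n)
        return {pos: k / total for pos, k in acc.items()}


@dataclass(frozen=True)
class SelectionParams:
    """FACS gate model for loss-of-binding selection.

    A displayed clone is binding-loss iff at least one of its amino-acid
    substitutions at an epitope position registers an effect
    (probability ``q_effect``, drawn once per clone substitution and
    persistent across rounds).  Each round captures binding-loss clones
    with probability ``p_hit`` and binding-retained clones with
    probability ``p_bg``, then expands back to a fixed population size.
    """

    epitope_positions: frozenset[int]
    q_effect: float = 0.8
    p_hit: float = 0.9
    p_bg: float = 0.005
    rounds: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_effect <= 1.0:
            raise ValueError("q_effect must be in [0, 1]")
        if not 0.0 <= self.p_bg <= self.p_hit <= 1.0:
            raise ValueError("require 0 <= p_bg <= p_hit <= 1")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        object.__setattr__(self, "epitope_positions", frozenset(self.epitope_positions))


@dataclass(frozen=True)
class GroundTruth:
    """Record of what the simulator planted, for recovery scoring."""

    epitope_positions: frozenset[int]
    q_effect: float
    p_hit: float
    p_bg: float
    rounds: int
    lambda_nt: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "epitope_positions", frozenset(self.epitope_positions))


def mutagenize_library(
    ref: ReferenceConstruct,
    n_clones: int,
    lambda_nt: float,
    seed: int,
) -> CloneLibrary:
    """Simulate error-prone PCR at a low mutation rate.

    Per clone the number of nucleotide substitutions is Poisson
    distributed with mean ``lambda_nt``; substituted positions are drawn
    uniformly without replacement over the ORF and the alternative base
    uniformly over the three non-reference bases.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if lambda_nt < 0:
        raise ValueError("lambda_nt must be >= 0")
    if lambda_nt > ref.orf_length:
        raise ValueError(
            f"lambda_nt={lambda_nt} exceeds ORF length {ref.orf_length}: "
            "cannot place substitutions without replacement"
        )
    rng = np.random.default_rng(seed)
    orf_len = ref.orf_length
    n_subs = rng.poisson(lambda_nt, size=n_clones)
    n_subs = np.minimum(n_subs, orf_len)  # Poisson tail cannot exceed the ORF
    clones: list[Clone] = []
    orf = ref.nt_orf
    for m in n_subs:
        if m == 0:
            clones.append(Clone((), (), True))
            continue
        positions = rng.choice(orf_len, size=int(m), replace=False)
        subs = []
        for idx in sorted(int(p) for p in positions):
            ref_base = orf[idx]
            alternatives = [b for b in NT_ALPHABET if b != ref_base]
            alt = alternatives[int(rng.integers(3))]
            subs.append((idx, ref_base, alt))
        clones.append(derive_clone(ref, subs))
    return CloneLibrary(ref=ref, clones=clones, counts=np.ones(len(clones), dtype=np.int64))


def _binding_loss_status(
    lib: CloneLibrary, params: SelectionParams, rng: np.random.Generator
) -> np.ndarray:
    """Per-genotype binding-loss indicator.

    The effect of each epitope-position substitution is drawn once here
    and held fixed for all rounds: a clone's phenotype is a property of
    its genotype, not re-rolled every sort.
    """
    loss = np.zeros(len(lib.clones), dtype=bool)
    for i, clone in enumerate(lib.clones):
        for pos, _, alt in clone.aa_substitutions:
            if alt != STOP and pos in params.epitope_positions:
                if rng.random() < params.q_effect:
                    loss[i] = True
                    # remaining substitutions still consume no draws:
                    # one draw per *effect test*, stop at first hit
                    break
    return loss


def select_library(
    lib: CloneLibrary,
    params: SelectionParams,
    target_size: int,
    seed: int,
) -> CloneLibrary:
    """Run sequential rounds of gate-and-expand selection.

    Clones that are not displayed (stop codons) are never captured by
    the antigen-positive gate.  Each round captures every population
    member independently (``p_hit`` for binding-loss clones, ``p_bg``
    otherwise), then resamples with replacement back to ``target_size``,
    modeling regrowth of the sorted pool.
    """
    if lib.size == 0:
        raise ValueError("cannot select from an empty library")
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    rng = np.random.default_rng(seed)
    loss = _binding_loss_status(lib, params, rng)
    displayed = np.array([c.is_displayed for c in lib.clones])
    p_capture = np.where(displayed, np.where(loss, params.p_hit, params.p_bg), 0.0)
    counts = lib.counts.copy()
    for _ in range(params.rounds):
        captured = rng.binomial(counts, p_capture)
        total = int(captured.sum())
        if total == 0:
            raise SelectionExtinguishedError("selection extinguished library")
        counts = rng.multinomial(target_size, captured / total)
    keep = counts > 0
    return CloneLibrary(
        ref=lib.ref,
        clones=[c for c, k in zip(lib.clones, keep) if k],
        counts=counts[keep],
    )


def sequence_library(
    lib: CloneLibrary,
    ref: ReferenceConstruct,
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
) -> list[SeqRecord]:
    """Simulate fragment sequencing of a library.

    The number of reads is ``round(coverage * ORF_length /
    read_length)``; each read is drawn from a clone chosen uniformly
    from the library multiset, at a uniform forward-strand offset, with
    iid per-base substitution errors at ``error_rate``.  Base qualities
    are constant ('I').  The clone index and offset are recorded in the
    read id for debugging and oracle tests.
    """
    if lib.size == 0:
        raise ValueError("cannot sequence an empty library")
    if read_length > ref.orf_length:
        raise ValueError("read_length exceeds ORF length")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    orf_len = ref.orf_length
    n_reads = int(round(coverage * orf_len / read_length))
    probs = lib.counts / lib.size
    clone_idx = rng.choice(len(lib.clones), size=n_reads, p=probs)
    offsets = rng.integers(0, orf_len - read_length + 1, size=n_reads)
    orf_cache: dict[int, str] = {}
    records: list[SeqRecord] = []
    base_index = {b: i for i, b in enumerate(NT_ALPHABET)}
    for r, (ci, off) in enumerate(zip(clone_idx, offsets)):
        ci, off = int(ci), int(off)
        if ci not in orf_cache:
            orf_cache[ci] = lib.mutated_orf(ci)
        fragment = list(orf_cache[ci][off : off + read_length])
        if error_rate > 0:
            errs = np.nonzero(rng.random(read_length) < error_rate)[0]
            for e in errs:
                shift = int(rng.integers(1, 4))
                fragment[e] = NT_ALPHABET[(base_index[fragment[e]] + shift) % 4]
        rec = SeqRecord(
            Seq("".join(fragment)),
            id=f"r{r:06d}|clone={ci}|off={off}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [40] * read_length
        records.append(rec)
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    return SeqIO.write(list(records), str(path), "fastq")


_TRUTH_FIELDS = ("epitope_positions", "q_effect", "p_hit", "p_bg", "rounds", "lambda_nt", "seed")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the planted ground truth as a two-column TSV (key, value)."""
    rows = {
        "epitope_positions": ",".join(str(p) for p in sorted(truth.epitope_positions)),
        "q_effect": repr(truth.q_effect),
        "p_hit": repr(truth.p_hit),
        "p_bg": repr(truth.p_bg),
        "rounds": str(truth.rounds),
        "lambda_nt": repr(truth.lambda_nt),
        "seed": str(truth.seed),
    }
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["key", "value"])
        for key in _TRUTH_FIELDS:
            writer.writerow([key, rows[key]])


def read_truth(path: str | Path) -> GroundTruth:
    """Read back a ground-truth TSV; missing fields raise a schema error."""
    values: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["key", "value"]:
            raise ValueError(f"bad ground-truth header in {path}: {header}")
        for row in reader:
            if len(row) != 2:
                raise ValueError(f"malformed ground-truth row: {row}")
            values[row[0]] = row[1]
    missing = [f for f in _TRUTH_FIELDS if f not in values]
    if missing:
        raise ValueError(f"ground-truth file missing fields: {missing}")
    eps = values["epitope_positions"]
    positions = frozenset(int(p) for p in eps.split(",")) if eps else frozenset()
    return GroundTruth(
        epitope_positions=positions,
        q_effect=float(values["q_effect"]),
        p_hit=float(values["p_hit"]),
        p_bg=float(values["p_bg"]),
        rounds=int(values["rounds"]),
        lambda_nt=float(values["lambda_nt"]),
        seed=int(values["seed"]),
    )


def write_annotation(
    ref: ReferenceConstruct,
    path: str | Path,
    *,
    disulfide_positions: Iterable[int] = (),
    buried_positions: Iterable[int] = (),
    rsa_buried: float = 0.02,
    rsa_exposed_range: tuple[float, float] = (0.2, 0.9),
    seed: int = 0,
) -> None:
    """Write a synthetic per-residue structural annotation TSV.

    Stands in for annotations derived from a real structure: every
    position gets an RSA (buried positions get ``rsa_buried``, the rest
    a uniform draw from ``rsa_exposed_range``) and a disulfide flag.
    Disulfide flags are only allowed on cysteines of the construct.
    """
    disulfide_positions = frozenset(disulfide_positions)
    buried_positions = frozenset(buried_positions)
    for pos in disulfide_positions:
        if ref.aa_seq[ref.native_to_index(pos)] != "C":
            raise ValueError(f"disulfide annotation at non-cysteine position {pos}")
    rng = np.random.default_rng(seed)
    lo, hi = rsa_exposed_range
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "rsa", "disulfide"])
        for pos in ref.native_positions:
            if pos in buried_positions:
                rsa = rsa_buried
            else:
                rsa = float(rng.uniform(lo, hi))
            writer.writerow([pos, f"{rsa:.4f}", str(pos in disulfide_positions)])
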