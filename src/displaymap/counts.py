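"""Map fragment reads to the ORF and tabulate per-position mutation frequencies.

Reads are placed by exact k-mer anchoring followed by ungapped
extension; codon-level amino-acid substitutions are then called on
every codon a read fully covers.  The per-position estimator is
read-level: ``f_i = k_i / n_i`` where ``n_i`` counts reads whose span
covers codon ``i`` with no ambiguous base and ``k_i`` those among them
carrying a non-synonymous change at ``i``.  Fragments cannot be phased
back to clones, so reads are the sampling unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement

from displaymap.reference import ReferenceConstruct

DEFAULT_ANCHOR_K = 21
DEFAULT_MAX_MISMATCH = 10
DEFAULT_MIN_COVERAGE = 20


@dataclass(frozen=True)
class AlignedRead:
    """Ungapped placement of a read on the reference ORF.

    ``orf_offset`` is the 0-based ORF index of the first aligned base;
    ``read_start`` the index within the (possibly reverse-complemented)
    read where the aligned region begins; ``matched_length`` the length
    of the aligned region.  ``mismatch_indices`` are ORF indices.
    """

    read_id: str
    orf_offset: int
    read_start: int
    matched_length: int
    mismatch_indices: tuple[int, ...]
    is_reverse_complement: bool = False


@dataclass(frozen=True)
class AlignmentRejection:
    read_id: str
    reason: str  # "no anchor" | "ambiguous anchor" | "too many mismatches" | "no overlap"


class KmerIndex:
    """Exact k-mer lookup table over the reference ORF."""

    def __init__(self, ref: ReferenceConstruct, k: int = DEFAULT_ANCHOR_K):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.ref = ref
        index: dict[str, list[int]] = {}
        orf = ref.nt_orf
        for i in range(len(orf) - k + 1):
            index.setdefault(orf[i : i + k], []).append(i)
        self._index = index

    def lookup(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])


def _align_one_strand(
    read: str, read_id: str, ref: ReferenceConstruct, index: KmerIndex,
    max_mismatch: int, rc: bool,
) -> AlignedRead | AlignmentRejection:
    k = index.k
    orf = ref.nt_orf
    saw_ambiguous = False
    offset = None
    for start in range(0, len(read) - k + 1):
        hits = index.lookup(read[start : start + k])
        if not hits:
            continue
        if len(hits) > 1:
            saw_ambiguous = True
            continue
        offset = hits[0] - start
        break
    if offset is None:
        return AlignmentRejection(read_id, "ambiguous anchor" if saw_ambiguous else "no anchor")
    # clip the read to the ORF span (reads anchored near an end may overhang)
    read_start = max(0, -offset)
    orf_start = max(0, offset)
    matched = min(len(read) - read_start, len(orf) - orf_start)
    if matched < k:
        return AlignmentRejection(read_id, "no overlap")
    mismatches = tuple(
        orf_start + j
        for j in range(matched)
        if read[read_start + j] != orf[orf_start + j]
    )
    if len(mismatches) > max_mismatch:
        return AlignmentRejection(read_id, "too many mismatches")
    return AlignedRead(
        read_id=read_id,
        orf_offset=orf_start,
        read_start=read_start,
        matched_length=matched,
        mismatch_indices=mismatches,
        is_reverse_complement=rc,
    )


def anchor_align(
    read: str,
    ref: ReferenceConstruct,
    index: KmerIndex | None = None,
    *,
    read_id: str = "",
    k: int = DEFAULT_ANCHOR_K,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    search_rc: bool = False,
) -> AlignedRead | AlignmentRejection:
    """Place a read on the ORF by its first uniquely matching k-mer.

    Anchors are scanned left to right; the first k-mer with a unique
    exact match fixes the ungapped offset, which is then extended and
    scored.  Rejection (no anchor, only ambiguous anchors, too many
    mismatches) is a return state, not an exception.  With
    ``search_rc`` the reverse complement is tried when the forward
    strand fails.
    """
    read = read.upper()
    if index is None:
        index = KmerIndex(ref, k)
    if index.k > len(read):
        raise ValueError(f"anchor length {index.k} exceeds read length {len(read)}")
    result = _align_one_strand(read, read_id, ref, index, max_mismatch, rc=False)
    if isinstance(result, AlignedRead) or not search_rc:
        return result
    rc_read = reverse_complement(read)
    rc_result = _align_one_strand(rc_read, read_id, ref, index, max_mismatch, rc=True)
    return rc_result if isinstance(rc_result, AlignedRead) else result


def call_aa_mutations(
    ar: AlignedRead,
    read: str,
    ref: ReferenceConstruct,
) -> tuple[list[tuple[int, str, str]], list[int]]:
    """Call amino-acid substitutions on the codons a read fully covers.

    Returns ``(calls, callable_positions)``: calls are
    ``(native_position, ref_aa, alt_aa)`` for codons whose translation
    differs from the reference (synonymous changes emit nothing; a
    stop gain is a call with alt '*'); ``callable_positions`` lists the
    native positions of every fully covered codon without an ambiguous
    base -- the read contributes coverage exactly there.  Pass the
    reverse-complemented read when ``ar.is_reverse_complement``.
    """
    read = read.upper()
    if ar.is_reverse_complement:
        read = reverse_complement(read)
    span_start, span_end = ar.orf_offset, ar.orf_offset + ar.matched_length
    first_codon = (span_start + 2) // 3
    last_codon = span_end // 3  # exclusive
    calls: list[tuple[int, str, str]] = []
    callable_positions: list[int] = []
    for c in range(first_codon, last_codon):
        codon_read = read[ar.read_start + 3 * c - span_start : ar.read_start + 3 * c - span_start + 3]
        if "N" in codon_read:
            continue  # ambiguous codon: neither coverage nor call
        native = ref.index_to_native(c)
        callable_positions.append(native)
        if codon_read != ref.codon(c):
            alt_aa = str(Seq(codon_read).translate())
            ref_aa = ref.aa_seq[c]
            if alt_aa != ref_aa:
                calls.append((native, ref_aa, alt_aa))
    return calls, callable_positions


def tabulate_counts(
    calls_per_read: Sequence[Sequence[tuple[int, str, str]]],
    coverage_per_read: Sequence[Sequence[int]],
    library_id: str,
    ref: ReferenceConstruct,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Aggregate per-read calls into a per-position count table.

    Output columns: library, position, ref_aa, k, n, f, flag.  ``f`` is
    NaN where no read covers the position; positions with
    ``n < min_coverage`` are flagged ``low_coverage`` and excluded from
    downstream scoring.
    """
    if len(calls_per_read) == 0:
        raise ValueError("empty read set")
    if len(calls_per_read) != len(coverage_per_read):
        raise ValueError("calls and coverage lists differ in length")
    npos = len(ref)
    k_arr = np.zeros(npos, dtype=np.int64)
    n_arr = np.zeros(npos, dtype=np.int64)
    for calls, covered in zip(calls_per_read, coverage_per_read):
        for pos in covered:
            n_arr[ref.native_to_index(pos)] += 1
        for pos, _, _ in calls:
            k_arr[ref.native_to_index(pos)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        f_arr = np.where(n_arr > 0, k_arr / np.maximum(n_arr, 1), np.nan)
    flags = np.where(
        n_arr == 0, "no_coverage", np.where(n_arr < min_coverage, "low_coverage", "")
    )
    return pd.DataFrame(
        {
            "library": library_id,
            "position": [ref.index_to_native(i) for i in range(npos)],
            "ref_aa": list(ref.aa_seq),
            "k": k_arr,
            "n": n_arr,
            "f": f_arr,
            "flag": flags,
        }
    )


def count_reads(
    reads: Iterable[tuple[str, str]],
    ref: ReferenceConstruct,
    library_id: str,
    *,
    k: int = DEFAULT_ANCHOR_K,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    search_rc: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Align reads, call substitutions, tabulate counts for one library.

    ``reads`` yields ``(read_id, sequence)``.  Returns the per-position
    count table, an auxiliary per-substitution table (position, ref_aa,
    alt_aa, count; not used for calling), and alignment statistics
    including per-reason rejection counts.
    """
    index = KmerIndex(ref, k)
    calls_per_read: list[list[tuple[int, str, str]]] = []
    coverage_per_read: list[list[int]] = []
    stats = {"total": 0, "aligned": 0, "rejected": 0}
    aux: dict[tuple[int, str, str], int] = {}
    for read_id, seq in reads:
        stats["total"] += 1
        result = anchor_align(
            seq, ref, index, read_id=read_id, max_mismatch=max_mismatch, search_rc=search_rc
        )
        if isinstance(result, AlignmentRejection):
            stats["rejected"] += 1
            key = f"rejected[{result.reason}]"
            stats[key] = stats.get(key, 0) + 1
            continue
        stats["aligned"] += 1
        calls, covered = call_aa_mutations(result, seq, ref)
        calls_per_read.append(calls)
        coverage_per_read.append(covered)
        for call in calls:
            aux[call] = aux.get(call, 0) + 1
    if stats["aligned"] == 0:
        raise ValueError("no reads aligned; cannot tabulate counts")
    table = tabulate_counts(calls_per_read, coverage_per_read, library_id, ref, min_coverage)
    aux_df = pd.DataFrame(
        [
            {"library": library_id, "position": p, "ref_aa": r, "alt_aa": a, "count": c}
            for (p, r, a), c in sorted(aux.items())
        ],
        columns=["library", "position", "ref_aa", "alt_aa", "count"],
    )
    return table, aux_df, stats


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Load a FASTQ file as (read_id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_counts(table: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a count table as TSV with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["flag"] = df["flag"].fillna("")
    return df
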