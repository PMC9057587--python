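"""Library normalization and enrichment calling.

Mutation frequencies are made comparable across libraries with the
median-of-geometric-mean-ratios size factor (the median-of-ratios
normalization familiar from count-based differential analysis, applied
to per-position frequencies): for each position present at non-zero
frequency in every library, the geometric mean across libraries is the
pseudo-reference, and a library's size factor is the median of its
ratios to that reference.  A position is called a loss-of-binding
(epitope) candidate when its log2 normalized frequency is at least 2
above the median of the sample it was observed in -- i.e. at least
four-fold the within-sample median mutation frequency.  The ratio to
the unselected reference library is reported alongside as an auxiliary
diagnostic but is not used for calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 2.0


@dataclass
class FrequencyMatrix:
    """Positions x libraries matrix of defined mutation frequencies.

    ``F`` rows are native positions, columns library ids; every retained
    position has a defined frequency in all libraries.  Exactly one
    library is the unselected reference.
    """

    F: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.F.columns:
            raise ValueError(f"reference library {self.reference!r} not among columns")
        values = self.F.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("frequency matrix contains non-finite entries")
        if (values < 0).any():
            raise ValueError("frequency matrix contains negative entries")

    @property
    def selected(self) -> list[str]:
        return [c for c in self.F.columns if c != self.reference]


def build_frequency_matrix(
    count_tables: Iterable[pd.DataFrame],
    reference: str,
    pseudocount: float = 0.0,
) -> FrequencyMatrix:
    """Join per-library count tables into a frequency matrix.

    Only positions with a defined, unflagged frequency (adequate
    coverage) in every library are retained.  An optional pseudocount
    is added to every frequency (default 0).
    """
    columns = {}
    keep: pd.Index | None = None
    for table in count_tables:
        lib = table["library"].iloc[0]
        ok = table[table["flag"] == ""].set_index("position")["f"]
        columns[lib] = ok
        keep = ok.index if keep is None else keep.intersection(ok.index)
    if keep is None or len(keep) == 0:
        raise ValueError("no position has defined frequency in all libraries")
    F = pd.DataFrame({lib: col.loc[keep] for lib, col in columns.items()})
    F = F.sort_index()
    if pseudocount:
        F = F + pseudocount
    return FrequencyMatrix(F=F, reference=reference)


def size_factors(fm: FrequencyMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-geometric-mean-ratios size factor per library.

    Positions with a zero frequency in any library are excluded from
    the computation (their geometric mean vanishes) but are still
    scored downstream.
    """
    F = fm.F if isinstance(fm, FrequencyMatrix) else fm
    if F.shape[1] < 2:
        raise ValueError("size factors need at least 2 libraries")
    positive = F[(F > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("normalization undefined: no position positive in all libraries")
    g = np.exp(np.log(positive).mean(axis=1))  # rowwise geometric mean
    ratios = positive.div(g, axis=0)
    s = ratios.median(axis=0)  # even count: mean of the two central ratios
    s.name = "size_factor"
    return s


def normalize_frequencies(F: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Divide each library column by its size factor."""
    if list(F.columns) != list(s.index):
        raise ValueError("size-factor index does not match matrix columns")
    return F.div(s, axis=1)


def enrichment_scores(f_norm: pd.DataFrame, library: str) -> pd.Series:
    """Per-position log2 enrichment relative to the within-sample median.

    ``e_i = log2(f_i / median_i'(f_i'))`` over the retained positions of
    one library; zero frequencies score -inf and can never be called.
    """
    col = f_norm[library]
    if int((col > 0).sum()) < 3:
        raise ValueError(f"library {library!r} has fewer than 3 positive positions")
    med = float(np.median(col.to_numpy()))
    if med == 0:
        raise ValueError("degenerate sample: median normalized frequency is 0")
    with np.errstate(divide="ignore"):
        e = pd.Series(np.log2(col.to_numpy() / med), index=col.index, name=f"e[{library}]")
    return e


def call_positions(e: pd.Series, threshold: float = DEFAULT_THRESHOLD) -> set[int]:
    """Positions with enrichment at or above the threshold (inclusive)."""
    return set(e.index[e >= threshold])


def reference_delta(f_norm: pd.DataFrame, library: str, reference: str) -> pd.Series:
    """Auxiliary log2 ratio of a selected library to the unselected reference.

    Positions where the reference frequency is zero are flagged NaN
    rather than computed.  Reported alongside the within-sample score,
    not used for calling.
    """
    sel = f_norm[library].to_numpy(dtype=float)
    ref = f_norm[reference].to_numpy(dtype=float)
    out = np.full(len(sel), np.nan)
    ok = ref > 0
    with np.errstate(divide="ignore"):
        out[ok] = np.log2(sel[ok] / ref[ok])
    return pd.Series(out, index=f_norm.index, name=f"ref_delta[{library}]")


def enrichment_table(
    fm: FrequencyMatrix,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Full enrichment analysis of every selected library.

    Long-format output with one row per (position, selected library):
    raw frequency, size factor, normalized frequency, within-sample
    log2 enrichment, auxiliary reference delta, and the call flag.
    """
    s = size_factors(fm)
    f_norm = normalize_frequencies(fm.F, s)
    frames = []
    for lib in fm.selected:
        e = enrichment_scores(f_norm, lib)
        called = e >= threshold
        delta = reference_delta(f_norm, lib, fm.reference)
        frames.append(
            pd.DataFrame(
                {
                    "position": fm.F.index,
                    "library": lib,
                    "f": fm.F[lib].to_numpy(),
                    "s_j": s[lib],
                    "f_norm": f_norm[lib].to_numpy(),
                    "e_log2": e.to_numpy(),
                    "ref_delta": delta.to_numpy(),
                    "called": called.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_enrichment(table: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_enrichment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
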