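"""Position profiles (sequence-logo data) and PROSITE-style patterns.

From an alignment of OR proteins this module computes per-column residue
frequencies and information content, and induces conserved patterns in
dashed PROSITE notation — fixed residues, residue sets ``[FL]``, wildcards
``x`` and flexible wildcards ``x(m,n)`` — which can be matched back against
arbitrary protein sequences.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

GAP = "-"
MAX_BITS = math.log2(20)


@dataclass
class PositionProfile:
    length: int
    frequencies: pd.DataFrame     # columns x residues (incl. gap), rows sum 1
    information: np.ndarray       # bits per column

    def to_table(self) -> pd.DataFrame:
        long = self.frequencies.stack().rename("freq").reset_index()
        long.columns = ["column", "residue", "freq"]
        long = long[long["freq"] > 0]
        long["bits"] = self.information[long["column"]]
        return long.reset_index(drop=True)


def build_profile(alignment: list[str]) -> PositionProfile:
    """Column frequencies and information content of an alignment.

    Information is log2(20) minus the Shannon entropy of the non-gap
    residues, scaled by the column's non-gap fraction; no pseudocounts.
    """
    if not alignment:
        raise ValueError("empty alignment")
    n = len(alignment[0])
    if any(len(row) != n for row in alignment):
        raise ValueError("ragged alignment")
    rows = len(alignment)
    freqs = []
    info = np.zeros(n)
    for j in range(n):
        col = [row[j] for row in alignment]
        counts = pd.Series(col).value_counts()
        freqs.append(counts / rows)
        non_gap = [c for c in col if c != GAP]
        if non_gap:
            p = pd.Series(non_gap).value_counts(normalize=True)
            entropy = float(-(p * np.log2(p)).sum())
            info[j] = (MAX_BITS - entropy) * (len(non_gap) / rows)
    freq_df = pd.DataFrame(freqs).fillna(0.0)
    freq_df.index = pd.RangeIndex(n, name="column")
    return PositionProfile(n, freq_df, info)


@dataclass(frozen=True)
class PatternElement:
    kind: str                 # "fixed" | "set" | "wildcard" | "flex"
    residues: str = ""        # for fixed/set
    min_len: int = 1          # for flex
    max_len: int = 1

    def __str__(self) -> str:
        if self.kind == "fixed":
            return self.residues
        if self.kind == "set":
            return f"[{self.residues}]"
        if self.kind == "wildcard":
            return "x"
        if self.min_len == self.max_len:
            return f"x({self.min_len})"
        return f"x({self.min_len},{self.max_len})"

    def to_regex(self) -> str:
        if self.kind == "fixed":
            return re.escape(self.residues)
        if self.kind == "set":
            return f"[{self.residues}]"
        if self.kind == "wildcard":
            return "."
        return f".{{{self.min_len},{self.max_len}}}"


@dataclass(frozen=True)
class PatternExpression:
    elements: tuple[PatternElement, ...]

    def __str__(self) -> str:
        return "-".join(str(e) for e in self.elements)

    def to_regex(self) -> str:
        return "".join(e.to_regex() for e in self.elements)

    @classmethod
    def parse(cls, text: str) -> "PatternExpression":
        """Parse dashed PROSITE-like notation; 'x' or 'X' is a wildcard,
        'x(m,n)' a flexible one, '[AB]' a residue set, '_' is read as '-'
        (tolerates typographic artifacts)."""
        elements = []
        for token in text.replace("_", "-").split("-"):
            token = token.strip()
            if not token:
                continue
            m = re.fullmatch(r"[xX]\((\d+)(?:,(\d+))?\)", token)
            if m:
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                if lo > hi:
                    raise ValueError(f"bad flexible wildcard: {token}")
                elements.append(PatternElement("flex", min_len=lo, max_len=hi))
            elif token in ("x", "X"):
                elements.append(PatternElement("wildcard"))
            elif re.fullmatch(r"\[[A-WYZ]+\]", token):
                elements.append(PatternElement("set", token[1:-1]))
            elif re.fullmatch(r"[A-WYZ]", token):
                elements.append(PatternElement("fixed", token))
            else:
                raise ValueError(f"cannot parse pattern element: {token!r}")
        return cls(tuple(elements))


def induce_pattern(alignment: list[str], region: tuple[int, int],
                   conservation_min: float = 0.9) -> PatternExpression:
    """Deterministic per-column pattern induction over an alignment region.

    A column becomes a fixed residue when one residue reaches
    ``conservation_min`` frequency, a bracketed set when the top 2-3
    residues jointly reach it, and a wildcard otherwise. Runs of >=2
    wildcard columns with variable gap content collapse to x(m,n) with
    m, n the min/max ungapped run lengths observed.
    """
    lo, hi = region
    if not alignment:
        raise ValueError("empty alignment")
    if not (0 <= lo < hi <= len(alignment[0])):
        raise ValueError(f"region {region} outside alignment")
    rows = len(alignment)

    raw: list[PatternElement | None] = []   # None marks a wildcard column
    for j in range(lo, hi):
        col = [row[j] for row in alignment]
        counts = pd.Series([c for c in col]).value_counts()
        counts = counts[counts.index != GAP]
        if len(counts) and counts.iloc[0] / rows >= conservation_min:
            raw.append(PatternElement("fixed", str(counts.index[0])))
            continue
        for k in (2, 3):
            if len(counts) >= k \
                    and counts.iloc[:k].sum() / rows >= conservation_min:
                residues = "".join(sorted(counts.index[:k]))
                raw.append(PatternElement("set", residues))
                break
        else:
            raw.append(None)

    elements: list[PatternElement] = []
    j = 0
    while j < len(raw):
        if raw[j] is not None:
            elements.append(raw[j])
            j += 1
            continue
        k = j
        while k < len(raw) and raw[k] is None:
            k += 1
        run_cols = range(lo + j, lo + k)
        ungapped = [sum(1 for c in run_cols if row[c] != GAP)
                    for row in alignment]
        m, n = min(ungapped), max(ungapped)
        if k - j >= 2 and m != n:
            elements.append(PatternElement("flex", min_len=m, max_len=n))
        else:
            elements.extend([PatternElement("wildcard")] * (k - j))
        j = k
    return PatternExpression(tuple(elements))


def match_pattern(pattern: PatternExpression, protein: str
                  ) -> tuple[bool, list[int]]:
    """All (possibly overlapping) match start positions of a pattern."""
    rx = re.compile(f"(?=({pattern.to_regex()}))")
    positions = [m.start() for m in rx.finditer(protein)]
    return bool(positions), positions
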