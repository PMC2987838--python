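"""Binding-site sequence conservation from multiple sequence alignments.

Consumes precomputed alignments (FASTA or Clustal), maps reference residue
numbers to alignment columns, and reports per-column identity and
substitution percentages against a designated reference sequence — the
statistics behind a per-site conservation table (identity I%, dominant
substitution S% by residue or by physicochemical class, gap percentage).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

from .structure_io import load_default_tables

__all__ = [
    "Alignment",
    "ConservationRow",
    "read_alignment",
    "map_reference_positions",
    "column_conservation",
    "default_substitution_classes",
]

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}

GAP = "-"


def default_substitution_classes() -> dict[str, set[str]]:
    """Packaged substitution classes as one-letter residue sets."""
    raw = load_default_tables()["substitution_classes"]
    return {
        name: {_AA3_TO_1[r] for r in members if r in _AA3_TO_1}
        for name, members in raw.items()
    }


@dataclass(frozen=True)
class Alignment:
    records: tuple[tuple[str, str], ...]  # (id, aligned sequence)
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.reference_id not in {rid for rid, _ in self.records}:
            raise KeyError(f"reference {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def reference_seq(self) -> str:
        return dict(self.records)[self.reference_id]

    def non_reference(self) -> list[tuple[str, str]]:
        return [(rid, seq) for rid, seq in self.records if rid != self.reference_id]


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    reference_id: str | None = None,
) -> Alignment:
    """Read a FASTA or Clustal alignment; gap characters normalized to '-'.

    The reference defaults to the first record.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    aln = AlignIO.read(str(path), format)
    records = tuple(
        (rec.id, str(rec.seq).upper().replace(".", GAP).replace("~", GAP))
        for rec in aln
    )
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in {path}")
    ref = reference_id if reference_id is not None else records[0][0]
    return Alignment(records=records, reference_id=ref)


def map_reference_positions(a: Alignment, positions: list[int]) -> list[int]:
    """0-based alignment columns of 1-based reference residue positions.

    Reference gaps are skipped, so an ungapped reference maps position p to
    column p - 1.
    """
    ref = a.reference_seq
    cols: list[int] = []
    ungapped_cols = [c for c, ch in enumerate(ref) if ch != GAP]
    for p in positions:
        if p < 1 or p > len(ungapped_cols):
            raise IndexError(
                f"reference position {p} beyond ungapped length {len(ungapped_cols)}"
            )
        cols.append(ungapped_cols[p - 1])
    return cols


@dataclass(frozen=True)
class ConservationRow:
    """Conservation of one alignment column against the reference residue.

    ``identity_pct`` counts non-reference sequences matching the reference
    residue (the reference is excluded from the denominator).
    ``top_substitution`` is the dominant non-identical category — a single
    residue ("Ser"), a substitution class ("polar") when the class explains
    more sequences than any single residue, or "gap".  ``fractions`` holds
    the raw per-category percentages (identity + substitutions + gap sum to
    100 over the denominator).
    """

    column: int  # 0-based alignment column
    reference_position: int | None  # 1-based reference residue number
    reference_residue: str
    identity_pct: float
    top_substitution: tuple[str, float] | None
    fractions: dict[str, float]
    n_sequences: int
    count_gaps: bool


def column_conservation(
    a: Alignment,
    column: int,
    classes: dict[str, set[str]] | None = None,
    count_gaps: bool = True,
    reference_position: int | None = None,
) -> ConservationRow:
    """Identity and substitution percentages for one alignment column.

    With ``count_gaps`` (default) gapped sequences stay in the denominator
    and gaps form their own category; otherwise they are dropped before
    percentages are computed. When ``classes`` is given, a substitution
    class (e.g. polar, polar/charged) is reported as the dominant
    substitution if it covers more sequences than any single residue.
    """
    if not 0 <= column < a.length:
        raise IndexError(f"column {column} out of range 0..{a.length - 1}")
    ref_res = a.reference_seq[column]
    observed = [seq[column] for _, seq in a.non_reference()]
    if not count_gaps:
        observed = [c for c in observed if c != GAP]
    n = len(observed)
    if n == 0:
        raise ValueError("no sequences to compare at this column")
    matches = sum(1 for c in observed if c == ref_res)
    identity = 100.0 * matches / n
    subs = Counter(c for c in observed if c != ref_res)
    fractions = {"identity": identity}
    for c, k in sorted(subs.items()):
        label = "gap" if c == GAP else _AA1_TO_3.get(c, c).capitalize()
        fractions[label] = fractions.get(label, 0.0) + 100.0 * k / n

    top: tuple[str, float] | None = None
    if subs:
        best_char, best_count = max(subs.items(), key=lambda kv: (kv[1], kv[0]))
        if best_char == GAP:
            top = ("gap", 100.0 * best_count / n)
        else:
            top = (_AA1_TO_3.get(best_char, best_char).capitalize(),
                   100.0 * best_count / n)
        if classes:
            non_gap_subs = {c: k for c, k in subs.items() if c != GAP}
            for name, members in classes.items():
                covered = sum(k for c, k in non_gap_subs.items() if c in members)
                if covered > best_count and covered > (subs.get(GAP, 0)):
                    best_count = covered
                    top = (name, 100.0 * covered / n)
    return ConservationRow(
        column=column,
        reference_position=reference_position,
        reference_residue=ref_res,
        identity_pct=identity,
        top_substitution=top,
        fractions=fractions,
        n_sequences=n,
        count_gaps=count_gaps,
    )
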