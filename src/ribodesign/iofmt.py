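"""Domain types and text-format I/O.

Coordinate convention: every public interface speaks 1-based, closed
intervals, matching the position numbering used throughout hammerhead
literature (e.g. the conserved site 6-8, 22-25, 27-29, 44-49).

Formats handled: FASTA, Stockholm (with ``#=GC SS_cons``), plain
dot-bracket text, and TSV with a header row.  FASTA and Stockholm parsing
delegate to Biopython; TSV to pandas.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGU"

#: IUPAC degenerate nucleotide codes -> the subset of {A,C,G,U} they admit.
IUPAC_DOMAINS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: Inverse map from a nucleotide subset to its canonical IUPAC code.
DOMAIN_CODES: Mapping[frozenset[str], str] = {v: k for k, v in IUPAC_DOMAINS.items()}

#: Minimum number of unpaired nucleotides in a hairpin loop (Turner convention).
MIN_HAIRPIN_LOOP = 3


class ParseError(ValueError):
    """Raised when an input file or string violates its format."""


def normalize_residues(text: str, strict: bool = False) -> str:
    """Uppercase and map T->U.  In strict mode reject anything but A/C/G/U."""
    if strict:
        if not re.fullmatch(r"[ACGU]*", text):
            raise ParseError(f"non-ACGU residue in strict mode: {text!r}")
        return text
    out = text.upper().replace("T", "U")
    bad = set(out) - set(NUCLEOTIDES)
    if bad:
        raise ParseError(f"invalid residue(s) {sorted(bad)} in sequence")
    return out


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with identifier, residues over {A,C,G,U}."""

    id: str
    residues: str
    strict: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues, self.strict))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """1-based position access."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


def gc_percent(seq: RnaSequence | str) -> float:
    """GC content as a percentage in [0, 100]."""
    s = seq.residues if isinstance(seq, RnaSequence) else normalize_residues(seq)
    if not s:
        raise ValueError("empty sequence has no GC content")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def not_code(nt: str) -> str:
    """The 3-letter IUPAC code excluding ``nt``: A->B, C->D, G->H, U->V."""
    nt = normalize_residues(nt)
    if len(nt) != 1:
        raise ValueError("not_code expects a single nucleotide")
    return DOMAIN_CODES[frozenset(NUCLEOTIDES) - {nt}]


@dataclass(frozen=True)
class DotBracket:
    """A pseudoknot-free secondary structure in dot-bracket notation.

    ``pairs`` holds 1-based (i, j) with i < j, derived by a stack parse.
    """

    text: str
    pairs: frozenset[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(_stack_parse(self.text)))

    def __len__(self) -> int:
        return len(self.text)

    def partner(self) -> dict[int, int]:
        """Map each paired position to its partner (both directions)."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def partner_or_self(self, i: int) -> int:
        """Partner of i, or i itself when unpaired."""
        return self.partner().get(i, i)


def _stack_parse(text: str) -> set[tuple[int, int]]:
    if not text:
        raise ParseError("empty structure string")
    bad = set(text) - set(".()")
    if bad:
        raise ParseError(f"invalid structure character(s) {sorted(bad)}")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            if pos - i <= MIN_HAIRPIN_LOOP:
                raise ParseError(
                    f"pair ({i},{pos}) encloses fewer than {MIN_HAIRPIN_LOOP} nucleotides"
                )
            pairs.add((i, pos))
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def parse_dotbracket(text: str) -> DotBracket:
    """Parse dot-bracket text (whitespace stripped) into a DotBracket."""
    return DotBracket("".join(text.split()))


def write_dotbracket(db: DotBracket) -> str:
    return db.text


@dataclass(frozen=True)
class IupacPattern:
    """Per-position degenerate-nucleotide design constraints.

    Whitespace in the input is ignored (patterns are often printed in
    blocks of 10).
    """

    codes: str

    def __post_init__(self) -> None:
        clean = "".join(self.codes.split()).upper().replace("T", "U")
        bad = set(clean) - set(IUPAC_DOMAINS)
        if bad:
            raise ParseError(f"invalid IUPAC code(s) {sorted(bad)}")
        object.__setattr__(self, "codes", clean)

    def __len__(self) -> int:
        return len(self.codes)

    def domain(self, pos: int) -> frozenset[str]:
        """Admissible nucleotides at 1-based position ``pos``."""
        return IUPAC_DOMAINS[self.codes[pos - 1]]

    def domains(self) -> list[frozenset[str]]:
        return [IUPAC_DOMAINS[c] for c in self.codes]

    def matches(self, seq: RnaSequence | str) -> bool:
        s = seq.residues if isinstance(seq, RnaSequence) else seq
        return len(s) == len(self.codes) and all(
            nt in IUPAC_DOMAINS[c] for nt, c in zip(s, self.codes)
        )


@dataclass(frozen=True)
class AlignmentBlock:
    """A multiple alignment: (id, aligned string) records plus an optional
    consensus-structure line (Stockholm ``#=GC SS_cons``).

    Gap characters are '-' and '.'; both are treated as gaps.
    """

    records: tuple[tuple[str, str], ...]
    ss_cons: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ParseError(f"aligned strings of unequal length: {sorted(lengths)}")
        if self.ss_cons is not None and self.records and len(self.ss_cons) != next(iter(lengths)):
            raise ParseError("SS_cons length differs from alignment length")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def row(self, rec_id: str) -> str:
        for rid, s in self.records:
            if rid == rec_id:
                return s
        raise KeyError(f"record {rec_id!r} not in alignment")


GAP_CHARS = frozenset("-.")


def is_gap(ch: str) -> bool:
    return ch in GAP_CHARS


# ---------------------------------------------------------------------------
# File readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[RnaSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return [RnaSequence(r.id, str(r.seq)) for r in records]


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs],
        str(path),
        "fasta",
    )


def read_stockholm(path: str | Path) -> AlignmentBlock:
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise ParseError(f"malformed Stockholm file {path}: {exc}") from exc
    ss = aln.column_annotations.get("secondary_structure")
    return AlignmentBlock(
        records=tuple((r.id, str(r.seq)) for r in aln),
        ss_cons=ss,
    )


def write_stockholm(block: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max((len(rid) for rid, _ in block.records), default=0)
        width = max(width, len("#=GC SS_cons"))
        for rid, s in block.records:
            fh.write(f"{rid:<{width}} {s}\n")
        if block.ss_cons is not None:
            fh.write(f"{'#=GC SS_cons':<{width}} {block.ss_cons}\n")
        fh.write("//\n")


def read_dotbracket_file(path: str | Path) -> DotBracket:
    """First non-empty, non-comment line of a plain text file as a structure."""
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if line and not line.startswith(("#", ">")):
            try:
                return parse_dotbracket(line)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    raise ParseError(f"no structure line in {path}")


def write_tsv(records: Sequence[Mapping[str, object]] | pd.DataFrame, path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
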