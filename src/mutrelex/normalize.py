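"""Mutation-mention normalization, SEQ_Filter, and entity-token merging.

Protein substitution mentions come in several spellings — ``V600E``,
``Val600Glu``, ``p.V600E``, ``p.Val600Glu`` — and are mapped to the canonical
one-letter HGVS-style form ``XnY``.  DNA-level mentions (``c.1799T>A``) have
no amino-acid reading and are passed through unparsed so they can still take
part in co-occurrence features.

SEQ_Filter is the wild-type residue check used to discard erroneous
mutation-gene pairings: ``XnY`` is compatible with a gene only if the gene's
protein sequence carries residue ``X`` at (1-based) position ``n``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


@dataclass(frozen=True)
class ProteinMutation:
    """A parsed protein substitution: wild type, 1-based position, variant."""

    wild_type: str
    position: int
    variant: str

    def __post_init__(self) -> None:
        if self.wild_type not in AMINO_ACIDS or self.variant not in AMINO_ACIDS:
            raise ValueError(f"non-amino-acid code in {self.canonical}")
        if self.position < 1:
            raise ValueError("residue positions are 1-based and positive")

    @property
    def canonical(self) -> str:
        return f"{self.wild_type}{self.position}{self.variant}"


@dataclass(frozen=True)
class ProteinRecord:
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_symbol}")


_AA1 = f"[{AMINO_ACIDS}]"
_AA3 = "|".join(THREE_TO_ONE)
_SUBSTITUTION_RE = re.compile(
    rf"^(?:p\.)?\(?(?P<wt>{_AA3}|{_AA1})\s?(?P<pos>\d+)\s?(?P<var>{_AA3}|{_AA1})\)?$"
)


def normalize_mutation(surface: str) -> tuple[str, bool]:
    """Map a protein substitution mention to canonical one-letter ``XnY`` form.

    Returns ``(canonical, True)`` for recognized one-letter, three-letter and
    ``p.``-prefixed forms; for DNA-level or unrecognized mentions the input is
    returned unchanged with ``parsed=False``.  Idempotent on canonical forms.
    """
    s = surface.strip()
    match = _SUBSTITUTION_RE.match(s)
    if match is None:
        return surface, False
    wt, var = match.group("wt"), match.group("var")
    wt = THREE_TO_ONE.get(wt, wt)
    var = THREE_TO_ONE.get(var, var)
    return f"{wt}{match.group('pos')}{var}", True


def parse_mutation(surface: str) -> ProteinMutation | None:
    """Parse to a :class:`ProteinMutation`, or None when not a substitution."""
    canonical, ok = normalize_mutation(surface)
    if not ok:
        return None
    m = re.match(rf"^({_AA1})(\d+)({_AA1})$", canonical)
    assert m is not None
    return ProteinMutation(m.group(1), int(m.group(2)), m.group(3))


def seq_filter(protein: ProteinRecord, mutation: ProteinMutation) -> bool:
    """Wild-type residue check: sequence[position] (1-based) == wild_type."""
    if mutation.position > len(protein.sequence):
        return False
    return protein.sequence[mutation.position - 1] == mutation.wild_type


# ---------------------------------------------------------------------------
# Protein record I/O


def read_protein_fasta(path_or_handle) -> dict[str, ProteinRecord]:
    """Read protein records from FASTA; the first header token is the gene symbol."""
    records = {}
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        symbol = rec.id.split()[0]
        records[symbol] = ProteinRecord(symbol, str(rec.seq))
    return records


def read_protein_table(lines: Iterable[str]) -> dict[str, ProteinRecord]:
    """Read a two-column (gene_symbol TAB sequence) protein table."""
    records = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, sequence = line.split("\t")[:2]
        records[symbol] = ProteinRecord(symbol, sequence)
    return records


def write_protein_fasta(proteins: Sequence[ProteinRecord] | dict, stream) -> None:
    values = proteins.values() if isinstance(proteins, dict) else proteins
    for rec in values:
        stream.write(f">{rec.gene_symbol}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Multi-token entity merging


def merge_entity_tokens(text: str, lexicon: Iterable[str]) -> list[str]:
    """Tokenize, collapsing multi-word lexicon phrases into single tokens.

    Longest-match-first greedy replacement: on overlapping lexicon entries the
    longer phrase wins.  Matching is case-insensitive on whitespace-delimited
    token boundaries; emitted merged tokens preserve the lexicon casing with
    internal spaces replaced by underscores (``non-small cell lung cancer`` ->
    ``non-small_cell_lung_cancer``).
    """
    phrases = sorted(
        ((tuple(p.split()), p) for p in lexicon if len(p.split()) >= 1),
        key=lambda item: -len(item[0]),
    )
    tokens = text.split()
    lowered = [t.lower() for t in tokens]
    out: list[str] = []
    i = 0
    while i < len(tokens):
        for words, original in phrases:
            n = len(words)
            if n > 1 and lowered[i : i + n] == [w.lower() for w in words]:
                out.append("_".join(original.split()))
                i += n
                break
        else:
            out.append(tokens[i])
            i += 1
    return out
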