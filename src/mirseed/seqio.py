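"""Sequence records and alphabet-safe primitives.

Mature miRNAs are kept in the RNA alphabet (5'→3', {A,C,G,U}); 3'-UTRs in
the DNA alphabet ({A,C,G,T,N}, position 0 = first base after the stop
codon). Every cross-alphabet comparison in the package goes through the
explicit normalization here; coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Union

from Bio import SeqIO

from .errors import ParseError, ValidationError

Moltype = Literal["rna", "dna"]

_RNA_ALPHABET = frozenset("ACGU")
_DNA_ALPHABET = frozenset("ACGTN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: WC partner of an RNA base on the DNA (target) strand.
RNA_TO_DNA_PAIR = {"A": "T", "C": "G", "G": "C", "U": "A"}

# Realistic mature-miRNA length band; the hard floor of 9 nt is what the
# seed arithmetic (positions 1-8) requires.
MIN_MIRNA_LEN = 9
MAX_MIRNA_LEN = 30


def normalize(seq: str, moltype: Moltype) -> str:
    """Upper-case *seq* and map it onto the requested alphabet (U↔T).

    Raises :class:`ValidationError` naming the first disallowed symbol.
    """
    s = seq.upper()
    if moltype == "rna":
        s = s.replace("T", "U")
        allowed = _RNA_ALPHABET
    elif moltype == "dna":
        s = s.replace("U", "T")
        allowed = _DNA_ALPHABET
    else:
        raise ValidationError(f"unknown moltype {moltype!r}")
    bad = set(s) - allowed
    if bad:
        raise ValidationError(
            f"disallowed character {sorted(bad)[0]!r} for moltype {moltype!r}"
        )
    return s


def revcomp(seq: str, out_alphabet: Moltype = "dna") -> str:
    """Reverse complement of *seq*, written 5'→3' in *out_alphabet*.

    The input alphabet is inferred (RNA iff it contains U and no T);
    revcomp is an involution when in and out alphabets match.
    """
    in_rna = "U" in seq.upper() and "T" not in seq.upper()
    s = normalize(seq, "rna" if in_rna else "dna")
    table = _RNA_COMPLEMENT if in_rna else _DNA_COMPLEMENT
    rc = s.translate(table)[::-1]
    return normalize(rc, out_alphabet)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'→3', RNA alphabet."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("miRNA id must be non-empty")
        seq = normalize(self.sequence, "rna")
        object.__setattr__(self, "sequence", seq)
        if not MIN_MIRNA_LEN <= len(seq) <= MAX_MIRNA_LEN:
            raise ValidationError(
                f"miRNA {self.id!r}: length {len(seq)} outside "
                f"[{MIN_MIRNA_LEN}, {MAX_MIRNA_LEN}]"
            )
        if not self.species:
            object.__setattr__(self, "species", infer_species(self.id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UTRRecord:
    """A 3'-UTR sequence; position 0 is the first base after the stop codon."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("UTR id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"UTR {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", normalize(self.sequence, "dna"))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


def infer_species(mirna_id: str) -> str:
    """Species tag from a miRBase-style id prefix ('hsa-miR-182-5p' → 'hsa')."""
    head = mirna_id.split("-", 1)[0]
    return head.lower() if head and head.lower() != mirna_id.lower() else ""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, moltype: Moltype) -> list[Union[MatureMiRNA, UTRRecord]]:
    """Read a (possibly gzipped) FASTA file into sequence records.

    moltype 'rna' yields :class:`MatureMiRNA`, 'dna' yields
    :class:`UTRRecord`; T/U and case are normalized, record order preserved.
    """
    records: list[Union[MatureMiRNA, UTRRecord]] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            if not rec.id:
                raise ParseError(f"{path}: record {i}: malformed/empty header")
            if not str(rec.seq):
                raise ParseError(f"{path}: record {i} ({rec.id}): empty sequence")
            if rec.id in seen:
                raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if moltype == "rna":
                records.append(MatureMiRNA(id=rec.id, sequence=str(rec.seq)))
            else:
                records.append(UTRRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def read_mirnas(path) -> list[MatureMiRNA]:
    return read_fasta(path, "rna")  # type: ignore[return-value]


def read_utrs(path) -> list[UTRRecord]:
    return read_fasta(path, "dna")  # type: ignore[return-value]


def write_fasta(records: Iterable[Union[MatureMiRNA, UTRRecord]], path, width: int = 70) -> None:
    """Write records as wrapped multi-FASTA."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            seq = rec.sequence
            for j in range(0, len(seq), width):
                out.write(seq[j : j + width] + "\n")
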