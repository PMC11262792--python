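"""Canonical seed-match detection in 3'-UTRs.

Five pairing modes are scanned, defined off miRNA positions 1–8 (1-based
from the 5' end):

====== =================================== ======================
mode    target motif (DNA, 5'→3')           span relative to anchor
====== =================================== ======================
8mer        revcomp(nt 2–8) + 'A'           [anchor-6, anchor+2)
7mer-m8     revcomp(nt 2–8)                 [anchor-6, anchor+1)
7mer-A1     revcomp(nt 2–7) + 'A'           [anchor-5, anchor+2)
6mer        revcomp(nt 2–7)                 [anchor-5, anchor+1)
offset-6mer revcomp(nt 3–8)                 [anchor-6, anchor)
====== =================================== ======================

The *anchor* is the UTR index of the base facing miRNA position 2 in the
seed register. All modes matching in the same register therefore share one
anchor, and a locus is reported once, labelled with its highest-priority
mode, with the full mode set retained.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .seqio import MatureMiRNA, UTRRecord, revcomp


class SiteType(enum.Enum):
    """Canonical site classes, ordered by expected repression efficacy."""

    MER8 = ("8mer", 5)
    MER7_M8 = ("7mer-m8", 4)
    MER7_A1 = ("7mer-A1", 3)
    MER6 = ("6mer", 2)
    OFFSET6 = ("offset-6mer", 1)

    def __init__(self, label: str, priority: int):
        self.label = label
        self.priority = priority

    @classmethod
    def from_label(cls, label: str) -> "SiteType":
        for m in cls:
            if m.label == label:
                return m
        raise ValidationError(f"unknown site type {label!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: span of each mode in UTR coordinates, as offsets from the anchor.
_SPAN_FROM_ANCHOR = {
    SiteType.MER8: (-6, 2),
    SiteType.MER7_M8: (-6, 1),
    SiteType.MER7_A1: (-5, 2),
    SiteType.MER6: (-5, 1),
    SiteType.OFFSET6: (-6, 0),
}


def seed_motifs(mirna: MatureMiRNA) -> dict[SiteType, str]:
    """Target-strand motif (DNA, 5'→3') for each pairing mode.

    miRNA positions are numbered 1..n from the 5' end; requires length ≥ 9.
    """
    seq = mirna.sequence
    if len(seq) < 9:
        raise ValidationError(f"miRNA {mirna.id!r} shorter than 9 nt")
    core27 = revcomp(seq[1:7], "dna")   # nt 2-7
    core28 = revcomp(seq[1:8], "dna")   # nt 2-8
    core38 = revcomp(seq[2:8], "dna")   # nt 3-8
    return {
        SiteType.MER8: core28 + "A",
        SiteType.MER7_M8: core28,
        SiteType.MER7_A1: core27 + "A",
        SiteType.MER6: core27,
        SiteType.OFFSET6: core38,
    }


def _anchor_of(mode: SiteType, start: int) -> int:
    return start - _SPAN_FROM_ANCHOR[mode][0]


@dataclass(frozen=True)
class SeedSite:
    """One seed-match locus of a miRNA in a UTR.

    ``start``/``end`` are the 0-based half-open coordinates of the motif of
    the primary (highest-priority) mode; ``all_modes`` lists every mode
    whose motif matches in the same seed register.
    """

    mirna_id: str
    utr_id: str
    site_type: SiteType
    start: int
    end: int
    motif: str
    all_modes: frozenset[SiteType]

    @property
    def anchor(self) -> int:
        """UTR index of the base facing miRNA position 2."""
        return _anchor_of(self.site_type, self.start)

    def mode_spans(self) -> dict[SiteType, tuple[int, int]]:
        """Per-mode (start, end) of every matching mode at this locus."""
        a = self.anchor
        return {
            m: (a + _SPAN_FROM_ANCHOR[m][0], a + _SPAN_FROM_ANCHOR[m][1])
            for m in self.all_modes
        }

    def expand(self) -> set[tuple[int, str]]:
        """Raw (start, mode label) matches represented by this locus."""
        return {(s, m.label) for m, (s, _) in self.mode_spans().items()}


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_utr(mirna: MatureMiRNA, utr: UTRRecord) -> list[SeedSite]:
    """All seed-match loci of *mirna* in *utr*, sorted by start.

    Every UTR locus whose substring equals a mode motif is reported exactly
    once (grouped by seed register), labelled with the highest-priority
    matching mode. Loci overlapping 'N' are never reported because the
    match is by exact string equality over {A,C,G,T}.
    """
    motifs = seed_motifs(mirna)
    by_anchor: dict[int, set[SiteType]] = {}
    seq = utr.sequence
    for mode, motif in motifs.items():
        for start in _find_all(seq, motif):
            by_anchor.setdefault(_anchor_of(mode, start), set()).add(mode)
    sites = []
    for anchor, modes in by_anchor.items():
        primary = max(modes, key=lambda m: m.priority)
        off = _SPAN_FROM_ANCHOR[primary]
        start, end = anchor + off[0], anchor + off[1]
        sites.append(
            SeedSite(
                mirna_id=mirna.id,
                utr_id=utr.id,
                site_type=primary,
                start=start,
                end=end,
                motif=seq[start:end],
                all_modes=frozenset(modes),
            )
        )
    sites.sort(key=lambda s: (s.start, s.end))
    return sites


def scan_many(
    mirnas: Sequence[MatureMiRNA], utrs: Sequence[UTRRecord]
) -> list[SeedSite]:
    """scan_utr over the Cartesian product, ordered by (utr, mirna, start)."""
    if not mirnas or not utrs:
        raise ValidationError("scan_many requires non-empty miRNA and UTR lists")
    for name, recs in (("miRNA", mirnas), ("UTR", utrs)):
        ids = [r.id for r in recs]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})[0]
            raise ValidationError(f"duplicate {name} id {dup!r}")
    out: list[SeedSite] = []
    for utr in utrs:
        for mirna in mirnas:
            out.extend(scan_utr(mirna, utr))
    return out


def sites_to_frame(sites: Iterable[SeedSite]) -> pd.DataFrame:
    """Tabulate sites with columns matching the TSV export."""
    rows = [
        {
            "utr_id": s.utr_id,
            "mirna_id": s.mirna_id,
            "site_type": s.site_type.label,
            "start0": s.start,
            "end0": s.end,
            "motif": s.motif,
            "all_modes": ",".join(
                m.label for m in sorted(s.all_modes, key=lambda x: -x.priority)
            ),
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=["utr_id", "mirna_id", "site_type", "start0", "end0", "motif", "all_modes"],
    )


def write_sites_tsv(sites: Iterable[SeedSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def write_sites_bed(sites: Iterable[SeedSite], path) -> None:
    """BED6 export: chrom = utr_id, name = mirna_id|site_type, strand '+'."""
    with open(path, "w") as out:
        for s in sites:
            out.write(
                f"{s.utr_id}\t{s.start}\t{s.end}\t{s.mirna_id}|{s.site_type.label}\t0\t+\n"
            )
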