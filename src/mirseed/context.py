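"""Binding-context annotation for detected seed sites.

For each site the features reported are: local AU content in the flanks
(default 30 nt per side, 60 nt total, site excluded), the longest run of
contiguous 3'-supplementary Watson-Crick pairs (miRNA positions 12-17,
target offset tolerance ±2 nt), the position of the site within the UTR
(distance to the stop codon and to the 3' end, relative position,
near-stop flag), and cooperative partner sites within a gap window. No
composite score is computed; the features are reported independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ValidationError
from .seedsites import SeedSite
from .seqio import RNA_TO_DNA_PAIR, MatureMiRNA, UTRRecord

DEFAULT_FLANK = 30
DEFAULT_TP_WINDOW = (12, 17)
DEFAULT_TP_OFFSET_TOL = 2
DEFAULT_MIN_GAP = 8
DEFAULT_MAX_GAP = 40
NEAR_STOP_NT = 15


@dataclass(frozen=True)
class SiteContext:
    """Binding-condition features of one seed site (no combined score)."""

    mirna_id: str
    utr_id: str
    start: int
    end: int
    local_au: Optional[float]
    tp_pairing: int
    dist_stop: int
    dist_end: int
    rel_pos: float
    near_stop: bool
    coop_partners: tuple = field(default_factory=tuple)  # ((mirna_id, start, gap), ...)


def _check_site(utr: UTRRecord, site: SeedSite) -> None:
    if site.utr_id != utr.id:
        raise ValidationError(f"site {site.utr_id!r} does not belong to UTR {utr.id!r}")
    if not (0 <= site.start < site.end <= len(utr)):
        raise ValidationError("site does not lie within the UTR")


def au_content(utr: UTRRecord, site: SeedSite, flank: int = DEFAULT_FLANK) -> Optional[float]:
    """Fraction of A/T among the up-to-*flank* nt on each side of the site.

    Site residues are excluded; windows truncate at UTR boundaries; N
    residues count in neither numerator nor denominator. Returns None when
    no flank residue is available at all.
    """
    _check_site(utr, site)
    seq = utr.sequence
    left = seq[max(0, site.start - flank) : site.start]
    right = seq[site.end : site.end + flank]
    window = left + right
    usable = [c for c in window if c != "N"]
    if not usable:
        return None
    return sum(c in "AT" for c in usable) / len(usable)


def three_prime_pairing(
    mirna: MatureMiRNA,
    utr: UTRRecord,
    site: SeedSite,
    window: tuple[int, int] = DEFAULT_TP_WINDOW,
    offset_tol: int = DEFAULT_TP_OFFSET_TOL,
) -> int:
    """Longest run of contiguous WC pairs between miRNA 3' positions and the UTR.

    In the seed-anchored antiparallel register, miRNA position p (1-based)
    faces UTR index ``anchor + 2 - p``; an offset of ±*offset_tol* nt on the
    target side is allowed. Positions outside the UTR or facing 'N' do not
    pair, so a truncated window simply shortens the attainable run.
    """
    _check_site(utr, site)
    lo, hi = window
    if not 1 <= lo <= hi <= len(mirna):
        raise ValidationError(f"3'-pairing window {window} outside miRNA length {len(mirna)}")
    seq = utr.sequence
    anchor = site.anchor
    best = 0
    for d in range(-offset_tol, offset_tol + 1):
        run = 0
        for p in range(lo, hi + 1):
            t = anchor + 2 - p + d
            paired = (
                0 <= t < len(seq)
                and seq[t] == RNA_TO_DNA_PAIR[mirna.sequence[p - 1]]
            )
            run = run + 1 if paired else 0
            best = max(best, run)
    return best


def positional_features(utr: UTRRecord, site: SeedSite) -> tuple[int, int, float, bool]:
    """(dist_stop, dist_end, rel_pos, near_stop_flag) for a site in its UTR."""
    _check_site(utr, site)
    dist_stop = site.start
    dist_end = len(utr) - site.end
    rel_pos = min(dist_stop, dist_end) / len(utr)
    return dist_stop, dist_end, rel_pos, dist_stop < NEAR_STOP_NT


def cooperative_sites(
    sites: Sequence[SeedSite],
    min_gap: int = DEFAULT_MIN_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[tuple[SeedSite, SeedSite, int]]:
    """Unordered site pairs on one UTR whose inter-site gap is in [min_gap, max_gap].

    The gap is measured from the end of the upstream site to the start of
    the downstream one; overlapping or abutting pairs (gap < min_gap) are
    excluded. Same- and different-miRNA pairs both count.
    """
    utr_ids = {s.utr_id for s in sites}
    if len(utr_ids) > 1:
        raise ValidationError(f"cooperative_sites mixes UTRs: {sorted(utr_ids)}")
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.mirna_id))
    pairs = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            lo, hi = (a, b) if a.end <= b.start else (b, a)
            gap = hi.start - lo.end
            if min_gap <= gap <= max_gap:
                pairs.append((a, b, gap))
    return pairs


def annotate(
    mirna: MatureMiRNA,
    utr: UTRRecord,
    site: SeedSite,
    all_sites: Sequence[SeedSite] = (),
    flank: int = DEFAULT_FLANK,
    tp_window: tuple[int, int] = DEFAULT_TP_WINDOW,
    tp_offset_tol: int = DEFAULT_TP_OFFSET_TOL,
    min_gap: int = DEFAULT_MIN_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> SiteContext:
    """Assemble the full SiteContext for one site.

    *all_sites* is the pool (on the same UTR) searched for cooperative
    partners; the site itself is matched by identity, not recomputed.
    """
    if site.mirna_id != mirna.id:
        raise ValidationError("site/miRNA identity mismatch")
    dist_stop, dist_end, rel_pos, near = positional_features(utr, site)
    partners = []
    pool = [s for s in all_sites if s != site]
    for a, b, gap in cooperative_sites([site] + pool, min_gap=min_gap, max_gap=max_gap):
        if a == site:
            partners.append((b.mirna_id, b.start, gap))
        elif b == site:
            partners.append((a.mirna_id, a.start, gap))
    return SiteContext(
        mirna_id=site.mirna_id,
        utr_id=site.utr_id,
        start=site.start,
        end=site.end,
        local_au=au_content(utr, site, flank=flank),
        tp_pairing=three_prime_pairing(mirna, utr, site, window=tp_window, offset_tol=tp_offset_tol),
        dist_stop=dist_stop,
        dist_end=dist_end,
        rel_pos=rel_pos,
        near_stop=near,
        coop_partners=tuple(sorted(partners)),
    )
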