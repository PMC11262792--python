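"""Cross-species miRNA conservation by 7mer seed identity.

Two mature miRNAs are assigned to the same seed family when their
nucleotides 2-8 (the 7mer seed) are identical; a miRNA expressed in one
species is called conserved in another when the other species' set holds a
member of the same family. The counting unit for overlap tallies is the
mature miRNA of the query species (a family may carry several members);
family-level tallies are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .seqio import MatureMiRNA


def seed7(mirna: MatureMiRNA) -> str:
    """Nucleotides 2-8 (1-based) of the mature sequence, RNA alphabet."""
    if len(mirna) < 8:
        raise ValidationError(f"miRNA {mirna.id!r} shorter than 8 nt")
    return mirna.sequence[1:8]


@dataclass(frozen=True)
class SeedFamily:
    """All miRNAs sharing one 7mer seed, grouped by species tag."""

    seed: str
    members: tuple[tuple[str, str], ...]  # ((species, mirna_id), ...)

    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}

    def ids(self, species: str | None = None) -> list[str]:
        return [i for sp, i in self.members if species is None or sp == species]


def seed_families(mirnas: Sequence[MatureMiRNA]) -> list[SeedFamily]:
    """Partition miRNAs by exact nt 2-8 identity, ordered by seed string."""
    groups: dict[str, list[tuple[str, str]]] = {}
    for m in mirnas:
        groups.setdefault(seed7(m), []).append((m.species, m.id))
    return [
        SeedFamily(seed=s, members=tuple(sorted(groups[s])))
        for s in sorted(groups)
    ]


@dataclass(frozen=True)
class ConservationResult:
    """Three-way seed-family overlap between two species' miRNA sets."""

    shared: tuple[str, ...]       # seeds present in both sets
    a_only: tuple[str, ...]
    b_only: tuple[str, ...]
    n_a_mirnas_shared: int        # per-miRNA tallies of the query (A) species
    n_a_mirnas_only: int
    n_b_mirnas_shared: int
    n_b_mirnas_only: int

    @property
    def n_shared_families(self) -> int:
        return len(self.shared)


def conserved_between(
    set_a: Sequence[MatureMiRNA], set_b: Sequence[MatureMiRNA]
) -> ConservationResult:
    """Seed-family overlap of two mature-miRNA sets (e.g. human vs mouse)."""
    seeds_a = {seed7(m) for m in set_a}
    seeds_b = {seed7(m) for m in set_b}
    shared = seeds_a & seeds_b
    return ConservationResult(
        shared=tuple(sorted(shared)),
        a_only=tuple(sorted(seeds_a - seeds_b)),
        b_only=tuple(sorted(seeds_b - seeds_a)),
        n_a_mirnas_shared=sum(seed7(m) in shared for m in set_a),
        n_a_mirnas_only=sum(seed7(m) not in shared for m in set_a),
        n_b_mirnas_shared=sum(seed7(m) in shared for m in set_b),
        n_b_mirnas_only=sum(seed7(m) not in shared for m in set_b),
    )


def families_to_frame(families: Iterable[SeedFamily]) -> pd.DataFrame:
    rows = [
        {
            "seed7": f.seed,
            "n_members": len(f.members),
            "species": ",".join(sorted(f.species())),
            "members": ",".join(i for _, i in f.members),
        }
        for f in families
    ]
    return pd.DataFrame(rows, columns=["seed7", "n_members", "species", "members"])
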