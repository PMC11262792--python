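"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mirseed.seqio import MatureMiRNA, UTRRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Watson-Crick partner of an RNA base on the DNA strand (test-local copy).
PAIR = {"A": "T", "C": "G", "G": "C", "U": "A"}

MIR182_SEQ = "UUUGGCAAUGGUAGAACUCACACU"
LRP6_UTR_SEQ = "ACGTACGTTGCCAATACGT"          # carries the 7mer-m8 site at [7, 14)
LRP6_UTR_MUT = "ACGTACGTTGACAATACGT"          # central C -> A seed mutation


@pytest.fixture
def mir182() -> MatureMiRNA:
    return MatureMiRNA(id="hsa-miR-182-5p", sequence=MIR182_SEQ)


@pytest.fixture
def lrp6_utr() -> UTRRecord:
    return UTRRecord(id="LRP6", sequence=LRP6_UTR_SEQ)


def oracle_motifs(mirna: MatureMiRNA) -> dict[str, str]:
    """Brute-force antiparallel pairing oracle for the five mode motifs.

    Builds each target motif base-by-base by pairing the listed miRNA
    positions in antiparallel orientation (highest position first),
    independently of the implementation's revcomp-based construction.
    """
    m = mirna.sequence

    def pair_positions(positions):  # positions are 1-based, 5'->3' on the miRNA
        return "".join(PAIR[m[p - 1]] for p in reversed(positions))

    return {
        "8mer": pair_positions(range(2, 9)) + "A",
        "7mer-m8": pair_positions(range(2, 9)),
        "7mer-A1": pair_positions(range(2, 8)) + "A",
        "6mer": pair_positions(range(2, 8)),
        "offset-6mer": pair_positions(range(3, 9)),
    }


def naive_scan(mirna: MatureMiRNA, utr: UTRRecord) -> set[tuple[int, str]]:
    """Sliding-window oracle: every (start, mode) whose motif matches exactly."""
    motifs = oracle_motifs(mirna)
    by_len: dict[int, list[tuple[str, str]]] = {}
    for mode, motif in motifs.items():
        by_len.setdefault(len(motif), []).append((mode, motif))
    seq = utr.sequence
    hits = set()
    for i in range(len(seq)):
        for L, entries in by_len.items():
            window = seq[i : i + L]
            if len(window) < L:
                continue
            for mode, motif in entries:
                if window == motif:
                    hits.add((i, mode))
    return hits


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
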