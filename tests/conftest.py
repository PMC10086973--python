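"""Shared fixtures: random sequence/alignment builders with seeded RNGs."""

from __future__ import annotations

import numpy as np
import pytest

from pestid.seqio import Msa, SequenceRecord, msa_from_strings

BASES = "ACGT"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def random_seq(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    return "".join(rng.choice(list(alphabet), length))


def random_records(rng: np.random.Generator, n: int, min_len=1, max_len=80) -> list[SequenceRecord]:
    return [
        SequenceRecord(
            id=f"r{i}",
            residues=random_seq(rng, int(rng.integers(min_len, max_len + 1))),
            description=f"random record {i}",
        )
        for i in range(n)
    ]


def random_gapped_msa(
    rng: np.random.Generator, nsp: int, ncols: int, gap_prob: float = 0.15
) -> Msa:
    """A random alignment; every row keeps at least one non-gap column."""
    rows = []
    for s in range(nsp):
        while True:
            chars = [
                "-" if rng.random() < gap_prob else str(rng.choice(list(BASES)))
                for _ in range(ncols)
            ]
            if any(c != "-" for c in chars):
                break
        rows.append((f"sp{s + 1}", "".join(chars)))
    return msa_from_strings(rows)


def write_lines(path, text: str) -> str:
    path.write_text(text)
    return str(path)
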