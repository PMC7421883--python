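"""Low-level random protein sequence helpers shared by the packaged
reference bundle and the synthetic-cohort generator.

All functions take an explicit :class:`numpy.random.Generator`; nothing
here touches global random state.
"""
from __future__ import annotations

import numpy as np

from .io import AMINO_ACIDS

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_AA_INDEX = {chr(c): i for i, c in enumerate(_AA)}


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. sequence over the 20 standard residues."""
    return bytes(_AA[rng.integers(0, 20, size=length)]).decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-position independent substitution with probability `rate`.

    A substituted position receives one of the 19 *other* residues uniformly
    (an X position receives any of the 20).  Length is preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must be in [0,1], got {rate}")
    if rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n == 0:
        return seq
    # Draw from 19 alternatives by skipping the original residue's index.
    orig = arr[hit]
    draws = rng.integers(0, 19, size=n)
    orig_idx = np.full(n, 20, dtype=np.int64)
    for aa, idx in _AA_INDEX.items():
        orig_idx[orig == ord(aa)] = idx
    # X (index 20) positions: any of 20; others: skip own index.
    repl = np.where(draws >= orig_idx, draws + 1, draws)
    repl = np.where(orig_idx == 20, rng.integers(0, 20, size=n), repl)
    arr[hit] = _AA[repl]
    return bytes(arr).decode()
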