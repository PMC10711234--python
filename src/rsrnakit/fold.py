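"""Secondary-structure prediction for short fragments (dot-bracket output).

rsRNAs are at most 40 nt, so base-pair maximization (the Nussinov
dynamic program) is an adequate structural sketch for reporting: legal
pairs are the Watson-Crick pairs AU and GC plus the GU wobble, with a
minimum hairpin loop of 3 unpaired bases. The traceback is
deterministic: among co-optimal structures, the pairing that closes
earliest wins (leftmost 5' partner, then its nearest legal 3' partner).

``fold_dot_bracket`` accepts a ``folder`` hook so an external
thermodynamic predictor can be substituted without touching the
reporting code.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable

MIN_LOOP = 3

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_VALID = set("ACGU")


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def fold_dot_bracket(
    sequence: str,
    folder: Callable[[str], str] | None = None,
) -> str:
    """Return the dot-bracket structure of an RNA (or DNA) fragment.

    T is read as U. When ``folder`` is given it fully replaces the
    built-in Nussinov maximization (it must return a balanced
    dot-bracket string of the same length).
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"non-nucleotide characters {sorted(bad)} in sequence {sequence!r}"
        )
    if folder is not None:
        structure = folder(sequence)
        if len(structure) != len(sequence):
            raise ValueError("external folder returned a structure of wrong length")
        return structure
    return _nussinov(seq)


def _nussinov(seq: str) -> str:
    n = len(seq)
    if n == 0:
        return ""
    # dp[i][j] = max pairs in seq[i..j] inclusive
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    inner = dp[i + 1][k - 1] if k - i > 1 else 0
                    right = dp[k + 1][j] if k < j else 0
                    best = max(best, 1 + inner + right)
            dp[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        # prefer pairing the leftmost base with its smallest co-optimal partner
        paired = False
        for k in range(i + MIN_LOOP + 1, j + 1):
            if not _can_pair(seq[i], seq[k]):
                continue
            inner = dp[i + 1][k - 1] if k - i > 1 else 0
            right = dp[k + 1][j] if k < j else 0
            if 1 + inner + right == dp[i][j]:
                structure[i] = "("
                structure[k] = ")"
                stack.append((i + 1, k - 1))
                if k < j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return "".join(structure)


@lru_cache(maxsize=4096)
def max_pairs(seq: str) -> int:
    """Maximum legal pair count of an (uppercase, U-normalized) sequence."""
    structure = _nussinov(seq)
    return structure.count("(")
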