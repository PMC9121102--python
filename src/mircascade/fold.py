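"""RNA secondary structure by maximum base pairing (Nussinov recursion).

The annotation stage only needs the pairing topology of a candidate hairpin
(duplex mismatches, bulges, star arm position), not thermodynamic energies,
so the default folder maximises the number of {GC, AU, GU} pairs subject to
a minimum hairpin loop of 3 unpaired nucleotides. Among the (typically many)
structures attaining the maximum pair count, the folder returns one with the
largest number of stacked pairs — a helix-contiguity tie-break that plays
the role stacking energies play in thermodynamic folders and keeps designed
stems intact instead of scattering equivalent pairs over flanking sequence.
The reported pair count is exactly the Nussinov maximum.

Pre-computed structures (e.g. from an external thermodynamic folder) can be
supplied instead wherever a dot-bracket string is accepted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .seqio import to_rna

__all__ = ["fold", "max_pairs", "pair_table", "validate_structure", "MIN_LOOP"]

MIN_LOOP = 3
_NEG = np.int32(-(10**9))

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# allowed pairs: AU, UA, CG, GC, GU, UG
_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for a, b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _CAN_PAIR[a, b] = True


def encode(seq: str) -> np.ndarray:
    rna = to_rna(seq)
    try:
        return np.array([_CODE[c] for c in rna], dtype=np.int8)
    except KeyError as exc:
        bad = next(c for c in rna if c not in _CODE)
        raise ValueError(f"sequence contains non-ACGU(T) character {bad!r}") from exc


@njit(cache=True)
def _nussinov_tables(x, can_pair, min_loop, big):  # pragma: no cover - jit
    """S[i,j]: best big*pairs + stacks on [i,j]; P[i,j]: ditto, (i,j) paired."""
    n = x.shape[0]
    S = np.zeros((n, n), dtype=np.int32)
    P = np.full((n, n), _NEG, dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can_pair[x[i], x[j]]:
                inner = S[i + 1, j - 1]
                if P[i + 1, j - 1] + 1 > inner:
                    inner = P[i + 1, j - 1] + 1  # stacking bonus
                P[i, j] = big + inner
            best = S[i + 1, j]
            if S[i, j - 1] > best:
                best = S[i, j - 1]
            if P[i, j] > best:
                best = P[i, j]
            for k in range(i + 1, j):
                v = S[i, k] + S[k + 1, j]
                if v > best:
                    best = v
            S[i, j] = best
    return S, P


def _tables(seq: str):
    x = encode(seq)
    n = len(x)
    big = np.int32(n + 1)
    S, P = _nussinov_tables(x, _CAN_PAIR, MIN_LOOP, big)
    return x, S, P, int(big)


def max_pairs(seq: str) -> int:
    """Maximum number of base pairs attainable for ``seq``."""
    if len(seq) <= MIN_LOOP:
        encode(seq)
        return 0
    _x, S, _P, big = _tables(seq)
    return int(S[0, len(seq) - 1]) // big


def _traceback(x: np.ndarray, S: np.ndarray, P: np.ndarray) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(x) - 1, 0)]  # mode 0 = free, 1 = (i,j) paired
    big = len(x) + 1
    while stack:
        i, j, mode = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if mode == 1:
            pairs.append((i, j))
            # prefer continuing the helix (stacked inner pair) on ties
            if P[i + 1, j - 1] != _NEG and P[i, j] == big + P[i + 1, j - 1] + 1:
                stack.append((i + 1, j - 1, 1))
            else:
                stack.append((i + 1, j - 1, 0))
            continue
        v = S[i, j]
        if v == S[i + 1, j]:  # unpaired-first keeps outer flanks open on ties
            stack.append((i + 1, j, 0))
        elif v == S[i, j - 1]:
            stack.append((i, j - 1, 0))
        elif v == P[i, j]:
            stack.append((i, j, 1))
        else:
            for k in range(i + 1, j):
                if S[i, k] + S[k + 1, j] == v:
                    stack.append((i, k, 0))
                    stack.append((k + 1, j, 0))
                    break
            else:  # pragma: no cover - DP invariant
                raise RuntimeError("inconsistent traceback")
    return pairs


def fold(seq: str) -> str:
    """Fold ``seq`` and return a dot-bracket string of the same length.

    Maximum-base-pairing model: pairs in {GC, AU, GU}, hairpin loops of at
    least :data:`MIN_LOOP` unpaired bases, stacking-preferring tie-break.
    Raises ``ValueError`` on characters outside the ACGU/T alphabet.
    """
    n = len(seq)
    if n <= MIN_LOOP:
        encode(seq)
        return "." * n
    x, S, P, _big = _tables(seq)
    struct = ["."] * n
    for i, j in _traceback(x, S, P):
        struct[i] = "("
        struct[j] = ")"
    return "".join(struct)


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return pt


def validate_structure(seq: str, structure: str) -> None:
    """Check balance, alphabet, pairability and the minimum-loop constraint."""
    if len(seq) != len(structure):
        raise ValueError("sequence/structure length mismatch")
    x = encode(seq)
    pt = pair_table(structure)
    for i, j in enumerate(pt):
        if j >= 0 and j > i:
            if not _CAN_PAIR[x[i], x[j]]:
                raise ValueError(f"non-canonical pair at ({i},{j})")
            if j - i <= MIN_LOOP:
                raise ValueError(f"hairpin loop below {MIN_LOOP} at ({i},{j})")
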