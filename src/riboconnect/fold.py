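"""RNA secondary structure prediction by weighted base-pair maximization.

The chimeric signal-connector devices built elsewhere in this package are
selected by a fold-and-inspect step: the assembled RNA is folded and designs
are kept only when the antisense domain stays single-stranded and the aptamer
domains keep their reference stems.  That selection step needs a structure
model that is deterministic, constraint-aware, and simple enough to admit an
exact brute-force oracle for testing — so the engine here is a weighted
Nussinov-style dynamic program (GC=3, AU=2, GU=1, minimum hairpin loop of 3
unpaired nucleotides) rather than a full nearest-neighbor thermodynamic
model.  Pseudoknots are outside the model.

The scoring weights order pair stabilities the way stacking energies do
(G:C > A:U > G:U) without claiming thermodynamic accuracy; scores are in
arbitrary stability units, higher = more stable.  ``enumerate_structures``
exhaustively lists every valid structure of a short sequence and is the
independent oracle used by the test suite; it refuses sequences longer than
25 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

RNA_ALPHABET = frozenset("ACGU")

#: pair → score, in stability units.  GU wobble pairs are allowed (weight 1):
#: they occur in natural aptamer stems and excluding them would misfold the
#: packaged aptamer references.
PAIR_WEIGHTS: dict[tuple[str, str], int] = {
    ("G", "C"): 3,
    ("C", "G"): 3,
    ("A", "U"): 2,
    ("U", "A"): 2,
    ("G", "U"): 1,
    ("U", "G"): 1,
}

#: minimum number of unpaired nucleotides enclosed by a pair (hairpin loop).
MIN_LOOP = 3

#: enumerate_structures guard: structure count grows exponentially.
MAX_ENUM_LENGTH = 25


class FoldError(ValueError):
    """Raised for invalid sequences, constraints or structures."""


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise FoldError("cannot fold an empty sequence")
    for pos, ch in enumerate(sequence):
        if ch not in RNA_ALPHABET:
            raise FoldError(
                f"invalid character {ch!r} at position {pos}; "
                "expected RNA over {A,C,G,U}"
            )
    return sequence


def pair_weight(a: str, b: str) -> int:
    """Score of pairing bases ``a``:``b`` (0 if not pairable)."""
    return PAIR_WEIGHTS.get((a, b), 0)


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing set of base pairs with its total pairing score.

    ``pairs`` holds ``(i, j)`` index tuples with ``i < j``; ``dotbracket``
    is the equivalent parenthesis notation; ``score`` is the sum of pair
    weights in stability units.
    """

    dotbracket: str
    pairs: frozenset = field(default_factory=frozenset)
    score: int = 0

    def __len__(self) -> int:
        return len(self.dotbracket)


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def dotbracket_to_pairs(dotbracket: str) -> frozenset:
    """Parse dot-bracket notation; raises on unbalanced strings."""
    stack: list[int] = []
    pairs = set()
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise FoldError(f"unbalanced ')' at position {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise FoldError(f"invalid dot-bracket character {ch!r} at {idx}")
    if stack:
        raise FoldError(f"unbalanced '(' at position {stack[-1]}")
    return frozenset(pairs)


def validate_structure(structure: SecondaryStructure) -> None:
    """Check the structural invariants: pairing is a partial matching of
    indices, pairs are non-crossing, loops respect MIN_LOOP, and the
    dot-bracket string is consistent with the pair set."""
    seen: set[int] = set()
    for i, j in structure.pairs:
        if not (0 <= i < j < len(structure.dotbracket)):
            raise FoldError(f"pair ({i},{j}) out of range")
        if j - i < MIN_LOOP + 1:
            raise FoldError(f"pair ({i},{j}) closes a loop shorter than {MIN_LOOP}")
        if i in seen or j in seen:
            raise FoldError(f"index reused in pair ({i},{j})")
        seen.update((i, j))
    ordered = sorted(structure.pairs)
    for a in range(len(ordered)):
        i, j = ordered[a]
        for b in range(a + 1, len(ordered)):
            k, l = ordered[b]
            if i < k < j < l:
                raise FoldError(f"crossing pairs ({i},{j}) and ({k},{l})")
    if pairs_to_dotbracket(structure.pairs, len(structure.dotbracket)) != structure.dotbracket:
        raise FoldError("dot-bracket inconsistent with pair set")


def _score_pairs(sequence: str, pairs: Iterable[tuple[int, int]]) -> int:
    return sum(pair_weight(sequence[i], sequence[j]) for i, j in pairs)


def structure_from_pairs(sequence: str, pairs: Iterable[tuple[int, int]]) -> SecondaryStructure:
    """Build (and validate) a SecondaryStructure from explicit pairs."""
    fs = frozenset(tuple(sorted(p)) for p in pairs)
    s = SecondaryStructure(
        dotbracket=pairs_to_dotbracket(fs, len(sequence)),
        pairs=fs,
        score=_score_pairs(sequence, fs),
    )
    validate_structure(s)
    return s


def fold(
    sequence: str,
    constraints: Optional[Iterable[int]] = None,
    min_loop: int = MIN_LOOP,
) -> SecondaryStructure:
    """Maximum-score secondary structure of ``sequence``.

    Parameters
    ----------
    sequence:
        RNA string over {A,C,G,U}.
    constraints:
        Indices forced to remain unpaired (e.g. an antisense domain held
        single-stranded to model its target-bound state).
    min_loop:
        Minimum hairpin loop length (default 3).

    The traceback is deterministic: at every subproblem the 5ʹ-most index is
    left unpaired whenever an optimal structure allows it (at equal score the
    more accessible structure wins); when it must pair, the nearest optimal
    partner (shortest span) is chosen.
    """
    seq = _check_sequence(sequence)
    n = len(seq)
    blocked = frozenset(constraints or ())
    for idx in blocked:
        if not (0 <= idx < n):
            raise FoldError(f"constraint index {idx} out of range for length {n}")

    # W[i][j] = best score on seq[i..j] inclusive
    W = [[0] * n for _ in range(n)]
    weights = PAIR_WEIGHTS
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1][j]
            if i not in blocked:
                si = seq[i]
                for k in range(i + min_loop + 1, j + 1):
                    if k in blocked:
                        continue
                    w = weights.get((si, seq[k]))
                    if w is None:
                        continue
                    cand = w + (W[i + 1][k - 1] if k - 1 > i else 0) + (
                        W[k + 1][j] if k + 1 <= j else 0
                    )
                    if cand > best:
                        best = cand
            W[i][j] = best

    pairs: set[tuple[int, int]] = set()
    stack: list[tuple[int, int]] = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or W[i][j] == 0:
            continue
        target = W[i][j]
        if W[i + 1][j] == target:  # prefer accessibility at equal score
            stack.append((i + 1, j))
            continue
        paired = False
        if i not in blocked:
            si = seq[i]
            for k in range(i + min_loop + 1, j + 1):
                if k in blocked:
                    continue
                w = weights.get((si, seq[k]))
                if w is None:
                    continue
                cand = w + (W[i + 1][k - 1] if k - 1 > i else 0) + (
                    W[k + 1][j] if k + 1 <= j else 0
                )
                if cand == target:
                    pairs.add((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))

    return SecondaryStructure(
        dotbracket=pairs_to_dotbracket(pairs, n),
        pairs=frozenset(pairs),
        score=W[0][n - 1],
    )


def enumerate_structures(
    sequence: str, min_loop: int = MIN_LOOP
) -> list[SecondaryStructure]:
    """Exhaustively enumerate every valid structure of a short sequence.

    Test oracle only: refuses sequences longer than 25 nt because the number
    of structures grows exponentially.  Returns each structure scored; the
    empty structure is always included.
    """
    seq = _check_sequence(sequence)
    n = len(seq)
    if n > MAX_ENUM_LENGTH:
        raise FoldError(
            f"enumerate_structures is a brute-force oracle limited to "
            f"{MAX_ENUM_LENGTH} nt (got {n}); use fold() for real inputs"
        )

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple[frozenset, ...]:
        """All pair sets over seq[i..j] inclusive."""
        if j - i < min_loop + 1:
            return (frozenset(),)
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if pair_weight(seq[i], seq[k]) == 0:
                continue
            for inner in region(i + 1, k - 1):
                for outer in region(k + 1, j):
                    out.append(inner | outer | {(i, k)})
        return tuple(out)

    result = []
    for pairset in region(0, n - 1):
        result.append(
            SecondaryStructure(
                dotbracket=pairs_to_dotbracket(pairset, n),
                pairs=pairset,
                score=_score_pairs(seq, pairset),
            )
        )
    return result


def pair_partner_map(structure: SecondaryStructure, length: int) -> list[Optional[int]]:
    """Per-index partner array: ``partner[i] == j`` iff (i,j) or (j,i) is a
    pair; unpaired positions map to ``None``."""
    partner: list[Optional[int]] = [None] * length
    for i, j in structure.pairs:
        if j >= length:
            raise FoldError(f"pair ({i},{j}) exceeds stated length {length}")
        partner[i] = j
        partner[j] = i
    return partner


def write_ct(structure: SecondaryStructure, sequence: str, path) -> None:
    """Write a connect-format (.ct) file for interoperability with other
    structure tools."""
    partner = pair_partner_map(structure, len(sequence))
    lines = [f"{len(sequence)} riboconnect score={structure.score}"]
    for i, base in enumerate(sequence):
        p = partner[i] + 1 if partner[i] is not None else 0
        lines.append(f"{i + 1} {base} {i} {i + 2} {p} {i + 1}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
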