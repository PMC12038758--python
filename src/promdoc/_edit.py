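"""Bounded Damerau-Levenshtein distance (restricted / optimal string alignment).

Single-character substitutions, insertions, deletions and adjacent
transpositions each cost 1 — the edit classes a clinician's typo most often
falls into.  Only small bounds are ever needed (fuzzy lexicon matching uses
distance <= 1), so a plain O(len_a * len_b) dynamic program is ample.
"""

from __future__ import annotations


def damerau_levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Restricted Damerau-Levenshtein distance between ``a`` and ``b``.

    With ``max_dist`` set, returns ``max_dist + 1`` as soon as the distance
    provably exceeds the bound (an early-exit band check).
    """
    la, lb = len(a), len(b)
    if max_dist is not None and abs(la - lb) > max_dist:
        return max_dist + 1
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                prev2 is not None
                and i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        if max_dist is not None and min(cur) > max_dist:
            return max_dist + 1
        prev2, prev = prev, cur
    return prev[lb]
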