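"""Levenshtein edit distance.

Implemented here rather than taken from a third-party wheel because the
distance is the package's core matching primitive: unit-cost insertions,
deletions and substitutions, i.e. the number of letters allowed to
disagree between a submitted and a matched name component.
"""

from __future__ import annotations

__all__ = ["edit_distance", "edit_distance_at_most"]


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between *a* and *b*.

    Symmetric, non-negative, zero iff the strings are equal.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, 1):
            append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def edit_distance_at_most(a: str, b: str, limit: int) -> int | None:
    """Levenshtein distance if it does not exceed *limit*, else ``None``.

    Abandons the computation as soon as every cell of the current DP row
    exceeds *limit*, which keeps bulk scans over a backbone cheap for the
    small thresholds used in practice.
    """
    if limit < 0:
        return None
    if a == b:
        return 0
    if abs(len(a) - len(b)) > limit:
        return None
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        append = cur.append
        row_min = i
        for j, cb in enumerate(b, 1):
            val = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            append(val)
            if val < row_min:
                row_min = val
        if row_min > limit:
            return None
        prev = cur
    d = prev[-1]
    return d if d <= limit else None
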