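"""Pairwise-alignment primitives shared across the package.

Fast edit-distance style alignment is delegated to edlib; the unit-cost
global aligner with an explicit tie-break policy (used for SNP/indel
counting between consensus sequences) is implemented here because the
tie-break — fewest gap openings, then leftmost gaps — is part of the
method definition and no library exposes it.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_columns(cigar: str) -> int:
    """Total number of alignment columns (matches + mismatches + gaps)."""
    return sum(n for n, _ in parse_cigar(cigar))


def identity_from_result(result: dict) -> float:
    """Identity = matching columns / total alignment columns.

    Gap columns count against identity; this is the single identity
    definition used throughout the package.
    """
    cols = cigar_columns(result["cigar"])
    if cols == 0:
        return 0.0
    return 1.0 - result["editDistance"] / cols


def nw_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences."""
    res = edlib.align(a, b, mode="NW", task="path")
    return identity_from_result(res)


def infix_align(query: str, target: str) -> dict:
    """Best local placement of ``query`` inside ``target`` (free target ends)."""
    return edlib.align(query, target, mode="HW", task="path")


def prefix_align(query: str, target: str) -> dict:
    """Align ``query`` against a prefix of ``target`` (target end free)."""
    return edlib.align(query, target, mode="SHW", task="path")


# --- unit-cost global alignment with explicit tie-breaking -----------------

_DIAG, _UP, _LEFT = 0, 1, 2  # UP consumes a, LEFT consumes b


def global_unit_alignment(a: str, b: str) -> list[tuple[str, str]]:
    """Optimal global alignment under unit costs (match 0, mismatch 1, gap 1).

    Among co-optimal alignments the one with the fewest gap openings is
    chosen, and gaps are pushed leftmost by the traceback preference
    (gap-in-b, then gap-in-a, then diagonal at equal cost keys).

    Returns the alignment as a list of column pairs, ``'-'`` marking gaps.
    """
    n, m = len(a), len(b)
    INF = (1 << 30, 1 << 30)
    # state: cost tuples (edits, gap_openings) per incoming move
    prev = [(INF, INF, INF) for _ in range(m + 1)]
    prev[0] = ((0, 0), INF, INF)
    for j in range(1, m + 1):
        prev[j] = (INF, INF, (j, 1))
    moves = [[0] * (m + 1) for _ in range(n + 1)]
    rows = [prev]
    for i in range(1, n + 1):
        cur = [(INF, INF, INF)] * (m + 1)
        cur[0] = (INF, (i, 1), INF)
        for j in range(1, m + 1):
            sub = 0 if a[i - 1] == b[j - 1] else 1
            pd = min(prev[j - 1])
            diag = (pd[0] + sub, pd[1])
            # gap in b (consume a): cheaper opening count if already in UP state
            pu = prev[j]
            up = min(
                (pu[_UP][0] + 1, pu[_UP][1]) if pu[_UP] is not INF else INF,
                (min(pu[_DIAG], pu[_LEFT])[0] + 1, min(pu[_DIAG], pu[_LEFT])[1] + 1),
            )
            pl = cur[j - 1]
            left = min(
                (pl[_LEFT][0] + 1, pl[_LEFT][1]) if pl[_LEFT] is not INF else INF,
                (min(pl[_DIAG], pl[_UP])[0] + 1, min(pl[_DIAG], pl[_UP])[1] + 1),
            )
            cur[j] = (diag, up, left)
        rows.append(cur)
        prev = cur
    # traceback from the best final state; prefer LEFT, UP, DIAG so that
    # gaps are emitted as late as possible in reverse = leftmost in forward order
    i, j = n, m
    state = min(range(3), key=lambda s: (rows[n][m][s], s))
    cols: list[tuple[str, str]] = []
    while i > 0 or j > 0:
        cell = rows[i][j]
        if state == _DIAG:
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
            cell = rows[i][j]
            state = min(range(3), key=lambda s: (cell[s], s))
        elif state == _UP:
            cols.append((a[i - 1], "-"))
            i -= 1
            pu = rows[i][j]
            cont = pu[_UP]
            other = min(pu[_DIAG], pu[_LEFT])
            key_cont = cont
            key_open = (other[0], other[1] + 1) if other is not INF else INF
            if key_cont <= key_open:
                state = _UP
            else:
                state = min((_DIAG, _LEFT), key=lambda s: (pu[s], s))
        else:  # _LEFT
            cols.append(("-", b[j - 1]))
            j -= 1
            pl = rows[i][j]
            cont = pl[_LEFT]
            other = min(pl[_DIAG], pl[_UP])
            key_cont = cont
            key_open = (other[0], other[1] + 1) if other is not INF else INF
            if key_cont <= key_open:
                state = _LEFT
            else:
                state = min((_DIAG, _UP), key=lambda s: (pl[s], s))
    cols.reverse()
    return cols
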