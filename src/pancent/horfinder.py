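"""Higher-order repeat (HOR) detection over a monomer-variant alphabet.

Monomers are first labeled into variant classes by greedy single-pass
clustering against representative sequences; arrays then become label
strings in which tandem repetitions of primitive label tuples are mined
and ranked by copy number.  Unit length 1 is allowed and reported —
monomic expansions are a prominent feature of real satellite arrays.

This is a deliberately simplified, deterministic take on HOR annotation;
it does not reproduce hierarchical HOR-merging tools.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import nw_identity
from .monomerize import MonomerRecord


@dataclass
class VariantLabeling:
    labels: list[str]  # one label per monomer, in input order
    representatives: dict[str, str]  # label -> representative sequence
    identity_threshold: float


@dataclass
class HORRecord:
    unit: tuple[str, ...]
    unit_length: int
    copy_number: int
    start: int  # monomer index of the run start
    end: int  # monomer index one past the run end
    rank: int = 0


def _label_alphabet() -> list[str]:
    # A..Z then A1, B1, ... for large variant sets
    import itertools
    import string

    letters = list(string.ascii_uppercase)
    yield from letters
    for i in itertools.count(1):
        for c in letters:
            yield f"{c}{i}"


def label_monomers(
    monomers: list[MonomerRecord] | list[str],
    identity_threshold: float = 0.95,
    refine: bool = True,
) -> VariantLabeling:
    """Greedy first-fit variant labeling with an optional refinement pass.

    Pass 1: each monomer joins the first existing representative whose
    global identity is at least the threshold, else founds a new label;
    labels are assigned in first-occurrence order, so the result is
    deterministic given input order.

    With ``refine`` (default), each label's representative is then rebuilt
    as the majority consensus of its members — washing out the noise the
    founding copy happened to carry — and every monomer is reassigned to
    its *best* representative at or above the threshold (keeping its pass-1
    label when none qualifies).  Labels left empty are dropped and the rest
    renumbered in final first-occurrence order.
    """
    seqs = [m.sequence if isinstance(m, MonomerRecord) else m for m in monomers]
    if not seqs:
        raise ValueError("empty monomer list")
    reps: list[tuple[str, str]] = []  # (label, representative)
    labels: list[str] = []
    for s, lab in zip(seqs, _first_fit(seqs, identity_threshold, reps)):
        labels.append(lab)
    if refine and len(reps) > 1:
        from .monomerize import _majority_consensus

        members: dict[str, list[str]] = {}
        for s, lab in zip(seqs, labels):
            members.setdefault(lab, []).append(s)
        refined = []
        strong = []  # labels whose representative is a multi-member consensus
        for lab, rep in reps:
            mem = members.get(lab, [])
            if len(mem) >= 2:
                rep = _majority_consensus(mem)
                strong.append((lab, rep))
            refined.append((lab, rep))
        # reassign against multi-member consensus representatives; a monomer is
        # never compared to a representative derived solely from itself
        new_labels = []
        for s, old in zip(seqs, labels):
            cands = strong if strong else refined
            best = max(
                ((nw_identity(s, rep), lab) for lab, rep in cands),
                key=lambda t: (t[0], t[1] == old),
            )
            new_labels.append(best[1] if best[0] >= identity_threshold else old)
        labels = new_labels
        reps = [(lab, rep) for lab, rep in refined if lab in set(labels)]
        # renumber by final first-occurrence order
        gen = _label_alphabet()
        remap = {}
        for lab in labels:
            if lab not in remap:
                remap[lab] = next(gen)
        labels = [remap[lab] for lab in labels]
        reps = [(remap[lab], rep) for lab, rep in reps]
        reps.sort(key=lambda t: t[0])
    return VariantLabeling(labels, dict(reps), identity_threshold)


def _first_fit(
    seqs: list[str], threshold: float, reps: list[tuple[str, str]]
) -> list[str]:
    gen = _label_alphabet()
    labels = []
    for s in seqs:
        assigned = None
        for lab, rep in reps:
            if threshold == 0 or nw_identity(s, rep) >= threshold:
                assigned = lab
                break
        if assigned is None:
            assigned = next(gen)
            reps.append((assigned, s))
        labels.append(assigned)
    return labels


def _is_primitive(unit: tuple[str, ...]) -> bool:
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return False
    return True


def find_hors(
    labels: list[str] | str,
    max_unit: int = 20,
    min_copies: int = 2,
    top: int | None = 5,
) -> list[HORRecord]:
    """Mine ranked tandem HOR units from one array's label string.

    For every primitive unit of length at most ``max_unit``, maximal tandem
    runs with at least ``min_copies`` copies are collected; candidates are
    ranked by copy number (ties: longer unit, then leftmost) and selected
    greedily without overlap.  ``top=None`` returns all non-overlapping
    records.
    """
    s = list(labels)
    n = len(s)
    candidates: list[HORRecord] = []
    for u in range(1, min(max_unit, n) + 1):
        i = 0
        while i + u <= n:
            unit = tuple(s[i : i + u])
            if not _is_primitive(unit):
                i += 1
                continue
            # maximality to the left: skip runs that are continuations
            if i >= u and tuple(s[i - u : i]) == unit:
                i += 1
                continue
            copies = 1
            while i + (copies + 1) * u <= n and tuple(
                s[i + copies * u : i + (copies + 1) * u]
            ) == unit:
                copies += 1
            if copies >= min_copies:
                candidates.append(
                    HORRecord(unit, u, copies, i, i + copies * u)
                )
            i += 1
    candidates.sort(key=lambda r: (-r.copy_number, -r.unit_length, r.start))
    chosen: list[HORRecord] = []
    taken = [False] * n
    for cand in candidates:
        if top is not None and len(chosen) >= top:
            break
        if any(taken[cand.start : cand.end]):
            continue
        cand.rank = len(chosen) + 1
        chosen.append(cand)
        for j in range(cand.start, cand.end):
            taken[j] = True
    return chosen


def hors_from_monomers(
    monomers: list[MonomerRecord],
    identity_threshold: float = 0.95,
    max_unit: int = 20,
    min_copies: int = 2,
    top: int | None = 5,
) -> dict[str, list[HORRecord]]:
    """Label monomers and mine HORs separately within each array."""
    labeling = label_monomers(monomers, identity_threshold)
    by_array: dict[str, list[str]] = {}
    for m, lab in zip(monomers, labeling.labels):
        by_array.setdefault(m.array_id, []).append(lab)
    return {
        arr: find_hors(labs, max_unit=max_unit, min_copies=min_copies, top=top)
        for arr, labs in by_array.items()
    }
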