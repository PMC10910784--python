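"""Satellite monomer extraction.

Two extraction routes are implemented, mirroring how centromeric satellite
units are harvested in practice:

* ``decompose_array`` — consensus-anchored decomposition of assembled
  sequence: seed the array with the best placement of the (canonicalized)
  consensus, then walk outwards monomer by monomer with prefix-anchored
  alignments so every monomer is cut at the same consensus phase.
* ``merge_pairs`` / ``filter_fragments`` / ``assign_fragments`` — harvest
  satellite-covering fragments from paired-end reads: merge overlapping
  mates, keep fragments in the mononucleosome length window (146-166 bp by
  default) and assign them to a consensus by scored local alignment with a
  Karlin-Altschul E-value cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align
from scipy.optimize import brentq

from ._align import (
    identity_from_result,
    infix_align,
    parse_cigar,
    prefix_align,
    revcomp,
)


class InvalidParameterError(ValueError):
    pass


@dataclass
class ConsensusRepeat:
    """A named canonical satellite monomer (e.g. the CentBd / CentBs role)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 50:
            raise InvalidParameterError("consensus shorter than 50 bp")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def canonicalized(self) -> "ConsensusRepeat":
        return ConsensusRepeat(self.name, canonical_rotation(self.sequence))


@dataclass
class MonomerRecord:
    """One satellite monomer occurrence on a chromosome.

    ``sequence`` is the monomer as read on the annotated strand; coordinates
    are 0-based half-open on the forward strand.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    consensus_name: str
    identity: float
    array_id: str = ""


@dataclass
class FragmentRecord:
    id: str
    sequence: str
    source: str = "WGS"
    assigned_consensus: str | None = None
    evalue: float = math.inf

    @property
    def length(self) -> int:
        return len(self.sequence)


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation of ``seq`` (idempotent).

    Tandem monomers have arbitrary phase; fixing the rotation gives every
    array a shared, comparable monomer frame.
    """
    if not seq:
        raise InvalidParameterError("empty sequence")
    n = len(seq)
    doubled = seq + seq
    return min(doubled[i : i + n] for i in range(n))


# ---------------------------------------------------------------------------
# consensus-anchored decomposition


def _walk_right(
    seq: str, pos: int, cons: dict[str, str], strand: str, min_identity: float
) -> list[tuple[int, int, str, float]]:
    """Extend an array rightwards from ``pos``, one monomer per step."""
    L = len(cons["+"])
    band = max(20, L // 4)
    out = []
    while True:
        window = seq[pos : pos + L + band]
        if len(window) < L // 2 or "N" in window:
            break
        best = None
        for st in (strand, "-" if strand == "+" else "+"):
            res = prefix_align(cons[st], window)
            if res["editDistance"] < 0:
                continue
            ident = identity_from_result(res)
            # choose the co-optimal end closest to the consensus length
            end = min(
                (loc[1] for loc in res["locations"]), key=lambda e: abs(e + 1 - L)
            )
            if best is None or ident > best[0]:
                best = (ident, end + 1, st)
        if best is None or best[0] < min_identity:
            break
        ident, span, st = best
        out.append((pos, pos + span, st, ident))
        strand = st
        pos += span
    return out


def decompose_array(
    genome: str | dict[str, str],
    consensus: ConsensusRepeat,
    min_identity: float = 0.6,
    search_both_strands: bool = True,
    max_gap: int = 2000,
) -> list[MonomerRecord]:
    """Decompose satellite arrays into phase-aligned monomers.

    Seeds each array with the best infix placement of the canonicalized
    consensus (both strands unless ``search_both_strands`` is off), then
    walks left and right with prefix-anchored alignments so boundaries are
    cut at consensus position 0.  Monomers closer than ``max_gap`` share an
    ``array_id``; found spans are masked and seeding repeats until no
    placement reaches ``min_identity``.
    """
    if not 0.0 < min_identity <= 1.0:
        raise InvalidParameterError("min_identity must be in (0, 1]")
    if isinstance(genome, dict):
        records: list[MonomerRecord] = []
        for chrom, seq in genome.items():
            records.extend(
                _decompose_one(
                    chrom, seq, consensus, min_identity, search_both_strands, max_gap
                )
            )
        return records
    return _decompose_one(
        "chr", genome, consensus, min_identity, search_both_strands, max_gap
    )


def _decompose_one(
    chrom: str,
    seq: str,
    consensus: ConsensusRepeat,
    min_identity: float,
    search_both_strands: bool,
    max_gap: int,
) -> list[MonomerRecord]:
    if not seq:
        return []
    consensus = consensus.canonicalized()
    cons = {"+": consensus.sequence, "-": revcomp(consensus.sequence)}
    L = consensus.length
    seq = seq.upper()
    masked = bytearray(seq.encode())
    found: list[tuple[int, int, str, float]] = []

    strands = ("+", "-") if search_both_strands else ("+",)
    while True:
        best_seed = None
        text = masked.decode()
        for st in strands:
            res = infix_align(cons[st], text)
            if res["editDistance"] < 0:
                continue
            ident = identity_from_result(res)
            if best_seed is None or ident > best_seed[0]:
                s, e = res["locations"][0]
                best_seed = (ident, s, e + 1, st)
        if best_seed is None or best_seed[0] < min_identity:
            break
        ident, s, e, st = best_seed
        chain = [(s, e, st, ident)]
        chain += _walk_right(text, e, cons, st, min_identity)
        # leftwards walk: mirror the problem and walk right
        rtext = text[::-1]
        rcons = {k: v[::-1] for k, v in cons.items()}
        lchain = _walk_right(rtext, len(text) - s, rcons, st, min_identity)
        for a, b, lst, lident in lchain:
            chain.append((len(text) - b, len(text) - a, lst, lident))
        chain.sort()
        found.extend(chain)
        lo, hi = chain[0][0], chain[-1][1]
        masked[lo:hi] = b"N" * (hi - lo)

    found.sort()
    records: list[MonomerRecord] = []
    array_idx = 0
    prev_end = None
    for s, e, st, ident in found:
        if prev_end is not None and s < prev_end:
            continue  # drop rare overlap from independent seeds
        if prev_end is None or s - prev_end > max_gap:
            array_idx += 1
        prev_end = e
        sub = seq[s:e]
        records.append(
            MonomerRecord(
                chrom=chrom,
                start=s,
                end=e,
                strand=st,
                sequence=sub if st == "+" else revcomp(sub),
                consensus_name=consensus.name,
                identity=ident,
                array_id=f"{chrom}_arr{array_idx}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# fragment route: merge, filter, assign


def merge_pairs(
    r1: list[tuple[str, str]],
    r2: list[tuple[str, str]],
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> list[FragmentRecord]:
    """Merge overlapping mate pairs into single fragments.

    Mates must be in consistent order.  For each pair the reverse complement
    of R2 is slid over R1; the overlap with the fewest mismatches (ties to
    the longest overlap) is accepted when it spans at least ``min_overlap``
    bases with a mismatch rate at most ``max_mismatch_rate``.  Pairs without
    an acceptable overlap are dropped.
    """
    if len(r1) != len(r2):
        raise ValueError("mate-count mismatch between R1 and R2")
    out: list[FragmentRecord] = []
    for (name1, a), (_, b) in zip(r1, r2):
        brc = revcomp(b)
        best: tuple[float, int] | None = None  # (mismatch_rate, overlap)
        max_o = min(len(a), len(brc))
        for o in range(max_o, min_overlap - 1, -1):
            mism = sum(x != y for x, y in zip(a[-o:], brc[:o]))
            rate = mism / o
            if rate <= max_mismatch_rate and (
                best is None or rate < best[0] - 1e-12
            ):
                best = (rate, o)
        if best is None:
            continue
        o = best[1]
        merged = a + brc[o:]
        out.append(FragmentRecord(id=name1, sequence=merged))
    return out


def filter_fragments(
    fragments: list[FragmentRecord], min_len: int = 146, max_len: int = 166
) -> list[FragmentRecord]:
    """Keep fragments with ``min_len <= length <= max_len`` (inclusive)."""
    return [f for f in fragments if min_len <= f.length <= max_len]


def _karlin_altschul_lambda(match: float = 1.0, mismatch: float = -2.0) -> float:
    """Ungapped lambda for a match/mismatch score at uniform composition."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


_LAMBDA = _karlin_altschul_lambda()
_K = 0.621  # published ungapped K for +1/-2 at uniform composition


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def assign_fragments(
    fragments: list[FragmentRecord],
    consensi: list[ConsensusRepeat],
    evalue_max: float = 1e-5,
) -> list[FragmentRecord]:
    """Assign each fragment to its best-matching consensus by E-value.

    Each fragment is locally aligned on both strands to each consensus
    concatenated to itself (so alignments can span the arbitrary phase
    junction); the best score is converted to an E-value with
    Karlin-Altschul statistics for +1/-2 scoring over a search space of
    fragment length x total doubled-consensus length x 2 strands.
    Fragments with best E <= ``evalue_max`` get ``assigned_consensus`` set;
    ties break by higher identity, then consensus name order.
    """
    if not consensi:
        raise InvalidParameterError("at least one consensus required")
    aligner = _local_aligner()
    targets = [(c.name, c.sequence + c.sequence) for c in consensi]
    n_space = sum(len(t) for _, t in targets) * 2
    for frag in fragments:
        best: tuple[float, float, str] | None = None  # (-score, -identity, name)
        for name, target in sorted(targets):
            for q in (frag.sequence, revcomp(frag.sequence)):
                score = aligner.score(q, target)
                ident = identity_from_result(infix_align(q, target))
                cand = (-score, -ident, name)
                if best is None or cand < best:
                    best = cand
        score = -best[0]
        evalue = _K * frag.length * n_space * math.exp(-_LAMBDA * score)
        frag.evalue = evalue
        frag.assigned_consensus = best[2] if evalue <= evalue_max else None
    return fragments


# ---------------------------------------------------------------------------
# consensus recovery


def build_consensus(
    monomers: list[MonomerRecord] | list[str], name: str = "consensus"
) -> ConsensusRepeat:
    """Majority-rule consensus from phase-aligned monomers.

    Center-star alignment against the medoid monomer (the member with the
    smallest summed edit distance to a deterministic sample of the others);
    each monomer is globally aligned to the center, per-column base counts
    are accumulated (center-relative insertions are kept only when a
    majority of monomers insert at that junction) and the majority base is
    taken per column, gaps dropped.  Returned in canonical rotation.
    """
    seqs = [m.sequence if isinstance(m, MonomerRecord) else m for m in monomers]
    if len(seqs) < 2:
        raise InvalidParameterError("need at least 2 monomers")
    return ConsensusRepeat(name, canonical_rotation(_majority_consensus(seqs)))


def _majority_consensus(seqs: list[str]) -> str:
    """Center-star majority consensus in the phase of the medoid member."""
    sample = seqs[:: max(1, len(seqs) // 30)][:30]
    dists = []
    for s in sample:
        d = sum(edlib.align(s, t, mode="NW", task="distance")["editDistance"] for t in sample)
        dists.append(d)
    center = sample[int(np.argmin(dists))]
    Lc = len(center)
    counts = np.zeros((Lc, 5), dtype=int)  # A C G T -
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    insertions: dict[int, dict[str, int]] = {}
    for s in seqs:
        res = edlib.align(s, center, mode="NW", task="path")
        qi = ci = 0
        for ln, op in parse_cigar(res["cigar"]):
            if op in "=XM":
                for _ in range(ln):
                    counts[ci, base_idx.get(s[qi], 0)] += 1
                    qi += 1
                    ci += 1
            elif op == "D":  # center base absent from monomer
                for _ in range(ln):
                    counts[ci, 4] += 1
                    ci += 1
            elif op == "I":  # monomer bases absent from center
                ins = s[qi : qi + ln]
                d = insertions.setdefault(ci, {})
                d[ins] = d.get(ins, 0) + 1
                qi += ln
    n = len(seqs)
    out = []
    for ci in range(Lc + 1):
        if ci in insertions:
            ins, cnt = max(insertions[ci].items(), key=lambda kv: (kv[1], kv[0]))
            if cnt > n / 2:
                out.append(ins)
        if ci < Lc:
            j = int(np.argmax(counts[ci]))
            if j < 4:
                out.append("ACGT"[j])
    return "".join(out)
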