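"""Synthetic centromere generator.

Builds chromosomes whose centromeres have the statistical structure the
downstream analyses assume: head-to-tail ~156-bp satellite arrays with
per-copy substitutions and 1-bp indels, optionally organised into
higher-order repeat (HOR) units over planted monomer variants, strand
blocks applied as whole reverse-complemented segments, CRM retrotransposon
insertions carrying an aged LTR pair, elevated satellite divergence in a
window around each insertion, and ChIP/Input read pairs with a configurable
fold enrichment over the centromere and a phased positional bias within
monomers.  Everything is driven by a single integer seed and the ground
truth of every planted feature is returned alongside the sequence, so each
downstream estimator can be tested as a parameter-recovery problem.

Arrays are *generated*, not evolved: there is no forward-time model of
unequal crossover or homogenization dynamics.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._align import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_STR = "ACGT"


class InvalidParameterError(ValueError):
    """Raised when a simulation parameter is outside its valid range."""


# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass
class HORSpec:
    """A planted higher-order repeat unit.

    ``variants`` is an ordered list of variant definitions; each variant is a
    list of fixed substitutions ``(position, base)`` applied to the consensus.
    The unit (one monomer per variant, in order) is tiled ``unit_copies``
    times.
    """

    variants: list[list[tuple[int, str]]]
    unit_copies: int


@dataclass
class CRMSpec:
    """One planted centromeric retrotransposon (CRM) insertion.

    position_copies
        Insertion point, expressed as a monomer-copy index: the element is
        inserted between copies ``position_copies - 1`` and
        ``position_copies``.
    age_mya
        True insertion age; the two LTRs accumulate substitutions so their
        expected pairwise divergence is ``2 * clock_rate * age``.
    flank_hypermutation_factor
        Monomers within ``flank_window`` bp of the insertion are mutated at
        ``sub_rate * factor`` instead of ``sub_rate``.
    """

    position_copies: int
    element_length: int = 5000
    ltr_length: int = 400
    age_mya: float = 0.5
    flank_hypermutation_factor: float = 1.0
    flank_window: int = 2000


@dataclass
class ChipSpec:
    """ChIP/Input read simulation parameters.

    Read length follows the study design (101-nt paired ends); fragment
    lengths are Normal(mean, sd) truncated to [read_length, 2*read_length],
    the mononucleosome scale produced by MNase digestion.  ``phase_kappa``
    is the concentration of the von-Mises-like positional weight placing
    ChIP fragment midpoints at ``phase_offset`` within each monomer
    (``phase_kappa = 0`` disables the phasing).
    """

    fold: float = 8.0
    phase_offset: int = 80
    phase_kappa: float = 8.0
    read_length: int = 101
    fragment_mean: float = 156.0
    fragment_sd: float = 15.0
    coverage: float = 20.0
    error_rate: float = 0.0


@dataclass
class SimConfig:
    """Full specification of one synthetic centromeric chromosome."""

    seed: int = 0
    monomer_consensus: str | tuple[str, ...] | None = None
    n_copies: int = 500
    sub_rate: float = 0.02
    indel_rate: float = 0.002
    hor_spec: HORSpec | None = None
    strand_blocks: list[tuple[int, str]] | None = None
    crm_spec: list[CRMSpec] = field(default_factory=list)
    chip_spec: ChipSpec = field(default_factory=ChipSpec)
    flank_length: int = 10_000
    clock_rate: float = 1.3e-8  # substitutions / site / year

    def validate(self) -> None:
        for name in ("sub_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_copies < 1:
            raise InvalidParameterError("n_copies must be >= 1")
        if self.chip_spec.fold <= 0:
            raise InvalidParameterError("fold enrichment must be > 0")


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests.

    Monomer intervals are 0-based half-open, sorted and non-overlapping on
    the chromosome; ``centromere`` spans the satellite array including any
    CRM insertions.
    """

    monomer_intervals: list[tuple[int, int]]
    monomer_strands: list[str]
    monomer_labels: list[str]
    monomer_sub_counts: list[int]
    monomer_indel_counts: list[int]
    centromere: tuple[int, int]
    crm_intervals: list[dict]
    consensus: str
    phase_offset: int
    sub_rate: float
    indel_rate: float
    chrom_length: int = 0
    library_sizes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "monomers": [
                {
                    "start": s,
                    "end": e,
                    "strand": st,
                    "label": lab,
                    "n_subs": ns,
                    "n_indels": ni,
                }
                for (s, e), st, lab, ns, ni in zip(
                    self.monomer_intervals,
                    self.monomer_strands,
                    self.monomer_labels,
                    self.monomer_sub_counts,
                    self.monomer_indel_counts,
                )
            ],
            "centromere": list(self.centromere),
            "crm": self.crm_intervals,
            "consensus": self.consensus,
            "phase_offset": self.phase_offset,
            "sub_rate": self.sub_rate,
            "indel_rate": self.indel_rate,
            "chrom_length": self.chrom_length,
            "library_sizes": self.library_sizes,
        }
        return json.dumps(d, indent=1)


# ---------------------------------------------------------------------------
# sequence-level primitives


def make_consensus(length: int, gc: float = 0.45, seed: int = 0) -> str:
    """Random monomer consensus of exactly ``length`` bp with expected GC ``gc``.

    Deterministic given ``seed``.  ``length`` must be at least 50 (shorter
    sequences are not meaningful satellite monomers).
    """
    if length < 50:
        raise InvalidParameterError(f"consensus length must be >= 50, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise InvalidParameterError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASE_STR[i] for i in idx)


def mutate_copy(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Apply per-site substitutions and 1-bp indels to one monomer copy.

    Substitutions never reproduce the original base; indels are single-base
    insertions or deletions with equal probability.  Returns the mutated
    sequence together with the number of substitution and indel events
    actually applied.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_subs = 0
    if sub_rate > 0:
        hit = rng.random(n) < sub_rate
        idx = np.flatnonzero(hit)
        n_subs = len(idx)
        for i in idx:
            cur = arr[i]
            choices = _BASES[_BASES != cur]
            arr[i] = choices[rng.integers(len(choices))]
    out = arr.tobytes().decode()
    n_indels = 0
    if indel_rate > 0:
        hit = np.flatnonzero(rng.random(len(out)) < indel_rate)
        # apply right-to-left so earlier coordinates stay valid
        chars = list(out)
        for i in hit[::-1]:
            n_indels += 1
            if rng.random() < 0.5:
                del chars[i]
            else:
                chars.insert(i, _BASE_STR[rng.integers(4)])
        out = "".join(chars)
    return out, n_subs, int(n_indels)


def _canonical_rotation(seq: str) -> str:
    doubled = seq + seq
    n = len(seq)
    return min(doubled[i : i + n] for i in range(n))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _apply_variant(consensus: str, subs: list[tuple[int, str]]) -> str:
    chars = list(consensus)
    for pos, base in subs:
        if not 0 <= pos < len(chars):
            raise InvalidParameterError(f"variant position {pos} outside consensus")
        chars[pos] = base
    return "".join(chars)


def _make_crm_element(
    rng: np.random.Generator, spec: CRMSpec, clock_rate: float
) -> tuple[str, int, int, int]:
    """Random LTR element; returns (sequence, ltr_len, n_subs_5, n_subs_3).

    Both LTRs descend from one ancestral copy; each accumulates
    substitutions at per-site probability ``clock_rate * age`` years so the
    expected pairwise divergence is ``2 * clock_rate * age``.
    """
    if spec.element_length < 2 * spec.ltr_length:
        raise InvalidParameterError("element_length must hold two LTRs")
    anc = _random_dna(rng, spec.ltr_length)
    per_site = clock_rate * spec.age_mya * 1e6
    ltrs = []
    counts = []
    for _ in range(2):
        mutated, ns, _ = mutate_copy(anc, per_site, 0.0, rng)
        ltrs.append(mutated)
        counts.append(ns)
    internal = _random_dna(rng, spec.element_length - 2 * spec.ltr_length)
    return ltrs[0] + internal + ltrs[1], spec.ltr_length, counts[0], counts[1]


# ---------------------------------------------------------------------------
# chromosome assembly


def simulate_centromere(config: SimConfig) -> tuple[str, GroundTruth]:
    """Build one synthetic chromosome and its ground truth.

    The satellite array is the HOR unit tiled ``unit_copies`` times (or
    plain tandem copies of the consensus), each copy independently mutated;
    strand blocks are reverse-complemented as whole blocks *after* mutation
    so both orientations carry the same divergence distribution; CRM
    elements are inserted at monomer-copy boundaries and monomers within
    ``flank_window`` of an insertion are hypermutated.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cons = config.monomer_consensus
    if cons is None:
        cons = make_consensus(156, 0.45, seed=config.seed)
    if isinstance(cons, (tuple, list)):
        cons = cons[0]
    cons = _canonical_rotation(cons.upper())
    L = len(cons)

    # per-copy base sequences and labels
    if config.hor_spec is not None:
        unit = [
            (_apply_variant(cons, subs), chr(ord("A") + i))
            for i, subs in enumerate(config.hor_spec.variants)
        ]
        copies = unit * config.hor_spec.unit_copies
    else:
        copies = [(cons, "A")] * config.n_copies
    n = len(copies)

    for spec in config.crm_spec:
        if not 0 <= spec.position_copies <= n:
            raise InvalidParameterError(
                f"CRM insertion at copy {spec.position_copies} beyond array of {n}"
            )

    # mark hypermutated copies (within flank_window bp of an insertion point)
    rate = np.full(n, config.sub_rate)
    for spec in config.crm_spec:
        w = int(np.ceil(spec.flank_window / L))
        lo = max(0, spec.position_copies - w)
        hi = min(n, spec.position_copies + w)
        rate[lo:hi] = config.sub_rate * spec.flank_hypermutation_factor

    mutated: list[tuple[str, str, int, int, str]] = []  # seq,label,nsub,nind,strand
    for i, (base, lab) in enumerate(copies):
        seq, ns, ni = mutate_copy(base, float(rate[i]), config.indel_rate, rng)
        mutated.append((seq, lab, ns, ni, "+"))

    # strand blocks: reverse-complement whole blocks after mutation
    if config.strand_blocks:
        pos = 0
        out: list[tuple[str, str, int, int, str]] = []
        for count, orient in config.strand_blocks:
            block = mutated[pos : pos + count]
            if orient == "-":
                block = [
                    (revcomp(s), lab, ns, ni, "-") for s, lab, ns, ni, _ in block
                ][::-1]
            out.extend(block)
            pos += count
        out.extend(mutated[pos:])
        mutated = out

    # assemble: left flank + (CRMs interleaved with monomers) + right flank
    crm_at: dict[int, list[CRMSpec]] = {}
    for spec in config.crm_spec:
        crm_at.setdefault(spec.position_copies, []).append(spec)

    parts: list[str] = []
    pos = 0
    left_flank = _random_dna(rng, config.flank_length)
    parts.append(left_flank)
    pos += len(left_flank)
    cen_start = pos

    intervals, strands, labels, subc, indc = [], [], [], [], []
    crm_records: list[dict] = []

    def _insert_crms(copy_idx: int) -> None:
        nonlocal pos
        for spec in crm_at.get(copy_idx, []):
            elem, ltr_len, ns5, ns3 = _make_crm_element(rng, spec, config.clock_rate)
            start = pos
            parts.append(elem)
            pos += len(elem)
            crm_records.append(
                {
                    "start": start,
                    "end": pos,
                    "ltr5": [start, start + ltr_len],
                    "ltr3": [pos - ltr_len, pos],
                    "age_mya": spec.age_mya,
                    "ltr_sub_counts": [ns5, ns3],
                    "flank_hypermutation_factor": spec.flank_hypermutation_factor,
                    "flank_window": spec.flank_window,
                }
            )

    for i, (seq, lab, ns, ni, strand) in enumerate(mutated):
        _insert_crms(i)
        parts.append(seq)
        intervals.append((pos, pos + len(seq)))
        strands.append(strand)
        labels.append(lab)
        subc.append(ns)
        indc.append(ni)
        pos += len(seq)
    _insert_crms(n)
    cen_end = pos
    parts.append(_random_dna(rng, config.flank_length))
    pos += config.flank_length

    chrom = "".join(parts)
    truth = GroundTruth(
        monomer_intervals=intervals,
        monomer_strands=strands,
        monomer_labels=labels,
        monomer_sub_counts=subc,
        monomer_indel_counts=indc,
        centromere=(cen_start, cen_end),
        crm_intervals=crm_records,
        consensus=cons,
        phase_offset=config.chip_spec.phase_offset,
        sub_rate=config.sub_rate,
        indel_rate=config.indel_rate,
        chrom_length=len(chrom),
    )
    return chrom, truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSet:
    """Paired reads plus the true fragment intervals they were cut from."""

    r1: list[tuple[str, str]]  # (name, sequence)
    r2: list[tuple[str, str]]
    fragments: list[tuple[int, int]]

    def write_fastq(self, path_r1: str | Path, path_r2: str | Path) -> None:
        for path, reads in ((path_r1, self.r1), (path_r2, self.r2)):
            text = "".join(
                f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n" for name, seq in reads
            )
            if str(path).endswith(".gz"):
                # fixed mtime / empty name so identical reads give identical bytes
                with open(path, "wb") as raw, gzip.GzipFile(
                    filename="", mode="wb", fileobj=raw, mtime=0
                ) as fh:
                    fh.write(text.encode())
            else:
                Path(path).write_text(text)


def simulate_reads(
    chrom: str, truth: GroundTruth, config: SimConfig
) -> tuple[ReadSet, ReadSet]:
    """Simulate (ChIP, Input) paired-end read sets.

    Input fragment midpoints are uniform over the chromosome.  ChIP
    midpoint density is ``fold`` times background inside the centromere
    interval and, within each monomer, additionally weighted by a
    von-Mises-like periodic factor peaking at ``phase_offset`` (the factor
    averages to 1 over a monomer so the interval-level fold is preserved).
    Mates are reverse-complements in FR orientation; qualities are constant
    Q40.  Deterministic given the config seed.
    """
    spec = config.chip_spec
    if spec.coverage <= 0:
        raise InvalidParameterError("coverage must be > 0")
    G = len(chrom)
    cs, ce = truth.centromere
    if not (0 <= cs < ce <= G):
        raise InvalidParameterError("centromere interval outside chromosome")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    n_frag = max(1, int(spec.coverage * G / (2 * spec.read_length)))

    weight = np.ones(G)
    weight[cs:ce] = spec.fold
    if spec.phase_kappa > 0:
        for (s, e), strand in zip(truth.monomer_intervals, truth.monomer_strands):
            ln = e - s
            off = np.arange(ln)
            if strand == "-":
                off = ln - 1 - off
            w = np.exp(
                spec.phase_kappa * np.cos(2 * np.pi * (off - spec.phase_offset) / ln)
            )
            weight[s:e] *= w / w.mean()

    def _sample(n: int, w: np.ndarray | None, tag: str) -> ReadSet:
        if w is None:
            mids = rng.integers(0, G, size=n)
        else:
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            mids = np.searchsorted(cdf, rng.random(n))
        lens = rng.normal(spec.fragment_mean, spec.fragment_sd, size=n)
        lens = np.clip(np.rint(lens), spec.read_length, 2 * spec.read_length).astype(int)
        starts = np.clip(mids - lens // 2, 0, None)
        ends = np.minimum(starts + lens, G)
        starts = np.maximum(ends - lens, 0)
        r1, r2, frags = [], [], []
        for k, (s, e) in enumerate(zip(starts, ends)):
            frag = chrom[s:e]
            if spec.error_rate > 0:
                frag, _, _ = mutate_copy(frag, spec.error_rate, 0.0, rng)
            name = f"{tag}_{k}:{s}-{e}"
            r1.append((name, frag[: spec.read_length]))
            r2.append((name, revcomp(frag)[: spec.read_length]))
            frags.append((int(s), int(e)))
        return ReadSet(r1, r2, frags)

    chip = _sample(n_frag, weight, "chip")
    inpt = _sample(n_frag, None, "input")
    truth.library_sizes = {"chip": n_frag, "input": n_frag}
    return chip, inpt
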