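"""CENH3 enrichment profiling and centromere calling.

Coverage is binned, library-size normalized and turned into log2(ChIP/Input)
tracks with a pseudocount; the centromere of a chromosome is the
threshold-and-merge region with the maximal summed signal, and its
enrichment level is the mean ChIP depth inside the call relative to the
genome-wide mean.  Repeat clusters are classified as centromeric with the
strict (ratio > 2.6, genome fraction > 0.5%) rule; metaprofiles and the
within-monomer phasing of fragment midpoints complete the picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .monomerize import MonomerRecord


@dataclass
class EnrichmentTrack:
    """Binned, library-normalized ChIP/Input signal for one chromosome."""

    chrom: str
    bin_size: int
    chip: np.ndarray  # normalized depth per bin
    input: np.ndarray
    log2_ratio: np.ndarray


@dataclass
class CentromereCall:
    chrom: str
    start: int
    end: int
    mean_log2: float
    enrichment_level: float = float("nan")


@dataclass
class RepeatClusterSummary:
    cluster_id: str
    chip_read_count: int
    input_read_count: int
    genome_fraction: float
    ratio: float = float("nan")
    is_centromeric: bool = False


@dataclass
class MetaProfile:
    n_features: int
    flank_bins: int
    body_bins: int
    profile: np.ndarray  # length = 2*flank_bins + body_bins


def depth_array(intervals, chrom_length: int) -> np.ndarray:
    """Per-base depth from half-open intervals (e.g. fragment coordinates)."""
    diff = np.zeros(chrom_length + 1)
    for s, e in intervals:
        s = max(0, int(s))
        e = min(chrom_length, int(e))
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff)[:-1]


def bin_coverage(depth, bin_size: int, chrom_length: int | None = None) -> np.ndarray:
    """Per-bin mean depth; the partial terminal bin averages its true width.

    ``depth`` is either a per-base depth array or a sorted list of
    half-open intervals (each contributing depth 1), in which case
    ``chrom_length`` is required.
    """
    if not isinstance(depth, np.ndarray):
        if chrom_length is None:
            raise ValueError("chrom_length required for interval input")
        prev = -1
        for s, e in depth:
            if s < prev:
                raise ValueError("intervals must be sorted by start")
            prev = s
        depth = depth_array(depth, chrom_length)
    n = len(depth)
    nbins = (n + bin_size - 1) // bin_size
    out = np.empty(nbins)
    for i in range(nbins):
        out[i] = depth[i * bin_size : (i + 1) * bin_size].mean()
    return out


def log2_ratio(
    chip_bins: np.ndarray,
    input_bins: np.ndarray,
    bin_size: int,
    chrom: str = "chr",
    pseudocount: float = 0.5,
    chip_library: float | None = None,
    input_library: float | None = None,
) -> EnrichmentTrack:
    """log2((chip + p) / (input + p)) on library-size-normalized depths.

    Each track is divided by its mean library depth, so the genome-wide
    mean normalized depth is 1 for both libraries regardless of sequencing
    depth: scaling either library leaves the ratios exactly unchanged.
    The pseudocount is expressed in these normalized-depth units and keeps
    every bin finite (including zero-input bins).
    """
    chip_bins = np.asarray(chip_bins, dtype=float)
    input_bins = np.asarray(input_bins, dtype=float)
    if chip_bins.shape != input_bins.shape:
        raise ValueError("ChIP and Input bin grids differ")
    n = len(chip_bins)
    ct = chip_library if chip_library is not None else chip_bins.sum()
    it = input_library if input_library is not None else input_bins.sum()
    if ct <= 0 or it <= 0:
        raise ValueError("library sizes must be positive")
    chip_n = chip_bins / (ct / n)
    input_n = input_bins / (it / n)
    ratio = np.log2((chip_n + pseudocount) / (input_n + pseudocount))
    return EnrichmentTrack(chrom, bin_size, chip_n, input_n, ratio)


def call_centromere(
    track: EnrichmentTrack,
    threshold_log2: float = 1.0,
    merge_gap: int = 100_000,
) -> CentromereCall | None:
    """Call the chromosome's centromere from a log2 enrichment track.

    Bins at or above the threshold are merged across gaps of at most
    ``merge_gap`` bp; the merged region with the maximal summed log2 signal
    is returned.  ``None`` when no bin passes.
    """
    hits = np.flatnonzero(track.log2_ratio >= threshold_log2)
    if len(hits) == 0:
        return None
    gap_bins = merge_gap // track.bin_size
    regions: list[tuple[int, int]] = []
    start = prev = hits[0]
    for h in hits[1:]:
        if h - prev - 1 > gap_bins:
            regions.append((start, prev))
            start = h
        prev = h
    regions.append((start, prev))
    best = max(regions, key=lambda r: track.log2_ratio[r[0] : r[1] + 1].sum())
    s, e = best
    return CentromereCall(
        chrom=track.chrom,
        start=int(s * track.bin_size),
        end=int((e + 1) * track.bin_size),
        mean_log2=float(track.log2_ratio[s : e + 1].mean()),
    )


def enrichment_level(call: CentromereCall, track: EnrichmentTrack) -> float:
    """Mean normalized ChIP depth in the call over the genome-wide mean."""
    gw = track.chip.mean()
    if gw == 0:
        raise ValueError("genome-wide mean depth is zero")
    s = call.start // track.bin_size
    e = (call.end + track.bin_size - 1) // track.bin_size
    level = float(track.chip[s:e].mean() / gw)
    call.enrichment_level = level
    return level


def classify_clusters(
    clusters: list[RepeatClusterSummary],
    ratio_min: float = 2.6,
    fraction_min: float = 0.005,
    chip_library: float | None = None,
    input_library: float | None = None,
) -> list[RepeatClusterSummary]:
    """Flag repeat clusters as centromeric.

    The ratio is computed from library-normalized read counts; a cluster is
    centromeric when ratio > ``ratio_min`` AND genome fraction >
    ``fraction_min`` (both strictly).
    """
    ct = chip_library or sum(c.chip_read_count for c in clusters) or 1
    it = input_library or sum(c.input_read_count for c in clusters) or 1
    for c in clusters:
        if np.isnan(c.ratio):
            chip_n = c.chip_read_count / ct
            input_n = c.input_read_count / it
            c.ratio = chip_n / input_n if input_n > 0 else float("inf")
        c.is_centromeric = bool(c.ratio > ratio_min and c.genome_fraction > fraction_min)
    return clusters


def quantile_groups(
    values, n_groups: int = 5, direction: str = "decreasing"
) -> np.ndarray:
    """Rank-based split into ``n_groups`` near-equal groups.

    Group 0 holds the largest values when ``direction='decreasing'``; ties
    keep stable input order; group sizes differ by at most one.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_groups:
        raise ValueError("fewer values than groups")
    order = np.argsort(-values if direction == "decreasing" else values, kind="stable")
    sizes = [n // n_groups + (1 if i < n % n_groups else 0) for i in range(n_groups)]
    labels = np.empty(n, dtype=int)
    pos = 0
    for g, size in enumerate(sizes):
        labels[order[pos : pos + size]] = g
        pos += size
    return labels


def metaprofile(
    track: EnrichmentTrack,
    features: list[tuple[int, int]] | list[tuple[int, int, str]],
    flank: int = 1000,
    body_bins: int = 20,
) -> MetaProfile:
    """Mean signal profile over scaled feature bodies with fixed flanks.

    Each feature body is rescaled to ``body_bins`` (mean of the per-base
    signal falling in each segment); flanks keep the track's native bin
    resolution.  Minus-strand features are flipped before averaging.
    """
    if not features:
        raise ValueError("no features")
    flank_bins = max(0, int(round(flank / track.bin_size)))
    per_base = np.repeat(track.log2_ratio, track.bin_size)
    G = len(per_base)
    profiles = []
    for feat in features:
        s, e = feat[0], feat[1]
        strand = feat[2] if len(feat) > 2 else "+"
        body = np.empty(body_bins)
        edges = np.linspace(s, e, body_bins + 1)
        for j in range(body_bins):
            lo, hi = int(np.floor(edges[j])), int(np.ceil(edges[j + 1]))
            hi = max(hi, lo + 1)
            body[j] = per_base[max(0, lo) : min(G, hi)].mean()
        up = np.empty(flank_bins)
        down = np.empty(flank_bins)
        for j in range(flank_bins):
            us = s - flank + j * track.bin_size
            up[j] = per_base[max(0, us) : max(0, us + track.bin_size)].mean() if us + track.bin_size > 0 else np.nan
            ds = e + j * track.bin_size
            down[j] = per_base[min(G, ds) : min(G, ds + track.bin_size)].mean() if ds < G else np.nan
        row = np.concatenate([up, body, down])
        if strand == "-":
            row = row[::-1]
        profiles.append(row)
    profile = np.nanmean(np.vstack(profiles), axis=0)
    return MetaProfile(len(features), flank_bins, body_bins, profile)


def phase_profile(
    fragment_midpoints,
    monomers: list[MonomerRecord],
    smooth: int = 5,
) -> tuple[np.ndarray, int]:
    """Within-monomer positional density of ChIP fragment midpoints.

    Every midpoint falling inside a monomer is mapped to its strand-aware
    offset within that monomer (offset 0 = consensus position 0).  Returns
    the raw per-offset density over ``0..L-1`` (L = modal monomer length)
    and the peak offset, taken as the argmax of a circularly smoothed copy
    of the density (``smooth`` = moving-average window in bp; 1 disables).
    """
    if not monomers:
        raise ValueError("no monomers")
    lengths = [m.end - m.start for m in monomers]
    L = int(np.bincount(lengths).argmax())
    starts = np.array([m.start for m in monomers])
    ends = np.array([m.end for m in monomers])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    strands = np.array([monomers[i].strand for i in order])
    mids = np.asarray(fragment_midpoints, dtype=int)
    idx = np.searchsorted(starts, mids, side="right") - 1
    density = np.zeros(L)
    n_in = 0
    for mid, i in zip(mids, idx):
        if i < 0 or mid >= ends[i]:
            continue
        ln = ends[i] - starts[i]
        off = mid - starts[i]
        if strands[i] == "-":
            off = ln - 1 - off
        off = int(off * L / ln)  # rescale off-length monomers to the modal frame
        if 0 <= off < L:
            density[off] += 1
            n_in += 1
    if n_in == 0:
        raise ValueError("no fragment midpoints fall inside monomers")
    density /= n_in
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        padded = np.concatenate([density[-(smooth // 2):], density, density[: smooth // 2]])
        smoothed = np.convolve(padded, kernel, mode="valid")[:L]
    else:
        smoothed = density
    return density, int(np.argmax(smoothed))
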