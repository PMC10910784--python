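"""Satellite / retrotransposon interplay.

Insertion-time dating of LTR elements from the divergence of their LTR
pair (T = K / 2r under a molecular clock), the contrast of satellite
identity near CRM insertions versus array interiors, and the per-window
relationship between LTR density and mean satellite identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._align import parse_cigar
import edlib

from .monomerize import MonomerRecord

#: grass-standard substitution clock, substitutions / site / year
DEFAULT_CLOCK_RATE = 1.3e-8


@dataclass
class CRMAnnotation:
    """One annotated CRM retrotransposon with its LTR pair."""

    chrom: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    location_class: str = "centromeric"
    divergence: float = float("nan")
    age_mya: float = float("nan")


@dataclass
class WindowStats:
    chrom: str
    start: int
    end: int
    ltr_density: float
    mean_identity: float
    n_monomers: int


def ltr_divergence(ltr5: str, ltr3: str, correction: str = "JC69") -> float:
    """Divergence K between an element's two LTRs.

    Raw p-distance = mismatches / aligned columns with gap columns
    excluded; the JC69 correction maps p to -(3/4) ln(1 - 4p/3) and is
    undefined (error) for p >= 0.75.
    """
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    res = edlib.align(ltr5.upper(), ltr3.upper(), mode="NW", task="path")
    mismatches = aligned = 0
    for n, op in parse_cigar(res["cigar"]):
        if op == "=":
            aligned += n
        elif op == "X":
            aligned += n
            mismatches += n
        # I/D columns are excluded from the p-distance denominator
    if aligned == 0:
        raise ValueError("no aligned columns")
    p = mismatches / aligned
    if correction.upper() == "NONE" or correction.lower() == "raw":
        return p
    if correction.upper() == "JC69":
        if p >= 0.75:
            raise ValueError(f"JC69 undefined for p = {p:.3f} >= 0.75")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown correction {correction!r}")


def insertion_time(K: float, rate: float = DEFAULT_CLOCK_RATE) -> float:
    """Insertion age in Mya from LTR-pair divergence: T = K / (2 r)."""
    if rate <= 0:
        raise ValueError("clock rate must be > 0")
    if K < 0:
        raise ValueError("divergence must be >= 0")
    return K / (2.0 * rate) / 1e6


def date_crms(
    crms: list[CRMAnnotation],
    chrom_seq: str,
    rate: float = DEFAULT_CLOCK_RATE,
    correction: str = "JC69",
) -> pd.DataFrame:
    """Date each CRM from its LTR pair extracted from the chromosome."""
    rows = []
    for c in crms:
        l5 = chrom_seq[c.ltr5[0] : c.ltr5[1]]
        l3 = chrom_seq[c.ltr3[0] : c.ltr3[1]]
        c.divergence = ltr_divergence(l5, l3, correction)
        c.age_mya = insertion_time(c.divergence, rate)
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "location_class": c.location_class,
                "K": c.divergence,
                "age_mya": c.age_mya,
            }
        )
    return pd.DataFrame(rows)


def crm_adjacent_identity(
    monomers: list[MonomerRecord],
    identities: np.ndarray | list[float],
    crms: list[CRMAnnotation] | list[tuple[int, int]],
    window: int = 5000,
) -> dict:
    """Satellite identity near CRM insertions vs array interiors.

    Monomers overlapping ``[element_start - window, element_end + window)``
    of any CRM form the "near" group; all others are "interior" (every
    monomer lands in exactly one group).  Returns the group values and a
    Welch two-sided t-test; statistics are omitted (with a warning) when a
    group is empty.
    """
    identities = np.asarray(identities, dtype=float)
    spans = [
        (c.start, c.end) if isinstance(c, CRMAnnotation) else (c[0], c[1])
        for c in crms
    ]
    near_mask = np.zeros(len(monomers), dtype=bool)
    for i, m in enumerate(monomers):
        for s, e in spans:
            if m.start < e + window and m.end > s - window:
                near_mask[i] = True
                break
    near = identities[near_mask]
    interior = identities[~near_mask]
    out = {
        "near": near,
        "interior": interior,
        "t": float("nan"),
        "p": float("nan"),
    }
    if len(near) < 2 or len(interior) < 2:
        warnings.warn("one adjacency group is (nearly) empty; t-test omitted")
        return out
    t, p = stats.ttest_ind(near, interior, equal_var=False)
    out["t"], out["p"] = float(t), float(p)
    return out


def ltr_density_vs_identity(
    monomers: list[MonomerRecord],
    identities: np.ndarray | list[float],
    ltr_intervals: list[tuple[int, int]],
    chrom_length: int,
    window: int = 100_000,
    min_monomers: int = 10,
) -> tuple[list[WindowStats], float, float]:
    """Per-window LTR bp density vs mean satellite identity, with Pearson r.

    The chromosome is tiled with half-open windows; windows with fewer than
    ``min_monomers`` monomers are excluded.  The correlation is omitted
    (NaN, with a warning) with fewer than 3 eligible windows or zero
    variance in either variable.
    """
    identities = np.asarray(identities, dtype=float)
    nwin = (chrom_length + window - 1) // window
    ltr_bp = np.zeros(nwin)
    for s, e in ltr_intervals:
        for w in range(max(0, s // window), min(nwin, (e - 1) // window + 1)):
            ws, we = w * window, min((w + 1) * window, chrom_length)
            ltr_bp[w] += max(0, min(e, we) - max(s, ws))
    sums = np.zeros(nwin)
    counts = np.zeros(nwin, dtype=int)
    for m, ident in zip(monomers, identities):
        w = ((m.start + m.end) // 2) // window
        if 0 <= w < nwin:
            sums[w] += ident
            counts[w] += 1
    out: list[WindowStats] = []
    chrom = monomers[0].chrom if monomers else "chr"
    for w in range(nwin):
        if counts[w] < min_monomers:
            continue
        ws, we = w * window, min((w + 1) * window, chrom_length)
        out.append(
            WindowStats(
                chrom, ws, we, ltr_bp[w] / (we - ws), sums[w] / counts[w], int(counts[w])
            )
        )
    if len(out) < 3:
        warnings.warn("fewer than 3 eligible windows; correlation omitted")
        return out, float("nan"), float("nan")
    x = np.array([w.ltr_density for w in out])
    y = np.array([w.mean_identity for w in out])
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance; correlation undefined")
        return out, float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return out, float(r), float(p)
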