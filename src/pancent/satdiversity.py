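"""Satellite diversity statistics.

Identity of individual monomers to a genome-wide consensus, SNP/indel
divergence between consensus pairs, exact-duplicate sharing within and
between chromosomes or genomes, and the 5-mer composition PCA with
hierarchical clustering used to separate satellite families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from ._align import (
    global_unit_alignment,
    identity_from_result,
    infix_align,
    revcomp,
)
from .monomerize import ConsensusRepeat, MonomerRecord


@dataclass
class SharingSummary:
    scope: str
    proportion: float
    n_duplicated: int
    n_total: int


@dataclass
class KmerPCAResult:
    frequencies: np.ndarray  # rows = sequences, columns = 4^k k-mers
    scores: np.ndarray  # rows = sequences, columns = principal components
    explained_variance_ratio: np.ndarray
    labels: np.ndarray | None = None


def identity_to_consensus(monomer: str, consensus: ConsensusRepeat | str) -> float:
    """Identity of a monomer to a consensus over the circularly best phase.

    The consensus is doubled so the alignment can start at any rotation;
    identity = matching columns / total alignment columns (gap columns
    count against identity).
    """
    cons = consensus.sequence if isinstance(consensus, ConsensusRepeat) else consensus
    if not monomer or not cons:
        raise ValueError("empty sequence")
    res = infix_align(monomer.upper(), cons.upper() + cons.upper())
    return identity_from_result(res)


def identity_table(
    monomers: list[MonomerRecord], consensus: ConsensusRepeat
) -> pd.DataFrame:
    """Per-monomer identity table (one row per monomer record)."""
    rows = [
        {
            "monomer_id": f"{m.chrom}:{m.start}-{m.end}",
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "length": m.end - m.start,
            "identity": identity_to_consensus(m.sequence, consensus),
        }
        for m in monomers
    ]
    return pd.DataFrame(rows)


def count_snps_indels(a: str, b: str) -> tuple[int, int]:
    """SNP and indel counts between two sequences.

    Optimal global alignment under unit costs; SNPs are mismatch columns and
    indels are maximal runs of gap columns on one side.  Among co-optimal
    alignments the one with the fewest gap openings (then leftmost gaps) is
    used, making the counts deterministic.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    cols = global_unit_alignment(a.upper(), b.upper())
    n_snp = sum(1 for x, y in cols if x != "-" and y != "-" and x != y)
    n_indel = 0
    prev = None
    for x, y in cols:
        side = "a" if x == "-" else "b" if y == "-" else None
        if side is not None and side != prev:
            n_indel += 1
        prev = side
    return n_snp, n_indel


def _normalized(seq: str) -> str:
    """Strand-normalized form: the smaller of seq and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def duplication_proportion(
    monomers: list[MonomerRecord], scope: str = "within-chromosome"
) -> list[SharingSummary]:
    """Proportion of monomers having an exact duplicate within a scope.

    A monomer counts as duplicated when its strand-normalized sequence
    occurs at least twice in the scope (self excluded).  For
    ``within-chromosome`` one summary per chromosome is returned; for
    ``between-chromosomes`` one summary per chromosome counts monomers
    whose sequence also occurs on a different chromosome.
    """
    if not monomers:
        raise ValueError("empty monomer set")
    if scope not in ("within-chromosome", "between-chromosomes"):
        raise ValueError(f"unknown scope {scope!r}")
    df = pd.DataFrame(
        {
            "chrom": [m.chrom for m in monomers],
            "seq": [_normalized(m.sequence.upper()) for m in monomers],
        }
    )
    out = []
    if scope == "within-chromosome":
        for chrom, grp in df.groupby("chrom", sort=True):
            vc = grp["seq"].value_counts()
            dup = int(grp["seq"].map(vc).gt(1).sum())
            out.append(
                SharingSummary(scope, dup / len(grp), dup, len(grp))
            )
    else:
        for chrom, grp in df.groupby("chrom", sort=True):
            other = set(df.loc[df["chrom"] != chrom, "seq"])
            dup = int(grp["seq"].isin(other).sum())
            out.append(SharingSummary(scope, dup / len(grp), dup, len(grp)))
    return out


def shared_monomer_proportion(
    set_a: list[str] | list[MonomerRecord], set_b: list[str] | list[MonomerRecord]
) -> tuple[float, float]:
    """Fraction of each set whose sequence occurs in the other set.

    Sequences are strand-normalized; returns (A-in-B, B-in-A).
    """

    def _seqs(s):
        return [
            _normalized((m.sequence if isinstance(m, MonomerRecord) else m).upper())
            for m in s
        ]

    a, b = _seqs(set_a), _seqs(set_b)
    if not a or not b:
        raise ValueError("empty monomer set")
    sa, sb = set(a), set(b)
    return (
        sum(1 for s in a if s in sb) / len(a),
        sum(1 for s in b if s in sa) / len(b),
    )


def kmer_table(seqs: list[str], k: int = 5) -> np.ndarray:
    """Row-normalized k-mer frequency matrix over the 4^k alphabet.

    k-mers are counted linearly on the given strand; windows containing
    non-ACGT symbols are dropped before normalization.  Sequences shorter
    than k yield an all-zero row.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    mat = np.zeros((len(seqs), 4**k))
    for r, seq in enumerate(seqs):
        codes = lut[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
        n = len(codes) - k + 1
        if n <= 0:
            continue
        valid = np.ones(n, dtype=bool)
        idx = np.zeros(n, dtype=np.int64)
        for j in range(k):
            c = codes[j : j + n]
            valid &= c >= 0
            idx = idx * 4 + np.where(c >= 0, c, 0)
        idx = idx[valid]
        if len(idx) == 0:
            continue
        np.add.at(mat[r], idx, 1.0)
        mat[r] /= len(idx)
    return mat


def pca_project(matrix: np.ndarray, n_components: int = 100) -> KmerPCAResult:
    """PCA of k-mer frequency rows (mean-centered, unscaled columns).

    Scores are returned for ``min(n_components, rank)`` components; the
    total variance of the scores equals the total centered variance of the
    input when all components are kept.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    n_comp = min(n_components, matrix.shape[0] - 1, matrix.shape[1])
    if np.allclose(matrix.var(axis=0), 0.0):
        # degenerate: identical rows carry no variance to decompose
        return KmerPCAResult(
            frequencies=matrix,
            scores=np.zeros((matrix.shape[0], n_comp)),
            explained_variance_ratio=np.zeros(n_comp),
        )
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(matrix)
    return KmerPCAResult(
        frequencies=matrix,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def hca_groups(scores: np.ndarray, n_groups: int) -> np.ndarray:
    """Hierarchical clustering (Ward linkage, Euclidean) of PC scores.

    Cluster labels are renumbered by first occurrence so they are
    deterministic given input order.
    """
    scores = np.asarray(scores, dtype=float)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n_groups > scores.shape[0]:
        raise ValueError("more groups than rows")
    raw = AgglomerativeClustering(n_clusters=n_groups, linkage="ward").fit_predict(
        scores
    )
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return labels


def subsample_fragments(fragments: list, n: int = 500, seed: int = 0) -> list:
    """Uniform sample of ``n`` fragments without replacement (seeded)."""
    if n > len(fragments):
        raise ValueError(f"cannot sample {n} from {len(fragments)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(fragments), size=n, replace=False)
    return [fragments[i] for i in sorted(idx)]


def group_compare(a, b) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between two score groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
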