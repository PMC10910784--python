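import numpy as np
import pytest

from pancent import ConsensusRepeat, canonical_rotation
from pancent.synthgen import make_consensus


def build_consensus_pair(seed: int = 11, n_snp: int = 19, n_indel: int = 1):
    """Synthetic satellite consensus pair: 156 bp and a partner carrying
    ``n_snp`` planted substitutions plus ``n_indel`` planted 1-bp insertions
    (157 bp for the defaults) — the divergence scale separating the two
    centromeric satellite families this package is designed around.
    """
    cons_a = canonical_rotation(make_consensus(156, 0.45, seed=seed))
    rng = np.random.default_rng(seed + 1)
    # substitution sites spaced >= 4 apart and away from the insertion point,
    # so the planted events are the unique optimal alignment explanation
    pos = rng.choice(np.arange(4, len(cons_a) - 4, 4), n_snp, replace=False)
    chars = list(cons_a)
    for p in pos:
        chars[p] = [b for b in "ACGT" if b != chars[p]][rng.integers(3)]
    for _ in range(n_indel):
        candidates = [
            i
            for i in range(10, len(chars) - 10)
            if i % 4 == 2  # midway between possible substitution sites
        ]
        i = int(rng.choice(candidates))
        base = [b for b in "ACGT" if b != chars[i - 1] and b != chars[i]][0]
        chars.insert(i, base)
    return cons_a, "".join(chars)


@pytest.fixture(scope="session")
def consensus_pair():
    return build_consensus_pair()


@pytest.fixture(scope="session")
def consensus_repeats(consensus_pair):
    a, b = consensus_pair
    return ConsensusRepeat("CentA", a), ConsensusRepeat("CentB", b)
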