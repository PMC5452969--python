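import numpy as np
import pytest

from mitoprofile import (
    FilterPolicy,
    PileupColumn,
    ReadRecord,
    ReferenceGenome,
)


def make_read(
    start,
    bases,
    quals=None,
    cigar=None,
    rid="r",
    mapq=60,
    dup=False,
    secondary=False,
    reverse=False,
):
    if quals is None:
        quals = [40] * len(bases)
    if isinstance(quals, int):
        quals = [quals] * len(bases)
    if cigar is None:
        cigar = (("M", len(bases)),)
    return ReadRecord(
        id=rid,
        mapped_start=start,
        cigar=tuple(cigar),
        bases=bases,
        qualities=np.array(quals, dtype=np.uint8),
        mapping_quality=mapq,
        is_duplicate=dup,
        is_secondary=secondary,
        is_reverse=reverse,
    )


def make_column(counts=None, best_quality=None, deletion_count=0, raw_depth=None, position=1):
    counts = counts or {}
    if best_quality is None:
        best_quality = {b: 40 for b in counts}
    if raw_depth is None:
        raw_depth = sum(counts.values()) + deletion_count
    return PileupColumn(
        position=position,
        counts=dict(counts),
        best_quality=dict(best_quality),
        deletion_count=deletion_count,
        raw_depth=raw_depth,
    )


@pytest.fixture
def small_ref():
    rng = np.random.default_rng(42)
    return ReferenceGenome("toy", "".join(rng.choice(list("ACGT"), size=300)))


@pytest.fixture
def mito_ref():
    """Synthetic 16,569 bp reference at rCRS scale."""
    rng = np.random.default_rng(20259)
    return ReferenceGenome("synthMT", "".join(rng.choice(list("ACGT"), size=16569)))


@pytest.fixture
def default_policy():
    return FilterPolicy()


@pytest.fixture
def toy_tree_file(tmp_path):
    """3-node tree: root R (reference state), A adds G5A, B adds T7C on top."""
    p = tmp_path / "tree.tsv"
    p.write_text("R\t\t\nA\tR\tG5A\nB\tA\tT7C\n")
    return p


def random_column(rng, max_count=30, max_q=45, min_q=30, p_zero=0.15, p_del=0.2):
    """A random filter-passing pileup column for oracle sweeps."""
    counts, bestq = {}, {}
    for b in "ACGT":
        if rng.random() < p_zero:
            continue
        c = int(rng.integers(0, max_count + 1))
        if c > 0:
            counts[b] = c
            bestq[b] = int(rng.integers(min_q, max_q + 1))
    dels = int(rng.integers(0, max_count + 1)) if rng.random() < p_del else 0
    return make_column(counts, bestq, deletion_count=dels)
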