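"""Alignment input, filtering and pileup construction.

Reads a single-sequence mitochondrial reference (FASTA) and a coordinate-
sorted BAM/SAM of reads mapped against it, applies read- and base-level
filters, and builds the per-position pileup matrix that every downstream
analysis (consensus, heteroplasmy, haplogroup scoring, damage) consumes.

Coordinates are 1-based and fully closed throughout the toolkit, matching
rCRS variant nomenclature (C150T is reference position 150).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGT"
# byte -> base code; A=0 C=1 G=2 T=3, everything else (incl. N, IUPAC) = 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

N_CODE = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ReferenceGenome:
    """A single mitochondrial reference sequence (e.g. rCRS, RSRS, chrM)."""

    name: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("reference sequence is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequence[position - 1]

    def codes(self) -> np.ndarray:
        return encode_bases(self.sequence)


def load_reference(path) -> ReferenceGenome:
    """Load the reference FASTA; the file must hold exactly one record.

    The sequence is uppercased and RNA-style U is mapped to T so that
    downstream base bookkeeping only ever sees {A,C,G,T,N}.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no sequence records found in {path}")
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one sequence in {path}, found {len(records)} records"
        )
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    return ReferenceGenome(name=rec.id, sequence=seq)


@dataclass(frozen=True)
class FilterPolicy:
    """Base- and read-level filters applied before any base is counted.

    min_base_quality: phred threshold; a base is counted iff its quality is
        >= the threshold (so the default of 30 admits Q30 bases).
    min_mapping_quality: reads below this MAPQ are excluded entirely.
    """

    min_base_quality: int = 30
    min_mapping_quality: int = 20
    exclude_duplicates: bool = True
    exclude_secondary: bool = True

    def __post_init__(self):
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be >= 0")


@dataclass
class ReadRecord:
    """One aligned single-end read, bases stored in reference orientation."""

    id: str
    mapped_start: int  # 1-based leftmost reference position
    cigar: tuple  # ((op, length), ...) with op in MIDNSHP=X
    bases: str
    qualities: np.ndarray  # uint8 phred scores, one per base
    mapping_quality: int = 60
    is_duplicate: bool = False
    is_secondary: bool = False
    is_unmapped: bool = False
    is_reverse: bool = False

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} qualities"
            )

    def passes_read_filters(self, policy: FilterPolicy) -> bool:
        if self.is_unmapped:
            return False
        if policy.exclude_duplicates and self.is_duplicate:
            return False
        if policy.exclude_secondary and self.is_secondary:
            return False
        return self.mapping_quality >= policy.min_mapping_quality

    def aligned_pairs(self):
        """Yield (ref_position_1based, read_index, is_deletion).

        Deletions yield read_index=None; insertions and soft clips consume
        read bases without yielding reference positions.
        """
        rpos = self.mapped_start
        ri = 0
        for op, length in self.cigar:
            if op in ("M", "=", "X"):
                for k in range(length):
                    yield rpos + k, ri + k, False
                rpos += length
                ri += length
            elif op == "I":
                ri += length
            elif op == "D":
                for k in range(length):
                    yield rpos + k, None, True
                rpos += length
            elif op == "N":
                rpos += length
            elif op == "S":
                ri += length
            elif op in ("H", "P"):
                pass
            else:
                raise ValueError(f"read {self.id}: unsupported CIGAR op {op!r}")

    def reference_end(self) -> int:
        """Last reference position covered (1-based, inclusive)."""
        span = sum(l for op, l in self.cigar if op in ("M", "=", "X", "D", "N"))
        return self.mapped_start + span - 1


_CIGAR_OPS = "MIDNSHP=X"


def read_alignment(path, reference: ReferenceGenome | None = None) -> list[ReadRecord]:
    """Read a BAM or SAM file into ReadRecord objects (mapped reads only).

    pysam auto-detects the container; an index is not required because the
    mitochondrial genome is small enough to stream whole.
    """
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            quals = aln.query_qualities
            records.append(
                ReadRecord(
                    id=aln.query_name,
                    mapped_start=aln.reference_start + 1,
                    cigar=tuple((_CIGAR_OPS[op], ln) for op, ln in aln.cigartuples),
                    bases=aln.query_sequence or "",
                    qualities=np.asarray(quals, dtype=np.uint8)
                    if quals is not None
                    else np.zeros(len(aln.query_sequence or ""), dtype=np.uint8),
                    mapping_quality=aln.mapping_quality,
                    is_duplicate=aln.is_duplicate,
                    is_secondary=aln.is_secondary or aln.is_supplementary,
                    is_unmapped=False,
                    is_reverse=aln.is_reverse,
                )
            )
    if reference is not None:
        for r in records:
            if r.reference_end() > reference.length:
                raise ValueError(
                    f"read {r.id} extends past reference end "
                    f"({r.reference_end()} > {reference.length})"
                )
    return records


@dataclass
class PileupColumn:
    """Quality-filtered base counts at one reference position."""

    position: int
    counts: dict  # base -> count, only filter-passing A/C/G/T
    best_quality: dict  # base -> max phred among counted bases
    deletion_count: int
    raw_depth: int

    @property
    def filtered_depth(self) -> int:
        return sum(self.counts.values()) + self.deletion_count


class Pileup:
    """Dense per-position pileup over the whole reference.

    Backed by numpy arrays; `column(pos)` gives the per-site dict view used
    by the site-level operations.
    """

    def __init__(self, ref_length: int):
        self.ref_length = ref_length
        self.counts = np.zeros((ref_length, 4), dtype=np.int64)
        self.best_quality = np.full((ref_length, 4), -1, dtype=np.int16)
        self.deletion_count = np.zeros(ref_length, dtype=np.int64)
        self.raw_depth = np.zeros(ref_length, dtype=np.int64)

    @property
    def filtered_depth(self) -> np.ndarray:
        return self.counts.sum(axis=1) + self.deletion_count

    def column(self, position: int) -> PileupColumn:
        i = position - 1
        counts = {}
        bestq = {}
        for b, base in enumerate(BASES):
            c = int(self.counts[i, b])
            if c > 0:
                counts[base] = c
                bestq[base] = int(self.best_quality[i, b])
        return PileupColumn(
            position=position,
            counts=counts,
            best_quality=bestq,
            deletion_count=int(self.deletion_count[i]),
            raw_depth=int(self.raw_depth[i]),
        )

    def __len__(self):
        return self.ref_length

    def __iter__(self):
        for pos in range(1, self.ref_length + 1):
            yield self.column(pos)


def _simple_match_cigar(read: ReadRecord) -> bool:
    return len(read.cigar) == 1 and read.cigar[0][0] in ("M", "=", "X")


_warned_ambiguous = False


def build_pileup(
    reads, ref: ReferenceGenome, policy: FilterPolicy | None = None
) -> Pileup:
    """Build the pileup matrix from aligned reads.

    A base is counted iff its read passes the read-level filters, its phred
    quality is >= policy.min_base_quality and it is one of A/C/G/T; N and
    IUPAC-ambiguous bases are never counted (logged once). CIGAR deletions
    increment deletion_count (deletions carry no quality and always pass).
    raw_depth counts every reference position spanned by a read passing the
    read-level filters, before the base-quality filter.
    """
    global _warned_ambiguous
    if policy is None:
        policy = FilterPolicy()
    pile = Pileup(ref.length)
    kept = [r for r in reads if r.passes_read_filters(policy)]
    for r in kept:
        if r.mapped_start < 1 or r.reference_end() > ref.length:
            raise ValueError(
                f"read {r.id} extends outside the reference "
                f"[{r.mapped_start}, {r.reference_end()}] vs length {ref.length}; "
                "origin-spanning (circular) alignments are not supported"
            )

    # fast path: plain fully-aligned reads, vectorised in batch
    simple = [r for r in kept if _simple_match_cigar(r)]
    complex_ = [r for r in kept if not _simple_match_cigar(r)]

    if simple:
        lens = np.array([len(r.bases) for r in simple], dtype=np.int64)
        starts = np.array([r.mapped_start - 1 for r in simple], dtype=np.int64)
        # positions: for each read, start + 0..len-1, laid out contiguously
        total = int(lens.sum())
        step = np.ones(total, dtype=np.int64)
        head = np.cumsum(lens)[:-1]
        step[0] = starts[0]
        step[head] = starts[1:] - starts[:-1] - lens[:-1] + 1
        pos = np.cumsum(step)
        codes = encode_bases("".join(r.bases for r in simple))
        quals = np.concatenate([r.qualities for r in simple]).astype(np.int16)
        pile.raw_depth += np.bincount(pos, minlength=ref.length)
        ok = (codes < 4) & (quals >= policy.min_base_quality)
        flat = pos[ok] * 4 + codes[ok]
        pile.counts += np.bincount(flat, minlength=ref.length * 4).reshape(-1, 4)
        np.maximum.at(pile.best_quality, (pos[ok], codes[ok]), quals[ok])
        if not _warned_ambiguous and np.any(
            codes == 4
        ):  # N or IUPAC codes: uncounted
            _warned_ambiguous = True
            logger.warning("non-ACGT bases present in reads; treated as N (uncounted)")

    for r in complex_:
        codes = encode_bases(r.bases)
        for rpos, ri, is_del in r.aligned_pairs():
            i = rpos - 1
            pile.raw_depth[i] += 1
            if is_del:
                pile.deletion_count[i] += 1
                continue
            c = codes[ri]
            q = int(r.qualities[ri])
            if c < 4 and q >= policy.min_base_quality:
                pile.counts[i, c] += 1
                if q > pile.best_quality[i, c]:
                    pile.best_quality[i, c] = q
            elif c == 4 and not _warned_ambiguous:
                _warned_ambiguous = True
                logger.warning(
                    "non-ACGT bases present in reads; treated as N (uncounted)"
                )
    return pile


@dataclass
class SummaryStats:
    """Run-level QC statistics of the alignment."""

    total_reads: int
    mapped_reads: int
    duplicate_reads: int
    depth: dict
    read_length: dict
    gc_content: dict
    mapping_quality: dict
    base_quality: dict
    coverage_breadth: dict  # depth threshold -> fraction of genome strictly above
    no_data: bool = False

    def as_flat_dict(self) -> dict:
        out = {
            "total_reads": self.total_reads,
            "mapped_reads": self.mapped_reads,
            "duplicate_reads": self.duplicate_reads,
            "no_data": self.no_data,
        }
        for name, d in [
            ("depth", self.depth),
            ("read_length", self.read_length),
            ("gc_content", self.gc_content),
            ("mapping_quality", self.mapping_quality),
            ("base_quality", self.base_quality),
        ]:
            for k, v in d.items():
                out[f"{name}_{k}"] = v
        for t, frac in self.coverage_breadth.items():
            out[f"breadth_gt_{t}"] = frac
        return out


def _dist_stats(values: np.ndarray) -> dict:
    if values.size == 0:
        return {"mean": 0.0, "std": 0.0, "min": 0.0, "q1": 0.0, "median": 0.0, "q3": 0.0, "max": 0.0}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "mean": float(np.mean(values)),
        "std": float(np.std(values)),
        "min": float(np.min(values)),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(np.max(values)),
    }


DEFAULT_BREADTH_THRESHOLDS = (10, 20, 30, 40, 50)


def gc_content(bases: str) -> float:
    """(G+C) / read length over A/C/G/T bases, ignoring N."""
    codes = encode_bases(bases)
    acgt = codes < 4
    n = int(acgt.sum())
    if n == 0:
        return 0.0
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n


def summarize_alignment(
    reads,
    pileup: Pileup,
    ref: ReferenceGenome,
    breadth_thresholds=DEFAULT_BREADTH_THRESHOLDS,
) -> SummaryStats:
    """Depth-of-coverage, GC-content, quality and read-length summaries.

    Depth statistics are computed over raw_depth at every reference position;
    coverage breadth at threshold t is the fraction of the genome with depth
    strictly greater than t.
    """
    reads = list(reads)
    total = len(reads)
    mapped = sum(1 for r in reads if not r.is_unmapped)
    dups = sum(1 for r in reads if r.is_duplicate)
    depth = pileup.raw_depth.astype(float)
    no_data = mapped == 0

    lengths = np.array([len(r.bases) for r in reads if not r.is_unmapped], dtype=float)
    gcs = np.array([gc_content(r.bases) for r in reads if not r.is_unmapped])
    mapqs = np.array([r.mapping_quality for r in reads if not r.is_unmapped], dtype=float)
    if reads:
        bquals = np.concatenate([r.qualities for r in reads if not r.is_unmapped]) if mapped else np.array([])
    else:
        bquals = np.array([])

    breadth = {
        int(t): float(np.mean(depth > t)) if depth.size else 0.0
        for t in breadth_thresholds
    }
    return SummaryStats(
        total_reads=total,
        mapped_reads=mapped,
        duplicate_reads=dups,
        depth=_dist_stats(depth if not no_data else np.array([])),
        read_length=_dist_stats(lengths),
        gc_content=_dist_stats(gcs),
        mapping_quality=_dist_stats(mapqs),
        base_quality=_dist_stats(np.asarray(bquals, dtype=float)),
        coverage_breadth=breadth,
        no_data=no_data,
    )


def write_sam(reads, ref: ReferenceGenome, path) -> None:
    """Write ReadRecords as a SAM file with a single @SQ header line."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.name, "LN": ref.length}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in sorted(reads, key=lambda x: x.mapped_start):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.id
            a.query_sequence = r.bases
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qualities)
            )
            a.reference_id = 0
            a.reference_start = r.mapped_start - 1
            a.mapping_quality = r.mapping_quality
            a.cigarstring = "".join(f"{ln}{op}" for op, ln in r.cigar)
            flag = 0
            if r.is_reverse:
                flag |= 16
            if r.is_duplicate:
                flag |= 1024
            if r.is_secondary:
                flag |= 256
            a.flag = flag
            out.write(a)
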