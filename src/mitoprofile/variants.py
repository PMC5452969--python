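"""Heteroplasmy detection, consensus-vs-reference variants and annotation.

Heteroplasmic sites are scored by the minor-allele statistic

    MAF = N_diff / N_con

where N_diff is the number of filtered bases carrying the candidate allele
and N_con the number carrying the consensus base at the site. Note this is a
ratio to the concordant bases, not to total depth, and therefore exceeds 1
when a non-consensus allele outnumbers the consensus; the conventional
fraction N_diff / (N_diff + N_con) is reported alongside it in output tables
for comparison.

Consensus-vs-reference variants are derived from a deterministic global
pairwise alignment (match +1, mismatch -1, gap -2) and labelled in rCRS-style
nomenclature: C150T for a substitution, C150d for a deletion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .alignment_io import BASES, FilterPolicy, Pileup, ReferenceGenome, encode_bases
from .consensus import ConsensusSequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# variant labels

_SUB_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_DEL_RE = re.compile(r"^([ACGT])(\d+)d$")


@dataclass(frozen=True)
class Variant:
    """A consensus-vs-reference difference in rCRS-style nomenclature."""

    position: int
    ref: str
    alt: str  # 'd' for a deletion
    kind: str  # 'substitution' | 'deletion'

    @property
    def label(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"

    @classmethod
    def parse(cls, label: str) -> "Variant":
        m = _SUB_RE.match(label)
        if m:
            ref, pos, alt = m.groups()
            if ref == alt:
                raise ValueError(f"variant {label!r} has identical ref and alt")
            return cls(int(pos), ref, alt, "substitution")
        m = _DEL_RE.match(label)
        if m:
            ref, pos = m.groups()
            return cls(int(pos), ref, "d", "deletion")
        raise ValueError(f"cannot parse variant label {label!r}")


# ---------------------------------------------------------------------------
# heteroplasmy


def site_maf(column, consensus_base: str, allele: str) -> float:
    """MAF = N_diff / N_con for one candidate allele at one site."""
    if allele == consensus_base:
        raise ValueError("allele must differ from the consensus base")
    n_con = column.counts.get(consensus_base, 0)
    if n_con == 0:
        raise ValueError("MAF undefined when no base supports the consensus")
    n_diff = column.counts.get(allele, 0)
    return n_diff / n_con


@dataclass
class HeteroplasmySite:
    position: int
    consensus_base: str
    minor_alleles: dict  # base -> (count, maf)
    filtered_depth: int
    flagged: bool

    @property
    def max_maf(self) -> float:
        return max((m for _, m in self.minor_alleles.values()), default=0.0)


def detect_heteroplasmy(
    pileup: Pileup,
    consensus: ConsensusSequence,
    maf_threshold: float = 0.10,
    min_depth: int = 10,
) -> list[HeteroplasmySite]:
    """Flag sites where a non-consensus allele exceeds the MAF threshold.

    A site is reported iff its filtered depth is >= min_depth, the consensus
    base is a real base (A/C/G/T) and some other allele has
    MAF strictly greater than maf_threshold. Sorted by position.
    """
    if maf_threshold < 0:
        raise ValueError("maf_threshold must be >= 0")
    codes = consensus.codes
    counts = pileup.counts
    depth = pileup.filtered_depth
    called = codes < 4
    idx = np.nonzero(called & (depth >= min_depth))[0]
    cons_counts = counts[idx, codes[idx].astype(np.intp)]
    # N_con = 0 cannot occur for a majority/bestscore-called base, but guard anyway
    ok = cons_counts > 0
    idx, cons_counts = idx[ok], cons_counts[ok]
    mafs = counts[idx] / cons_counts[:, None]
    mafs[np.arange(len(idx)), codes[idx].astype(np.intp)] = 0.0
    hit = (mafs > maf_threshold).any(axis=1)
    out = []
    for i, row in zip(idx[hit], mafs[hit]):
        cons = "ACGT"[codes[i]]
        minors = {
            BASES[b]: (int(counts[i, b]), float(row[b]))
            for b in range(4)
            if BASES[b] != cons and counts[i, b] > 0
        }
        out.append(
            HeteroplasmySite(
                position=int(i) + 1,
                consensus_base=cons,
                minor_alleles=minors,
                filtered_depth=int(depth[i]),
                flagged=True,
            )
        )
    return out


def heteroplasmy_table(sites: list[HeteroplasmySite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        n_con = s.filtered_depth  # recomputed below per allele from counts
        for allele, (count, maf) in sorted(s.minor_alleles.items()):
            rows.append(
                {
                    "position": s.position,
                    "consensus": s.consensus_base,
                    "minor_allele": allele,
                    "minor_count": count,
                    "maf": maf,
                    # conventional minor fraction (not the headline statistic)
                    "minor_fraction": count / (count + count / maf) if maf > 0 else 0.0,
                    "filtered_depth": s.filtered_depth,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "consensus", "minor_allele", "minor_count",
            "maf", "minor_fraction", "filtered_depth",
        ],
    )


# ---------------------------------------------------------------------------
# consensus-vs-reference alignment and variant calling

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH_SCORE
    a.mismatch_score = MISMATCH_SCORE
    a.open_gap_score = GAP_SCORE
    a.extend_gap_score = GAP_SCORE
    return a


def alignment_score(seq_a: str, seq_b: str) -> float:
    """Optimal global alignment score under the fixed published scoring."""
    return float(_aligner().score(seq_a, seq_b))


@dataclass
class PositionMap:
    """Monotonic partial mapping consensus index <-> reference position.

    pairs: list of (consensus_position_1based, reference_position_1based)
    for aligned (substitution or match) columns; reference positions absent
    from the map were deleted in the consensus, consensus positions absent
    were inserted relative to the reference.
    """

    pairs: list
    consensus_length: int
    reference_length: int
    score: float

    def ref_to_consensus(self) -> dict:
        return {r: c for c, r in self.pairs}

    def consensus_to_ref(self) -> dict:
        return {c: r for c, r in self.pairs}

    @property
    def deleted_reference_positions(self) -> list:
        mapped = {r for _, r in self.pairs}
        return [r for r in range(1, self.reference_length + 1) if r not in mapped]

    @property
    def inserted_consensus_positions(self) -> list:
        mapped = {c for c, _ in self.pairs}
        return [c for c in range(1, self.consensus_length + 1) if c not in mapped]


def align_consensus_to_reference(consensus_seq: str, ref: ReferenceGenome) -> PositionMap:
    """Global pairwise alignment of the consensus against the reference.

    Deterministic: of co-optimal alignments the aligner's first traceback is
    taken. N consensus bases align as mismatches, never as errors.
    """
    if not consensus_seq:
        raise ValueError("consensus sequence is empty")
    aligner = _aligner()
    alignments = aligner.align(ref.sequence, consensus_seq)
    aln = alignments[0]
    pairs = []
    for (r0, r1), (c0, c1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            pairs.append((c0 + k + 1, r0 + k + 1))
    return PositionMap(
        pairs=pairs,
        consensus_length=len(consensus_seq),
        reference_length=ref.length,
        score=float(aln.score),
    )


def call_variants(
    consensus_seq: str, ref: ReferenceGenome, position_map: PositionMap
) -> tuple[list[Variant], list[int]]:
    """Variants of the consensus relative to the reference.

    Returns (variants, inserted_consensus_positions). Substitutions where the
    consensus base is N produce no variant (no-call). Deletions are reference
    positions absent from the position map. Insertions carry no rCRS-style
    label and are returned as a side list of consensus positions.
    """
    variants = []
    for c, r in position_map.pairs:
        cb = consensus_seq[c - 1]
        rb = ref.base(r)
        if cb in "ACGT" and rb in "ACGT" and cb != rb:
            variants.append(Variant(r, rb, cb, "substitution"))
    for r in position_map.deleted_reference_positions:
        rb = ref.base(r)
        if rb in "ACGT":
            variants.append(Variant(r, rb, "d", "deletion"))
    variants.sort(key=lambda v: v.position)
    return variants, position_map.inserted_consensus_positions


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class AnnotationRecord:
    variant_label: str
    info: str
    source: str


def load_annotation_db(path, source: str | None = None) -> tuple[list[AnnotationRecord], int]:
    """Parse a two-column CSV annotation database (allele, information).

    A header row is tolerated (detected by an unparseable first-row allele).
    Malformed rows are skipped with a warning; the skip count is returned so
    the run report can surface it.
    """
    name = source or str(path)
    df = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"annotation DB {path} needs two columns (allele, info)")
    records, skipped = [], 0
    for i, row in df.iterrows():
        label = str(row[0]).strip()
        try:
            Variant.parse(label)
        except ValueError:
            if i == 0:
                continue  # header row
            skipped += 1
            logger.warning("annotation DB %s row %d: unparseable allele %r", name, i + 1, label)
            continue
        records.append(AnnotationRecord(label, str(row[1]), name))
    return records, skipped


def annotate_variants(variants: list[Variant], db: list[AnnotationRecord]) -> pd.DataFrame:
    """Join called variants against annotation records on exact label match.

    Every variant appears in the output; unmatched ones carry empty
    annotation fields, and every matching DB row for an allele is reported.
    """
    index: dict[str, list[AnnotationRecord]] = {}
    for rec in db:
        index.setdefault(rec.variant_label, []).append(rec)
    rows = []
    for v in variants:
        hits = index.get(v.label, [])
        if not hits:
            rows.append({"variant": v.label, "position": v.position, "type": v.kind,
                         "info": "", "source": ""})
        for rec in hits:
            rows.append({"variant": v.label, "position": v.position, "type": v.kind,
                         "info": rec.info, "source": rec.source})
    return pd.DataFrame(rows, columns=["variant", "position", "type", "info", "source"])


# ---------------------------------------------------------------------------
# base-substitution spectrum

SPECTRUM_KEYS = tuple(f"{r}>{q}" for r in BASES for q in BASES if r != q)


@dataclass
class SubstitutionSpectrum:
    """Counts and percentages of the 12 ordered ref->read substitutions."""

    counts: dict  # "A>C" -> int
    no_mismatches: bool

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict:
        t = self.total
        if t == 0:
            return {k: 0.0 for k in SPECTRUM_KEYS}
        return {k: v / t * 100.0 for k, v in self.counts.items()}

    def as_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {"substitution": list(SPECTRUM_KEYS),
             "count": [self.counts[k] for k in SPECTRUM_KEYS],
             "percent": [pct[k] for k in SPECTRUM_KEYS]}
        )


def substitution_spectrum(
    reads, ref: ReferenceGenome, policy: FilterPolicy | None = None
) -> SubstitutionSpectrum:
    """Genome-wide spectrum of read bases differing from the reference.

    Every aligned, quality-filtered read base that differs from the reference
    base is tallied by (reference base -> read base); percentages are
    normalised over all mismatches.
    """
    if policy is None:
        policy = FilterPolicy()
    ref_codes = ref.codes()
    table = np.zeros((4, 4), dtype=np.int64)
    for r in reads:
        if not r.passes_read_filters(policy):
            continue
        codes = encode_bases(r.bases)
        for rpos, ri, is_del in r.aligned_pairs():
            if is_del:
                continue
            c = codes[ri]
            if c >= 4 or r.qualities[ri] < policy.min_base_quality:
                continue
            rc = ref_codes[rpos - 1]
            if rc < 4 and rc != c:
                table[rc, c] += 1
    counts = {
        f"{BASES[i]}>{BASES[j]}": int(table[i, j])
        for i in range(4)
        for j in range(4)
        if i != j
    }
    return SubstitutionSpectrum(counts=counts, no_mismatches=sum(counts.values()) == 0)
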