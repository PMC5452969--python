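"""Ancient-DNA damage indicators.

Post-mortem cytosine deamination shows up as C→T substitutions enriched at
the 5′ ends of fragments (and complementary G→A at 3′ ends), together with
short fragment lengths. This module computes per-read-offset substitution
rates anchored at both fragment ends plus the read-length distribution; it
fits no damage model — these are the standard descriptive indicators.

Offsets are expressed in original-molecule coordinates: reads flagged as
reverse-strand (whose stored bases are reference-oriented) have their offsets
counted from the opposite end and their base pairs complemented, so a 5′
C→T event is tallied as such regardless of the strand sequenced.

Rates default to a base-quality floor of 20 rather than the pileup's 30:
damage bases are genuine low-frequency mismatches and an aggressive quality
cut biases the rates downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .alignment_io import BASES, FilterPolicy, ReferenceGenome, encode_bases

# complement in code space: A<->T, C<->G, N stays N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

DEFAULT_DAMAGE_POLICY = FilterPolicy(min_base_quality=20)


@dataclass
class DamageProfile:
    """Per-offset substitution rates anchored at the 5′ and 3′ fragment ends.

    subs_5p / subs_3p: (K, 4, 4) mismatch count tensors indexed by
    (offset-1, ref base, read base); denom_5p / denom_3p: (K, 4) counts of
    eligible reference bases per offset. A rate at an offset with zero
    eligible positions is NaN (missing), never 0.
    """

    K: int
    subs_5p: np.ndarray
    subs_3p: np.ndarray
    denom_5p: np.ndarray
    denom_3p: np.ndarray
    read_lengths: np.ndarray

    def rate(self, end: str, ref_base: str, read_base: str) -> np.ndarray:
        """Length-K array of rates for one substitution at one end."""
        subs = self.subs_5p if end == "5p" else self.subs_3p
        denom = self.denom_5p if end == "5p" else self.denom_3p
        i, j = BASES.index(ref_base), BASES.index(read_base)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom[:, i] > 0, subs[:, i, j] / np.maximum(denom[:, i], 1), np.nan)

    @property
    def rate_5p(self) -> dict:
        """offset -> C→T rate at the 5′ end (NaN where no reference C seen)."""
        r = self.rate("5p", "C", "T")
        return {o + 1: float(r[o]) for o in range(self.K)}

    @property
    def rate_3p(self) -> dict:
        """offset -> G→A rate at the 3′ end."""
        r = self.rate("3p", "G", "A")
        return {o + 1: float(r[o]) for o in range(self.K)}

    def as_frame(self, end: str) -> pd.DataFrame:
        rows = {"offset": np.arange(1, self.K + 1)}
        for rb in BASES:
            for qb in BASES:
                if rb == qb:
                    continue
                rows[f"{rb}>{qb}"] = self.rate(end, rb, qb)
        return pd.DataFrame(rows)


def damage_profile(
    reads,
    ref: ReferenceGenome,
    policy: FilterPolicy | None = None,
    K: int = 25,
) -> DamageProfile:
    """Substitution rates at read offsets 1..K from each fragment end.

    rate_5p[o] = (# aligned positions at molecule 5′ offset o with ref C read
    as T) / (# aligned positions at that offset with ref C), after strand
    normalization; symmetrically G→A for the 3′ end. Bases failing the
    quality filter and non-ACGT bases are excluded from numerator and
    denominator alike.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if policy is None:
        policy = DEFAULT_DAMAGE_POLICY
    ref_codes = ref.codes()
    subs_5p = np.zeros((K, 4, 4), dtype=np.int64)
    subs_3p = np.zeros((K, 4, 4), dtype=np.int64)
    denom_5p = np.zeros((K, 4), dtype=np.int64)
    denom_3p = np.zeros((K, 4), dtype=np.int64)
    lengths = []
    longest = 0
    for r in reads:
        if not r.passes_read_filters(policy):
            continue
        n = len(r.bases)
        lengths.append(n)
        longest = max(longest, n)
        codes = encode_bases(r.bases)
        if len(r.cigar) == 1 and r.cigar[0][0] in ("M", "=", "X"):
            ridx = np.arange(n, dtype=np.int64)
            rpos = r.mapped_start + ridx
        else:
            pairs = [(rp, ri) for rp, ri, is_del in r.aligned_pairs() if not is_del]
            if not pairs:
                continue
            rpos = np.fromiter((p[0] for p in pairs), dtype=np.int64)
            ridx = np.fromiter((p[1] for p in pairs), dtype=np.int64)
        read_c = codes[ridx]
        ref_c = ref_codes[rpos - 1]
        ok = (read_c < 4) & (ref_c < 4) & (r.qualities[ridx] >= policy.min_base_quality)
        if r.is_reverse:
            # molecule coordinates: offsets flip ends, bases complement
            off5 = n - 1 - ridx  # 0-based offset from molecule 5' end
            read_c = _COMP[read_c]
            ref_c = _COMP[ref_c]
        else:
            off5 = ridx
        off3 = n - 1 - off5
        read_c = read_c.astype(np.intp)
        ref_c = ref_c.astype(np.intp)
        m5 = ok & (off5 < K)
        m3 = ok & (off3 < K)
        np.add.at(denom_5p, (off5[m5], ref_c[m5]), 1)
        np.add.at(denom_3p, (off3[m3], ref_c[m3]), 1)
        mm5 = m5 & (ref_c != read_c)
        mm3 = m3 & (ref_c != read_c)
        np.add.at(subs_5p, (off5[mm5], ref_c[mm5], read_c[mm5]), 1)
        np.add.at(subs_3p, (off3[mm3], ref_c[mm3], read_c[mm3]), 1)
    if lengths and K > longest:
        warnings.warn(
            f"K={K} exceeds the longest read ({longest} bp); rates computed "
            "over available offsets only",
            stacklevel=2,
        )
    return DamageProfile(
        K=K,
        subs_5p=subs_5p,
        subs_3p=subs_3p,
        denom_5p=denom_5p,
        denom_3p=denom_3p,
        read_lengths=np.array(lengths, dtype=np.int64),
    )


@dataclass
class FragmentationSummary:
    mean: float
    median: float
    bin_width: int
    histogram: dict  # bin lower edge -> count

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length_bin_start": list(self.histogram),
             "count": list(self.histogram.values())}
        )


def fragmentation_summary(reads, bin_width: int = 5) -> FragmentationSummary:
    """Read-length histogram (fixed-width bins) with mean and median."""
    lengths = np.array([len(r.bases) for r in reads if not r.is_unmapped], dtype=int)
    if lengths.size == 0:
        return FragmentationSummary(0.0, 0.0, bin_width, {})
    lo = int(lengths.min() // bin_width * bin_width)
    hi = int(lengths.max() // bin_width * bin_width) + bin_width
    edges = np.arange(lo, hi + 1, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    hist = {int(edges[i]): int(counts[i]) for i in range(len(counts)) if counts[i] > 0}
    return FragmentationSummary(
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        bin_width=bin_width,
        histogram=hist,
    )
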