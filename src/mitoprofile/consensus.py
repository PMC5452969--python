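"""Consensus base calling under three site rules.

Every reference position is called from its quality-filtered pileup column
under one of three modes:

* ``majority`` — the most frequently read base wins; a tie among the top
  counts yields ``N`` (no uncertain calls are forced).
* ``bestscore`` — the base with the strictly highest best phred score among
  observed bases wins, regardless of read depth; a tie in the maximum score
  yields ``N``.
* ``majority+bestscore`` — majority first; count ties (with data) are broken
  by the highest best phred score among the tied bases, and only a double tie
  yields ``N``.

A site whose deletion count strictly exceeds every base count is called
``-`` under the majority-based modes; deletions carry no phred score, so the
pure best-score mode ignores them. The consensus FASTA drops ``-`` sites and
keeps ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import BASES, FilterPolicy, Pileup, PileupColumn

MODES = ("majority", "bestscore", "majority+bestscore")

_MODE_ALIASES = {
    "majority": "majority",
    "bestscore": "bestscore",
    "best-score": "bestscore",
    "majority+bestscore": "majority+bestscore",
    "majority-bestscore": "majority+bestscore",
}


def normalize_mode(mode: str) -> str:
    try:
        return _MODE_ALIASES[mode.lower()]
    except KeyError:
        raise ValueError(
            f"unknown consensus mode {mode!r}; valid modes are "
            "'majority', 'bestscore', 'majority+bestscore'"
        ) from None


def call_site_majority(column: PileupColumn) -> str:
    """Most-read base; 'N' on a count tie or no data; '-' if deletions dominate."""
    counts = column.counts
    max_count = max(counts.values()) if counts else 0
    if column.deletion_count > max_count:
        return "-"
    if max_count == 0:
        return "N"
    top = [b for b, c in counts.items() if c == max_count]
    if len(top) > 1:
        return "N"
    return top[0]


def call_site_bestscore(column: PileupColumn) -> str:
    """Base with the strictly highest best phred score; 'N' on ties or no data."""
    bq = column.best_quality
    if not bq:
        return "N"
    max_q = max(bq.values())
    top = [b for b, q in bq.items() if q == max_q]
    if len(top) > 1:
        return "N"
    return top[0]


def call_site_combined(column: PileupColumn) -> str:
    """Majority first; count ties broken by best phred score among tied bases."""
    maj = call_site_majority(column)
    if maj != "N":
        return maj
    counts = column.counts
    max_count = max(counts.values()) if counts else 0
    if max_count == 0:
        return "N"  # no data: nothing for best-score to call either
    tied = [b for b, c in counts.items() if c == max_count]
    best_q = max(column.best_quality[b] for b in tied)
    winners = [b for b in tied if column.best_quality[b] == best_q]
    if len(winners) > 1:
        return "N"
    return winners[0]


_SITE_CALLERS = {
    "majority": call_site_majority,
    "bestscore": call_site_bestscore,
    "majority+bestscore": call_site_combined,
}


def call_site(column: PileupColumn, mode: str) -> str:
    return _SITE_CALLERS[normalize_mode(mode)](column)


def support_ratio(column: PileupColumn, called_base: str) -> float | None:
    """Percent of filtered bases at the site agreeing with the consensus base.

    P_support = (N_agree / N_depth) x 100 with N_depth the filtered depth.
    Returns None (missing) at zero-depth sites. Undefined for 'N' calls.
    """
    if called_base == "N":
        raise ValueError("support ratio is undefined for a no-call (N)")
    if called_base not in "ACGT-":
        raise ValueError(f"invalid consensus base {called_base!r}")
    depth = column.filtered_depth
    if depth == 0:
        return None
    if called_base == "-":
        agree = column.deletion_count
    else:
        agree = column.counts.get(called_base, 0)
    return agree / depth * 100.0


# ---------------------------------------------------------------------------
# vectorised genome-wide calling

GAP_CODE = 5  # consensus '-' ; N is 4
CONSENSUS_ALPHABET = "ACGTN-"


def majority_codes(pileup: Pileup) -> np.ndarray:
    """Vectorised majority call for every position (codes into 'ACGTN-')."""
    counts = pileup.counts
    max_count = counts.max(axis=1)
    n_top = (counts == max_count[:, None]).sum(axis=1)
    best = counts.argmax(axis=1).astype(np.int8)
    out = np.where((max_count > 0) & (n_top == 1), best, 4).astype(np.int8)
    out[pileup.deletion_count > max_count] = GAP_CODE
    return out


def bestscore_codes(pileup: Pileup) -> np.ndarray:
    bq = pileup.best_quality
    max_q = bq.max(axis=1)
    n_top = (bq == max_q[:, None]).sum(axis=1)
    best = bq.argmax(axis=1).astype(np.int8)
    return np.where((max_q >= 0) & (n_top == 1), best, 4).astype(np.int8)


def combined_codes(pileup: Pileup) -> np.ndarray:
    maj = majority_codes(pileup)
    counts = pileup.counts
    max_count = counts.max(axis=1)
    tie = (maj == 4) & (max_count > 0)
    if np.any(tie):
        # among count-tied bases, pick the strictly best phred score
        bq = np.where(counts[tie] == max_count[tie, None], pileup.best_quality[tie], -1)
        q_max = bq.max(axis=1)
        n_top = (bq == q_max[:, None]).sum(axis=1)
        pick = bq.argmax(axis=1).astype(np.int8)
        maj[tie] = np.where(n_top == 1, pick, 4)
    return maj


_CODE_CALLERS = {
    "majority": majority_codes,
    "bestscore": bestscore_codes,
    "majority+bestscore": combined_codes,
}


@dataclass
class ConsensusSite:
    position: int
    base: str
    mode: str
    n_agree: int
    support_pct: float | None
    filtered_depth: int


class ConsensusSequence:
    """Genome-wide consensus with per-site support, array-backed."""

    def __init__(
        self,
        codes: np.ndarray,
        n_agree: np.ndarray,
        filtered_depth: np.ndarray,
        mode: str,
        policy: FilterPolicy,
        reference_name: str,
    ):
        self.codes = codes
        self.n_agree = n_agree
        self.filtered_depth = filtered_depth
        self.mode = mode
        self.policy = policy
        self.reference_name = reference_name

    def __len__(self):
        return len(self.codes)

    @property
    def support_pct(self) -> np.ndarray:
        """P_support per position; NaN where depth is 0 or the call is N."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(
                (self.filtered_depth > 0) & (self.codes != 4),
                self.n_agree / np.maximum(self.filtered_depth, 1) * 100.0,
                np.nan,
            )
        return pct

    def sequence(self) -> str:
        """Full-length consensus string over 'ACGTN-' (one char per ref position)."""
        return "".join(CONSENSUS_ALPHABET[c] for c in self.codes)

    def fasta_sequence(self) -> str:
        """FASTA body: deletion sites dropped, N kept."""
        return self.sequence().replace("-", "")

    def site(self, position: int) -> ConsensusSite:
        i = position - 1
        pct = self.support_pct[i]
        return ConsensusSite(
            position=position,
            base=CONSENSUS_ALPHABET[self.codes[i]],
            mode=self.mode,
            n_agree=int(self.n_agree[i]),
            support_pct=None if np.isnan(pct) else float(pct),
            filtered_depth=int(self.filtered_depth[i]),
        )

    def sites(self):
        for pos in range(1, len(self) + 1):
            yield self.site(pos)

    def fasta_header(self) -> str:
        return (
            f"{self.reference_name}_consensus mode={self.mode} "
            f"min_bq={self.policy.min_base_quality} min_mq={self.policy.min_mapping_quality}"
        )

    def write_fasta(self, path) -> None:
        seq = self.fasta_sequence()
        with open(path, "w") as fh:
            fh.write(f">{self.fasta_header()}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def build_consensus(
    pileup: Pileup, mode: str = "majority", policy: FilterPolicy | None = None,
    reference_name: str = "reference",
) -> ConsensusSequence:
    """Apply the selected site caller at every reference position."""
    mode = normalize_mode(mode)
    if policy is None:
        policy = FilterPolicy()
    codes = _CODE_CALLERS[mode](pileup)
    base_counts = pileup.counts
    n_agree = np.zeros(len(codes), dtype=np.int64)
    is_base = codes < 4
    idx = np.nonzero(is_base)[0]
    n_agree[idx] = base_counts[idx, codes[idx].astype(np.intp)]
    n_agree[codes == GAP_CODE] = pileup.deletion_count[codes == GAP_CODE]
    return ConsensusSequence(
        codes=codes,
        n_agree=n_agree,
        filtered_depth=pileup.filtered_depth,
        mode=mode,
        policy=policy,
        reference_name=reference_name,
    )
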