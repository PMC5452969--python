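"""Haplogroup assignment from PhyloTree-style defining variants.

The tree file is tab-delimited with three columns: haplogroup name, parent
name (empty for the root) and a comma-separated list of defining-variant
tokens in PhyloTree nomenclature:

* substitutions ``A73G`` (optionally suffixed ``!`` for a back-mutation,
  which cancels the variant previously acquired at that position along the
  root-to-node path),
* deletions ``A249d``,
* insertions ``16182.1C`` (parsed and stored, but excluded from pileup-based
  scoring since an insertion has no single reference column to score; the
  exclusion count is reported).

A sample is scored against every node's cumulative (root-to-node, effective
after back-mutation cancellation) variant set; the assignment score is
(matches - mismatches) / scorable sites, with ties broken by more matches,
then deeper node, then name. Exogenous contamination is estimated by
P_mismatch, the mean per-defining-site ratio of bases inconsistent vs
consistent with the defining allele, expressed as a percentage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import BASES, FilterPolicy, Pileup, ReferenceGenome
from .consensus import ConsensusSequence, majority_codes

logger = logging.getLogger(__name__)

_SUB_TOKEN = re.compile(r"^([ACGT])(\d+)([ACGT])(!?)$")
_DEL_TOKEN = re.compile(r"^([ACGT])?(\d+)d$")
_INS_TOKEN = re.compile(r"^(\d+)\.(\d+)([ACGT]+)$")


@dataclass(frozen=True)
class VariantToken:
    kind: str  # 'substitution' | 'deletion' | 'insertion'
    position: int
    allele: str  # derived allele; '-' for deletion; inserted bases for insertion
    ancestral: str | None = None
    back_mutation: bool = False
    raw: str = ""


def parse_token(token: str) -> VariantToken:
    token = token.strip()
    m = _SUB_TOKEN.match(token)
    if m:
        anc, pos, der, bang = m.groups()
        return VariantToken("substitution", int(pos), der, anc, bang == "!", token)
    m = _DEL_TOKEN.match(token)
    if m:
        anc, pos = m.groups()
        return VariantToken("deletion", int(pos), "-", anc, False, token)
    m = _INS_TOKEN.match(token)
    if m:
        pos, _idx, ins = m.groups()
        return VariantToken("insertion", int(pos), ins, None, False, token)
    raise ValueError(f"unparseable variant token {token!r}")


@dataclass
class HaploNode:
    name: str
    parent: str | None
    defining_variants: list  # of VariantToken


class HaploTree:
    """Rooted haplogroup tree with per-branch defining variants."""

    def __init__(self, nodes: dict):
        self.nodes = nodes
        roots = [n for n in nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0].name
        for n in nodes.values():
            if n.parent is not None and n.parent not in nodes:
                raise ValueError(f"node {n.name!r} has unknown parent {n.parent!r}")
        self._check_acyclic()
        self._cum_cache: dict = {}

    def _check_acyclic(self):
        for name in self.nodes:
            seen = set()
            cur = name
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle detected through node {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def path(self, name: str) -> list:
        """Root-to-node list of node names."""
        if name not in self.nodes:
            raise KeyError(f"unknown haplogroup {name!r}")
        out = []
        cur = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def cumulative_variants(self, name: str) -> dict:
        """Effective position -> allele state along the root-to-node path.

        Back-mutation tokens ('!') cancel the variant previously present at
        that position (reversion to the reference state). Insertions are not
        part of the positional state; see `cumulative_insertions`.
        """
        if name in self._cum_cache:
            return dict(self._cum_cache[name])
        state: dict = {}
        for node_name in self.path(name):
            for tok in self.nodes[node_name].defining_variants:
                if tok.kind == "insertion":
                    continue
                if tok.back_mutation:
                    state.pop(tok.position, None)
                else:
                    state[tok.position] = tok.allele
        self._cum_cache[name] = dict(state)
        return state

    def cumulative_insertions(self, name: str) -> list:
        return [
            tok
            for node_name in self.path(name)
            for tok in self.nodes[node_name].defining_variants
            if tok.kind == "insertion"
        ]

    def names(self):
        return list(self.nodes)


def parse_haplotree(path, reference: ReferenceGenome | None = None) -> HaploTree:
    """Parse the tab-delimited tree dialect (name, parent, variant tokens).

    Lines starting with '#' are comments. Positions are validated against the
    reference length when a reference is supplied. Errors carry the 1-based
    line number of the offending row.
    """
    nodes: dict = {}
    n_insertions = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >= 2 tab-delimited fields")
            name = fields[0].strip()
            parent = fields[1].strip() or None
            if not name:
                raise ValueError(f"line {lineno}: empty haplogroup name")
            if name in nodes:
                raise ValueError(f"line {lineno}: duplicate haplogroup name {name!r}")
            tokens = []
            raw_tokens = fields[2].strip() if len(fields) > 2 else ""
            if raw_tokens:
                for t in raw_tokens.split(","):
                    if not t.strip():
                        continue
                    try:
                        tok = parse_token(t)
                    except ValueError as e:
                        raise ValueError(f"line {lineno}: {e}") from None
                    if reference is not None and not (
                        1 <= tok.position <= reference.length
                    ):
                        raise ValueError(
                            f"line {lineno}: variant {tok.raw!r} position "
                            f"{tok.position} outside reference length {reference.length}"
                        )
                    if tok.kind == "insertion":
                        n_insertions += 1
                    tokens.append(tok)
            nodes[name] = HaploNode(name=name, parent=parent, defining_variants=tokens)
    if n_insertions:
        logger.info(
            "%d insertion token(s) parsed; insertions are excluded from "
            "pileup-based haplogroup scoring",
            n_insertions,
        )
    return HaploTree(nodes)


def write_haplotree(tree: HaploTree, path) -> None:
    """Serialise a tree back to the tab-delimited dialect (tests/simulation)."""
    with open(path, "w") as fh:
        # parents before children so the file reads top-down
        done = set()
        order = []

        def visit(name):
            if name in done:
                return
            parent = tree.nodes[name].parent
            if parent is not None:
                visit(parent)
            done.add(name)
            order.append(name)

        for name in tree.nodes:
            visit(name)
        for name in order:
            n = tree.nodes[name]
            toks = ",".join(t.raw for t in n.defining_variants)
            fh.write(f"{n.name}\t{n.parent or ''}\t{toks}\n")


# ---------------------------------------------------------------------------
# scoring


def _site_base_getter(source, policy: FilterPolicy | None):
    """Return f(position) -> called base char over 'ACGTN-' for either input."""
    if isinstance(source, ConsensusSequence):
        seq = source.sequence()
        return lambda pos: seq[pos - 1]
    if isinstance(source, Pileup):
        codes = majority_codes(source)
        alphabet = "ACGTN-"
        return lambda pos: alphabet[codes[pos - 1]]
    raise TypeError(f"cannot score from {type(source).__name__}")


def score_haplogroup(
    source, tree: HaploTree, node_name: str, policy: FilterPolicy | None = None
) -> tuple[int, int, int]:
    """(n_match, n_mismatch, n_nocall) of a sample against one node.

    `source` is a ConsensusSequence or a Pileup (scored by per-site majority).
    A defining site matches when the called base equals the derived allele
    ('-' for deletions), is a nocall when the call is N or the site has no
    data, and mismatches otherwise. Insertions are not scorable.
    """
    if node_name not in tree.nodes:
        raise KeyError(f"unknown haplogroup {node_name!r}")
    get_base = _site_base_getter(source, policy)
    cum = tree.cumulative_variants(node_name)
    n_match = n_mismatch = n_nocall = 0
    for pos, allele in cum.items():
        called = get_base(pos)
        if called == "N":
            n_nocall += 1
        elif called == allele:
            n_match += 1
        else:
            n_mismatch += 1
    return n_match, n_mismatch, n_nocall


@dataclass
class HaplogroupCall:
    """Ranked haplogroup assignment plus the contamination indicator."""

    ranking: list  # of dict(name, score, n_match, n_mismatch, n_nocall, k_covered)
    p_mismatch: float | None = None
    excluded_insertions: int = 0
    excluded_zero_match_sites: int = 0

    @property
    def best(self) -> str:
        return self.ranking[0]["name"]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ranking,
            columns=["name", "score", "n_match", "n_mismatch", "n_nocall", "k_covered"],
        )


def assign_haplogroup(
    source, tree: HaploTree, policy: FilterPolicy | None = None
) -> HaplogroupCall:
    """Score every node and rank by (matches - mismatches) / scorable sites.

    Ties are broken by more matches, then deeper node, then lexicographic
    name — a deeper node that matches everything its ancestor does carries
    more specific information and wins.
    """
    if not tree.nodes:
        raise ValueError("empty haplogroup tree")
    get_base = _site_base_getter(source, policy)
    rows = []
    for name in tree.names():
        cum = tree.cumulative_variants(name)
        n_match = n_mismatch = n_nocall = 0
        for pos, allele in cum.items():
            called = get_base(pos)
            if called == "N":
                n_nocall += 1
            elif called == allele:
                n_match += 1
            else:
                n_mismatch += 1
        scorable = n_match + n_mismatch
        score = (n_match - n_mismatch) / max(1, scorable)
        rows.append(
            {
                "name": name,
                "score": score,
                "n_match": n_match,
                "n_mismatch": n_mismatch,
                "n_nocall": n_nocall,
                "k_covered": scorable,
            }
        )
    rows.sort(
        key=lambda r: (-r["score"], -r["n_match"], -tree.depth(r["name"]), r["name"])
    )
    call = HaplogroupCall(ranking=rows)
    call.excluded_insertions = len(tree.cumulative_insertions(call.best))
    return call


def p_mismatch(pileup: Pileup, tree: HaploTree, assigned: str) -> tuple[float, int, int]:
    """Contamination indicator over the assigned node's defining sites.

    P_mismatch = [ sum_i (N_mismatch_i / N_match_i) / k ] x 100 over the k
    defining sites with N_match >= 1, where N_match is the filtered base
    count consistent with the defining allele at site i and N_mismatch the
    count inconsistent with it. Sites with N_match = 0 (where the printed
    ratio would be infinite) are excluded from k and counted separately.

    Returns (p_mismatch_percent, k, n_excluded_zero_match).
    """
    if assigned not in tree.nodes:
        raise KeyError(f"unknown haplogroup {assigned!r}")
    cum = tree.cumulative_variants(assigned)
    ratios = []
    excluded = 0
    for pos, allele in cum.items():
        i = pos - 1
        depth = int(pileup.filtered_depth[i])
        if allele == "-":
            n_match = int(pileup.deletion_count[i])
        else:
            n_match = int(pileup.counts[i, BASES.index(allele)])
        n_mismatch = depth - n_match
        if n_match == 0:
            excluded += 1
            continue
        ratios.append(n_mismatch / n_match)
    k = len(ratios)
    if k == 0:
        raise ValueError("no scorable defining sites (every site has zero matching bases)")
    return float(np.mean(ratios) * 100.0), k, excluded


def assignment_accuracy(truth: list, predicted: list) -> float:
    """TP / (TP + FP) over paired truth and predicted haplogroup names."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted lists must have equal length")
    if not truth:
        raise ValueError("cannot compute accuracy of an empty prediction set")
    tp = sum(1 for t, p in zip(truth, predicted) if t == p)
    fp = len(truth) - tp
    return tp / (tp + fp)
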