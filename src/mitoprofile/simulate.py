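"""Synthetic single-end read generation with full ground truth.

Generates already-aligned reads from a known haplotype (optionally mixed with
a contaminant haplotype), with i.i.d. per-base sequencing errors, optional
terminal deamination damage, and a simple two-level quality model. Defaults
mirror a standard short-read validation setup for mitochondrial genomes:
100 bp single-end reads with a 1% base-call error rate, and read count
chosen as round(depth x genome length / read length) with uniform start
positions.

The generator is the testing ground for the rest of the toolkit: its truth
object records each read's source (host or contaminant) and every injected
error/damage position, so recovery of error rates, contamination fractions,
damage rates and haplogroup labels can be checked against known values.

The model deliberately omits several features of real sequencing: no
empirical quality profiles, no indels, no paired ends, no mapping step
(reads are emitted at their true positions with a single match CIGAR).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import BASES, ReadRecord, ReferenceGenome, encode_bases
from .haplogroup import HaploNode, HaploTree
from .variants import Variant


@dataclass
class SimulationConfig:
    haplotype: str
    seed: int
    contaminant: str | None = None
    contamination_fraction: float = 0.0
    depth: float = 50.0
    read_length: int = 100
    error_rate: float = 0.01
    base_quality: int = 37
    error_quality: int = 37  # set lower (e.g. 15) to exercise the quality filter
    deamination: tuple | None = None  # (rate0, decay_length) or None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.contamination_fraction <= 0.5):
            raise ValueError("contamination_fraction must be in [0, 0.5]")
        if self.read_length < 10:
            raise ValueError("read_length must be >= 10")
        if self.contamination_fraction > 0 and self.contaminant is None:
            raise ValueError(
                "contamination_fraction > 0 requires a contaminant haplotype"
            )
        if self.deamination is not None:
            rate0, decay = self.deamination
            if not (0 <= rate0 <= 1) or decay <= 0:
                raise ValueError("deamination needs 0<=rate0<=1 and decay > 0")

    def as_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "contamination_fraction": self.contamination_fraction,
            "depth": self.depth,
            "read_length": self.read_length,
            "error_rate": self.error_rate,
            "base_quality": self.base_quality,
            "error_quality": self.error_quality,
            "deamination": list(self.deamination) if self.deamination else None,
            "haplotype_length": len(self.haplotype),
            "has_contaminant": self.contaminant is not None,
        }
        return d


@dataclass
class SimulationTruth:
    """Everything needed to audit the simulated reads."""

    source: np.ndarray  # bool per read: True = contaminant
    error_positions: list  # per read: list of 0-based read offsets
    damage_positions: list  # per read: list of 0-based read offsets
    realized_depth: np.ndarray  # per reference position
    starts: np.ndarray  # 1-based per read

    @property
    def n_host(self) -> int:
        return int((~self.source).sum())

    @property
    def n_contaminant(self) -> int:
        return int(self.source.sum())

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_host": self.n_host,
                    "n_contaminant": self.n_contaminant,
                    "source": ["contaminant" if s else "host" for s in self.source],
                    "starts": self.starts.tolist(),
                    "error_positions": [list(map(int, e)) for e in self.error_positions],
                    "damage_positions": [list(map(int, d)) for d in self.damage_positions],
                    "realized_depth": self.realized_depth.tolist(),
                },
                fh,
            )


def make_haplotype(ref: ReferenceGenome, variants) -> str:
    """Apply substitution variants to the reference (length-preserving).

    `variants` may hold Variant objects or rCRS-style labels (C150T).
    """
    seq = list(ref.sequence)
    seen: dict = {}
    for v in variants:
        if isinstance(v, str):
            v = Variant.parse(v)
        if v.kind != "substitution":
            raise ValueError(f"only substitution variants are supported, got {v.label}")
        if v.position in seen and seen[v.position] != v.alt:
            raise ValueError(f"conflicting variants at position {v.position}")
        if ref.base(v.position) != v.ref:
            raise ValueError(
                f"variant {v.label}: reference has {ref.base(v.position)} at "
                f"position {v.position}, not {v.ref}"
            )
        seen[v.position] = v.alt
        seq[v.position - 1] = v.alt
    return "".join(seq)


def haplotype_from_tree(ref: ReferenceGenome, tree: HaploTree, node: str) -> str:
    """Haplotype carrying the cumulative substitutions of one tree node."""
    seq = list(ref.sequence)
    for pos, allele in tree.cumulative_variants(node).items():
        if allele == "-":
            raise ValueError("deletion variants cannot be simulated (substitution-only)")
        seq[pos - 1] = allele
    return "".join(seq)


def simulate_reads(
    config: SimulationConfig, ref: ReferenceGenome
) -> tuple[list[ReadRecord], SimulationTruth]:
    """Draw reads with known truth; deterministic given (config, seed).

    Per read: start uniform on [1, L - read_length + 1]; source haplotype is
    the contaminant with probability contamination_fraction; deamination
    (C→T decaying from the 5′ end, G→A from the 3′ end, probability
    rate0 * exp(-(offset-1)/decay)) is applied before sequencing error;
    errors are i.i.d. per base at error_rate, uniform over the three
    alternative bases. Reads come out coordinate-sorted, forward strand,
    single match CIGAR.
    """
    L = len(config.haplotype)
    if L != ref.length:
        raise ValueError(
            f"haplotype length {L} != reference length {ref.length}; "
            "substitution-only haplotypes must preserve length"
        )
    if config.contaminant is not None and len(config.contaminant) != L:
        raise ValueError("contaminant haplotype length must match the reference")
    rl = config.read_length
    if rl > L:
        raise ValueError("read_length exceeds the genome length")
    rng = np.random.default_rng(config.seed)
    n_reads = int(round(config.depth * L / rl))

    starts = np.sort(rng.integers(1, L - rl + 2, size=n_reads))  # 1-based
    is_contam = (
        rng.random(n_reads) < config.contamination_fraction
        if config.contaminant is not None
        else np.zeros(n_reads, dtype=bool)
    )

    host = encode_bases(config.haplotype)
    offsets = np.arange(rl)
    posmat = (starts - 1)[:, None] + offsets[None, :]
    bases = host[posmat].astype(np.uint8)
    if config.contaminant is not None:
        contam = encode_bases(config.contaminant)
        bases[is_contam] = contam[posmat[is_contam]]

    damage_mask = np.zeros((n_reads, rl), dtype=bool)
    if config.deamination is not None:
        rate0, decay = config.deamination
        p = rate0 * np.exp(-offsets / decay)  # offset 1 -> exponent 0
        r5 = rng.random((n_reads, rl))
        ct = (bases == 1) & (r5 < p[None, :])
        r3 = rng.random((n_reads, rl))
        ga = (bases == 2) & (r3 < p[None, ::-1])
        bases[ct] = 3  # C -> T
        bases[ga] = 0  # G -> A
        damage_mask = ct | ga

    err_mask = rng.random((n_reads, rl)) < config.error_rate
    if err_mask.any():
        shift = rng.integers(1, 4, size=int(err_mask.sum()))
        bases[err_mask] = (bases[err_mask] + shift) % 4

    quals = np.full((n_reads, rl), config.base_quality, dtype=np.uint8)
    quals[err_mask] = config.error_quality

    realized_depth = np.zeros(L, dtype=np.int64)
    np.add.at(realized_depth, posmat.ravel(), 1)

    def _per_read_offsets(mask):
        rows, cols = np.nonzero(mask)
        split = np.searchsorted(rows, np.arange(1, n_reads))
        return [c.tolist() for c in np.split(cols, split)]

    all_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)[bases].tobytes()
    cigar = (("M", rl),)
    reads = [
        ReadRecord(
            id=f"sim_{i:07d}",
            mapped_start=int(starts[i]),
            cigar=cigar,
            bases=all_bytes[i * rl : (i + 1) * rl].decode("ascii"),
            qualities=quals[i],
            mapping_quality=60,
        )
        for i in range(n_reads)
    ]
    err_list = _per_read_offsets(err_mask)
    dmg_list = _per_read_offsets(damage_mask)

    truth = SimulationTruth(
        source=is_contam,
        error_positions=err_list,
        damage_positions=dmg_list,
        realized_depth=realized_depth,
        starts=starts.copy(),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# synthetic haplogroup trees (ground truth for assignment tests)


def random_haplotree(
    ref: ReferenceGenome,
    n_nodes: int = 16,
    variants_per_branch: int = 4,
    seed: int = 0,
    root_name: str = "ROOT",
) -> HaploTree:
    """A random rooted tree whose branches carry disjoint substitutions.

    The root represents the reference state (no defining variants); every
    other node attaches to a uniformly chosen existing node and acquires
    `variants_per_branch` substitutions at globally unique positions, so
    cumulative variant sets along any path never collide.
    """
    if n_nodes < 2:
        raise ValueError("need at least a root and one child")
    rng = np.random.default_rng(seed)
    n_branch_vars = (n_nodes - 1) * variants_per_branch
    positions = rng.choice(ref.length, size=n_branch_vars, replace=False) + 1
    nodes = {root_name: HaploNode(root_name, None, [])}
    names = [root_name]
    vi = 0
    from .haplogroup import parse_token

    for k in range(1, n_nodes):
        parent = names[int(rng.integers(0, len(names)))]
        name = f"HG{k:02d}"
        tokens = []
        for _ in range(variants_per_branch):
            pos = int(positions[vi])
            vi += 1
            ref_base = ref.base(pos)
            alts = [b for b in BASES if b != ref_base]
            alt = alts[int(rng.integers(0, 3))]
            tokens.append(parse_token(f"{ref_base}{pos}{alt}"))
        nodes[name] = HaploNode(name, parent, tokens)
        names.append(name)
    return HaploTree(nodes)
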