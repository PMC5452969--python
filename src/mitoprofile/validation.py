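"""Whole-pipeline validation experiments on simulated data.

These functions reproduce, at desk scale, the validation designs the toolkit
is built around: haplogroup-assignment accuracy as a function of sequencing
depth, support-ratio and P_mismatch behaviour under exogenous contamination,
terminal-deamination parameter recovery, and MAF-threshold heteroplasmy
detection. Each experiment simulates reads with known truth, runs the
ordinary pipeline entry points (build_pileup, assign_haplogroup, ...) and
measures the outcome; nothing is read from disk.

Default conditions follow the simulator's standard setup: 16,569 bp genome,
100 bp single-end reads, 1% base-call error.
"""

from __future__ import annotations

import numpy as np

from .alignment_io import ReferenceGenome, build_pileup
from .consensus import build_consensus
from .damage import damage_profile
from .haplogroup import (
    HaploNode,
    HaploTree,
    assign_haplogroup,
    assignment_accuracy,
    p_mismatch,
    parse_token,
)
from .simulate import (
    SimulationConfig,
    haplotype_from_tree,
    make_haplotype,
    random_haplotree,
    simulate_reads,
)
from .variants import detect_heteroplasmy

GENOME_LENGTH = 16569


def synthetic_reference(seed: int, length: int = GENOME_LENGTH) -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    return ReferenceGenome("synthMT", "".join(rng.choice(list("ACGT"), size=length)))


def haplogroup_accuracy_by_depth(
    seed: int,
    depths=(1, 5, 10, 50),
    n_samples: int = 100,
    n_nodes: int = 16,
    variants_per_branch: int = 4,
    error_rate: float = 0.01,
    read_length: int = 100,
) -> dict:
    """Assignment accuracy TP/(TP+FP) per depth on a synthetic tree.

    For each depth, n_samples haplotypes are drawn uniformly from the
    non-root tree nodes, reads are simulated, and the pileup-majority
    assignment is compared with the truth label.
    """
    ref = synthetic_reference(seed)
    tree = random_haplotree(ref, n_nodes=n_nodes,
                            variants_per_branch=variants_per_branch, seed=seed + 1)
    names = [n for n in tree.names() if n != "ROOT"]
    rng = np.random.default_rng(seed + 2)
    out = {}
    for depth in depths:
        truth, pred = [], []
        for _ in range(n_samples):
            node = names[int(rng.integers(0, len(names)))]
            hap = haplotype_from_tree(ref, tree, node)
            cfg = SimulationConfig(
                haplotype=hap,
                seed=int(rng.integers(2**31)),
                depth=depth,
                read_length=read_length,
                error_rate=error_rate,
            )
            reads, _ = simulate_reads(cfg, ref)
            pile = build_pileup(reads, ref)
            truth.append(node)
            pred.append(assign_haplogroup(pile, tree).best)
        out[depth] = assignment_accuracy(truth, pred)
    return out


def _two_haplotype_setup(seed: int, n_variants: int = 30):
    """Host haplotype with n private variants; contaminant = reference."""
    ref = synthetic_reference(seed)
    rng = np.random.default_rng(seed + 10)
    positions = np.sort(rng.choice(ref.length, size=n_variants, replace=False) + 1)
    tokens = []
    for pos in positions:
        rb = ref.base(int(pos))
        alt = "ACGT"[("ACGT".index(rb) + 1 + int(rng.integers(0, 3))) % 4]
        tokens.append(f"{rb}{int(pos)}{alt}")
    tree = HaploTree(
        {
            "R": HaploNode("R", None, []),
            "HOST": HaploNode("HOST", "R", [parse_token(t) for t in tokens]),
        }
    )
    host = make_haplotype(ref, tokens)
    return ref, tree, host, positions


def contamination_sweep(
    seed: int,
    fractions=(0.0, 0.1, 0.2, 0.3),
    depth: float = 100.0,
    error_rate: float = 0.01,
) -> dict:
    """P_mismatch and mean support ratio at discriminating sites per fraction.

    The host carries 30 private variants; the contaminant is the reference
    state, so the two haplotypes differ at exactly those sites. Returns
    {fraction: {"p_mismatch": %, "mean_support_pct": %, "assigned": name}}.
    """
    ref, tree, host, positions = _two_haplotype_setup(seed)
    rng = np.random.default_rng(seed + 20)
    out = {}
    for frac in fractions:
        cfg = SimulationConfig(
            haplotype=host,
            contaminant=ref.sequence if frac > 0 else None,
            contamination_fraction=frac,
            depth=depth,
            error_rate=error_rate,
            seed=int(rng.integers(2**31)),
        )
        reads, _ = simulate_reads(cfg, ref)
        pile = build_pileup(reads, ref)
        call = assign_haplogroup(pile, tree)
        pm, k, _ = p_mismatch(pile, tree, "HOST")
        cons = build_consensus(pile, "majority")
        support = cons.support_pct[positions - 1]
        out[frac] = {
            "p_mismatch": pm,
            "mean_support_pct": float(np.nanmean(support)),
            "assigned": call.best,
            "k": k,
        }
    return out


def damage_recovery(
    seed: int,
    rate0: float = 0.3,
    decay: float = 3.0,
    depth: float = 100.0,
    K: int = 25,
) -> dict:
    """Recover the injected terminal deamination rate, plus a clean control.

    Returns recovered 5'/3' offset-1 rates for the damaged run and the
    maximum absolute deviation of any per-offset substitution rate from the
    expected per-substitution error rate in the zero-damage control.
    """
    ref = synthetic_reference(seed)
    cfg = SimulationConfig(
        haplotype=ref.sequence, seed=seed + 31, depth=depth, error_rate=0.0,
        deamination=(rate0, decay),
    )
    reads, _ = simulate_reads(cfg, ref)
    prof = damage_profile(reads, ref, K=K)

    error_rate = 0.01
    cfg0 = SimulationConfig(
        haplotype=ref.sequence, seed=seed + 32, depth=depth, error_rate=error_rate,
    )
    reads0, _ = simulate_reads(cfg0, ref)
    prof0 = damage_profile(reads0, ref, K=K)
    per_sub = error_rate / 3
    max_dev = 0.0
    for end in ("5p", "3p"):
        for rb in "ACGT":
            for qb in "ACGT":
                if rb == qb:
                    continue
                r = prof0.rate(end, rb, qb)
                dev = np.nanmax(np.abs(r - per_sub))
                max_dev = max(max_dev, float(dev))
    return {
        "rate_5p_1": prof.rate_5p[1],
        "rate_3p_1": prof.rate_3p[1],
        "injected_rate0": rate0,
        "control_max_rate_deviation": max_dev,
        "control_expected_rate": per_sub,
    }


def heteroplasmy_scenarios(seed: int, maf_threshold: float = 0.10) -> dict:
    """Two-allele mixtures at one site: 25% minor at 40x and 1% minor at 100x.

    The minor allele is introduced as a contaminant haplotype differing from
    the host at a single position; detection uses the given MAF threshold.
    Returns flag status and observed MAF for both scenarios.
    """
    ref = synthetic_reference(seed)
    pos = ref.length // 2
    rb = ref.base(pos)
    alt = "A" if rb != "A" else "G"
    minor_hap = make_haplotype(ref, [f"{rb}{pos}{alt}"])
    out = {}
    for label, frac, depth in (("minor25_depth40", 0.25, 40), ("minor01_depth100", 0.01, 100)):
        cfg = SimulationConfig(
            haplotype=ref.sequence, contaminant=minor_hap,
            contamination_fraction=frac, depth=depth, error_rate=0.0,
            seed=seed + 41,
        )
        reads, _ = simulate_reads(cfg, ref)
        pile = build_pileup(reads, ref)
        cons = build_consensus(pile, "majority")
        sites = detect_heteroplasmy(pile, cons, maf_threshold, min_depth=10)
        flagged_positions = {s.position for s in sites}
        col = pile.column(pos)
        n_con = col.counts.get(rb, 0)
        n_diff = col.counts.get(alt, 0)
        out[label] = {
            "flagged": pos in flagged_positions,
            "maf": n_diff / n_con if n_con else float("inf"),
            "depth": col.filtered_depth,
        }
    return out


def consensus_identity(seed: int, depth: float = 50.0, error_rate: float = 0.01) -> dict:
    """Consensus-vs-truth identity over covered sites for one noisy sample."""
    ref = synthetic_reference(seed)
    cfg = SimulationConfig(haplotype=ref.sequence, seed=seed + 51, depth=depth,
                           error_rate=error_rate)
    reads, _ = simulate_reads(cfg, ref)
    pile = build_pileup(reads, ref)
    cons = build_consensus(pile, "majority")
    covered = pile.filtered_depth > 0
    seq = np.frombuffer(cons.sequence().encode(), dtype=np.uint8)
    truth = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    identity = float((seq[covered] == truth[covered]).mean())
    return {"identity": identity, "covered_fraction": float(covered.mean())}
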