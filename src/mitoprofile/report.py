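"""Run orchestration and static HTML report rendering.

`run_profile` executes the full pipeline in a fixed order — alignment/pileup,
summary statistics, consensus, then the optional sections (haplogroup +
contamination, heteroplasmy, variants/annotation, damage, substitution
spectrum) — writes every table as TSV/JSON, and renders one self-contained
HTML report with inline SVG charts. All tabular outputs are byte-
deterministic for a given configuration; only the HTML carries a timestamp.
"""

from __future__ import annotations

import datetime
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment_io import (
    FilterPolicy,
    Pileup,
    ReferenceGenome,
    SummaryStats,
    build_pileup,
    load_reference,
    read_alignment,
    summarize_alignment,
)
from .consensus import ConsensusSequence, build_consensus, normalize_mode
from .damage import DamageProfile, FragmentationSummary, damage_profile, fragmentation_summary
from .haplogroup import HaplogroupCall, assign_haplogroup, p_mismatch, parse_haplotree
from .variants import (
    SubstitutionSpectrum,
    align_consensus_to_reference,
    annotate_variants,
    call_variants,
    detect_heteroplasmy,
    heteroplasmy_table,
    load_annotation_db,
    substitution_spectrum,
)

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "mitoprofile"


@dataclass
class RunConfig:
    """Everything a full profiling run needs; mirrors the CLI flags."""

    bam: str
    ref: str
    out_dir: str
    tree: str | None = None
    annotation_dbs: list = field(default_factory=list)
    min_base_quality: int = 30
    min_mapping_quality: int = 20
    exclude_duplicates: bool = True
    exclude_secondary: bool = True
    consensus_mode: str = "majority"
    maf_threshold: float = 0.10
    min_depth: int = 10
    heteroplasmy: bool = True
    annotation: bool = True
    ancient_dna: bool = True
    damage_min_bq: int = 20
    damage_K: int = 25

    def policy(self) -> FilterPolicy:
        return FilterPolicy(
            min_base_quality=self.min_base_quality,
            min_mapping_quality=self.min_mapping_quality,
            exclude_duplicates=self.exclude_duplicates,
            exclude_secondary=self.exclude_secondary,
        )

    def validate(self) -> None:
        for label, p in [("bam", self.bam), ("ref", self.ref), ("tree", self.tree)] + [
            ("annotation db", d) for d in self.annotation_dbs
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        normalize_mode(self.consensus_mode)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunResult:
    config: RunConfig
    summary: SummaryStats
    consensus: ConsensusSequence
    pileup: Pileup
    reference: ReferenceGenome
    haplogroup_call: HaplogroupCall | None = None
    heteroplasmy_sites: list | None = None
    variants: list | None = None
    inserted_positions: list | None = None
    annotation_table: pd.DataFrame | None = None
    annotation_skipped_rows: int = 0
    damage: DamageProfile | None = None
    fragmentation: FragmentationSummary | None = None
    spectrum: SubstitutionSpectrum | None = None
    skipped_sections: list = field(default_factory=list)

    def provenance(self) -> dict:
        return {
            "tool": "mitoprofile",
            "version": __version__,
            "config": self.config.to_dict(),
            "skipped_sections": sorted(self.skipped_sections),
        }


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_profile(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all outputs under config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    policy = config.policy()

    ref = load_reference(config.ref)
    tree = parse_haplotree(config.tree, ref) if config.tree else None
    dbs = []
    skipped_rows = 0
    if config.annotation and config.annotation_dbs:
        for p in config.annotation_dbs:
            recs, skipped = load_annotation_db(p)
            dbs.extend(recs)
            skipped_rows += skipped

    reads = read_alignment(config.bam, ref)
    pileup = build_pileup(reads, ref, policy)
    summary = summarize_alignment(reads, pileup, ref)
    consensus = build_consensus(pileup, config.consensus_mode, policy, ref.name)

    result = RunResult(
        config=config,
        summary=summary,
        consensus=consensus,
        pileup=pileup,
        reference=ref,
        annotation_skipped_rows=skipped_rows,
    )

    if tree is not None:
        call = assign_haplogroup(pileup, tree, policy)
        try:
            pm, k, excl = p_mismatch(pileup, tree, call.best)
            call.p_mismatch = pm
            call.excluded_zero_match_sites = excl
        except ValueError:
            call.p_mismatch = None  # no scorable sites (e.g. empty input)
        result.haplogroup_call = call
    else:
        result.skipped_sections.append("haplogroup")

    if config.heteroplasmy:
        result.heteroplasmy_sites = detect_heteroplasmy(
            pileup, consensus, config.maf_threshold, config.min_depth
        )
    else:
        result.skipped_sections.append("heteroplasmy")

    # consensus-vs-reference variants (needed for annotation)
    if config.annotation:
        fasta_seq = consensus.fasta_sequence()
        if fasta_seq.strip("N"):
            pos_map = align_consensus_to_reference(fasta_seq, ref)
            variants, inserted = call_variants(fasta_seq, ref, pos_map)
        else:
            variants, inserted = [], []  # all-N consensus: nothing to call
        result.variants = variants
        result.inserted_positions = inserted
        result.annotation_table = annotate_variants(variants, dbs)
    else:
        result.skipped_sections.append("annotation")

    if config.ancient_dna:
        dmg_policy = FilterPolicy(
            min_base_quality=config.damage_min_bq,
            min_mapping_quality=config.min_mapping_quality,
            exclude_duplicates=config.exclude_duplicates,
            exclude_secondary=config.exclude_secondary,
        )
        result.damage = damage_profile(reads, ref, dmg_policy, config.damage_K)
        result.fragmentation = fragmentation_summary(reads)
    else:
        result.skipped_sections.append("ancient_dna")

    result.spectrum = substitution_spectrum(reads, ref, policy)

    write_outputs(result, out)
    html = render_html(result)
    (out / "report.html").write_text(html)
    return result


def write_outputs(result: RunResult, out: Path) -> None:
    """Write every computed table/sequence as deterministic TSV/JSON/FASTA."""
    out = Path(out)
    summary = result.summary

    flat = summary.as_flat_dict()
    _write_tsv(pd.DataFrame({"metric": list(flat), "value": list(flat.values())}),
               out / "summary.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(flat, fh, indent=1, sort_keys=True)

    depth_df = pd.DataFrame(
        {
            "position": np.arange(1, result.pileup.ref_length + 1),
            "raw_depth": result.pileup.raw_depth,
            "filtered_depth": result.pileup.filtered_depth,
        }
    )
    _write_tsv(depth_df, out / "depth.tsv")

    result.consensus.write_fasta(out / "consensus.fasta")
    cons = result.consensus
    sites_df = pd.DataFrame(
        {
            "position": np.arange(1, len(cons) + 1),
            "base": list(cons.sequence()),
            "n_agree": cons.n_agree,
            "filtered_depth": cons.filtered_depth,
            "support_pct": cons.support_pct,
        }
    )
    _write_tsv(sites_df, out / "consensus_sites.tsv")

    if result.haplogroup_call is not None:
        _write_tsv(result.haplogroup_call.as_frame(), out / "haplogroups.tsv")
    if result.heteroplasmy_sites is not None:
        _write_tsv(heteroplasmy_table(result.heteroplasmy_sites), out / "heteroplasmy.tsv")
    if result.variants is not None:
        _write_tsv(
            pd.DataFrame(
                [{"variant": v.label, "position": v.position, "type": v.kind}
                 for v in result.variants],
                columns=["variant", "position", "type"],
            ),
            out / "variants.tsv",
        )
    if result.annotation_table is not None:
        _write_tsv(result.annotation_table, out / "variants_annotated.tsv")
    if result.spectrum is not None:
        _write_tsv(result.spectrum.as_frame(), out / "spectrum.tsv")
        with open(out / "spectrum.json", "w") as fh:
            json.dump(
                {"counts": result.spectrum.counts,
                 "percent": result.spectrum.percentages,
                 "no_mismatches": result.spectrum.no_mismatches},
                fh, indent=1, sort_keys=True,
            )
    if result.damage is not None:
        _write_tsv(result.damage.as_frame("5p"), out / "damage_5p.tsv")
        _write_tsv(result.damage.as_frame("3p"), out / "damage_3p.tsv")
    if result.fragmentation is not None:
        _write_tsv(result.fragmentation.as_frame(), out / "read_lengths.tsv")

    run_block = result.provenance()
    if result.haplogroup_call is not None:
        run_block["haplogroup"] = {
            "best": result.haplogroup_call.best,
            "p_mismatch": result.haplogroup_call.p_mismatch,
            "excluded_insertions": result.haplogroup_call.excluded_insertions,
            "excluded_zero_match_sites": result.haplogroup_call.excluded_zero_match_sites,
        }
    run_block["no_data"] = result.summary.no_data
    run_block["annotation_skipped_rows"] = result.annotation_skipped_rows
    with open(out / "run.json", "w") as fh:
        json.dump(run_block, fh, indent=1, sort_keys=True)

    result.config.to_yaml(out / "config_echo.yaml")


# ---------------------------------------------------------------------------
# HTML


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg") :]


def _depth_chart(pileup: Pileup) -> str:
    fig, ax = plt.subplots(figsize=(8, 2.4))
    x = np.arange(1, pileup.ref_length + 1)
    ax.fill_between(x, pileup.raw_depth, color="#4878a8", alpha=0.7, linewidth=0)
    ax.set_xlabel("reference position")
    ax.set_ylabel("depth")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _spectrum_pie(spectrum: SubstitutionSpectrum) -> str:
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    pct = spectrum.percentages
    labels = [k for k, v in pct.items() if v > 0]
    vals = [pct[k] for k in labels]
    if vals:
        ax.pie(vals, labels=labels, textprops={"fontsize": 7})
    else:
        ax.text(0.5, 0.5, "no mismatches", ha="center")
        ax.set_axis_off()
    fig.tight_layout()
    return _fig_to_svg(fig)


def _damage_lines(profile: DamageProfile) -> str:
    fig, axes = plt.subplots(1, 2, figsize=(7, 2.6), sharey=True)
    x = np.arange(1, profile.K + 1)
    for end, ax, key in (("5p", axes[0], ("C", "T")), ("3p", axes[1], ("G", "A"))):
        for rb in "ACGT":
            for qb in "ACGT":
                if rb == qb:
                    continue
                r = profile.rate(end, rb, qb)
                hi = (rb, qb) == key
                ax.plot(
                    x, r,
                    color="#c0392b" if hi else "#b0b0b0",
                    linewidth=1.6 if hi else 0.6,
                    label=f"{rb}>{qb}" if hi else None,
                )
        ax.set_xlabel(f"offset from {end[0]}' end")
        ax.legend(fontsize=7)
    axes[0].set_ylabel("substitution rate")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _table_html(df: pd.DataFrame, max_rows: int = 50) -> str:
    shown = df.head(max_rows)
    note = (
        f"<p class='note'>showing {max_rows} of {len(df)} rows</p>"
        if len(df) > max_rows
        else ""
    )
    return shown.to_html(index=False, border=0, float_format=lambda v: f"{v:.4g}") + note


_CSS = """
body{font-family:sans-serif;margin:2em;color:#222;max-width:62em}
h1{border-bottom:2px solid #4878a8}h2{color:#335}table{border-collapse:collapse}
td,th{padding:2px 10px;border-bottom:1px solid #ddd;text-align:right}
th{background:#eef}.note{color:#777;font-size:small}.skipped{color:#a33}
section{margin-bottom:2em}
"""


def render_html(result: RunResult, timestamp: str | None = None) -> str:
    """One self-contained HTML page: QC summary, charts and result tables."""
    if timestamp is None:
        timestamp = datetime.datetime.now().isoformat(timespec="seconds")
    cfg = result.config
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>mitoprofile report</title>",
        f"<style>{_CSS}</style></head><body>",
        "<h1>mitoprofile report</h1>",
        f"<p class='note'>mitoprofile {__version__} — generated {timestamp}</p>",
    ]

    flat = result.summary.as_flat_dict()
    summary_df = pd.DataFrame({"metric": list(flat), "value": list(flat.values())})
    parts.append("<section id='summary'><h2>Summary statistics</h2>")
    if result.summary.no_data:
        parts.append("<p class='skipped'>no mapped reads — all depth statistics are zero</p>")
    parts.append(_table_html(summary_df, max_rows=60))
    parts.append("</section>")

    parts.append("<section id='depth'><h2>Depth of coverage</h2>")
    parts.append(_depth_chart(result.pileup))
    parts.append("</section>")

    parts.append("<section id='consensus'><h2>Consensus</h2>")
    cons = result.consensus
    n_called = int((cons.codes < 4).sum())
    n_n = int((cons.codes == 4).sum())
    n_gap = int((cons.codes == 5).sum())
    parts.append(
        f"<p>mode <b>{cons.mode}</b>: {n_called} called bases, {n_n} N sites, "
        f"{n_gap} deletion sites (dropped from FASTA)</p></section>"
    )

    parts.append("<section id='haplogroup'><h2>Haplogroup</h2>")
    if result.haplogroup_call is None:
        parts.append("<p class='skipped'>not run (no haplogroup tree supplied)</p>")
    else:
        hc = result.haplogroup_call
        pm = "n/a" if hc.p_mismatch is None else f"{hc.p_mismatch:.3f}%"
        parts.append(
            f"<p>best assignment: <b>{hc.best}</b> — P<sub>mismatch</sub> = {pm} "
            f"({hc.excluded_zero_match_sites} zero-match sites excluded, "
            f"{hc.excluded_insertions} insertion tokens unscorable)</p>"
        )
        parts.append(_table_html(hc.as_frame(), max_rows=15))
    parts.append("</section>")

    parts.append("<section id='heteroplasmy'><h2>Heteroplasmic sites</h2>")
    if result.heteroplasmy_sites is None:
        parts.append("<p class='skipped'>not run</p>")
    else:
        parts.append(
            f"<p>{len(result.heteroplasmy_sites)} site(s) with MAF &gt; "
            f"{cfg.maf_threshold} at depth ≥ {cfg.min_depth}</p>"
        )
        parts.append(_table_html(heteroplasmy_table(result.heteroplasmy_sites)))
    parts.append("</section>")

    parts.append("<section id='annotation'><h2>Variants &amp; annotation</h2>")
    if result.annotation_table is None:
        parts.append("<p class='skipped'>not run</p>")
    else:
        nvar = len(result.variants or [])
        parts.append(
            f"<p>{nvar} consensus-vs-reference variant(s); "
            f"{result.annotation_skipped_rows} malformed annotation row(s) skipped</p>"
        )
        parts.append(_table_html(result.annotation_table))
    parts.append("</section>")

    parts.append("<section id='spectrum'><h2>Base-substitution spectrum</h2>")
    if result.spectrum is None:
        parts.append("<p class='skipped'>not run</p>")
    else:
        parts.append(_spectrum_pie(result.spectrum))
    parts.append("</section>")

    parts.append("<section id='damage'><h2>Ancient-DNA damage</h2>")
    if result.damage is None:
        parts.append("<p class='skipped'>not run</p>")
    else:
        parts.append(_damage_lines(result.damage))
        fr = result.fragmentation
        parts.append(
            f"<p>read length mean {fr.mean:.1f}, median {fr.median:.1f}</p>"
        )
    parts.append("</section>")

    parts.append("<section id='provenance'><h2>Provenance</h2><pre>")
    parts.append(json.dumps(result.provenance(), indent=1, sort_keys=True))
    parts.append("</pre></section>")
    parts.append("</body></html>")
    return "\n".join(parts)
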