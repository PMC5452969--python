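"""MAF/heteroplasmy, global alignment, variant calling, annotation, spectrum."""

import itertools

import numpy as np
import pytest

from mitoprofile import (
    AnnotationRecord,
    FilterPolicy,
    ReferenceGenome,
    SimulationConfig,
    Variant,
    align_consensus_to_reference,
    annotate_variants,
    build_consensus,
    build_pileup,
    call_variants,
    detect_heteroplasmy,
    load_annotation_db,
    simulate_reads,
    site_maf,
    substitution_spectrum,
)
from mitoprofile.variants import SPECTRUM_KEYS, alignment_score

from conftest import make_column, make_read


class TestVariantLabels:
    @pytest.mark.parametrize("label,pos,kind", [
        ("C150T", 150, "substitution"),
        ("A4282G", 4282, "substitution"),
        ("A249d", 249, "deletion"),
    ])
    def test_roundtrip(self, label, pos, kind):
        v = Variant.parse(label)
        assert v.position == pos and v.kind == kind and v.label == label

    @pytest.mark.parametrize("bad", ["C150", "150T", "C150C", "16182.1C", "x"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            Variant.parse(bad)


class TestSiteMaf:
    def test_no_discordant_bases(self):
        assert site_maf(make_column({"A": 10}), "A", "T") == 0.0

    def test_ratio_to_concordant_not_total(self):
        # 2 discordant vs 8 concordant: 0.25, not 0.2
        assert site_maf(make_column({"A": 8, "T": 2}), "A", "T") == pytest.approx(0.25)

    def test_fifty_fifty_boundary(self):
        assert site_maf(make_column({"A": 5, "T": 5}), "A", "T") == pytest.approx(1.0)

    def test_undefined_without_consensus_support(self):
        with pytest.raises(ValueError, match="MAF undefined"):
            site_maf(make_column({"T": 5}), "A", "T")

    def test_allele_must_differ(self):
        with pytest.raises(ValueError):
            site_maf(make_column({"A": 5}), "A", "A")


class TestDetectHeteroplasmy:
    def _pileup_with_site(self, ref, pos, counts):
        reads = []
        k = 0
        for base, n in counts.items():
            for _ in range(n):
                reads.append(make_read(pos, base, 40, rid=f"{base}{k}"))
                k += 1
        return build_pileup(reads, ref)

    def test_flags_above_threshold(self, small_ref):
        pile = self._pileup_with_site(small_ref, 50, {"A": 8, "T": 2})
        cons = build_consensus(pile, "majority")
        sites = detect_heteroplasmy(pile, cons, maf_threshold=0.10, min_depth=10)
        assert [s.position for s in sites] == [50]
        assert sites[0].minor_alleles["T"] == (2, pytest.approx(0.25))

    def test_below_threshold_not_flagged(self, small_ref):
        pile = self._pileup_with_site(small_ref, 50, {"A": 99, "T": 1})
        cons = build_consensus(pile, "majority")
        assert detect_heteroplasmy(pile, cons, 0.10, min_depth=10) == []

    def test_min_depth_gate(self, small_ref):
        pile = self._pileup_with_site(small_ref, 50, {"A": 4, "T": 2})
        cons = build_consensus(pile, "majority")
        assert detect_heteroplasmy(pile, cons, 0.10, min_depth=10) == []
        assert len(detect_heteroplasmy(pile, cons, 0.10, min_depth=5)) == 1

    def test_homoplasmic_genome_empty(self, small_ref):
        cfg = SimulationConfig(haplotype=small_ref.sequence, seed=4, depth=30,
                               read_length=30, error_rate=0.0)
        reads, _ = simulate_reads(cfg, small_ref)
        pile = build_pileup(reads, small_ref)
        cons = build_consensus(pile, "majority")
        assert detect_heteroplasmy(pile, cons, 0.0, min_depth=1) == []

    def test_negative_threshold_rejected(self, small_ref):
        pile = build_pileup([], small_ref)
        cons = build_consensus(pile, "majority")
        with pytest.raises(ValueError):
            detect_heteroplasmy(pile, cons, -0.1)

    def test_unanimous_site_consistency(self):
        """MAF 0 for every allele and P_support 100 at a unanimous site."""
        from mitoprofile import support_ratio

        col = make_column({"G": 17})
        for allele in "ACT":
            assert site_maf(col, "G", allele) == 0.0
        assert support_ratio(col, "G") == 100.0


def _enumerate_alignments(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive best global alignment score by recursion (oracle)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == len(a) and j == len(b):
            return 0
        opts = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            opts.append(s + best(i + 1, j + 1))
        if i < len(a):
            opts.append(gap + best(i + 1, j))
        if j < len(b):
            opts.append(gap + best(i, j + 1))
        return max(opts)

    return best(0, 0)


class TestAlignment:
    def test_identity_map(self):
        ref = ReferenceGenome("r", "ACGTACGT")
        m = align_consensus_to_reference("ACGTACGT", ref)
        assert m.pairs == [(i, i) for i in range(1, 9)]
        assert m.deleted_reference_positions == []

    def test_single_deletion_skips_reference_position(self):
        ref = ReferenceGenome("r", "ACGTACGT")
        m = align_consensus_to_reference("ACGACGT", ref)
        assert m.deleted_reference_positions == [4]
        # oracle: unique optimum under the stated scores
        assert _enumerate_alignments("ACGTACGT", "ACGACGT") == m.score

    def test_all_n_consensus_is_handled(self):
        ref = ReferenceGenome("r", "ACGTACGT")
        m = align_consensus_to_reference("N" * 8, ref)
        assert len(m.pairs) == 8  # every pair aligned, all mismatches
        assert m.score == -8

    def test_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(55)
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 9)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 9)))
            assert alignment_score(a, b) == _enumerate_alignments(a, b)


class TestCallVariants:
    def test_c150t_style_substitution(self, mito_ref):
        seq = list(mito_ref.sequence)
        refbase = seq[149]
        alt = {"A": "T", "T": "A", "C": "T", "G": "A"}[refbase]
        seq[149] = alt
        consensus = "".join(seq)
        m = align_consensus_to_reference(consensus, mito_ref)
        variants, inserted = call_variants(consensus, mito_ref, m)
        assert [v.label for v in variants] == [f"{refbase}150{alt}"]
        assert inserted == []

    def test_identical_consensus_no_variants(self, small_ref):
        m = align_consensus_to_reference(small_ref.sequence, small_ref)
        variants, _ = call_variants(small_ref.sequence, small_ref, m)
        assert variants == []

    def test_n_site_produces_no_variant(self, small_ref):
        seq = list(small_ref.sequence)
        seq[10] = "N"
        consensus = "".join(seq)
        m = align_consensus_to_reference(consensus, small_ref)
        variants, _ = call_variants(consensus, small_ref, m)
        assert variants == []

    def test_deletion_labelled_with_d(self, small_ref):
        consensus = small_ref.sequence[:19] + small_ref.sequence[20:]
        m = align_consensus_to_reference(consensus, small_ref)
        variants, _ = call_variants(consensus, small_ref, m)
        dels = [v for v in variants if v.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].label.endswith("d")


class TestAnnotation:
    def test_exact_match_join(self):
        db = [AnnotationRecord("C150T", "example-disease", "db1")]
        table = annotate_variants([Variant.parse("C150T")], db)
        assert len(table) == 1
        assert table.iloc[0]["info"] == "example-disease"

    def test_unmatched_variant_kept_empty(self):
        table = annotate_variants([Variant.parse("C150T")], [])
        assert len(table) == 1
        assert table.iloc[0]["info"] == ""

    def test_no_cross_matches(self):
        db = [AnnotationRecord("A4282G", "x", "db")]
        table = annotate_variants([Variant.parse("C150T")], db)
        assert (table["info"] == "").all()

    def test_multiple_db_rows_all_reported(self):
        db = [AnnotationRecord("C150T", "a", "db"), AnnotationRecord("C150T", "b", "db")]
        table = annotate_variants([Variant.parse("C150T")], db)
        assert sorted(table["info"]) == ["a", "b"]

    def test_csv_loading_skips_malformed_rows(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text("allele,disease\nC150T,thing one\nnot-an-allele,junk\nA4282G,thing two\n")
        records, skipped = load_annotation_db(p)
        assert [r.variant_label for r in records] == ["C150T", "A4282G"]
        assert skipped == 1  # header tolerated, junk row counted


class TestSpectrum:
    def test_identical_reads_zero_spectrum(self, small_ref):
        reads = [make_read(1, small_ref.sequence[:50], 40)]
        spec = substitution_spectrum(reads, small_ref)
        assert spec.no_mismatches
        assert all(v == 0 for v in spec.percentages.values())

    def test_counted_percentages(self, small_ref):
        # build reads giving exactly 3 C>T and 1 G>A mismatches
        seq = small_ref.sequence
        c_pos = [i + 1 for i, b in enumerate(seq) if b == "C"][:3]
        g_pos = [i + 1 for i, b in enumerate(seq) if b == "G"][:1]
        reads = [make_read(p, "T", 40, rid=f"c{p}") for p in c_pos]
        reads += [make_read(p, "A", 40, rid=f"g{p}") for p in g_pos]
        spec = substitution_spectrum(reads, small_ref)
        assert spec.counts["C>T"] == 3 and spec.counts["G>A"] == 1
        assert spec.percentages["C>T"] == pytest.approx(75.0)
        assert spec.percentages["G>A"] == pytest.approx(25.0)
        assert sum(spec.percentages.values()) == pytest.approx(100.0)

    def test_conservation_against_brute_force(self, small_ref):
        rng = np.random.default_rng(8)
        policy = FilterPolicy()
        reads = [
            make_read(
                int(rng.integers(1, 280)),
                "".join(rng.choice(list("ACGTN"), 15)),
                rng.integers(20, 45, 15).tolist(),
                rid=f"r{i}",
            )
            for i in range(60)
        ]
        spec = substitution_spectrum(reads, small_ref, policy)
        brute = 0
        for r in reads:
            for rpos, ri, is_del in r.aligned_pairs():
                if is_del:
                    continue
                b = r.bases[ri]
                if b in "ACGT" and r.qualities[ri] >= 30 and small_ref.base(rpos) != b:
                    brute += 1
        assert spec.total == brute

    def test_deamination_dominates_spectrum(self, small_ref):
        cfg = SimulationConfig(
            haplotype=small_ref.sequence, seed=31, depth=100, read_length=30,
            error_rate=0.0, deamination=(0.4, 5.0),
        )
        reads, _ = simulate_reads(cfg, small_ref)
        spec = substitution_spectrum(reads, small_ref)
        pct = spec.percentages
        assert pct["C>T"] + pct["G>A"] == pytest.approx(100.0)
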