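# Methods

`mitoprofile` profiles a single-sample alignment of short reads against one
mitochondrial reference sequence. Everything downstream of mapping is in
scope: pileup construction, consensus assembly, heteroplasmy detection,
haplogroup assignment, contamination and ancient-DNA damage indicators, and a
static QC report. Mapping itself, duplicate marking, indel realignment and
structural variation are out of scope; the expected input is a
coordinate-sorted BAM/SAM produced by a standard mapper.

## Coordinates and filtering

All positions are 1-based and fully closed, matching mitochondrial variant
nomenclature (C150T means reference position 150). The mitochondrial genome
is circular but mapped coordinates are linear; reads extending past the
reference end are rejected rather than wrapped, mirroring common
linear-rCRS practice. Origin-spanning analysis is a non-goal.

A `FilterPolicy` controls which bases enter the pileup:

| parameter | default | meaning |
|---|---|---|
| `min_base_quality` | 30 | a base is counted iff phred ≥ threshold |
| `min_mapping_quality` | 20 | reads below are excluded entirely |
| `exclude_duplicates` | true | honor the duplicate flag |
| `exclude_secondary` | true | drop secondary/supplementary alignments |

The quality boundary is inclusive (≥), so the default of 30 admits Q30 bases
— the common convention when a threshold is described as a cutoff "of 30".
No mapping-quality default is canonical for mtDNA; 20 is this package's
choice and is configurable everywhere. Non-ACGT read bases (N and IUPAC
ambiguity codes) are never counted and are logged once per process.

`raw_depth` at a position counts every read that spans it (including spans
deleted in the read) among reads passing the read-level filters, before the
base-quality filter; `filtered_depth` = counted bases + deletions. Defining
raw depth over spans keeps `filtered_depth ≤ raw_depth` true even at
deletion-only columns, since deletions carry no quality and always pass.

## Consensus rules

Three per-site rules, selected by `mode`:

* **majority** — argmax of filtered counts; a tie among the top counts gives
  `N`. A site where the deletion count strictly exceeds every base count is
  called `-`. (Tie between deletions and the best base: the base wins; a
  deletion call requires strict dominance.)
* **bestscore** — the base whose maximum observed phred is strictly highest,
  regardless of depth; ties give `N`. Deletions are ignored (no quality).
* **majority+bestscore** — majority first; a count tie with data is broken by
  the highest best phred among the tied bases; a double tie gives `N`.
  Zero-depth sites stay `N` (best-score has nothing to call there either).

The per-site support ratio is P_support = (N_agree / N_depth) × 100 with
N_depth the filtered depth; it is reported as missing (not 0) at zero-depth
sites. FASTA output drops `-` sites and keeps `N`; the header records mode
and thresholds. Heteroplasmy is never encoded in the consensus (no IUPAC
ambiguity calls).

## Heteroplasmy

A candidate allele's statistic at a site is MAF = N_diff / N_con, the ratio
of bases carrying the allele to bases carrying the consensus. This is
deliberately a ratio to the *concordant* bases — it exceeds 1 when the minor
allele outnumbers the consensus — and the conventional minor fraction
N_diff/(N_diff+N_con) is printed alongside it in the output table, clearly
labelled. A site is flagged when filtered depth ≥ `min_depth` (default 10),
the consensus is a real base, and some allele has MAF strictly above the
threshold (default 0.10). The depth gate is this package's addition: without
it a single discordant read at depth 2 is flagged.

## Consensus-vs-reference variants and annotation

The consensus FASTA string is globally aligned to the reference with
match +1, mismatch −1, gap −2 (linear gaps, end gaps penalised). The
alignment is delegated to Biopython's `PairwiseAligner`; of co-optimal
alignments, its first deterministic traceback is used. On small inputs the
score is property-tested against exhaustive enumeration. Aligned pairs with
differing A/C/G/T bases become substitutions (C150T), unmapped reference
positions become deletions (C150d), `N` sites yield nothing, and insertions
relative to the reference are reported as a side list without a
reference-position label. Annotation is an exact label join against
two-column CSV databases (allele, information); header rows are tolerated,
malformed rows are skipped and counted.

## Haplogroup assignment

The tree file is tab-delimited (name, parent, comma-separated tokens) in
PhyloTree-style nomenclature: `A73G`, back-mutations `A73G!`, deletions
`A249d`, insertions `16182.1C`. A node's cumulative state is the effective
position→allele map along the root-to-node path; a `!` token removes the
position from the map (reversion to reference), whether or not an ancestral
variant existed. Insertions are parsed and kept but excluded from scoring —
a pileup column cannot host an insertion under this data model — and the
excluded count is reported.

Each node is scored against the sample (per-site pileup majority by default,
or a consensus sequence): match / mismatch / nocall per cumulative variant.
The assignment score is (matches − mismatches) / max(1, scorable), ranked
descending with ties broken by more matches, then deeper node, then name.
The scoring function is the largest free design choice in the package and is
isolated behind `assign_haplogroup` for substitution. The deeper-node
tie-break means a node whose private variants are merely uncovered still
outranks its ancestor, which is the desired behaviour at low depth.

Contamination is summarised by
P_mismatch = [Σᵢ (N_mismatch,i / N_match,i) / k] × 100 over the k defining
sites of the assigned haplogroup, with N_match the filtered bases carrying
the defining allele. Sites with N_match = 0 would make the ratio infinite;
they are dropped from k and counted separately. P_mismatch is exactly 0 on a
clean, error-free sample and grows roughly like f/(1−f) with contamination
fraction f when the contaminant diverges at the defining sites.

## Damage indicators

Per-read-offset substitution rates are anchored at both fragment ends over
offsets 1..K (default K = 25, typical ancient-DNA reporting practice):
rate_5p[o] is the fraction of molecule-space reference-C positions at 5′
offset o read as T, and symmetrically G→A at the 3′ end; the other ten
substitutions are reported as background. Reverse-strand reads (bases stored
reference-oriented) are normalised into molecule coordinates by flipping
offsets to the opposite end and complementing both bases; flipping every
strand flag therefore exactly swaps the 5′ and 3′ tables, which the tests
pin. Rates condition on the reference base (the standard convention) and an
offset with no eligible positions is reported missing, not 0. The damage
module defaults to a base-quality floor of 20 instead of the pileup's 30,
since an aggressive cut biases damage rates downward; the CLI exposes it
separately. Fragment lengths are summarised as a histogram (bin width 5)
with mean and median. No likelihood-based damage model is fitted.

## Read simulator

The simulator provides ground truth for everything above. Reads are
single-end, length 100 by default, uniform start positions, read count
round(depth × L / read_length); the default error model is 1% i.i.d.
per-base substitutions uniform over the three alternatives. A contaminant
haplotype may be mixed in per-read with probability `contamination_fraction`
(capped at 0.5 so "host" stays the majority). Deamination is applied before
sequencing error: C→T at 5′ offset o with probability
rate0·exp(−(o−1)/decay), mirrored G→A at the 3′ end. Correct bases get Q37;
error bases get a configurable quality (default also Q37, so the quality
filter does not silently remove injected errors; setting it to 15 exercises
the filter path). Haplotypes are substitution-only so truth coordinates stay
aligned to the reference. Reads are emitted pre-aligned (mapping is upstream
of scope), coordinate-sorted, forward strand, bit-reproducible from
(config, seed).

What the simulator does **not** emulate: empirical quality profiles, indels,
paired ends, mapping artefacts, reference bias, coverage waviness. Passing
tests demonstrate internal correctness of the statistics and the pipeline's
recovery of known parameters under this idealised model — not performance on
real libraries.

## Validation experiment sizes

The bundled validation experiments (`mitoprofile.validation`, also driven by
`scripts/acceptance.py`) use a 16,569 bp synthetic reference, a 16-node
random tree with 4 defining variants per branch, 100 samples per depth in
the accuracy-by-depth experiment (depths 1–50×), a 30-variant host vs
reference-state contaminant for the contamination sweep at 100× over
fractions 0–30%, damage recovery at 100× with rate0 = 0.3 and decay 3, and
heteroplasmy scenarios of 25% minor at 40× and 1% minor at 100×. These sizes
were chosen as the package's standard desk-scale validation configuration.

## Numerical and degenerate-input choices

* Zero-depth consensus sites are `N`; empty inputs produce an all-N
  consensus, empty heteroplasmy list and a `no_data` flag rather than errors.
* Coverage breadth uses strict inequality (fraction of genome with depth
  > t) at thresholds {10, 20, 30, 40, 50}.
* Support ratio of an `N` call is an error by contract; of a zero-depth site,
  missing.
* `p_mismatch` with every defining site at zero matches raises rather than
  returning a number.
* All tabular outputs are byte-deterministic for a fixed configuration; the
  HTML report differs only in its timestamp. Chart SVGs use a fixed hash salt
  and no embedded date.

## Known limitations

* Insertion variants are second-class: parsed in trees, listed from the
  aligner, never scored or labelled positionally.
* The haplogroup score is a heuristic match ratio, not a likelihood; closely
  related nodes separated only by insertions or by sites with no coverage
  tie and resolve by the documented tie-break.
* MAF as defined here is not comparable across tools that divide by total
  depth; use the `minor_fraction` column for that.
* The global aligner is exact but O(L²); for a 16.5 kb genome it takes a few
  seconds, which is acceptable for a per-sample tool.
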