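# Methods

This note documents the models, conventions and numerical choices
behind `croma`, what the synthetic data emulate, and the limits of what
desk-scale tests can show.

## Probe geometry and coordinates

All internal coordinates are 0-based, half-open; exported tables use
1-based positions (the array-manifest convention) and label them as
such. A probe is a 50-mer flanking a target CpG, whose C sits at
`site` on the forward strand:

| option | window (forward coords) | contains target C? |
|---|---|---|
| Type II, forward | `[site-50, site)` | no |
| Type I, forward | `[site-49, site+1)` | yes (last base) |
| Type II, reverse | `[site+2, site+52)` | no |
| Type I, reverse | `[site+1, site+51)` | yes |

Reverse designs mirror the forward geometry about the G at `site+1`
and are synthesized as the reverse complement of the window. Which
physical side the manufactured probes occupy is not recoverable from
the assay chemistry alone; this convention is fixed here and used
consistently by every downstream module (selection, mapping, CpG
projection), so all internal bookkeeping is self-consistent. Degenerate
offsets are stored in genomic window orientation and remapped (offset
→ 49−offset, alternate complemented) when an oriented probe string is
built.

Degenerate bases inside the target CpG itself are forbidden: a species
lacking the CpG has nothing to measure, so tolerating the mutation is
meaningless.

## Selection model

The budget *M* is `design_cap` (default constant 3, the chemistry's
ceiling) minus, for Type II probes only, the number of CG dinucleotides
in the window — each needs both methylation states tolerated and
spends one unit. The proprietary per-probe design score that can lower
the cap is modelled as a pluggable callable of the window sequence.

Species feasibility is evaluated over the probe window *plus* the CpG
columns: any gap or unaligned column, an insertion relative to the
reference inside the window, a non-conserved CpG, or more than *M*
substitutions disqualifies the species. How insertions inside the
window should be treated is genuinely open; they are flagged and the
species excluded rather than silently resolved, because a
substitution-only degenerate set cannot re-align an indel.

The combination enumeration reads "all |P| choose M combinations" as
*distinct sub-multisets of size min(M, |P|)*, which also covers
|P| < M. Coverage is monotone in the tolerated set, so no smaller
sub-multiset can beat a full-size one. Ties break deterministically:
combinations are enumerated in sorted order and only strictly better
coverage replaces the incumbent, so the smallest offsets and
alphabetically first alternates win. Per offset at most 3 alternates
exist (all non-reference bases). The reference species always counts
toward coverage; the candidate tables carry the covered-species list,
so totals without the reference are one subtraction away.

Mismatches are compared in strict genomic space by default — the
design question is whether the alignment shows *any* difference.  A
`bisulfite_collapsed` mode (non-CpG C/T equivalence, oriented by the
design strand) exists because the manufactured assay reads converted
DNA; it is off by default and changes only the mismatch definition,
not the machinery.

No post-hoc pruning of coverage-neutral alternates is performed — the
greedy enumeration keeps whatever the top-k rule selected.

### Optimality

`exhaustive_coverage` enumerates every (offset, alternate) set of size
≤ *M* over the observed mismatch pairs and is the independent
cross-check used by tests and the acceptance script. The greedy
enumeration equals it whenever each position in *P* has one distinct
alternate among feasible species (then the top-k choice is forced);
with conflicting alternates at one offset it can in principle fall
short, though on the random-instance distribution used for validation
(≤ 8 species, window 10, M ≤ 2) the observed equality rate is 100 %.

## Assembly pipeline

Selection steps: **S1** all Type II probes covering the model species
(coordinate order); **S2** remaining sites by descending Type II
coverage until `total_after_topup`; **S3** EPIC-listed CpGs not yet
selected, with the EPIC probe type and strand but this pipeline's
degenerate bases, top `n_epic` by coverage; **S4** remaining sites by
descending Type I coverage, top `n_typeI`. All coverage sorts break
ties by ascending genomic coordinate; a CpG is selected at most once,
keeping its earliest provenance. Full-scale design totals
(53 000 / 3 000 / 4 000) are configuration defaults; fixture runs use
toy totals since the real counts require a genome-scale alignment.

The mappability filter retains a probe iff its unique fraction over the
high-quality panel genomes it targets is ≥ 0.8, or its species coverage
is ≥ 40. The fraction's denominator ("species the probe is expected to
target") admits two readings; both are implemented —
panel ∩ covered-species (default) and whole panel.

Design probes receive synthesized `cg` + zero-padded ordinal IDs
(manufacturer IDs are not derivable); S3 probes inherit their EPIC
CpG id. Biomarker probes keep their own ids (`cg`/`ch`/`rs`); a
biomarker colliding with a design probe at the same cytosine keeps
both rows, suffixed `.1` (design) and `.2` (biomarker).

## Mappability

A probe applies to a genome when all expanded versions of its IUPAC
sequence match the genome full-length with zero mismatches, on either
strand, and the union of all hits is a single locus (versions hitting
the same locus collapse — the union rule; a stricter per-version rule
is available by flag since the criterion admits either reading).
Comparison is in bisulfite-converted space with every CpG treated as
methylated; Type I probes contribute only their methylated
representative, which the genomic-space IUPAC encoding produces
naturally. No external aligner is wrapped or parameterized — the
accepted-match criterion (perfect full-length hit) is the contract,
and it is what defines the statistic.

The engine seeds with the converted 24-mer prefix (internal context
makes prefix conversion unambiguous) and verifies column-by-column; a
probe's terminal C borrows the genome's next base as CpG context,
since the probe represents a genomic window that continues there.
An independent vectorized sliding-window scan (`reference_search`)
checks every position directly; engine and scan are separate code
paths and are required to agree exactly. Strict-mode hits are a subset
of collapsed-mode hits by construction (conversion is a function of
the string).

Each unique hit is projected back to its implied target-CpG position
(Type II: 50 bases past the oriented probe start; Type I: 49; mirrored
for minus-strand hits) and verified to show an intact CG in the target
genome; only unique, CpG-verified probes are exported to per-species
coordinate tables.

## Annotation

The probe's position for all overlap purposes is the single C base.
Promoters span −10 kb/+100 bp around the nearest TSS *in gene
orientation* (upstream means 5′ of the gene — the biologically
meaningful reading of an upstream window).
Region priority: exon > promoter > intron > 5′UTR > 3′UTR >
intergenic, invariant to feature input order. Fold enrichment is
`(k_on/n_on) / (K_bg/N_bg)` with a zero background flagged rather than
returned. Ortholog concordance counts a probe as concordant only when
the species-side call is genic *and* its nearest gene is the ortholog
of the reference-side gene; discordant intergenic calls are tallied
separately since they usually indicate an unassignable rather than a
divergent probe. CpG-island calling itself is out of scope — islands
are consumed as BED intervals.

## Calibration model

The simulator emulates premixed calibration standards measured at the
five ProportionMethylated levels 0, 0.25, 0.5, 0.75, 1. Default
design: 4 replicate arrays per level (the mouse protocol; human used
2, rat 3). Per probe *i* and level *p*:

    beta = Binomial(depth, clip(p + bias_i, 0, 1)) / depth

with `depth = 100` sampled molecules, `bias_i ~ N(0, bias_scale)` and
`bias_scale = 0` by default — pure binomial sampling, the regime in
which variance = mean·(1−mean)/depth holds exactly. A planted
fraction `f_fail` of probes draws betas uniformly on [0, 1]
independent of level, standing in for probes that do not work in the
target species; their benchmark correlation is ≈ 0 in expectation, so
the r < 0.8 filter (strictly below; undefined correlations also
removed) should recover almost exactly the planted set.

What the simulator does *not* emulate: normalization artefacts (betas
are consumed post-normalization by design), probe-specific dynamic
range compression, dye/channel effects, or spatial artefacts. Passing
tests therefore demonstrate the *analysis* is correct, not that real
arrays are this clean — real calibration data show broad per-probe
peaks, which `bias_scale > 0` can imitate; note a per-probe bias σ
inflates the fitted heteroscedasticity constant above 1/depth by
roughly σ²/⟨m(1−m)⟩.

The mean–variance relation is fitted over per-level beta
*distributions*: at each level, the mean and unbiased variance of all
betas (probes × replicate arrays) give one (m·(1−m), v) point; c is
the least-squares slope through the origin and r the Pearson
correlation across levels. Two finer groupings were considered and
rejected: per probe across all arrays lets the level spread dominate
every variance (c → 0.5 regardless of depth), and per (probe, level)
cells with ≤ 4 replicates make each sample variance χ²-noisy with
noise proportional to signal, capping the achievable correlation near
0.65 at any depth. The distribution-level statistic recovers c = 1/d
exactly under binomial sampling and directly expresses the
heteroscedasticity claim (spread is largest mid-scale).

Threshold counts use strict `>` (matching "exceed a correlation of"),
excluding undefined correlations. Cross-platform comparison takes
per-probe means within each platform over its samples, then a Pearson
correlation over shared ids; sequencing-derived input is converted
from (methylated, total) counts with an optional minimum-depth filter
(≥ 3 reads is the convention used for WGBS comparisons).

## Synthetic fixtures

`make_fixtures(seed, out)` writes a byte-deterministic bundle: a 50 kb
random reference chromosome, a 10-species MAF in 1 kb blocks
(per-base substitution rate 1.2 %, deletion 0.2 %, insertion 0.08 %,
90 % species presence per block, one species periodically recorded on
the minus source strand to exercise coordinate bookkeeping), one
hand-planted site with a known mismatch structure, two derived target
genomes (one carrying a duplicated probe window, guaranteed non-unique),
a three-gene GFF3, island/state BED tracks, EPIC-style metadata and a
biomarker list. A sidecar `truth.json` records, for a sample of sites,
the exhaustive-optimizer coverage per design option, computed at
generation time — tests compare the production selector against these
frozen values. Random site alignments for selector stress tests use
window 10 with mixed substitution/gap/unaligned/CpG-loss/insertion
events at rates chosen to exercise every feasibility rule.

Problem sizes used throughout (500 selector instances, 50 mapper
genomes of 5–20 kb, 2000 calibration probes) are the package's chosen
desk-scale study conditions; a full-scale design additionally
requires a genome-scale 100-way alignment and a panel of reference
genomes, which these fixtures deliberately do not attempt to
reproduce.

## Known limitations

* The greedy top-k alternate choice is not globally optimal in
  adversarial cases with many conflicting alternates at one offset.
* The exact-match engine is designed for desk-scale genomes (full
  text scan per chromosome with seeding); genome-scale use would want
  an FM-index or aligner-backed backend behind the same match
  definition.
* Gene models assume exon features carry transcript→gene parentage in
  the GFF3; GTF input relies on gffutils inference.
* The assembly step cannot reproduce any manufactured array's exact
  probe content — manufacturer design scores are proprietary; the
  pipeline implements the *rules*, validated on fixtures.
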