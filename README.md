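# croma

**Cross-species methylation array design and validation toolkit.**

Infinium methylation arrays measure cytosine methylation with 50 bp
probes hybridizing to bisulfite-converted DNA. A probe designed against
one reference genome only works in another species if the probe window
is conserved there — unless the probe is synthesized with *degenerate
bases*, IUPAC mixtures at chosen positions that tolerate specified
cross-species substitutions. `croma` implements the full design loop
for a conserved, multi-species array:

* **probe selection** — for every CpG site of a reference genome and
  every design option (Infinium I/II × forward/reverse strand), choose
  up to *M* degenerate bases from a multiple-species alignment so that
  the probe is expected to work in as many species as possible;
* **array assembly** — the staged selection pipeline (model-species
  set, coverage top-up, EPIC-compatible sites, Type I complement),
  an in-silico bisulfite mappability filter (unique mapping in ≥ 80 %
  of targeted high-quality genomes, or ≥ 40 covered species), and a
  biomarker-probe merge with `.1`/`.2` duplicate suffixes;
* **mappability** — exact full-length matching of every expanded probe
  version against target genomes in bisulfite-converted space (all
  CpGs treated as methylated), uniqueness verdicts, and target-CpG
  verification per locus;
* **annotation** — nearest-TSS gene regions with the priority
  exon > promoter (−10 kb/+100 bp) > intron > 5′UTR > 3′UTR >
  intergenic, BED-interval overlap (CpG islands, chromatin states),
  fold enrichment, and ortholog concordance between species;
* **calibration benchmarking** — per-probe Pearson correlation of beta
  values against known methylation standards (ProportionMethylated ∈
  {0, 0.25, 0.5, 0.75, 1}), threshold counts, outlier removal at
  r < 0.8, the binomial mean–variance relation
  var = c·m·(1−m), and cross-platform mean-methylation comparison —
  plus a seeded simulator of calibration standards.

## The selection algorithm

For one CpG site and design option, let *M* be the degenerate-base
budget (a design-score cap, default 3; for Type II probes each CG
dinucleotide in the window spends one unit). For each aligned species
*s*, let *M*ₛ be its substitution count over the probe window. Species
with gaps, unaligned columns, insertions, a non-conserved CpG, or
*M*ₛ > *M* are infeasible; the rest form the feasible set *F*, and
their mismatch positions fill a multiset *P*. For every distinct
sub-multiset *S* ⊆ *P* of size min(*M*, |*P*|), each unique position
occurring *k* times in *S* takes the *k* alternative nucleotides
carried by the most species in *F*; the combination covering the most
species wins (deterministic tie-breaks). Per probe type, the strand
with the greater species coverage is retained, ties to forward.

An exhaustive optimizer over all (position, alternate) sets of size
≤ *M* ships alongside as an independent cross-check; the enumeration
provably equals it whenever each position in *P* carries a single
distinct alternate.

## Worked example

Selecting degenerate bases at one CpG from a toy six-species alignment
(probe window of 10 columns, target CpG appended):

```python
from croma import (ProbeDesignOption, ProbeType,
                   build_mismatch_profile, select_degenerate_bases)
from croma.alignment_io import SiteAlignment

ref = "ACGAACGTAA" + "CG"
rows = {
    "human": ref,
    "chimp": ref,
    "mouse": "ACTAACGTAA" + "CG",   # G->T at offset 2
    "rat":   "ACTAACGTAA" + "CG",   # same substitution
    "dog":   "ACGATCGTAA" + "CG",   # A->T at offset 4
    "cow":   "ACGAACGTAA" + "CA",   # CpG lost
}
sa = SiteAlignment(chrom="chr1", cpg_position=10,
                   option=ProbeDesignOption(ProbeType.II, "+"),
                   window=(0, 12), probe_interval=(0, 10),
                   reference_seq=ref, reference_species="human",
                   species_rows=rows, insertion={s: False for s in rows})

for M in (0, 1, 2):
    profile = build_mismatch_profile(sa, M)
    degenerate, covered = select_degenerate_bases(profile, M)
    print(f"M={M}: degenerate="
          f"{[(d.window_offset, d.alternate) for d in degenerate]}"
          f" covered={sorted(covered)}")
```

prints

```
M=0: degenerate=[] covered=['chimp', 'human']
M=1: degenerate=[(2, 'T')] covered=['chimp', 'human', 'mouse', 'rat']
M=2: degenerate=[(2, 'T'), (4, 'T')] covered=['chimp', 'dog', 'human', 'mouse', 'rat']
```

With no budget only the exact-match species are covered; one degenerate
base buys the substitution shared by mouse and rat; a second adds dog.
Cow lacks the target CpG, so no substitution set can rescue it.

Benchmarking simulated calibration standards (2000 probes, sampling
depth 100, four arrays per methylation level, 10 % planted failing
probes):

```python
from croma import (SimulatorConfig, simulate_calibration,
                   correlate_with_benchmark, threshold_counts,
                   filter_outliers, mean_variance_check)

config = SimulatorConfig(seed=1, n_probes=2000, depth=100,
                         replicates_per_level=4, f_fail=0.1)
ds = simulate_calibration(config)
r = correlate_with_benchmark(ds)
print("median r:", round(float(r.median()), 4))
print("threshold counts:", threshold_counts(r))
filtered, removed = filter_outliers(ds, r, cutoff=0.8)
print("removed:", len(removed), "of", ds.n_probes,
      "(planted failing:", len(ds.failing_probes), ")")
print(mean_variance_check(filtered).summary())
```

prints

```
median r: 0.9954
threshold counts: {0.85: 1784, 0.9: 1784, 0.95: 1784}
removed: 216 of 2000 (planted failing: 216 )
Mean-variance relation: variance = c * mean * (1 - mean)
  distribution cells:    5
  fitted c:              0.01001
  Pearson r(var, m(1-m)): 1.000
```

Working probes track the benchmark almost perfectly (median r ≈ 0.995),
the r < 0.8 filter removes exactly the 216 planted failing probes, and
the fitted heteroscedasticity constant recovers 1/depth = 0.01.

The same steps are available from a shell:

```bash
croma make-fixtures --seed 7 --out fixtures/
croma design --maf fixtures/alignment.maf --fasta fixtures/reference.fa \
      --reference-species refg1 --out candidates.csv
croma assemble --candidates candidates.csv --model-species spc1 \
      --total-after-topup 200 --out manifest.csv
croma map --manifest manifest.csv --genome fixtures/toyB.fa \
      --mode bisulfite_collapsed --out mappability.csv
croma annotate --manifest manifest.csv --gff3 fixtures/genes.gff3 \
      --bed island=fixtures/islands.bed --out annotated.csv
```

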