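"""Deterministic desk-scale fixture bundle.

Generates a toy study: a 50 kb reference chromosome, a 10-species MAF
alignment with controlled substitution/gap/insertion patterns (plus one
hand-planted site with a known coverage structure), two toy target
genomes for mappability (one with a deliberately duplicated probe
window), a small gene model, interval tracks, EPIC-style metadata and a
biomarker probe list.  A sidecar ``truth.json`` records ground truth
computed at generation time with the exhaustive (brute-force) coverage
optimizer, so tests can compare the production selector against an
independent oracle.

Everything is a plain-text format (FASTA, MAF, GFF3, BED, CSV, JSON)
and byte-identical for a given seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .alignment_io import (
    AlignmentBlock,
    AlignmentRow,
    ReferenceGenome,
    enumerate_cpg_sites,
    extract_site_alignment,
    write_maf,
)
from .selection import build_mismatch_profile, exhaustive_coverage
from .probe_model import ALL_OPTIONS, max_degenerate_budget
from .alignment_io import SiteSkipped

REFERENCE_SPECIES = "refg1"
SPECIES = [f"spc{i}" for i in range(1, 10)]  # nine non-reference species
CHROM = "chr1"
CHROM_LENGTH = 50_000
BLOCK_SIZE = 1_000
SRC_SIZE = 1_000_000

SUBSTITUTION_RATE = 0.012
GAP_RATE = 0.002
INSERTION_RATE = 0.0008
SPECIES_PRESENCE = 0.9

BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate_row(rng: np.random.Generator, ref: str) -> tuple[str, str]:
    """Species row aligned to a reference segment: returns (ref_aligned,
    species_aligned) with '-' gaps; may introduce insertion columns."""
    ref_out, sp_out = [], []
    for ch in ref:
        u = rng.random()
        if u < GAP_RATE:
            ref_out.append(ch)
            sp_out.append("-")
            continue
        if u < GAP_RATE + INSERTION_RATE:
            ins = "".join(rng.choice(BASES, size=rng.integers(1, 4)))
            ref_out.append("-" * len(ins))
            sp_out.append(ins)
        if rng.random() < SUBSTITUTION_RATE:
            alts = [b for b in "ACGT" if b != ch]
            ref_out.append(ch)
            sp_out.append(alts[rng.integers(0, 3)])
        else:
            ref_out.append(ch)
            sp_out.append(ch)
    return "".join(ref_out), "".join(sp_out)


def _merge_alignments(ref_seq: str, per_species: dict[str, tuple[str, str]],
                      ) -> tuple[str, dict[str, str]]:
    """Project pairwise ref/species alignments onto common columns."""
    # column plan: for each ref base, the max insertion length after it
    n = len(ref_seq)
    ins_after = np.zeros(n + 1, dtype=int)
    parsed = {}
    for s, (ra, sa) in per_species.items():
        cols = []
        ref_i = 0
        pending_ins = ""
        per_base = []  # (species_char_at_ref_base, insertion_after)
        lead_ins = ""
        for rc, sc in zip(ra, sa):
            if rc == "-":
                if ref_i == 0:
                    lead_ins += sc
                else:
                    per_base[-1][1].append(sc)
            else:
                per_base.append([sc, []])
                ref_i += 1
        parsed[s] = (lead_ins, per_base)
        if lead_ins:
            ins_after[0] = max(ins_after[0], len(lead_ins))
        for i, (_, ins) in enumerate(per_base):
            if ins:
                ins_after[i + 1] = max(ins_after[i + 1], len(ins))
    ref_cols = []
    ref_cols.append("-" * ins_after[0])
    for i, ch in enumerate(ref_seq):
        ref_cols.append(ch + "-" * ins_after[i + 1])
    ref_aligned = "".join(ref_cols)
    out = {}
    for s, (lead_ins, per_base) in parsed.items():
        cols = [lead_ins.ljust(ins_after[0], "-")]
        for i, (sc, ins) in enumerate(per_base):
            cols.append(sc + "".join(ins).ljust(ins_after[i + 1], "-"))
        out[s] = "".join(cols)
    return ref_aligned, out


def _build_blocks(rng: np.random.Generator, ref: str) -> list[AlignmentBlock]:
    blocks = []
    counters = {s: 0 for s in SPECIES}
    for start in range(0, len(ref), BLOCK_SIZE):
        seg = ref[start:start + BLOCK_SIZE]
        present = [s for s in SPECIES if rng.random() < SPECIES_PRESENCE]
        pair = {s: _mutate_row(rng, seg) for s in present}
        ref_aligned, sp_aligned = _merge_alignments(seg, pair)
        rows = {REFERENCE_SPECIES: AlignmentRow(
            src=f"{REFERENCE_SPECIES}.{CHROM}", start=start, size=len(seg),
            strand="+", src_size=len(ref), text=ref_aligned)}
        for s in present:
            text = sp_aligned[s]
            size = sum(1 for c in text if c != "-")
            strand = "-" if (s == SPECIES[0] and (start // BLOCK_SIZE) % 3 == 1) \
                else "+"
            src_start = counters[s] if strand == "+" else \
                SRC_SIZE - counters[s] - size
            rows[s] = AlignmentRow(
                src=f"{s}.scaf1", start=src_start, size=size,
                strand=strand, src_size=SRC_SIZE, text=text)
            counters[s] += size
        blocks.append(AlignmentBlock(reference=rows[REFERENCE_SPECIES],
                                     rows=rows))
    return blocks


def _plant_known_site(blocks: list[AlignmentBlock], ref: str) -> int | None:
    """Overwrite species rows around one CpG with a known structure:
    spc1 exact, spc2/spc3 share one substitution, spc4 a different one,
    spc5 lacks the CpG.  Returns the planted site or None."""
    genome = ReferenceGenome({CHROM: ref})
    sites = [p for p in enumerate_cpg_sites(genome, CHROM)
             if 30_100 < p < 30_800]
    if not sites:
        return None
    site = sites[0]
    block = next(b for b in blocks
                 if b.reference_start <= site and site + 2 <= b.reference_end)
    ref_text = block.reference.text
    # column index of each reference position in the block
    col_of = {}
    pos = block.reference_start
    for col, ch in enumerate(ref_text):
        if ch != "-":
            col_of[pos] = col
            pos += 1
    window = [col_of[p] for p in range(site - 52, site + 4)
              if p in col_of and p >= block.reference_start]

    def overwrite(species: str, edits: dict[int, str]) -> None:
        row = block.rows.get(species)
        base = list(ref_text)
        for col, ch in edits.items():
            base[col] = ch
        text = "".join(base)
        size = sum(1 for c in text if c != "-")
        block.rows[species] = AlignmentRow(
            src=f"{species}.scaf1",
            start=row.start if row else 0, size=size, strand="+",
            src_size=SRC_SIZE, text=text)

    c_mm = col_of[site - 10]
    c_mm2 = col_of[site - 25]
    ref_at = ref_text[c_mm]
    alt = "A" if ref_at != "A" else "G"
    ref_at2 = ref_text[c_mm2]
    alt2 = "T" if ref_at2 != "T" else "C"
    overwrite("spc1", {})
    overwrite("spc2", {c_mm: alt})
    overwrite("spc3", {c_mm: alt})
    overwrite("spc4", {c_mm2: alt2})
    g_col = col_of[site + 1]
    g_ref = ref_text[g_col]
    overwrite("spc5", {g_col: "A" if g_ref != "A" else "T"})
    return site


def _design_truth(blocks, genome, sites, comparison="strict"):
    """Exhaustive-oracle coverage per site and option, recorded as truth."""
    records = []
    for site in sites:
        for option in ALL_OPTIONS:
            try:
                sa = extract_site_alignment(
                    blocks, genome, CHROM, site, option,
                    reference_species=REFERENCE_SPECIES,
                    all_species=SPECIES)
            except SiteSkipped:
                continue
            M = max_degenerate_budget(option, sa.reference_probe_seq())
            profile = build_mismatch_profile(sa, M, comparison)
            _, covered = exhaustive_coverage(profile, M)
            records.append({
                "site": site, "probe_type": option.probe_type.value,
                "strand": option.strand, "M": M,
                "optimal_coverage": len(covered),
            })
    return records


def _toy_target_genomes(rng: np.random.Generator, ref: str,
                        dup_site: int) -> dict[str, str]:
    """Two target genomes derived from the reference.  toyA carries a
    duplicated copy of the window around ``dup_site``."""
    a = list(ref[20_000:40_000])
    protected = range(dup_site - 60 - 20_000, dup_site + 10 - 20_000)
    for i in range(len(a)):  # sparse mutations away from the dup region
        if i not in protected and rng.random() < 0.001:
            a[i] = "ACGT"[rng.integers(0, 4)]
    dup = ref[dup_site - 55: dup_site + 5]
    toy_a = "".join(a) + _random_sequence(rng, 200) + dup
    b = list(ref[10_000:30_000])
    for i in range(len(b)):
        if rng.random() < 0.002:
            b[i] = "ACGT"[rng.integers(0, 4)]
    return {"toyA": toy_a, "toyB": "".join(b)}


def random_site_alignment(rng: np.random.Generator, n_species: int = 8,
                          window: int = 10, mismatch_rate: float = 0.15,
                          gap_prob: float = 0.08,
                          unaligned_prob: float = 0.05,
                          cpg_loss_prob: float = 0.12,
                          insertion_prob: float = 0.05,
                          option=None):
    """A random per-CpG site alignment for selector stress-testing.

    The probe window has ``window`` columns followed by the two CpG
    columns.  Species carry independent random substitutions, and with
    small probabilities a gap column, an unaligned column, a broken
    CpG, or an insertion flag — the event mix of a diverged but mostly
    alignable mammalian site.
    """
    from .alignment_io import SiteAlignment
    from .probe_model import ProbeDesignOption, ProbeType

    if option is None:
        option = ProbeDesignOption(ProbeType.II, "+")
    ref = "".join(rng.choice(BASES, size=window)) + "CG"
    rows = {}
    insertion = {}
    for i in range(n_species):
        name = f"s{i:02d}"
        chars = list(ref)
        for j in range(window):
            u = rng.random()
            if u < gap_prob:
                chars[j] = "-"
            elif u < gap_prob + unaligned_prob:
                chars[j] = "."
            elif u < gap_prob + unaligned_prob + mismatch_rate:
                alts = [b for b in "ACGT" if b != ref[j]]
                chars[j] = alts[rng.integers(0, 3)]
        if rng.random() < cpg_loss_prob:
            which = window + int(rng.integers(0, 2))
            alts = [b for b in "ACGT" if b != ref[which]]
            chars[which] = alts[rng.integers(0, 3)]
        rows[name] = "".join(chars)
        insertion[name] = bool(rng.random() < insertion_prob)
    ref_name = "ref"
    rows[ref_name] = ref
    insertion[ref_name] = False
    return SiteAlignment(
        chrom="chrT", cpg_position=window, option=option,
        window=(0, window + 2), probe_interval=(0, window),
        reference_seq=ref, reference_species=ref_name,
        species_rows=rows, insertion=insertion)


GFF3_TEMPLATE = """##gff-version 3
{chrom}\ttoy\tgene\t{g1s}\t{g1e}\t.\t+\t.\tID=geneA
{chrom}\ttoy\tmRNA\t{g1s}\t{g1e}\t.\t+\t.\tID=geneA.t1;Parent=geneA
{chrom}\ttoy\texon\t{g1s}\t{e1e}\t.\t+\t.\tID=geneA.e1;Parent=geneA.t1
{chrom}\ttoy\texon\t{e2s}\t{g1e}\t.\t+\t.\tID=geneA.e2;Parent=geneA.t1
{chrom}\ttoy\tfive_prime_UTR\t{g1s}\t{u1e}\t.\t+\t.\tID=geneA.u5;Parent=geneA.t1
{chrom}\ttoy\tthree_prime_UTR\t{u3s}\t{g1e}\t.\t+\t.\tID=geneA.u3;Parent=geneA.t1
{chrom}\ttoy\tgene\t{g2s}\t{g2e}\t.\t-\t.\tID=geneB
{chrom}\ttoy\tmRNA\t{g2s}\t{g2e}\t.\t-\t.\tID=geneB.t1;Parent=geneB
{chrom}\ttoy\texon\t{g2s}\t{x1e}\t.\t-\t.\tID=geneB.e1;Parent=geneB.t1
{chrom}\ttoy\texon\t{x2s}\t{g2e}\t.\t-\t.\tID=geneB.e2;Parent=geneB.t1
{chrom}\ttoy\tgene\t{g3s}\t{g3e}\t.\t+\t.\tID=geneC
{chrom}\ttoy\tmRNA\t{g3s}\t{g3e}\t.\t+\t.\tID=geneC.t1;Parent=geneC
{chrom}\ttoy\texon\t{g3s}\t{g3e}\t.\t+\t.\tID=geneC.e1;Parent=geneC.t1
"""


def _write_gff3(path: Path) -> None:
    path.write_text(GFF3_TEMPLATE.format(
        chrom=CHROM,
        g1s=12_001, g1e=16_000, e1e=12_800, e2s=14_500,
        u1e=12_200, u3s=15_700,
        g2s=25_001, g2e=28_000, x1e=25_900, x2s=27_200,
        g3s=42_001, g3e=44_000,
    ))


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write the fixture bundle; returns a manifest of paths and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    ref = _random_sequence(rng, CHROM_LENGTH)
    genome = ReferenceGenome({CHROM: ref}, assembly_label=REFERENCE_SPECIES)
    blocks = _build_blocks(rng, ref)
    planted_site = _plant_known_site(blocks, ref)

    fasta_path = out / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(ref), 60):
            fh.write(ref[i:i + 60] + "\n")
    maf_path = out / "alignment.maf"
    write_maf(blocks, maf_path)

    sites = enumerate_cpg_sites(genome, CHROM)
    sample = [s for s in sites if 10_000 <= s < 11_500][:25]
    if planted_site is not None:
        sample.append(planted_site)
    truth_design = _design_truth(blocks, genome, sample)

    dup_site = next(s for s in sites if s > 25_000)
    targets = _toy_target_genomes(rng, ref, dup_site)
    genome_paths = {}
    for name, seq in targets.items():
        p = out / f"{name}.fa"
        with open(p, "w") as fh:
            fh.write(f">{name}_chr1\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
        genome_paths[name] = str(p)

    _write_gff3(out / "genes.gff3")
    (out / "islands.bed").write_text(
        f"{CHROM}\t12000\t12600\n{CHROM}\t25400\t26000\n{CHROM}\t42100\t42500\n")
    (out / "states.bed").write_text(
        f"{CHROM}\t11500\t13000\tTSS\n{CHROM}\t30000\t32000\tquiescent\n")

    epic_sites = [s for s in sites if 15_000 <= s < 20_000][::7][:10]
    with open(out / "epic.csv", "w") as fh:
        fh.write("cpg_id,chrom,position,probe_type,strand\n")
        for i, s in enumerate(epic_sites):
            ptype = "II" if i % 2 == 0 else "I"
            strand = "+" if i % 3 != 0 else "-"
            fh.write(f"cgE{i + 1:07d},{CHROM},{s + 1},{ptype},{strand}\n")

    bio_site = next(s for s in sites if s > 35_000)
    with open(out / "biomarkers.csv", "w") as fh:
        fh.write("probe_id,chrom,position,probe_type,strand,sequence\n")
        fh.write(f"cgB0000001,{CHROM},{bio_site + 1},II,+,"
                 f"{ref[bio_site - 50:bio_site]}\n")
        fh.write(f"ch.1.0000001,{CHROM},{bio_site + 201},II,+,"
                 f"{ref[bio_site + 150:bio_site + 200]}\n")
        fh.write(f"rs000001,{CHROM},{bio_site + 401},II,+,"
                 f"{ref[bio_site + 350:bio_site + 400]}\n")

    truth = {
        "seed": int(seed),
        "reference_species": REFERENCE_SPECIES,
        "species": SPECIES,
        "chrom": CHROM,
        "planted_site": planted_site,
        "design_truth": truth_design,
        "duplicated_probe_site": int(dup_site),
        "epic_sites": [int(s) for s in epic_sites],
        "biomarker_site": int(bio_site),
        "paths": {
            "reference": str(fasta_path),
            "maf": str(maf_path),
            "gff3": str(out / "genes.gff3"),
            "islands": str(out / "islands.bed"),
            "states": str(out / "states.bed"),
            "epic": str(out / "epic.csv"),
            "biomarkers": str(out / "biomarkers.csv"),
            **{f"genome_{k}": v for k, v in genome_paths.items()},
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
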