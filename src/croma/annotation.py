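"""Genomic annotation of probe coordinates.

Gene-region assignment against a GFF3/GTF gene model (nearest TSS,
promoter window −10 kb/+100 bp in gene orientation, priority
exon > promoter > intron > 5'UTR > 3'UTR > intergenic), interval
overlap against BED tracks (CpG islands, chromatin or conservation
states, constrained elements), fold enrichment against a genomic
background, and ortholog concordance of gene assignments between
species.

The probe "position" for overlap purposes is the single C base of the
target CpG: island and state calls are per site, not per 50-mer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

PROMOTER_UPSTREAM = 10_000
PROMOTER_DOWNSTREAM = 100

REGION_PRIORITY = ["exon", "promoter", "intron",
                   "five_prime_UTR", "three_prime_UTR"]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    tss: int                    # 0-based position of the TSS base
    exons: list[tuple[int, int]] = field(default_factory=list)
    five_utrs: list[tuple[int, int]] = field(default_factory=list)
    three_utrs: list[tuple[int, int]] = field(default_factory=list)
    ortholog_id: str | None = None

    @property
    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _)
                in zip(exons, exons[1:]) if b_start > a_end]

    @property
    def promoter(self) -> tuple[int, int]:
        """Half-open window −10 kb / +100 bp around the TSS, oriented by
        gene strand (upstream means 5' of the gene)."""
        if self.strand == "+":
            return self.tss - PROMOTER_UPSTREAM, self.tss + PROMOTER_DOWNSTREAM + 1
        return self.tss - PROMOTER_DOWNSTREAM, self.tss + PROMOTER_UPSTREAM + 1


@dataclass
class GeneModel:
    """Gene features indexed for point queries."""

    genes: dict[str, Gene]
    _trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)

    def __post_init__(self) -> None:
        per: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for g in self.genes.values():
            feats = ([("exon", iv) for iv in g.exons]
                     + [("promoter", g.promoter)]
                     + [("intron", iv) for iv in g.introns]
                     + [("five_prime_UTR", iv) for iv in g.five_utrs]
                     + [("three_prime_UTR", iv) for iv in g.three_utrs])
            for cat, (start, end) in feats:
                if end > start:
                    per.setdefault((g.chrom, cat), []).append(
                        (start, end, g.gene_id))
        for key, ivs in per.items():
            tree = IntervalTree()
            for start, end, gid in ivs:
                tree[start:end] = gid
            self._trees[key] = tree

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModel":
        import gffutils

        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
        genes: dict[str, Gene] = {}
        for gf in db.features_of_type("gene"):
            gid = gf.id
            tss = gf.start - 1 if gf.strand == "+" else gf.end - 1
            genes[gid] = Gene(gene_id=gid, chrom=gf.seqid,
                              strand=gf.strand, tss=tss)
        for ftype, attr in (("exon", "exons"),
                            ("five_prime_UTR", "five_utrs"),
                            ("three_prime_UTR", "three_utrs")):
            for f in db.features_of_type(ftype):
                for parent in db.parents(f, featuretype="gene"):
                    getattr(genes[parent.id], attr).append(
                        (f.start - 1, f.end))  # GFF3 is 1-based inclusive
        return cls(genes)

    def categories_at(self, chrom: str, pos: int) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for cat in REGION_PRIORITY:
            tree = self._trees.get((chrom, cat))
            if tree:
                hits = {iv.data for iv in tree[pos]}
                if hits:
                    out[cat] = hits
        return out


@dataclass
class RegionCall:
    probe_id: str
    category: str                 # one of REGION_PRIORITY or 'intergenic'
    nearest_gene: str | None
    tss_distance: int | None      # signed, gene orientation (+ = downstream)


def assign_gene_region(probe_id: str, chrom: str, position: int,
                       model: GeneModel) -> RegionCall:
    """Classify one CpG (0-based C position) against the gene model.

    Category is the highest-priority feature overlapping the C base;
    nearest gene is by absolute TSS distance on the same chromosome.
    """
    nearest, best = None, None
    for g in model.genes.values():
        if g.chrom != chrom:
            continue
        d = position - g.tss
        signed = d if g.strand == "+" else -d
        if best is None or abs(signed) < abs(best) or \
                (abs(signed) == abs(best) and g.gene_id < nearest):
            nearest, best = g.gene_id, signed
    cats = model.categories_at(chrom, position)
    for cat in REGION_PRIORITY:
        if cat in cats:
            return RegionCall(probe_id, cat, nearest, best)
    return RegionCall(probe_id, "intergenic", nearest, best)


def region_calls(manifest: pd.DataFrame, model: GeneModel) -> pd.DataFrame:
    rows = []
    for _, r in manifest.iterrows():
        call = assign_gene_region(r["probe_id"], r["chrom"],
                                  int(r["position"]) - 1, model)
        rows.append(vars(call))
    return pd.DataFrame(rows, columns=["probe_id", "category",
                                       "nearest_gene", "tss_distance"])


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Minimal BED3 reader with per-line validation (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates") from None
            if end < start or start < 0:
                raise BedParseError(f"{path}:{lineno}: invalid interval")
            intervals.append((parts[0], start, end))
    return intervals


def overlap_annotate(positions: Iterable[tuple[str, int]],
                     intervals: Iterable[tuple[str, int, int]]) -> list[bool]:
    """True per (chrom, 0-based C position) overlapping any interval.

    Half-open semantics: a C at an interval's start overlaps, a C at its
    end coordinate does not.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end > start:
            trees.setdefault(chrom, IntervalTree())[start:end] = True
    return [bool(trees.get(chrom) and trees[chrom][pos])
            for chrom, pos in positions]


def enrichment_fold(k_on: int, n_on: int, K_bg: int, N_bg: int) -> float:
    """Fold enrichment of an annotation on the array over the genomic
    background: (k_on/n_on) / (K_bg/N_bg)."""
    if n_on <= 0 or N_bg <= 0:
        raise ValueError("counts must be positive")
    if K_bg == 0:
        raise ZeroDivisionError("background annotation count is zero; "
                                "fold enrichment undefined")
    return (k_on / n_on) / (K_bg / N_bg)


@dataclass
class ConcordanceResult:
    n_compared: int
    n_concordant: int
    n_discordant: int
    n_discordant_intergenic: int

    @property
    def fraction_concordant(self) -> float:
        return self.n_concordant / self.n_compared if self.n_compared else float("nan")


def ortholog_concordance(reference_calls: pd.DataFrame,
                         species_calls: pd.DataFrame,
                         ortholog_table: Mapping[str, str]) -> ConcordanceResult:
    """Agreement of gene assignments between reference and another species.

    A probe is concordant when the species-assigned nearest gene is the
    ortholog of the reference-assigned gene.  Discordant probes whose
    species call is intergenic (outside promoters, by the priority
    rules) are counted separately — those often indicate an inaccurate
    assignment rather than true divergence.
    """
    if ortholog_table is None:
        raise ValueError("ortholog table required")
    ref = reference_calls.set_index("probe_id")
    sp = species_calls.set_index("probe_id")
    shared = ref.index.intersection(sp.index)
    n_conc = n_disc = n_disc_inter = 0
    for pid in shared:
        ref_gene = ref.loc[pid, "nearest_gene"]
        expected = ortholog_table.get(ref_gene)
        sp_gene = sp.loc[pid, "nearest_gene"]
        if expected is not None and sp_gene == expected and \
                sp.loc[pid, "category"] != "intergenic":
            n_conc += 1
        else:
            n_disc += 1
            if sp.loc[pid, "category"] == "intergenic":
                n_disc_inter += 1
    return ConcordanceResult(len(shared), n_conc, n_disc, n_disc_inter)
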