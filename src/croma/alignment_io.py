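"""Reference genomes, MAF alignment blocks and per-CpG site alignments.

The designer consumes a multiple-species alignment anchored to a
reference genome (e.g. a Multiz vertebrate alignment anchored to human).
This module reads the alignment in MAF, enumerates CpG sites on the
reference, and slices out per-site probe-window alignments, classifying
every reference column per species as a base, a gap, or unaligned.

Internal coordinates are 0-based half-open throughout.  The species key
for an alignment row is the assembly identifier — the text before the
first '.' in the MAF ``src`` field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .probe_model import ProbeDesignOption, probe_window, site_window

logger = logging.getLogger(__name__)

GAP = "-"
UNALIGNED = "."

VALID_ALPHABET = set("ACGTN")


class MafParseError(ValueError):
    """Raised when a MAF file does not conform to the format."""


class SiteSkipped(Exception):
    """A CpG site cannot be designed against; carries a reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class ReferenceGenome:
    """In-memory reference genome: chromosome name -> A/C/G/T/N string."""

    sequences: dict[str, str]
    assembly_label: str = ""

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid symbols {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path: str | Path, assembly_label: str = "") -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls(seqs, assembly_label or Path(path).stem)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        try:
            seq = self.sequences[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None
        if start < 0 or end > len(seq):
            raise IndexError(
                f"[{start}, {end}) outside chromosome {chrom} (len {len(seq)})")
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class AlignmentRow:
    """One species row of a MAF block, coordinates as in the MAF spec."""

    src: str          # full source name, e.g. 'hg19.chr1'
    start: int        # 0-based start on the source strand
    size: int         # ungapped length
    strand: str       # '+' or '-'
    src_size: int     # length of the source sequence
    text: str         # aligned sequence with '-' gaps

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]


@dataclass
class AlignmentBlock:
    """A MAF alignment block anchored to the reference species.

    The reference row is always on the '+' strand (Multiz convention);
    its ungapped length equals the block's reference span.
    """

    reference: AlignmentRow
    rows: dict[str, AlignmentRow] = field(default_factory=dict)  # keyed by species

    def __post_init__(self) -> None:
        width = len(self.reference.text)
        for row in self.rows.values():
            if len(row.text) != width:
                raise MafParseError(
                    f"row {row.src} width {len(row.text)} != block width {width}")
        ungapped = sum(1 for c in self.reference.text if c != GAP)
        if ungapped != self.reference.size:
            raise MafParseError(
                f"reference row {self.reference.src}: ungapped length {ungapped} "
                f"does not match declared size {self.reference.size}")
        if self.reference.strand != "+":
            raise MafParseError(
                f"reference row {self.reference.src} not on '+' strand")

    @property
    def reference_chrom(self) -> str:
        return self.reference.chrom

    @property
    def reference_start(self) -> int:
        return self.reference.start

    @property
    def reference_end(self) -> int:
        return self.reference.start + self.reference.size

    @property
    def species(self) -> set[str]:
        return set(self.rows)


def _row_from_record(rec: SeqRecord) -> AlignmentRow:
    ann = rec.annotations
    strand = "+" if ann.get("strand", 1) in (1, "+", "+1") else "-"
    return AlignmentRow(
        src=rec.id,
        start=int(ann["start"]),
        size=int(ann["size"]),
        strand=strand,
        src_size=int(ann["srcSize"]),
        text=str(rec.seq).upper(),
    )


def read_maf(path: str | Path, reference_species: str) -> Iterator[AlignmentBlock]:
    """Yield :class:`AlignmentBlock` objects from a MAF file, in file order.

    Blocks without a row for ``reference_species`` are skipped with a
    warning; malformed blocks raise :class:`MafParseError` naming the
    offending content.
    """
    try:
        alignments = AlignIO.parse(str(path), "maf")
        for i, msa in enumerate(alignments):
            rows = [_row_from_record(rec) for rec in msa]
            ref = next((r for r in rows if r.species == reference_species), None)
            if ref is None:
                warnings.warn(
                    f"MAF block {i} in {path} lacks reference species "
                    f"{reference_species!r}; skipped")
                continue
            yield AlignmentBlock(reference=ref,
                                 rows={r.species: r for r in rows})
    except ValueError as exc:
        raise MafParseError(f"malformed MAF in {path}: {exc}") from exc


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    """Serialize blocks back to MAF (reference row first per block)."""
    msas = []
    for block in blocks:
        records = []
        ordered = [block.reference] + [
            r for r in block.rows.values() if r is not block.reference]
        for row in ordered:
            rec = SeqRecord(Seq(row.text), id=row.src, name=row.src, description="")
            rec.annotations.update({
                "start": row.start,
                "size": row.size,
                "strand": 1 if row.strand == "+" else -1,
                "srcSize": row.src_size,
            })
            records.append(rec)
        msas.append(MultipleSeqAlignment(records))
    AlignIO.write(msas, str(path), "maf")


def enumerate_cpg_sites(genome: ReferenceGenome, chrom: str) -> list[int]:
    """0-based positions p with base(p) == C and base(p+1) == G, ascending."""
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome.sequences[chrom]
    sites = []
    p = seq.find("CG")
    while p != -1:
        sites.append(p)
        p = seq.find("CG", p + 1)
    return sites


@dataclass
class SiteAlignment:
    """Per-CpG probe-window slice of the multiple alignment.

    ``species_rows[s]`` holds one observation character per reference
    column of ``window``: A/C/G/T, '-' for a gap against the reference,
    '.' for unaligned.  ``insertion[s]`` flags species with bases
    inserted relative to the reference inside the window — the designer
    treats those species as infeasible rather than silently resolving
    the insertion.
    """

    chrom: str
    cpg_position: int
    option: ProbeDesignOption
    window: tuple[int, int]          # site window (probe window + CpG columns)
    probe_interval: tuple[int, int]  # the 50-mer itself
    reference_seq: str               # reference bases over `window`
    reference_species: str
    species_rows: dict[str, str]
    insertion: dict[str, bool]
    cpg_conserved: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        width = self.window[1] - self.window[0]
        if len(self.reference_seq) != width:
            raise ValueError("reference_seq length does not match window")
        for s, row in self.species_rows.items():
            if len(row) != width:
                raise ValueError(f"species row {s} width mismatch")
        if not self.cpg_conserved:
            c0 = self.cpg_position - self.window[0]
            for s, row in self.species_rows.items():
                self.cpg_conserved[s] = row[c0] == "C" and row[c0 + 1] == "G"

    @property
    def species(self) -> list[str]:
        return sorted(self.species_rows)

    def probe_columns(self, species: str) -> str:
        """Observation characters over the probe 50-mer only."""
        off = self.probe_interval[0] - self.window[0]
        return self.species_rows[species][off:off + (
            self.probe_interval[1] - self.probe_interval[0])]

    def reference_probe_seq(self) -> str:
        off = self.probe_interval[0] - self.window[0]
        return self.reference_seq[off:off + (
            self.probe_interval[1] - self.probe_interval[0])]


def _classify_block_columns(block: AlignmentBlock, win_start: int, win_end: int,
                            species: str) -> tuple[dict[int, str], bool]:
    """Map reference positions in [win_start, win_end) to observations
    for one species of one block; second value flags an insertion."""
    row = block.rows[species]
    ref_text = block.reference.text
    obs: dict[int, str] = {}
    insertion = False
    pos = block.reference_start
    for ref_ch, sp_ch in zip(ref_text, row.text):
        if ref_ch == GAP:
            # column is an insertion relative to the reference
            if sp_ch != GAP and win_start < pos < win_end:
                insertion = True
            continue
        if win_start <= pos < win_end:
            if sp_ch == GAP:
                obs[pos] = GAP
            elif sp_ch in "ACGT":
                obs[pos] = sp_ch
            else:  # N or other ambiguity: no usable observation
                obs[pos] = UNALIGNED
        pos += 1
    return obs, insertion


def extract_site_alignment(blocks: Iterable[AlignmentBlock],
                           genome: ReferenceGenome,
                           chrom: str,
                           cpg_position: int,
                           option: ProbeDesignOption,
                           reference_species: str | None = None,
                           all_species: Iterable[str] | None = None,
                           ) -> SiteAlignment:
    """Slice the probe-window alignment for one CpG and design option.

    The block containing the CpG columns supplies the observations;
    window columns outside it are unaligned (Multiz blocks do not
    overlap on the reference).  Raises :class:`SiteSkipped` when the
    window leaves the chromosome or the reference window contains N.
    """
    win_start, win_end = site_window(cpg_position, option)
    chrom_len = len(genome.sequences[chrom])
    if win_start < 0 or win_end > chrom_len:
        raise SiteSkipped("window_out_of_bounds")
    ref_seq = genome.fetch(chrom, win_start, win_end)
    if "N" in ref_seq:
        raise SiteSkipped("reference_N_in_window")
    if ref_seq[cpg_position - win_start: cpg_position - win_start + 2] != "CG":
        raise SiteSkipped("not_a_cpg")

    covering = None
    for block in blocks:
        if block.reference_chrom != chrom:
            continue
        if block.reference_start <= cpg_position and \
                cpg_position + 2 <= block.reference_end:
            covering = block
            break

    species = set(all_species or [])
    if covering is not None:
        species |= covering.species
    if reference_species:
        species.add(reference_species)
    species.discard(None)

    width = win_end - win_start
    rows: dict[str, str] = {}
    insertion: dict[str, bool] = {}
    for s in species:
        if covering is not None and s in covering.rows:
            obs, ins = _classify_block_columns(covering, win_start, win_end, s)
            rows[s] = "".join(obs.get(p, UNALIGNED)
                              for p in range(win_start, win_end))
            insertion[s] = ins
        else:
            rows[s] = UNALIGNED * width
            insertion[s] = False
    if reference_species:
        # the reference always matches itself exactly
        rows[reference_species] = ref_seq
        insertion[reference_species] = False

    return SiteAlignment(
        chrom=chrom,
        cpg_position=cpg_position,
        option=option,
        window=(win_start, win_end),
        probe_interval=probe_window(cpg_position, option),
        reference_seq=ref_seq,
        reference_species=reference_species or "",
        species_rows=rows,
        insertion=insertion,
    )


def sites_to_bed(sites: Iterable[int], chrom: str) -> str:
    """BED text (0-based half-open, the C base) for a list of CpG sites."""
    return "".join(f"{chrom}\t{p}\t{p + 1}\n" for p in sites)
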