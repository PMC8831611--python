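"""Infinium probe chemistry primitives.

Window geometry, degenerate-base budgets, IUPAC expansion and in-silico
bisulfite conversion.  Array probes are 50-mers flanking a target CpG;
the two Infinium chemistries differ in whether the probe sequence itself
contains the target cytosine:

* **Type II** (single bead, single-base extension): the 50-mer sits
  immediately 5' of the target C and excludes the CpG.
* **Type I** (two beads, methylated/unmethylated versions): the 50-mer
  ends on (and includes) the target C.

Each chemistry can be designed against either genomic strand; reverse
designs mirror the forward geometry about the G of the CpG.  All
coordinates here are 0-based, half-open genomic intervals; exports use
1-based coordinates and say so.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Callable, Iterable

PROBE_LENGTH = 50

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes keyed by the sorted base set they cover.
IUPAC_FOR_BASES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
BASES_FOR_IUPAC = {code: bases for bases, code in IUPAC_FOR_BASES.items()}

IUPAC_COMPLEMENT = {
    code: IUPAC_FOR_BASES[frozenset(b.translate(COMPLEMENT) for b in bases)]
    for bases, code in IUPAC_FOR_BASES.items()
}


class ProbeType(str, enum.Enum):
    I = "I"
    II = "II"


@dataclass(frozen=True, order=True)
class ProbeDesignOption:
    """One of the four probe design options: chemistry x strand."""

    probe_type: ProbeType
    strand: str  # '+' (forward) or '-' (reverse)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def is_forward(self) -> bool:
        return self.strand == "+"

    def __str__(self) -> str:
        return f"Type{self.probe_type.value}{self.strand}"


ALL_OPTIONS: tuple[ProbeDesignOption, ...] = (
    ProbeDesignOption(ProbeType.II, "+"),
    ProbeDesignOption(ProbeType.II, "-"),
    ProbeDesignOption(ProbeType.I, "+"),
    ProbeDesignOption(ProbeType.I, "-"),
)


@dataclass(frozen=True, order=True)
class DegenerateBase:
    """A tolerated alternative nucleotide at one probe-window offset.

    ``window_offset`` is 0-based within the probe window in *genomic*
    orientation (the orientation of the reference interval returned by
    :func:`probe_window`); oriented probe strings remap it.
    """

    window_offset: int
    alternate: str

    def __post_init__(self) -> None:
        if self.alternate not in "ACGT":
            raise ValueError(f"alternate must be A/C/G/T, got {self.alternate!r}")
        if not 0 <= self.window_offset < PROBE_LENGTH:
            raise ValueError(f"window_offset {self.window_offset} outside probe")


def probe_window(site: int, option: ProbeDesignOption,
                 probe_length: int = PROBE_LENGTH) -> tuple[int, int]:
    """Genomic interval (0-based, half-open) of the probe 50-mer.

    ``site`` is the position of the C of the target CpG on the forward
    strand.  Type II excludes the CpG (window abuts the C); Type I ends
    on the C.  Reverse designs mirror about the G at ``site + 1``.
    """
    if option.probe_type is ProbeType.II:
        if option.is_forward:
            return site - probe_length, site
        return site + 2, site + 2 + probe_length
    if option.is_forward:
        return site - probe_length + 1, site + 1
    return site + 1, site + 1 + probe_length


def site_window(site: int, option: ProbeDesignOption,
                probe_length: int = PROBE_LENGTH) -> tuple[int, int]:
    """Probe window extended to always include both CpG columns."""
    start, end = probe_window(site, option, probe_length)
    return min(start, site), max(end, site + 2)


def count_cpgs(seq: str) -> int:
    """Number of CG dinucleotides in ``seq`` (they cannot overlap)."""
    return seq.count("CG")


def max_degenerate_budget(option: ProbeDesignOption, window_seq: str,
                          design_cap: int | Callable[[str], int] = 3) -> int:
    """Maximum number M of degenerate bases allowed in this probe.

    ``design_cap`` stands in for the proprietary per-probe design score:
    either a constant (default 3, the chemistry's ceiling) or a callable
    of the window sequence.  For Type II probes every CG dinucleotide in
    the window spends one unit of the budget, because the assay must
    tolerate either methylation state there.
    """
    cap = design_cap(window_seq) if callable(design_cap) else design_cap
    if option.probe_type is ProbeType.I:
        return cap
    return max(0, cap - count_cpgs(window_seq))


def reverse_complement(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are handled, N kept."""
    return "".join(IUPAC_COMPLEMENT.get(b, b) for b in reversed(seq))


def iupac_code(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering a set of bases."""
    key = frozenset(bases)
    try:
        return IUPAC_FOR_BASES[key]
    except KeyError:
        raise ValueError(f"not a nucleotide set: {sorted(key)}") from None


def apply_degenerate(window_seq: str,
                     degenerate: Iterable[DegenerateBase]) -> str:
    """Write degenerate bases into a genomic-orientation window sequence."""
    chars = list(window_seq)
    by_offset: dict[int, set[str]] = {}
    for d in degenerate:
        by_offset.setdefault(d.window_offset, set()).add(d.alternate)
    for off, alts in by_offset.items():
        chars[off] = iupac_code(alts | {window_seq[off]})
    return "".join(chars)


def oriented_probe_sequence(window_seq: str, option: ProbeDesignOption,
                            degenerate: Iterable[DegenerateBase] = ()) -> str:
    """Probe string in synthesis orientation, with IUPAC degenerate bases.

    ``window_seq`` is the forward-strand reference sequence over
    :func:`probe_window`.  Reverse designs are reverse-complemented.
    """
    iupac = apply_degenerate(window_seq, degenerate)
    return iupac if option.is_forward else reverse_complement(iupac)


def expand_degenerate(seq: str) -> list[str]:
    """All explicit sequences encoded by an IUPAC string.

    Cardinality is the product over positions of the number of bases the
    code at that position covers; the reference allele is always among
    them.  For Type I probes only the methylated representative exists
    in this encoding (the target C is written as C), so no extra
    unmethylated variant is emitted.
    """
    choices = []
    for ch in seq:
        try:
            choices.append(sorted(BASES_FOR_IUPAC[ch]))
        except KeyError:
            raise ValueError(f"unknown IUPAC symbol {ch!r}") from None
    return ["".join(p) for p in itertools.product(*choices)]


def expansion_cardinality(seq: str) -> int:
    """Number of explicit sequences an IUPAC string expands into."""
    n = 1
    for ch in seq:
        try:
            n *= len(BASES_FOR_IUPAC[ch])
        except KeyError:
            raise ValueError(f"unknown IUPAC symbol {ch!r}") from None
    return n


def bisulfite_convert(seq: str, strand: str = "forward",
                      methylation_mode: str = "all_CpG_methylated",
                      next_base: str | None = None,
                      prev_base: str | None = None) -> str:
    """In-silico bisulfite conversion of a nucleotide string.

    Forward strand: C -> T, except a C immediately followed by G when
    ``methylation_mode == 'all_CpG_methylated'`` (methylated CpGs are
    protected).  The reverse-strand reading of the same duplex is
    represented in forward coordinates as G -> A with the mirrored CpG
    exception (G preceded by C).  ``next_base`` / ``prev_base`` supply
    context beyond the string boundary (e.g. the genome base following a
    probe window); without it a terminal C (or leading G) converts.
    """
    if methylation_mode not in ("all_CpG_methylated", "fully_unmethylated"):
        raise ValueError(f"unknown methylation_mode {methylation_mode!r}")
    protect = methylation_mode == "all_CpG_methylated"
    chars = list(seq)
    n = len(chars)
    if strand == "forward":
        for i, ch in enumerate(chars):
            if ch == "C":
                nxt = chars[i + 1] if i + 1 < n else next_base
                if not (protect and nxt == "G"):
                    chars[i] = "T"
    elif strand == "reverse":
        for i, ch in enumerate(chars):
            if ch == "G":
                prv = chars[i - 1] if i > 0 else prev_base
                if not (protect and prv == "C"):
                    chars[i] = "A"
    else:
        raise ValueError(f"strand must be 'forward' or 'reverse', got {strand!r}")
    return "".join(chars)
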