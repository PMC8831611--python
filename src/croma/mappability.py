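"""In-silico bisulfite mapping of expanded probe sequences.

A probe "applies" to a genome when every expanded version of its
degenerate sequence matches the genome exactly, full length, at a single
locus, under bisulfite-converted comparison with all CpGs treated as
methylated.  Only perfect full-length matches count; the accepted-match
criterion is the contract here, not any particular aligner.

Two search paths are provided:

* :func:`map_probe_versions` — the engine: a seed-and-extend exact
  search (24-mer seed over converted text, column-level verification);
* :func:`reference_search` — an independent vectorized sliding-window
  scan used to cross-check the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .alignment_io import ReferenceGenome
from .probe_model import (
    PROBE_LENGTH,
    ProbeDesignOption,
    ProbeType,
    expand_degenerate,
    reverse_complement,
)

SEED_LENGTH = 24

Locus = tuple[str, int, str]  # chrom, 0-based forward start, strand


def _convert_text(seq: str) -> str:
    """Genome-wide forward bisulfite conversion, CpGs methylated."""
    out = []
    n = len(seq)
    for i, ch in enumerate(seq):
        if ch == "C" and not (i + 1 < n and seq[i + 1] == "G"):
            out.append("T")
        else:
            out.append(ch)
    return "".join(out)


def _convert_probe_prefix(seq: str, length: int) -> str:
    """Convert the first ``length`` bases of a probe using the probe's own
    internal context (valid because length < len(seq))."""
    out = []
    for i in range(length):
        ch = seq[i]
        if ch == "C" and seq[i + 1] != "G":
            out.append("T")
        else:
            out.append(ch)
    return "".join(out)


def _verify_at(version: str, text: str, pos: int, mode: str) -> bool:
    """Full-length perfect match of ``version`` against ``text`` at ``pos``.

    In bisulfite_collapsed mode each column is compared after conversion
    with each string's own next-base context; the probe's terminal base
    borrows the genome's following base as context (the probe represents
    a genomic window, so the genome continues where the probe ends).
    """
    n = len(version)
    tlen = len(text)
    for i in range(n):
        a = version[i]
        g = text[pos + i]
        if a == g:
            continue
        if mode == "strict":
            return False
        next_g = text[pos + i + 1] if pos + i + 1 < tlen else None
        next_a = version[i + 1] if i + 1 < n else next_g
        ca = "T" if a == "C" and next_a != "G" else a
        cg = "T" if g == "C" and next_g != "G" else g
        if ca != cg:
            return False
    return True


@dataclass
class _IndexedChrom:
    name: str
    forward: str
    rc: str
    forward_converted: str
    rc_converted: str


def _index_genome(genome: ReferenceGenome) -> list[_IndexedChrom]:
    idx = []
    for name, seq in genome.sequences.items():
        rc = reverse_complement(seq)
        idx.append(_IndexedChrom(name, seq, rc,
                                 _convert_text(seq), _convert_text(rc)))
    return idx


def _seed_hits(seed: str, text: str) -> Iterable[int]:
    p = text.find(seed)
    while p != -1:
        yield p
        p = text.find(seed, p + 1)


def map_probe_versions(sequence: str, genome: ReferenceGenome,
                       mode: str = "bisulfite_collapsed",
                       _index: list[_IndexedChrom] | None = None,
                       ) -> list[list[Locus]]:
    """Loci of every expanded version of a (possibly IUPAC) probe string.

    Returns one locus list per version, in the order of
    :func:`~croma.probe_model.expand_degenerate`.  Both strands are
    searched; loci are (chrom, 0-based forward start, strand).  No hits
    is an empty list, not an error.
    """
    if mode not in ("strict", "bisulfite_collapsed"):
        raise ValueError(f"unknown mode {mode!r}")
    index = _index if _index is not None else _index_genome(genome)
    versions = expand_degenerate(sequence)
    results: list[list[Locus]] = []
    for v in versions:
        if len(v) < SEED_LENGTH + 1:
            raise ValueError("probe shorter than seed length")
        seed = v[:SEED_LENGTH] if mode == "strict" \
            else _convert_probe_prefix(v, SEED_LENGTH)
        loci: list[Locus] = []
        for chrom in index:
            fwd_text = chrom.forward if mode == "strict" else chrom.forward_converted
            rc_text = chrom.rc if mode == "strict" else chrom.rc_converted
            L = len(chrom.forward)
            for p in _seed_hits(seed, fwd_text):
                if p + len(v) <= L and _verify_at(v, chrom.forward, p, mode):
                    loci.append((chrom.name, p, "+"))
            for p in _seed_hits(seed, rc_text):
                if p + len(v) <= L and _verify_at(v, chrom.rc, p, mode):
                    loci.append((chrom.name, L - (p + len(v)), "-"))
        results.append(sorted(loci))
    return results


def reference_search(sequence: str, genome: ReferenceGenome,
                     mode: str = "bisulfite_collapsed") -> list[list[Locus]]:
    """Sliding-window scan over every position; independent of the
    seed-based engine.  Vectorized per chromosome with numpy."""
    versions = expand_degenerate(sequence)
    results: list[list[Locus]] = []
    chrom_arrays = {}
    for name, seq in genome.sequences.items():
        rc = reverse_complement(seq)
        chrom_arrays[name] = (
            np.frombuffer(seq.encode(), dtype="S1"),
            np.frombuffer(rc.encode(), dtype="S1"),
        )
    for v in versions:
        n = len(v)
        loci: list[Locus] = []
        for name, (fwd, rc) in chrom_arrays.items():
            L = len(fwd)
            if L < n:
                continue
            for arr, strand in ((fwd, "+"), (rc, "-")):
                hits = _scan_array(v, arr, mode)
                for p in hits:
                    start = p if strand == "+" else L - (p + n)
                    loci.append((name, int(start), strand))
        results.append(sorted(loci))
    return results


def _scan_array(version: str, arr: np.ndarray, mode: str) -> np.ndarray:
    n = len(version)
    L = len(arr)
    win = np.lib.stride_tricks.sliding_window_view(arr, n)
    probe = np.frombuffer(version.encode(), dtype="S1")
    if mode == "strict":
        return np.nonzero((win == probe).all(axis=1))[0]
    # collapsed space: convert genome with full context, probe with
    # internal context; the probe's final base uses the genome's context.
    conv = arr.copy()
    is_c = arr == b"C"
    next_g = np.zeros(L, dtype=bool)
    next_g[:-1] = arr[1:] == b"G"
    conv[is_c & ~next_g] = b"T"
    cwin = np.lib.stride_tricks.sliding_window_view(conv, n)
    pconv = np.frombuffer(_convert_probe_prefix(version, n - 1).encode(), dtype="S1")
    head_ok = (cwin[:, :-1] == pconv).all(axis=1)
    last = version[-1]
    tail_raw = arr[n - 1:]
    tail_next = np.full(len(tail_raw), b"", dtype="S1")
    tail_next[:-1] = arr[n:]
    if last == "C":
        # probe terminal C stays C only when the genome continues with G
        expected = np.where(tail_next == b"G", b"C", b"T")
    else:
        expected = np.full(len(tail_raw), last.encode(), dtype="S1")
    tail_conv = conv[n - 1:]
    tail_ok = tail_conv == expected
    return np.nonzero(head_ok & tail_ok)[0]


@dataclass
class ProbeMappability:
    """Mapping outcome for one probe in one genome."""

    probe_id: str
    genome_label: str
    loci_per_version: list[list[Locus]]
    unique: bool
    target_cpg_ok: bool
    locus: Locus | None = None


@dataclass
class MappabilityReport:
    """Per-probe, per-genome uniqueness and CpG-verification verdicts."""

    genome_label: str
    records: dict[str, ProbeMappability] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "probe_id": r.probe_id,
            "genome": r.genome_label,
            "n_versions": len(r.loci_per_version),
            "n_loci": len({l for ls in r.loci_per_version for l in ls}),
            "unique": r.unique,
            "target_cpg_ok": r.target_cpg_ok,
        } for r in self.records.values()]
        return pd.DataFrame(
            rows, columns=["probe_id", "genome", "n_versions", "n_loci",
                           "unique", "target_cpg_ok"])


def is_unique(loci_per_version: list[list[Locus]],
              rule: str = "union") -> bool:
    """Uniqueness of a probe's collapsed locus list.

    ``union`` (default): every version has at most one hit and the union
    of all hits is exactly one locus.  ``per_version``: every version
    has at most one hit and all hitting versions agree on the locus.
    The two differ only in whether zero-hit unions count; under the
    collapsing-to-loci reading, union is the criterion.
    """
    union = {l for ls in loci_per_version for l in ls}
    if rule == "union":
        return all(len(ls) <= 1 for ls in loci_per_version) and len(union) == 1
    if rule == "per_version":
        # stricter per-version reading: each version individually maps to
        # at most one place, and at least one version maps at all
        return bool(union) and all(len(ls) <= 1 for ls in loci_per_version)
    raise ValueError(f"unknown uniqueness rule {rule!r}")


def projected_cpg(locus: Locus, option: ProbeDesignOption,
                  probe_length: int = PROBE_LENGTH) -> tuple[str, int]:
    """Forward-strand position of the target C implied by a hit locus.

    For a '+' hit the probe orientation runs along the forward strand:
    Type II targets the CG at start+50, Type I at start+49.  For a '-'
    hit the orientation is mirrored: Type II targets the forward CG at
    start-2, Type I at start-1.
    """
    chrom, start, strand = locus
    if strand == "+":
        c = start + probe_length if option.probe_type is ProbeType.II \
            else start + probe_length - 1
    else:
        c = start - 2 if option.probe_type is ProbeType.II else start - 1
    return chrom, c


def verify_target_cpg(locus: Locus, genome: ReferenceGenome,
                      option: ProbeDesignOption,
                      probe_length: int = PROBE_LENGTH) -> bool:
    """True iff the genome shows an intact CG at the projected target.

    The CG dinucleotide is strand-symmetric (forward CG implies reverse
    CG), so the check reads the forward strand.  Out-of-bounds
    projections are False.
    """
    chrom, c = projected_cpg(locus, option, probe_length)
    seq = genome.sequences.get(chrom)
    if seq is None or c < 0 or c + 2 > len(seq):
        return False
    return seq[c:c + 2] == "CG"


def map_manifest(manifest: pd.DataFrame, genome: ReferenceGenome,
                 genome_label: str, mode: str = "bisulfite_collapsed",
                 uniqueness_rule: str = "union") -> MappabilityReport:
    """Map every manifest probe against one genome.

    ``manifest`` needs columns probe_id, sequence, probe_type, strand.
    """
    index = _index_genome(genome)
    report = MappabilityReport(genome_label=genome_label)
    for _, row in manifest.iterrows():
        option = ProbeDesignOption(ProbeType(row["probe_type"]), row["strand"])
        loci = map_probe_versions(row["sequence"], genome, mode, _index=index)
        unique = is_unique(loci, uniqueness_rule)
        locus = None
        cpg_ok = False
        if unique:
            locus = next(l for ls in loci for l in ls)
            cpg_ok = verify_target_cpg(locus, genome, option)
        report.records[row["probe_id"]] = ProbeMappability(
            probe_id=row["probe_id"], genome_label=genome_label,
            loci_per_version=loci, unique=unique,
            target_cpg_ok=cpg_ok, locus=locus)
    return report


def coordinate_export(report: MappabilityReport,
                      manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-species CpG coordinate table: one row per probe with a unique,
    CpG-verified locus (probe_id, chrom, 1-based C position, strand)."""
    opt_by_probe = {}
    if manifest is not None:
        for _, row in manifest.iterrows():
            opt_by_probe[row["probe_id"]] = ProbeDesignOption(
                ProbeType(row["probe_type"]), row["strand"])
    rows = []
    for rec in report.records.values():
        if not (rec.unique and rec.target_cpg_ok and rec.locus):
            continue
        option = opt_by_probe.get(rec.probe_id)
        if option is None:
            continue
        chrom, c = projected_cpg(rec.locus, option)
        rows.append({"probe_id": rec.probe_id, "chrom": chrom,
                     "position": c + 1, "strand": rec.locus[2]})
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "position", "strand"])
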