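"""Degenerate-base selection maximizing cross-species probe coverage.

For each CpG site and probe design option, the selector asks: given a
budget of at most M degenerate bases, which (position, alternative
nucleotide) choices let the probe tolerate mismatches in the largest
number of aligned species?  A species is *feasible* for a probe when its
alignment over the probe window has no gaps or unaligned columns, no
insertion relative to the reference, a conserved target CpG, and at
most M substitutions.  The selector uses a greedy
enumeration:

1. collect every feasible species' mismatch positions into a multiset P;
2. for each distinct sub-multiset S of P of size min(M, |P|): at each
   unique position of S occurring k times, pick the k alternative
   nucleotides carried by the most feasible species;
3. keep the combination covering the most species.

An exhaustive optimizer over all (position, alternate) sets of size <= M
is provided as an independent cross-check; the enumeration above equals
it whenever each position in P has a single distinct alternate among the
feasible species.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from .alignment_io import SiteAlignment, SiteSkipped
from .probe_model import (
    DegenerateBase,
    ProbeDesignOption,
    ProbeType,
    max_degenerate_budget,
    oriented_probe_sequence,
)

MAX_ALTERNATES_PER_OFFSET = 3  # all non-reference bases


@dataclass
class MismatchProfile:
    """Per-species mismatch bookkeeping for one site and design option."""

    site_alignment: SiteAlignment
    M: int
    comparison: str = "strict"  # or 'bisulfite_collapsed'
    feasible: set[str] = field(default_factory=set)          # the set F
    mismatches: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    position_multiset: Counter = field(default_factory=Counter)  # the multiset P
    infeasible_reason: dict[str, str] = field(default_factory=dict)

    @property
    def reference_species(self) -> str:
        return self.site_alignment.reference_species


def _collapse_forward(base: str, nxt: str | None) -> str:
    return "T" if base == "C" and nxt != "G" else base


def _collapse_reverse(base: str, prv: str | None) -> str:
    return "A" if base == "G" and prv != "C" else base


def _bases_match(ref: str, obs: str, i: int, ref_row: str, obs_row: str,
                 option: ProbeDesignOption, comparison: str) -> bool:
    if ref == obs:
        return True
    if comparison == "strict":
        return False
    # bisulfite-collapsed space: the assay reads converted DNA, so a
    # non-CpG C (reference or species) is indistinguishable from T on
    # the strand the probe interrogates.
    if option.is_forward:
        nxt_r = ref_row[i + 1] if i + 1 < len(ref_row) else None
        nxt_o = obs_row[i + 1] if i + 1 < len(obs_row) else None
        return _collapse_forward(ref, nxt_r) == _collapse_forward(obs, nxt_o)
    prv_r = ref_row[i - 1] if i > 0 else None
    prv_o = obs_row[i - 1] if i > 0 else None
    return _collapse_reverse(ref, prv_r) == _collapse_reverse(obs, prv_o)


def build_mismatch_profile(site_alignment: SiteAlignment, M: int,
                           comparison: str = "strict") -> MismatchProfile:
    """Classify species as feasible/infeasible and collect mismatches.

    Mismatch offsets are 0-based within the probe window, genomic
    orientation.  Species with any gap/unaligned column anywhere in the
    site window, an insertion flag, a non-conserved CpG, or more than M
    mismatches are infeasible.
    """
    if comparison not in ("strict", "bisulfite_collapsed"):
        raise ValueError(f"unknown comparison mode {comparison!r}")
    sa = site_alignment
    prof = MismatchProfile(site_alignment=sa, M=M, comparison=comparison)
    ref_probe = sa.reference_probe_seq()
    for s in sa.species:
        if s == sa.reference_species:
            continue  # trivially matches itself; counted in coverage directly
        row_full = sa.species_rows[s]
        if any(c in "-." for c in row_full):
            prof.infeasible_reason[s] = "gap_or_unaligned"
            continue
        if sa.insertion.get(s, False):
            prof.infeasible_reason[s] = "insertion"
            continue
        if not sa.cpg_conserved.get(s, False):
            prof.infeasible_reason[s] = "cpg_not_conserved"
            continue
        row = sa.probe_columns(s)
        mm = [(i, row[i]) for i in range(len(ref_probe))
              if not _bases_match(ref_probe[i], row[i], i, ref_probe, row,
                                  sa.option, comparison)]
        if len(mm) > M:
            prof.infeasible_reason[s] = "too_many_mismatches"
            continue
        prof.feasible.add(s)
        prof.mismatches[s] = mm
        for off, _ in mm:
            prof.position_multiset[off] += 1
    return prof


def _coverage(profile: MismatchProfile,
              chosen: frozenset[tuple[int, str]]) -> set[str]:
    """Feasible species whose every mismatch is tolerated, plus reference."""
    covered = {profile.reference_species} if profile.reference_species else set()
    for s in profile.feasible:
        if all((off, base) in chosen for off, base in profile.mismatches[s]):
            covered.add(s)
    return covered


def _alternate_counts(profile: MismatchProfile, offset: int) -> Counter:
    counts: Counter = Counter()
    for s in profile.feasible:
        for off, base in profile.mismatches[s]:
            if off == offset:
                counts[base] += 1
    return counts


def _sub_multisets(multiset: Counter, size: int):
    """Distinct sub-multisets of a given size, as sorted offset tuples."""
    offsets = sorted(multiset)
    bounds = [multiset[o] for o in offsets]

    def rec(i: int, remaining: int, acc: list[int]):
        if remaining == 0:
            yield tuple(acc)
            return
        if i == len(offsets):
            return
        if sum(bounds[i:]) < remaining:
            return
        for k in range(min(bounds[i], remaining), -1, -1):
            yield from rec(i + 1, remaining - k, acc + [offsets[i]] * k)

    yield from rec(0, size, [])


def select_degenerate_bases(profile: MismatchProfile, M: int | None = None,
                            ) -> tuple[tuple[DegenerateBase, ...], set[str]]:
    """Choose degenerate bases maximizing covered species.

    Returns the chosen set (sorted by offset, then alternate) and the
    covered species (always including the reference).  Deterministic:
    candidate combinations are enumerated in sorted order and only a
    strictly better coverage replaces the incumbent, so ties resolve to
    the lexicographically smallest offsets / alphabetically first
    alternates.
    """
    if M is None:
        M = profile.M
    P = profile.position_multiset
    size = min(M, sum(P.values()))
    best_cov = _coverage(profile, frozenset())
    best_set: tuple[tuple[int, str], ...] = ()
    if size == 0:
        return (), best_cov
    ranked_alternates = {
        offset: [base for base, _ in sorted(
            _alternate_counts(profile, offset).items(),
            key=lambda kv: (-kv[1], kv[0]))]
        for offset in P
    }
    seen: set[tuple[tuple[int, str], ...]] = set()
    for combo in sorted(_sub_multisets(P, size)):
        chosen: list[tuple[int, str]] = []
        for offset, k in sorted(Counter(combo).items()):
            ranked = ranked_alternates[offset]
            take = min(k, len(ranked), MAX_ALTERNATES_PER_OFFSET)
            chosen.extend((offset, base) for base in ranked[:take])
        key = tuple(sorted(chosen))
        if key in seen:  # distinct combos can induce the same tolerated set
            continue
        seen.add(key)
        cov = _coverage(profile, frozenset(key))
        if len(cov) > len(best_cov):
            best_cov = cov
            best_set = key
    degenerate = tuple(DegenerateBase(off, base) for off, base in best_set)
    return degenerate, best_cov


def exhaustive_coverage(profile: MismatchProfile, M: int | None = None,
                        ) -> tuple[tuple[DegenerateBase, ...], set[str]]:
    """Brute-force optimum over every (offset, alternate) set of size <= M.

    Independent of :func:`select_degenerate_bases`; used as a
    cross-check.  Only observed mismatch pairs can enlarge coverage, so
    the candidate universe is the union of feasible species' mismatches.
    """
    if M is None:
        M = profile.M
    universe = sorted({pair for s in profile.feasible
                       for pair in profile.mismatches[s]})
    best_cov = _coverage(profile, frozenset())
    best_set: tuple[tuple[int, str], ...] = ()
    for r in range(1, min(M, len(universe)) + 1):
        for combo in itertools.combinations(universe, r):
            per_offset = Counter(off for off, _ in combo)
            if any(k > MAX_ALTERNATES_PER_OFFSET for k in per_offset.values()):
                continue
            cov = _coverage(profile, frozenset(combo))
            if len(cov) > len(best_cov):
                best_cov = cov
                best_set = tuple(sorted(combo))
    return tuple(DegenerateBase(o, b) for o, b in best_set), best_cov


def verify_coverage(profile: MismatchProfile,
                    degenerate: tuple[DegenerateBase, ...],
                    covered: set[str]) -> bool:
    """Soundness replay: each covered species' probe-window row, with the
    degenerate substitutions applied, must equal the reference window."""
    sa = profile.site_alignment
    ref = sa.reference_probe_seq()
    tolerated = {(d.window_offset, d.alternate) for d in degenerate}
    for s in covered:
        if s == profile.reference_species:
            continue
        row = list(sa.probe_columns(s))
        if any(c in "-." for c in row):
            return False
        for off, alt in tolerated:
            if row[off] == alt:
                row[off] = ref[off]
        replayed = "".join(row)
        if profile.comparison == "strict":
            if replayed != ref:
                return False
        else:
            if any(not _bases_match(ref[i], replayed[i], i, ref, replayed,
                                    sa.option, profile.comparison)
                   for i in range(len(ref))):
                return False
    return True


@dataclass
class ProbeCandidate:
    """A designed probe for one CpG: option, degenerate set, coverage."""

    chrom: str
    site: int                       # 0-based C position
    option: ProbeDesignOption
    degenerate_set: tuple[DegenerateBase, ...]
    covered_species: frozenset[str]
    budget_M: int
    sequence: str = ""              # oriented IUPAC probe string

    @property
    def coverage(self) -> int:
        return len(self.covered_species)

    def coverage_excluding_reference(self, reference_species: str) -> int:
        return len(self.covered_species - {reference_species})


def design_option_candidate(site_alignment: SiteAlignment,
                            design_cap: int | object = 3,
                            comparison: str = "strict") -> ProbeCandidate:
    """Run the selector for one site/option and package the result."""
    sa = site_alignment
    window_seq = sa.reference_probe_seq()
    M = max_degenerate_budget(sa.option, window_seq, design_cap)
    profile = build_mismatch_profile(sa, M, comparison)
    degenerate, covered = select_degenerate_bases(profile, M)
    seq = oriented_probe_sequence(window_seq, sa.option, degenerate)
    return ProbeCandidate(
        chrom=sa.chrom,
        site=sa.cpg_position,
        option=sa.option,
        degenerate_set=degenerate,
        covered_species=frozenset(covered),
        budget_M=M,
        sequence=seq,
    )


def best_design_for_site(candidates: dict[ProbeDesignOption, ProbeCandidate],
                         ) -> dict[ProbeType, ProbeCandidate]:
    """Per probe type, retain the strand with the greater coverage.

    Ties go to the forward strand.  Options missing from ``candidates``
    (window out of bounds etc.) are simply not considered; an empty
    input yields an empty result.
    """
    retained: dict[ProbeType, ProbeCandidate] = {}
    for ptype in (ProbeType.II, ProbeType.I):
        fwd = next((c for o, c in candidates.items()
                    if o.probe_type is ptype and o.is_forward), None)
        rev = next((c for o, c in candidates.items()
                    if o.probe_type is ptype and not o.is_forward), None)
        if fwd is None and rev is None:
            continue
        if fwd is None:
            retained[ptype] = rev
        elif rev is None or rev.coverage <= fwd.coverage:
            retained[ptype] = fwd
        else:
            retained[ptype] = rev
    return retained


def design_site(blocks, genome, chrom: str, cpg_position: int,
                reference_species: str, all_species=None,
                design_cap: int | object = 3, comparison: str = "strict",
                ) -> dict[ProbeDesignOption, ProbeCandidate]:
    """Evaluate all four design options for one CpG site.

    Options whose window leaves the chromosome are omitted; sites with N
    in the reference window raise :class:`SiteSkipped` upstream.
    """
    from .alignment_io import extract_site_alignment
    from .probe_model import ALL_OPTIONS

    out: dict[ProbeDesignOption, ProbeCandidate] = {}
    for option in ALL_OPTIONS:
        try:
            sa = extract_site_alignment(
                blocks, genome, chrom, cpg_position, option,
                reference_species=reference_species, all_species=all_species)
        except SiteSkipped:
            continue
        out[option] = design_option_candidate(sa, design_cap, comparison)
    return out
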