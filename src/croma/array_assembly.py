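"""Selection pipeline turning per-site probe candidates into an array manifest.

Four selection steps build the design content of a pan-mammalian
array:

* **S1** — every Type II probe expected to work in the model species
  (e.g. mouse): guarantees utility in the key model organism.
* **S2** — remaining CpGs by descending Type II species coverage, until
  the design reaches ``total_after_topup`` CpGs.
* **S3** — CpGs present on an EPIC-style human array and not yet
  selected, designed with the EPIC probe type and strand but this
  pipeline's degenerate bases, top ``n_epic`` by coverage: eases
  integration with existing human cohort data.
* **S4** — remaining CpGs by descending Type I coverage, top
  ``n_typeI``: Type I chemistry handles CpG-dense regions and is needed
  by normalization methods.

A mappability filter then drops probes that do not map uniquely in at
least a configured fraction (default 80%) of the high-quality genomes
they target, unless they cover at least ``rescue_species_count``
(default 40) species.  Finally a human-biomarker probe list is merged;
probes targeting an already-selected cytosine keep both rows with
'.1'/'.2' suffixes, non-CpG probes carry a 'ch' prefix and SNP probes
an 'rs' prefix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .selection import ProbeCandidate, best_design_for_site
from .probe_model import (
    DegenerateBase,
    ProbeDesignOption,
    ProbeType,
    expansion_cardinality,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "probe_id", "chrom", "position", "probe_type", "strand", "sequence",
    "degenerate", "coverage", "covered_species", "provenance_step",
    "duplicate_suffix",
]


@dataclass
class AssemblyConfig:
    """Targets and thresholds for the selection pipeline.

    A full-scale mammalian design uses total_after_topup=53000,
    n_epic=3000, n_typeI=4000 against a 100-way alignment;
    fixture-scale runs use toy totals.
    """

    model_species: str
    total_after_topup: int
    n_epic: int = 0
    n_typeI: int = 0
    mappability_fraction_threshold: float = 0.8
    rescue_species_count: int = 40
    panel_genomes: tuple[str, ...] = ()
    mappability_denominator: str = "targeted"  # or 'panel'

    def __post_init__(self) -> None:
        if not 0 <= self.mappability_fraction_threshold <= 1:
            raise ValueError("mappability_fraction_threshold must be in [0,1]")
        for name in ("total_after_topup", "n_epic", "n_typeI",
                     "rescue_species_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def format_degenerate(degenerate: Iterable[DegenerateBase]) -> str:
    return ";".join(f"{d.window_offset}:{d.alternate}" for d in degenerate)


def parse_degenerate(text: str) -> tuple[DegenerateBase, ...]:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        off, alt = part.split(":")
        out.append(DegenerateBase(int(off), alt))
    return tuple(out)


def candidates_to_frame(per_site: Iterable[Mapping[ProbeDesignOption,
                                                   ProbeCandidate]]) -> pd.DataFrame:
    """Flatten per-site option dicts into the candidate table."""
    rows = []
    for options in per_site:
        for option, cand in options.items():
            rows.append({
                "chrom": cand.chrom,
                "site": cand.site,
                "probe_type": option.probe_type.value,
                "strand": option.strand,
                "coverage": cand.coverage,
                "covered_species": ";".join(sorted(cand.covered_species)),
                "degenerate": format_degenerate(cand.degenerate_set),
                "budget_M": cand.budget_M,
                "sequence": cand.sequence,
            })
    return pd.DataFrame(rows)


def _winners_per_type(candidates: pd.DataFrame) -> pd.DataFrame:
    """Per CpG site and probe type, the strand with greater coverage
    (ties to forward)."""
    df = candidates.copy()
    df["_fwd"] = (df["strand"] == "+").astype(int)
    df = df.sort_values(["chrom", "site", "probe_type", "coverage", "_fwd"],
                        ascending=[True, True, True, False, False],
                        kind="mergesort")
    winners = df.drop_duplicates(["chrom", "site", "probe_type"], keep="first")
    return winners.drop(columns="_fwd")


def _covers(row: pd.Series, species: str) -> bool:
    return species in str(row["covered_species"]).split(";")


def assemble(candidates: pd.DataFrame, config: AssemblyConfig,
             epic_metadata: pd.DataFrame | None = None,
             ) -> pd.DataFrame:
    """Run selection steps S1-S4 and return the manifest table.

    ``candidates`` has one row per (site, probe_type, strand) as made by
    :func:`candidates_to_frame`.  ``epic_metadata`` needs columns
    cpg_id, chrom, position (1-based C), probe_type, strand.
    """
    if config.n_epic > 0 and epic_metadata is None:
        raise ValueError("n_epic > 0 but no EPIC metadata supplied")

    winners = _winners_per_type(candidates)
    t2 = winners[winners["probe_type"] == "II"]
    t1 = winners[winners["probe_type"] == "I"]

    selected: list[pd.Series] = []
    chosen_sites: set[tuple[str, int]] = set()

    def take(row: pd.Series, step: str) -> None:
        r = row.copy()
        r["provenance_step"] = step
        selected.append(r)
        chosen_sites.add((row["chrom"], row["site"]))

    # S1: all Type II probes expected to work in the model species
    s1 = t2[t2.apply(_covers, axis=1, species=config.model_species)]
    s1 = s1.sort_values(["chrom", "site"], kind="mergesort")
    for _, row in s1.iterrows():
        take(row, "S1_model_species")
    logger.info("S1: %d probes cover model species %s", len(s1),
                config.model_species)

    # S2: top up with remaining sites by descending Type II coverage
    n_s2 = config.total_after_topup - len(s1)
    if n_s2 < 0:
        warnings.warn("total_after_topup below S1 size; no top-up performed")
        n_s2 = 0
    rest = t2[~t2.set_index(["chrom", "site"]).index.isin(chosen_sites)]
    rest = rest.sort_values(["coverage", "chrom", "site"],
                            ascending=[False, True, True], kind="mergesort")
    if n_s2 > len(rest):
        warnings.warn(f"only {len(rest)} candidates available for "
                      f"{n_s2} top-up slots")
    for _, row in rest.head(n_s2).iterrows():
        take(row, "S2_topup")

    # S3: EPIC-listed CpGs, same probe type and strand as on EPIC, with
    # this pipeline's degenerate bases
    if config.n_epic > 0:
        epic_rows = []
        keyed = candidates.set_index(["chrom", "site", "probe_type", "strand"])
        for _, em in epic_metadata.iterrows():
            if pd.isna(em.get("strand")) or em.get("strand") not in "+-":
                warnings.warn(f"EPIC row {em.get('cpg_id')} lacks strand; skipped")
                continue
            site = int(em["position"]) - 1
            key = (em["chrom"], site, str(em["probe_type"]), em["strand"])
            if (em["chrom"], site) in chosen_sites:
                continue
            if key not in keyed.index:
                continue
            row = keyed.loc[key]
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            r = row.copy()
            r["chrom"], r["site"] = em["chrom"], site
            r["probe_type"], r["strand"] = str(em["probe_type"]), em["strand"]
            r["epic_id"] = em["cpg_id"]
            epic_rows.append(r)
        if epic_rows:
            s3 = pd.DataFrame(epic_rows)
            s3 = s3.sort_values(["coverage", "chrom", "site"],
                                ascending=[False, True, True], kind="mergesort")
            for _, row in s3.head(config.n_epic).iterrows():
                take(row, "S3_epic")

    # S4: remaining sites by descending Type I coverage
    if config.n_typeI > 0:
        rest1 = t1[~t1.set_index(["chrom", "site"]).index.isin(chosen_sites)]
        rest1 = rest1.sort_values(["coverage", "chrom", "site"],
                                  ascending=[False, True, True],
                                  kind="mergesort")
        for _, row in rest1.head(config.n_typeI).iterrows():
            take(row, "S4_typeI")

    manifest = pd.DataFrame(selected).reset_index(drop=True)
    if manifest.empty:
        return pd.DataFrame(columns=MANIFEST_COLUMNS)
    manifest["position"] = manifest["site"].astype(int) + 1  # 1-based C
    ids = []
    for i, row in manifest.iterrows():
        epic_id = row.get("epic_id")
        ids.append(epic_id if isinstance(epic_id, str) and epic_id
                   else f"cg{i + 1:08d}")
    manifest["probe_id"] = ids
    manifest["duplicate_suffix"] = ""
    keep = MANIFEST_COLUMNS + ["site", "budget_M"]
    return manifest[[c for c in keep if c in manifest.columns]]


def apply_mappability_filter(manifest: pd.DataFrame,
                             uniqueness: pd.DataFrame,
                             config: AssemblyConfig) -> pd.DataFrame:
    """Keep probes unique in enough of the targeted panel genomes.

    ``uniqueness``: boolean table indexed by probe_id with one column per
    panel genome.  A probe is retained iff its unique fraction over the
    panel genomes it targets is >= the threshold, or its species
    coverage reaches ``rescue_species_count``.  With
    ``mappability_denominator='panel'`` the fraction is over the whole
    panel instead of panel ∩ covered species.
    """
    panel = list(config.panel_genomes) or list(uniqueness.columns)
    keep = []
    for _, row in manifest.iterrows():
        pid = row["probe_id"]
        if pid not in uniqueness.index:
            raise KeyError(f"probe {pid} absent from uniqueness report")
        if int(row["coverage"]) >= config.rescue_species_count:
            keep.append(True)
            continue
        covered = set(str(row["covered_species"]).split(";"))
        if config.mappability_denominator == "targeted":
            denom = [g for g in panel if g in covered]
        else:
            denom = panel
        if not denom:
            keep.append(False)
            continue
        frac = sum(bool(uniqueness.loc[pid, g]) for g in denom) / len(denom)
        keep.append(frac >= config.mappability_fraction_threshold)
    out = manifest[pd.Series(keep, index=manifest.index)].reset_index(drop=True)
    logger.info("mappability filter: %d of %d probes retained",
                len(out), len(manifest))
    return out


REQUIRED_BIOMARKER_FIELDS = ["probe_id", "chrom", "position", "probe_type",
                             "strand", "sequence"]


def merge_biomarkers(manifest: pd.DataFrame,
                     biomarker_list: pd.DataFrame | None) -> pd.DataFrame:
    """Append biomarker probes; duplicate cytosine targets keep both rows.

    Biomarker rows carry their own IDs and sequences ('cg...' CpG
    probes, 'ch...' non-CpG cytosines accepted without CpG validation,
    'rs...' SNP probes).  A collision with a design probe at the same
    (chrom, position) suffixes both rows '.1' (design) and '.2'
    (biomarker).
    """
    if biomarker_list is None or len(biomarker_list) == 0:
        return manifest.copy()
    out = manifest.copy()
    if "duplicate_suffix" not in out.columns:
        out["duplicate_suffix"] = ""
    design_pos = {(r["chrom"], int(r["position"])): i
                  for i, r in out.iterrows()}
    new_rows = []
    for idx, row in biomarker_list.iterrows():
        missing = [f for f in REQUIRED_BIOMARKER_FIELDS
                   if f not in row or pd.isna(row[f])]
        if missing:
            raise ValueError(
                f"biomarker row {idx} ({row.get('probe_id', '?')}) missing "
                f"fields: {missing}")
        r = {c: "" for c in MANIFEST_COLUMNS}
        for f in REQUIRED_BIOMARKER_FIELDS:
            r[f] = row[f]
        r["position"] = int(row["position"])
        r["coverage"] = int(row.get("coverage", 0) or 0)
        r["provenance_step"] = "biomarker"
        r["duplicate_suffix"] = ""
        key = (r["chrom"], r["position"])
        if key in design_pos:
            i = design_pos[key]
            out.at[i, "duplicate_suffix"] = ".1"
            r["duplicate_suffix"] = ".2"
        new_rows.append(r)
    merged = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
    return merged


def final_probe_ids(manifest: pd.DataFrame) -> pd.Series:
    return manifest["probe_id"].astype(str) + \
        manifest["duplicate_suffix"].fillna("").astype(str)


def manifest_summary(manifest: pd.DataFrame) -> dict[str, int]:
    """Counts reported for a finished array: unique targeted cytosines,
    probe sets, and total expanded sequences to synthesize."""
    cytosines = manifest[["chrom", "position"]].drop_duplicates()
    n_expanded = int(sum(
        expansion_cardinality(s) for s in manifest["sequence"] if s))
    return {
        "unique_cytosines": int(len(cytosines)),
        "probe_sets": int(len(manifest)),
        "expanded_sequences": n_expanded,
    }


def manifest_to_bed(manifest: pd.DataFrame) -> str:
    """BED (0-based half-open) of targeted cytosines."""
    lines = []
    for _, r in manifest.iterrows():
        p = int(r["position"]) - 1
        lines.append(f"{r['chrom']}\t{p}\t{p + 1}\t{r['probe_id']}\n")
    return "".join(lines)
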