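"""Domain-architecture assembly.

The architecture of a protein is the ordered N->C sequence of its accepted
Pfam domains and transmembrane helices.  Assembly proceeds in three steps:

1. *Conflict resolution* among accepted domain hits: whenever two domain
   envelopes overlap by more than a set fraction (default 25%) of the length
   of either one of them, only the hit with the lower independent E-value
   survives.  Resolution is greedy by ascending E-value with a strict
   tie-break (longer envelope, then domain name, then envelope start), making
   the survivor set independent of input order.
2. *Topology integration*: predicted transmembrane helices are added, but a
   Pfam domain takes precedence — any helix overlapping a surviving domain by
   at least one residue is dropped.  Retained helices get an orientation from
   their flanking loop segments (iTMHo: inside N-terminally, outside
   C-terminally; oTMHi: the reverse), and a lone N-terminal helix is flagged
   as a putative signal peptide.
3. *Repeat grouping*: maximal runs of consecutive identical labels collapse
   into a single element with a repeat count; the canonical architecture key
   ignores repeat counts.

A protein counts as a metacaspase only if the bacterial metacaspase domain
survives into its final architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import DomainHit, GenomeRecord, TopologySegment
from .stats import round_half_away

#: Pfam-style name of the bacterial metacaspase domain used throughout.
METACASPASE_DOMAIN = "Bac_PepC14"

#: Residue position threshold under which a lone helix is a putative signal peptide.
SIGNAL_PEPTIDE_MAX_START = 30


@dataclass(frozen=True)
class OverlapRule:
    """Conflict threshold: overlap beyond this fraction of either envelope."""

    conflict_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.conflict_fraction <= 1):
            raise ValidationError("conflict_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ArchitectureElement:
    """One element of an architecture: a Pfam domain or a transmembrane helix."""

    label: str  # domain name, or "TMH"
    kind: str  # "pfam" | "tmh"
    start: int
    end: int
    repeat_count: int = 1
    orientation: str | None = None  # "iTMHo" | "oTMHi" (tmh only)
    signal_peptide_flag: bool = False  # tmh only

    def display_label(self, include_orientation: bool = False) -> str:
        if self.kind == "tmh" and include_orientation and self.orientation:
            return self.orientation
        return self.label


@dataclass(frozen=True)
class Architecture:
    """The conflict-resolved, repeat-grouped architecture of one protein."""

    protein_id: str
    elements: tuple[ArchitectureElement, ...]
    canonical: str
    is_metacaspase: bool
    genome_id: str = ""


def _rank_key(hit: DomainHit) -> tuple:
    # strict total order: best E-value, then longer envelope, then name, then position
    return (hit.i_evalue, -hit.env_length, hit.domain_name, hit.env_from, hit.env_to)


def _overlap(a_from: int, a_to: int, b_from: int, b_to: int) -> int:
    return max(0, min(a_to, b_to) - max(a_from, b_from) + 1)


def hits_conflict(a: DomainHit, b: DomainHit, rule: OverlapRule | None = None) -> bool:
    """True when the envelopes overlap more than the fraction of either one."""
    rule = rule or OverlapRule()
    ov = _overlap(a.env_from, a.env_to, b.env_from, b.env_to)
    return ov > rule.conflict_fraction * min(a.env_length, b.env_length)


def resolve_domain_conflicts(
    hits: Sequence[DomainHit], rule: OverlapRule | None = None
) -> list[DomainHit]:
    """Greedy lowest-E-value-first resolution of overlapping domain hits.

    A hit is accepted iff it conflicts with no already-accepted hit; survivors
    are returned sorted by envelope start.  All hits must share a protein.
    """
    rule = rule or OverlapRule()
    if len({h.protein_id for h in hits}) > 1:
        raise ValidationError("resolve_domain_conflicts: hits span several proteins")
    survivors: list[DomainHit] = []
    for hit in sorted(hits, key=_rank_key):
        if not any(hits_conflict(hit, kept, rule) for kept in survivors):
            survivors.append(hit)
    survivors.sort(key=lambda h: (h.env_from, h.env_to, h.domain_name))
    return survivors


def _helix_orientation(
    helix: TopologySegment, segments: Sequence[TopologySegment]
) -> str | None:
    before = [s for s in segments if s.kind != "helix" and s.end < helix.start]
    after = [s for s in segments if s.kind != "helix" and s.start > helix.end]
    kind_before = before[-1].kind if before else None
    kind_after = after[0].kind if after else None
    if kind_before == "inside" and kind_after == "outside":
        return "iTMHo"
    if kind_before == "outside" and kind_after == "inside":
        return "oTMHi"
    return None


def integrate_topology(
    survivors: Sequence[DomainHit],
    segments: Sequence[TopologySegment],
    protein_id: str | None = None,
) -> list[ArchitectureElement]:
    """Merge surviving domains with membrane topology into ordered elements.

    Helices overlapping any surviving domain by >= 1 residue are dropped
    (Pfam domain precedence).  A retained helix starting at residue
    <= ``SIGNAL_PEPTIDE_MAX_START`` that is the protein's only predicted helix
    is flagged as a putative signal peptide.
    """
    if protein_id is None and survivors:
        protein_id = survivors[0].protein_id
    for seg in segments:
        if protein_id is not None and seg.protein_id != protein_id:
            raise ValidationError(
                f"topology segment for {seg.protein_id!r} passed to protein "
                f"{protein_id!r}"
            )
    elements: list[ArchitectureElement] = [
        ArchitectureElement(
            label=h.domain_name,
            kind="pfam",
            start=h.env_from,
            end=h.env_to,
        )
        for h in survivors
    ]
    helices = [s for s in segments if s.kind == "helix"]
    for helix in helices:
        if any(_overlap(helix.start, helix.end, h.env_from, h.env_to) >= 1 for h in survivors):
            continue  # domain takes precedence
        elements.append(
            ArchitectureElement(
                label="TMH",
                kind="tmh",
                start=helix.start,
                end=helix.end,
                orientation=_helix_orientation(helix, segments),
                signal_peptide_flag=(
                    helix.start <= SIGNAL_PEPTIDE_MAX_START and len(helices) == 1
                ),
            )
        )
    elements.sort(key=lambda e: (e.start, e.end))
    return elements


def build_architecture(
    elements: Sequence[ArchitectureElement],
    protein_id: str = "",
    genome_id: str = "",
    metacaspase_label: str = METACASPASE_DOMAIN,
    include_orientation: bool = False,
) -> Architecture:
    """Group consecutive repeats and derive the canonical architecture key.

    The canonical key joins element labels N->C with ``|``, ignoring repeat
    counts; helix orientation labels (iTMHo/oTMHi) replace the plain "TMH"
    only when ``include_orientation`` is set.  An empty element list yields an
    empty, non-metacaspase architecture.
    """
    merged: list[ArchitectureElement] = []
    for el in sorted(elements, key=lambda e: (e.start, e.end)):
        if merged and merged[-1].display_label(include_orientation) == el.display_label(
            include_orientation
        ):
            prev = merged[-1]
            merged[-1] = replace(
                prev,
                end=el.end,
                repeat_count=prev.repeat_count + el.repeat_count,
                signal_peptide_flag=prev.signal_peptide_flag or el.signal_peptide_flag,
            )
        else:
            merged.append(el)
    canonical = "|".join(e.display_label(include_orientation) for e in merged)
    return Architecture(
        protein_id=protein_id,
        elements=tuple(merged),
        canonical=canonical,
        is_metacaspase=any(
            e.kind == "pfam" and e.label == metacaspase_label for e in merged
        ),
        genome_id=genome_id,
    )


def assemble_protein(
    hits: Sequence[DomainHit],
    segments: Sequence[TopologySegment],
    protein_id: str,
    genome_id: str = "",
    rule: OverlapRule | None = None,
    metacaspase_label: str = METACASPASE_DOMAIN,
    include_orientation: bool = False,
) -> Architecture:
    """Full assembly for one protein: conflicts -> topology -> repeat grouping."""
    survivors = resolve_domain_conflicts(list(hits), rule)
    elements = integrate_topology(survivors, segments, protein_id=protein_id)
    return build_architecture(
        elements,
        protein_id=protein_id,
        genome_id=genome_id,
        metacaspase_label=metacaspase_label,
        include_orientation=include_orientation,
    )


def architecture_census(
    architectures: Sequence[Architecture], genomes: Sequence[GenomeRecord]
) -> pd.DataFrame:
    """Count sequences and group incidence per canonical architecture key.

    Only metacaspase architectures are tallied.  Columns: canonical,
    n_sequences, n_groups, groups (';'-joined, sorted), group_unique.
    """
    group_of = {g.genome_id: g.group for g in genomes}
    rows: dict[str, dict] = {}
    for arch in architectures:
        if not arch.is_metacaspase:
            continue
        if arch.genome_id not in group_of:
            raise ValidationError(
                f"architecture {arch.protein_id}: genome {arch.genome_id!r} has no group"
            )
        entry = rows.setdefault(arch.canonical, {"n_sequences": 0, "groups": set()})
        entry["n_sequences"] += 1
        entry["groups"].add(group_of[arch.genome_id])
    out = pd.DataFrame(
        [
            {
                "canonical": key,
                "n_sequences": entry["n_sequences"],
                "n_groups": len(entry["groups"]),
                "groups": ";".join(sorted(entry["groups"])),
                "group_unique": len(entry["groups"]) == 1,
            }
            for key, entry in rows.items()
        ],
        columns=["canonical", "n_sequences", "n_groups", "groups", "group_unique"],
    )
    return out.sort_values(
        ["n_sequences", "canonical"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def domain_prevalence(architectures: Sequence[Architecture]) -> pd.DataFrame:
    """Per-element prevalence among metacaspase sequences.

    For each element label (Pfam domain or TMH): the number and percentage
    (one decimal) of metacaspase sequences containing at least one instance.
    """
    metacaspases = [a for a in architectures if a.is_metacaspase]
    total = len(metacaspases)
    counts: dict[str, int] = {}
    for arch in metacaspases:
        for label in {e.label for e in arch.elements}:
            counts[label] = counts.get(label, 0) + 1
    out = pd.DataFrame(
        [
            {
                "domain": label,
                "n_sequences": n,
                "percent": survey_pct(n, total) if total else 0.0,
            }
            for label, n in counts.items()
        ],
        columns=["domain", "n_sequences", "percent"],
    )
    return out.sort_values(
        ["n_sequences", "domain"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def survey_pct(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, rounded half away from zero."""
    return round_half_away(100.0 * numerator / denominator, 1)
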