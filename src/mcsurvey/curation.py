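"""Training-set curation preceding profile construction.

Reproduces the curation pipeline applied to domain envelopes before a search
profile is trained from them: extract the envelope slice of every hit, keep
only envelopes with an intact catalytic dyad, collapse redundancy by greedy
identity clustering (cd-hit style: longest sequence first, identity measured
as matched residues over the shorter sequence's length), and keep the longest
member of each cluster as its representative.  The curated representatives are
written as FASTA, ready for external alignment and profile building; a quality
report (reference column occupancy, terminal-gap fractions) stands in for the
manual alignment editing a human curator would perform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dyad import DyadReference, classify_dyad, global_align
from .errors import ValidationError
from .io_formats import DomainHit, ProteinRecord


@dataclass(frozen=True)
class CurationConfig:
    """Redundancy-clustering parameters (identity threshold, representative rule)."""

    identity_threshold: float = 0.90
    representative_rule: str = "longest"

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValidationError("identity_threshold must be in (0, 1]")
        if self.representative_rule != "longest":
            raise ValidationError("only the 'longest' representative rule is supported")


@dataclass(frozen=True)
class Envelope:
    """One extracted domain envelope."""

    protein_id: str
    sequence: str


def extract_envelopes(
    hits: Sequence[DomainHit],
    sequences: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
) -> list[Envelope]:
    """Slice the envelope residues ``env_from..env_to`` out of each hit's protein."""
    if not isinstance(sequences, Mapping):
        sequences = {p.protein_id: p for p in sequences}
    envelopes = []
    for hit in hits:
        protein = sequences.get(hit.protein_id)
        if protein is None:
            raise ValidationError(
                f"hit {hit.protein_id}/{hit.domain_name}: protein sequence missing"
            )
        if hit.env_to > len(protein.sequence):
            raise ValidationError(
                f"hit {hit.protein_id}/{hit.domain_name}: envelope end "
                f"{hit.env_to} beyond sequence length {len(protein.sequence)}"
            )
        envelopes.append(
            Envelope(hit.protein_id, protein.sequence[hit.env_from - 1 : hit.env_to])
        )
    return envelopes


def dyad_filter(envelopes: Sequence[Envelope], ref: DyadReference) -> list[Envelope]:
    """Keep exactly the envelopes whose catalytic dyad is conserved."""
    return [
        env
        for env in envelopes
        if classify_dyad(env.sequence, ref, env.protein_id).status == "Positive"
    ]


def sequence_identity(a: str, b: str) -> float:
    """Identity of two sequences: matched residues / length of the shorter one."""
    aln = global_align(a, b)
    matches = sum(1 for ra, rb in aln.columns() if ra == rb and ra != "-")
    return matches / min(len(a), len(b))


def cluster_representatives(
    envelopes: Sequence[Envelope], cfg: CurationConfig | None = None
) -> tuple[list[Envelope], dict[str, str]]:
    """Greedy incremental identity clustering, longest sequence first.

    Each sequence joins the first existing cluster whose representative it
    matches at or above the identity threshold, else founds a new cluster; the
    founder (the longest member, by processing order) is the representative.
    Returns the representatives in founding order and the protein_id ->
    representative protein_id assignment.
    """
    cfg = cfg or CurationConfig()
    if not envelopes:
        raise ValidationError("cluster_representatives: no envelopes")
    ordered = sorted(envelopes, key=lambda e: (-len(e.sequence), e.protein_id))
    representatives: list[Envelope] = []
    assignment: dict[str, str] = {}
    for env in ordered:
        for rep in representatives:
            if sequence_identity(env.sequence, rep.sequence) >= cfg.identity_threshold:
                assignment[env.protein_id] = rep.protein_id
                break
        else:
            representatives.append(env)
            assignment[env.protein_id] = env.protein_id
    return representatives, assignment


def curation_report(
    envelopes: Sequence[Envelope], ref: DyadReference
) -> dict:
    """Reference-anchored alignment quality report for human review.

    Aligns every envelope pairwise to the reference and reports, per reference
    column, the fraction of envelopes contributing a residue (insertions
    relative to the reference are ignored), plus each envelope's unaligned
    reference fraction (the share of reference columns it leaves gapped —
    driven by terminal truncation).  Low-occupancy columns are the positions
    a curator would trim.
    """
    n_ref = len(ref.reference_sequence)
    occupancy = [0] * n_ref
    rows = []
    for env in envelopes:
        aln = global_align(ref.reference_sequence, env.sequence)
        ref_pos = 0
        occupied = []
        for ra, rb in aln.columns():
            if ra != "-":
                ref_pos += 1
                if rb != "-":
                    occupied.append(ref_pos)
        for p in occupied:
            occupancy[p - 1] += 1
        terminal_gap = 1.0 - len(set(occupied)) / n_ref
        rows.append(
            {"protein_id": env.protein_id, "terminal_gap_fraction": terminal_gap}
        )
    n = max(len(envelopes), 1)
    return {
        "column_occupancy": [c / n for c in occupancy],
        "per_sequence": pd.DataFrame(rows, columns=["protein_id", "terminal_gap_fraction"]),
    }


def curate(
    hits: Sequence[DomainHit],
    sequences: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    ref: DyadReference,
    cfg: CurationConfig | None = None,
) -> tuple[list[Envelope], dict[str, str], dict]:
    """Full curation: extract -> dyad filter -> cluster; returns reps, assignment, report."""
    envelopes = dyad_filter(extract_envelopes(hits, sequences), ref)
    if not envelopes:
        return [], {}, {"column_occupancy": [], "per_sequence": pd.DataFrame()}
    reps, assignment = cluster_representatives(envelopes, cfg)
    return reps, assignment, curation_report(reps, ref)


def write_curated_fasta(representatives: Sequence[Envelope], path: str | Path) -> None:
    """Write cluster representatives as FASTA, ready for external profile building."""
    SeqIO.write(
        [SeqRecord(Seq(e.sequence), id=e.protein_id, description="") for e in representatives],
        str(path),
        "fasta",
    )
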