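"""Operon context of metacaspases.

Operon predictions are consumed, never computed: membership of metacaspase
genes in precomputed operons is tabulated, operon neighbors annotated through
the same domain-architecture machinery as the metacaspases themselves, and
conserved operon configurations grouped by identical ordered neighbor-domain
signatures.  Genomes absent from the operon table are excluded from operon
denominators (prediction databases rarely cover every surveyed genome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import annotate_functions
from .architecture import METACASPASE_DOMAIN, Architecture
from .io_formats import DomainAnnotation, OperonRecord


@dataclass(frozen=True)
class OperonSummary:
    """Survey-level operon statistics.

    ``n_metacaspases_covered`` counts metacaspases in genomes the operon table
    covers (the denominator of ``fraction_in_operons``).
    """

    n_covered_genomes: int
    n_metacaspases_covered: int
    n_in_operons: int
    n_operons_with_metacaspase: int
    n_multi_metacaspase_operons: int
    max_metacaspases_per_operon: int

    @property
    def fraction_in_operons(self) -> float:
        if self.n_metacaspases_covered == 0:
            return 0.0
        return self.n_in_operons / self.n_metacaspases_covered


def map_to_operons(
    metacaspase_ids: Iterable[str],
    operons: Sequence[OperonRecord],
    protein_genomes: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, OperonSummary]:
    """Assign each metacaspase to its operon (if any) and summarize.

    Returns a membership table (protein_id, operon_id or empty) and the
    summary counts.  When ``protein_genomes`` maps metacaspase ids to genome
    ids, only metacaspases in genomes present in the operon table count
    toward the coverage denominator; without it every metacaspase counts.
    """
    mc_ids = sorted(set(metacaspase_ids))
    operon_of: dict[str, str] = {}
    for op in operons:
        for gene in op.gene_ids:
            if gene in set(mc_ids):
                operon_of[gene] = op.operon_id
    covered_genomes = {op.genome_id for op in operons}
    if protein_genomes is not None:
        covered_ids = [p for p in mc_ids if protein_genomes[p] in covered_genomes]
    else:
        covered_ids = mc_ids
    membership = pd.DataFrame(
        [{"protein_id": p, "operon_id": operon_of.get(p, "")} for p in mc_ids],
        columns=["protein_id", "operon_id"],
    )
    per_operon = (
        membership[membership["operon_id"] != ""]
        .groupby("operon_id")["protein_id"]
        .count()
    )
    summary = OperonSummary(
        n_covered_genomes=len(covered_genomes),
        n_metacaspases_covered=len(covered_ids),
        n_in_operons=int(sum(1 for p in covered_ids if p in operon_of)),
        n_operons_with_metacaspase=int(len(per_operon)),
        n_multi_metacaspase_operons=int((per_operon >= 2).sum()),
        max_metacaspases_per_operon=int(per_operon.max()) if len(per_operon) else 0,
    )
    return membership, summary


def annotate_operon_neighbors(
    operons: Sequence[OperonRecord],
    metacaspase_ids: Iterable[str],
    architectures: Mapping[str, Architecture],
    annotations: Mapping[str, DomainAnnotation] | Sequence[DomainAnnotation],
    metacaspase_label: str = METACASPASE_DOMAIN,
) -> pd.DataFrame:
    """Per metacaspase-containing operon: the union of neighbor function labels.

    Neighbors are the operon's non-metacaspase genes; each contributes the
    function categories of its architected domains (the metacaspase domain
    itself excluded).  Neighbors without an architecture contribute nothing;
    an operon with no informative neighbor is labelled ``unknown``.

    Columns: operon_id, genome_id, metacaspase_count, n_neighbors, functions
    (';'-joined, sorted).
    """
    mc_set = set(metacaspase_ids)
    rows = []
    for op in operons:
        members = set(op.gene_ids)
        mc_here = members & mc_set
        if not mc_here:
            continue
        neighbors = [g for g in op.gene_ids if g not in mc_set]
        functions: set[str] = set()
        for gene in neighbors:
            arch = architectures.get(gene)
            if arch is None or not arch.elements:
                continue  # no hits for this neighbor: contributes nothing
            functions |= annotate_functions(arch, annotations, metacaspase_label)
        functions -= {"unknown"}
        if not functions:
            functions = {"unknown"}
        rows.append(
            {
                "operon_id": op.operon_id,
                "genome_id": op.genome_id,
                "metacaspase_count": len(mc_here),
                "n_neighbors": len(neighbors),
                "functions": ";".join(sorted(functions)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["operon_id", "genome_id", "metacaspase_count", "n_neighbors", "functions"],
    )


def operon_signatures(
    operons: Sequence[OperonRecord],
    metacaspase_ids: Iterable[str],
    architectures: Mapping[str, Architecture],
) -> pd.DataFrame:
    """Group metacaspase operons by their ordered neighbor-domain signature.

    The signature is the N->C tuple of canonical architectures of the operon's
    genes (metacaspase genes rendered as their canonical key, neighbors
    without hits as "-").  Identical signatures across genomes indicate a
    conserved operon configuration.
    """
    mc_set = set(metacaspase_ids)
    rows: dict[str, list[str]] = {}
    for op in operons:
        if not (set(op.gene_ids) & mc_set):
            continue
        sig = "+".join(
            architectures[g].canonical
            if g in architectures and architectures[g].elements
            else "-"
            for g in op.gene_ids
        )
        rows.setdefault(sig, []).append(op.operon_id)
    out = pd.DataFrame(
        [
            {"signature": sig, "n_operons": len(ops), "operon_ids": ";".join(sorted(ops))}
            for sig, ops in rows.items()
        ],
        columns=["signature", "n_operons", "operon_ids"],
    )
    return out.sort_values(
        ["n_operons", "signature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
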