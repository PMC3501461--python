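"""Per-genome and per-group metacaspase abundance statistics.

Abundance is normalized as metacaspases per 1000 proteome proteins; group
summaries report the unweighted mean of per-genome abundances (a pooled
counts/proteins mode is available), genome counts per abundance bin, and fold
sparsely sequenced metacaspase-free groups into an "Other" category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import GenomeRecord

#: Inner bin edges for the abundance histogram: zero / (0, .5] / (.5, 1] / >1.
DEFAULT_ABUNDANCE_BINS = (0.5, 1.0)

#: Groups with at most this many genomes and no metacaspases fold into "Other".
OTHER_MAX_GENOMES = 5


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero (so 0.5 -> 1, not banker's 0)."""
    factor = 10**decimals
    scaled = value * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor


def survey_percentages(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half away from zero."""
    if denominator == 0:
        raise ValidationError("zero denominator in percentage")
    if numerator < 0 or denominator < 0:
        raise ValidationError("negative count in percentage")
    return round_half_away(100.0 * numerator / denominator, decimals)


@dataclass(frozen=True)
class AbundanceRecord:
    """Metacaspase count and per-1000-proteins abundance of one genome."""

    genome_id: str
    metacaspase_count: int
    abundance: float  # 1000 * metacaspase_count / protein_count


def genome_abundance(
    architectures: Sequence, genomes: Sequence[GenomeRecord]
) -> list[AbundanceRecord]:
    """Count metacaspase-positive proteins per genome and normalize.

    Every genome in the table gets a record (zero counts included).
    ``architectures`` is any sequence of objects with ``genome_id`` and
    ``is_metacaspase`` attributes.
    """
    by_genome = {g.genome_id: g for g in genomes}
    counts: dict[str, int] = {g.genome_id: 0 for g in genomes}
    for arch in architectures:
        if not arch.is_metacaspase:
            continue
        if arch.genome_id not in by_genome:
            raise ValidationError(
                f"metacaspase {arch.protein_id}: genome {arch.genome_id!r} "
                "missing from the genome table"
            )
        counts[arch.genome_id] += 1
    return [
        AbundanceRecord(
            genome_id=gid,
            metacaspase_count=n,
            abundance=1000.0 * n / by_genome[gid].protein_count,
        )
        for gid, n in counts.items()
    ]


def _bin_label(abundance: float, bins: Sequence[float]) -> str:
    if abundance == 0:
        return "0"
    lo = 0.0
    for edge in bins:
        if abundance <= edge:
            return f"({lo:g},{edge:g}]"
        lo = edge
    return f">{bins[-1]:g}" if bins else ">0"


def group_summary(
    records: Sequence[AbundanceRecord],
    genomes: Sequence[GenomeRecord],
    bins: Sequence[float] = DEFAULT_ABUNDANCE_BINS,
    other_max_genomes: int = OTHER_MAX_GENOMES,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-group abundance table, ordered by descending mean abundance.

    Columns: group, n_genomes, n_metacaspases, mean_abundance, and one count
    column per abundance bin.  Groups with ``<= other_max_genomes`` genomes
    and zero metacaspases are folded into "Other" (per superkingdom, labelled
    "Other (<superkingdom>)" when superkingdoms are mixed).  ``pooled``
    switches the mean from the unweighted per-genome mean to pooled
    counts/proteins x 1000.
    """
    by_genome = {g.genome_id: g for g in genomes}
    for rec in records:
        if rec.genome_id not in by_genome:
            raise ValidationError(f"abundance record for unknown genome {rec.genome_id!r}")

    bin_labels = ["0"] + [
        f"({lo:g},{hi:g}]"
        for lo, hi in zip((0.0, *bins), bins)
    ] + ([f">{bins[-1]:g}"] if bins else [])

    frame = pd.DataFrame(
        [
            {
                "group": by_genome[r.genome_id].group,
                "superkingdom": by_genome[r.genome_id].superkingdom,
                "protein_count": by_genome[r.genome_id].protein_count,
                "count": r.metacaspase_count,
                "abundance": r.abundance,
                "bin": _bin_label(r.abundance, bins),
            }
            for r in records
        ]
    )
    if frame.empty:
        return pd.DataFrame(
            columns=["group", "n_genomes", "n_metacaspases", "mean_abundance", *bin_labels]
        )

    fold = (
        frame.groupby("group")["count"]
        .agg(["size", "sum"])
        .pipe(lambda df: df[(df["size"] <= other_max_genomes) & (df["sum"] == 0)])
        .index
    )
    superkingdoms = set(frame["superkingdom"])
    if len(superkingdoms) > 1:
        other_label = {
            sk: f"Other ({sk})" for sk in superkingdoms
        }
        frame["group"] = [
            other_label[sk] if g in set(fold) else g
            for g, sk in zip(frame["group"], frame["superkingdom"])
        ]
    else:
        frame.loc[frame["group"].isin(fold), "group"] = "Other"

    rows = []
    for group, sub in frame.groupby("group", sort=False):
        if pooled:
            mean = 1000.0 * sub["count"].sum() / sub["protein_count"].sum()
        else:
            mean = sub["abundance"].mean()
        row = {
            "group": group,
            "n_genomes": len(sub),
            "n_metacaspases": int(sub["count"].sum()),
            "mean_abundance": mean,
        }
        bin_counts = sub["bin"].value_counts()
        for label in bin_labels:
            row[label] = int(bin_counts.get(label, 0))
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["mean_abundance", "group"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def carrier_split(records: Sequence[AbundanceRecord]) -> dict[str, int]:
    """Split metacaspase-carrying genomes into single-copy vs multi-copy carriers."""
    single = sum(1 for r in records if r.metacaspase_count == 1)
    multi = sum(1 for r in records if r.metacaspase_count >= 2)
    return {
        "carriers": single + multi,
        "single_copy": single,
        "multi_copy": multi,
    }
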