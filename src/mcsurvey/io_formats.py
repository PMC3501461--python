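"""Readers and writers for the external formats the survey touches.

Sequences travel as FASTA (Biopython ``SeqIO``), per-domain hits as either the
full 23-column HMMER3 ``--domtblout`` dialect or a reduced 10-column headered
TSV, membrane topology as TMHMM-style segment lines, and the genome / operon /
domain-annotation tables as headered TSV.  All residue and model coordinates
are 1-based inclusive, following the HMMER and TMHMM conventions.

Parsing is strict: malformed rows raise :class:`~mcsurvey.errors.ValidationError`
with the offending line number rather than being silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, ValidationError

#: Amino-acid alphabet accepted in survey sequences (20 standard letters + X).
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}

#: Function-category vocabulary used by the bundled domain-annotation table
#: (protein-protein interaction, modification, NTPase, ... , unknown).  User
#: tables may extend it with additional labels.
FUNCTION_CATEGORIES = frozenset(
    {
        "protein-protein interaction",
        "protein modification",
        "NTPase",
        "enzymatic",
        "PCD-related",
        "cell wall binding",
        "signaling",
        "helicase",
        "chaperone",
        "protein-carbohydrate interaction",
        "proteolysis",
        "unknown",
    }
)

LOCALIZATIONS = frozenset({"intracellular", "membrane", "extracellular"})

#: Default FASTA header convention: ``>genome_id|protein_id``.
DEFAULT_HEADER_REGEX = r"^(?P<genome>[^|]+)\|(?P<protein>.+)$"


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its source genome."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match on one protein.

    ``hmm_from``/``hmm_to`` are model (match-state) coordinates and
    ``env_from``/``env_to`` the residue coordinates of the domain envelope,
    all 1-based inclusive.  ``i_evalue`` is the domain independent E-value.
    """

    protein_id: str
    domain_name: str
    model_length: int
    hmm_from: int
    hmm_to: int
    env_from: int
    env_to: int
    i_evalue: float
    score: float
    bias: float

    def __post_init__(self) -> None:
        if self.model_length <= 0:
            raise ValidationError(
                f"hit {self.protein_id}/{self.domain_name}: model_length must be positive"
            )
        if not (1 <= self.hmm_from <= self.hmm_to <= self.model_length):
            raise ValidationError(
                f"hit {self.protein_id}/{self.domain_name}: require "
                f"1 <= hmm_from <= hmm_to <= model_length, got "
                f"{self.hmm_from}..{self.hmm_to} on {self.model_length}"
            )
        if not (1 <= self.env_from <= self.env_to):
            raise ValidationError(
                f"hit {self.protein_id}/{self.domain_name}: bad envelope "
                f"{self.env_from}..{self.env_to}"
            )
        if self.i_evalue < 0:
            raise ValidationError(
                f"hit {self.protein_id}/{self.domain_name}: negative E-value"
            )
        if self.bias < 0:
            raise ValidationError(
                f"hit {self.protein_id}/{self.domain_name}: negative bias"
            )

    @property
    def env_length(self) -> int:
        return self.env_to - self.env_from + 1


@dataclass(frozen=True)
class TopologySegment:
    """One TMHMM-style topology segment (inside loop, membrane helix, outside loop)."""

    protein_id: str
    kind: str  # "inside" | "helix" | "outside"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in {"inside", "helix", "outside"}:
            raise ValidationError(
                f"segment {self.protein_id}: unknown kind {self.kind!r}"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"segment {self.protein_id}: bad coordinates {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class GenomeRecord:
    """Taxon assignment and proteome size of one genome."""

    genome_id: str
    organism: str
    group: str
    superkingdom: str
    protein_count: int

    def __post_init__(self) -> None:
        if self.superkingdom not in {"Bacteria", "Archaea"}:
            raise ValidationError(
                f"genome {self.genome_id}: superkingdom must be Bacteria or Archaea"
            )
        if self.protein_count <= 0:
            raise ValidationError(
                f"genome {self.genome_id}: protein_count must be positive"
            )


@dataclass(frozen=True)
class OperonRecord:
    """One predicted operon: an ordered run of co-transcribed genes."""

    operon_id: str
    genome_id: str
    gene_ids: tuple[str, ...]
    strand: str = "+"
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"operon {self.operon_id}: no genes")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"operon {self.operon_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainAnnotation:
    """Function categories and optional localization of one Pfam domain type."""

    domain_name: str
    functions: frozenset[str]
    localization: str | None = None

    def __post_init__(self) -> None:
        if not self.functions:
            raise ValidationError(f"domain {self.domain_name}: no function labels")
        if "unknown" in self.functions and len(self.functions) > 1:
            raise ValidationError(
                f"domain {self.domain_name}: 'unknown' excludes other labels"
            )
        if self.localization is not None and self.localization not in LOCALIZATIONS:
            raise ValidationError(
                f"domain {self.domain_name}: bad localization {self.localization!r}"
            )


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_sequences(
    path: str | Path, header_regex: str = DEFAULT_HEADER_REGEX
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The genome id is extracted from each header with ``header_regex``, which
    must define named groups ``genome`` and ``protein`` (default convention
    ``genome_id|protein_id``).  Order is preserved and sequences upper-cased.
    """
    pattern = re.compile(header_regex)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(rec.id)
        if not m:
            raise ValidationError(
                f"{path}: header {rec.id!r} does not match convention {header_regex!r}"
            )
        protein_id = m.group("protein")
        if protein_id in seen:
            raise ValidationError(f"{path}: duplicate protein_id {protein_id!r}")
        seen.add(protein_id)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                genome_id=m.group("genome"),
                sequence=str(rec.seq).upper(),
            )
        )
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    return records


def write_sequences(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write proteins as FASTA with ``genome_id|protein_id`` headers."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=f"{r.genome_id}|{r.protein_id}", description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# domain hits
# ---------------------------------------------------------------------------

_INTERNAL_HIT_COLUMNS = [
    "protein_id",
    "domain_name",
    "model_length",
    "hmm_from",
    "hmm_to",
    "env_from",
    "env_to",
    "i_evalue",
    "score",
    "bias",
]


def _hit_from_fields(fields: Sequence[str], lineno: int, path: str | Path) -> DomainHit:
    try:
        return DomainHit(
            protein_id=fields[0],
            domain_name=fields[1],
            model_length=int(fields[2]),
            hmm_from=int(fields[3]),
            hmm_to=int(fields[4]),
            env_from=int(fields[5]),
            env_to=int(fields[6]),
            i_evalue=float(fields[7]),
            score=float(fields[8]),
            bias=float(fields[9]),
        )
    except ValueError as exc:  # malformed numeric
        raise ValidationError(f"{path}:{lineno}: malformed hit row ({exc})") from exc


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Parse a per-domain hit table.

    Two dialects are accepted and auto-detected:

    * full HMMER3 ``--domtblout`` (whitespace-delimited, >= 23 columns,
      ``#`` comments) as written by ``hmmscan``: the target is the domain
      model and the query the protein;
    * the reduced 10-column internal TSV with a header line
      (``protein_id .. bias``, see ``_INTERNAL_HIT_COLUMNS``).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.split("\t")[0] == "protein_id":  # internal TSV header
                continue
            fields = line.split()
            if len(fields) >= 23:
                # domtblout (hmmscan): target = model, query = protein
                mapped = [
                    fields[3],  # protein_id  (query name)
                    fields[0],  # domain_name (target name)
                    fields[2],  # model_length (tlen)
                    fields[15],  # hmm_from
                    fields[16],  # hmm_to
                    fields[19],  # env_from
                    fields[20],  # env_to
                    fields[12],  # i-Evalue
                    fields[13],  # score
                    fields[14],  # bias
                ]
                hits.append(_hit_from_fields(mapped, lineno, path))
            elif len(fields) == 10:
                hits.append(_hit_from_fields(fields, lineno, path))
            else:
                raise ValidationError(
                    f"{path}:{lineno}: expected 10-column TSV or >=23-column "
                    f"domtblout row, got {len(fields)} fields"
                )
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the reduced 10-column internal TSV dialect."""
    df = pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "domain_name": h.domain_name,
                "model_length": h.model_length,
                "hmm_from": h.hmm_from,
                "hmm_to": h.hmm_to,
                "env_from": h.env_from,
                "env_to": h.env_to,
                "i_evalue": repr(h.i_evalue),
                "score": repr(h.score),
                "bias": repr(h.bias),
            }
            for h in hits
        ],
        columns=_INTERNAL_HIT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

_KIND_TOKENS = {
    "inside": "inside",
    "tmhelix": "helix",
    "helix": "helix",
    "outside": "outside",
}


def _validate_topology(segments: list[TopologySegment]) -> None:
    """Check that one protein's segments are sorted, disjoint and alternate."""
    for prev, cur in zip(segments, segments[1:]):
        if cur.start <= prev.end:
            raise ValidationError(
                f"segments of {cur.protein_id} overlap: "
                f"{prev.start}..{prev.end} and {cur.start}..{cur.end}"
            )
        if prev.kind == cur.kind:
            raise ValidationError(
                f"segments of {cur.protein_id}: consecutive {cur.kind!r} segments"
            )
        if "helix" not in (prev.kind, cur.kind):
            # inside directly next to outside: no membrane crossing between them
            raise ValidationError(
                f"segments of {cur.protein_id}: {prev.kind} adjacent to {cur.kind} "
                "without a separating helix"
            )
    # the loop kind must flip across each helix
    for i in range(1, len(segments) - 1):
        if segments[i].kind == "helix" and segments[i - 1].kind == segments[i + 1].kind:
            raise ValidationError(
                f"segments of {segments[i].protein_id}: topology does not flip "
                f"across helix {segments[i].start}..{segments[i].end}"
            )


def read_topology_segments(path: str | Path) -> list[TopologySegment]:
    """Parse TMHMM-style long-format topology lines.

    Accepts both the raw TMHMM form ``protein_id TMHMM2.0 kind start end`` and
    the reduced ``protein_id kind start end``; ``TMhelix`` maps to ``helix``.
    Segments are returned grouped per protein, sorted by start, with the
    alternation invariant validated.
    """
    segments: list[TopologySegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] in ("protein_id",):
                continue
            if len(fields) == 5:
                pid, _method, kind_tok, start, end = fields
            elif len(fields) == 4:
                pid, kind_tok, start, end = fields
            else:
                raise ValidationError(f"{path}:{lineno}: expected 4 or 5 fields")
            kind = _KIND_TOKENS.get(kind_tok.lower())
            if kind is None:
                raise ValidationError(f"{path}:{lineno}: unknown kind {kind_tok!r}")
            try:
                seg = TopologySegment(pid, kind, int(start), int(end))
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed coordinates") from exc
            segments.append(seg)

    by_protein: dict[str, list[TopologySegment]] = {}
    for seg in segments:
        by_protein.setdefault(seg.protein_id, []).append(seg)
    out: list[TopologySegment] = []
    for pid, segs in by_protein.items():
        segs.sort(key=lambda s: s.start)
        _validate_topology(segs)
        out.extend(segs)
    return out


def write_topology_segments(segments: Iterable[TopologySegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tkind\tstart\tend\n")
        for s in segments:
            fh.write(f"{s.protein_id}\t{s.kind}\t{s.start}\t{s.end}\n")


# ---------------------------------------------------------------------------
# genome / operon / annotation tables
# ---------------------------------------------------------------------------


def read_genome_table(path: str | Path) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "organism", "group", "superkingdom", "protein_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        if pd.isna(row["protein_count"]) or str(row["protein_count"]).strip() == "":
            raise ValidationError(f"{path}: genome {row['genome_id']}: missing protein_count")
        try:
            count = int(row["protein_count"])
        except ValueError as exc:
            raise ValidationError(
                f"{path}: genome {row['genome_id']}: bad protein_count"
            ) from exc
        records.append(
            GenomeRecord(
                genome_id=row["genome_id"],
                organism=row["organism"],
                group=row["group"],
                superkingdom=row["superkingdom"],
                protein_count=count,
            )
        )
    ids = [r.genome_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{path}: duplicate genome ids")
    return records


def write_genome_table(records: Iterable[GenomeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "organism": g.organism,
                "group": g.group,
                "superkingdom": g.superkingdom,
                "protein_count": g.protein_count,
            }
            for g in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_operon_table(path: str | Path) -> list[OperonRecord]:
    """Read the long-format operon TSV (one row per gene, ordered by rank)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"operon_id", "genome_id", "gene_id", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    gene_owner: dict[str, str] = {}
    records: list[OperonRecord] = []
    for operon_id, sub in df.groupby("operon_id", sort=False):
        sub = sub.copy()
        sub["rank"] = sub["rank"].astype(int)
        sub = sub.sort_values("rank")
        genomes = set(sub["genome_id"])
        if len(genomes) != 1:
            raise ValidationError(f"{path}: operon {operon_id} spans several genomes")
        genes = tuple(sub["gene_id"])
        for g in genes:
            if g in gene_owner:
                raise ValidationError(
                    f"{path}: gene {g!r} assigned to operons "
                    f"{gene_owner[g]!r} and {operon_id!r}"
                )
            gene_owner[g] = str(operon_id)
        strand = sub["strand"].iloc[0] if "strand" in sub.columns else "+"
        start = int(sub["start"].iloc[0]) if "start" in sub.columns else 0
        end = int(sub["end"].iloc[0]) if "end" in sub.columns else 0
        records.append(
            OperonRecord(
                operon_id=str(operon_id),
                genome_id=genomes.pop(),
                gene_ids=genes,
                strand=str(strand),
                start=start,
                end=end,
            )
        )
    return records


def write_operon_table(records: Iterable[OperonRecord], path: str | Path) -> None:
    rows = []
    for op in records:
        for rank, gene in enumerate(op.gene_ids, start=1):
            rows.append(
                {
                    "operon_id": op.operon_id,
                    "genome_id": op.genome_id,
                    "gene_id": gene,
                    "rank": rank,
                    "strand": op.strand,
                    "start": op.start,
                    "end": op.end,
                }
            )
    pd.DataFrame(
        rows,
        columns=["operon_id", "genome_id", "gene_id", "rank", "strand", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"domain_name", "functions"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        functions = frozenset(
            f.strip() for f in str(row["functions"]).split(";") if f.strip()
        )
        loc = row.get("localization")
        if loc is not None and (pd.isna(loc) or str(loc).strip() == ""):
            loc = None
        records.append(
            DomainAnnotation(
                domain_name=row["domain_name"],
                functions=functions,
                localization=None if loc is None else str(loc),
            )
        )
    names = [r.domain_name for r in records]
    if len(names) != len(set(names)):
        raise ValidationError(f"{path}: duplicate domain names")
    return records


def write_annotation_table(records: Iterable[DomainAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "domain_name": a.domain_name,
                "functions": ";".join(sorted(a.functions)),
                "localization": a.localization or "",
            }
            for a in records
        ]
    ).to_csv(path, sep="\t", index=False)


def load_default_annotations() -> list[DomainAnnotation]:
    """Load the bundled domain-annotation table.

    Covers the Pfam domain types most commonly co-occurring with the bacterial
    metacaspase domain; every function label is drawn from
    :data:`FUNCTION_CATEGORIES`.  Domains absent from the table are treated as
    unknown-function by downstream annotation.
    """
    with resources.as_file(
        resources.files("mcsurvey").joinpath("data/domain_annotations.tsv")
    ) as p:
        return read_annotation_table(p)


def read_tables(
    genomes_path: str | Path,
    operons_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
) -> tuple[list[GenomeRecord], list[OperonRecord], list[DomainAnnotation]]:
    """Read the genome, operon and annotation tables with cross-validation.

    Operon genome ids must exist in the genome table.  When no annotation
    table is supplied the bundled default is used.
    """
    genomes = read_genome_table(genomes_path)
    genome_ids = {g.genome_id for g in genomes}
    operons: list[OperonRecord] = []
    if operons_path is not None:
        operons = read_operon_table(operons_path)
        for op in operons:
            if op.genome_id not in genome_ids:
                raise ValidationError(
                    f"operon {op.operon_id}: unknown genome {op.genome_id!r}"
                )
    if annotations_path is not None:
        annotations = read_annotation_table(annotations_path)
    else:
        annotations = load_default_annotations()
    return genomes, operons, annotations


def validate_proteins_against_genomes(
    proteins: Sequence[ProteinRecord], genomes: Sequence[GenomeRecord]
) -> None:
    """Check every protein's genome exists and proteome sizes are consistent."""
    counts: dict[str, int] = {}
    genome_ids = {g.genome_id for g in genomes}
    for p in proteins:
        if p.genome_id not in genome_ids:
            raise ValidationError(
                f"protein {p.protein_id}: unknown genome {p.genome_id!r}"
            )
        counts[p.genome_id] = counts.get(p.genome_id, 0) + 1
    for g in genomes:
        supplied = counts.get(g.genome_id, 0)
        if g.protein_count < supplied:
            raise ValidationError(
                f"genome {g.genome_id}: protein_count {g.protein_count} < "
                f"{supplied} proteins supplied"
            )
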