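"""Synthetic multi-genome survey generator with planted ground truth.

Emulates the statistical structure of a prokaryotic metacaspase survey: a
configurable fraction of genomes carry metacaspases, carriers hold a
zero-truncated-geometric number of copies, each copy realizes one entry of an
architecture palette (including planted overlap conflicts and transmembrane
helices that the pipeline must resolve), catalytic dyads are intact or
substituted (C->S / H->Y) at a configurable rate, sub-threshold decoy hits are
sprinkled in, and metacaspases co-occur in predicted operons.  Every planted
entity is recorded in a :class:`SurveyTruth` manifest so recovery by the
analysis pipeline can be checked exactly.

The generator is not a sequence-evolution simulator: residues outside planted
domains are i.i.d. uniform, which suffices because no pipeline stage models
residue composition beyond the two catalytic columns.

Randomness: one master seed; every genome draws from its own
``default_rng([seed, genome_index])`` stream, so partial regeneration is
stable and identical seed + config gives byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .architecture import METACASPASE_DOMAIN
from .errors import ConfigError
from .io_formats import (
    DomainHit,
    GenomeRecord,
    OperonRecord,
    ProteinRecord,
    TopologySegment,
    write_domain_hits,
    write_genome_table,
    write_operon_table,
    write_sequences,
    write_topology_segments,
)
from .dyad import DyadReference, load_default_reference

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Model lengths (match states) of the domain models the generator can plant.
DOMAIN_MODEL_LENGTHS: dict[str, int] = {
    METACASPASE_DOMAIN: 252,
    "WD40": 40,
    "TPR_1": 34,
    "TPR_2": 34,
    "Sel1": 36,
    "FGE-sulfatase": 260,
    "Polysacc_deac_1": 120,
    "NACHT": 160,
    "CHASE2": 230,
    "Amidase_2": 125,
    "Lactamase_B": 210,
    "Peptidase_S8": 280,
    "OmpA": 80,
}

_DECOY_DOMAINS = (METACASPASE_DOMAIN, "WD40", "Peptidase_S8", "Sel1")
_NEIGHBOR_DOMAINS = ("Lactamase_B", "Amidase_2", "Peptidase_S8", "TPR_1", "OmpA")

_HELIX_LENGTH = 21


@dataclass(frozen=True)
class ElementTemplate:
    """One planted architecture element.

    ``shadow`` plants an additional overlapping decoy domain hit with a worse
    E-value that must lose conflict resolution; ``overlap_helices`` plants
    that many predicted helices inside the domain's envelope, which domain
    precedence must drop.
    """

    label: str
    kind: str = "pfam"  # "pfam" | "tmh"
    length: int = 0
    repeats: int = 1
    shadow: str | None = None
    overlap_helices: int = 0


@dataclass(frozen=True)
class PaletteEntry:
    """A canonical architecture key, its sampling weight, and its elements."""

    key: str
    weight: float
    elements: tuple[ElementTemplate, ...]


_MC = ElementTemplate(METACASPASE_DOMAIN, "pfam", 252)

DEFAULT_PALETTE: tuple[PaletteEntry, ...] = (
    PaletteEntry(METACASPASE_DOMAIN, 0.40, (_MC,)),
    PaletteEntry(
        f"TMH|{METACASPASE_DOMAIN}",
        0.12,
        (ElementTemplate("TMH", "tmh", _HELIX_LENGTH), _MC),
    ),
    PaletteEntry(
        f"{METACASPASE_DOMAIN}|TMH",
        0.08,
        (_MC, ElementTemplate("TMH", "tmh", _HELIX_LENGTH)),
    ),
    PaletteEntry(
        f"{METACASPASE_DOMAIN}|WD40",
        0.10,
        (_MC, ElementTemplate("WD40", "pfam", 40, repeats=3, shadow="TPR_1")),
    ),
    PaletteEntry(
        f"{METACASPASE_DOMAIN}|FGE-sulfatase",
        0.10,
        (_MC, ElementTemplate("FGE-sulfatase", "pfam", 260)),
    ),
    PaletteEntry(
        f"Polysacc_deac_1|{METACASPASE_DOMAIN}|TPR_1",
        0.08,
        (
            ElementTemplate("Polysacc_deac_1", "pfam", 120),
            _MC,
            ElementTemplate("TPR_1", "pfam", 34, repeats=2),
        ),
    ),
    PaletteEntry(
        f"{METACASPASE_DOMAIN}|NACHT|WD40",
        0.07,
        (
            _MC,
            ElementTemplate("NACHT", "pfam", 160),
            ElementTemplate("WD40", "pfam", 40, repeats=4),
        ),
    ),
    PaletteEntry(
        f"{METACASPASE_DOMAIN}|CHASE2",
        0.05,
        (_MC, ElementTemplate("CHASE2", "pfam", 230, overlap_helices=2)),
    ),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Survey-shape parameters.

    Defaults mirror the survey structure the pipeline targets: 18% of genomes
    carry metacaspases, carriers hold a zero-truncated geometric copy number
    with mean 1.7 (so ~59% are single-copy), dyads are substituted in 16% of
    domains, and operon predictions cover 75% of carrier genomes.
    """

    seed: int = 0
    n_genomes: int = 200
    p_positive_genome: float = 0.18
    copy_number_mean: float = 1.7
    max_copies: int = 28
    proteome_size_range: tuple[int, int] = (1500, 8000)
    architecture_palette: tuple[PaletteEntry, ...] = DEFAULT_PALETTE
    p_dyad_negative: float | Mapping[str, float] = 0.16
    decoy_hit_rate: float = 1.0
    p_operon_comembership: float = 0.2
    p_in_operon: float = 0.5
    operon_db_coverage: float = 0.75
    n_groups: int = 8

    def __post_init__(self) -> None:
        probs = [
            self.p_positive_genome,
            self.p_operon_comembership,
            self.p_in_operon,
            self.operon_db_coverage,
        ]
        if isinstance(self.p_dyad_negative, Mapping):
            probs.extend(self.p_dyad_negative.values())
        else:
            probs.append(self.p_dyad_negative)
        if any(not (0 <= p <= 1) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.n_genomes < 0 or self.n_groups < 1:
            raise ConfigError("n_genomes must be >= 0 and n_groups >= 1")
        if self.copy_number_mean < 1:
            raise ConfigError("copy_number_mean must be >= 1")
        if not math.isclose(
            sum(e.weight for e in self.architecture_palette), 1.0, abs_tol=1e-9
        ):
            raise ConfigError("palette weights must sum to 1")
        for entry in self.architecture_palette:
            for el in entry.elements:
                if el.kind == "pfam" and el.label not in DOMAIN_MODEL_LENGTHS:
                    raise ConfigError(f"palette references unknown domain {el.label!r}")
                if el.shadow is not None and el.shadow not in DOMAIN_MODEL_LENGTHS:
                    raise ConfigError(f"palette references unknown shadow {el.shadow!r}")

    def dyad_negative_rate(self, group: str) -> float:
        if isinstance(self.p_dyad_negative, Mapping):
            return self.p_dyad_negative.get(group, 0.0)
        return self.p_dyad_negative


@dataclass(frozen=True)
class SurveyFiles:
    """Paths of the files one simulation emits."""

    proteins: Path
    hits: Path
    topology: Path
    genomes: Path
    operons: Path
    manifest: Path
    manifest_hits: Path


@dataclass
class SurveyTruth:
    """Planted ground truth of one simulated survey."""

    metacaspase_ids: frozenset[str]
    canonical: dict[str, str]
    dyad_status: dict[str, str]
    signal_peptide: dict[str, bool]
    genome_counts: dict[str, int]
    proteome_sizes: dict[str, int]
    groups: dict[str, str]
    operon_of: dict[str, str]
    covered_genomes: frozenset[str]
    hits: list[dict]
    n_positive_genomes: int

    def expected_operon_summary(self) -> dict[str, int]:
        per_operon: dict[str, int] = {}
        for op in self.operon_of.values():
            per_operon[op] = per_operon.get(op, 0) + 1
        return {
            "n_in_operons": len(self.operon_of),
            "n_operons_with_metacaspase": len(per_operon),
            "n_multi_metacaspase_operons": sum(1 for v in per_operon.values() if v >= 2),
            "max_metacaspases_per_operon": max(per_operon.values(), default=0),
        }

    def expected_abundance(self) -> dict[str, tuple[int, float]]:
        return {
            gid: (n, 1000.0 * n / self.proteome_sizes[gid])
            for gid, n in self.genome_counts.items()
        }


class _ProteinBuilder:
    """Accumulates residue runs and records planted segment coordinates."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.parts: list[str] = []
        self.length = 0

    def random_run(self, n: int) -> None:
        self.parts.append("".join(self.rng.choice(_AA, size=n)))
        self.length += n

    def literal_run(self, seq: str) -> tuple[int, int]:
        start = self.length + 1
        self.parts.append(seq)
        self.length += len(seq)
        return start, self.length

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def _mutated_reference(
    rng: np.random.Generator, ref: DyadReference, negative: bool
) -> tuple[str, str]:
    """A copy of the reference domain with background noise and a dyad fate."""
    seq = np.array(list(ref.reference_sequence))
    catalytic = {ref.cys_pos - 1, ref.his_pos - 1}
    mask = rng.random(len(seq)) < 0.04
    for i in np.flatnonzero(mask):
        if i in catalytic:
            continue
        choices = _AA[_AA != seq[i]]
        seq[i] = rng.choice(choices)
    status = "Positive"
    if negative:
        status = "Negative"
        if rng.random() < 0.5:
            seq[ref.cys_pos - 1] = "S"
        else:
            seq[ref.his_pos - 1] = "Y"
    return "".join(seq), status


def _passing_scores(rng: np.random.Generator) -> tuple[float, float, float]:
    i_evalue = float(10.0 ** rng.uniform(-40, -3))
    score = float(np.round(rng.uniform(60, 300), 1))
    bias = 0.0 if rng.random() < 0.3 else float(np.round(rng.uniform(0.01, score / 20), 2))
    return i_evalue, score, bias


def _topology_for(
    rng: np.random.Generator, pid: str, helices: list[tuple[int, int]], length: int
) -> list[TopologySegment]:
    if not helices:
        kind = "inside" if rng.random() < 0.5 else "outside"
        return [TopologySegment(pid, kind, 1, length)]
    helices = sorted(helices)
    loop = "inside" if rng.random() < 0.5 else "outside"
    segs: list[TopologySegment] = []
    pos = 1
    for start, end in helices:
        segs.append(TopologySegment(pid, loop, pos, start - 1))
        segs.append(TopologySegment(pid, "helix", start, end))
        loop = "outside" if loop == "inside" else "inside"
        pos = end + 1
    segs.append(TopologySegment(pid, loop, pos, length))
    return segs


def simulate_survey(
    cfg: SimulationConfig, outdir: str | Path
) -> tuple[SurveyFiles, SurveyTruth]:
    """Generate one complete synthetic survey under ``cfg`` into ``outdir``.

    Emits proteins.fasta, hits.tsv, topology.tsv, genomes.tsv, operons.tsv
    plus the truth manifests, and returns the file paths with the
    :class:`SurveyTruth`.  Only survey-relevant proteins (metacaspases, decoy
    targets, operon neighbors) are written to FASTA; the genome table's
    ``protein_count`` carries the full nominal proteome size used for
    abundance normalization.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = load_default_reference()
    groups = [f"group_{i + 1:02d}" for i in range(cfg.n_groups)]

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    segments: list[TopologySegment] = []
    genome_rows: list[GenomeRecord] = []
    operon_rows: list[OperonRecord] = []

    truth = SurveyTruth(
        metacaspase_ids=frozenset(),
        canonical={},
        dyad_status={},
        signal_peptide={},
        genome_counts={},
        proteome_sizes={},
        groups={},
        operon_of={},
        covered_genomes=frozenset(),
        hits=[],
        n_positive_genomes=0,
    )
    mc_ids: set[str] = set()
    covered: set[str] = set()

    for gi in range(cfg.n_genomes):
        rng = np.random.default_rng([cfg.seed, gi])
        gid = f"g{gi:04d}"
        group = groups[int(rng.integers(cfg.n_groups))]
        superkingdom = (
            "Archaea" if (cfg.n_groups > 1 and group == groups[-1]) else "Bacteria"
        )
        proteome = int(rng.integers(*cfg.proteome_size_range, endpoint=True))
        genome_rows.append(
            GenomeRecord(gid, f"Synthetic organism {gi}", group, superkingdom, proteome)
        )
        truth.groups[gid] = group
        truth.proteome_sizes[gid] = proteome
        truth.genome_counts[gid] = 0

        positive = rng.random() < cfg.p_positive_genome
        genome_mc: list[str] = []
        if positive:
            truth.n_positive_genomes += 1
            copies = min(
                int(rng.geometric(1.0 / cfg.copy_number_mean)), cfg.max_copies
            )
            truth.genome_counts[gid] = copies
            weights = [e.weight for e in cfg.architecture_palette]
            for ci in range(copies):
                pid = f"{gid}_mc{ci}"
                entry = cfg.architecture_palette[
                    int(rng.choice(len(cfg.architecture_palette), p=weights))
                ]
                record, copy_hits, copy_segments, dyad_status, sp_flag = _realize_entry(
                    rng, pid, gid, entry, ref, cfg.dyad_negative_rate(group)
                )
                proteins.append(record)
                hits.extend(h for h, _ in copy_hits)
                truth.hits.extend(
                    {
                        "protein_id": h.protein_id,
                        "domain_name": h.domain_name,
                        "env_from": h.env_from,
                        "env_to": h.env_to,
                        "passes_screen": True,
                        "survives_conflict": survives,
                    }
                    for h, survives in copy_hits
                )
                segments.extend(copy_segments)
                mc_ids.add(pid)
                genome_mc.append(pid)
                truth.canonical[pid] = entry.key
                truth.dyad_status[pid] = dyad_status
                truth.signal_peptide[pid] = sp_flag

        # decoy hits: violate at least one acceptance threshold
        for di in range(int(rng.poisson(cfg.decoy_hit_rate))):
            pid = f"{gid}_dx{di}"
            plen = int(rng.integers(150, 401))
            builder = _ProteinBuilder(rng)
            builder.random_run(plen)
            proteins.append(ProteinRecord(pid, gid, builder.sequence))
            domain = _DECOY_DOMAINS[int(rng.integers(len(_DECOY_DOMAINS)))]
            model_length = DOMAIN_MODEL_LENGTHS[domain]
            env_len = int(rng.integers(80, min(200, plen - 1) + 1))
            env_from = int(rng.integers(1, plen - env_len + 2))
            mode = int(rng.integers(3))  # 0 bad E, 1 bad ratio, 2 both
            score = float(np.round(rng.uniform(10, 60), 1))
            if mode in (0, 2):
                i_evalue = float(10.0 ** rng.uniform(math.log10(0.02), 1.0))
            else:
                i_evalue = float(10.0 ** rng.uniform(-40, -3))
            if mode in (1, 2):
                bias = float(np.round(score / rng.uniform(2, 9), 2))
            else:
                bias = 0.0 if rng.random() < 0.5 else float(np.round(score / 50, 2))
            hit = DomainHit(
                pid, domain, model_length, 1, model_length,
                env_from, env_from + env_len - 1, i_evalue, score, bias,
            )
            hits.append(hit)
            truth.hits.append(
                {
                    "protein_id": pid,
                    "domain_name": domain,
                    "env_from": hit.env_from,
                    "env_to": hit.env_to,
                    "passes_screen": False,
                    "survives_conflict": False,
                }
            )
            segments.extend(_topology_for(rng, pid, [], plen))

        # operons
        if genome_mc and rng.random() < cfg.operon_db_coverage:
            covered.add(gid)
            in_operon = [p for p in genome_mc if rng.random() < cfg.p_in_operon]
            operon_groups: list[list[str]] = []
            for p in in_operon:
                if (
                    operon_groups
                    and len(operon_groups[-1]) < 3
                    and rng.random() < cfg.p_operon_comembership
                ):
                    operon_groups[-1].append(p)
                else:
                    operon_groups.append([p])
            nb_counter = 0
            for oi, members in enumerate(operon_groups):
                op_id = f"{gid}_op{oi}"
                neighbors: list[str] = []
                for _ in range(int(rng.integers(1, 5))):
                    nb_id = f"{gid}_nb{nb_counter}"
                    nb_counter += 1
                    plen = int(rng.integers(150, 401))
                    b = _ProteinBuilder(rng)
                    b.random_run(plen)
                    proteins.append(ProteinRecord(nb_id, gid, b.sequence))
                    segments.extend(_topology_for(rng, nb_id, [], plen))
                    if rng.random() < 0.5:
                        domain = _NEIGHBOR_DOMAINS[int(rng.integers(len(_NEIGHBOR_DOMAINS)))]
                        model_length = DOMAIN_MODEL_LENGTHS[domain]
                        env_len = min(model_length, plen - 10)
                        env_from = int(rng.integers(1, plen - env_len + 2))
                        i_evalue, score, bias = _passing_scores(rng)
                        hit = DomainHit(
                            nb_id, domain, model_length, 1, model_length,
                            env_from, env_from + env_len - 1, i_evalue, score, bias,
                        )
                        hits.append(hit)
                        truth.hits.append(
                            {
                                "protein_id": nb_id,
                                "domain_name": domain,
                                "env_from": hit.env_from,
                                "env_to": hit.env_to,
                                "passes_screen": True,
                                "survives_conflict": True,
                            }
                        )
                    neighbors.append(nb_id)
                k = int(rng.integers(0, len(neighbors) + 1))
                gene_ids = tuple(neighbors[:k]) + tuple(members) + tuple(neighbors[k:])
                strand = "+" if rng.random() < 0.5 else "-"
                operon_rows.append(
                    OperonRecord(op_id, gid, gene_ids, strand, 1000 * oi + 1, 1000 * oi + 900)
                )
                for p in members:
                    truth.operon_of[p] = op_id

    truth.metacaspase_ids = frozenset(mc_ids)
    truth.covered_genomes = frozenset(covered)

    files = SurveyFiles(
        proteins=outdir / "proteins.fasta",
        hits=outdir / "hits.tsv",
        topology=outdir / "topology.tsv",
        genomes=outdir / "genomes.tsv",
        operons=outdir / "operons.tsv",
        manifest=outdir / "manifest.tsv",
        manifest_hits=outdir / "manifest_hits.tsv",
    )
    write_sequences(proteins, files.proteins)
    write_domain_hits(hits, files.hits)
    write_topology_segments(segments, files.topology)
    write_genome_table(genome_rows, files.genomes)
    write_operon_table(operon_rows, files.operons)
    _write_manifests(files, truth)
    return files, truth


def _realize_entry(
    rng: np.random.Generator,
    pid: str,
    gid: str,
    entry: PaletteEntry,
    ref: DyadReference,
    p_dyad_negative: float,
) -> tuple[ProteinRecord, list[tuple[DomainHit, bool]], list[TopologySegment], str, bool]:
    """Build one metacaspase protein realizing a palette entry.

    Returns the protein, its (hit, survives_conflict) pairs, its topology
    segments, the planted dyad status, and the signal-peptide truth flag.
    """
    builder = _ProteinBuilder(rng)
    copy_hits: list[tuple[DomainHit, bool]] = []
    helices: list[tuple[int, int]] = []
    dyad_status = "Positive"

    first_is_tmh = entry.elements[0].kind == "tmh"
    builder.random_run(int(rng.integers(5, 9)) if first_is_tmh else int(rng.integers(10, 41)))

    for ei, el in enumerate(entry.elements):
        if el.kind == "tmh":
            seq = "".join(rng.choice(_AA, size=el.length or _HELIX_LENGTH))
            start, end = builder.literal_run(seq)
            helices.append((start, end))
        else:
            repeat_spans: list[tuple[int, int]] = []
            repeat_evalues: list[float] = []
            for ri in range(el.repeats):
                if ri > 0:
                    builder.random_run(int(rng.integers(6, 13)))
                if el.label == METACASPASE_DOMAIN:
                    seq, dyad_status = _mutated_reference(
                        rng, ref, rng.random() < p_dyad_negative
                    )
                else:
                    seq = "".join(rng.choice(_AA, size=el.length))
                start, end = builder.literal_run(seq)
                repeat_spans.append((start, end))
                i_evalue, score, bias = _passing_scores(rng)
                model_length = DOMAIN_MODEL_LENGTHS[el.label]
                if el.label == METACASPASE_DOMAIN and rng.random() < 0.3:
                    hmm_to = int(rng.integers(160, model_length + 1))
                else:
                    hmm_to = model_length
                copy_hits.append(
                    (
                        DomainHit(
                            pid, el.label, model_length, 1, hmm_to,
                            start, end, i_evalue, score, bias,
                        ),
                        True,
                    )
                )
                repeat_evalues.append(i_evalue)
            if el.shadow is not None:
                # an overlapping worse-E hit that conflict resolution must drop
                s_start, s_end = repeat_spans[0]
                shadow_len = DOMAIN_MODEL_LENGTHS[el.shadow]
                env_from = s_start + 10
                env_to = env_from + min(shadow_len, (s_end - s_start + 1)) - 1
                shadow_e = 5.0 * max(repeat_evalues)
                _, score, bias = _passing_scores(rng)
                copy_hits.append(
                    (
                        DomainHit(
                            pid, el.shadow, shadow_len, 1, shadow_len,
                            env_from, env_to, shadow_e, score, bias,
                        ),
                        False,
                    )
                )
            if el.overlap_helices:
                # predicted helices inside the domain envelope: dropped by precedence
                s_start, _ = repeat_spans[0]
                for hi in range(el.overlap_helices):
                    h_start = s_start + 20 + 60 * hi
                    helices.append((h_start, h_start + _HELIX_LENGTH - 1))
        if ei < len(entry.elements) - 1:
            builder.random_run(int(rng.integers(5, 26)))
    builder.random_run(int(rng.integers(5, 31)))

    n_retained_first = (
        first_is_tmh and helices and helices[0][0] <= 30 and len(helices) == 1
    )
    record = ProteinRecord(pid, gid, builder.sequence)
    topo = _topology_for(rng, pid, helices, builder.length)
    return record, copy_hits, topo, dyad_status, bool(n_retained_first)


def _write_manifests(files: SurveyFiles, truth: SurveyTruth) -> None:
    with open(files.manifest, "w") as fh:
        fh.write(
            "protein_id\tgenome_id\tgroup\tcanonical\tdyad_status\t"
            "signal_peptide\toperon_id\n"
        )
        for pid in sorted(truth.metacaspase_ids):
            gid = pid.split("_")[0]
            fh.write(
                f"{pid}\t{gid}\t{truth.groups[gid]}\t{truth.canonical[pid]}\t"
                f"{truth.dyad_status[pid]}\t{truth.signal_peptide[pid]}\t"
                f"{truth.operon_of.get(pid, '')}\n"
            )
    with open(files.manifest_hits, "w") as fh:
        fh.write(
            "protein_id\tdomain_name\tenv_from\tenv_to\tpasses_screen\t"
            "survives_conflict\n"
        )
        for row in truth.hits:
            fh.write(
                f"{row['protein_id']}\t{row['domain_name']}\t{row['env_from']}\t"
                f"{row['env_to']}\t{row['passes_screen']}\t{row['survives_conflict']}\n"
            )


def end_to_end_recovery(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Simulate a survey, run the full pipeline on its files, compare to truth.

    Reports exact-match rates for the five recovery surfaces: metacaspase
    identification, canonical architectures, dyad statuses, the operon
    summary, and the per-genome abundance table.
    """
    from .pipeline import PipelineConfig, SurveyInputs, run_survey

    files, truth = simulate_survey(cfg, outdir)
    if not Path(files.proteins).stat().st_size:
        return {"n_proteins": 0, "rates": {}, "all_exact": True}
    result = run_survey(
        SurveyInputs(
            proteins=files.proteins,
            hits=files.hits,
            topology=files.topology,
            genomes=files.genomes,
            operons=files.operons,
        ),
        PipelineConfig(),
        seed=cfg.seed,
    )
    rates: dict[str, float] = {}

    found = set(result.metacaspase_ids)
    planted = set(truth.metacaspase_ids)
    union = found | planted
    rates["identification"] = (
        1.0 if not union else len(found & planted) / len(union)
    )

    if planted:
        rates["architecture"] = sum(
            1
            for pid in planted
            if pid in result.architectures
            and result.architectures[pid].canonical == truth.canonical[pid]
        ) / len(planted)
        rates["dyad"] = sum(
            1
            for pid in planted
            if pid in result.dyad_results
            and result.dyad_results[pid].status == truth.dyad_status[pid]
        ) / len(planted)
    else:
        rates["architecture"] = 1.0
        rates["dyad"] = 1.0

    expected = truth.expected_operon_summary()
    got = {
        "n_in_operons": result.operon_summary.n_in_operons,
        "n_operons_with_metacaspase": result.operon_summary.n_operons_with_metacaspase,
        "n_multi_metacaspase_operons": result.operon_summary.n_multi_metacaspase_operons,
        "max_metacaspases_per_operon": result.operon_summary.max_metacaspases_per_operon,
    }
    rates["operon_summary"] = sum(
        1 for k in expected if expected[k] == got[k]
    ) / len(expected)

    expected_ab = truth.expected_abundance()
    got_ab = {r.genome_id: r for r in result.abundance_records}
    matches = sum(
        1
        for gid, (count, ab) in expected_ab.items()
        if gid in got_ab
        and got_ab[gid].metacaspase_count == count
        and abs(got_ab[gid].abundance - ab) < 1e-9
    )
    rates["abundance"] = matches / len(expected_ab) if expected_ab else 1.0

    return {
        "n_proteins": len(result.architectures),
        "n_metacaspases_found": len(found),
        "n_metacaspases_planted": len(planted),
        "rates": rates,
        "all_exact": all(v == 1.0 for v in rates.values()),
    }
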