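"""End-to-end survey orchestration.

``run_survey`` composes the stages in pipeline order — screen hits, resolve
per-protein domain architectures with membrane topology, assess catalytic-dyad
conservation, assign functions and localization, map operon context, and
aggregate taxonomic abundance — and emits per-stage TSVs plus a JSON report.
Every number in the report is recomputable from the stage outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .annotate import classify_localization, annotate_functions, molecular_weight
from .architecture import (
    METACASPASE_DOMAIN,
    Architecture,
    OverlapRule,
    architecture_census,
    assemble_protein,
    domain_prevalence,
)
from .curation import extract_envelopes
from .dyad import DyadReference, classify_dyad, load_default_reference, load_reference, substitution_profile
from .errors import ConfigError, ValidationError
from .io_formats import (
    DEFAULT_HEADER_REGEX,
    read_domain_hits,
    read_sequences,
    read_tables,
    read_topology_segments,
    validate_proteins_against_genomes,
)
from .operons import annotate_operon_neighbors, map_to_operons
from .screen import ScreenConfig, hmm_coverage, is_low_coverage, screen_hits
from .stats import (
    DEFAULT_ABUNDANCE_BINS,
    carrier_split,
    genome_abundance,
    group_summary,
    survey_percentages,
)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters with their survey defaults."""

    max_i_evalue: float = 0.01
    min_score_bias_ratio: float = 10.0
    low_coverage_threshold: float = 0.60
    conflict_fraction: float = 0.25
    identity_threshold: float = 0.90
    metacaspase_label: str = METACASPASE_DOMAIN
    include_orientation: bool = False
    abundance_bins: tuple[float, ...] = DEFAULT_ABUNDANCE_BINS
    pooled_group_mean: bool = False
    header_regex: str = DEFAULT_HEADER_REGEX
    reference_path: str | None = None
    cys_pos: int | None = None
    his_pos: int | None = None
    allow_ambiguous_mw: bool = True

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            max_i_evalue=self.max_i_evalue,
            min_score_bias_ratio=self.min_score_bias_ratio,
            low_coverage_threshold=self.low_coverage_threshold,
        )

    def overlap_rule(self) -> OverlapRule:
        return OverlapRule(conflict_fraction=self.conflict_fraction)

    def reference(self) -> DyadReference:
        if self.reference_path is None:
            return load_default_reference()
        return load_reference(self.reference_path, self.cys_pos, self.his_pos)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(source: str | Path | Mapping[str, Any] | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or mapping.

    Missing keys take the survey defaults; unknown keys and out-of-range
    thresholds raise :class:`~mcsurvey.errors.ConfigError`.
    """
    if source is None:
        data: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{source}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "abundance_bins" in data:
        data["abundance_bins"] = tuple(float(x) for x in data["abundance_bins"])
    try:
        cfg = PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    for key, lo, hi in (
        ("max_i_evalue", 0.0, None),
        ("min_score_bias_ratio", 0.0, None),
        ("low_coverage_threshold", 0.0, 1.0),
        ("conflict_fraction", 0.0, 1.0),
        ("identity_threshold", 0.0, 1.0),
    ):
        value = getattr(cfg, key)
        if value <= lo or (hi is not None and value > hi):
            raise ConfigError(f"config {key}={value} out of range")
    if sorted(cfg.abundance_bins) != list(cfg.abundance_bins) or any(
        b <= 0 for b in cfg.abundance_bins
    ):
        raise ConfigError("abundance_bins must be positive and increasing")
    return cfg


@dataclass(frozen=True)
class SurveyInputs:
    """Paths of the five survey input files (annotations optional)."""

    proteins: str | Path
    hits: str | Path
    topology: str | Path | None
    genomes: str | Path
    operons: str | Path | None = None
    annotations: str | Path | None = None


@dataclass
class SurveyResult:
    """All in-memory artifacts of one survey run plus the summary report."""

    architectures: dict[str, Architecture]
    metacaspase_ids: list[str]
    dyad_results: dict
    functions: dict[str, set[str]]
    localizations: dict[str, str]
    molecular_weights: dict[str, float]
    abundance_records: list
    group_table: pd.DataFrame
    census: pd.DataFrame
    prevalence: pd.DataFrame
    operon_membership: pd.DataFrame
    operon_summary: Any
    operon_functions: pd.DataFrame
    report: dict


def run_survey(
    inputs: SurveyInputs,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> SurveyResult:
    """Run the full survey pipeline on the input files.

    Stage order: read/validate -> screen -> architect -> dyad -> annotate ->
    operons -> stats.  With ``outdir`` set, stage TSVs (with a provenance
    header) and ``report.json`` are written there.  Identical inputs and
    config give bit-identical outputs.
    """
    cfg = cfg or PipelineConfig()
    proteins = read_sequences(inputs.proteins, cfg.header_regex)
    protein_map = {p.protein_id: p for p in proteins}
    hits = read_domain_hits(inputs.hits)
    segments = read_topology_segments(inputs.topology) if inputs.topology else []
    genomes, operons, annotations = read_tables(
        inputs.genomes, inputs.operons, inputs.annotations
    )
    validate_proteins_against_genomes(proteins, genomes)
    for h in hits:
        if h.protein_id not in protein_map:
            raise ValidationError(f"hit references unknown protein {h.protein_id!r}")
    for s in segments:
        if s.protein_id not in protein_map:
            raise ValidationError(
                f"topology references unknown protein {s.protein_id!r}"
            )
    annotation_map = {a.domain_name: a for a in annotations}
    reference = cfg.reference()

    # --- screen ---
    accepted, rejected = screen_hits(hits, cfg.screen_config())

    # --- architect (per protein) ---
    hits_by_protein: dict[str, list] = {}
    for h in accepted:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    segments_by_protein: dict[str, list] = {}
    for s in segments:
        segments_by_protein.setdefault(s.protein_id, []).append(s)
    architectures: dict[str, Architecture] = {}
    for pid, phits in hits_by_protein.items():
        architectures[pid] = assemble_protein(
            phits,
            segments_by_protein.get(pid, []),
            protein_id=pid,
            genome_id=protein_map[pid].genome_id,
            rule=cfg.overlap_rule(),
            metacaspase_label=cfg.metacaspase_label,
            include_orientation=cfg.include_orientation,
        )
    metacaspase_ids = sorted(
        pid for pid, arch in architectures.items() if arch.is_metacaspase
    )

    # --- dyad (best surviving metacaspase hit per protein) ---
    dyad_results = {}
    for pid in metacaspase_ids:
        mc_hits = [
            h for h in hits_by_protein[pid] if h.domain_name == cfg.metacaspase_label
        ]
        # restrict to hits that survived into the final architecture
        spans = {
            (el.start, el.end)
            for el in architectures[pid].elements
            if el.kind == "pfam"
        }
        surviving = [h for h in mc_hits if _hit_in_architecture(h, architectures[pid])]
        best = min(surviving or mc_hits, key=lambda h: (h.i_evalue, h.env_from))
        envelope = extract_envelopes([best], protein_map)[0]
        dyad_results[pid] = classify_dyad(envelope.sequence, reference, pid)

    # --- annotate ---
    functions = {
        pid: annotate_functions(architectures[pid], annotation_map, cfg.metacaspase_label)
        for pid in metacaspase_ids
    }
    localizations = {
        pid: classify_localization(architectures[pid], annotation_map).category
        for pid in metacaspase_ids
    }
    molecular_weights = {
        pid: molecular_weight(protein_map[pid].sequence, cfg.allow_ambiguous_mw)
        for pid in metacaspase_ids
    }

    # --- operons ---
    protein_genomes = {pid: protein_map[pid].genome_id for pid in metacaspase_ids}
    operon_membership, operon_summary = map_to_operons(
        metacaspase_ids, operons, protein_genomes
    )
    operon_functions = annotate_operon_neighbors(
        operons, metacaspase_ids, architectures, annotation_map, cfg.metacaspase_label
    )

    # --- stats ---
    mc_architectures = [architectures[pid] for pid in metacaspase_ids]
    abundance_records = genome_abundance(mc_architectures, genomes)
    group_table = group_summary(
        abundance_records, genomes, bins=cfg.abundance_bins, pooled=cfg.pooled_group_mean
    )
    census = architecture_census(mc_architectures, genomes)
    prevalence = domain_prevalence(mc_architectures)

    report = _build_report(
        cfg,
        seed,
        genomes,
        metacaspase_ids,
        architectures,
        dyad_results,
        protein_genomes,
        localizations,
        abundance_records,
        group_table,
        census,
        prevalence,
        operon_summary,
        operon_functions,
        accepted,
        rejected,
    )

    result = SurveyResult(
        architectures=architectures,
        metacaspase_ids=metacaspase_ids,
        dyad_results=dyad_results,
        functions=functions,
        localizations=localizations,
        molecular_weights=molecular_weights,
        abundance_records=abundance_records,
        group_table=group_table,
        census=census,
        prevalence=prevalence,
        operon_membership=operon_membership,
        operon_summary=operon_summary,
        operon_functions=operon_functions,
        report=report,
    )
    if outdir is not None:
        _write_outputs(result, accepted, rejected, Path(outdir), cfg, seed)
    return result


def _hit_in_architecture(hit, architecture: Architecture) -> bool:
    for el in architecture.elements:
        if el.kind == "pfam" and el.label == hit.domain_name:
            if el.start <= hit.env_from and hit.env_to <= el.end:
                return True
    return False


def _build_report(
    cfg,
    seed,
    genomes,
    metacaspase_ids,
    architectures,
    dyad_results,
    protein_genomes,
    localizations,
    abundance_records,
    group_table,
    census,
    prevalence,
    operon_summary,
    operon_functions,
    accepted,
    rejected,
) -> dict:
    group_of = {g.genome_id: g.group for g in genomes}
    carriers = carrier_split([r for r in abundance_records if r.metacaspase_count > 0])
    n_genomes = len(genomes)
    dyad_profile = substitution_profile(
        list(dyad_results.values()),
        {pid: group_of[protein_genomes[pid]] for pid in dyad_results},
    )
    n_positive = sum(1 for r in dyad_results.values() if r.status == "Positive")
    loc_counts: dict[str, int] = {}
    for cat in localizations.values():
        loc_counts[cat] = loc_counts.get(cat, 0) + 1
    report = {
        "provenance": {
            "tool": "mcsurvey",
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": seed,
        },
        "totals": {
            "n_genomes": n_genomes,
            "n_metacaspases": len(metacaspase_ids),
            "n_metacaspase_genomes": carriers["carriers"],
            "pct_metacaspase_genomes": survey_percentages(
                carriers["carriers"], n_genomes, 0
            )
            if n_genomes
            else 0.0,
            "single_copy_carriers": carriers["single_copy"],
            "multi_copy_carriers": carriers["multi_copy"],
            "n_hits_accepted": len(accepted),
            "n_hits_rejected": len(rejected),
        },
        "architectures": {
            "n_unique": int(len(census)),
            "n_group_unique": int(census["group_unique"].sum()) if len(census) else 0,
            "census": census.to_dict(orient="records"),
            "domain_prevalence": prevalence.to_dict(orient="records"),
        },
        "dyad": {
            "n_positive": n_positive,
            "fraction_positive": (n_positive / len(dyad_results)) if dyad_results else 0.0,
            "per_group": dyad_profile["per_group"].to_dict(orient="records"),
            "cys_substitutions": {
                k: {"count": c, "fraction": f}
                for k, (c, f) in dyad_profile["cys_substitutions"].items()
            },
            "his_substitutions": {
                k: {"count": c, "fraction": f}
                for k, (c, f) in dyad_profile["his_substitutions"].items()
            },
        },
        "localization": loc_counts,
        "operons": {
            "n_covered_genomes": operon_summary.n_covered_genomes,
            "n_metacaspases_covered": operon_summary.n_metacaspases_covered,
            "n_in_operons": operon_summary.n_in_operons,
            "pct_in_operons": survey_percentages(
                operon_summary.n_in_operons,
                operon_summary.n_metacaspases_covered,
                1,
            )
            if operon_summary.n_metacaspases_covered
            else 0.0,
            "n_operons_with_metacaspase": operon_summary.n_operons_with_metacaspase,
            "n_multi_metacaspase_operons": operon_summary.n_multi_metacaspase_operons,
            "max_metacaspases_per_operon": operon_summary.max_metacaspases_per_operon,
            "n_operons_unknown_function": int(
                (operon_functions["functions"] == "unknown").sum()
            )
            if len(operon_functions)
            else 0,
        },
        "abundance": {
            "per_group": group_table.to_dict(orient="records"),
        },
    }
    return report


def _provenance_line(cfg: PipelineConfig, seed) -> str:
    return (
        f"# mcsurvey v{__version__} config={cfg.config_hash()} "
        f"seed={'-' if seed is None else seed}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, seed) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(cfg, seed))
        df.to_csv(fh, sep="\t", index=False)


def _write_outputs(
    result: SurveyResult, accepted, rejected, outdir: Path, cfg: PipelineConfig, seed
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_id": h.protein_id,
                    "domain_name": h.domain_name,
                    "i_evalue": h.i_evalue,
                    "score": h.score,
                    "bias": h.bias,
                    "hmm_coverage": hmm_coverage(h),
                    "low_coverage": is_low_coverage(h, cfg.screen_config()),
                }
                for h in accepted
            ]
        ),
        outdir / "accepted_hits.tsv",
        cfg,
        seed,
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_id": r.hit.protein_id,
                    "domain_name": r.hit.domain_name,
                    "reason": r.reason,
                }
                for r in rejected
            ]
        ),
        outdir / "rejected_hits.tsv",
        cfg,
        seed,
    )
    arch_rows = []
    for pid in sorted(result.architectures):
        arch = result.architectures[pid]
        arch_rows.append(
            {
                "protein_id": pid,
                "genome_id": arch.genome_id,
                "canonical": arch.canonical,
                "is_metacaspase": arch.is_metacaspase,
                "elements": ";".join(
                    f"{el.label}:{el.start}-{el.end}x{el.repeat_count}"
                    + (f"({el.orientation})" if el.orientation else "")
                    + ("[SP]" if el.signal_peptide_flag else "")
                    for el in arch.elements
                ),
            }
        )
    _write_tsv(pd.DataFrame(arch_rows), outdir / "architectures.tsv", cfg, seed)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_id": pid,
                    "status": r.status,
                    "residue_at_cys": r.residue_at_cys,
                    "residue_at_his": r.residue_at_his,
                    "low_confidence": r.low_confidence,
                }
                for pid, r in sorted(result.dyad_results.items())
            ]
        ),
        outdir / "dyad.tsv",
        cfg,
        seed,
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_id": pid,
                    "functions": ";".join(sorted(result.functions[pid])),
                    "localization": result.localizations[pid],
                    "molecular_weight_da": round(result.molecular_weights[pid], 2),
                }
                for pid in result.metacaspase_ids
            ]
        ),
        outdir / "annotations.tsv",
        cfg,
        seed,
    )
    _write_tsv(result.operon_membership, outdir / "operon_membership.tsv", cfg, seed)
    _write_tsv(result.operon_functions, outdir / "operon_functions.tsv", cfg, seed)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "genome_id": r.genome_id,
                    "metacaspase_count": r.metacaspase_count,
                    "abundance_per_1000": r.abundance,
                }
                for r in result.abundance_records
            ]
        ),
        outdir / "abundance.tsv",
        cfg,
        seed,
    )
    _write_tsv(result.group_table, outdir / "group_summary.tsv", cfg, seed)
    _write_tsv(result.census, outdir / "architecture_census.tsv", cfg, seed)
    _write_tsv(result.prevalence, outdir / "domain_prevalence.tsv", cfg, seed)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
        fh.write("\n")


def report_from_outputs(outdir: str | Path) -> dict:
    """Recompute the headline totals from a run's stage output TSVs.

    Demonstrates that the report holds no state of its own: genomes carrying
    metacaspases, carrier split and dyad conservation are re-derived from
    ``architectures.tsv``, ``abundance.tsv`` and ``dyad.tsv``.
    """
    outdir = Path(outdir)
    arch = pd.read_csv(outdir / "architectures.tsv", sep="\t", comment="#")
    abundance = pd.read_csv(outdir / "abundance.tsv", sep="\t", comment="#")
    dyad = pd.read_csv(outdir / "dyad.tsv", sep="\t", comment="#")
    carriers = abundance[abundance["metacaspase_count"] > 0]
    n_mc = int(arch["is_metacaspase"].sum()) if len(arch) else 0
    return {
        "n_metacaspases": n_mc,
        "n_metacaspase_genomes": int(len(carriers)),
        "single_copy_carriers": int((carriers["metacaspase_count"] == 1).sum()),
        "multi_copy_carriers": int((carriers["metacaspase_count"] >= 2).sum()),
        "n_dyad_positive": int((dyad["status"] == "Positive").sum()) if len(dyad) else 0,
    }
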