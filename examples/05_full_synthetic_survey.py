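"""Run the complete survey pipeline on a simulated 200-genome dataset.

Generates a synthetic survey (18% metacaspase-positive genomes, geometric
copy numbers, an architecture palette with planted overlap conflicts, 16%
substituted dyads, decoy hits, operon co-membership), runs the full pipeline
on the emitted files, and checks every planted truth is recovered exactly.
"""

import json
import tempfile
from pathlib import Path

from mcsurvey import (
    PipelineConfig,
    SimulationConfig,
    SurveyInputs,
    end_to_end_recovery,
    run_survey,
    simulate_survey,
)

workdir = Path(tempfile.mkdtemp(prefix="mcsurvey_demo_"))
cfg = SimulationConfig(seed=7, n_genomes=200)
files, truth = simulate_survey(cfg, workdir)
print(f"simulated {cfg.n_genomes} genomes -> {len(truth.metacaspase_ids)} planted "
      f"metacaspases in {truth.n_positive_genomes} genomes")

result = run_survey(
    SurveyInputs(
        proteins=files.proteins, hits=files.hits, topology=files.topology,
        genomes=files.genomes, operons=files.operons,
    ),
    PipelineConfig(),
    outdir=workdir / "out",
    seed=cfg.seed,
)
totals = result.report["totals"]
print(f"pipeline found {totals['n_metacaspases']} metacaspases in "
      f"{totals['n_metacaspase_genomes']} genomes "
      f"({totals['pct_metacaspase_genomes']:g}% of the survey); "
      f"{totals['single_copy_carriers']} single-copy vs "
      f"{totals['multi_copy_carriers']} multi-copy carriers")
print(f"dyad conserved in {result.report['dyad']['n_positive']} "
      f"({100 * result.report['dyad']['fraction_positive']:.1f}%)")
print(f"{result.report['architectures']['n_unique']} unique architecture types; "
      f"operon stats: {json.dumps(result.report['operons'])}")

recovery = end_to_end_recovery(cfg, workdir / "recheck")
print("planted-truth recovery rates:", recovery["rates"])

# With the default palette every decoy fails screening and every conflict is
# unambiguous, so all five recovery rates are exactly 1.0; stage TSVs and
# report.json are under the printed working directory.
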