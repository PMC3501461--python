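# Methods

This note documents the decision rules, parameters, numerical choices and
limitations of the `mcsurvey` pipeline. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Survey model

The pipeline models a genome survey for one protein family — prokaryotic
metacaspases, i.e. Peptidase C14-type cysteine proteases with a catalytic
cysteine–histidine dyad — driven entirely by precomputed evidence: profile-HMM
per-domain hits (HMMER-style), membrane-topology segments (TMHMM-style), and
operon predictions. The pipeline never runs the external predictors; it
re-implements the decision rules applied to their output. All residue and
model coordinates are 1-based inclusive, following the HMMER/TMHMM
convention.

## Hit screening

A hit is accepted iff

- domain independent E-value *i*-E ≤ `max_i_evalue` (default **0.01**), and
- score/bias ratio ≥ `min_score_bias_ratio` (default **10**).

Both thresholds are inclusive. A bias of exactly 0 makes the ratio +∞ and
passes the ratio test: rejecting strong hits for having *no* composition
bias would invert the filter's intent. Screening is total (accepted ∪
rejected = input), idempotent, and monotone in both thresholds.

Profile coverage is (hmm_to − hmm_from + 1) / model_length, with the model's
match-state count as denominator. Coverage below `low_coverage_threshold`
(default **0.60**) flags a hit as a possible partial/false positive but never
removes it — low-coverage sequences remain in the survey, flagged for the
reader.

## Architecture resolution

Two domain envelopes *conflict* when their overlap exceeds
`conflict_fraction` (default **0.25**) of the length of **either** envelope,
i.e. overlap > 0.25 × min(len_A, len_B). The alternative reading ("of both")
would almost never trigger and would contradict the intended behavior of a
short domain nested in a long one. Resolution is greedy by ascending
E-value; ties break by longer envelope, then domain name, then position —
a strict total order, which makes the survivor set invariant under input
permutation and equal to the fixed point of pairwise "lower E-value wins"
elimination. Exactly 25% overlap is tolerated.

Transmembrane helices join the architecture afterwards: any helix sharing at
least one residue with a surviving domain is dropped (domain precedence; no
fraction is defined for this case, so any overlap counts). Retained helices
get an orientation from their flanking loop segments — inside before and
outside after is `iTMHo`, the reverse `oTMHi` — and a retained helix starting
at residue ≤ 30 that is the protein's only predicted helix is flagged as a
putative signal peptide. The flag is advisory only; nothing is removed.

Maximal runs of consecutive identical labels collapse into one element with
a repeat count. The canonical architecture key joins element labels N→C with
`|`, ignoring repeat counts; by default it ignores helix orientation too
(`TMH`), since orientation-aware keys would split otherwise identical
architectures — a config switch (`include_orientation`) enables the finer
key. A protein is a metacaspase iff the metacaspase domain label (default
`Bac_PepC14`) survives into its final architecture; a protein whose
metacaspase hit loses a conflict is excluded from the survey.

## Dyad assessment

Each metacaspase envelope is aligned to a single annotated reference domain
by global Needleman–Wunsch alignment: BLOSUM62 substitution scores, linear
gap penalty **8** per gap residue, deterministic traceback preferring
diagonal, then up, then left. A pairwise reference-anchored alignment
replaces a multiple alignment because the only information consumed is the
identity of two columns; it is deterministic and dependency-free. The
envelope residues aligned to the reference's Cys and His positions decide
the call: `Positive` iff they are C and H; a substitution or a gap
(substitution by deletion) is `Negative`. When *both* catalytic columns are
deletions — e.g. a terminal fragment that never reaches them — the call is
additionally flagged low-confidence, because the alignment carries no signal
at either position.

With a linear gap penalty, global alignments of a short fragment to a long
reference have many co-optimal variants; the tie-break picks one
deterministically, but column-position-sensitive quantities (e.g. "which
reference column does envelope residue *k* occupy") are not meaningful for
heavily gapped alignments. The dyad call only reads two columns and is
robust to this; the curation report (below) therefore measures occupancy,
not positions.

The bundled reference (`data/synthetic_reference_domain.fasta`) is a
**synthetic** 252-residue metacaspase-like sequence with dyad positions
His 90 / Cys 150 (His N-terminal of Cys, as in caspase folds). It exists so
the pipeline, generator and tests are self-contained; real surveys must
supply a curated reference, and the dyad positions are mandatory
configuration because no universal positions exist within the family model.

## Profile-training-set curation

Mirrors the standard curation chain before `hmmbuild`: extract each hit's
envelope slice, discard envelopes whose dyad is not intact, cluster at
`identity_threshold` (default **0.90**) and keep the longest member of each
cluster. Clustering is greedy and incremental in cd-hit's style: sequences
are processed longest-first (ties by id) and join the first existing cluster
whose representative they match at ≥ threshold identity, where identity =
matched residues / length of the shorter sequence under the global aligner;
otherwise they found a new cluster, whose founder is by construction its
longest member and representative. Word-filter speedups are omitted — the
curation sets this pipeline handles are desk-scale. Manual alignment editing
is out of scope; a quality report (per-reference-column occupancy and each
envelope's unaligned-reference fraction) is emitted for human review
instead. Profile construction itself is external: the module emits the
curated representative FASTA ready for it.

## Function, localization, molecular weight

Function categories come from a domain-annotation table (the bundled one
covers ~30 domain types with a 12-category vocabulary: protein-protein
interaction, protein modification, NTPase, enzymatic, PCD-related, cell wall
binding, signaling, helicase, chaperone, protein-carbohydrate interaction,
proteolysis, unknown). A protein's functions are the union over its
auxiliary (non-metacaspase) domains; unannotated domains contribute
`unknown`, and a metacaspase-only protein is `unknown`. Annotation is
monotone: adding a domain never removes a label.

Localization assigns exactly one of five categories. Membrane evidence is
any retained helix or membrane-annotated domain; extracellular and
intracellular evidence comes from domain annotations. Membrane +
extracellular evidence → `Membrane and extracellular`; membrane only →
`Membrane`; extracellular only → `Extracellular`; intracellular only →
`Intracellular`; none → `Unknown`. The exact precedence between membrane and
extracellular evidence is not canonical anywhere; this rule is declared here
and configurable by supplying a different annotation table.

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da), computed via Biopython; the empty chain weighs one water, and
the ambiguity code X is rejected unless an average-residue-mass fallback is
explicitly enabled.

## Operon context

Operon predictions are consumed, never computed. Genomes absent from the
operon table are excluded from operon denominators, mirroring the reality
that prediction databases cover only part of any survey. Per
metacaspase-containing operon the pipeline reports the metacaspase count and
the union of neighbor function categories (neighbors without hits contribute
nothing; an operon with no informative neighbor is `unknown`). Conserved
operon configurations are grouped by identical ordered per-gene architecture
signatures; cross-genome homology search is out of scope.

## Abundance statistics

Per-genome abundance = 1000 × metacaspase count / proteome protein count.
Group summaries use the **unweighted mean** of per-genome abundances (a
pooled counts/proteins mode is available via config): the unweighted mean
answers "how metacaspase-rich is a typical genome of this group" and is not
dominated by the largest proteomes. Genome counts are histogrammed into
abundance bins {0}, (0, 0.5], (0.5, 1.0], > 1.0 by default; the edges are a
convention, not derivable from anything, and are fully configurable. Groups
with ≤ 5 genomes and zero metacaspases fold into an "Other" category (per
superkingdom when both are present). Percentages round half-away-from-zero
at 0 or 1 decimals.

## Synthetic survey generator

The generator emulates the statistical structure the analysis assumes, with
defaults fixed to the survey shape the pipeline targets:

- `p_positive_genome = 0.18` — fraction of genomes carrying metacaspases;
- copy number ~ zero-truncated geometric with mean **1.7**, so ~59% of
  carriers are single-copy; capped at 28 copies;
- proteome sizes uniform in **1500–8000** proteins (spanning typical
  finished prokaryotic proteomes);
- an eight-entry architecture palette (metacaspase-only 40%, N- or
  C-terminal helices, WD40 repeats with a planted overlapping decoy that
  must lose conflict resolution, FGE-sulfatase, polysaccharide
  deacetylase + TPR, NACHT + WD40, and a CHASE2 entry with helices planted
  inside the receptor domain that topology precedence must drop);
- `p_dyad_negative = 0.16` per domain (84% intact dyads), substitutions
  planted as the canonical C→S or H→Y; 4% background mutation elsewhere;
- decoy hits ~ Poisson(1) per genome, each violating at least one screening
  threshold (E-value in [0.02, 10], or bias drawn so the ratio falls below
  10, or both); planted positives draw E-values log-uniform in
  [1e-40, 1e-3];
- operon predictions cover 75% of carrier genomes; covered metacaspases
  enter operons with probability 0.5 and co-occupy one with probability 0.2
  (max 3 per operon), alongside 1–4 neighbor genes, half of which carry an
  annotatable domain hit.

Randomness uses one master seed with a per-genome `default_rng([seed, i])`
stream, so outputs are byte-identical across runs and partial regeneration
is stable. Sequences outside planted domains are i.i.d. uniform over the 20
residues — adequate because no pipeline stage models residue composition
beyond the two catalytic columns. The generator writes only survey-relevant
proteins to FASTA while the genome table carries nominal proteome sizes; it
is not a sequence-evolution simulator and plants no phylogenetic correlation
between genomes. Consequently, passing recovery tests demonstrate the
correctness of the decision rules on unambiguous evidence, not robustness to
borderline HMM scores, compositional bias, or homology structure in real
proteomes.

## Verification strategy and problem sizes

- Conflict resolution is checked against an exhaustive pairwise-elimination
  oracle on 1000 random hit sets of ≤ 8 hits.
- Alignment scores are checked against brute-force enumeration of all
  alignments for 200 random pairs of length ≤ 6, and against an independent
  dynamic-programming implementation (Biopython's `PairwiseAligner`) on
  longer pairs.
- End-to-end planted-truth recovery is asserted at 100% on the default
  200-genome survey across five surfaces: identification, canonical
  architectures, dyad statuses, operon summary, abundance table.
- The generator's carrier fraction is checked at 1000 genomes against a
  3-standard-deviation binomial band around 0.18.
- Clustering output is re-verified post hoc against the greedy membership
  rule's definition.

These sizes keep the whole suite around ten seconds on one CPU while leaving
each property's sample large enough to exercise every code path.

## Known limitations

- Architecture canonicalization with orientation-aware keys and
  signal-peptide distinctions is supported but not the default; counts of
  "unique architectures" depend on this choice.
- The dyad reference is pairwise, not a profile: envelopes highly diverged
  from the reference may align poorly, and the low-confidence flag only
  catches the fully-gapped case.
- Operon functional classification is an automatic category union; a human
  curator using gene names and context would classify more operons and
  occasionally differently.
- No E-values are computed anywhere; the pipeline trusts the hit table.
- No phylogenetic analyses (trees, contrasts) and no sequencing-bias
  correction are included.
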