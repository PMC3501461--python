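"""Resolve a protein's domain architecture from overlapping hits and topology.

Two Pfam domains overlapping by more than 25% of either envelope conflict and
only the lower-E-value hit survives; a predicted transmembrane helix is
dropped wherever a surviving domain occupies the same region, and a lone
N-terminal helix is flagged as a putative signal peptide.
"""

from mcsurvey import DomainHit, TopologySegment, assemble_protein


def hit(name, env_from, env_to, i_evalue):
    length = env_to - env_from + 1
    return DomainHit(
        protein_id="p1", domain_name=name, model_length=length,
        hmm_from=1, hmm_to=length, env_from=env_from, env_to=env_to,
        i_evalue=i_evalue, score=120.0, bias=0.5,
    )


hits = [
    hit("Bac_PepC14", 60, 311, 1e-35),   # the metacaspase domain
    hit("TPR_1", 300, 345, 1e-4),        # overlaps the metacaspase by 12 of 46: conflict
    hit("WD40", 400, 439, 1e-8),         # three consecutive WD40 repeats
    hit("WD40", 450, 489, 1e-7),
    hit("WD40", 500, 539, 1e-9),
]
topology = [
    TopologySegment("p1", "inside", 1, 19),
    TopologySegment("p1", "helix", 20, 42),   # overlaps nothing: retained
    TopologySegment("p1", "outside", 43, 600),
]

arch = assemble_protein(hits, topology, protein_id="p1")
print("canonical architecture:", arch.canonical)
print("is metacaspase:", arch.is_metacaspase)
for el in arch.elements:
    extras = []
    if el.repeat_count > 1:
        extras.append(f"x{el.repeat_count}")
    if el.orientation:
        extras.append(el.orientation)
    if el.signal_peptide_flag:
        extras.append("putative signal peptide")
    print(f"  {el.label:12s} {el.start:4d}-{el.end:<4d} {' '.join(extras)}")

# TPR_1 loses its overlap conflict with the much stronger metacaspase hit, the
# three WD40 repeats collapse into one element with repeat_count=3, and the
# N-terminal helix (start <= 30, only helix) is a putative signal peptide.
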