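"""Independent brute-force oracles used to cross-check the implementations."""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def overlap_len(a, b):
    return max(0, min(a.env_to, b.env_to) - max(a.env_from, b.env_from) + 1)


def pair_conflicts(a, b, fraction=0.25):
    """Conflict: overlap exceeds the fraction of either envelope's length."""
    ov = overlap_len(a, b)
    return ov > fraction * a.env_length or ov > fraction * b.env_length


def dominant_elimination(hits, fraction=0.25):
    """Fixed point of the pairwise rule: in every conflicting pair the hit
    with the lower E-value wins, so the best remaining hit eliminates all of
    its conflictors; recurse on what is left."""
    remaining = sorted(
        hits,
        key=lambda h: (h.i_evalue, -h.env_length, h.domain_name, h.env_from, h.env_to),
    )
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [h for h in remaining if not pair_conflicts(best, h, fraction)]
    return sorted(kept, key=lambda h: (h.env_from, h.env_to, h.domain_name))


def brute_force_align_score(a, b, gap_penalty=8):
    """Maximum global-alignment score by exhaustive enumeration of alignments."""
    best = [None]

    def recurse(i, j, score):
        if i == len(a) and j == len(b):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + _B62[a[i], b[j]])
        if i < len(a):
            recurse(i + 1, j, score - gap_penalty)
        if j < len(b):
            recurse(i, j + 1, score - gap_penalty)

    recurse(0, 0, 0.0)
    return best[0]
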