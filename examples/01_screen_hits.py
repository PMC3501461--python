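"""Screen profile-HMM domain hits on E-value and score/bias thresholds.

Builds three hits by hand, applies the survey's acceptance rule (domain
independent E-value <= 0.01 AND score/bias ratio >= 10), and reports profile
coverage — the fraction of model match states the hit spans, which flags
likely partial/spurious matches below 60% without removing them.
"""

from mcsurvey import DomainHit, ScreenConfig, hmm_coverage, is_low_coverage, screen_hits


def hit(pid, i_evalue, score, bias, hmm_to=252):
    return DomainHit(
        protein_id=pid, domain_name="Bac_PepC14", model_length=252,
        hmm_from=1, hmm_to=hmm_to, env_from=1, env_to=hmm_to,
        i_evalue=i_evalue, score=score, bias=bias,
    )


hits = [
    hit("strong", 1.7e-37, 132.0, 0.1),          # clear metacaspase
    hit("weak_evalue", 0.02, 100.0, 1.0),        # fails the E-value ceiling
    hit("partial", 3.0e-11, 80.0, 0.5, hmm_to=58),  # passes, but low coverage
]

accepted, rejected = screen_hits(hits, ScreenConfig())
for h in accepted:
    print(
        f"accepted {h.protein_id}: i-E={h.i_evalue:g}, "
        f"coverage={hmm_coverage(h):.10f}, low_coverage={is_low_coverage(h)}"
    )
for r in rejected:
    print(f"rejected {r.hit.protein_id}: failed {r.reason} test")

# The 'partial' hit spans 58 of 252 match states (coverage 0.23): it stays in
# the dataset but is flagged as a possible false positive.
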