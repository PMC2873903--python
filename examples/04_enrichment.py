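"""Cross-validating a motif against an interaction network.

If a motif really mediates binding to a domain family, proteins that
interact with family carriers should match the motif (outside their own
globular domains) more often than the proteomic background. The classic
worked numbers: 50 of 593 interactors match versus 206 of 7215
non-interactors, a 2.57x enrichment, one-sided Fisher p = 2.8e-10.

The same machinery then runs on a synthetic network with planted 3x
enrichment and on a matched null network.
"""

from dmiminer import enrichment_factor, fisher_one_sided, synth_interactome, test_enrichment

table = (50, 593, 50 + 206, 593 + 7215)  # (i_m, i, m, p)
print(f"worked example: enrichment {enrichment_factor(table):.2f}x, "
      f"Fisher p = {fisher_one_sided(table):.3e}")
print(f"  interactors matching: {50/593:.1%}; background matching: {206/7215:.1%}")

planted = synth_interactome(1000, seed=2)  # interactors match at 0.15 vs 0.05
res = test_enrichment(planted, "DOM", "WWKW")
print(f"\nplanted 3x network:  i_m/i = {res.i_m}/{res.i}, m/p = {res.m}/{res.p}; "
      f"enrichment {res.enrichment:.2f}x, p = {res.p_value:.2e}")

null = synth_interactome(1000, match_prob_interactor=0.05, match_prob_other=0.05, seed=3)
res0 = test_enrichment(null, "DOM", "WWKW")
print(f"null network:        i_m/i = {res0.i_m}/{res0.i}, m/p = {res0.m}/{res0.p}; "
      f"enrichment {res0.enrichment:.2f}x, p = {res0.p_value:.2f}")
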