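"""Drug set enrichment (DSEA) curve for a ranked list against a reference set.

Builds a 6-drug ranked list with reference matches at ranks 1, 2 and 4 and
prints the running score under the default (corrected) convention.
"""

from epilit import dsea_curve, dsea_max
from epilit.fixtures import gen_reference_set

ranked, reference = gen_reference_set(6, match_positions=[1, 2, 4], set_size=4)
curve = dsea_curve(ranked, reference)

print(f"{'i':>2} {'drug':<12} {'match':<6} {'tau':>3} {'increment':>10} {'score':>8}")
for i, drug in enumerate(ranked.drugs, start=1):
    print(f"{i:>2} {drug:<12} {str(curve.is_match[i-1]):<6} "
          f"{curve.tau[i-1]:>3} {curve.increments[i-1]:>10.4f} "
          f"{curve.scores[i]:>8.4f}")
score, k = dsea_max(curve)
print(f"maximum enrichment {score:.4f} at position k={k}")
# Matches earn a growing bonus ln((S+tau)/(S-tau)); misses pay a growing
# penalty ln((N-tau)/(N+tau)). The peak position k marks how deep into the
# ranking the reference drugs are concentrated.
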