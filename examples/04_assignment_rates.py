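"""Held-out assignment experiments: cousins vs half-cousins and beyond.

Estimates outcome distributions for two competing relationships, then
simulates fresh genomes under each truth (independent random stream) and
classifies every genome by the sign of its summed log-likelihood ratio.
Pairs differing in Wright's R separate well when at least one R is
large; pairs sharing the same small R barely separate at all.
"""

import numpy as np

import segshare as ss

genome = ss.make_genome("human5")
rng = np.random.default_rng(13)
N, M = 50_000, 5_000

for a, b in [("C", "HC"), ("2C1R", "3C"), ("HS", "UN")]:
    bank = ss.DistributionBank.build([a, b], genome, N, rng)
    ra, rb = ss.assignment_experiment(a, b, genome, bank, M, rng)
    print(f"{a:5s} vs {b:5s}: correct {100 * ra:.1f}% (truth {a}), "
          f"{100 * rb:.1f}% (truth {b}), average {100 * (ra + rb) / 2:.1f}%")
print("\ncousins vs half-cousins (~98.5%) are far easier than second "
      "cousins once removed vs third cousins (~75%); half-sib vs "
      "uncle-nephew, identical R = 1/4, lands near 5/6.")
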