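"""Frequency rank of a slippery heptamer in two gene sets.

Highly expressed genes avoid shift-prone sequences: in a set where
phased A_AAA_AAG occurrences were disrupted five-fold, the heptamer's
frequency rank (1 = most frequent phased 7-mer) drops relative to the
untouched set drawn from the same composition.
"""

from fsgene import rank_heptamer_usage
from fsgene.simulate import generate_expression_sets

depleted, normal = generate_expression_sets(
    seed=1, n_genes=30, gene_len=900, heptamer="A_AAA_AAG", depletion=5.0
)
(rank_depleted, _), (rank_normal, _) = rank_heptamer_usage(
    depleted, normal, "A_AAA_AAG"
)
print(f"rank in depleted ('highly expressed') set: {rank_depleted}")
print(f"rank in background set:                    {rank_normal}")
print("a larger rank number means rarer relative to other phased 7-mers")
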