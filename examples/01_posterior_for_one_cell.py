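"""Fuse two conflicting satellite readings for a single cell.

Source A distinguishes three classes with the conditional probabilities of a
fairly sharp cropland mapper; source B is a coarser two-class product.  The
cell reads A1 (A's cropland-like class) and B2.  The posterior combines the
two witnesses with a uniform prior.
"""
import numpy as np

import landfuse as lf

table_a = lf.ConditionalTable(
    alphabet=(1, 2, 3),
    probs=np.array([[0.8, 0.2, 0.0],   # truth: arable
                    [0.1, 0.6, 0.3],   # truth: abandoned
                    [0.1, 0.3, 0.6]]), # truth: other
    support=np.zeros((3, 3)),
)
table_b = lf.ConditionalTable(
    alphabet=(1, 2),
    probs=np.array([[0.6, 0.4], [0.2, 0.8], [0.5, 0.5]]),
    support=np.zeros((3, 2)),
)

posterior, degenerate = lf.posterior_cell([1, 2], [table_a, table_b])
print("posterior (arable, abandoned, other):", np.round(posterior, 4))
print("as fractions of 45:", np.round(posterior * 45, 10))
print("classified as:", lf.CLASS_NAMES[int(np.argmax(posterior)) + 1])

# A missing source simply drops out of the product:
posterior_b_only, _ = lf.posterior_cell([None, 2], [table_a, table_b])
print("with source A missing:", np.round(posterior_b_only, 4))

# The printed posterior (0.7111, 0.1778, 0.1111) = (32, 8, 5)/45 says the two
# sources together make 'arable' about 4x as likely as 'abandoned', even
# though B alone leans the other way.
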