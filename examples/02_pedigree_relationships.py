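"""Pedigree I/O, progeny counting and additive relationships.

Builds a small two-family pedigree, writes and re-reads it in the
3-column text dialect, and computes the numerator-relationship quantities
that the selection strategies use: progeny/grandprogeny counts and the
relationship between a candidate subset and the rest of the population.
"""

import tempfile

import numpy as np

from peelsim import (count_progeny, make_pedigree, read_pedigree,
                     relationship_view, write_pedigree)

ped = make_pedigree(
    ids=[1, 2, 3, 4, 5, 6],
    sire_labels=[None, None, 1, 1, None, 3],
    dam_labels=[None, None, 2, 2, None, 5],
    sex=["M", "F", "M", "F", "F", "M"])

with tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False) as fh:
    path = fh.name
write_pedigree(ped, path)
print("pedigree text dialect:")
print(open(path).read())

again = read_pedigree(path)
prog, grand = count_progeny(again)
print("id  progeny  grandprogeny")
for i in range(again.n):
    print(f"{again.ids[i]:>2}  {prog[i]:>7}  {grand[i]:>12}")

view = relationship_view(again, subset=[0, 5])  # founder sire + grandson
print("\nA over subset {ids 1, 6}:")
print(np.round(view.A_s, 3))
print("average relationship of each to the rest:", np.round(view.a_s, 3))
# Individual 1 is parent/grandparent of half the pedigree, so its average
# relationship to the rest is high; the off-diagonal 0.25 is the
# grandparent-grandchild relationship.
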