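"""Encode a single aptamer with pseudo K-tuple nucleotide composition.

The 91-dimensional vector concatenates a pseudo 2-tuple block (16 dinucleotide
frequencies + 6 correlation factors) and a pseudo 3-tuple block (64 trinucleotide
frequencies + 5 correlation factors); each block sums to one, and the theta tail
carries sequence-order information the plain composition misses.
"""

import numpy as np

import aptapair as ap

aptamer = ap.NucleotideSequence("demo-rna", "GGGAGCUCAGAAUAAACGCUCAA")
values, names = ap.encode_aptamer(aptamer)

print(f"aptamer {aptamer.id}: L={len(aptamer)} -> {len(values)} features")
for block, prefix in (("pse2", "pse2_"), ("pse3", "pse3_")):
    idx = [i for i, n in enumerate(names) if n.startswith(prefix)]
    print(f"  {block}: {len(idx)} features, sum={values[idx].sum():.6f}")
top = np.argsort(values)[::-1][:5]
print("largest components:")
for i in top:
    print(f"  {names[i]:>12s} = {values[i]:.4f}")
print("Each block is a probability-like vector; the theta entries near the end")
print("grow when K-tuples far apart differ physicochemically (order signal).")
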