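"""Build a constraint library and apply the triplet consistency transform.

The library holds weighted evidence that residue x of one sequence
belongs in the same column as residue y of another; the transformation
reinforces each entry with evidence routed through every third sequence
(W' = W + sum_z min(W(i,z), W(z,j))), creating the anchor points that
steer Stage 4.
"""

from msaforge import (
    Sequence,
    build_primary_library,
    consistency_transform,
)

seqs = [
    Sequence("a", "MKVLITAGHE"),
    Sequence("b", "MKVLTAGHE"),   # one internal deletion
    Sequence("c", "MKVLITAGWE"),  # one substitution
]

primary = build_primary_library(seqs, mode="posterior")
extended = consistency_transform(primary)

print(f"primary library : {primary.n_entries()} entries")
print(f"extended library: {extended.n_entries()} entries\n")

print("pair (a, b), first residues (posterior weight -> extended weight):")
for (x, y), w in sorted(primary.pair_entries("a", "b").items())[:6]:
    w2 = extended.get_weight("a", "b", x, y)
    print(f"  a[{x}] ~ b[{y}]  {w:.3f} -> {w2:.3f}")

print(
    "\nEvery extended weight is at least its primary value; an entry\n"
    "supported through the third sequence roughly doubles (direct\n"
    "evidence plus one a-c-b route), which is what anchors it during\n"
    "profile alignment."
)
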