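"""Compare the five similarity techniques and four guide-tree builders.

Stage 1 scores every sequence pair on a common 0-100 scale; Stage 2
clusters the similarity matrix into the rooted binary tree that fixes
the progressive merge order.
"""

from msaforge import (
    Sequence,
    SubstitutionMatrix,
    build_nj,
    build_similarity_matrix,
    build_slink,
    build_upgma,
    to_newick,
)

seqs = [
    Sequence("hbb_like", "MVHLTPEEKSAVTALWGKVNV"),
    Sequence("hba_like", "MVLSPADKTNVKAAWGKVGA"),
    Sequence("mgb_like", "MGLSDGEWQLVLNVWGKVEA"),
    Sequence("far_relative", "MKTAYIAKQRQISFVKSHFS"),
]
blosum62 = SubstitutionMatrix.load("BLOSUM62")

for method, label in [("F", "FULL   global-alignment identity"),
                      ("Q", "QUICK  shared 1-tuples"),
                      ("L", "LCS    longest common subsequence"),
                      ("K", "KMERS  shared 3-mers"),
                      ("P", "PROBA  pair-HMM expected accuracy")]:
    sim = build_similarity_matrix(seqs, method, matrix=blosum62)
    pairs = "  ".join(f"{i}-{j}:{v:5.1f}" for i, j, v in sim.pairs())
    print(f"{label}\n  {pairs}")

sim = build_similarity_matrix(seqs, "F", matrix=blosum62)
print("\nguide trees from the FULL similarity matrix:")
print("  UPGMA :", to_newick(build_upgma(sim), lengths=False))
print("  SLMIN :", to_newick(build_slink(sim, "SLMIN"), lengths=False))
print("  SLMAX :", to_newick(build_slink(sim, "SLMAX"), lengths=False))
print("  NJ    :", to_newick(build_nj(sim), lengths=False))
print(
    "\nAll five scorers agree the globin-like trio is mutually closer than\n"
    "the unrelated sequence; the four builders may still group them\n"
    "differently, which is exactly the variation the framework explores."
)
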