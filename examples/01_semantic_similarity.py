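"""Disease semantic similarity from descriptor DAGs.

Builds a three-disease descriptor corpus by hand, computes the
contribution profiles and the two semantic measures for one pair, and
prints their combination.
"""
from mirlink import (
    DiseaseDAG,
    information_content,
    semantic_profile,
    wang_similarity,
    xuan_similarity,
)

# Shared hierarchy: root R; X under R; Z under X; Y under R.
corpus = [
    DiseaseDAG("disease-X", "X", frozenset({"R", "X"}), frozenset({("R", "X")})),
    DiseaseDAG("disease-Y", "Y", frozenset({"R", "Y"}), frozenset({("R", "Y")})),
    DiseaseDAG(
        "disease-Z", "Z", frozenset({"R", "X", "Z"}), frozenset({("R", "X"), ("X", "Z")})
    ),
]
x, _, z = corpus

p_x = semantic_profile(x, theta=0.5)
p_z = semantic_profile(z, theta=0.5)
print("contributions of disease-Z:", dict(sorted(p_z.contributions.items())))
print("semantic value of disease-Z:", p_z.semantic_value)

ss1 = wang_similarity(p_x, p_z)
ic = information_content(corpus)
print("information content:", {t: round(v, 4) for t, v in sorted(ic.values.items())})
ss2 = xuan_similarity(x, z, ic)
print(f"Wang similarity SS1 = {ss1:.6f}  (shared-ancestor contributions)")
print(f"Xuan similarity SS2 = {ss2:.6f}  (information-content weighted)")
print(f"combined SS = {(ss1 + ss2) / 2:.6f}")
# SS1 counts decayed contributions of the shared terms {R, X}; SS2
# weights shared terms by how rare they are across the corpus (the
# ubiquitous root contributes nothing). Their average is the disease
# similarity used to build the heterogeneous network.
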