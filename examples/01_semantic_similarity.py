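"""Score functional similarity between two enriched-term sets.

Builds a small random ontology, computes structural information content
(IC = -ln of the descendant-count probability), and compares two term
sets with Lin similarity combined by best-match average (BMA).
"""

from mirlink import bma_similarity, information_content, lin_similarity
from mirlink.synthetic import make_dag

dag = make_dag(n_terms=60, branching=2, seed=0)
ic_map = information_content(dag)

terms = sorted(dag.terms - {dag.root})
set_a = set(terms[:6])
set_b = set(terms[3:9])  # overlaps set_a in 3 of 6 terms

pair = lin_similarity(terms[0], terms[1], ic_map, dag)
result = bma_similarity(set_a, set_b, ic_map, dag)

print(f"ontology: {len(dag)} terms, root {dag.root}")
print(f"Lin({terms[0]}, {terms[1]}) = {pair:.4f}")
print(f"BMA similarity of the two 6-term sets = {result.score:.4f}")
print("A BMA near 1 means the sets annotate the same functions;")
print("near 0 means they only meet at the uninformative root.")
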