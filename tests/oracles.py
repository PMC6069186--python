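"""Independent reference implementations used as test oracles.

These are deliberately written from first principles, separate from the
package code paths they check: a plain Gotoh dynamic program (plus a
truly exhaustive alignment enumerator for tiny inputs), a codon-by-codon
translation built on Bio.Seq, and a brute-force parsimony minimizer that
enumerates every internal-node labeling of a tree.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

NEG = float("-inf")


def sw_score_oracle(query: str, target: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score; a gap of length k costs open + k*extend."""
    m, n = len(query), len(target)
    open_cost = gap_open + gap_extend
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (consumes target)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target (consumes query)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            s = matrix[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _global_alignments(a: str, b: str):
    """Yield every global alignment of a vs b as a list of ops.

    Ops: ('m', i, j) aligned pair, ('ga', i) gap consuming a[i],
    ('gb', j) gap consuming b[j].  Exponential; tiny inputs only.
    """
    if not a and not b:
        yield []
        return
    if a:
        for rest in _global_alignments(a[1:], b):
            yield [("ga", a[0])] + rest
    if b:
        for rest in _global_alignments(a, b[1:]):
            yield [("gb", b[0])] + rest
    if a and b:
        for rest in _global_alignments(a[1:], b[1:]):
            yield [("m", a[0], b[0])] + rest


def sw_score_exhaustive(query: str, target: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Max over all substring pairs and all of their global alignments.

    Gap runs cost open + k*extend (sign flipped: penalties subtracted).
    Only feasible for sequences of length <= ~5.
    """
    best = 0.0
    for i1 in range(len(query) + 1):
        for i2 in range(i1 + 1, len(query) + 1):
            for j1 in range(len(target) + 1):
                for j2 in range(j1 + 1, len(target) + 1):
                    a, b = query[i1:i2], target[j1:j2]
                    for ops in _global_alignments(a, b):
                        score = 0.0
                        prev = None
                        for op in ops:
                            if op[0] == "m":
                                score += matrix[op[1], op[2]]
                            else:
                                score -= gap_extend
                                if prev != op[0]:
                                    score -= gap_open
                            prev = op[0]
                        best = max(best, score)
    return best


def translate_oracle(dna: str, frame: int) -> str:
    """Codon-by-codon translation of one of the six frames via Bio.Seq."""
    if frame < 0:
        dna = str(Seq(dna).reverse_complement())
    sub = dna[abs(frame) - 1 :]
    out = []
    for i in range(0, len(sub) - len(sub) % 3, 3):
        codon = sub[i : i + 3]
        if set(codon) <= set("ACGT"):
            out.append(str(Seq(codon).translate()))
        else:
            out.append("X")
    return "".join(out)


def random_polytomy_tree(n_tips: int, labels, rng):
    """Random rooted tree (binary or multifurcating) with random tip labels.

    Returns an AnnotatedTree whose tips are all anchored.
    """
    import dendropy

    from cvescreen import AnnotatedTree

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label=f"t{i}")
        nodes.append(node)
    while len(nodes) > 1:
        k = int(rng.integers(2, min(3, len(nodes)) + 1))
        idx = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        parent = dendropy.Node()
        for i in idx:
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    host = {f"t{i}": labels[int(rng.integers(len(labels)))] for i in range(n_tips)}
    return AnnotatedTree(
        tree=tree, host_group=host, evidence_tier={t: "cve" for t in host}
    )


def fitch_bruteforce(tree, tip_state: dict, states) -> int:
    """Minimum label changes over all internal-node state assignments."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = None
    for assignment in itertools.product(states, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assignment)}
        for lf in leaves:
            state[id(lf)] = tip_state[lf.taxon.label]
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and state[id(node)] != state[id(node.parent_node)]:
                changes += 1
        best = changes if best is None else min(best, changes)
    return best
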