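"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately implemented without touching the package
internals it checks: a three-state global affine aligner plus substring
enumeration for local alignment, an all-anchor-pairs scan for exact
repeat pairs, and exhaustive state-assignment enumeration for two-state
ancestral-state posteriors.
"""

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(dna: str) -> str:
    return dna.translate(_COMP)[::-1]


def nw_affine_global(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Global affine alignment score; a gap of length k costs open + k·ext."""
    NEG = -1e9
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, lb + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    go = gap_open + gap_extend
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = BLOSUM62[ai, b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - gap_extend)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def brute_force_local(a: str, b: str) -> float:
    """O(n²m²) enumeration: best global score over all substring pairs, floored at 0."""
    best = 0.0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            sub_a = a[i:j]
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    best = max(best, nw_affine_global(sub_a, b[k:l]))
    return best


def brute_force_pairs(dna: str, min_len: int = 100) -> set:
    """All-anchor-pairs comparison for exact maximal repeat pairs."""
    n = len(dna)
    rc = _revcomp(dna)
    found = set()
    for i in range(n):
        for j in range(i + 1, n):
            if dna[i] != dna[j]:
                continue
            if i > 0 and dna[i - 1] == dna[j - 1]:
                continue  # not start-maximal
            k = 0
            while j + k < n and i + k < j and dna[i + k] == dna[j + k]:
                k += 1
            if k >= min_len:
                found.add((i, j, k, "direct"))
    for i in range(n):
        for r in range(n):
            if dna[i] != rc[r]:
                continue
            if i > 0 and r > 0 and dna[i - 1] == rc[r - 1]:
                continue
            k = 0
            while i + k < n and r + k < n and dna[i + k] == rc[r + k]:
                k += 1
            partner = n - (r + k)
            a_, b_ = min(i, partner), max(i, partner)
            if k >= min_len and a_ != b_ and b_ >= a_ + k:
                found.add((a_, b_, k, "inverted"))
    return found


def enumeration_posteriors(tree, tips, params):
    """Exhaustive sum over all node-state assignments (small trees only)."""
    prior = params.prior()
    pm = {i: params.transition_matrix(float(tree.blen[i])) for i in range(tree.n_nodes)}
    parent = [-1] * tree.n_nodes
    for i in range(tree.n_nodes):
        for c in tree.children[i]:
            parent[c] = i
    leaves = tree.leaves
    internals = [i for i in range(tree.n_nodes) if tree.children[i]]
    leaf_opts = {
        i: [0, 1] if tips[tree.labels[i]] == "?" else [int(tips[tree.labels[i]])]
        for i in leaves
    }
    acc = {i: np.zeros(2) for i in range(tree.n_nodes)}
    total = 0.0
    for istates in itertools.product([0, 1], repeat=len(internals)):
        for lstates in itertools.product(*[leaf_opts[i] for i in leaves]):
            assign = dict(zip(internals, istates))
            assign.update(dict(zip(leaves, lstates)))
            p = prior[assign[tree.root]]
            for i in range(tree.n_nodes):
                if i != tree.root:
                    p *= pm[i][assign[parent[i]], assign[i]]
            total += p
            for i, s in assign.items():
                acc[i][s] += p
    return {i: v / total for i, v in acc.items()}, math.log(total)


def random_tree_newick(n_tips, rng) -> str:
    """Random binary topology with random branch lengths."""
    nodes = [f"t{i}:{rng.uniform(0.05, 2.0):.3f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 2.0):.3f}")
    return nodes[0].rsplit(":", 1)[0] + ";"
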