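"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's dynamic programs: parsimony costs and
tree likelihoods are computed by exhaustive enumeration over all internal
ancestral-state assignments, which is exact for the small trees used in
tests.
"""

import itertools

import numpy as np

from intronfun.patterns import UniquePattern
from intronfun.phylo import Phylogeny, parse_tree


def brute_force_sankoff(pattern: UniquePattern, tree: Phylogeny,
                        gain_cost: float, loss_cost: float) -> float:
    """Minimum cost over all 2^(n_internal) ancestral state assignments."""
    tips = {name: pattern.values[pattern.species.index(name)] for name in tree.taxa}
    internal = [n for n in range(tree.n_nodes) if tree.children[n]]
    leaves = {int(tree.leaf_nodes[i]): tree.taxa[i] for i in range(tree.n_leaves)}
    trans = {(0, 1): gain_cost, (1, 0): loss_cost, (0, 0): 0.0, (1, 1): 0.0}
    best = np.inf
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        # missing tips may take either state: enumerate those too
        missing = [n for n, name in leaves.items() if tips[name] == 2]
        fixed = {n: int(tips[name]) for n, name in leaves.items() if tips[name] != 2}
        for miss_assign in itertools.product((0, 1), repeat=len(missing)):
            full = dict(state)
            full.update(fixed)
            full.update(dict(zip(missing, miss_assign)))
            cost = 0.0
            for node in range(tree.n_nodes):
                parent = tree.parent[node]
                if parent >= 0:
                    cost += trans[(full[parent], full[node])]
            best = min(best, cost)
    return best


def brute_force_log_likelihood(pattern: UniquePattern, tree: Phylogeny, model) -> float:
    """log P(tips) by summing over all internal-node state combinations."""
    internal = [n for n in range(tree.n_nodes) if tree.children[n]]
    leaves = {int(tree.leaf_nodes[i]): tree.taxa[i] for i in range(tree.n_leaves)}
    tips = {name: pattern.values[pattern.species.index(name)] for name in tree.taxa}
    pi = np.array([1 - model.pi1, model.pi1])
    total = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        prob = pi[state[tree.root]]
        ok = True
        for node in range(tree.n_nodes):
            parent = tree.parent[node]
            if parent < 0:
                continue
            P = model.transition_matrix(float(tree.edge_length[node]))
            if node in leaves:
                tip = tips[leaves[node]]
                if tip == 2:
                    prob *= 1.0  # both states admissible with likelihood 1
                else:
                    prob *= P[state[parent], int(tip)]
            else:
                prob *= P[state[parent], state[node]]
            if prob == 0.0:
                ok = False
                break
        if ok or prob > 0:
            total += prob
    return float(np.log(total))


def random_ultrametric_tree(n_leaves: int, rng: np.random.Generator) -> Phylogeny:
    """Random topology by successive pairwise joins at increasing ages."""
    clusters = [(f"L{i}", 0.0) for i in range(n_leaves)]
    age = 0.0
    while len(clusters) > 1:
        age += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (si, ai), (sj, aj) = clusters[i], clusters[j]
        merged = (f"({si}:{age - ai:.6f},{sj}:{age - aj:.6f})", age)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return parse_tree(clusters[0][0] + ";")


def random_pattern(tree: Phylogeny, rng: np.random.Generator,
                   missing_prob: float = 0.2) -> UniquePattern:
    values = rng.integers(0, 2, size=tree.n_leaves).astype(np.int8)
    miss = rng.random(tree.n_leaves) < missing_prob
    values[miss] = 2
    if not (values == 1).any():
        values[int(rng.integers(tree.n_leaves))] = 1
    return UniquePattern(values=values, species=list(tree.taxa),
                         occurrences=[], label="non-functional")
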