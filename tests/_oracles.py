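"""Independent brute-force oracles used only by the tests.

Each oracle solves the same problem as the package operation it checks, but
by naive enumeration with no shared computation path, so agreement is a
genuine cross-validation.
"""

from itertools import combinations, product

import dendropy


# -- hypergeometric by subset enumeration ------------------------------------


def hypergeom_by_enumeration(T: int, n: int, r: int, x: int) -> float:
    """P(exactly x of r marked items land in the recovered first-n block),
    by enumerating every C(T, r) placement of the marked items."""
    recovered = set(range(n))
    hits = 0
    total = 0
    for placement in combinations(range(T), r):
        total += 1
        if sum(1 for p in placement if p in recovered) == x:
            hits += 1
    return hits / total


# -- light rooted-tree indexing (independent of the package's) ----------------


def _index(tree: dendropy.Tree):
    nodes = list(tree.postorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    children = [[idx[id(c)] for c in nd.child_nodes()] for nd in nodes]
    parent = [-1] * len(nodes)
    for i, kids in enumerate(children):
        for k in kids:
            parent[k] = i
    label = []
    for nd in nodes:
        label.append(nd.taxon.label if nd.taxon else None)
    return nodes, children, parent, label


# -- Dollo gains by exhaustive internal-state assignment ----------------------


def dollo_gains_by_search(tree: dendropy.Tree, states: dict) -> int:
    """Min 0->1 edges over all internal 0/1 labelings with no 1->0 edge
    (irreversible character; the origin above the root counts as state 0)."""
    nodes, children, parent, label = _index(tree)
    internals = [i for i, kids in enumerate(children) if kids]
    fixed = {
        i: states[label[i]] for i, kids in enumerate(children) if not kids
    }
    best = None
    for assign in product((0, 1), repeat=len(internals)):
        full = dict(fixed)
        full.update(dict(zip(internals, assign)))
        ok = True
        gains = 0
        for i in range(len(nodes)):
            p = parent[i]
            up = full[p] if p != -1 else 0
            if up == 1 and full[i] == 0:
                ok = False
                break
            if up == 0 and full[i] == 1:
                gains += 1
        if ok and (best is None or gains < best):
            best = gains
    return best


# -- vertical losses by exhaustive assignment ---------------------------------


def vertical_losses_by_search(tree: dendropy.Tree, present: set) -> int:
    """Min 1->0 edges under single origin at the MRCA of `present`, vertical
    descent only (no re-gain), leaves matching `present`."""
    nodes, children, parent, label = _index(tree)
    # MRCA = deepest node covering all present leaves
    cover = [set() for _ in nodes]
    for i, kids in enumerate(children):
        if kids:
            for k in kids:
                cover[i] |= cover[k]
        else:
            cover[i] = {label[i]}
    mrca = min(
        (i for i in range(len(nodes)) if present <= cover[i]),
        key=lambda i: len(cover[i]),
    )
    sub = [i for i in range(len(nodes)) if present <= cover[mrca] and _under(i, mrca, parent)]
    internals = [i for i in sub if children[i]]
    fixed = {i: (1 if label[i] in present else 0) for i in sub if not children[i]}
    best = None
    for assign in product((0, 1), repeat=len(internals)):
        full = dict(fixed)
        full.update(dict(zip(internals, assign)))
        full[mrca] = 1  # origin
        ok = True
        losses = 0
        for i in sub:
            if i == mrca:
                continue
            up = full[parent[i]]
            if up == 0 and full[i] == 1:
                ok = False  # no re-gain under vertical-only descent
                break
            if up == 1 and full[i] == 0:
                losses += 1
        if ok and (best is None or losses < best):
            best = losses
    return best


def _under(i, anc, parent):
    while i != -1:
        if i == anc:
            return True
        i = parent[i]
    return False


# -- RF distance by bipartition enumeration -----------------------------------


def rf_by_enumeration(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    def splits(tree):
        nodes, children, parent, label = _index(tree)
        leaves = set()
        under = [set() for _ in nodes]
        for i, kids in enumerate(children):
            if kids:
                for k in kids:
                    under[i] |= under[k]
            else:
                under[i] = {label[i]}
                leaves.add(label[i])
        out = set()
        for i, kids in enumerate(children):
            if not kids or parent[i] == -1:
                continue
            side, other = frozenset(under[i]), frozenset(leaves - under[i])
            if len(side) < 2 or len(other) < 2:
                continue  # trivial in the unrooted sense
            out.add(min((side, other), key=lambda s: sorted(s)))
        return out, leaves

    s1, l1 = splits(t1)
    s2, l2 = splits(t2)
    assert l1 == l2
    return len(s1 ^ s2)


# -- minimum-event reconciliation by pruned exhaustive map enumeration --------


def reconcile_min_cost_by_enumeration(
    species: dendropy.Tree, gene: dendropy.Tree, tau: float = 1.0, lam: float = 1.0
) -> float:
    """Min total cost over every valid mapping of gene nodes to species
    branches, enumerated recursively (no dynamic programming)."""
    s_nodes, s_children, s_parent, s_label = _index(species)
    g_nodes, g_children, g_parent, g_label = _index(gene)
    nS = len(s_nodes)

    anc = [set() for _ in range(nS)]  # ancestor-or-self ids
    for i in range(nS):
        j = i
        while j != -1:
            anc[i].add(j)
            j = s_parent[j]

    def comparable(a, b):
        return a in anc[b] or b in anc[a]

    def drop(x, x1):
        """losses charged passing from branch x down to branch x1"""
        if x == x1:
            return 0.0
        chain = []
        j = x1
        while j != x:
            chain.append(j)
            j = s_parent[j]
        # pass through the bottom node of x and of every intermediate branch
        return sum(
            lam * (len(s_children[j]) - 1) for j in [x] + chain[::-1][:-1]
        )

    leaf_branch = {s_label[i]: i for i in range(nS) if not s_children[i]}

    def options(x1, x2):
        """(x, event cost) choices for a parent of children mapped at x1, x2."""
        out = []
        if not comparable(x1, x2):
            # speciation at the LCA
            lca = max(anc[x1] & anc[x2], key=lambda j: _depth(j, s_parent))
            y1 = _child_toward(lca, x1, s_children, s_parent)
            y2 = _child_toward(lca, x2, s_children, s_parent)
            out.append(
                (
                    lca,
                    lam * (len(s_children[lca]) - 2)
                    + drop(y1, x1)
                    + drop(y2, x2),
                )
            )
        # transfers: one child stays below x, the other lands incomparable
        for stay, go in ((x1, x2), (x2, x1)):
            for x in anc[stay]:
                if not comparable(x, go):
                    out.append((x, tau + drop(x, stay)))
        return out

    def enum(u):
        kids = g_children[u]
        if not kids:
            return [(leaf_branch[g_label[u]], 0.0)]
        u1, u2 = kids
        results = []
        for x1, c1 in enum(u1):
            for x2, c2 in enum(u2):
                for x, ec in options(x1, x2):
                    results.append((x, c1 + c2 + ec))
        # keep only the cheapest per branch to bound growth (still exhaustive
        # over event structures, since cost fully determines the comparison)
        best = {}
        for x, c in results:
            if x not in best or c < best[x]:
                best[x] = c
        return list(best.items())

    root = len(g_nodes) - 1
    return min(c for _, c in enum(root))


def _depth(j, parent):
    d = 0
    while parent[j] != -1:
        j = parent[j]
        d += 1
    return d


def _child_toward(anc_node, target, children, parent):
    j = target
    while parent[j] != anc_node:
        j = parent[j]
    return j
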