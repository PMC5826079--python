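"""Minimum-event reconciliation of a gene tree with a rooted organismal tree.

The model: a gene family originates exactly once on a species-tree branch
(origin, cost 0) and then evolves by speciation (free), horizontal transfer
(a gene lineage is copied from a donor branch onto an incomparable recipient
branch), and loss.  The branching order of the surviving copies must equal
the observed rooted gene tree; each sampled species carries at most one copy
(no paralogs).  An irreversible binary fusion character evolves on the gene
lineages: once gained it is never lost, so the minimum number of gains equals
the number of maximal fully-fused gene-tree clades, independent of the
species mapping.

The optimum is found exactly by dynamic programming over (gene node, species
branch) pairs, the undated transfer-loss analogue of classic tree
reconciliation; co-optimal scenarios are enumerated by backtracking up to a
configurable cap.  No temporal feasibility constraint is applied to
transfers beyond donor/recipient incomparability: the reasoning is purely
topological.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice
from typing import Iterable, Mapping

import dendropy

from magtrace.errors import BoundedSearchError, InputError
from magtrace.tree_ops import leaf_labels

_INF = (math.inf, 0, 0)
_ISCLOSE = dict(rel_tol=1e-9, abs_tol=1e-9)


@dataclass(frozen=True)
class EventCosts:
    """Per-event costs; the single mandatory origin is free."""

    transfer: float = 1.0
    loss: float = 1.0
    fusion: float = 1.0

    def __post_init__(self):
        for name in ("transfer", "loss", "fusion"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} cost must be > 0")


@dataclass(frozen=True)
class Scenario:
    """One event history: origin branch, transfers, losses, fusion gains."""

    origin_branch: str
    transfers: tuple[tuple[str, str], ...]  # (donor branch, recipient branch)
    losses: tuple[str, ...]
    fusion_gains: tuple[str, ...]
    total_cost: float

    @property
    def n_events(self) -> int:
        return len(self.transfers) + len(self.losses) + len(self.fusion_gains)

    def sort_key(self):
        return (
            len(self.transfers),
            len(self.losses),
            len(self.fusion_gains),
            self.transfers,
            self.losses,
            self.origin_branch,
        )


@dataclass(frozen=True)
class Reconciliation:
    scenarios: tuple[Scenario, ...]
    min_cost: float
    min_transfers: int
    min_losses: int
    min_fusions: int

    def to_dict(self) -> dict:
        return {
            "min_cost": self.min_cost,
            "min_transfers": self.min_transfers,
            "min_losses": self.min_losses,
            "min_fusions": self.min_fusions,
            "n_scenarios": len(self.scenarios),
            "scenarios": [
                {
                    "origin_branch": s.origin_branch,
                    "transfers": [list(t) for t in s.transfers],
                    "losses": list(s.losses),
                    "fusion_gains": list(s.fusion_gains),
                    "total_cost": s.total_cost,
                }
                for s in self.scenarios
            ],
        }


class _TreeIndex:
    """Array view of a rooted dendropy tree for the DP."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.parent = [-1] * self.n
        self.leafset: list[frozenset[str]] = [frozenset()] * self.n
        self.label: list[str] = [""] * self.n
        self.leaf_of: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            kids = [ids[id(c)] for c in nd.child_nodes()]
            self.children[i] = kids
            for k in kids:
                self.parent[k] = i
            if kids:
                ls = frozenset().union(*(self.leafset[k] for k in kids))
                self.leafset[i] = ls
                self.label[i] = "+".join(sorted(ls))
            else:
                lab = nd.taxon.label if nd.taxon else nd.label
                self.leafset[i] = frozenset([lab])
                self.label[i] = lab
                self.leaf_of[lab] = i
        self.root = self.n - 1
        self.postorder = list(range(self.n))
        # descendant-or-self sets -> incomparability lists
        desc = [set() for _ in range(self.n)]
        for i in range(self.n):
            desc[i].add(i)
            for k in self.children[i]:
                desc[i] |= desc[k]
        self.incomp: list[list[int]] = [
            [
                y
                for y in range(self.n)
                if y not in desc[x] and x not in desc[y]
            ]
            for x in range(self.n)
        ]


def _check_states(tree: dendropy.Tree, states: Mapping[str, int]) -> None:
    missing = [l for l in leaf_labels(tree) if l not in states]
    if missing:
        raise InputError(f"fusion state missing for leaves: {', '.join(missing)}")
    bad = {l: v for l, v in states.items() if v not in (0, 1)}
    if bad:
        raise InputError(f"fusion states must be 0/1, got {bad}")


def dollo_gains(
    tree: dendropy.Tree, states: Mapping[str, int]
) -> tuple[int, list[str]]:
    """Minimum 0->1 gains of an irreversible binary character.

    Because the character can never revert, a gain may only be placed on a
    branch whose entire clade is in state 1; the minimum equals the number of
    maximal all-1 clades.  Returns (count, gain branch labels).
    """
    _check_states(tree, states)
    idx = _TreeIndex(tree)
    all_one = [False] * idx.n
    for i in idx.postorder:
        kids = idx.children[i]
        if not kids:
            all_one[i] = states[idx.label[i]] == 1
        else:
            all_one[i] = all(all_one[k] for k in kids)
    gains = [
        idx.label[i]
        for i in range(idx.n)
        if all_one[i] and (idx.parent[i] == -1 or not all_one[idx.parent[i]])
    ]
    return len(gains), sorted(gains)


def min_vertical_losses(
    species_tree: dendropy.Tree, present: Iterable[str]
) -> tuple[int, list[str]]:
    """Losses required under single-origin, vertical-only inheritance.

    Places the origin at the most recent common ancestor of ``present`` and
    counts the maximal subtrees below it containing no present leaf (each
    needs one loss).  Returns (count, lost branch labels).
    """
    present = set(present)
    if not present:
        raise InputError("present set is empty")
    labels = set(leaf_labels(species_tree))
    unknown = present - labels
    if unknown:
        raise InputError(f"present leaves not in tree: {', '.join(sorted(unknown))}")
    idx = _TreeIndex(species_tree)
    has = [False] * idx.n
    for i in idx.postorder:
        kids = idx.children[i]
        if not kids:
            has[i] = idx.label[i] in present
        else:
            has[i] = any(has[k] for k in kids)
    # MRCA = deepest node whose leafset covers `present`
    mrca = idx.root
    changed = True
    while changed:
        changed = False
        for k in idx.children[mrca]:
            if present <= idx.leafset[k]:
                mrca = k
                changed = True
                break
    losses = []
    stack = list(idx.children[mrca])
    while stack:
        i = stack.pop()
        if not has[i]:
            losses.append(idx.label[i])
        else:
            stack.extend(idx.children[i])
    return len(losses), sorted(losses)


def _t3(a, b, c=(0.0, 0, 0)):
    return (a[0] + b[0] + c[0], a[1] + b[1] + c[1], a[2] + b[2] + c[2])


def min_event_reconciliation(
    species_tree: dendropy.Tree,
    gene_tree: dendropy.Tree,
    present: Iterable[str] | None = None,
    fusion_states: Mapping[str, int] | None = None,
    costs: EventCosts = EventCosts(),
    max_scenarios: int = 25,
    max_events: int | None = None,
) -> Reconciliation:
    """Exact minimum-cost event history mapping ``gene_tree`` into
    ``species_tree``.

    ``present`` (defaulting to the gene-tree leaf set) must equal the gene
    leaves and be a subset of the species leaves.  The gene tree must be
    binary; the species tree may contain polytomies, across which a
    pass-through charges one loss per bypassed child lineage.

    Returns all cost-co-optimal scenarios up to ``max_scenarios``, sorted by
    (transfers, losses, fusions, events); ``min_transfers``/``min_losses``
    are taken from the cost-then-transfers-then-losses lexicographic optimum.
    """
    s_labels = set(leaf_labels(species_tree))
    g_labels = set(leaf_labels(gene_tree))
    missing = g_labels - s_labels
    if missing:
        raise InputError(
            f"gene leaves missing from species tree: {', '.join(sorted(missing))}"
        )
    if present is not None:
        present = set(present)
        if present != g_labels:
            raise InputError(
                "present set must equal the gene tree leaf set "
                f"(difference: {sorted(present ^ g_labels)})"
            )
    S = _TreeIndex(species_tree)
    G = _TreeIndex(gene_tree)
    for u in range(G.n):
        if len(G.children[u]) not in (0, 2):
            raise InputError("gene tree must be binary for reconciliation")

    tau, lam = costs.transfer, costs.loss
    TC = (tau, 1, 0)

    n_fusions, fusion_gains = (0, [])
    if fusion_states is not None:
        n_fusions, fusion_gains = dollo_gains(gene_tree, fusion_states)
    fusion_cost = n_fusions * costs.fusion

    nS = S.n
    INF = _INF
    c: list[list[tuple]] = [None] * G.n
    cin: list[list[tuple]] = [None] * G.n
    cout: list[list[tuple]] = [None] * G.n

    for u in range(G.n):
        kids = G.children[u]
        cu = [INF] * nS
        if not kids:
            cu[S.leaf_of[G.label[u]]] = (0.0, 0, 0)
        else:
            u1, u2 = kids
            for x in range(nS):
                best = INF
                ch = S.children[x]
                if len(ch) >= 2:
                    extra = (lam * (len(ch) - 2), 0, len(ch) - 2)
                    for y1 in ch:
                        for y2 in ch:
                            if y1 == y2:
                                continue
                            cand = _t3(cin[u1][y1], cin[u2][y2], extra)
                            if cand < best:
                                best = cand
                for stay, go in ((u1, u2), (u2, u1)):
                    cand = _t3(cin[stay][x], cout[go][x], TC)
                    if cand < best:
                        best = cand
                cu[x] = best
        c[u] = cu
        ci = [INF] * nS
        for x in range(nS):  # postorder: children precede parents
            best = cu[x]
            ch = S.children[x]
            if ch:
                extra = (lam * (len(ch) - 1), 0, len(ch) - 1)
                for y in ch:
                    cand = _t3(ci[y], extra)
                    if cand < best:
                        best = cand
            ci[x] = best
        cin[u] = ci
        cout[u] = [
            min((ci[y] for y in S.incomp[x]), default=INF) for x in range(nS)
        ]

    root = G.root
    best = min(c[root])
    if not math.isfinite(best[0]):
        raise InputError("no feasible reconciliation (inconsistent inputs)")
    min_cost = best[0] + fusion_cost
    needed = best[1] + best[2] + n_fusions
    if max_events is not None and needed > max_events:
        raise BoundedSearchError(bound=max_events, needed=needed)

    close = lambda a, b: math.isclose(a, b, **_ISCLOSE)

    def enum_at(u: int, x: int):
        kids = G.children[u]
        if not kids:
            yield ()
            return
        target = c[u][x][0]
        u1, u2 = kids
        ch = S.children[x]
        if len(ch) >= 2:
            extra = lam * (len(ch) - 2)
            for y1 in ch:
                for y2 in ch:
                    if y1 == y2:
                        continue
                    if not close(cin[u1][y1][0] + cin[u2][y2][0] + extra, target):
                        continue
                    lost = tuple(
                        ("L", S.label[z]) for z in ch if z not in (y1, y2)
                    )
                    for e1 in enum_in(u1, y1):
                        for e2 in enum_in(u2, y2):
                            yield lost + e1 + e2
        for stay, go in ((u1, u2), (u2, u1)):
            if not close(cin[stay][x][0] + cout[go][x][0] + tau, target):
                continue
            for es in enum_in(stay, x):
                for y in S.incomp[x]:
                    if not close(cin[go][y][0], cout[go][x][0]):
                        continue
                    for eg in enum_in(go, y):
                        yield (("T", S.label[x], S.label[y]),) + es + eg

    def enum_in(u: int, x: int):
        target = cin[u][x][0]
        if close(c[u][x][0], target):
            yield from enum_at(u, x)
        ch = S.children[x]
        if ch:
            extra = lam * (len(ch) - 1)
            for y in ch:
                if close(cin[u][y][0] + extra, target):
                    lost = tuple(("L", S.label[z]) for z in ch if z != y)
                    for e in enum_in(u, y):
                        yield lost + e

    seen = set()
    scenarios = []
    for x in range(nS):
        if not close(c[root][x][0], best[0]):
            continue
        for events in islice(enum_at(root, x), max_scenarios * 4):
            transfers = tuple(sorted((e[1], e[2]) for e in events if e[0] == "T"))
            losses = tuple(sorted(e[1] for e in events if e[0] == "L"))
            key = (S.label[x], transfers, losses)
            if key in seen:
                continue
            seen.add(key)
            scenarios.append(
                Scenario(
                    origin_branch=S.label[x],
                    transfers=transfers,
                    losses=losses,
                    fusion_gains=tuple(fusion_gains),
                    total_cost=min_cost,
                )
            )
    scenarios.sort(key=Scenario.sort_key)
    scenarios = tuple(scenarios[:max_scenarios])

    return Reconciliation(
        scenarios=scenarios,
        min_cost=min_cost,
        min_transfers=best[1],
        min_losses=best[2],
        min_fusions=n_fusions,
    )


def _branch_phrase(label: str, names: Mapping[str, str] | None) -> str:
    if names and label in names:
        label = names[label]
    if "+" in label:
        return f"branch leading to {{{label.replace('+', ', ')}}}"
    return f"branch leading to {label}"


def scenario_narrative(
    rec: Reconciliation, names: Mapping[str, str] | None = None
) -> str:
    """Deterministic human-readable listing of every optimal scenario."""
    if not rec.scenarios:
        raise InputError("reconciliation has no scenarios to narrate")
    lines = [
        f"{len(rec.scenarios)} optimal scenario(s), cost {rec.min_cost:g} "
        f"(minimum {rec.min_transfers} transfer(s), {rec.min_losses} loss(es), "
        f"{rec.min_fusions} fusion gain(s))"
    ]
    for i, s in enumerate(rec.scenarios, start=1):
        lines.append(f"scenario {i} (cost {s.total_cost:g}):")
        lines.append(f"  origin on {_branch_phrase(s.origin_branch, names)}")
        if not s.transfers:
            lines.append("  no transfers")
        for donor, recip in s.transfers:
            lines.append(
                f"  transfer from {_branch_phrase(donor, names)} "
                f"into {_branch_phrase(recip, names)}"
            )
        for lost in s.losses:
            lines.append(f"  loss on {_branch_phrase(lost, names)}")
        for gain in s.fusion_gains:
            lines.append(f"  fusion gained on gene {_branch_phrase(gain, names)}")
    return "\n".join(lines) + "\n"
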