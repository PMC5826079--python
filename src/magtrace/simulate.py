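"""Synthetic data generators matching the statistical assumptions of the
analysis: uniform gene subsampling of bins with contaminant admixture, Yule
random trees, and gene-tree histories with planted lateral transfers plus an
optional irreversible fusion character.

Every generator takes an explicit integer seed and draws from its own
``numpy.random.Generator``; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import dendropy

from magtrace.bin_confidence import GeneSet
from magtrace.errors import DomainError, GenerationError, InputError
from magtrace.tree_ops import leaf_labels, parse_newick


@dataclass(frozen=True)
class SyntheticBin:
    """Ground-truth record of one simulated bin subsampling."""

    true_gene_set: tuple[str, ...]
    sampled: tuple[str, ...]
    pathway: GeneSet
    contaminant_genes: tuple[str, ...]
    seed: int

    @property
    def n_pathway_recovered(self) -> int:
        members = set(self.pathway.members)
        return sum(1 for g in self.sampled if g in members)


@dataclass(frozen=True)
class SyntheticHistory:
    """Ground truth for a planted-transfer gene history."""

    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree
    true_events: tuple[tuple[str, str], ...]  # (donor clade, recipient clade)
    fusion_gain_branch: str | None
    fusion_states: dict[str, int] | None
    seed: int


def simulate_bin_sampling(
    T: int,
    n: int,
    pathway: GeneSet,
    contamination: float = 0.0,
    seed: int = 0,
) -> SyntheticBin:
    """Sample ``n`` of ``T`` genes uniformly without replacement.

    Pathway members occupy the start of the true gene id space; contaminant
    genes come from a disjoint ``foreign`` id space and are appended at rate
    ``round(contamination * n)``.
    """
    if n > T:
        raise DomainError(f"n ({n}) exceeds T ({T})")
    if n < 0 or T < 0:
        raise DomainError("counts must be non-negative")
    if pathway.size > T:
        raise DomainError(f"pathway size {pathway.size} exceeds T ({T})")
    if not (0 <= contamination < 1):
        raise DomainError(f"contamination must be in [0, 1), got {contamination}")
    rng = np.random.default_rng(seed)
    filler = [f"g{i:06d}" for i in range(T - pathway.size)]
    true_genes = tuple(pathway.members) + tuple(filler)
    picked = rng.choice(T, size=n, replace=False) if n else np.array([], dtype=int)
    sampled = tuple(true_genes[i] for i in sorted(picked.tolist()))
    n_contam = round(contamination * n)
    contaminants = tuple(f"foreign{i:06d}" for i in range(n_contam))
    return SyntheticBin(
        true_gene_set=true_genes,
        sampled=sampled + contaminants,
        pathway=pathway,
        contaminant_genes=contaminants,
        seed=seed,
    )


# -- nested-tuple tree surgery ------------------------------------------------
# A tree is a leaf label (str) or a tuple of >= 2 subtrees.  Topology-only.


def _to_nested(tree: dendropy.Tree):
    def rec(node):
        kids = node.child_nodes()
        if not kids:
            return node.taxon.label if node.taxon else node.label
        return tuple(rec(k) for k in kids)

    return rec(tree.seed_node)


def _nested_newick(n) -> str:
    if isinstance(n, str):
        return n
    return "(" + ",".join(_nested_newick(c) for c in n) + ")"


def _nested_to_tree(n) -> dendropy.Tree:
    return parse_newick(_nested_newick(n) + ";")


def _leafset(n) -> frozenset:
    if isinstance(n, str):
        return frozenset([n])
    return frozenset().union(*(_leafset(c) for c in n))


def _prune(n, target: frozenset):
    """Remove the clade with leaf set ``target``; suppress unifurcations."""
    if isinstance(n, str):
        return n
    kept = [c for c in n if _leafset(c) != target]
    kept = [_prune(c, target) for c in kept]
    kept = [c for c in kept if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return tuple(kept)


def _graft_sister(n, donor: frozenset, graft):
    """Insert ``graft`` as sister of the clade with leaf set ``donor``."""
    if isinstance(n, str):
        if donor == frozenset([n]):
            return (n, graft)
        return n
    if _leafset(n) == donor:
        return (n, graft)
    return tuple(_graft_sister(c, donor, graft) for c in n)


def _find(n, target: frozenset):
    if _leafset(n) == target:
        return n
    if isinstance(n, str):
        return None
    for c in n:
        hit = _find(c, target)
        if hit is not None:
            return hit
    return None


def simulate_yule_tree(n_leaves: int, seed: int = 0, prefix: str = "T") -> dendropy.Tree:
    """Random rooted binary tree via the Yule (uniform leaf split) process."""
    if n_leaves < 2:
        raise DomainError(f"need at least 2 leaves, got {n_leaves}")
    rng = np.random.default_rng(seed)
    leaves: list = [f"{prefix}1", f"{prefix}2"]
    nested = tuple(leaves)
    next_id = 3
    while next_id <= n_leaves:
        victim = leaves[rng.integers(len(leaves))]
        new = f"{prefix}{next_id}"

        def split(n):
            if isinstance(n, str):
                return (n, new) if n == victim else n
            return tuple(split(c) for c in n)

        nested = split(nested)
        leaves.append(new)
        next_id += 1
    return _nested_to_tree(nested)


def _collect_clades(n, parent=None, out=None):
    """All non-root clades as (leafset, parent leafset-of-siblings info)."""
    if out is None:
        out = []
    if isinstance(n, str):
        return out
    for c in n:
        out.append((_leafset(c), _leafset(n), tuple(_leafset(s) for s in n)))
        _collect_clades(c, n, out)
    return out


def _comparable(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a


def plant_transfers(
    species_tree: dendropy.Tree,
    k: int,
    seed: int = 0,
    well_separated: bool = True,
    forced_pairs: Sequence[tuple[Sequence[str], Sequence[str]]] | None = None,
    plant_fusion: bool = False,
    max_tries: int = 2000,
) -> SyntheticHistory:
    """Plant ``k`` donor->recipient transfers into a copy of the species tree.

    Each transfer replaces the recipient clade's gene copy with a copy
    branching from the donor clade's stem (prune recipient, regraft as sister
    of donor).  With ``well_separated`` the donor/recipient clades of all
    transfers are pairwise disjoint, non-sibling and non-adjacent, so every
    planted event is individually detectable and events do not interact.

    ``forced_pairs`` bypasses random choice: a list of (donor leaf set,
    recipient leaf set) pairs.
    """
    if k < 0:
        raise DomainError("k must be >= 0")
    labels = leaf_labels(species_tree)
    if len(labels) < k + 3:
        raise DomainError(f"species tree needs >= k+3 leaves for k={k}")
    rng = np.random.default_rng(seed)
    nested = _to_nested(species_tree)

    def candidate_clades(n):
        out = []
        if isinstance(n, str):
            return out
        for c in n:
            out.append(_leafset(c))
            out.extend(candidate_clades(c))
        return out

    def siblings(n, clade):
        """Leafsets of the siblings of `clade` in nested tree `n`."""
        if isinstance(n, str):
            return None
        subs = [_leafset(c) for c in n]
        if clade in subs:
            return [s for s in subs if s != clade]
        for c in n:
            got = siblings(c, clade)
            if got is not None:
                return got
        return None

    if forced_pairs is not None:
        pairs = [
            (frozenset(d), frozenset(r)) for d, r in forced_pairs
        ]
        if len(pairs) != k:
            raise InputError(f"forced_pairs has {len(pairs)} pairs, expected k={k}")
    else:
        pairs = []
        clades = candidate_clades(nested)
        tries = 0
        while len(pairs) < k:
            tries += 1
            if tries > max_tries:
                raise GenerationError(
                    f"could not place {k} transfers under the separation "
                    f"constraints after {max_tries} tries"
                )
            d = clades[rng.integers(len(clades))]
            r = clades[rng.integers(len(clades))]
            if _comparable(d, r):
                continue
            sibs = siblings(nested, r) or []
            if d in sibs:  # prune+regraft would be a topological no-op
                continue
            if well_separated:
                d_sibs = siblings(nested, d) or []
                if r in d_sibs:
                    continue
                ok = True
                for pd, pr in pairs:
                    for new in (d, r):
                        for old in (pd, pr):
                            if new & old or _comparable(new, old):
                                ok = False
                    for old in (pd, pr):
                        if old in sibs or old in d_sibs:
                            ok = False
                if not ok:
                    continue
            pairs.append((d, r))

    gene = nested
    for d, r in pairs:
        if _find(gene, r) is None:
            raise GenerationError(
                f"recipient clade {sorted(r)} is not intact in the gene tree"
            )
        if _find(gene, d) is None:
            raise GenerationError(
                f"donor clade {sorted(d)} is not intact in the gene tree"
            )
        moved = _find(gene, r)
        gene = _prune(gene, r)
        gene = _graft_sister(gene, d, moved)

    fusion_branch = None
    fusion_states = None
    if plant_fusion:
        clades = candidate_clades(gene)
        pick = clades[rng.integers(len(clades))]
        fusion_branch = "+".join(sorted(pick))
        fusion_states = {l: (1 if l in pick else 0) for l in labels}

    return SyntheticHistory(
        species_tree=_nested_to_tree(nested),
        gene_tree=_nested_to_tree(gene),
        true_events=tuple(
            ("+".join(sorted(d)), "+".join(sorted(r))) for d, r in pairs
        ),
        fusion_gain_branch=fusion_branch,
        fusion_states=fusion_states,
        seed=seed,
    )


def add_sister_leaf(tree: dendropy.Tree, existing: str, new: str) -> dendropy.Tree:
    """Return a copy of ``tree`` with ``new`` grafted as sister of leaf
    ``existing`` (test helper for monotonicity properties)."""
    if new in leaf_labels(tree):
        raise InputError(f"leaf {new!r} already present")
    nested = _to_nested(tree)
    out = _graft_sister(nested, frozenset([existing]), new)
    return _nested_to_tree(out)
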