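"""Neighbor-joining trees from genetic distances, bootstrap support, Evanno dK.

The Saitou-Nei neighbor-joining algorithm reconstructs an unrooted tree
(represented with a trifurcating root) that exactly inverts any additive
distance matrix.  Branch support is the fraction of locus-bootstrap
replicates whose re-estimated tree contains the same bipartition.  The
Evanno table picks the number of genetic clusters K as the argmax of
dK = |L''(K)| / SD(L(K)) over replicate clustering log-likelihood runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix
from .markers import GenotypeTable, nei_distance

__all__ = [
    "TreeNode",
    "PhyloTree",
    "neighbor_joining",
    "bootstrap_support",
    "write_newick",
    "read_newick",
    "evanno_delta_k",
]

_NEEDS_QUOTE = set("()[]{}:;,' \t\n")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


@dataclass
class PhyloTree:
    """Unrooted tree stored with a (trifurcating) root node."""

    root: TreeNode
    n_clamped: int = 0  # negative NJ branch lengths clamped to zero

    @property
    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    def leaf_distances(self) -> DistanceMatrix:
        """Pairwise leaf-to-leaf path lengths (NJ inverse check)."""
        paths = {}

        def collect(node, path):
            if node.is_leaf:
                paths[node.name] = path + [node]
            for c in node.children:
                collect(c, path + [node])

        collect(self.root, [])
        names = self.leaf_names
        n = len(names)
        vals = np.zeros((n, n))
        lengths = {}

        def record(node):
            for c in node.children:
                lengths[id(c)] = c.length
                record(c)

        record(self.root)
        for i, j in itertools.combinations(range(n), 2):
            pa, pb = paths[names[i]], paths[names[j]]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            d = sum(lengths[id(x)] for x in pa[k:]) + sum(
                lengths[id(x)] for x in pb[k:])
            vals[i, j] = vals[j, i] = d
        return DistanceMatrix(names, vals)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, canonicalized to the side without the first leaf."""
        all_leaves = set(self.leaf_names)
        ref = min(all_leaves)
        out = set()

        def walk(node):
            side = {l.name for l in node.leaves()}
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset(all_leaves - side if ref in side else side))
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)
        return out

    def set_supports(self, support: dict[frozenset, float]) -> None:
        all_leaves = set(self.leaf_names)
        ref = min(all_leaves)

        def walk(node):
            side = {l.name for l in node.leaves()}
            if 2 <= len(side) <= len(all_leaves) - 2:
                key = frozenset(all_leaves - side if ref in side else side)
                node.support = support.get(key, 0.0)
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster labels (a cluster is labeled by its smallest leaf).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch; the clamp count is recorded on the result.
    """
    if len(dm) < 3:
        raise ValueError("need >= 3 labels")
    if dm.mask.any() or not np.isfinite(dm.values).all():
        raise ValueError("non-finite/masked distances: cap infinite Nei "
                         "distances before tree building")
    nodes = [TreeNode(name=l) for l in dm.labels]
    keys = [l for l in dm.labels]  # smallest leaf label per cluster
    D = dm.values.astype(float).copy()
    n_clamped = 0
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i, j in itertools.combinations(range(m), 2):
            q = (m - 2) * D[i, j] - r[i] - r[j]
            pair_key = tuple(sorted((keys[i], keys[j])))
            cand = (q, pair_key, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            n_clamped += 1
            li, lj = 0.0, D[i, j]
        elif lj < 0:
            n_clamped += 1
            li, lj = D[i, j], 0.0
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        new = TreeNode(children=[ni, nj])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        D = D2
    a, b, c = nodes
    la = (D[0, 1] + D[0, 2] - D[1, 2]) / 2
    lb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2
    lc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2
    for node, ln in zip((a, b, c), (la, lb, lc)):
        if ln < 0:
            n_clamped += 1
            ln = 0.0
        node.length = ln
    return PhyloTree(root=TreeNode(children=[a, b, c]), n_clamped=n_clamped)


def bootstrap_support(gt: GenotypeTable, n_boot: int = 1000,
                      seed: int | None = 0) -> PhyloTree:
    """NJ tree on Nei distance with locus-bootstrap bipartition supports.

    Loci are resampled with replacement; each replicate re-estimates the
    Nei distance matrix and its NJ tree.  Support on an internal edge is
    the fraction of usable replicates containing that bipartition.
    Replicates with an infinite Nei distance (no shared alleles at the
    resampled loci) are skipped and counted.
    """
    if len(gt.loci) < 2:
        raise ValueError("need >= 2 loci to bootstrap")
    base_dm = nei_distance(gt)
    if base_dm.mask.any():
        raise ValueError("infinite Nei distances in the full data: cap first")
    tree = neighbor_joining(base_dm)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    used = 0
    skipped = 0
    L = len(gt.loci)
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        sub = gt.subset_loci(idx)
        dm = nei_distance(sub)
        if dm.mask.any():
            skipped += 1
            continue
        used += 1
        for bp in neighbor_joining(dm).bipartitions():
            if bp in counts:
                counts[bp] += 1
    if used == 0:
        raise ValueError("all bootstrap replicates degenerate")
    tree.set_supports({bp: c / used for bp, c in counts.items()})
    tree.n_boot_used = used
    tree.n_boot_skipped = skipped
    return tree


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _quote(name: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _node_newick(node: TreeNode, with_length: bool = True) -> str:
    if node.is_leaf:
        s = _quote(node.name or "")
    else:
        s = "(" + ",".join(_node_newick(c, with_length)
                           for c in node.children) + ")"
        if node.support is not None:
            s += format(node.support, "g")
    if with_length:
        s += f":{node.length:.10g}"
    return s


def write_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths and supports as internal labels."""
    root = tree.root
    return ("(" + ",".join(_node_newick(c) for c in root.children) + ");")


class _NewickParser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def parse(self) -> TreeNode:
        node = self._subtree()
        self._expect(";")
        return node

    def _peek(self):
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _expect(self, ch):
        if self._peek() != ch:
            raise ValueError(f"expected {ch!r} at position {self.pos}")
        self.pos += 1

    def _subtree(self) -> TreeNode:
        node = TreeNode()
        if self._peek() == "(":
            self.pos += 1
            node.children.append(self._subtree())
            while self._peek() == ",":
                self.pos += 1
                node.children.append(self._subtree())
            self._expect(")")
            label = self._label()
            if label:
                node.support = float(label)
        else:
            node.name = self._label()
        if self._peek() == ":":
            self.pos += 1
            node.length = float(self._label())
        return node

    def _label(self) -> str:
        if self._peek() == "'":
            self.pos += 1
            out = []
            while True:
                ch = self.text[self.pos]
                if ch == "'":
                    if self.text[self.pos:self.pos + 2] == "''":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    break
                out.append(ch)
                self.pos += 1
            return "".join(out)
        out = []
        while self._peek() not in ("", "(", ")", ",", ":", ";"):
            out.append(self.text[self.pos])
            self.pos += 1
        return "".join(out)


def read_newick(text: str) -> PhyloTree:
    """Parse Newick written by :func:`write_newick` (round-trip identity)."""
    root = _NewickParser(text.strip()).parse()
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(runs: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno table from per-K replicate clustering log-likelihoods.

    L'(K) = mean L(K) - mean L(K-1); L''(K) = |L'(K+1) - L'(K)|;
    dK = L''(K) / SD(L(K)).  dK is defined only for interior K; a K with
    zero run SD gets NaN dK and ``sd_zero=True``.  The argmax K is stored
    in ``df.attrs['best_k']``.
    """
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError(f"need >= 2 runs per K (K={k})")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        lpp = (abs((mean[k + 1] - mean[k]) - (mean[k] - mean[k - 1]))
               if (k - 1 in mean and k + 1 in mean) else np.nan)
        dk = lpp / sd[k] if (np.isfinite(lpp) and sd[k] > 0) else np.nan
        rows.append((k, mean[k], sd[k], lp, lpp, dk,
                     bool(np.isfinite(lpp) and sd[k] == 0)))
    df = pd.DataFrame(rows, columns=["k", "mean_lnl", "sd_lnl", "lprime",
                                     "ldoubleprime", "delta_k", "sd_zero"])
    valid = df.dropna(subset=["delta_k"])
    df.attrs["best_k"] = int(valid.loc[valid["delta_k"].idxmax(), "k"]) \
        if len(valid) else None
    return df
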