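"""Rooted phylogeny as flat arrays, for fast pruning and simulation.

Branches are identified by their child node, following the convention that
a per-branch substitution table describes parent(i) -> i.  Newick parsing
is delegated to dendropy; internally the tree is a parent-index array with
a postorder traversal, which is what both the simulator and the
sum-product inference actually need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class Phylogeny:
    names: list                # node names, index = node id
    parent: np.ndarray         # parent id per node, -1 at root
    lengths: np.ndarray        # branch length above each node (0 at root)
    root: int = 0
    children: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.names)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if (self.parent == -1).sum() != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(np.flatnonzero(self.parent == -1)[0])
        self.children = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        names, parent, lengths = [], [], []
        n_anon = 0
        for nd in nodes:
            if nd.taxon is not None:
                names.append(nd.taxon.label)
            elif nd.label:
                names.append(nd.label)
            else:
                names.append(f"node{n_anon}")
                n_anon += 1
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            lengths.append(nd.edge.length or 0.0)
        return cls(names, np.array(parent), np.array(lengths))

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        def render(i):
            if not self.children[i]:
                body = self.names[i]
            else:
                body = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if self.parent[i] >= 0:
                body += f":{self.lengths[i]:g}"
            return body

        return render(self.root) + ";"

    # -- traversals ---------------------------------------------------------

    @property
    def n_nodes(self):
        return len(self.names)

    def postorder(self):
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        return order[::-1]

    def preorder(self):
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def leaves(self):
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def leaf_names(self):
        return [self.names[i] for i in self.leaves()]

    def branch_nodes(self):
        """Non-root nodes, each identifying the branch above it."""
        return [i for i in self.preorder() if i != self.root]

    def index(self, name):
        return self.names.index(name)
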