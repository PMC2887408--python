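"""Felsenstein independent contrasts on a fixed, user-supplied tree.

The comparative analyses treat each study group (eight castrator species
plus the two uninfected host genders) as a tip of a rooted bifurcating
tree.  Branch lengths default to one throughout, reflecting ignorance of
how evolution proceeds along these lineages, and contrasts are computed
by the standard pruning pass: a contrast is the difference between the
two daughter values scaled by the square root of their summed branch
variances, the ancestral value is the reciprocal-variance weighted mean
of the daughters, and the ancestor's own branch is extended by
v1*v2/(v1+v2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "Contrast",
    "ContrastSet",
    "read_tree",
    "independent_contrasts",
    "contrast_correlation",
]


@dataclass(frozen=True)
class PhyloTree:
    """Rooted bifurcating tree with unique tip labels and positive branch lengths."""

    tree: dendropy.Tree
    tip_labels: tuple[str, ...]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


@dataclass(frozen=True)
class Contrast:
    node_id: str
    raw_difference: float
    standardizing_variance: float
    standardized: float


@dataclass(frozen=True)
class ContrastSet:
    trait: str
    contrasts: tuple[Contrast, ...]

    @property
    def values(self) -> np.ndarray:
        return np.array([c.standardized for c in self.contrasts])

    def __len__(self) -> int:
        return len(self.contrasts)


def read_tree(newick: str, default_branch_length: float = 1.0) -> PhyloTree:
    """Parse a Newick string into a rooted bifurcating tree.

    Branch lengths absent from the Newick text are set to
    ``default_branch_length`` (one, by default).  Polytomies are
    rejected outright rather than arbitrarily resolved: with unit branch
    lengths an arbitrary resolution changes the contrasts, so resolution
    is left to the caller.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
        raise ValueError(f"duplicate tip labels: {err}") from err
    except Exception as err:
        raise ValueError(f"malformed Newick: {err}") from err
    tree.is_rooted = True
    labels: list[str] = []
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("every tip must carry a label")
            labels.append(node.taxon.label)
        elif len(children) != 2:
            raise ValueError(
                f"polytomy ({len(children)} children) at an internal node: "
                "the tree must be fully bifurcating; resolve it explicitly "
                "before computing contrasts"
            )
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = default_branch_length
        if node.parent_node is not None and node.edge.length <= 0:
            raise ValueError("branch lengths must be positive")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    return PhyloTree(tree=tree, tip_labels=tuple(labels))


def independent_contrasts(tree: PhyloTree, trait: dict[str, float],
                          name: str = "trait") -> ContrastSet:
    """Standardized independent contrasts of a tip trait.

    ``trait`` maps every tip label to its value.  Returns exactly
    ``n_tips - 1`` contrasts in post-order, each with its raw daughter
    difference and the standardizing variance (sum of the daughters'
    effective branch lengths, including pruning extensions).
    """
    missing = [t for t in tree.tip_labels if t not in trait]
    if missing:
        raise ValueError(f"missing trait value for tip(s): {', '.join(missing)}")

    contrasts: list[Contrast] = []
    value: dict[int, float] = {}
    # effective branch length above each node (extended during pruning)
    vlen: dict[int, float] = {}
    counter = 0
    for node in tree.tree.postorder_node_iter():
        nid = id(node)
        edge = node.edge.length if node.parent_node is not None else 0.0
        if node.is_leaf():
            value[nid] = float(trait[node.taxon.label])
            vlen[nid] = float(edge)
        else:
            left, right = node.child_nodes()
            x1, x2 = value[id(left)], value[id(right)]
            v1, v2 = vlen[id(left)], vlen[id(right)]
            counter += 1
            var = v1 + v2
            contrasts.append(
                Contrast(
                    node_id=f"node{counter}",
                    raw_difference=x1 - x2,
                    standardizing_variance=var,
                    standardized=(x1 - x2) / np.sqrt(var),
                )
            )
            value[nid] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
            vlen[nid] = float(edge) + v1 * v2 / (v1 + v2)
    return ContrastSet(trait=name, contrasts=tuple(contrasts))


def contrast_correlation(tree: PhyloTree, trait_x: dict[str, float],
                         trait_y: dict[str, float], iterations: int = 100_000,
                         seed: int | None = None):
    """Correlate independent contrasts of two traits.

    The x-contrast at each node is made positive (the paired y-contrast
    flips sign with it; the direction of subtraction at a node is
    arbitrary), then a randomization correlation test and a regression
    through the origin are run on the paired contrasts.  Returns
    ``(RandomizationResult, OriginRegression)``.
    """
    from . import comparative_stats as cs

    cx = independent_contrasts(tree, trait_x, "x").values
    cy = independent_contrasts(tree, trait_y, "y").values
    sign = np.where(cx < 0, -1.0, 1.0)
    cx, cy = cx * sign, cy * sign
    rand = cs.randomization_correlation(cx, cy, iterations=iterations, seed=seed)
    origin = cs.regression_through_origin(cx, cy)
    return rand, origin


# Illustrative 10-tip topology (synthetic stand-in, clearly not the
# study's published tree): eight castrator species in nested clades plus
# the two uninfected host genders as sister tips.
EXAMPLE_NEWICK = (
    "(((((hime:1,echi:1):1,(para:1,euha:1):1):1,(stic:1,pygi:1):1):1,"
    "(renc:1,smcy:1):1):1,(male:1,female:1):1);"
)
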