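"""Phylogenetic independent contrasts and contrast-based comparative tests.

Implements the comparative layer of the pipeline: standardized independent
contrasts via the classic pruning algorithm, the contrast-variance measure of
phylogenetic signal with a tip-shuffle randomization null, and through-origin
correlation of contrasts between traits.

Under Brownian-motion evolution the contrast between two sister lineages,
``(x_i - x_j) / sqrt(v_i + v_j)``, is a mean-zero normal variate independent
of every other contrast; low variance of the standardized contrasts relative
to a null in which trait values are shuffled across the tips indicates that
related species resemble each other (phylogenetic signal).
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats


class PhyloError(ValueError):
    """Raised for malformed trees or invalid comparative inputs."""


# Ordinal coding of the nesting guilds used when nesting strategy enters a
# contrast analysis as a numeric trait. The ordering dweller < tunneler <
# roller is an assumption; callers may supply their own map.
NESTING_CODES: dict[str, float] = {"dweller": 0.0, "tunneler": 1.0, "roller": 2.0}


@dataclasses.dataclass
class Node:
    """One node of a rooted bifurcating tree.

    ``length`` is the branch length of the edge above the node (None for the
    root). ``index`` is assigned in post-order by :class:`PhyloTree`.
    """

    length: float | None = None
    label: str | None = None
    children: list["Node"] = dataclasses.field(default_factory=list)
    index: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted, fully bifurcating tree with positive branch lengths.

    Tip labels must be unique and act as species identifiers. Polytomies,
    unifurcations (knuckles), and missing or non-positive branch lengths are
    rejected at construction because contrast standardization divides by the
    square root of branch lengths.
    """

    def __init__(self, root: Node):
        self.root = root
        self._postorder: list[Node] = []
        self._validate_and_index()

    def _validate_and_index(self) -> None:
        order: list[Node] = []
        stack = [self.root]
        seen_labels: set[str] = set()
        while stack:
            node = stack.pop()
            order.append(node)
            if node.is_tip:
                if not node.label:
                    raise PhyloError("unlabeled tip encountered")
                if node.label in seen_labels:
                    raise PhyloError(f"duplicate tip label {node.label!r}")
                seen_labels.add(node.label)
            else:
                if len(node.children) != 2:
                    where = node.label or self._nearest_tip_label(node)
                    kind = "polytomy" if len(node.children) > 2 else "unifurcation"
                    raise PhyloError(
                        f"unsupported topology: {kind} at node near {where!r} "
                        f"({len(node.children)} children); tree must be bifurcating"
                    )
                stack.extend(node.children)
            if node is not self.root:
                if node.length is None:
                    where = node.label or self._nearest_tip_label(node)
                    raise PhyloError(f"missing branch length on edge above {where!r}")
                if node.length <= 0:
                    where = node.label or self._nearest_tip_label(node)
                    raise PhyloError(
                        f"non-positive branch length ({node.length}) above {where!r}"
                    )
        # post-order: children before parents
        self._postorder = list(reversed(order))
        for i, node in enumerate(self._postorder):
            node.index = i

    @staticmethod
    def _nearest_tip_label(node: Node) -> str:
        cur = node
        while cur.children:
            cur = cur.children[0]
        return cur.label or "<unlabeled>"

    @property
    def postorder(self) -> list[Node]:
        return self._postorder

    @property
    def tips(self) -> list[Node]:
        return [n for n in self._postorder if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self._postorder if not n.is_tip]

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None:
                return f"{core}:{node.length:.12g}"
            return core

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree(n_tips={self.n_tips})"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Branch lengths are mandatory on every edge except above the root;
    polytomies raise :class:`PhyloError` rather than being resolved with
    zero-length branches.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhyloError(f"could not parse Newick input: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.is_leaf():
            label = dnode.label
        node = Node(length=dnode.edge.length, label=label)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.length = None  # a root edge length carries no information here
    return PhyloTree(root)


@dataclasses.dataclass
class ContrastSet:
    """Standardized independent contrasts for one trait on one tree.

    One contrast per internal node (``n_tips - 1`` in total), in post-order.
    ``variances`` holds the expected variance ``v_i + v_j`` used to
    standardize each contrast.
    """

    trait: str
    node_ids: np.ndarray
    contrasts: np.ndarray
    variances: np.ndarray

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)


def independent_contrasts(
    tree: PhyloTree, traits: Mapping[str, float], trait_name: str = ""
) -> ContrastSet:
    """Felsenstein's standardized contrasts by post-order pruning.

    At each internal node the contrast is ``(x_i - x_j)/sqrt(V_i + V_j)``
    where ``V`` is the branch length of a daughter plus any extra variance
    accumulated from estimating its value; the node is then assigned the
    ``1/V``-weighted mean of its daughters and its own branch is lengthened
    by ``V_i V_j / (V_i + V_j)``.
    """
    missing = [t for t in tree.tip_labels if t not in traits]
    if missing:
        raise PhyloError(f"missing trait values for tips: {', '.join(sorted(missing))}")

    x: dict[int, float] = {}
    v: dict[int, float] = {}
    node_ids, contrasts, variances = [], [], []
    for node in tree.postorder:
        blen = 0.0 if node.length is None else node.length
        if node.is_tip:
            x[node.index] = float(traits[node.label])  # type: ignore[index]
            v[node.index] = blen
        else:
            a, b = node.children
            va, vb = v[a.index], v[b.index]
            total = va + vb
            contrasts.append((x[a.index] - x[b.index]) / np.sqrt(total))
            variances.append(total)
            node_ids.append(node.index)
            x[node.index] = (x[a.index] / va + x[b.index] / vb) / (1 / va + 1 / vb)
            v[node.index] = blen + va * vb / total
    return ContrastSet(
        trait=trait_name,
        node_ids=np.asarray(node_ids, dtype=int),
        contrasts=np.asarray(contrasts, dtype=float),
        variances=np.asarray(variances, dtype=float),
    )


def contrast_variance(contrasts: ContrastSet) -> float:
    """Variance of the standardized contrasts (the signal statistic).

    Uses the mean-centred population variance (denominator ``n``). The choice
    of denominator rescales observed and null variances identically, leaving
    the randomization p-value unchanged. A single contrast is degenerate
    (its variance is identically 0) and is rejected.
    """
    if contrasts.n_contrasts < 2:
        raise PhyloError(
            "contrast variance requires at least 2 contrasts "
            f"(got {contrasts.n_contrasts}); a 2-tip tree is degenerate"
        )
    return float(np.var(contrasts.contrasts))


@dataclasses.dataclass
class SignalResult:
    """Outcome of the contrast-variance randomization test for one trait."""

    trait: str
    observed_variance: float
    null_variances: np.ndarray
    p_value: float
    n_randomizations: int
    seed: int
    two_tailed: bool = False


def signal_test(
    tree: PhyloTree,
    traits: Mapping[str, float],
    n_randomizations: int = 999,
    seed: int = 0,
    trait_name: str = "",
    two_tailed: bool = False,
) -> SignalResult:
    """Phylogenetic-signal test: observed contrast variance vs tip-shuffle null.

    The null distribution is built by shuffling trait values across tips with
    the topology fixed. The one-tailed p-value is the (add-one corrected)
    proportion of null variances less than or equal to the observed variance:
    low contrast variance means related species resemble each other. A
    two-tailed variant doubles the smaller tail.
    """
    if n_randomizations < 99:
        raise ValueError("n_randomizations must be at least 99")
    labels = tree.tip_labels
    values = np.array([float(traits[t]) for t in labels])
    if np.ptp(values) == 0:
        raise PhyloError(
            f"trait {trait_name or '<unnamed>'} is constant across tips; "
            "the randomization null is degenerate"
        )
    observed = contrast_variance(independent_contrasts(tree, traits, trait_name))
    rng = np.random.default_rng(seed)
    null = np.empty(n_randomizations)
    for i in range(n_randomizations):
        shuffled = dict(zip(labels, rng.permutation(values)))
        null[i] = contrast_variance(independent_contrasts(tree, shuffled, trait_name))
    p_low = (np.sum(null <= observed) + 1) / (n_randomizations + 1)
    if two_tailed:
        p_high = (np.sum(null >= observed) + 1) / (n_randomizations + 1)
        p = min(1.0, 2 * min(p_low, p_high))
    else:
        p = p_low
    return SignalResult(
        trait=trait_name,
        observed_variance=observed,
        null_variances=null,
        p_value=float(p),
        n_randomizations=n_randomizations,
        seed=seed,
        two_tailed=two_tailed,
    )


@dataclasses.dataclass
class PicResult:
    """Through-origin correlation between two traits' contrasts."""

    trait_x: str
    trait_y: str
    r: float
    p_parametric: float
    p_randomization: float | None
    n_contrasts: int


def pic_correlation(
    cx: ContrastSet,
    cy: ContrastSet,
    n_randomizations: int = 0,
    seed: int = 0,
) -> PicResult:
    """Correlation of two contrast sets constrained through the origin.

    ``r = sum(x*y)/sqrt(sum(x^2) sum(y^2))``; because contrasts have
    arbitrary sign the regression has no intercept. The parametric p comes
    from ``t = r sqrt((n-1)/(1-r^2))`` on ``n-1`` degrees of freedom; an
    optional randomization p flips contrast signs at random.
    """
    if not np.array_equal(cx.node_ids, cy.node_ids):
        raise PhyloError("contrast sets come from different trees or node orders")
    x, y = cx.contrasts, cy.contrasts
    n = len(x)
    sxx, syy = float(np.dot(x, x)), float(np.dot(y, y))
    if sxx == 0 or syy == 0:
        raise PhyloError("all-zero contrasts: correlation undefined")
    r = float(np.dot(x, y) / np.sqrt(sxx * syy))
    df = n - 1
    if abs(r) >= 1.0:
        p_param = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p_param = float(2 * stats.t.sf(abs(t), df))
    p_rand: float | None = None
    if n_randomizations > 0:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_randomizations, n))
        ry = signs * y
        r_null = (x @ ry.T) / np.sqrt(sxx * np.sum(ry**2, axis=1))
        p_rand = float((np.sum(np.abs(r_null) >= abs(r)) + 1) / (n_randomizations + 1))
    return PicResult(
        trait_x=cx.trait,
        trait_y=cy.trait,
        r=r,
        p_parametric=p_param,
        p_randomization=p_rand,
        n_contrasts=n,
    )


def encode_nesting(strategy: str, codes: Mapping[str, float] | None = None) -> float:
    """Ordinal numeric code for a nesting guild (dweller 0, tunneler 1, roller 2).

    Case-insensitive. The ordering is a documented convention, not a measured
    quantity; downstream reports flag it as a methodological caveat.
    """
    table = NESTING_CODES if codes is None else dict(codes)
    key = strategy.strip().lower()
    if key not in table:
        raise PhyloError(
            f"unknown nesting strategy {strategy!r}; expected one of {sorted(table)}"
        )
    return float(table[key])
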