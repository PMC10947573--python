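"""Phylogeny container, backbone grafting, phylogenetic covariance and Brownian simulation.

The central object is :class:`Phylogeny`, a thin wrapper around a rooted
:class:`dendropy.Tree` that enforces the invariants the rest of the package
relies on (unique tip labels, non-negative branch lengths, a single root) and
exposes the quantities comparative methods need: the shared path-length
(phylogenetic covariance) matrix ``C``, Pagel's lambda transform of ``C``,
Faith's phylogenetic diversity of a tip subset, and Brownian-motion trait
simulation with covariance ``rate * C``.

Grafting follows the BLADJ-style midpoint rule used when adding species that
are missing from a dated backbone tree: the new tip's stem attaches at the
midpoint of its sister lineage's subtending edge, and the terminal branch
length is chosen so the new tip is contemporaneous with its sister tips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "MissingTaxonError",
    "InfeasibleLambdaError",
    "GraftResult",
    "graft_missing_species",
    "covariance_matrix",
    "lambda_transform",
    "simulate_bm",
]


class MissingTaxonError(KeyError):
    """A requested tip label is not present in the tree."""


class InfeasibleLambdaError(ValueError):
    """The lambda-transformed covariance matrix is not positive semi-definite."""


class Phylogeny:
    """Rooted tree with branch lengths and unique tip labels.

    Branch lengths are in arbitrary time units. The root edge may carry no
    length (treated as 0); every other edge must have a non-negative length.
    Polytomies are permitted.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
            raise ValueError(f"duplicate tip labels in Newick: {err}") from err
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- basic properties -------------------------------------------------

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("every tip must carry a label")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("branch lengths are required on all edges")
            if edge.length < 0:
                raise ValueError(f"negative branch length: {edge.length}")

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def _node_depths(self) -> dict:
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = float(node.edge.length or 0.0)
            else:
                depths[node] = depths[node.parent_node] + float(node.edge.length)
        return depths

    def tip_depths(self) -> pd.Series:
        """Root-to-tip path length for every tip."""
        depths = self._node_depths()
        return pd.Series(
            {lf.taxon.label: depths[lf] for lf in self._tree.leaf_node_iter()}
        )

    # -- Faith's phylogenetic diversity -----------------------------------

    def faith_pd(self, tips, include_root_path: bool = True) -> float:
        """Sum of branch lengths of the minimal subtree spanning ``tips``.

        With ``include_root_path`` (default) the subtree is anchored at the
        root, so even a single-species community has positive diversity.
        """
        tipset = set(tips)
        known = set(self.tip_labels)
        unknown = tipset - known
        if unknown:
            raise MissingTaxonError(f"tips not in tree: {sorted(unknown)}")
        if not tipset:
            return 0.0
        # mark every node with whether its subtree contains a requested tip
        marked = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                marked[node] = node.taxon.label in tipset
            else:
                marked[node] = any(marked[c] for c in node.child_nodes())
        total = 0.0
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node or not marked[node]:
                continue
            total += float(node.edge.length)
        if not include_root_path:
            # subtract the chain of edges between the root and the MRCA of
            # the community (edges on which only one child path is marked)
            node = self._tree.seed_node
            while True:
                marked_children = [c for c in node.child_nodes() if marked[c]]
                if len(marked_children) != 1:
                    break
                total -= float(marked_children[0].edge.length)
                if marked_children[0].is_leaf():
                    break
                node = marked_children[0]
        return total


# -- covariance ----------------------------------------------------------


def covariance_matrix(tree: Phylogeny, tips=None) -> pd.DataFrame:
    """Shared path-length matrix: C[i, j] = depth of the MRCA of tips i, j.

    The diagonal holds root-to-tip depths. ``tips`` restricts (and orders)
    the result; unknown labels raise :class:`MissingTaxonError`.
    """
    dtree = tree.tree
    depths = tree._node_depths()
    leaves = list(dtree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    tip_sets: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tip_sets[node] = [i]
            C[i, i] = depths[node]
        else:
            groups = [tip_sets[c] for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        C[i, groups[b]] = d
                        C[np.ix_(groups[b], [i])] = d
            merged = [i for g in groups for i in g]
            tip_sets[node] = merged
    out = pd.DataFrame(C, index=labels, columns=labels)
    if tips is not None:
        tips = list(tips)
        unknown = [t for t in tips if t not in index]
        if unknown:
            raise MissingTaxonError(f"tips not in tree: {unknown}")
        out = out.loc[tips, tips]
    return out


def lambda_transform(C: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Pagel's lambda transform: off-diagonal entries scaled by ``lam``.

    ``lam`` must be non-negative; values above 1 are permitted as long as the
    result stays positive semi-definite (they arise when profiling the
    likelihood slightly beyond the Brownian case).
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    V = np.asarray(C, dtype=float)
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    if lam > 1:
        w = np.linalg.eigvalsh(out)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise InfeasibleLambdaError(
                f"lambda={lam} makes the covariance matrix indefinite"
            )
    if isinstance(C, pd.DataFrame):
        return pd.DataFrame(out, index=C.index, columns=C.columns)
    return out


def max_feasible_lambda(C: pd.DataFrame, upper: float = 1.5) -> float:
    """Largest lambda in [1, upper] keeping the transform positive definite."""
    def feasible(lam):
        try:
            V = lambda_transform(C, lam)
        except InfeasibleLambdaError:
            return False
        try:
            np.linalg.cholesky(np.asarray(V) + 1e-10 * np.eye(len(V)))
            return True
        except np.linalg.LinAlgError:
            return False

    if feasible(upper):
        return upper
    lo, hi = 1.0, upper
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo


def simulate_bm(
    tree: Phylogeny,
    rate: float,
    n_reps: int,
    seed=None,
    tips=None,
) -> pd.DataFrame:
    """Brownian-motion tip traits: ``n_reps`` draws from N(0, rate * C).

    The root state is 0. ``rate`` is the Brownian variance per unit branch
    length; ``rate = 0`` returns all-zero traits (the degenerate limit).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    C = covariance_matrix(tree, tips=tips)
    labels = list(C.columns)
    n = len(labels)
    rng = np.random.default_rng(seed)
    if rate == 0:
        return pd.DataFrame(np.zeros((n_reps, n)), columns=labels)
    L = np.linalg.cholesky(np.asarray(C) + 1e-12 * np.eye(n))
    Z = rng.standard_normal((n_reps, n))
    X = Z @ (np.sqrt(rate) * L.T)
    return pd.DataFrame(X, columns=labels)


# -- grafting ------------------------------------------------------------


@dataclass
class GraftResult:
    """Outcome of grafting missing species into a backbone."""

    tree: Phylogeny
    placed: list = field(default_factory=list)
    unplaced: list = field(default_factory=list)


def _genus_of(label: str, taxonomy_genus: dict) -> str | None:
    if label in taxonomy_genus:
        return taxonomy_genus[label]
    if "_" in label:
        return label.split("_", 1)[0]
    return None


def graft_missing_species(backbone: Phylogeny, taxonomy: pd.DataFrame) -> GraftResult:
    """Attach species missing from ``backbone`` inside their genus or family.

    ``taxonomy`` needs columns ``species``, ``genus`` and (optionally)
    ``family``. Each missing species is attached at the midpoint of the
    subtending edge of its anchor lineage (the genus crown group, or the
    single congeneric tip; the family crown if the genus is absent), with a
    terminal branch length making it contemporaneous with the anchor's tips.
    Species with no congeneric or confamilial anchor are returned in
    ``unplaced`` rather than dropped. Depths of pre-existing nodes are
    preserved.
    """
    required = {"species", "genus"}
    if not required.issubset(taxonomy.columns):
        raise ValueError(f"taxonomy needs columns {sorted(required)}")
    has_family = "family" in taxonomy.columns

    tax_genus = dict(zip(taxonomy["species"], taxonomy["genus"]))
    tax_family = (
        dict(zip(taxonomy["species"], taxonomy["family"])) if has_family else {}
    )
    genus_family = (
        dict(zip(taxonomy["genus"], taxonomy["family"])) if has_family else {}
    )

    work = backbone.copy()
    dtree = work.tree
    present = set(work.tip_labels)
    missing = sorted(set(taxonomy["species"]) - present)

    placed, unplaced = [], []
    for sp in missing:
        genus = tax_genus.get(sp)
        family = tax_family.get(sp)
        anchor_tips = _anchor_tips(dtree, genus, tax_genus, level="genus")
        if not anchor_tips and family:
            anchor_tips = _anchor_tips(
                dtree, family, tax_family, level="family", genus_family=genus_family,
                tax_genus=tax_genus,
            )
        if not anchor_tips:
            unplaced.append(sp)
            continue
        _graft_one(dtree, anchor_tips, sp)
        placed.append(sp)

    return GraftResult(tree=Phylogeny(dtree), placed=placed, unplaced=unplaced)


def _anchor_tips(dtree, name, sp_map, level, genus_family=None, tax_genus=None):
    """Leaf nodes whose taxonomy matches ``name`` at the given rank."""
    hits = []
    for lf in dtree.leaf_node_iter():
        lab = lf.taxon.label
        if level == "genus":
            if _genus_of(lab, sp_map) == name:
                hits.append(lf)
        else:
            fam = sp_map.get(lab)
            if fam is None and genus_family is not None:
                g = _genus_of(lab, tax_genus or {})
                fam = genus_family.get(g)
            if fam == name:
                hits.append(lf)
    return hits


def _graft_one(dtree, anchor_tips, new_label):
    depths = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = float(node.edge.length or 0.0)
        else:
            depths[node] = depths[node.parent_node] + float(node.edge.length)

    if len(anchor_tips) == 1:
        anchor = anchor_tips[0]
    else:
        anchor = _mrca_node(anchor_tips)

    # contemporaneity target: mean depth of the anchor's tips
    tip_depths = [depths[lf] for lf in anchor.leaf_iter()] if not anchor.is_leaf() \
        else [depths[anchor]]
    target_depth = float(np.mean(tip_depths))

    parent = anchor.parent_node
    if parent is None:
        # anchor is the whole tree: attach as a new child of the root
        attach = anchor
        attach_depth = depths[anchor]
    else:
        stem = float(anchor.edge.length)
        attach_depth = depths[parent] + stem / 2.0
        knee = dendropy.Node()
        parent.remove_child(anchor)
        parent.add_child(knee)
        knee.edge.length = stem / 2.0
        knee.add_child(anchor)
        anchor.edge.length = stem / 2.0
        attach = knee

    tip = dendropy.Node()
    tip.taxon = dtree.taxon_namespace.require_taxon(label=new_label)
    tip.edge.length = max(target_depth - attach_depth, 0.0)
    attach.add_child(tip)


def _mrca_node(nodes):
    chains = []
    for nd in nodes:
        chain, cur = [], nd
        while cur is not None:
            chain.append(cur)
            cur = cur.parent_node
        chains.append(chain)
    common = set(chains[0])
    for ch in chains[1:]:
        common &= set(ch)
    for nd in chains[0]:
        if nd in common:
            return nd
    raise RuntimeError("nodes share no ancestor")  # pragma: no cover
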