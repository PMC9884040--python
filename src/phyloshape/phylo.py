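"""Phylogeny handling: Newick I/O, pruning, and phylogenetic covariance.

Trees are wrapped around :mod:`dendropy` so that parsing, writing and
subtree extraction rely on a mature implementation; the covariance
construction and the Pagel-lambda transform are implemented here.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "CovarianceFamily",
    "NewickParseError",
    "TaxonMismatchError",
    "parse_newick",
    "lambda_transform",
    "taxa_overlap_report",
    "normalize_name",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be turned into a valid tree."""


class TaxonMismatchError(ValueError):
    """Raised when requested taxa are not present in the tree."""

    def __init__(self, missing: Iterable[str], message: str | None = None):
        self.missing = sorted(missing)
        super().__init__(
            message or f"taxa not found in tree: {', '.join(self.missing)}"
        )


def normalize_name(name: str) -> str:
    """Normalize a taxon label: strip quotes/whitespace, spaces -> underscores.

    Museum trait tables and published trees routinely disagree on
    ``Genus species`` vs ``Genus_species``; matching is exact and
    case-sensitive after this normalization.
    """
    return name.strip().strip("'\"").strip().replace(" ", "_")


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and unique, normalized tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = []
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise NewickParseError("tree has an unlabeled tip")
            leaf.taxon.label = normalize_name(leaf.taxon.label)
            labels.append(leaf.taxon.label)
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue  # a missing root edge is legal
            if edge.length is None:
                raise NewickParseError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if not np.isfinite(edge.length) or edge.length < 0:
                raise NewickParseError(f"invalid branch length {edge.length!r}")

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def write(self, path: str | Path | None = None) -> str:
        """Serialize to Newick; writes to *path* when given, returns the string."""
        text = self.tree.as_string(schema="newick", suppress_rooting=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip (root edge length included)."""
        out = {}
        base = self.tree.seed_node.edge.length or 0.0
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node is not self.tree.seed_node:
                d += node.edge.length
                node = node.parent_node
            out[leaf.taxon.label] = d + base
        return out

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        d = np.array(list(self.depths().values()))
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-10))

    def prune(self, keep: Iterable[str]) -> "Phylogeny":
        """Induced subtree on *keep*; root-to-tip depths are preserved."""
        keep = [normalize_name(k) for k in keep]
        if not keep:
            raise TaxonMismatchError([], "cannot prune to an empty taxon set")
        have = set(self.taxa)
        missing = [k for k in keep if k not in have]
        if missing:
            raise TaxonMismatchError(missing)
        sub = self.tree.extract_tree_with_taxa_labels(keep)
        return Phylogeny(sub)

    def vcv(self) -> "PhyloCovariance":
        """Brownian-motion covariance: shared root-to-MRCA path lengths."""
        if self.tree.seed_node is None:
            raise ValueError("rooting required to build a covariance matrix")
        taxa = self.taxa
        idx = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        V = np.zeros((n, n))
        base = self.tree.seed_node.edge.length or 0.0
        # depth per node, then each internal node sets the covariance of
        # every cross-child tip pair to its own depth
        depth: dict[int, float] = {id(self.tree.seed_node): base}
        tipsets: dict[int, list[int]] = {}
        for node in self.tree.preorder_node_iter():
            if node is not self.tree.seed_node:
                depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                tipsets[id(node)] = [i]
                V[i, i] = depth[id(node)]
            else:
                children = [tipsets[id(c)] for c in node.child_nodes()]
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        block = np.ix_(children[a], children[b])
                        V[block] = depth[id(node)]
                        V[np.ix_(children[b], children[a])] = depth[id(node)]
                tipsets[id(node)] = [i for c in children for i in c]
        return PhyloCovariance(taxa=taxa, V=V, lam=1.0)


def parse_newick(source: str | Path) -> Phylogeny:
    """Parse Newick text (or a file path) into a :class:`Phylogeny`."""
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(") and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


@dataclass
class PhyloCovariance:
    """Among-species covariance with an applied Pagel's lambda."""

    taxa: list[str]
    V: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        n = len(self.taxa)
        if self.V.shape != (n, n):
            raise ValueError("covariance shape does not match taxa")
        if not np.allclose(self.V, self.V.T):
            raise ValueError("covariance must be symmetric")

    def reorder(self, taxa: Sequence[str]) -> "PhyloCovariance":
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise TaxonMismatchError(missing)
        order = [idx[t] for t in taxa]
        return PhyloCovariance(list(taxa), self.V[np.ix_(order, order)], self.lam)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by ``lam``; diagonal unchanged."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = cov.V * lam
    np.fill_diagonal(V, np.diag(cov.V))
    return PhyloCovariance(cov.taxa, V, lam)


class CovarianceFamily:
    """The one-parameter family ``V(lam)`` used for profile-likelihood fits.

    When the base matrix has a constant diagonal (ultrametric tree),
    ``V(lam) = lam*V + (1-lam)*c*I`` shares eigenvectors with ``V``; one
    eigendecomposition then makes every lambda evaluation O(n) instead of a
    fresh Cholesky. Non-ultrametric trees fall back to a per-lambda
    factorization.
    """

    def __init__(self, cov: PhyloCovariance):
        self.taxa = list(cov.taxa)
        self.V = cov.V
        self.diag = np.diag(self.V).copy()
        self.n = len(self.taxa)
        self.const_diag = bool(
            np.allclose(self.diag, self.diag[0], rtol=1e-8, atol=1e-12)
        )
        if self.const_diag:
            evals, evecs = np.linalg.eigh(self.V)
            self._evals = np.clip(evals, 0.0, None)
            self._evecs = evecs
        else:
            self._evals = self._evecs = None

    @classmethod
    def from_tree(cls, tree: Phylogeny) -> "CovarianceFamily":
        return cls(tree.vcv())

    def matrix(self, lam: float) -> PhyloCovariance:
        return lambda_transform(PhyloCovariance(self.taxa, self.V, 1.0), lam)

    # --- whitening -------------------------------------------------------
    def rotate(self, A: np.ndarray) -> np.ndarray:
        """Rotate data into the eigenbasis (fast path only)."""
        assert self._evecs is not None
        return self._evecs.T @ A

    def scale(self, lam: float) -> np.ndarray:
        """Eigenvalues of V(lam) on the fast path."""
        assert self._evals is not None
        c = self.diag[0]
        return lam * self._evals + (1.0 - lam) * c

    def whitener(self, lam: float) -> tuple[np.ndarray, float]:
        """Return (W, logdet V(lam)) with W V(lam) W' = I."""
        if self.const_diag:
            e = self.scale(lam)
            if np.any(e <= 0):
                raise np.linalg.LinAlgError("V(lambda) is not positive definite")
            W = (self._evecs / np.sqrt(e)).T
            return W, float(np.sum(np.log(e)))
        Vl = self.matrix(lam).V
        L = np.linalg.cholesky(Vl)
        W = np.linalg.inv(L)
        return W, float(2.0 * np.sum(np.log(np.diag(L))))

    def sqrt(self, lam: float) -> np.ndarray:
        """A matrix L with L L' = V(lam), for simulating correlated noise."""
        if self.const_diag:
            e = self.scale(lam)
            return self._evecs * np.sqrt(np.clip(e, 0.0, None))
        return np.linalg.cholesky(self.matrix(lam).V)

    def subset(self, taxa: Sequence[str]) -> "CovarianceFamily":
        return CovarianceFamily(
            PhyloCovariance(self.taxa, self.V, 1.0).reorder(taxa)
        )


def taxa_overlap_report(
    data_taxa: Iterable[str], tree_taxa: Iterable[str]
) -> dict:
    """Compare species names in a trait table against tree tips.

    Returns a dict with the shared set and both one-sided mismatch lists
    (normalized names); also renders a human-readable text block.
    """
    data_set = {normalize_name(t) for t in data_taxa}
    tree_set = {normalize_name(t) for t in tree_taxa}
    shared = sorted(data_set & tree_set)
    only_data = sorted(data_set - tree_set)
    only_tree = sorted(tree_set - data_set)
    lines = [
        f"species shared by data and tree: {len(shared)}",
        f"species in data but not tree ({len(only_data)}): "
        + (", ".join(only_data) or "-"),
        f"species in tree but not data ({len(only_tree)}): "
        + (", ".join(only_tree) or "-"),
    ]
    return {
        "shared": shared,
        "data_only": only_data,
        "tree_only": only_tree,
        "text": "\n".join(lines),
    }
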