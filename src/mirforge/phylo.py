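"""Cross-species miRNA expression phylogeny.

Species are characterized by which catalogue miRNAs they express (any library
at the read threshold).  Pairwise distances are Jaccard distances on
presence/absence sets, or proportion-of-differing-columns on concatenated
mature sequences; the tree is average-linkage hierarchical clustering, with
branch support estimated by ordinary nonparametric bootstrap over characters
(miRNA columns).  Ordinary bootstrap proportions are used rather than
multiscale/AU resampling: supports are reported as plain percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform


@dataclass
class PresenceMatrix:
    presence: pd.DataFrame            # species x miRNA booleans
    expressed_counts: pd.Series       # per-species number of expressed miRNAs
    novel_vs_reference: pd.Series     # expressed here but not in the reference species


def build_presence_matrix(
    counts: pd.DataFrame,
    min_reads: int = 5,
    reference_species: str | None = None,
) -> PresenceMatrix:
    """Any-library presence calls from a (species, library) x miRNA count table.

    ``reference_species`` (default: first species) defines the
    "expressed here but not in the reference" counts reported alongside.
    """
    if counts.index.nlevels != 2:
        raise ValueError("counts must be indexed by (species, library)")
    hit = counts >= min_reads
    presence = hit.groupby(level="species", sort=True).any()
    if presence.shape[0] < 2:
        raise ValueError("need at least two species")
    ref = reference_species or presence.index[0]
    ref_absent = ~presence.loc[ref]
    return PresenceMatrix(
        presence=presence,
        expressed_counts=presence.sum(axis=1),
        novel_vs_reference=(presence & ref_absent).sum(axis=1),
    )


def species_distance(
    matrix: pd.DataFrame | dict[str, str],
    mode: str = "presence",
) -> pd.DataFrame:
    """Pairwise species distances.

    presence: Jaccard distance on the expressed-miRNA sets (species x miRNA
    boolean DataFrame).  sequence: proportion of differing characters over
    concatenated mature sequences (dict species -> equal-length string; gap
    '-' columns are ignored pairwise).
    """
    if mode == "presence":
        df = matrix.astype(bool)
        species = sorted(df.index)
        X = df.loc[species].to_numpy()
        if X.shape[0] < 2:
            raise ValueError("need at least two species")
        D = squareform(pdist(X, metric="jaccard"))
        D = np.nan_to_num(D)  # two all-empty species are identical
        return pd.DataFrame(D, index=species, columns=species)
    if mode == "sequence":
        species = sorted(matrix)
        rows = [matrix[sp] for sp in species]
        length = len(rows[0])
        if any(len(r) != length for r in rows):
            raise ValueError("concatenated sequences must be equal length")
        arr = np.array([list(r) for r in rows])
        D = np.zeros((len(species), len(species)))
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                ok = (arr[i] != "-") & (arr[j] != "-")
                D[i, j] = D[j, i] = (
                    float(np.mean(arr[i][ok] != arr[j][ok])) if ok.any() else 0.0
                )
        return pd.DataFrame(D, index=species, columns=species)
    raise ValueError(f"unknown mode {mode!r}")


def _clades_from_linkage(Z: np.ndarray, labels: list[str]) -> set[frozenset[str]]:
    """Leaf sets of all non-trivial internal nodes (excluding root and leaves)."""
    tree = to_tree(Z)
    clades: set[frozenset[str]] = set()

    def walk(node) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([labels[node.id]])
        left = walk(node.left)
        right = walk(node.right)
        clade = left | right
        if 1 < len(clade) < len(labels):
            clades.add(clade)
        return clade

    walk(tree)
    return clades


def _newick(node, labels: list[str], supports: dict[frozenset[str], float]) -> str:
    if node.is_leaf():
        return labels[node.id]

    def leafset(n) -> frozenset[str]:
        return frozenset(labels[i] for i in n.pre_order(lambda x: x.id))

    left = _newick(node.left, labels, supports)
    right = _newick(node.right, labels, supports)
    clade = leafset(node)
    label = ""
    if clade in supports:
        label = f"{supports[clade]:.0f}"
    return f"({left},{right}){label}:{node.dist:.4g}"


@dataclass
class BootTree:
    newick: str
    clades: set[frozenset[str]]
    supports: dict[frozenset[str], float]  # percentage per internal clade
    species: list[str]

    def min_support(self) -> float:
        return min(self.supports.values()) if self.supports else float("nan")


def _presence_linkage(X: np.ndarray, method: str) -> np.ndarray:
    d = pdist(X, metric="jaccard")
    return linkage(np.nan_to_num(d), method=method)


def bootstrap_tree(
    matrix: pd.DataFrame,
    n_boot: int = 1000,
    method: str = "average",
    seed: int = 0,
) -> BootTree:
    """Average-linkage tree over species with bootstrap clade supports.

    Characters (miRNA columns) are resampled with replacement ``n_boot``
    times; each internal bipartition's support is the percentage of
    replicates whose tree contains it.  Species are canonicalized to sorted
    order so the result is invariant to input row order.
    """
    df = matrix.astype(bool)
    species = sorted(df.index)
    if len(species) < 3:
        raise ValueError("need at least three species for a tree")
    X = df.loc[species].to_numpy()
    Z = _presence_linkage(X, method)
    clades = _clades_from_linkage(Z, species)

    rng = np.random.default_rng(seed)
    n_char = X.shape[1]
    hits = {c: 0 for c in clades}
    for _ in range(n_boot):
        cols = rng.integers(0, n_char, n_char)
        Zb = _presence_linkage(X[:, cols], method)
        boot_clades = _clades_from_linkage(Zb, species)
        for c in clades:
            if c in boot_clades:
                hits[c] += 1
    supports = {c: 100.0 * hits[c] / n_boot for c in clades}
    newick = _newick(to_tree(Z), species, supports) + ";"
    return BootTree(newick=newick, clades=clades, supports=supports, species=species)


def tree_clades_from_newick(newick: str) -> set[frozenset[str]]:
    """Non-trivial clades of a rooted newick tree (for topology comparison)."""
    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(newick), "newick")
    all_leaves = {t.name for t in tree.get_terminals()}
    clades = set()
    for cl in tree.get_nonterminals():
        leaves = frozenset(t.name for t in cl.get_terminals())
        if 1 < len(leaves) < len(all_leaves):
            clades.add(leaves)
    return clades
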