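"""Do the short amplicon regions separate species? K2P + neighbour joining.

Before trusting threshold-based identification, the amplicon-sized
reference regions are checked for a barcode gap: intraspecific K2P
distances must sit well below interspecific ones, and every species should
form its own clade in a bootstrapped neighbour-joining tree.

The Kimura 2-parameter distance for a pair of aligned sequences is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the proportions of transition and transversion differences
over the compared sites. Sites where either base is not a concrete
A/C/G/T are excluded pairwise from both numerator and denominator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np

_PURINES = {"A", "G"}
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


class SaturationError(ValueError):
    """K2P distance undefined: the log argument is non-positive."""


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance between two equal-length aligned sequences.

    Raises :class:`SaturationError` when the divergence is too large for
    the model ((1-2P-Q) ≤ 0 or (1-2Q) ≤ 0) and ValueError when no site is
    comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences must have equal length ({len(a)} vs {len(b)})")
    sites = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITION_PAIRS:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites (all ambiguous)")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"distance undefined (saturation): P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distance matrix with specimen labels.

    Saturated pairs (K2P undefined) hold NaN and are listed in
    ``excluded``; downstream tree building requires a fully finite matrix.
    """

    labels: list[str]
    d: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path, sep="\t")


def pairwise_matrix(seqs: Mapping[str, str]) -> DistanceMatrix:
    """Full pairwise K2P matrix over a label→sequence mapping."""
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences must be equal length; got lengths {sorted(lengths)}")
    n = len(labels)
    d = np.zeros((n, n))
    excluded = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = k2p_distance(seqs[labels[i]], seqs[labels[j]])
            except SaturationError:
                dij = math.nan
                excluded.append((labels[i], labels[j]))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d, excluded)


def neighbor_joining(m: DistanceMatrix, clamp_negative: bool = True) -> dendropy.Tree:
    """Saitou–Nei neighbour joining; recovers additive matrices exactly.

    Returns an unrooted dendropy tree. Negative branch-length estimates
    are clamped to zero with the deficit moved to the sibling branch
    (disable with ``clamp_negative=False``).
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(m.d).any():
        raise ValueError("matrix contains undefined (saturated) distances")

    taxa = dendropy.TaxonNamespace(m.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in m.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = m.d.copy()
    active = list(range(n))

    def _pair_lengths(li: float, lj: float) -> tuple[float, float]:
        if not clamp_negative:
            return li, lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 2:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest (i, j) in active order
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = _pair_lengths(li, lj)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # new distances to every other active node
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d[i, active] = new_row
        d[active, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j = active
    root = dendropy.Node()
    nodes[i].edge.length = max(d[i, j], 0.0) if clamp_negative else d[i, j]
    nodes[j].edge.length = 0.0
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _norm_split(mask: int, fill: int) -> int:
    """Canonical form of an unrooted bipartition bitmask (side containing taxon 0)."""
    return mask if (mask & 1) else (~mask) & fill


def _nontrivial_splits(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    n_taxa = len(tree.taxon_namespace)
    fill = (1 << n_taxa) - 1
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        mask = edge.bipartition.leafset_bitmask
        size = bin(mask).count("1")
        if 2 <= size <= n_taxa - 2:
            out.add(_norm_split(mask, fill))
    return out


def bootstrap_support(
    seqs: Mapping[str, str],
    B: int = 100,
    seed: int = 0,
    clamp_negative: bool = True,
) -> dendropy.Tree:
    """NJ tree with bootstrap support percentages on internal edges.

    Alignment columns are resampled with replacement ``B`` times; the
    support of each internal bipartition of the point-estimate tree is the
    percentage of replicate NJ trees containing it. Replicates whose
    resampled matrix is saturated or degenerate are counted as
    non-supporting. Deterministic for a given seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels = list(seqs)
    length = len(next(iter(seqs.values())))
    if length < 2:
        raise ValueError("alignment must have at least 2 columns")
    rng = np.random.default_rng(seed)
    arrays = {lab: np.frombuffer(seqs[lab].encode(), dtype="S1") for lab in labels}

    point = neighbor_joining(pairwise_matrix(seqs), clamp_negative)
    n_taxa = len(labels)
    fill = (1 << n_taxa) - 1
    point.encode_bipartitions()
    counts: dict[int, int] = {}
    edges = []
    for edge in point.preorder_edge_iter():
        if edge.bipartition is None or edge.head_node is point.seed_node:
            continue
        mask = edge.bipartition.leafset_bitmask
        size = bin(mask).count("1")
        if 2 <= size <= n_taxa - 2:
            key = _norm_split(mask, fill)
            counts[key] = 0
            edges.append((edge, key))

    for _ in range(B):
        cols = rng.integers(0, length, size=length)
        resampled = {lab: arrays[lab][cols].tobytes().decode() for lab in labels}
        try:
            rep = neighbor_joining(pairwise_matrix(resampled), clamp_negative)
        except (SaturationError, ValueError):
            continue
        rep_splits = _nontrivial_splits(rep)
        for key in counts:
            if key in rep_splits:
                counts[key] += 1

    for edge, key in edges:
        support = 100.0 * counts[key] / B
        node = edge.head_node
        if node is not None and node.taxon is None:
            node.label = f"{support:g}"
    return point


def species_monophyly(tree: dendropy.Tree, species_of: Mapping[str, str]) -> dict[str, float | None]:
    """Per-species: bootstrap support of its clade, or None if not monophyletic.

    Species with a single specimen are trivially monophyletic (support 100).
    """
    taxa = tree.taxon_namespace
    tree.encode_bipartitions()
    fill = (1 << len(taxa)) - 1
    split_support: dict[int, float] = {}
    splits: set[int] = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        mask = _norm_split(edge.bipartition.leafset_bitmask, fill)
        splits.add(mask)
        node = edge.head_node
        if node is not None and node.label is not None and node.taxon is None:
            split_support[mask] = float(node.label)
    out: dict[str, float | None] = {}
    for sp in sorted(set(species_of.values())):
        members = [t for t in taxa if species_of[t.label] == sp]
        if len(members) == 1 or len(members) >= len(taxa) - 1:
            out[sp] = 100.0  # single-specimen or trivial split: always present
            continue
        mask = 0
        for t in members:
            mask |= taxa.taxon_bitmask(t)
        norm = _norm_split(mask, fill)
        out[sp] = split_support.get(norm, 100.0) if norm in splits else None
    return out


def divergence_summary(db) -> dict[str, dict[str, tuple[float, float] | None]]:
    """Min/max of per-species mean intra- and per-pair mean inter-specific
    K2P distance, in percent, per gene.

    ``db`` is a ReferenceDB of equal-length amplicon regions. Species with
    a single record contribute nothing to the intra summary; a single
    species yields no inter summary. Saturated pairs are skipped.
    """
    from .refdb import GENES

    out: dict[str, dict[str, tuple[float, float] | None]] = {}
    for gene in GENES:
        recs = db.by_gene(gene)
        if not recs:
            continue
        by_species: dict[str, list[str]] = {}
        for r in recs:
            by_species.setdefault(r.species, []).append(r.sequence)
        intra_means = []
        for sp, seqs in sorted(by_species.items()):
            if len(seqs) < 2:
                continue
            ds = []
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    try:
                        ds.append(k2p_distance(seqs[i], seqs[j]))
                    except SaturationError:
                        pass
            if ds:
                intra_means.append(float(np.mean(ds)))
        species = sorted(by_species)
        inter_means = []
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                ds = []
                for a in by_species[species[i]]:
                    for b in by_species[species[j]]:
                        try:
                            ds.append(k2p_distance(a, b))
                        except SaturationError:
                            pass
                if ds:
                    inter_means.append(float(np.mean(ds)))
        out[gene] = {
            "intra": (100 * min(intra_means), 100 * max(intra_means)) if intra_means else None,
            "inter": (100 * min(inter_means), 100 * max(inter_means)) if inter_means else None,
        }
    return out
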