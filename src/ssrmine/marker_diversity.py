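"""Marker polymorphism and genetic-similarity analysis.

Takes a band matrix scored from PAGE gels (accessions × SSR markers, each
cell a set of band sizes or "no amplification"), computes per-marker
polymorphism information content PIC = 1 − Σ pᵢ², Jaccard similarity
between accessions over binary band presence, and a UPGMA dendrogram with
Newick export. Heights on the dendrogram are the similarity at each merge;
Newick branch lengths are on the distance scale d = 1 − S, with node
heights d/2 so the cophenetic distance between two leaves equals one minus
their merge similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MarkerPolymorphism",
    "SimilarityMatrix",
    "DendrogramNode",
    "score_alleles",
    "mean_alleles_per_marker",
    "pic",
    "jaccard_similarity",
    "upgma",
    "to_newick",
    "write_newick",
]

NO_AMP = None  # sentinel for "no amplification" (missing), not "no shared bands"


@dataclass
class GenotypeMatrix:
    """Band calls for accessions × markers.

    ``bands[(marker, accession)]`` is a frozenset of band sizes (bp);
    a missing key or ``None`` means the primer did not amplify in that
    accession — distinct from amplifying but sharing no bands with another
    accession.
    """

    accessions: list[str]
    markers: list[str]
    bands: dict[tuple[str, str], frozenset | None]

    def __post_init__(self):
        if len(self.accessions) < 2:
            raise ValueError("need at least 2 accessions")
        if not self.markers:
            raise ValueError("need at least 1 marker")
        for key, val in self.bands.items():
            if val is not None and any(b <= 0 for b in val):
                raise ValueError(f"non-positive band size at {key}")

    def bands_for(self, marker: str, accession: str):
        return self.bands.get((marker, accession), NO_AMP)

    def accession_profile(self, accession: str) -> frozenset:
        """All (marker, band) presences of one accession (binary encoding)."""
        out = set()
        for m in self.markers:
            b = self.bands_for(m, accession)
            if b:
                out.update((m, size) for size in b)
        return frozenset(out)

    @classmethod
    def from_long_csv(cls, path) -> "GenotypeMatrix":
        """Read long-format CSV with columns marker, accession, band_size.

        An empty or ``NA`` band_size row records explicit non-amplification.
        """
        df = pd.read_csv(path, dtype={"marker": str, "accession": str})
        markers = list(dict.fromkeys(df["marker"]))
        accessions = list(dict.fromkeys(df["accession"]))
        bands: dict[tuple[str, str], set | None] = {}
        for _, row in df.iterrows():
            key = (row["marker"], row["accession"])
            if pd.isna(row["band_size"]):
                bands.setdefault(key, None)
            else:
                cur = bands.get(key)
                cur = set() if cur is None else set(cur or ())
                cur.add(int(row["band_size"]))
                bands[key] = cur
        frozen = {k: (frozenset(v) if v is not None else None) for k, v in bands.items()}
        return cls(accessions, markers, frozen)

    def to_long_csv(self, path) -> None:
        rows = []
        for m in self.markers:
            for a in self.accessions:
                b = self.bands_for(m, a)
                if b is NO_AMP:
                    rows.append({"marker": m, "accession": a, "band_size": pd.NA})
                else:
                    for size in sorted(b):
                        rows.append({"marker": m, "accession": a, "band_size": size})
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class MarkerPolymorphism:
    marker: str
    n_alleles: int
    allele_freqs: tuple[float, ...]
    pic: float


def pic(allele_freqs: Sequence[float]) -> float:
    """Polymorphism information content, 1 − Σ pᵢ².

    0 for a monomorphic marker, at most 1 − 1/k for k equally frequent
    alleles.
    """
    freqs = np.asarray(allele_freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("allele frequencies must be positive")
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError(f"allele frequencies sum to {freqs.sum()}, not 1")
    return float(1.0 - np.sum(freqs**2))


def score_alleles(matrix: GenotypeMatrix) -> list[MarkerPolymorphism]:
    """Per-marker allele counts, frequencies and PIC.

    Alleles are the distinct band sizes observed among amplifying
    accessions; pᵢ is the fraction of allele observations that are allele i
    (non-amplification is treated as missing data, not a null allele).
    Markers that amplify in no accession are excluded with a warning.
    """
    out = []
    for m in matrix.markers:
        carriers: dict[int, int] = {}
        for a in matrix.accessions:
            b = matrix.bands_for(m, a)
            if b:
                for size in b:
                    carriers[size] = carriers.get(size, 0) + 1
        if not carriers:
            warnings.warn(f"marker {m!r} amplified in no accession; excluded")
            continue
        total = sum(carriers.values())
        freqs = tuple(carriers[size] / total for size in sorted(carriers))
        out.append(MarkerPolymorphism(m, len(carriers), freqs, pic(freqs)))
    return out


def mean_alleles_per_marker(polymorphisms: Sequence[MarkerPolymorphism]) -> float:
    """Mean allele count across markers, 2 decimals (74 alleles over 32
    markers reports 2.31)."""
    from .catalogue_stats import round2

    if not polymorphisms:
        raise ValueError("no markers")
    return round2(sum(p.n_alleles for p in polymorphisms) / len(polymorphisms))


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("similarities must lie in [0, 1]")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def jaccard_similarity(matrix: GenotypeMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard similarity over binary (marker, band) presence.

    S(x, y) = a / (a + b + c): shared bands over the union of bands scored
    in either accession. Pairs with an empty union get similarity 0 with a
    warning (nothing was comparable).
    """
    profiles = {a: matrix.accession_profile(a) for a in matrix.accessions}
    n = len(matrix.accessions)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = profiles[matrix.accessions[i]], profiles[matrix.accessions[j]]
            union = len(pi | pj)
            if union == 0:
                warnings.warn(
                    f"accessions {matrix.accessions[i]!r}/{matrix.accessions[j]!r}"
                    " share no scored bands; similarity set to 0"
                )
                s = 0.0
            else:
                s = len(pi & pj) / union
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(list(matrix.accessions), values)


@dataclass(frozen=True)
class DendrogramNode:
    """Leaf (``name`` set) or internal node with two children and the
    similarity at which they merged (1.0 at leaves)."""

    height: float
    name: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return self.children[0].leaves() + self.children[1].leaves()


def upgma(sim: SimilarityMatrix) -> DendrogramNode:
    """UPGMA tree over a similarity matrix.

    Repeatedly merges the most similar pair of clusters; the similarity of
    a merged cluster to any other is the size-weighted arithmetic mean of
    its members' similarities (equivalently, the mean over all leaf pairs).
    Node height is the similarity at the merge, so heights are
    non-increasing from leaves (height 1) to the root. Ties break on the
    lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest accession id), making trees reproducible.
    """
    n = len(sim.ids)
    if n < 2:
        raise ValueError("need at least 2 accessions")
    clusters = {
        i: (DendrogramNode(height=1.0, name=sim.ids[i]), 1, sim.ids[i])
        for i in range(n)
    }
    s = {
        (i, j): float(sim.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        sij = max(s.values())
        # deterministic tie-break: among equal similarities prefer the
        # lexicographically smallest (label_i, label_j) pair
        ties = [k for k, v in s.items() if v == sij]
        i, j = min(ties, key=lambda k: tuple(sorted((clusters[k[0]][2], clusters[k[1]][2]))))
        node_i, size_i, lab_i = clusters.pop(i)
        node_j, size_j, lab_j = clusters.pop(j)
        merged = DendrogramNode(height=sij, children=(node_i, node_j))
        for k in list(clusters):
            ski = s.pop((min(i, k), max(i, k)))
            skj = s.pop((min(j, k), max(j, k)))
            s[(min(next_id, k), max(next_id, k))] = (
                size_i * ski + size_j * skj
            ) / (size_i + size_j)
        for key in [k for k in s if i in k or j in k]:
            del s[key]
        clusters[next_id] = (merged, size_i + size_j, min(lab_i, lab_j))
        next_id += 1
    (root, _, _), = clusters.values()
    return root


def _fmt(x: float) -> str:
    out = f"{x:.6f}".rstrip("0").rstrip(".")
    return out or "0"


def _newick(node: DendrogramNode, parent_dist: float) -> str:
    # node height on the distance scale: d = (1 - similarity) / 2
    d = (1.0 - node.height) / 2.0
    branch = parent_dist - d
    if node.is_leaf:
        return f"{node.name}:{_fmt(branch)}"
    inner = ",".join(_newick(c, d) for c in node.children)
    return f"({inner}):{_fmt(branch)}"


def to_newick(tree: DendrogramNode) -> str:
    """Newick string with ultrametric branch lengths on the 1 − S scale."""
    if tree.is_leaf:
        raise ValueError("cannot serialize a single leaf as a dendrogram")
    d_root = (1.0 - tree.height) / 2.0
    inner = ",".join(_newick(c, d_root) for c in tree.children)
    return f"({inner});"


def write_newick(tree: DendrogramNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
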