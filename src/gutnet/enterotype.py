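"""Community typing: sqrt-Jensen-Shannon distances, complete-linkage
clustering, silhouette model selection, PCoA ordination, and repeat-sample
stability.

The community-typing procedure is: compute the Jensen-Shannon divergence
between every pair of genus-level relative-abundance profiles, take its
square root (a metric), cluster the samples by agglomerative complete
linkage, and cut the dendrogram into its top-level clades.  Mean silhouette
width over candidate k gauges whether the data support discrete clusters or
a gradient.  Classical multidimensional scaling (PCoA) of the same distance
matrix provides the ordination view.

The complete-linkage clusterer and silhouette are authored here (with
deterministic tie-breaks) rather than delegated, because the merge history
and its exact tie behaviour are part of the analysis contract; PCoA is
delegated to scikit-bio's implementation of Gower centering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import CommunityProfile
from .exceptions import AlignmentError, GutnetError

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "OrdinationResult",
    "jsd",
    "jsd_matrix",
    "hclust_complete",
    "cut_top_clades",
    "mean_silhouette",
    "silhouette_widths",
    "pcoa",
    "stability",
    "StabilityResult",
]

#: Upper bound of sqrt-JSD in nats.
SQRT_LN2 = math.sqrt(math.log(2.0))


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise GutnetError("distance matrix shape does not match ids")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise GutnetError("distance matrix is not symmetric")
        if np.max(np.abs(np.diag(self.values))) > 1e-12:
            raise GutnetError("distance matrix diagonal is not zero")
        if np.min(self.values) < 0:
            raise GutnetError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index.astype(str)), frame.to_numpy(dtype=float))


def _entropy_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise Shannon entropy in nats with 0*log0 == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=-1)


def jsd(p: CommunityProfile | np.ndarray, q: CommunityProfile | np.ndarray) -> float:
    """Jensen-Shannon divergence (nats) between two aligned simplex vectors.

    JSD(p, q) = H((p+q)/2) - (H(p) + H(q))/2, bounded by [0, ln 2].
    """
    if isinstance(p, CommunityProfile) and isinstance(q, CommunityProfile):
        if list(p.abundances.index) != list(q.abundances.index):
            raise AlignmentError("profiles have mismatched taxon sets")
        pv, qv = p.values, q.values
    else:
        pv = np.asarray(p, dtype=float)
        qv = np.asarray(q, dtype=float)
        if pv.shape != qv.shape:
            raise AlignmentError("profiles have mismatched lengths")
    m = 0.5 * (pv + qv)
    val = float(_entropy_rows(m) - 0.5 * (_entropy_rows(pv) + _entropy_rows(qv)))
    return min(max(val, 0.0), math.log(2.0))


def jsd_matrix(profiles: Sequence[CommunityProfile] | pd.DataFrame) -> DistanceMatrix:
    """Pairwise sqrt-JSD distance matrix.

    Accepts a list of profiles or a taxa-by-samples relative-abundance frame.
    """
    if isinstance(profiles, pd.DataFrame):
        ids = [str(c) for c in profiles.columns]
        mat = profiles.to_numpy(dtype=float).T
    else:
        if len(profiles) < 2:
            raise GutnetError("need at least two profiles")
        idx0 = list(profiles[0].abundances.index)
        for prof in profiles[1:]:
            if list(prof.abundances.index) != idx0:
                raise AlignmentError(
                    f"profile {prof.sample_id!r} has mismatched taxon set"
                )
        ids = [prof.sample_id for prof in profiles]
        mat = np.vstack([prof.values for prof in profiles])
    n = mat.shape[0]
    if n < 2:
        raise GutnetError("need at least two profiles")
    h = _entropy_rows(mat)
    out = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        m = 0.5 * (mat[i][None, :] + mat[i + 1:])
        div = _entropy_rows(m) - 0.5 * (h[i] + h[i + 1:])
        out[i, i + 1:] = np.sqrt(np.clip(div, 0.0, math.log(2.0)))
    out = out + out.T
    return DistanceMatrix(ids, out)


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` has one row per merge: (left id, right id, height, new size),
    with original samples numbered 0..n-1 and the i-th merge creating cluster
    n+i (the linkage-matrix convention).
    """

    ids: list[str]
    merges: np.ndarray  # (n-1, 4)

    @property
    def n(self) -> int:
        return len(self.ids)

    def linkage(self) -> np.ndarray:
        """The merge history as a (n-1, 4) float array (scipy layout)."""
        return np.asarray(self.merges, dtype=float)


def hclust_complete(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative complete-linkage clustering with deterministic tie-breaks.

    At each step the pair of active clusters with the smallest complete-link
    distance merges; exact ties break on the lexicographically smallest
    (cluster id, cluster id) pair.  Heights are non-decreasing.
    """
    n = d.n
    if n < 2:
        raise GutnetError("need at least two samples to cluster")
    # working distance matrix indexed by active cluster slots
    work = d.values.copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))          # slot -> currently active?
    cluster_id = list(range(n))      # slot -> cluster id (linkage numbering)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4), dtype=float)
    alive = np.ones(n, dtype=bool)
    for step in range(n - 1):
        sub = np.where(alive)[0]
        block = work[np.ix_(sub, sub)]
        mval = block.min()
        # deterministic tie-break: smallest (id_a, id_b) among minimal pairs
        cand = np.argwhere(np.isclose(block, mval, rtol=0.0, atol=0.0))
        best = None
        for a, b in cand:
            if a >= b:
                continue
            ia, ib = sub[a], sub[b]
            ca, cb = sorted((cluster_id[ia], cluster_id[ib]))
            if best is None or (ca, cb) < best[:2]:
                best = (ca, cb, ia, ib)
        assert best is not None
        ca, cb, ia, ib = best
        new_id = n + step
        size = len(members[ia]) + len(members[ib])
        merges[step] = (ca, cb, mval, size)
        # complete-linkage (Lance-Williams max) update into slot ia
        row = np.maximum(work[ia], work[ib])
        work[ia, :] = row
        work[:, ia] = row
        work[ia, ia] = np.inf
        work[ib, :] = np.inf
        work[:, ib] = np.inf
        alive[ib] = False
        members[ia] = members[ia] + members[ib]
        del members[ib]
        cluster_id[ia] = new_id
    return Dendrogram(list(d.ids), merges)


@dataclass
class ClusterAssignment:
    """Sample -> group label (1..k) with the rule that produced it."""

    labels: pd.Series  # index: sample ids, values 1..k
    k: int
    provenance: str  # "clade-cut" or "dominant-taxon"

    def __post_init__(self) -> None:
        got = sorted(set(int(v) for v in self.labels))
        if got != list(range(1, self.k + 1)):
            raise GutnetError(
                f"labels must be contiguous 1..{self.k}, got {got}"
            )

    def groups(self) -> dict[int, list[str]]:
        return {
            g: list(self.labels.index[self.labels == g])
            for g in range(1, self.k + 1)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.labels, "provenance": self.provenance}
        ).rename_axis("sample_id")


def cut_top_clades(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into its k top-level clades (drop the k-1 highest merges).

    Groups are renumbered 1..k by the smallest sample index they contain.
    """
    n = dend.n
    if not 1 <= k <= n:
        raise GutnetError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):  # keep out the k-1 last (highest) merges
        a, b, _, _ = dend.merges[step]
        ra, rb = find(int(a)), find(int(b))
        parent[ra] = n + step
        parent[rb] = n + step
    roots: dict[int, int] = {}
    raw = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        raw[i] = roots[r]
    labels = pd.Series(raw, index=dend.ids, name="group")
    return ClusterAssignment(labels, k, "clade-cut")


def silhouette_widths(d: DistanceMatrix, a: ClusterAssignment) -> pd.Series:
    """Per-sample silhouette widths s(i) = (b-a)/max(a,b); singletons get 0."""
    if a.k < 2:
        raise GutnetError("silhouette undefined for a single cluster")
    labels = a.labels.reindex(d.ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise GutnetError(f"samples without a group label: {missing[:5]}")
    lab = labels.to_numpy(dtype=int)
    dist = d.values
    out = np.zeros(d.n, dtype=float)
    for i in range(d.n):
        own = lab == lab[i]
        n_own = own.sum()
        if n_own == 1:  # singleton cluster
            out[i] = 0.0
            continue
        a_i = dist[i, own].sum() / (n_own - 1)
        b_i = np.inf
        for g in range(1, a.k + 1):
            if g == lab[i]:
                continue
            other = lab == g
            if other.any():
                b_i = min(b_i, dist[i, other].mean())
        if a_i == 0.0 and b_i == 0.0:
            out[i] = 0.0
        else:
            out[i] = (b_i - a_i) / max(a_i, b_i)
    return pd.Series(out, index=d.ids, name="silhouette")


def mean_silhouette(d: DistanceMatrix, a: ClusterAssignment) -> float:
    """Mean silhouette width over all samples, in [-1, 1]."""
    return float(silhouette_widths(d, a).mean())


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalues and per-axis variance fractions."""

    coordinates: pd.DataFrame  # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix, ndim: int = 2) -> OrdinationResult:
    """Classical multidimensional scaling (principal coordinates).

    Gower double-centering of -0.5 * D^2 followed by eigendecomposition; only
    axes with positive eigenvalues are returned, so fewer than ``ndim`` axes
    may come back (with a warning).
    """
    if ndim < 1:
        raise GutnetError("ndim must be >= 1")
    from skbio.stats.ordination import pcoa as _skbio_pcoa
    from skbio import DistanceMatrix as _SkbioDM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(_SkbioDM(d.values, ids=d.ids), method="eigh")
    eig = res.eigvals.to_numpy(dtype=float)
    positive = eig > max(1e-12, 1e-10 * abs(eig).max())
    n_pos = int(positive.sum())
    if ndim > n_pos:
        warnings.warn(
            f"requested {ndim} axes but only {n_pos} positive eigenvalues; "
            f"returning {n_pos}",
            stacklevel=2,
        )
        ndim = n_pos
    coords = res.samples.iloc[:, :ndim].copy()
    coords.columns = [f"PC{i + 1}" for i in range(ndim)]
    coords.index = pd.Index(d.ids, name="sample_id")
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig[:ndim],
        proportion_explained=res.proportion_explained.to_numpy(dtype=float)[:ndim],
    )


@dataclass
class StabilityResult:
    """Fraction of repeat samples whose label persisted, plus the transition table."""

    fraction_unchanged: float
    n_pairs: int
    transitions: pd.DataFrame  # first-label x second-label counts


def stability(
    first: Mapping[str, str] | pd.Series,
    second: Mapping[str, str] | pd.Series,
    pair_map: Mapping[str, str],
) -> StabilityResult:
    """Label stability across repeat samples.

    ``pair_map`` maps each second-visit sample id to its first-visit sample
    id; labels may be cluster groups or dominant-taxon categories.
    """
    first = pd.Series(first)
    second = pd.Series(second)
    if len(pair_map) == 0:
        raise GutnetError("no repeat pairs supplied")
    rows = []
    for second_id, first_id in pair_map.items():
        if second_id not in second.index:
            raise GutnetError(f"unmapped second-visit sample {second_id!r}")
        if first_id not in first.index:
            raise GutnetError(f"unmapped first-visit sample {first_id!r}")
        rows.append((first[first_id], second[second_id]))
    cats = sorted({c for pair in rows for c in pair})
    trans = pd.DataFrame(0, index=cats, columns=cats)
    unchanged = 0
    for a, b in rows:
        trans.loc[a, b] += 1
        unchanged += int(a == b)
    trans.index.name = "first"
    trans.columns.name = "second"
    return StabilityResult(unchanged / len(rows), len(rows), trans)
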