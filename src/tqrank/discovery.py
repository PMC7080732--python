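"""Per-gene ON/OFF pattern calling and Transquartile Range ranking.

Rather than clustering cells once for the whole dataset, each gene is
analysed separately: the known cell types are grouped into an ON and an
OFF class by single-linkage hierarchical clustering of their replicate
φ vectors (Euclidean distance), stopping one step before the final merge
so that exactly two top-level clusters remain.  Because single linkage
merges by minimum pairwise distance, this two-cluster cut is equivalent to
deleting the heaviest edge of a minimum spanning tree over the cell types.

Each call is scored with the Transquartile Range (TQR): the first quartile
of the ON cluster's values minus the third quartile of the OFF cluster's
values, with quartiles computed by the "hydrologist" type-5 linear
interpolation.  The TQR grows with the separation of the cluster means and
shrinks as within-cluster spread grows, without any parametric model of
dispersion.  Genes are ranked by TQR descending.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import PatternCall, SampleSheet
from .transform import PhiMatrix


@dataclass
class GeneProfile:
    """One gene's φ values as a cell types × embryos matrix.

    The embryo (replicate) order is fixed and identical across cell types,
    so rows are directly comparable as vectors.
    """

    gene_id: str
    values: np.ndarray
    cell_types: tuple[str, ...]
    embryos: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_types), len(self.embryos)):
            raise ValueError(
                f"gene {self.gene_id}: values shape {self.values.shape} does not "
                f"match {len(self.cell_types)} cell types × {len(self.embryos)} embryos"
            )
        if np.any(np.isnan(self.values)):
            raise ValueError(f"gene {self.gene_id}: missing replicate values")


@dataclass
class TwoClusterCut:
    """The two top-level single-linkage clusters (as index tuples) and the
    linkage distance of the final, skipped merge."""

    cluster_a: tuple[int, ...]
    cluster_b: tuple[int, ...]
    merge_height: float

    def __post_init__(self) -> None:
        a, b = set(self.cluster_a), set(self.cluster_b)
        if not a or not b or a & b:
            raise ValueError("clusters must be disjoint and non-empty")


def celltype_distances(profile: GeneProfile) -> np.ndarray:
    """Euclidean distance between the replicate vectors of every pair of
    cell types; symmetric with zero diagonal."""
    return squareform(pdist(profile.values, metric="euclidean"))


def single_linkage_two_cut(d: np.ndarray) -> TwoClusterCut:
    """Agglomerate under single linkage and stop before the final merge.

    At each step the two clusters at minimum single-linkage distance
    (minimum pairwise distance between members) are merged.  Exact ties are
    broken deterministically: the candidate pair with the lowest smallest
    member index wins, then the lowest other smallest index.  The cluster
    containing item 0 is returned first.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items to cut")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(d, d.T, rtol=0, atol=0):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")

    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 2:
        best_key = None
        best_pair = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = float(d[np.ix_(clusters[i], clusters[j])].min())
                key = (dist, min(clusters[i][0], clusters[j][0]),
                       max(clusters[i][0], clusters[j][0]))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair  # type: ignore[misc]
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]

    height = float(d[np.ix_(clusters[0], clusters[1])].min())
    a, b = clusters
    if 0 in b:
        a, b = b, a
    return TwoClusterCut(tuple(a), tuple(b), height)


def quantile_type5(values: Sequence[float], p: float) -> float:
    """Hydrologist (Hyndman–Fan type 5) quantile with linear interpolation.

    With sorted values x_1..x_n and h = n·p + 1/2: returns x_1 if h ≤ 1,
    x_n if h ≥ n, otherwise x_⌊h⌋ + (h − ⌊h⌋)·(x_⌊h⌋₊₁ − x_⌊h⌋).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("quantile of empty list")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"quantile probability {p} outside [0, 1]")
    h = n * p + 0.5
    if h <= 1.0:
        return float(x[0])
    if h >= n:
        return float(x[-1])
    lo = math.floor(h)
    return float(x[lo - 1] + (h - lo) * (x[lo] - x[lo - 1]))


def tqr_score(on_values: Sequence[float], off_values: Sequence[float]) -> float:
    """Transquartile Range: Q1 of the ON values minus Q3 of the OFF values
    (type-5 quantiles).  Negative when the clusters overlap."""
    if len(on_values) == 0 or len(off_values) == 0:
        raise ValueError("TQR requires non-empty ON and OFF value lists")
    return quantile_type5(on_values, 0.25) - quantile_type5(off_values, 0.75)


def call_pattern(profile: GeneProfile,
                 quartile_basis: str = "pooled",
                 _cut: TwoClusterCut | None = None) -> PatternCall:
    """Cluster one gene's cell types into ON/OFF and score the call.

    The ON cluster is the side whose pooled replicate φ values have the
    larger mean (ties go to the cluster containing the earlier canonical
    cell type).  Quartiles are computed over the pooled replicate values of
    each cluster by default, or over per-cell means with
    ``quartile_basis="cellmean"``.
    """
    if quartile_basis not in ("pooled", "cellmean"):
        raise ValueError(f"unknown quartile_basis {quartile_basis!r}")
    cut = _cut if _cut is not None else single_linkage_two_cut(celltype_distances(profile))
    vals_a = profile.values[list(cut.cluster_a)]
    vals_b = profile.values[list(cut.cluster_b)]
    mean_a, mean_b = float(vals_a.mean()), float(vals_b.mean())
    if mean_a > mean_b:
        on_idx, off_idx = cut.cluster_a, cut.cluster_b
    elif mean_b > mean_a:
        on_idx, off_idx = cut.cluster_b, cut.cluster_a
    else:  # tie: the cluster holding the earlier canonical cell type is ON
        if min(cut.cluster_a) < min(cut.cluster_b):
            on_idx, off_idx = cut.cluster_a, cut.cluster_b
        else:
            on_idx, off_idx = cut.cluster_b, cut.cluster_a
    on_pool = profile.values[list(on_idx)].ravel()
    off_pool = profile.values[list(off_idx)].ravel()
    if quartile_basis == "pooled":
        tqr = tqr_score(on_pool, off_pool)
    else:
        tqr = tqr_score(profile.values[list(on_idx)].mean(axis=1),
                        profile.values[list(off_idx)].mean(axis=1))
    pattern = tuple(1 if i in set(on_idx) else 0 for i in range(len(profile.cell_types)))
    return PatternCall(
        gene_id=profile.gene_id,
        pattern=pattern,
        tqr=tqr,
        on_values=tuple(float(v) for v in on_pool),
        off_values=tuple(float(v) for v in off_pool),
    )


def build_profile_tensor(phi: PhiMatrix, sheet: SampleSheet,
                         platform: str | None = None
                         ) -> tuple[np.ndarray, list[str], tuple[str, ...], tuple[str, ...]]:
    """Arrange a φ matrix as a genes × cell types × embryos tensor.

    Replicates are aligned by embryo label, not column order, so permuting
    input samples changes nothing.  Only embryos with a sample for every
    cell type are used (missing replicates are not imputed).  If the sheet
    mixes platforms, ``platform`` must select one.
    """
    if platform is not None:
        sheet = sheet.filter_platform(platform)
    platforms = [p for p in sheet.platforms]
    if len(platforms) > 1:
        raise ValueError(
            f"sample sheet mixes platforms {platforms}; pass platform= to select one"
        )
    missing = [s for s in sheet.sample_ids if s not in phi.values.columns]
    if missing:
        raise ValueError(f"sample(s) in sheet but not in matrix: {missing}")

    cell_types = tuple(sheet.cell_types)
    by_pair = {(r["embryo"], r["cell_type"]): r["sample_id"]
               for _, r in sheet.table.iterrows()}
    complete = tuple(e for e in sheet.embryos
                     if all((e, ct) in by_pair for ct in cell_types))
    if not complete:
        raise ValueError("no embryo has a sample for every cell type")
    order = [by_pair[(e, ct)] for ct in cell_types for e in complete]
    mat = phi.values[order].to_numpy()
    tensor = mat.reshape(mat.shape[0], len(cell_types), len(complete))
    return tensor, phi.values.index.tolist(), cell_types, complete


def discover_and_rank(phi: PhiMatrix, sheet: SampleSheet,
                      platform: str | None = None,
                      quartile_basis: str = "pooled") -> list[PatternCall]:
    """Call and rank every gene: one PatternCall per gene, sorted by TQR
    descending with ties broken by gene id, ranks 1..G.

    Constant (including all-zero) genes get TQR 0 and therefore sort after
    every positive-scoring gene.
    """
    tensor, gene_ids, cell_types, embryos = build_profile_tensor(phi, sheet, platform)
    constant_cut: TwoClusterCut | None = None
    calls = []
    for g, gene_id in enumerate(gene_ids):
        values = tensor[g]
        profile = GeneProfile(gene_id, values, cell_types, embryos)
        if np.all(values == values.flat[0]):
            # constant profile: the cut depends only on the tie-break rule,
            # so compute it once and reuse
            if constant_cut is None:
                constant_cut = single_linkage_two_cut(
                    np.zeros((len(cell_types), len(cell_types))))
            calls.append(call_pattern(profile, quartile_basis, _cut=constant_cut))
        else:
            calls.append(call_pattern(profile, quartile_basis))
    calls.sort(key=lambda c: (-c.tqr, c.gene_id))
    for i, call in enumerate(calls, start=1):
        call.rank = i
    return calls
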