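"""Quality-control surfaces: detection tallies, sample correlation, PCA.

Small multiplexed designs (a handful of embryos, one library batch per
embryo) confound biological and technical between-batch variation.  The
useful QC questions are therefore: how many genes does each sample detect,
how strongly do samples correlate (within an embryo versus across embryos
for the same cell type), and how much variance the leading principal
components carry.  A gene is "detected" in a sample when its count is
greater than zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import single_linkage_two_cut  # noqa: F401  (shared machinery)
from .io import CountMatrix, SampleSheet
from .transform import PhiMatrix, ProportionMatrix


def detected_genes_per_sample(counts: CountMatrix,
                              include_spikes: bool = False) -> pd.Series:
    """Number of genes with count > 0 per sample (spikes excluded by default)."""
    df = counts.counts if include_spikes else counts.counts.loc[~counts.is_spike]
    return (df > 0).sum(axis=0)


def _as_frame(norm) -> pd.DataFrame:
    if isinstance(norm, (PhiMatrix, ProportionMatrix)):
        return norm.values
    if isinstance(norm, pd.DataFrame):
        return norm
    raise TypeError(f"expected PhiMatrix, ProportionMatrix or DataFrame, got {type(norm)}")


def sample_correlation(norm, drop_all_zero_genes: bool = True,
                       method: str = "pearson") -> pd.DataFrame:
    """Sample–sample correlation of normalised expression.

    Genes that are zero in every sample are removed when
    ``drop_all_zero_genes`` is set.  A constant sample column has no
    defined correlation; those entries are reported as NaN, never as 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    df = _as_frame(norm)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples for a correlation matrix")
    if drop_all_zero_genes:
        df = df.loc[(df != 0).any(axis=1)]
    corr = df.corr(method=method)
    # pandas leaves the diagonal at 1 even for constant columns; a constant
    # column has no defined self-correlation either, keep those NaN
    const = df.nunique(axis=0) <= 1
    for s in df.columns[const]:
        corr.loc[s, :] = np.nan
        corr.loc[:, s] = np.nan
    return corr


def pca_variance_explained(norm) -> np.ndarray:
    """Fraction of total variance per principal component, descending.

    Computed from the singular values of the gene-centred matrix (each
    gene's mean across samples removed); the fractions sum to 1.
    """
    df = _as_frame(norm)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    x = df.to_numpy(dtype=float)
    centred = x - x.mean(axis=1, keepdims=True)
    s = np.linalg.svd(centred, compute_uv=False)
    total = float(np.sum(s ** 2))
    if total == 0:
        raise ValueError("matrix has no variance after centring")
    frac = np.sort(s ** 2)[::-1] / total
    return frac[: df.shape[1]]


def pca_coordinates(norm, n_components: int = 2) -> pd.DataFrame:
    """Sample coordinates on the leading principal components."""
    df = _as_frame(norm)
    x = df.to_numpy(dtype=float)
    centred = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    coords = (vt[:n_components].T * s[:n_components])
    return pd.DataFrame(coords, index=df.columns,
                        columns=[f"PC{i + 1}" for i in range(n_components)])


def correlation_structure(norm, sheet: SampleSheet,
                          drop_all_zero_genes: bool = True) -> dict[str, float]:
    """Mean correlation within embryos versus across embryos.

    ``within_embryo``: pairs of different cell types from the same embryo.
    ``cross_embryo_same_celltype``: pairs of the same cell type from
    different embryos.  In a batch-dominated design the former exceeds the
    latter.
    """
    corr = sample_correlation(norm, drop_all_zero_genes=drop_all_zero_genes)
    meta = sheet.table.set_index("sample_id")
    within, cross = [], []
    samples = [s for s in corr.columns if s in meta.index]
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            r = corr.loc[si, sj]
            if np.isnan(r):
                continue
            ei, ci = meta.loc[si, "embryo"], meta.loc[si, "cell_type"]
            ej, cj = meta.loc[sj, "embryo"], meta.loc[sj, "cell_type"]
            if ei == ej and ci != cj:
                within.append(float(r))
            elif ei != ej and ci == cj:
                cross.append(float(r))
    return {
        "within_embryo": float(np.mean(within)) if within else float("nan"),
        "cross_embryo_same_celltype": float(np.mean(cross)) if cross else float("nan"),
    }


def _single_linkage_order(corr: pd.DataFrame) -> list[str]:
    """Display order for the heat map: recursive two-cluster single-linkage
    splits of the correlation-distance matrix (1 − r)."""
    samples = list(corr.columns)
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.where(np.isnan(dist), np.nanmax(dist[np.isfinite(dist)], initial=1.0), dist)
    dist = (dist + dist.T) / 2.0

    def order(idx: list[int]) -> list[int]:
        if len(idx) <= 1:
            return idx
        sub = dist[np.ix_(idx, idx)]
        cut = single_linkage_two_cut(sub)
        left = [idx[i] for i in cut.cluster_a]
        right = [idx[i] for i in cut.cluster_b]
        return order(left) + order(right)

    return [samples[i] for i in order(list(range(len(samples))))]


@dataclass
class QcReport:
    """Detection counts, correlation matrix with display order, and PCA
    variance fractions for one dataset."""

    detected: pd.Series
    correlation: pd.DataFrame
    sample_order: list[str]
    variance_fractions: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "detected_genes": {k: int(v) for k, v in self.detected.items()},
            "correlation": {
                s: {t: (None if np.isnan(self.correlation.loc[s, t])
                        else round(float(self.correlation.loc[s, t]), 9))
                    for t in self.correlation.columns}
                for s in self.correlation.index
            },
            "sample_order": self.sample_order,
            "pca_variance_fractions": [round(float(f), 9) for f in self.variance_fractions],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def qc_report(counts: CountMatrix, norm, sheet: SampleSheet | None = None) -> QcReport:
    corr = sample_correlation(norm)
    return QcReport(
        detected=detected_genes_per_sample(counts),
        correlation=corr,
        sample_order=_single_linkage_order(corr),
        variance_fractions=pca_variance_explained(norm),
    )


def plot_correlation_heatmap(report: QcReport, path: str | Path,
                             sheet: SampleSheet | None = None) -> None:
    """Save a clustered correlation heat map (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = report.sample_order
    mat = report.correlation.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(norm, sheet: SampleSheet, path: str | Path) -> None:
    """Save a PC1/PC2 scatter coloured by embryo and labelled by cell type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = pca_coordinates(norm)
    frac = pca_variance_explained(norm)
    meta = sheet.table.set_index("sample_id")
    embryos = sorted(meta["embryo"].unique())
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(6, 5))
    for k, embryo in enumerate(embryos):
        sel = [s for s in coords.index if meta.loc[s, "embryo"] == embryo]
        ax.scatter(coords.loc[sel, "PC1"], coords.loc[sel, "PC2"],
                   color=cmap(k % 10), label=f"embryo {embryo}")
        for s in sel:
            ax.annotate(meta.loc[s, "cell_type"],
                        (coords.loc[s, "PC1"], coords.loc[s, "PC2"]), fontsize=6)
    ax.set_xlabel(f"PC1 ({100 * frac[0]:.0f}% of variance)")
    ax.set_ylabel(f"PC2 ({100 * frac[1]:.0f}% of variance)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
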