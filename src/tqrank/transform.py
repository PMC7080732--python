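"""Proportion normalisation and the φ (arcsine-square-root) transform.

Counts are normalised only for sequencing depth, by dividing each sample's
counts by its total: the resulting proportion p_ij = k_ij / N_j is the
fraction of sample j's reads contributed by gene i.  No across-gene
normalisation (GC content, transcript length) is applied — the analysis
compares the same gene across cell types, where such factors cancel.

Proportions are then variance-stabilised with

    φ(p) = 2·arcsin(√p),   φ: [0, 1] → [0, π].

The difference of two φ values is Cohen's h, the standard effect-size
index for a difference of proportions, so distances in φ space are
effect-size distances.  For the small proportions typical of expression
data, φ(p) ≈ 2√p, i.e. the arcsine is nearly the identity on top of a
square-root transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleSheet

_CLAMP_TOL = 1e-12


@dataclass
class ProportionMatrix:
    """Per-sample proportions p_ij with the totals N_j actually used."""

    values: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("proportions must lie in [0, 1]")
        colsums = vals.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"sample {self.values.columns[j]!r}: proportions sum to "
                f"{colsums[j]!r}, expected 1"
            )


@dataclass
class PhiMatrix:
    """φ-transformed proportions, entries in [0, π]; φ = 0 iff the count was 0."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if np.any(vals < 0) or np.any(vals > np.pi + 1e-12):
            raise ValueError("φ values must lie in [0, π]")

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.map(lambda v: float(f"{v:.9g}"))
        out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.9g")


def to_proportions(counts: CountMatrix, exclude_spikes: bool = True) -> ProportionMatrix:
    """Divide each sample by its total count N_j.

    With ``exclude_spikes`` (the default) spike-in rows are dropped and N_j
    sums endogenous genes only, so proportions measure the biological
    fraction.  A sample whose included total is zero is an error.
    """
    df = counts.counts
    if exclude_spikes:
        df = df.loc[~counts.is_spike]
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(
            f"sample(s) with zero total count over included genes: "
            f"{zero.index.tolist()}"
        )
    props = df / totals
    return ProportionMatrix(props, totals.astype(float))


def phi(p):
    """φ(p) = 2·arcsin(√p) elementwise; values within 1e-12 of [0, 1] are
    clamped, anything further out raises."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -_CLAMP_TOL) or np.any(arr > 1 + _CLAMP_TOL):
        raise ValueError("proportion outside [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    out = 2.0 * np.arcsin(np.sqrt(arr))
    return out if out.ndim else float(out)


def phi_transform(props: ProportionMatrix) -> PhiMatrix:
    """Apply φ entrywise to a proportion matrix."""
    return PhiMatrix(pd.DataFrame(
        phi(props.values.to_numpy()),
        index=props.values.index,
        columns=props.values.columns,
    ))


def cohens_h(p1, p2):
    """Cohen's h = φ(p1) − φ(p2); antisymmetric in its arguments."""
    return phi(p1) - phi(p2)


def celltype_mean_matrix(phi_mat: PhiMatrix, sheet: SampleSheet,
                         clip_at: float | None = None) -> pd.DataFrame:
    """Average φ across each cell type's replicates (genes × cell types).

    ``clip_at`` caps values for display (heat-map scaling); clipping is
    never applied before clustering or TQR scoring.
    """
    cols = {}
    for ct in sheet.cell_types:
        samples = sheet.table.loc[sheet.table["cell_type"] == ct, "sample_id"]
        samples = [s for s in samples if s in phi_mat.values.columns]
        if not samples:
            raise ValueError(f"cell type {ct!r} has no samples in the φ matrix")
        cols[ct] = phi_mat.values[samples].mean(axis=1)
    out = pd.DataFrame(cols, columns=list(sheet.cell_types))
    if clip_at is not None:
        out = out.clip(upper=clip_at)
    return out
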