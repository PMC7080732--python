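"""Synthetic 16-cell-embryo count generator with planted ON/OFF patterns.

The generator emulates the statistical structure the discovery method
assumes: a genes × samples count matrix over 8 cell types × a few embryos,
where embryo (batch) variation exceeds within-embryo variation, library
sizes vary log-normally, spike-in rows are present at fixed expected
proportions, and a known subset of genes carries a planted ON/OFF pattern
with a target Cohen's h contrast.  Counts are negative-binomial, the
standard overdispersed model for sequencing counts.

Generation, given a seed:

1. per-gene baseline expected proportions b_i ~ log-normal;
2. patterned genes (drawn among genes whose baseline is large enough for
   the requested contrast) get a planted bit vector: ON cells keep b_i,
   OFF cells get the level with φ(ON·s) − φ(OFF·s) = effect_size_h under
   the provisional column scale s; "intermediate" genes additionally place
   two designated OFF-side cells at an in-between level (the geometric mean
   of the ON and OFF levels, or a configurable position in φ space) — the
   failure mode where mid-level cells join the OFF cluster;
3. each gene × embryo gets a shared multiplicative log-normal batch factor
   (identical across that embryo's cells);
4. every sample's expected proportions are renormalised to sum to 1;
5. library sizes are drawn log-normally;
6. counts k_ij ~ NB(mean = p_ij · L_j, dispersion); silent genes stay at
   zero, spike rows keep fixed expected proportions (no batch factor).

Ground truth (class, planted pattern, realised levels and Cohen's h) is
returned for recovery scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalogue import NAMED_PATTERNS, Bits
from .celltypes import CANONICAL_CELL_TYPES
from .io import CountMatrix, PatternCall, SampleSheet, write_count_table, write_sample_sheet
from .transform import phi

DEFAULT_PATTERN_SET: tuple[Bits, ...] = tuple(NAMED_PATTERNS.values())


@dataclass
class SimConfig:
    """Parameters of the synthetic embryo experiment.

    Defaults give a desk-scale experiment: 1,000 genes over the canonical
    8 cell types × 4 embryos with 40 planted patterned genes, 40% silent
    genes, a spike-in panel, 200k-read libraries and a batch effect large
    enough to dominate within-embryo noise.
    """

    n_genes: int = 1000
    n_embryos: int = 4
    cell_types: tuple[str, ...] = CANONICAL_CELL_TYPES
    n_patterned: int = 40
    pattern_set: tuple[Bits, ...] = DEFAULT_PATTERN_SET
    effect_size_h: float = 0.08          # target Cohen's h between ON and OFF
    baseline_logmean: float = math.log(1e-4)
    baseline_logsd: float = 1.5
    batch_logsd: float = 0.35            # gene × embryo multiplicative batch effect
    dispersion: float = 0.125            # NB overdispersion (variance = μ + dispersion·μ²)
    library_size_mean: float = 2e5
    library_size_logsd: float = 0.3
    n_silent: int | None = None          # default: 40% of n_genes
    n_spikes: int = 16
    spike_total_proportion: float = 0.03
    intermediate_fraction: float = 0.0   # fraction of patterned genes made intermediate
    intermediate_phi_ratio: float | None = None  # position in φ space, None = geometric mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_silent is None:
            self.n_silent = int(round(0.4 * self.n_genes))
        if self.n_patterned + self.n_silent > self.n_genes:
            raise ValueError("n_patterned + n_silent exceeds n_genes")
        if not 0.0 < self.effect_size_h <= math.pi:
            raise ValueError("effect_size_h must lie in (0, π]")
        for name in ("baseline_logsd", "batch_logsd", "dispersion",
                     "library_size_logsd", "spike_total_proportion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.intermediate_fraction <= 1.0:
            raise ValueError("intermediate_fraction must lie in [0, 1]")
        self.cell_types = tuple(self.cell_types)
        self.pattern_set = tuple(tuple(int(b) for b in p) for p in self.pattern_set)
        for p in self.pattern_set:
            if len(p) != len(self.cell_types) or not 1 <= sum(p) <= len(p) - 1:
                raise ValueError(f"invalid planted pattern {p}")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["cell_types"] = list(self.cell_types)
        payload["pattern_set"] = ["".join(map(str, p)) for p in self.pattern_set]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "cell_types" in payload:
            payload["cell_types"] = tuple(payload["cell_types"])
        if "pattern_set" in payload:
            payload["pattern_set"] = tuple(
                tuple(int(c) for c in p) for p in payload["pattern_set"])
        return cls(**payload)


@dataclass
class SimTruth:
    """Per-gene ground truth: class, planted pattern, expected ON/OFF
    proportions and realised Cohen's h."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        planted = self.table[self.table["class"].isin(["patterned", "intermediate"])]
        for gene, pat in planted["pattern"].items():
            n_on = sum(int(c) for c in pat)
            if not 1 <= n_on <= len(pat) - 1:
                raise ValueError(f"gene {gene}: planted pattern {pat} has {n_on} ON cells")

    def genes_of_class(self, cls: str) -> list[str]:
        return self.table.index[self.table["class"] == cls].tolist()

    def pattern_of(self, gene_id: str) -> Bits | None:
        pat = self.table.loc[gene_id, "pattern"]
        return tuple(int(c) for c in pat) if pat else None

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", index_col="gene_id",
                         dtype={"pattern": str, "intermediate_cells": str})
        df["pattern"] = df["pattern"].fillna("")
        df["intermediate_cells"] = df["intermediate_cells"].fillna("")
        return cls(df)


def simulate_dataset(cfg: SimConfig) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Generate a synthetic count matrix, sample sheet and ground truth.

    Deterministic given ``cfg.seed``: the random stream is consumed in a
    fixed order (baselines, class assignment, patterns, batch factors,
    library sizes, counts).
    """
    rng = np.random.default_rng(cfg.seed)
    n_ct, n_emb = len(cfg.cell_types), cfg.n_embryos
    n_samples = n_ct * n_emb
    gene_ids = [f"SIMG{i + 1:05d}" for i in range(cfg.n_genes)]
    spike_ids = [f"ERCC-{i + 1:05d}" for i in range(cfg.n_spikes)]

    b = rng.lognormal(cfg.baseline_logmean, cfg.baseline_logsd, cfg.n_genes)
    classes = np.array(["uniform"] * cfg.n_genes, dtype=object)
    silent_idx = rng.choice(cfg.n_genes, size=cfg.n_silent, replace=False)
    classes[silent_idx] = "silent"
    b[silent_idx] = 0.0

    # spike panel: fixed levels spanning three decades, summing to the
    # requested fraction of the expected library
    if cfg.n_spikes > 0:
        raw = np.logspace(0, -3, cfg.n_spikes)
        spike_levels = raw / raw.sum() * (
            cfg.spike_total_proportion / max(1e-12, 1 - cfg.spike_total_proportion)
        ) * b.sum()
    else:
        spike_levels = np.zeros(0)

    s0 = 1.0 / (b.sum() + spike_levels.sum())  # provisional column scale
    phi_base = phi(np.clip(b * s0, 0, 1))
    feasible = np.where((classes == "uniform") & (phi_base >= cfg.effect_size_h))[0]
    if len(feasible) < cfg.n_patterned:
        raise ValueError(
            f"only {len(feasible)} genes can carry a Cohen's h of "
            f"{cfg.effect_size_h}; requested {cfg.n_patterned} patterned genes"
        )
    pat_idx = rng.choice(feasible, size=cfg.n_patterned, replace=False)
    classes[pat_idx] = "patterned"
    n_inter = int(round(cfg.intermediate_fraction * cfg.n_patterned))

    levels = np.tile(b[:, None], (1, n_ct))  # expected level per gene × cell type
    pattern_str = np.array([""] * cfg.n_genes, dtype=object)
    inter_cells = np.array([""] * cfg.n_genes, dtype=object)
    on_level = np.full(cfg.n_genes, np.nan)
    off_level = np.full(cfg.n_genes, np.nan)

    pat_choices = rng.integers(0, len(cfg.pattern_set), size=cfg.n_patterned)
    for k, g in enumerate(pat_idx):
        bits = cfg.pattern_set[pat_choices[k]]
        phi_on = float(phi(b[g] * s0))
        phi_off = phi_on - cfg.effect_size_h
        if phi_off < 0:
            raise ValueError(f"gene {gene_ids[g]}: OFF level would be negative")
        lvl_off = math.sin(phi_off / 2.0) ** 2 / s0
        off_cells = [c for c, bit in enumerate(bits) if bit == 0]
        for c in off_cells:
            levels[g, c] = lvl_off
        pattern_str[g] = "".join(map(str, bits))
        on_level[g], off_level[g] = b[g], lvl_off
        if k < n_inter and len(off_cells) >= 2:
            classes[g] = "intermediate"
            chosen = off_cells[:2]
            if cfg.intermediate_phi_ratio is not None:
                phi_mid = phi_off + cfg.intermediate_phi_ratio * (phi_on - phi_off)
                lvl_mid = math.sin(phi_mid / 2.0) ** 2 / s0
            elif lvl_off > 0:
                lvl_mid = math.sqrt(b[g] * lvl_off)
            else:
                lvl_mid = b[g] / 4.0  # φ midpoint when OFF is exactly zero
            for c in chosen:
                levels[g, c] = lvl_mid
            inter_cells[g] = ",".join(cfg.cell_types[c] for c in chosen)

    batch = np.exp(rng.normal(0.0, cfg.batch_logsd, size=(cfg.n_genes, n_emb)))

    embryo_labels = [f"E{e + 1}" for e in range(n_emb)]
    sample_ids = [f"{emb}_{ct}" for emb in embryo_labels for ct in cfg.cell_types]
    expected = np.empty((cfg.n_genes + cfg.n_spikes, n_samples))
    for e in range(n_emb):
        for c in range(n_ct):
            j = e * n_ct + c
            expected[: cfg.n_genes, j] = levels[:, c] * batch[:, e]
            expected[cfg.n_genes:, j] = spike_levels
    expected /= expected.sum(axis=0, keepdims=True)

    lib = rng.lognormal(math.log(cfg.library_size_mean), cfg.library_size_logsd,
                        size=n_samples)
    mu = expected * lib[None, :]
    if cfg.dispersion > 0:
        size = 1.0 / cfg.dispersion
        p_nb = size / (size + mu)
        counts = rng.negative_binomial(size, p_nb)
    else:
        counts = rng.poisson(mu)

    all_ids = gene_ids + spike_ids
    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64), index=all_ids,
                                  columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "embryo": [s.split("_", 1)[0] for s in sample_ids],
        "cell_type": [s.split("_", 1)[1] for s in sample_ids],
        "platform": "sim",
    }), cell_types=cfg.cell_types)

    # realised Cohen's h from the renormalised expected proportions,
    # averaged over samples
    endog = expected[: cfg.n_genes]
    realised_h = np.full(cfg.n_genes, np.nan)
    for g in pat_idx:
        bits = [int(c) for c in pattern_str[g]]
        on_cols = [e * n_ct + c for e in range(n_emb) for c in range(n_ct) if bits[c]]
        off_cols = [e * n_ct + c for e in range(n_emb) for c in range(n_ct) if not bits[c]]
        realised_h[g] = float(phi(endog[g, on_cols].mean()) - phi(endog[g, off_cols].mean()))

    truth_rows = pd.DataFrame({
        "class": np.concatenate([classes, ["spike"] * cfg.n_spikes]),
        "pattern": np.concatenate([pattern_str, [""] * cfg.n_spikes]),
        "intermediate_cells": np.concatenate([inter_cells, [""] * cfg.n_spikes]),
        "on_prop": np.concatenate([on_level * s0, [np.nan] * cfg.n_spikes]),
        "off_prop": np.concatenate([off_level * s0, [np.nan] * cfg.n_spikes]),
        "realised_h": np.concatenate([realised_h, [np.nan] * cfg.n_spikes]),
    }, index=pd.Index(all_ids, name="gene_id"))
    return cm, sheet, SimTruth(truth_rows)


@dataclass
class RecoveryMetrics:
    """How well a ranked call list recovers the planted truth."""

    n_planted: int
    fraction_in_top: float | None
    fraction_exact_pattern: float | None
    median_planted_rank: float | None
    class_median_rank: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_planted": self.n_planted,
            "fraction_in_top": self.fraction_in_top,
            "fraction_exact_pattern": self.fraction_exact_pattern,
            "median_planted_rank": self.median_planted_rank,
            "class_median_rank": self.class_median_rank,
        }


def evaluate_recovery(calls: list[PatternCall], truth: SimTruth,
                      top_n: int | None = None) -> RecoveryMetrics:
    """Score a ranked call list against the planted truth.

    Reports the fraction of planted patterned genes in the top
    ``top_n`` ranks (default: the number planted), the fraction of those
    recovered whose called bit vector is exactly the planted one, the
    median rank of planted genes, and median ranks per truth class.
    """
    call_genes = {c.gene_id for c in calls}
    truth_genes = set(truth.table.index[truth.table["class"] != "spike"])
    if call_genes != truth_genes:
        raise ValueError(
            f"calls and truth cover different genes "
            f"({len(call_genes ^ truth_genes)} differ)"
        )
    by_gene = {c.gene_id: c for c in calls}
    planted = truth.genes_of_class("patterned")
    rank_of = {g: by_gene[g].rank for g in call_genes}

    class_median = {}
    for cls in ("patterned", "intermediate", "uniform", "silent"):
        genes = truth.genes_of_class(cls)
        if genes:
            class_median[cls] = float(np.median([rank_of[g] for g in genes]))

    if not planted:
        return RecoveryMetrics(0, None, None, None, class_median)

    n = top_n if top_n is not None else len(planted)
    in_top = [g for g in planted if rank_of[g] <= n]
    exact = [g for g in in_top
             if by_gene[g].pattern == truth.pattern_of(g)]
    return RecoveryMetrics(
        n_planted=len(planted),
        fraction_in_top=len(in_top) / len(planted),
        fraction_exact_pattern=(len(exact) / len(in_top)) if in_top else None,
        median_planted_rank=float(np.median([rank_of[g] for g in planted])),
        class_median_rank=class_median,
    )


def write_simulation(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run :func:`simulate_dataset` and write counts, sample sheet, truth
    and the config as four plain-text files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm, sheet, truth = simulate_dataset(cfg)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.yaml",
    }
    write_count_table(cm, paths["counts"])
    write_sample_sheet(sheet, paths["samples"])
    truth.to_tsv(paths["truth"])
    cfg.to_yaml(paths["config"])
    return paths
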