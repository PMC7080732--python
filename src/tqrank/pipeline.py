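"""End-to-end discovery pipeline and run manifests.

``run_discovery`` wires the standard workflow: counts → proportions →
φ transform → per-gene two-cluster calls → TQR ranking.  Clustering can
alternatively run on raw proportions (``clustering_space="proportion"``)
for sensitivity analysis.  Every run can emit a JSON manifest recording
the configuration, input content hashes and package version, so a result
can be traced to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .discovery import discover_and_rank
from .io import CountMatrix, PatternCall, SampleSheet
from .transform import PhiMatrix, phi_transform, to_proportions


@dataclass
class DiscoveryConfig:
    exclude_spikes: bool = True
    platform: str | None = None
    clustering_space: str = "phi"     # "phi" or "proportion"
    quartile_basis: str = "pooled"    # "pooled" or "cellmean"
    top_n: int = 40                   # reporting depth for summaries

    def __post_init__(self) -> None:
        if self.clustering_space not in ("phi", "proportion"):
            raise ValueError(f"unknown clustering_space {self.clustering_space!r}")


def run_discovery(counts: CountMatrix, sheet: SampleSheet,
                  config: DiscoveryConfig | None = None) -> list[PatternCall]:
    """Normalise, transform and rank: one PatternCall per endogenous gene."""
    cfg = config or DiscoveryConfig()
    props = to_proportions(counts, exclude_spikes=cfg.exclude_spikes)
    if cfg.clustering_space == "phi":
        norm = phi_transform(props)
    else:
        # proportion space: p ∈ [0,1] ⊂ [0,π], so the φ container validates
        norm = PhiMatrix(props.values)
    return discover_and_rank(norm, sheet, platform=cfg.platform,
                             quartile_basis=cfg.quartile_basis)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict | DiscoveryConfig,
                   inputs: dict[str, str | Path]) -> None:
    """Write a run manifest: config, input hashes, version, timestamp."""
    cfg = asdict(config) if isinstance(config, DiscoveryConfig) else dict(config)
    payload = {
        "tool": "tqrank",
        "version": __version__,
        "config": cfg,
        "inputs": {name: {"path": str(p), "sha256": file_sha256(p)}
                   for name, p in inputs.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
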