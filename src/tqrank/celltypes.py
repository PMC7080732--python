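"""Canonical cell-type vocabulary for the 16-cell ascidian embryo.

Conklin nomenclature: lowercase a/b are animal-hemisphere cells, uppercase
A/B vegetal; a/A anterior, b/B posterior.  The canonical order used for
every bit vector and serialised table is animal row then vegetal row, each
anterior to posterior.  The vocabulary is configurable for other systems,
but it is fixed within a run.
"""

from __future__ import annotations

from collections.abc import Sequence

CANONICAL_CELL_TYPES: tuple[str, ...] = (
    "a5.3", "a5.4", "b5.3", "b5.4",
    "A5.1", "A5.2", "B5.1", "B5.2",
)

ANIMAL_CELL_TYPES: tuple[str, ...] = CANONICAL_CELL_TYPES[:4]
VEGETAL_CELL_TYPES: tuple[str, ...] = CANONICAL_CELL_TYPES[4:]


def validate_cell_types(labels: Sequence[str],
                        cell_types: Sequence[str] = CANONICAL_CELL_TYPES) -> None:
    """Raise ``ValueError`` naming the canonical set if any label is unknown."""
    known = set(cell_types)
    bad = sorted({str(x) for x in labels} - known)
    if bad:
        raise ValueError(
            f"unknown cell type(s) {bad}; expected one of {list(cell_types)}"
        )
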