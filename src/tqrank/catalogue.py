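"""Known-pattern catalogue: bit-vector encoding and top-N comparison.

An expression pattern over the 8 canonical blastomere types is an 8-bit
vector in the canonical order.  A catalogue maps gene ids to their known
in-situ pattern (or "unknown"), optionally with alternate acceptable
patterns for probes that cross-detect paralogues.  Comparison of a ranked
call list against the catalogue tallies exact matches, mismatches (with
Hamming distance for diagnostics), distinct patterns among the top N, and
patterns absent from the named reference set ("novel").

The packaged default catalogue (``data/known_patterns_synthetic.tsv``) is a
synthetic stand-in assembled from well-known marker genes of the 16-cell
ascidian embryo; it is a fixture for demonstrations and tests, not a
curated atlas.
"""

from __future__ import annotations

import importlib.resources
import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from .celltypes import CANONICAL_CELL_TYPES
from .io import PatternCall

Bits = tuple[int, ...]

#: Nine named reference patterns over the canonical cell-type order
#: (a5.3, a5.4, b5.3, b5.4, A5.1, A5.2, B5.1, B5.2).
NAMED_PATTERNS: dict[str, Bits] = {
    "animal": (1, 1, 1, 1, 0, 0, 0, 0),
    "vegetal": (0, 0, 0, 0, 1, 1, 1, 1),
    "anterior": (1, 1, 0, 0, 1, 1, 0, 0),
    "posterior": (0, 0, 1, 1, 0, 0, 1, 1),
    "anterior-animal": (1, 1, 0, 0, 0, 0, 0, 0),
    "anterior-vegetal": (0, 0, 0, 0, 1, 1, 0, 0),
    "posterior-vegetal": (0, 0, 0, 0, 0, 0, 1, 1),
    "B5.2-only": (0, 0, 0, 0, 0, 0, 0, 1),
    "all-except-B5.2": (1, 1, 1, 1, 1, 1, 1, 0),
}


def encode_pattern(on_cells: Iterable[str],
                   cell_types: Sequence[str] = CANONICAL_CELL_TYPES) -> Bits:
    """Bit i = 1 iff canonical cell i is in ``on_cells``."""
    on = {str(c) for c in on_cells}
    unknown = on - set(cell_types)
    if unknown:
        raise ValueError(f"unknown cell type(s): {sorted(unknown)}")
    return tuple(1 if ct in on else 0 for ct in cell_types)


def decode_pattern(bits: Sequence[int],
                   cell_types: Sequence[str] = CANONICAL_CELL_TYPES) -> frozenset[str]:
    """Inverse of :func:`encode_pattern`."""
    if len(bits) != len(cell_types):
        raise ValueError(f"expected {len(cell_types)} bits, got {len(bits)}")
    if any(int(b) not in (0, 1) for b in bits):
        raise ValueError(f"pattern bits must be 0/1, got {tuple(bits)}")
    return frozenset(ct for ct, b in zip(cell_types, bits) if int(b) == 1)


def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    if len(a) != len(b):
        raise ValueError("bit vectors differ in length")
    return sum(int(x) != int(y) for x, y in zip(a, b))


@dataclass
class KnownCatalogue:
    """Gene → known pattern(s) plus the named reference pattern set.

    ``entries`` maps gene id to a tuple of acceptable bit vectors (the
    first is the primary pattern) or to ``None`` for genes whose pattern
    is recorded as unknown.
    """

    entries: dict[str, tuple[Bits, ...] | None]
    named_patterns: dict[str, Bits] = field(default_factory=lambda: dict(NAMED_PATTERNS))

    def __post_init__(self) -> None:
        if len(set(self.named_patterns)) != len(self.named_patterns):
            raise ValueError("named pattern labels must be unique")
        for label, bits in self.named_patterns.items():
            if any(int(b) not in (0, 1) for b in bits):
                raise ValueError(f"pattern {label!r} has non-binary bits")

    def pattern_of(self, gene_id: str) -> Bits | None:
        pats = self.entries.get(gene_id)
        return pats[0] if pats else None

    def matches(self, gene_id: str, called: Bits) -> bool | None:
        """True/False for catalogued genes, None when the gene is absent or
        its pattern unknown.  Any listed alternate pattern counts."""
        pats = self.entries.get(gene_id)
        if pats is None:
            return None
        return tuple(called) in {tuple(p) for p in pats}

    def pattern_label(self, bits: Sequence[int]) -> str | None:
        target = tuple(int(b) for b in bits)
        for label, pat in self.named_patterns.items():
            if pat == target:
                return label
        return None


@dataclass
class MatchReport:
    """Summary of the top-N calls against a known catalogue."""

    top_n: int
    matched: int
    mismatched: list[dict]
    uncatalogued: list[str]
    distinct_patterns: int
    novel_patterns: list[Bits]
    pattern_tally: list[dict]

    def __post_init__(self) -> None:
        if self.matched + len(self.mismatched) + len(self.uncatalogued) != self.top_n:
            raise ValueError("match report does not partition the top-N genes")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "top_n": self.top_n,
            "matched": self.matched,
            "mismatched": self.mismatched,
            "uncatalogued": self.uncatalogued,
            "distinct_patterns": self.distinct_patterns,
            "novel_patterns": ["".join(map(str, p)) for p in self.novel_patterns],
            "pattern_tally": self.pattern_tally,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        """Human-readable summary table: one row per distinct called
        pattern with its gene count and known/novel status."""
        lines = [
            f"top {self.top_n} calls: {self.matched} matched, "
            f"{len(self.mismatched)} mismatched, "
            f"{len(self.uncatalogued)} not in catalogue",
            f"distinct patterns: {self.distinct_patterns} "
            f"({len(self.novel_patterns)} not in the named reference set)",
            "",
            f"{'pattern':>10}  {'label':<18} {'genes':>5}  status",
        ]
        for row in self.pattern_tally:
            lines.append(
                f"{row['pattern']:>10}  {row['label'] or '-':<18} "
                f"{row['n_genes']:>5}  {row['status']}"
            )
        return "\n".join(lines)


def load_catalogue(path: str | Path,
                   cell_types: Sequence[str] = CANONICAL_CELL_TYPES) -> KnownCatalogue:
    """Read a catalogue TSV.

    Each data row is ``gene_id`` followed by either the word ``unknown`` or
    one 0/1 column per cell type, optionally followed by alternate
    acceptable patterns given as contiguous bit strings (e.g. ``00000011``).
    """
    n = len(cell_types)
    entries: dict[str, tuple[Bits, ...] | None] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    start = 1 if lines and lines[0].split("\t")[0] == "gene_id" else 0
    for ln in lines[start:]:
        fields = ln.split("\t")
        gene = fields[0]
        if gene in entries:
            raise ValueError(f"duplicate catalogue entry for {gene!r}")
        rest = fields[1:]
        if len(rest) == 1 and rest[0] == "unknown":
            entries[gene] = None
            continue
        if len(rest) < n:
            raise ValueError(
                f"gene {gene!r}: expected {n} bit columns or 'unknown', got {len(rest)}"
            )
        primary = _parse_bits(rest[:n], gene)
        alts = [_parse_bitstring(s, n, gene) for s in rest[n:] if s]
        if len(rest) > n and any(not s for s in rest[n:]):
            pass  # trailing empty fields from padded TSV are fine
        entries[gene] = tuple([primary, *alts])
    return KnownCatalogue(entries)


def _parse_bits(fields: Sequence[str], gene: str) -> Bits:
    try:
        bits = tuple(int(f) for f in fields)
    except ValueError as exc:
        raise ValueError(f"gene {gene!r}: malformed pattern bits {fields}") from exc
    if any(b not in (0, 1) for b in bits):
        raise ValueError(f"gene {gene!r}: pattern bits must be 0/1, got {bits}")
    return bits


def _parse_bitstring(s: str, n: int, gene: str) -> Bits:
    if len(s) != n or any(c not in "01" for c in s):
        raise ValueError(f"gene {gene!r}: malformed alternate pattern {s!r}")
    return tuple(int(c) for c in s)


def default_catalogue() -> KnownCatalogue:
    """The packaged synthetic stand-in catalogue (marker genes of the
    16-cell ascidian embryo with the nine named reference patterns)."""
    ref = importlib.resources.files("tqrank.data") / "known_patterns_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_catalogue(path)


def compare_to_catalogue(calls: Sequence[PatternCall], cat: KnownCatalogue,
                         top_n: int = 40) -> MatchReport:
    """Compare the top-N ranked calls to the catalogue.

    A match is exact bit-vector equality with the catalogued pattern (or
    any listed alternate).  Genes absent from the catalogue, or catalogued
    as unknown, are counted separately as candidates for validation.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > len(calls):
        raise ValueError(f"top_n={top_n} exceeds {len(calls)} calls")
    ordered = sorted(calls, key=lambda c: c.rank if c.rank is not None else 0)
    top = ordered[:top_n]

    matched = 0
    mismatched: list[dict] = []
    uncatalogued: list[str] = []
    for call in top:
        verdict = cat.matches(call.gene_id, call.pattern)
        if verdict is None:
            uncatalogued.append(call.gene_id)
        elif verdict:
            matched += 1
        else:
            known = cat.pattern_of(call.gene_id)
            mismatched.append({
                "gene_id": call.gene_id,
                "called": call.pattern_string,
                "known": "".join(map(str, known)) if known else "unknown",
                "hamming": hamming(call.pattern, known) if known else None,
            })

    seen: dict[Bits, int] = {}
    for call in top:
        seen[call.pattern] = seen.get(call.pattern, 0) + 1
    named = {tuple(p) for p in cat.named_patterns.values()}
    novel = [p for p in seen if p not in named]
    tally = [
        {
            "pattern": "".join(map(str, pat)),
            "label": cat.pattern_label(pat),
            "n_genes": count,
            "status": "known" if pat in named else "novel",
        }
        for pat, count in sorted(seen.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return MatchReport(
        top_n=top_n,
        matched=matched,
        mismatched=mismatched,
        uncatalogued=uncatalogued,
        distinct_patterns=len(seen),
        novel_patterns=novel,
        pattern_tally=tally,
    )
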