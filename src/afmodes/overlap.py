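"""Overlap of survey-pruned mode residues with disorder-annotation ranges.

Annotation files follow the MobiDB-entry convention: a JSON object whose
keys are annotation names and whose values carry a ``regions`` list of
1-based inclusive residue ranges in sequence numbering. Continuous-score
annotations (no regions) are skipped with a warning; unknown keys inside
an annotation object are tolerated.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

__all__ = ["parse_annotation_ranges", "overlap_fractions", "format_overlap_table"]

_NON_ANNOTATION_KEYS = {"sequence", "acc", "name", "organism", "uniprot",
                        "length", "ncbi_taxon_id"}


def parse_annotation_ranges(document: str | dict) -> dict[str, list[tuple[int, int]]]:
    """Extract annotation-name -> [(start, end), ...] range lists.

    ``document`` is JSON text (or a file path, or an already-parsed dict).
    Inverted ranges raise ``ValueError`` naming the annotation.
    """
    if isinstance(document, dict):
        data = document
    else:
        text = str(document)
        if "\n" not in text and len(text) < 4096 and Path(text).exists():
            text = Path(text).read_text()
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("annotation document must be a JSON object")

    out: dict[str, list[tuple[int, int]]] = {}
    for name, value in data.items():
        if name in _NON_ANNOTATION_KEYS:
            continue
        if isinstance(value, dict):
            regions = value.get("regions")
        elif isinstance(value, list):
            regions = value
        else:
            regions = None
        if regions is None:
            warnings.warn(
                f"annotation {name!r} has no regions list; skipped", stacklevel=2
            )
            continue
        ranges = []
        for region in regions:
            start, end = int(region[0]), int(region[1])
            if start > end:
                raise ValueError(
                    f"annotation {name!r}: inverted range ({start}, {end})"
                )
            ranges.append((start, end))
        out[name] = ranges
    return out


def overlap_fractions(
    mode_residues: dict[str, set[int]],
    ranges: dict[str, list[tuple[int, int]]],
) -> dict[tuple[str, str], float]:
    """Fraction of each mode's residues covered by each annotation.

    ``mode_residues`` maps mode name -> set of residue sequence numbers
    (post survey pruning). Modes with zero residues are omitted.
    """
    table: dict[tuple[str, str], float] = {}
    for mode, residues in mode_residues.items():
        if not residues:
            continue
        for name, rngs in ranges.items():
            covered = sum(
                1 for r in residues if any(s <= r <= e for s, e in rngs)
            )
            table[(mode, name)] = covered / len(residues)
    return table


def format_overlap_table(table: dict[tuple[str, str], float]) -> str:
    """Render the (mode, annotation) -> fraction table as TSV."""
    lines = ["mode\tannotation\tfraction"]
    for (mode, name), frac in sorted(table.items()):
        lines.append(f"{mode}\t{name}\t{frac:.6f}")
    return "\n".join(lines) + "\n"
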