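"""Annotation renderers: text/JSON tables, kinemage markup, selection files."""

from __future__ import annotations

import json

from .classify import MODES, NEAR_PREDICTIVE, PREDICTIVE
from .pipeline import AnalysisResult
from .structure_io import write_structure_subset

__all__ = [
    "MODE_COLORS",
    "DEFAULT_SELECTION_MODES",
    "render_annotation",
    "render_kinemage",
    "write_selection_file",
]

#: kinemage palette tokens per mode
MODE_COLORS = {
    "predictive": "blue",
    "unpacked_high_plddt": "gray",
    "near_predictive": "green",
    "pseudostructure": "gold",
    "barbed_wire": "red",
    "unphysical": "purple",
}

DEFAULT_SELECTION_MODES = frozenset((PREDICTIVE, NEAR_PREDICTIVE))

_TEXT_HEADER = ("residue", "resname", "plddt", "ss", "pack_score", "packed",
                "mode_pre", "mode", "lprocg")


def _record_dict(rec) -> dict:
    return {
        "residue": rec.rid,
        "resname": rec.name,
        "plddt": round(rec.plddt, 2),
        "ss": rec.ss,
        "pack_score": round(rec.packing.score, 4) if rec.packing else None,
        "packed": rec.packed,
        "mode_pre": rec.mode_pre,
        "mode": rec.mode,
        "smoothed": rec.smoothed,
        "lprocg": rec.lprocg,
        "flags": {
            "rama_status": rec.flags.rama.status,
            "in_signature_box": rec.flags.rama.in_signature_box,
            "in_high_psi_band": rec.flags.rama.in_high_psi_band,
            "omega": rec.flags.omega_attr,
            "cis_pro": rec.flags.cis_pro_attr,
            "ca_geometry": rec.flags.ca_geom_outlier,
            "covalent": rec.flags.covalent_outlier,
            "high_density": rec.flags.high_density,
            "signature": rec.flags.signature,
        },
    }


def render_annotation(result: AnalysisResult, format: str = "text") -> str:
    """One record per eligible residue, chain order preserved.

    ``format='text'`` emits a TSV table; ``'structured'``/``'json'`` emits
    a JSON document with the same records.
    """
    if format in ("structured", "json"):
        return json.dumps({"residues": [_record_dict(r) for r in result.records]},
                          indent=1)
    lines = ["\t".join(_TEXT_HEADER)]
    for rec in result.records:
        d = _record_dict(rec)
        lines.append("\t".join(str(d[k]) for k in _TEXT_HEADER))
    return "\n".join(lines) + "\n"


def render_kinemage(result: AnalysisResult) -> str:
    """Kinemage markup: one toggleable group per mode present, each with
    mode-colored CA balls and per-residue Lprocg labels."""
    idx = result.model.index_of()
    lines = ["@kinemage 1", "@title {prediction-mode annotation}"]
    for mode in MODES:
        recs = [r for r in result.records if r.mode == mode]
        if not recs:
            continue
        color = MODE_COLORS[mode]
        lines.append(f"@group {{{mode}}} dominant")
        lines.append(f"@balllist {{{mode} CA}} color= {color} radius= 0.35")
        for rec in recs:
            ca = result.model.residues[idx[rec.rid]].coord("CA")
            if ca is None:
                continue
            lines.append(
                f"{{{rec.rid} {rec.name}}} {ca[0]:.3f} {ca[1]:.3f} {ca[2]:.3f}"
            )
        lines.append(f"@labellist {{{mode} labels}} color= {color}")
        for rec in recs:
            ca = result.model.residues[idx[rec.rid]].coord("CA")
            if ca is None:
                continue
            lines.append(
                f"{{{rec.lprocg}}} {ca[0]:.3f} {ca[1]:.3f} {ca[2] + 0.5:.3f}"
            )
    return "\n".join(lines) + "\n"


def write_selection_file(result: AnalysisResult, modes=None) -> str:
    """PDB text holding only residues whose post-smoothing mode is selected.

    Defaults to predictive + near_predictive. An empty selection raises
    ``ValueError`` carrying the mode census.
    """
    modes = frozenset(modes) if modes is not None else DEFAULT_SELECTION_MODES
    unknown = modes - set(MODES)
    if unknown:
        raise ValueError(f"unknown modes: {sorted(unknown)}")
    keep = {rec.rid for rec in result.records if rec.mode in modes}
    if not keep:
        census = result.mode_census()
        raise ValueError(
            f"no residues in modes {sorted(modes)}; mode census: {census}"
        )
    return write_structure_subset(result.model, keep)
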