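"""End-to-end annotation pipeline tying the stages together."""

from __future__ import annotations

import dataclasses

from .classify import classify_residue, smooth_modes
from .config import ClassifierConfig
from .geometry import (
    ResidueValidation,
    compute_backbone_dihedrals,
    compute_validation_flags,
    mark_outlier_density,
    mark_signature_outliers,
)
from .packing import PackingResult, compute_packing
from .secondary import SSAssignment, assign_secondary_structure
from .structure_io import StructureModel

__all__ = ["ResidueAnnotation", "AnalysisResult", "annotate_structure"]


@dataclasses.dataclass
class ResidueAnnotation:
    rid: str
    name: str
    plddt: float
    ss: str
    packing: PackingResult | None
    packed: bool
    flags: ResidueValidation
    mode_pre: str
    mode: str
    smoothed: bool
    lprocg: str = ""


@dataclasses.dataclass
class AnalysisResult:
    model: StructureModel
    config: ClassifierConfig
    ss: SSAssignment
    records: list[ResidueAnnotation]
    #: pre-smoothing labels keyed by model residue index (eligible residues)
    labels_pre: dict[int, str]
    labels_post: dict[int, str]

    def record_by_rid(self) -> dict[str, ResidueAnnotation]:
        return {r.rid: r for r in self.records}

    def mode_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for rec in self.records:
            census[rec.mode] = census.get(rec.mode, 0) + 1
        return census


def _lprocg(rec_plddt: float, packed: bool, flags: ResidueValidation,
            cfg: ClassifierConfig) -> str:
    low = rec_plddt < cfg.plddt_high
    unpacked = not packed
    letters = [
        "L" if low else "-",
        "p" if unpacked else "-",
        "r" if (flags.rama.status == "outlier"
                and flags.rama.in_high_psi_band) else "-",
        "o" if (flags.omega_attr
                or (flags.cis_pro_attr and low and unpacked)) else "-",
        "c" if flags.ca_geom_outlier else "-",
        "g" if flags.covalent_outlier else "-",
    ]
    return "".join(letters)


def annotate_structure(
    model: StructureModel,
    cfg: ClassifierConfig | None = None,
    inject: dict | None = None,
    radii: dict[str, float] | None = None,
) -> AnalysisResult:
    """Run secondary structure, packing, validation, classification and
    smoothing on a parsed model. Ineligible residues (missing backbone)
    receive no mode."""
    cfg = cfg or ClassifierConfig()
    if not model.segments:
        raise ValueError("model has no segments; run segment_chain first")

    ss = assign_secondary_structure(model, cfg)
    packing = compute_packing(model, ss, cfg, radii)
    packed = [p.packed if p is not None else False for p in packing]

    dihedrals = compute_backbone_dihedrals(model)
    flags = compute_validation_flags(model, dihedrals, cfg, inject)
    density = mark_outlier_density(flags, model.segments)
    signature = mark_signature_outliers(model, flags, packed, cfg)
    for i, f in enumerate(flags):
        f.high_density = density[i]
        f.signature = signature[i]

    labels_pre: dict[int, str] = {}
    for i, res in enumerate(model.residues):
        if not res.eligible:
            continue
        labels_pre[i] = classify_residue(
            res.plddt, packed[i], density[i], signature[i], cfg
        )
    labels_post, touched = smooth_modes(labels_pre, model.segments, cfg)

    records = []
    for i, res in enumerate(model.residues):
        if i not in labels_pre:
            continue
        records.append(
            ResidueAnnotation(
                rid=res.rid,
                name=res.name,
                plddt=res.plddt,
                ss=ss.ss[i],
                packing=packing[i],
                packed=packed[i],
                flags=flags[i],
                mode_pre=labels_pre[i],
                mode=labels_post[i],
                smoothed=i in touched,
                lprocg=_lprocg(res.plddt, packed[i], flags[i], cfg),
            )
        )
    return AnalysisResult(model=model, config=cfg, ss=ss, records=records,
                          labels_pre=labels_pre, labels_post=labels_post)
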