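"""Backbone dihedrals, covalent-geometry z-scores, peptide-bond classes,
Ramachandran status, CA-geometry flags, and the derived outlier-density
and signature-outlier booleans.

The Ramachandran evaluator is a coarse bundled region table with an
injection channel for externally computed statuses; the CA-geometry flag
is a virtual-angle/distance proxy with the same injection channel.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .config import ClassifierConfig
from .restraints import BACKBONE_RESTRAINTS, Restraint
from .structure_io import StructureModel

__all__ = [
    "DihedralRecord",
    "PeptideBondClass",
    "GeometryMeasure",
    "BondGeometryReport",
    "RamaEvaluation",
    "ResidueValidation",
    "dihedral_angle",
    "bond_angle",
    "compute_backbone_dihedrals",
    "classify_peptide_bond",
    "validate_bond_geometry",
    "residue_rama_class",
    "evaluate_ramachandran",
    "flag_ca_geometry",
    "mark_outlier_density",
    "mark_signature_outliers",
    "compute_validation_flags",
]


# ---------------------------------------------------------------------------
# vector primitives

def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral_angle(p0, p1, p2, p3) -> float | None:
    """Torsion p0-p1-p2-p3 in degrees, in (-180, 180].

    Returns ``None`` for degenerate (collinear) quadruples.
    """
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9:
        return None
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        return None
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


# ---------------------------------------------------------------------------
# domain types

@dataclasses.dataclass
class DihedralRecord:
    phi: float | None = None
    psi: float | None = None
    omega_prev: float | None = None  # omega of the bond entering the residue
    omega_next: float | None = None  # omega of the bond leaving the residue
    degenerate: bool = False


@dataclasses.dataclass
class PeptideBondClass:
    kind: str  # trans | cis_pro | cis_nonpro | twisted
    omega: float
    residues: tuple[int, int]  # model residue indices sharing the bond


@dataclasses.dataclass
class GeometryMeasure:
    name: str
    observed: float
    target: float
    sigma: float
    z: float
    residues: tuple[int, ...]  # residue indices the measure touches


@dataclasses.dataclass
class BondGeometryReport:
    measures: list[GeometryMeasure]
    #: z of the C(i-1)-N(i)-CA(i) angle, keyed by the bond (i-1, i)
    c_n_ca_z: dict[tuple[int, int], float]

    def per_residue(self, n: int) -> list[list[GeometryMeasure]]:
        out: list[list[GeometryMeasure]] = [[] for _ in range(n)]
        for m in self.measures:
            for i in m.residues:
                out[i].append(m)
        return out


@dataclasses.dataclass
class RamaEvaluation:
    status: str  # favored | allowed | outlier | unevaluable
    in_signature_box: bool
    in_high_psi_band: bool
    residue_class: str  # general | glycine | proline | pre_proline


@dataclasses.dataclass
class ResidueValidation:
    """Per-residue bundle of validation evidence."""

    rama: RamaEvaluation
    omega_attr: bool = False      # shares a cis-nonPro or twisted bond
    cis_pro_attr: bool = False    # shares a cis-Pro bond
    cnca_attr: bool = False       # shares a bond whose C-N-CA angle is an outlier
    ca_geom_outlier: bool = False
    covalent_outlier: bool = False
    high_density: bool = False
    signature: bool = False


_UNEVALUABLE = RamaEvaluation("unevaluable", False, False, "general")


# ---------------------------------------------------------------------------
# dihedrals

def compute_backbone_dihedrals(model: StructureModel) -> list[DihedralRecord]:
    """phi/psi/omega per residue; undefined at segment termini."""
    records = [DihedralRecord() for _ in model.residues]
    for seg in model.segments:
        for k, i in enumerate(seg):
            res = model.residues[i]
            n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
            prev = model.residues[seg[k - 1]] if k > 0 else None
            nxt = model.residues[seg[k + 1]] if k + 1 < len(seg) else None
            def defined(*coords) -> bool:
                return all(x is not None for x in coords)

            rec = records[i]
            if prev is not None and defined(prev.coord("C"), n, ca, c):
                rec.phi = dihedral_angle(prev.coord("C"), n, ca, c)
                if rec.phi is None:
                    rec.degenerate = True
            if nxt is not None and defined(n, ca, c, nxt.coord("N")):
                rec.psi = dihedral_angle(n, ca, c, nxt.coord("N"))
                if rec.psi is None:
                    rec.degenerate = True
                if defined(ca, c, nxt.coord("N"), nxt.coord("CA")):
                    omega = dihedral_angle(ca, c, nxt.coord("N"), nxt.coord("CA"))
                    rec.omega_next = omega
                    records[seg[k + 1]].omega_prev = omega
                    if omega is None:
                        rec.degenerate = True
    return records


# ---------------------------------------------------------------------------
# peptide-bond classes

def classify_peptide_bond(
    omega: float,
    next_residue_name: str,
    residues: tuple[int, int] = (-1, -1),
    cis_max: float = 30.0,
    trans_min: float = 150.0,
) -> PeptideBondClass:
    """|omega| <= 30 -> cis (cis_pro iff the following residue is PRO);
    |omega| >= 150 -> trans; otherwise twisted."""
    a = abs(omega)
    if a <= cis_max:
        kind = "cis_pro" if next_residue_name.upper() == "PRO" else "cis_nonpro"
    elif a >= trans_min:
        kind = "trans"
    else:
        kind = "twisted"
    return PeptideBondClass(kind=kind, omega=omega, residues=residues)


def peptide_bonds(
    model: StructureModel,
    dihedrals: list[DihedralRecord],
    cfg: ClassifierConfig | None = None,
) -> list[PeptideBondClass]:
    cfg = cfg or ClassifierConfig()
    bonds = []
    for seg in model.segments:
        for a, b in zip(seg, seg[1:]):
            omega = dihedrals[a].omega_next
            if omega is None:
                continue
            bonds.append(
                classify_peptide_bond(
                    omega,
                    model.residues[b].name,
                    residues=(a, b),
                    cis_max=cfg.omega_cis_max,
                    trans_min=cfg.omega_trans_min,
                )
            )
    return bonds


# ---------------------------------------------------------------------------
# covalent geometry

def _measure(res_atoms, names) -> tuple | None:
    coords = []
    for res, name in zip(res_atoms, names):
        c = res.coord(name)
        if c is None:
            return None
        coords.append(c)
    return tuple(coords)


def validate_bond_geometry(
    model: StructureModel,
    restraints: dict[str, Restraint] | None = None,
) -> BondGeometryReport:
    """z = (observed - target) / sigma for backbone bonds and angles.

    Missing atoms silently skip the affected measure. Inter-residue
    measures are evaluated along segments only and touch both residues.
    """
    restraints = restraints or BACKBONE_RESTRAINTS
    measures: list[GeometryMeasure] = []
    c_n_ca_z: dict[tuple[int, int], float] = {}

    def add(name: str, coords, residues: tuple[int, ...]) -> None:
        r = restraints[name]
        if r.kind == "bond":
            observed = float(np.linalg.norm(coords[0] - coords[1]))
        else:
            observed = bond_angle(*coords)
        z = (observed - r.target) / r.sigma
        measures.append(GeometryMeasure(name, observed, r.target, r.sigma, z, residues))
        if name == "C-N-CA":
            c_n_ca_z[residues] = z

    for seg in model.segments:
        for k, i in enumerate(seg):
            res = model.residues[i]
            for name, atom_names in (
                ("N-CA", ("N", "CA")),
                ("CA-C", ("CA", "C")),
                ("C-O", ("C", "O")),
            ):
                coords = _measure((res, res), atom_names)
                if coords:
                    add(name, coords, (i,))
            coords = _measure((res, res, res), ("N", "CA", "C"))
            if coords:
                add("N-CA-C", coords, (i,))
            coords = _measure((res, res, res), ("CA", "C", "O"))
            if coords:
                add("CA-C-O", coords, (i,))
            if k + 1 < len(seg):
                j = seg[k + 1]
                nxt = model.residues[j]
                coords = _measure((res, nxt), ("C", "N"))
                if coords:
                    add("C-N", coords, (i, j))
                coords = _measure((res, res, nxt), ("CA", "C", "N"))
                if coords:
                    add("CA-C-N", coords, (i, j))
                coords = _measure((res, nxt, nxt), ("C", "N", "CA"))
                if coords:
                    add("C-N-CA", coords, (i, j))
    return BondGeometryReport(measures=measures, c_n_ca_z=c_n_ca_z)


# ---------------------------------------------------------------------------
# Ramachandran

# Coarse region tables: (phi_lo, phi_hi, psi_lo, psi_hi) boxes. A point is
# favored if inside any favored box, allowed if inside any favored-or-allowed
# box, else an outlier. The tables are deliberately generous in the core
# regions and mark the upper-right signature box interior as outlier.
_GENERAL_FAVORED = [
    (-180.0, -45.0, 90.0, 180.0),    # beta / polyproline II
    (-180.0, -45.0, -180.0, -150.0),
    (-160.0, -20.0, -90.0, 30.0),    # right-handed alpha
]
_GENERAL_ALLOWED = [
    (-180.0, -20.0, 60.0, 180.0),
    (-180.0, -20.0, -180.0, -140.0),
    (-180.0, -20.0, -110.0, 45.0),
    (20.0, 90.0, -20.0, 90.0),       # left-handed alpha
]
_GLY_EXTRA_FAVORED = [
    (45.0, 180.0, -180.0, -90.0),
    (20.0, 160.0, -30.0, 90.0),
]
_GLY_EXTRA_ALLOWED = [
    (20.0, 180.0, -180.0, -60.0),
    (0.0, 180.0, -60.0, 100.0),
]
_PRO_FAVORED = [
    (-110.0, -40.0, 100.0, 180.0),   # polyproline II
    (-110.0, -40.0, -60.0, 10.0),
]
_PRO_ALLOWED = [
    (-120.0, -30.0, 60.0, 180.0),
    (-120.0, -30.0, -180.0, -160.0),
    (-120.0, -30.0, -75.0, 30.0),
]

_RAMA_TABLES = {
    "general": (_GENERAL_FAVORED, _GENERAL_ALLOWED),
    "pre_proline": (_GENERAL_FAVORED, _GENERAL_ALLOWED),
    "glycine": (
        _GENERAL_FAVORED + _GLY_EXTRA_FAVORED,
        _GENERAL_ALLOWED + _GLY_EXTRA_ALLOWED,
    ),
    "proline": (_PRO_FAVORED, _PRO_ALLOWED),
}


def _in_boxes(phi: float, psi: float, boxes) -> bool:
    return any(plo <= phi <= phi_hi and slo <= psi <= psi_hi
               for plo, phi_hi, slo, psi_hi in boxes)


def residue_rama_class(name: str, next_name: str | None) -> str:
    name = name.upper()
    if name == "GLY":
        return "glycine"
    if name == "PRO":
        return "proline"
    if next_name is not None and next_name.upper() == "PRO":
        return "pre_proline"
    return "general"


def evaluate_ramachandran(
    phi: float | None,
    psi: float | None,
    residue_class: str = "general",
    cfg: ClassifierConfig | None = None,
    injected_status: str | None = None,
) -> RamaEvaluation:
    """Status from the bundled coarse region table (or an injected status),
    plus membership in the signature box and the high-psi band."""
    cfg = cfg or ClassifierConfig()
    if phi is None or psi is None:
        return RamaEvaluation("unevaluable", False, False, residue_class)
    box = (cfg.signature_box_phi[0] < phi < cfg.signature_box_phi[1]
           and cfg.signature_box_psi[0] < psi < cfg.signature_box_psi[1])
    band = cfg.high_psi_band[0] < psi < cfg.high_psi_band[1]
    if injected_status is not None:
        status = injected_status
    else:
        favored, allowed = _RAMA_TABLES.get(residue_class, _RAMA_TABLES["general"])
        if _in_boxes(phi, psi, favored):
            status = "favored"
        elif _in_boxes(phi, psi, allowed):
            status = "allowed"
        else:
            status = "outlier"
    return RamaEvaluation(status, box, band, residue_class)


# ---------------------------------------------------------------------------
# CA-geometry proxy

def flag_ca_geometry(
    model: StructureModel,
    cfg: ClassifierConfig | None = None,
    injected_outliers: set[str] | None = None,
) -> list[bool]:
    """Proxy CA-trace outlier flag (virtual angle/distance thresholds).

    Residues without both intra-segment neighbors are never flagged. When
    an external outlier list is injected it fully overrides the proxy.
    """
    cfg = cfg or ClassifierConfig()
    flags = [False] * len(model.residues)
    if injected_outliers is not None:
        for i, res in enumerate(model.residues):
            flags[i] = res.rid in injected_outliers
        return flags
    for seg in model.segments:
        cas = [model.residues[i].coord("CA") for i in seg]
        for k in range(1, len(seg) - 1):
            a, b, c = cas[k - 1], cas[k], cas[k + 1]
            if a is None or b is None or c is None:
                continue
            ang = bond_angle(a, b, c)
            d1 = float(np.linalg.norm(b - a))
            d2 = float(np.linalg.norm(c - b))
            bad = (ang < cfg.ca_angle_min or ang > cfg.ca_angle_max
                   or not cfg.ca_dist_min <= d1 <= cfg.ca_dist_max
                   or not cfg.ca_dist_min <= d2 <= cfg.ca_dist_max)
            if bad:
                flags[seg[k]] = True
    return flags


# ---------------------------------------------------------------------------
# derived booleans

def mark_outlier_density(
    flags: list[ResidueValidation],
    segments: list[list[int]],
) -> list[bool]:
    """High outlier density over the 3-residue window {i-1, i, i+1}.

    Conditions, counted over the window (within one segment):
      c1: >=2 residues share a cis-nonPro or twisted peptide bond
      c2: >=2 residues have CA-geometry outliers
      c3: >=2 residues have covalent bond-length/angle outliers
      c4: all three residues in the high-psi band and >=1 is a
          Ramachandran outlier (never satisfied by truncated windows)
    High density iff >=2 conditions hold.
    """
    out = [False] * len(flags)
    for seg in segments:
        for k, i in enumerate(seg):
            window = seg[max(0, k - 1): k + 2]
            c1 = sum(flags[j].omega_attr for j in window) >= 2
            c2 = sum(flags[j].ca_geom_outlier for j in window) >= 2
            c3 = sum(flags[j].covalent_outlier for j in window) >= 2
            c4 = (
                len(window) == 3
                and all(flags[j].rama.in_high_psi_band for j in window)
                and any(flags[j].rama.status == "outlier" for j in window)
            )
            out[i] = (c1 + c2 + c3 + c4) >= 2
    return out


def mark_signature_outliers(
    model: StructureModel,
    flags: list[ResidueValidation],
    packed: list[bool],
    cfg: ClassifierConfig | None = None,
) -> list[bool]:
    """Signature outliers characteristic of barbed wire.

    s1: Ramachandran outlier inside the upper-right signature box
    s2: CA-geometry outlier in a low-pLDDT, unpacked region
    s3: shares a peptide bond carrying a C-N-CA outlier, a cis-nonPro,
        or any twisted omega (both sharers marked)
    s4: shares a cis-Pro bond in a low-pLDDT, unpacked region
    """
    cfg = cfg or ClassifierConfig()
    out = [False] * len(flags)
    for i, res in enumerate(model.residues):
        f = flags[i]
        low = res.plddt is not None and res.plddt < cfg.plddt_high
        s1 = f.rama.status == "outlier" and f.rama.in_signature_box
        s2 = f.ca_geom_outlier and low and not packed[i]
        s3 = f.omega_attr or f.cnca_attr
        s4 = f.cis_pro_attr and low and not packed[i]
        out[i] = s1 or s2 or s3 or s4
    return out


def compute_validation_flags(
    model: StructureModel,
    dihedrals: list[DihedralRecord],
    cfg: ClassifierConfig | None = None,
    inject: dict | None = None,
) -> list[ResidueValidation]:
    """Assemble per-residue validation evidence (density and signature
    are filled in later, once packing and pLDDT are known).

    ``inject`` optionally carries externally computed evidence:
    ``{"rama": {rid: status}, "cablam_outliers": [rid, ...]}``.
    """
    cfg = cfg or ClassifierConfig()
    inject = inject or {}
    rama_inject: dict[str, str] = inject.get("rama", {})
    cablam: set[str] | None = (
        set(inject["cablam_outliers"]) if "cablam_outliers" in inject else None
    )

    n = len(model.residues)
    next_name: list[str | None] = [None] * n
    for seg in model.segments:
        for a, b in zip(seg, seg[1:]):
            next_name[a] = model.residues[b].name

    flags: list[ResidueValidation] = []
    for i, res in enumerate(model.residues):
        rc = residue_rama_class(res.name, next_name[i])
        rama = evaluate_ramachandran(
            dihedrals[i].phi, dihedrals[i].psi, rc, cfg,
            injected_status=rama_inject.get(res.rid),
        )
        flags.append(ResidueValidation(rama=rama))

    for bond in peptide_bonds(model, dihedrals, cfg):
        a, b = bond.residues
        if bond.kind in ("cis_nonpro", "twisted"):
            flags[a].omega_attr = True
            flags[b].omega_attr = True
        elif bond.kind == "cis_pro":
            flags[a].cis_pro_attr = True
            flags[b].cis_pro_attr = True

    report = validate_bond_geometry(model)
    for m in report.measures:
        if abs(m.z) > cfg.bond_z_cutoff:
            for i in m.residues:
                flags[i].covalent_outlier = True
    for (a, b), z in report.c_n_ca_z.items():
        if abs(z) > cfg.bond_z_cutoff:
            flags[a].cnca_attr = True
            flags[b].cnca_attr = True

    for i, bad in enumerate(flag_ca_geometry(model, cfg, injected_outliers=cablam)):
        flags[i].ca_geom_outlier = bad

    return flags
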