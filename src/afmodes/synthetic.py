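"""Synthetic backbone decoys built from torsion scripts.

Backbones are constructed atom-by-atom in internal coordinates (natural
extension reference frames) from ideal restraint-table geometry plus the
scripted torsions, with optional distortions injected into named bonds,
angles, or torsions. Fixture recipes emulate the characteristic
prediction failure modes: distorted high-psi coils, isolated clean
secondary-structure elements, poly-proline II stretches, and packed
assemblies, each with an assignable pLDDT profile.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import classify as modes
from .restraints import (
    BACKBONE_RESTRAINTS,
    CB_BOND,
    CB_IMPROPER,
    N_CA_CB_ANGLE,
    Restraint,
)
from .structure_io import Atom, Residue, StructureModel, segment_chain

__all__ = [
    "TorsionScript",
    "FixtureSpec",
    "FIXTURE_KINDS",
    "place_atom",
    "build_backbone",
    "make_fixture",
    "make_smoothing_fixture",
]

#: torsion measures accepted as distortion targets besides the restraints
_TORSION_MEASURES = ("phi", "psi", "omega")

PLDDT_FLOOR = 20.0


@dataclasses.dataclass
class TorsionScript:
    """Recipe for one chain: residue names, torsions, distortions, pLDDT.

    ``torsions[i]`` is (phi, psi, omega) in degrees, where omega is the
    torsion of the bond leaving residue i. phi of the first residue and
    psi/omega of the last are unused. Distortions map
    (residue_index, measure_name) to an offset: sigma units for restraint
    measures, degrees for phi/psi/omega.
    """

    names: list[str]
    torsions: list[tuple[float, float, float]]
    distortions: dict[tuple[int, str], float] = dataclasses.field(default_factory=dict)
    plddt_profile: list[float] | None = None
    chain_id: str = "A"
    first_seq: int = 1

    def validate(self) -> None:
        if len(self.names) != len(self.torsions):
            raise ValueError("names and torsions length mismatch")
        if self.plddt_profile is not None and len(self.plddt_profile) != len(self.names):
            raise ValueError("plddt_profile length mismatch")
        for (idx, measure), _ in self.distortions.items():
            if not 0 <= idx < len(self.names):
                raise ValueError(f"distortion residue index {idx} out of range")
            if measure not in BACKBONE_RESTRAINTS and measure not in _TORSION_MEASURES:
                raise ValueError(f"unknown distortion measure {measure!r}")


@dataclasses.dataclass
class FixtureSpec:
    kind: str
    expected_mode: str
    seed: int = 0


FIXTURE_KINDS: dict[str, str] = {
    "predictive_bundle": modes.PREDICTIVE,
    "unpacked_helix": modes.UNPACKED_HIGH_PLDDT,
    "near_predictive_domain": modes.NEAR_PREDICTIVE,
    "pseudostructure_helix": modes.PSEUDOSTRUCTURE,
    "pseudostructure_strand": modes.PSEUDOSTRUCTURE,
    "polyproline_II": modes.PSEUDOSTRUCTURE,
    "barbed_wire_coil": modes.BARBED_WIRE,
    "unphysical_core": modes.UNPHYSICAL,
}


# ---------------------------------------------------------------------------
# internal-to-Cartesian construction

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C with |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion (natural extension reference frame)."""
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(tau),
        bond * math.sin(theta) * math.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _value(script: TorsionScript, idx: int, measure: str,
           restraints: dict[str, Restraint]) -> float:
    """Ideal (or scripted) value plus any distortion for a measure whose
    last-placed atom belongs to residue ``idx``."""
    offset = script.distortions.get((idx, measure), 0.0)
    if measure in _TORSION_MEASURES:
        phi, psi, omega = script.torsions[idx]
        base = {"phi": phi, "psi": psi, "omega": omega}[measure]
        return base + offset
    r = restraints[measure]
    return r.target + offset * r.sigma


def build_backbone(
    script: TorsionScript,
    restraints: dict[str, Restraint] | None = None,
) -> StructureModel:
    """Construct N/CA/C/O (+CB for non-GLY) coordinates from the script.

    Inter-residue measures ("C-N", "CA-C-N", "C-N-CA", and omega/psi used
    to place residue i+1's atoms) are indexed by the residue owning the
    last-placed atom, so a distortion at (k, "C-N-CA") lands on the bond
    into residue k.
    """
    restraints = restraints or BACKBONE_RESTRAINTS
    script.validate()
    n_res = len(script.names)
    if n_res == 0:
        raise ValueError("empty torsion script")

    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res

    # first residue in a canonical frame
    N[0] = np.zeros(3)
    CA[0] = np.array([_value(script, 0, "N-CA", restraints), 0.0, 0.0])
    theta = math.radians(_value(script, 0, "N-CA-C", restraints))
    r = _value(script, 0, "CA-C", restraints)
    C[0] = CA[0] + r * np.array([-math.cos(theta), math.sin(theta), 0.0])

    for i in range(1, n_res):
        # psi(i-1) places N(i); omega(i-1) places CA(i); phi(i) places C(i)
        psi = _value(script, i - 1, "psi", restraints)
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          _value(script, i, "C-N", restraints),
                          _value(script, i, "CA-C-N", restraints), psi)
        omega = _value(script, i - 1, "omega", restraints)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           _value(script, i, "N-CA", restraints),
                           _value(script, i, "C-N-CA", restraints), omega)
        phi = _value(script, i, "phi", restraints)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          _value(script, i, "CA-C", restraints),
                          _value(script, i, "N-CA-C", restraints), phi)

    residues: list[Residue] = []
    plddt = script.plddt_profile or [50.0] * n_res
    serial = 0
    for i, name in enumerate(script.names):
        atoms = []

        def add(atom_name: str, element: str, pos: np.ndarray) -> None:
            nonlocal serial
            serial += 1
            atoms.append(Atom(name=atom_name, element=element,
                              position=pos, b_value=float(plddt[i]),
                              serial=serial))

        add("N", "N", N[i])
        add("CA", "C", CA[i])
        add("C", "C", C[i])
        # carbonyl O in the peptide plane, anti to the next N
        r_co = _value(script, i, "C-O", restraints)
        a_co = _value(script, i, "CA-C-O", restraints)
        if i + 1 < n_res:
            O = place_atom(N[i + 1], CA[i], C[i], r_co, a_co, 180.0)
        else:
            psi = script.torsions[i][1]
            O = place_atom(N[i], CA[i], C[i], r_co, a_co, psi - 180.0)
        add("O", "O", O)
        if name.upper() != "GLY":
            CB = place_atom(N[i], C[i], CA[i], CB_BOND, N_CA_CB_ANGLE, CB_IMPROPER)
            add("CB", "C", CB)
        residues.append(
            Residue(chain_id=script.chain_id,
                    seq_number=script.first_seq + i,
                    insertion_code="",
                    name=name.upper(),
                    atoms=atoms,
                    plddt=float(plddt[i]))
        )
    return segment_chain(StructureModel(residues=residues))


# ---------------------------------------------------------------------------
# fixture recipes

HELIX = (-57.0, -47.0, 180.0)
STRAND = (-120.0, 120.0, 180.0)
PPII = (-75.0, 150.0, 180.0)

#: grid spacing for packed multi-chain assemblies (A); deliberately tight
#: so interior packing scores sit well above the helix/coil cutoff
BUNDLE_SPACING = 6.0


def _uniform_script(n: int, torsions, name: str = "ALA", plddt: float = 50.0,
                    chain_id: str = "A") -> TorsionScript:
    return TorsionScript(
        names=[name] * n,
        torsions=[torsions] * n,
        plddt_profile=[plddt] * n,
        chain_id=chain_id,
    )


def _translate(model: StructureModel, shift, chain_id: str) -> list[Residue]:
    shift = np.asarray(shift, float)
    out = []
    for res in model.residues:
        atoms = [Atom(a.name, a.element, a.position + shift, a.b_value, a.serial)
                 for a in res.atoms]
        out.append(Residue(chain_id=chain_id, seq_number=res.seq_number,
                           insertion_code="", name=res.name, atoms=atoms,
                           plddt=res.plddt))
    return out


def _bundle(base_script: TorsionScript, spacing: float) -> StructureModel:
    """Four translated copies of one chain on a 2x2 grid (chains A-D)."""
    base = build_backbone(base_script)
    shifts = {"A": (0.0, 0.0, 0.0), "B": (spacing, 0.0, 0.0),
              "C": (0.0, spacing, 0.0), "D": (spacing, spacing, 0.0)}
    residues: list[Residue] = []
    for chain_id, shift in shifts.items():
        residues.extend(_translate(base, shift, chain_id))
    return segment_chain(StructureModel(residues=residues))


def _interior(model: StructureModel, margin: int = 2) -> list[int]:
    out = []
    for seg in model.segments:
        out.extend(seg[margin: len(seg) - margin])
    return out


def _barbed_script(rng: np.random.Generator, n: int,
                   twist_frac: float = 0.5, cnca_frac: float = 0.5,
                   rama_only: bool = False) -> TorsionScript:
    """High-psi-band distorted coil emulating non-predicted filler:
    phi/psi drawn inside the upper-right signature box, with twisted
    peptide bonds and -4.5 sigma C-N-CA errors unless ``rama_only``.

    phi is drawn from the extended (high-phi) side of the box: low-phi
    draws curl the chain into compact self-contacting coils, whereas the
    failure mode being emulated is wide unpacked loops.
    """
    torsions = []
    distortions: dict[tuple[int, str], float] = {}
    for i in range(n):
        if rama_only:
            # stay clear of the marginally-allowed alpha-L corner so every
            # residue is a box Ramachandran outlier
            phi = float(rng.uniform(60.0, 165.0))
            psi = float(rng.uniform(95.0, 165.0))
        else:
            phi = float(rng.uniform(60.0, 170.0))
            psi = float(rng.uniform(60.0, 170.0))
        omega = 180.0
        if not rama_only and rng.uniform() < twist_frac:
            omega = float(rng.choice([-1.0, 1.0]) * rng.uniform(60.0, 140.0))
        torsions.append((phi, psi, omega))
        if not rama_only and rng.uniform() < cnca_frac and i > 0:
            distortions[(i, "C-N-CA")] = -4.5
    plddt = [float(rng.uniform(PLDDT_FLOOR, 45.0)) for _ in range(n)]
    return TorsionScript(names=["ALA"] * n, torsions=torsions,
                         distortions=distortions, plddt_profile=plddt)


def _unpacked_coil(rng: np.random.Generator, n: int,
                   rama_only: bool = False,
                   max_attempts: int = 50) -> StructureModel:
    """Draw coil scripts until the built chain has no packed residue.

    Random coils occasionally loop back onto themselves and pick up
    enough self-contacts to count as packed; those draws are rejected so
    the fixture reliably exercises the unpacked branch of the tree.
    """
    from .packing import compute_packing
    from .secondary import assign_secondary_structure

    for _ in range(max_attempts):
        model = build_backbone(_barbed_script(rng, n, rama_only=rama_only))
        ss = assign_secondary_structure(model)
        packing = compute_packing(model, ss)
        if not any(p is not None and p.packed for p in packing):
            return model
    raise RuntimeError("could not draw an unpacked coil")


def make_fixture(spec: FixtureSpec) -> tuple[StructureModel, dict[int, str]]:
    """Build a fixture model plus expected per-residue modes.

    The expectation map covers interior residues only (window truncation
    makes chain ends legitimately ambiguous); keys are model residue
    indices. Deterministic for a fixed seed.
    """
    if spec.kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    expected_mode = FIXTURE_KINDS[spec.kind]
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "predictive_bundle":
        model = _bundle(_uniform_script(16, HELIX, plddt=90.0), BUNDLE_SPACING)
        interior = _interior(model, 3)
    elif spec.kind == "near_predictive_domain":
        model = _bundle(_uniform_script(16, HELIX, plddt=60.0), BUNDLE_SPACING)
        interior = _interior(model, 3)
    elif spec.kind == "unpacked_helix":
        model = build_backbone(_uniform_script(16, HELIX, plddt=92.0))
        interior = _interior(model, 1)
    elif spec.kind == "pseudostructure_helix":
        model = build_backbone(_uniform_script(16, HELIX, plddt=35.0))
        interior = _interior(model, 1)
    elif spec.kind == "pseudostructure_strand":
        model = build_backbone(_uniform_script(12, STRAND, plddt=30.0))
        interior = _interior(model, 1)
    elif spec.kind == "polyproline_II":
        model = build_backbone(_uniform_script(12, PPII, name="PRO", plddt=40.0))
        interior = _interior(model, 1)
    elif spec.kind == "barbed_wire_coil":
        model = _unpacked_coil(rng, 24)
        interior = _interior(model, 2)
    else:  # unphysical_core
        script = _uniform_script(16, HELIX, plddt=55.0)
        script.distortions = {(i, "C-N-CA"): -4.5 for i in range(2, 15, 2)}
        model = _bundle(script, BUNDLE_SPACING)
        interior = _interior(model, 3)

    return model, {i: expected_mode for i in interior}


def make_smoothing_fixture(seed: int = 0) -> tuple[StructureModel, dict[int, str], dict[int, str]]:
    """Chain interleaving a 2-residue clean run inside a distorted coil.

    The distorted flanks carry only upper-right-box Ramachandran outliers
    (no peptide-bond evidence), so the clean pair classifies as
    pseudostructure pre-smoothing and is absorbed into barbed wire by
    smoothing. Returns (model, expected_pre, expected_post).
    """
    from .packing import compute_packing
    from .secondary import assign_secondary_structure

    rng = np.random.default_rng(seed)
    for _ in range(50):
        left = _barbed_script(rng, 8, rama_only=True)
        right = _barbed_script(rng, 8, rama_only=True)
        names = left.names + ["ALA", "ALA"] + right.names
        torsions = list(left.torsions) + [HELIX, HELIX] + list(right.torsions)
        plddt = list(left.plddt_profile) + [30.0, 30.0] + list(right.plddt_profile)
        model = build_backbone(TorsionScript(names=names, torsions=torsions,
                                             plddt_profile=plddt))
        packing = compute_packing(model, assign_secondary_structure(model))
        if not any(p is not None and p.packed for p in packing):
            break
    else:
        raise RuntimeError("could not draw an unpacked smoothing fixture")
    # chain termini lack phi or psi, so they carry no box outlier and stay
    # pseudostructure (terminal runs are never smoothed)
    pre = {i: modes.BARBED_WIRE for i in range(1, 17)}
    pre[0] = pre[17] = modes.PSEUDOSTRUCTURE
    pre[8] = pre[9] = modes.PSEUDOSTRUCTURE
    post = dict(pre)
    post[8] = post[9] = modes.BARBED_WIRE
    return model, pre, post
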