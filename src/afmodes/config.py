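"""Configuration for the mode classifier and its geometric thresholds."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class ClassifierConfig:
    """All numeric thresholds used by the classification pipeline.

    Defaults follow the published tool description: pLDDT >= 70 is "high
    confidence"; packing cutoffs are > 0.6 contacts per heavy atom for
    helix/coil and > 0.35 for strand; contacts require van der Waals
    surface separation <= 0.25 A; covalent outliers are |z| > 4.
    """

    plddt_high: float = 70.0
    pack_cutoff_helix_coil: float = 0.6
    pack_cutoff_strand: float = 0.35
    contact_gap: float = 0.25
    #: contacts at chain sequence separation <= this value are ignored
    local_sequence_exclusion: int = 4
    bond_z_cutoff: float = 4.0
    #: high-psi Ramachandran band, open interval on psi (degrees)
    high_psi_band: tuple[float, float] = (60.0, 170.0)
    #: signature upper-right Ramachandran box, open intervals (degrees)
    signature_box_phi: tuple[float, float] = (-15.0, 170.0)
    signature_box_psi: tuple[float, float] = (60.0, 170.0)
    #: |omega| <= cis_max -> cis; |omega| >= trans_min -> trans; else twisted
    omega_cis_max: float = 30.0
    omega_trans_min: float = 150.0
    density_window: int = 3
    packing_window: int = 5
    smoothing_max_run: int = 2
    #: peptide-bond continuity threshold on C(i)-N(i+1) distance (A)
    peptide_bond_max: float = 2.5
    #: CA-geometry proxy thresholds
    ca_angle_min: float = 73.0
    ca_angle_max: float = 155.0
    ca_dist_min: float = 2.7
    ca_dist_max: float = 4.1
    #: minimum run lengths for secondary-structure elements
    helix_min_len: int = 5
    strand_min_len: int = 3

    def validate(self) -> None:
        for name in ("plddt_high", "pack_cutoff_helix_coil", "pack_cutoff_strand",
                     "contact_gap", "bond_z_cutoff", "peptide_bond_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        for lo, hi in (self.high_psi_band, self.signature_box_phi,
                       self.signature_box_psi):
            if not lo < hi:
                raise ValueError("band/box bounds must be ordered (low < high)")

    @classmethod
    def from_file(cls, path: str | Path) -> "ClassifierConfig":
        """Load overrides from a JSON file; unknown keys are rejected."""
        data = json.loads(Path(path).read_text())
        data.pop("radii", None)  # consumed by the packing stage
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("high_psi_band", "signature_box_phi", "signature_box_psi"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def load_radii_overrides(path: str | Path) -> dict[str, float]:
    """Extract an element->radius mapping from a config file, if present."""
    data = json.loads(Path(path).read_text())
    radii = data.get("radii", {})
    return {str(k).upper(): float(v) for k, v in radii.items()}
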