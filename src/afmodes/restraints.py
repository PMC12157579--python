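"""Bundled covalent-geometry restraints (Engh & Huber style targets).

Bond lengths in Angstroms, angles in degrees. Each measure is named by
the backbone atoms it spans; measures crossing the peptide bond ("C-N",
"CA-C-N", "C-N-CA") are evaluated between consecutive residues of one
segment and attributed to both bond-sharing residues.
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class Restraint:
    name: str
    target: float
    sigma: float
    kind: str  # "bond" | "angle"


BACKBONE_RESTRAINTS: dict[str, Restraint] = {
    r.name: r
    for r in (
        Restraint("N-CA", 1.458, 0.019, "bond"),
        Restraint("CA-C", 1.525, 0.021, "bond"),
        Restraint("C-O", 1.231, 0.020, "bond"),
        Restraint("C-N", 1.329, 0.014, "bond"),
        Restraint("N-CA-C", 111.2, 2.8, "angle"),
        Restraint("CA-C-N", 116.2, 2.0, "angle"),
        Restraint("CA-C-O", 120.8, 1.7, "angle"),
        Restraint("C-N-CA", 121.7, 1.8, "angle"),
    )
}

#: auxiliary ideal values used only by the synthetic backbone builder
CB_BOND = 1.530
N_CA_CB_ANGLE = 110.4
CB_IMPROPER = -122.6  # dihedral N -> C -> CA -> CB
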