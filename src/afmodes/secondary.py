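"""CA-geometry secondary-structure assignment (P-SEA-style criteria).

Works from CA positions alone so it stays usable on distorted low-pLDDT
backbones. Helix wins over strand on ties; runs shorter than the minimum
element length revert to coil.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import ClassifierConfig
from .geometry import bond_angle, dihedral_angle
from .structure_io import StructureModel

__all__ = ["SSAssignment", "assign_secondary_structure"]

# CA-only criteria, calibrated on ideal generated geometry:
#   helix:  d(CA_i, CA_{i+3}) in [4.8, 5.6] A and the CA virtual dihedral
#           over (i..i+3) in [40, 70] degrees
#   strand: d(CA_i, CA_{i+2}) in [6.3, 7.1] A and the CA virtual angle at
#           the central residue in [110, 150] degrees
_HELIX_D13 = (4.8, 5.6)
_HELIX_DIH = (40.0, 70.0)
_STRAND_D02 = (6.3, 7.1)
_STRAND_ANG = (110.0, 150.0)


@dataclasses.dataclass
class SSAssignment:
    ss: list[str]                 # per-residue: helix | strand | coil
    element_id: list[int | None]  # id of the surviving element, or None

    def elements(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, e in enumerate(self.element_id):
            if e is not None:
                out.setdefault(e, []).append(i)
        return out


def _in(value: float, bounds: tuple[float, float]) -> bool:
    return bounds[0] <= value <= bounds[1]


def assign_secondary_structure(
    model: StructureModel,
    cfg: ClassifierConfig | None = None,
) -> SSAssignment:
    cfg = cfg or ClassifierConfig()
    n = len(model.residues)
    ss = ["coil"] * n

    for seg in model.segments:
        cas = [model.residues[i].coord("CA") for i in seg]
        m = len(seg)

        helix = [False] * m
        for j in range(m - 3):
            quad = cas[j: j + 4]
            if any(c is None for c in quad):
                continue
            d13 = float(np.linalg.norm(quad[3] - quad[0]))
            dih = dihedral_angle(*quad)
            if dih is not None and _in(d13, _HELIX_D13) and _in(dih, _HELIX_DIH):
                for k in range(j, j + 4):
                    helix[k] = True

        strand = [False] * m
        for k in range(1, m - 1):
            a, b, c = cas[k - 1], cas[k], cas[k + 1]
            if a is None or b is None or c is None:
                continue
            ang = bond_angle(a, b, c)
            ok_d = False
            if k + 2 < m and cas[k + 2] is not None:
                ok_d = ok_d or _in(float(np.linalg.norm(cas[k + 2] - b)), _STRAND_D02)
            if k - 2 >= 0 and cas[k - 2] is not None:
                ok_d = ok_d or _in(float(np.linalg.norm(b - cas[k - 2])), _STRAND_D02)
            if _in(ang, _STRAND_ANG) and ok_d:
                strand[k] = True

        for k, i in enumerate(seg):
            if helix[k]:
                ss[i] = "helix"  # helix wins ties
            elif strand[k]:
                ss[i] = "strand"

    # enforce minimum run lengths and assign element ids, per segment
    element_id: list[int | None] = [None] * n
    next_id = 0
    minimums = {"helix": cfg.helix_min_len, "strand": cfg.strand_min_len}
    for seg in model.segments:
        k = 0
        while k < len(seg):
            label = ss[seg[k]]
            j = k
            while j < len(seg) and ss[seg[j]] == label:
                j += 1
            if label != "coil":
                run = seg[k:j]
                if len(run) < minimums[label]:
                    for i in run:
                        ss[i] = "coil"
                else:
                    for i in run:
                        element_id[i] = next_id
                    next_id += 1
            k = j
    return SSAssignment(ss=ss, element_id=element_id)
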