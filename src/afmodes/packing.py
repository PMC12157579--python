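"""Tertiary-contact detection and the per-residue packing score.

Contacts are heavy-atom pairs whose van der Waals surfaces approach
within a small gap. Pairs internal to one secondary-structure element and
pairs at chain sequence separation <= 4 are excluded, so only tertiary
contacts count. The score is contacts per heavy atom over a 5-residue
window; helix/coil residues are packed above 0.6, strands above 0.35.

This replaces the reference Reduce+Probe hydrogen-inclusive dot-surface
pipeline with a documented heavy-atom distance criterion; absolute scores
therefore differ from the reference tool, and the cutoffs are exposed as
configuration.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .config import ClassifierConfig
from .secondary import SSAssignment
from .structure_io import StructureModel

__all__ = [
    "DEFAULT_RADII",
    "PackingResult",
    "find_contacts",
    "packing_score",
    "is_packed",
    "compute_packing",
]

# Probe-style van der Waals radii (Angstroms)
DEFAULT_RADII: dict[str, float] = {"C": 1.70, "N": 1.625, "O": 1.40, "S": 1.80}
_FALLBACK_RADIUS = 1.70


@dataclasses.dataclass
class PackingResult:
    contact_count: int
    window_heavy_atoms: int
    score: float
    packed: bool


def _radius(element: str, radii: dict[str, float]) -> float:
    try:
        return radii[element.upper()]
    except KeyError:
        warnings.warn(
            f"no van der Waals radius for element {element!r}; "
            f"using {_FALLBACK_RADIUS} A",
            stacklevel=2,
        )
        return _FALLBACK_RADIUS


def _atom_table(model: StructureModel, radii: dict[str, float]):
    """Flat arrays over all heavy atoms: positions, radii, residue index."""
    positions, rads, owner = [], [], []
    for i, res in enumerate(model.residues):
        for atom in res.atoms:
            positions.append(atom.position)
            rads.append(_radius(atom.element, radii))
            owner.append(i)
    if not positions:
        return np.empty((0, 3)), np.empty(0), np.empty(0, dtype=int)
    return np.asarray(positions), np.asarray(rads), np.asarray(owner, dtype=int)


def find_contacts(
    model: StructureModel,
    radii: dict[str, float] | None = None,
    ss: SSAssignment | None = None,
    gap: float = 0.25,
    local_sequence_exclusion: int = 4,
) -> set[tuple[int, int]]:
    """Qualifying heavy-atom contact pairs, as flat-atom index pairs (a<b).

    A pair qualifies iff dist <= r_a + r_b + gap (inclusive), the residues
    are not within ``local_sequence_exclusion`` positions on one chain,
    and they do not share a secondary-structure element.
    """
    radii = radii or DEFAULT_RADII
    positions, rads, owner = _atom_table(model, radii)
    if len(positions) == 0:
        return set()

    chain_pos = np.full(len(model.residues), -1, dtype=int)
    chain_of = np.empty(len(model.residues), dtype=object)
    for chain_id, idxs in model.chains().items():
        for pos, i in enumerate(idxs):
            chain_pos[i] = pos
            chain_of[i] = chain_id
    element = (ss.element_id if ss is not None
               else [None] * len(model.residues))

    tree = cKDTree(positions)
    max_cut = float(2 * rads.max() + gap)
    contacts: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(max_cut):
        ra, rb = owner[a], owner[b]
        if ra == rb:
            continue
        d = float(np.linalg.norm(positions[a] - positions[b]))
        if d > rads[a] + rads[b] + gap:
            continue
        if (chain_of[ra] == chain_of[rb]
                and abs(int(chain_pos[ra]) - int(chain_pos[rb])) <= local_sequence_exclusion):
            continue
        if element[ra] is not None and element[ra] == element[rb]:
            continue
        contacts.add((min(a, b), max(a, b)))
    return contacts


def packing_score(
    model: StructureModel,
    residue_index: int,
    contacts: set[tuple[int, int]],
    window: int = 5,
) -> PackingResult | None:
    """Contacts-per-heavy-atom over the residue's 5-residue segment window.

    Numerator: distinct contact pairs with at least one atom inside the
    window. Denominator: heavy atoms in the window. Returns ``None`` when
    the window holds no heavy atoms.
    """
    seg = None
    for s in model.segments:
        if residue_index in s:
            seg = s
            break
    if seg is None:
        return None
    k = seg.index(residue_index)
    half = window // 2
    window_res = set(seg[max(0, k - half): k + half + 1])

    # map flat atom indices back to residues
    owner: list[int] = []
    for i, res in enumerate(model.residues):
        owner.extend([i] * len(res.atoms))

    heavy = sum(len(model.residues[i].atoms) for i in window_res)
    if heavy == 0:
        return None
    count = sum(1 for a, b in contacts
                if owner[a] in window_res or owner[b] in window_res)
    return PackingResult(contact_count=count, window_heavy_atoms=heavy,
                         score=count / heavy, packed=False)


def is_packed(score: float, ss: str, cfg: ClassifierConfig | None = None) -> bool:
    """Strand residues pack above 0.35; helix and coil above 0.6 (strict)."""
    cfg = cfg or ClassifierConfig()
    cutoff = cfg.pack_cutoff_strand if ss == "strand" else cfg.pack_cutoff_helix_coil
    return score > cutoff


def compute_packing(
    model: StructureModel,
    ss: SSAssignment,
    cfg: ClassifierConfig | None = None,
    radii: dict[str, float] | None = None,
) -> list[PackingResult | None]:
    """Full packing stage: contacts, per-residue scores, packed verdicts."""
    cfg = cfg or ClassifierConfig()
    contacts = find_contacts(model, radii, ss, gap=cfg.contact_gap,
                             local_sequence_exclusion=cfg.local_sequence_exclusion)
    seg_of = model.segment_of()

    owner: list[int] = []
    for i, res in enumerate(model.residues):
        owner.extend([i] * len(res.atoms))
    per_window = {}
    results: list[PackingResult | None] = []
    half = cfg.packing_window // 2
    for i in range(len(model.residues)):
        s = seg_of[i]
        if s < 0:
            results.append(None)
            continue
        seg = model.segments[s]
        k = seg.index(i)
        window_res = frozenset(seg[max(0, k - half): k + half + 1])
        if window_res in per_window:
            count, heavy = per_window[window_res]
        else:
            heavy = sum(len(model.residues[j].atoms) for j in window_res)
            count = sum(1 for a, b in contacts
                        if owner[a] in window_res or owner[b] in window_res)
            per_window[window_res] = (count, heavy)
        if heavy == 0:
            results.append(None)
            continue
        score = count / heavy
        results.append(PackingResult(count, heavy, score,
                                     is_packed(score, ss.ss[i], cfg)))
    return results
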