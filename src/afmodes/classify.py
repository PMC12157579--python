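"""Six-mode residue classification, run smoothing, and survey pruning.

Classification order mirrors the decision tree: pLDDT first, then
packing, then validation outliers (only consulted below the pLDDT
threshold). Smoothing relabels isolated 1-2 residue low-confidence runs
into identical surroundings; survey pruning trims pre-smoothing runs to
their unambiguous interiors.
"""

from __future__ import annotations

from .config import ClassifierConfig

__all__ = [
    "MODES",
    "LOW_PLDDT_MODES",
    "classify_residue",
    "smooth_modes",
    "prune_segments_for_survey",
]

PREDICTIVE = "predictive"
UNPACKED_HIGH_PLDDT = "unpacked_high_plddt"
NEAR_PREDICTIVE = "near_predictive"
PSEUDOSTRUCTURE = "pseudostructure"
BARBED_WIRE = "barbed_wire"
UNPHYSICAL = "unphysical"

MODES = (PREDICTIVE, UNPACKED_HIGH_PLDDT, NEAR_PREDICTIVE,
         PSEUDOSTRUCTURE, BARBED_WIRE, UNPHYSICAL)
LOW_PLDDT_MODES = frozenset((NEAR_PREDICTIVE, PSEUDOSTRUCTURE,
                             BARBED_WIRE, UNPHYSICAL))
#: modes subject to survey pruning
SURVEY_MODES = (BARBED_WIRE, PSEUDOSTRUCTURE, NEAR_PREDICTIVE)


def classify_residue(
    plddt: float,
    packed: bool,
    high_density: bool,
    signature: bool,
    cfg: ClassifierConfig | None = None,
) -> str:
    """Assign one of the six prediction modes.

    High pLDDT (>= 70): packed -> predictive, else unpacked_high_plddt;
    outlier evidence is ignored. Low pLDDT: outlier evidence (high
    density or a signature outlier) splits packed residues into
    near_predictive/unphysical and unpacked ones into
    pseudostructure/barbed_wire.
    """
    cfg = cfg or ClassifierConfig()
    if plddt >= cfg.plddt_high:
        return PREDICTIVE if packed else UNPACKED_HIGH_PLDDT
    bad = high_density or signature
    if packed:
        return UNPHYSICAL if bad else NEAR_PREDICTIVE
    return BARBED_WIRE if bad else PSEUDOSTRUCTURE


def _runs(labels: list[str | None]) -> list[tuple[int, int, str | None]]:
    """Maximal same-label runs as (start, end_exclusive, label)."""
    runs = []
    k = 0
    while k < len(labels):
        j = k
        while j < len(labels) and labels[j] == labels[k]:
            j += 1
        runs.append((k, j, labels[k]))
        k = j
    return runs


def smooth_modes(
    labels: dict[int, str],
    segments: list[list[int]],
    cfg: ClassifierConfig | None = None,
) -> tuple[dict[int, str], set[int]]:
    """Relabel isolated 1-2 residue low-pLDDT runs into their surroundings.

    Within each chain segment, a maximal run of length <= 2 whose label is
    a low-pLDDT mode, flanked on both sides by residues sharing one
    identical other label, takes that label. Repeats to a fixed point;
    terminal runs are never relabeled. Returns the smoothed labels and
    the set of relabeled residue indices.
    """
    cfg = cfg or ClassifierConfig()
    out = dict(labels)
    touched: set[int] = set()
    for seg in segments:
        idxs = [i for i in seg]
        seq: list[str | None] = [out.get(i) for i in idxs]
        changed = True
        while changed:
            changed = False
            for start, end, label in _runs(seq):
                if label is None or label not in LOW_PLDDT_MODES:
                    continue
                if end - start > cfg.smoothing_max_run:
                    continue
                if start == 0 or end == len(seq):  # terminal run
                    continue
                left, right = seq[start - 1], seq[end]
                if left is None or left != right or left == label:
                    continue
                for k in range(start, end):
                    seq[k] = left
                    touched.add(idxs[k])
                changed = True
                break  # restart scan: runs have merged
        for k, i in enumerate(idxs):
            if seq[k] is not None:
                out[i] = seq[k]
    return out, touched


def prune_segments_for_survey(
    pre_labels: dict[int, str],
    segments: list[list[int]],
    trim: int = 3,
    min_keep: int = 3,
) -> dict[str, set[int]]:
    """Survey residue sets per mode from pre-smoothing labels.

    For each maximal pre-smoothing run of barbed_wire, pseudostructure,
    or near_predictive: drop ``trim`` residues from each end and keep the
    interior iff at least ``min_keep`` residues remain.
    """
    kept: dict[str, set[int]] = {m: set() for m in SURVEY_MODES}
    for seg in segments:
        idxs = list(seg)
        seq = [pre_labels.get(i) for i in idxs]
        for start, end, label in _runs(seq):
            if label not in SURVEY_MODES:
                continue
            interior = idxs[start + trim: end - trim]
            if len(interior) >= min_keep:
                kept[label].update(interior)
    return kept
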