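"""Shared fixtures and test helpers (including a minimal kinemage reader)."""

from __future__ import annotations

import re

import numpy as np
import pytest

from afmodes.structure_io import Atom, Residue, StructureModel, segment_chain
from afmodes.synthetic import (
    HELIX,
    STRAND,
    FixtureSpec,
    TorsionScript,
    build_backbone,
    make_fixture,
)


def uniform_script(n, torsions, name="ALA", plddt=50.0, chain_id="A",
                   distortions=None):
    script = TorsionScript(
        names=[name] * n,
        torsions=[torsions] * n,
        plddt_profile=[plddt] * n,
        chain_id=chain_id,
    )
    if distortions:
        script.distortions = dict(distortions)
    return script


@pytest.fixture
def helix_model():
    return build_backbone(uniform_script(12, HELIX))


@pytest.fixture
def strand_model():
    return build_backbone(uniform_script(12, STRAND))


@pytest.fixture
def bundle_model():
    model, _ = make_fixture(FixtureSpec("near_predictive_domain",
                                        "near_predictive", seed=1))
    return model


def merge_models(*models) -> StructureModel:
    """Concatenate chains of several models into one (chains relettered)."""
    residues = []
    letters = iter("ABCDEFGHIJKLMNOP")
    for model in models:
        mapping = {}
        for res in model.residues:
            if res.chain_id not in mapping:
                mapping[res.chain_id] = next(letters)
            residues.append(
                Residue(
                    chain_id=mapping[res.chain_id],
                    seq_number=res.seq_number,
                    insertion_code=res.insertion_code,
                    name=res.name,
                    atoms=[Atom(a.name, a.element, a.position.copy(),
                                a.b_value, a.serial) for a in res.atoms],
                    plddt=res.plddt,
                )
            )
    return segment_chain(StructureModel(residues=residues))


def translate_model(model: StructureModel, shift) -> StructureModel:
    shift = np.asarray(shift, float)
    for res in model.residues:
        for atom in res.atoms:
            atom.position = atom.position + shift
    return model


@pytest.fixture
def mixed_model():
    """Far-separated predictive bundle + pseudostructure helix + barbed coil:
    yields several modes in one model."""
    bundle, _ = make_fixture(FixtureSpec("predictive_bundle", "predictive", 1))
    ps, _ = make_fixture(FixtureSpec("pseudostructure_helix", "pseudostructure", 1))
    bw, _ = make_fixture(FixtureSpec("barbed_wire_coil", "barbed_wire", 1))
    return merge_models(
        bundle,
        translate_model(ps, (120.0, 0.0, 0.0)),
        translate_model(bw, (0.0, 120.0, 0.0)),
    )


# ---------------------------------------------------------------------------
# minimal kinemage reader (group / list / point grammar)

_POINT_RE = re.compile(r"^\{(?P<label>[^}]*)\}\s+(?P<coords>[-\d. \t]+)$")


def parse_kinemage(text: str) -> dict:
    """Parse kinemage text into {'groups': [{'name', 'lists': [...]}, ...]}.

    Each list is {'type': 'balllist'|'labellist', 'name', 'color',
    'points': [(label, x, y, z), ...]}. Raises ValueError on grammar
    violations (points outside a list, missing braces, bad coordinates).
    """
    groups: list[dict] = []
    current_group = None
    current_list = None
    saw_header = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("@kinemage"):
            saw_header = True
            continue
        if line.startswith("@title") or line.startswith("@text"):
            continue
        if line.startswith("@group"):
            m = re.match(r"@group\s+\{([^}]*)\}(.*)", line)
            if not m:
                raise ValueError(f"malformed group line: {line!r}")
            current_group = {"name": m.group(1), "flags": m.group(2).split(),
                             "lists": []}
            groups.append(current_group)
            current_list = None
            continue
        m = re.match(r"@(\w+?list)\s+\{([^}]*)\}(.*)", line)
        if m:
            if current_group is None:
                raise ValueError("list outside of a group")
            attrs = dict(re.findall(r"(\w+)=\s*(\S+)", m.group(3)))
            current_list = {"type": m.group(1), "name": m.group(2),
                            "color": attrs.get("color"), "points": []}
            current_group["lists"].append(current_list)
            continue
        pm = _POINT_RE.match(line)
        if pm:
            if current_list is None:
                raise ValueError(f"point outside of a list: {line!r}")
            coords = [float(x) for x in pm.group("coords").split()]
            if len(coords) != 3:
                raise ValueError(f"point needs 3 coordinates: {line!r}")
            current_list["points"].append((pm.group("label"), *coords))
            continue
        raise ValueError(f"unrecognized kinemage line: {line!r}")
    if not saw_header:
        raise ValueError("missing @kinemage header")
    return {"groups": groups}
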