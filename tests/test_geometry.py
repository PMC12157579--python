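import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afmodes.config import ClassifierConfig
from afmodes.geometry import (
    RamaEvaluation,
    ResidueValidation,
    classify_peptide_bond,
    compute_backbone_dihedrals,
    compute_validation_flags,
    dihedral_angle,
    evaluate_ramachandran,
    flag_ca_geometry,
    mark_outlier_density,
    mark_signature_outliers,
    residue_rama_class,
    validate_bond_geometry,
)
from afmodes.structure_io import Atom, Residue, StructureModel
from afmodes.synthetic import HELIX, build_backbone

from conftest import uniform_script


def rama(status="favored", box=False, band=False, cls="general"):
    return RamaEvaluation(status, box, band, cls)


def flags(n, **defaults):
    return [ResidueValidation(rama=rama(), **defaults) for _ in range(n)]


class TestDihedrals:
    def test_helix_roundtrip(self, helix_model):
        recs = compute_backbone_dihedrals(helix_model)
        for i in range(1, 11):
            assert recs[i].phi == pytest.approx(-57.0, abs=1e-4)
            assert recs[i].psi == pytest.approx(-47.0, abs=1e-4)
            assert abs(recs[i].omega_next) == pytest.approx(180.0, abs=1e-4)

    def test_termini_undefined(self, helix_model):
        recs = compute_backbone_dihedrals(helix_model)
        assert recs[0].phi is None
        assert recs[11].psi is None
        assert recs[11].omega_next is None
        assert recs[0].omega_prev is None

    def test_collinear_quadruple_undefined(self):
        p = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
        assert dihedral_angle(*p) is None

    def test_known_cis_arrangement(self):
        # planar, substituents on the same side -> 0 degrees
        p0 = np.array([0.0, 1.0, 0.0])
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([1.0, 0.0, 0.0])
        p3 = np.array([1.0, 1.0, 0.0])
        assert dihedral_angle(p0, p1, p2, p3) == pytest.approx(0.0, abs=1e-9)


class TestPeptideBondClass:
    @pytest.mark.parametrize(
        "omega,nxt,kind",
        [
            (180.0, "ALA", "trans"),
            (10.0, "PRO", "cis_pro"),
            (10.0, "GLY", "cis_nonpro"),
            (-90.0, "GLY", "twisted"),
            (30.0, "ALA", "cis_nonpro"),   # boundary: |omega| <= 30 is cis
            (-30.0, "PRO", "cis_pro"),
            (150.0, "ALA", "trans"),       # boundary: |omega| >= 150 is trans
            (-150.0, "ALA", "trans"),
            (30.0001, "ALA", "twisted"),
            (149.9999, "ALA", "twisted"),
        ],
    )
    def test_classification(self, omega, nxt, kind):
        assert classify_peptide_bond(omega, nxt).kind == kind

    @given(st.floats(min_value=-180.0, max_value=180.0,
                     allow_nan=False, allow_infinity=False))
    def test_classes_partition_omega(self, omega):
        kind = classify_peptide_bond(omega, "ALA").kind
        base = {"cis_pro": "cis", "cis_nonpro": "cis"}.get(kind, kind)
        expected = ("cis" if abs(omega) <= 30
                    else "trans" if abs(omega) >= 150 else "twisted")
        assert base == expected


class TestBondGeometry:
    def test_clean_fixture_zero_z(self, helix_model):
        report = validate_bond_geometry(helix_model)
        assert max(abs(m.z) for m in report.measures) < 1e-6

    def test_cnca_minus_4_sigma_not_outlier(self):
        # observed 114.5 with target 121.7, sigma 1.8 -> z of -4.0
        model = build_backbone(
            uniform_script(6, HELIX, distortions={(3, "C-N-CA"): -4.0}))
        report = validate_bond_geometry(model)
        z = report.c_n_ca_z[(2, 3)]
        assert z == pytest.approx(-4.0, abs=1e-3)
        # the outlier rule is strictly greater-than at the threshold
        cfg = ClassifierConfig()
        assert not abs(-4.0) > cfg.bond_z_cutoff
        # just inside the threshold: not an outlier through the real path
        model = build_backbone(
            uniform_script(6, HELIX, distortions={(3, "C-N-CA"): -3.99}))
        dihedrals = compute_backbone_dihedrals(model)
        fl = compute_validation_flags(model, dihedrals)
        assert not any(f.covalent_outlier for f in fl)

    def test_cnca_minus_5_sigma_marks_both_sharers(self):
        model = build_backbone(
            uniform_script(6, HELIX, distortions={(3, "C-N-CA"): -5.0}))
        dihedrals = compute_backbone_dihedrals(model)
        fl = compute_validation_flags(model, dihedrals)
        assert fl[2].covalent_outlier and fl[3].covalent_outlier
        assert fl[2].cnca_attr and fl[3].cnca_attr
        assert not fl[4].covalent_outlier

    def test_bond_at_target_zero_z(self, helix_model):
        report = validate_bond_geometry(helix_model)
        n_ca = [m for m in report.measures if m.name == "N-CA"]
        assert n_ca and all(m.z == pytest.approx(0.0, abs=1e-6) for m in n_ca)
        assert n_ca[0].observed == pytest.approx(1.458, abs=1e-6)

    def test_missing_atom_skips_measure(self, helix_model):
        helix_model.residues[5].atoms = [
            a for a in helix_model.residues[5].atoms if a.name != "O"]
        report = validate_bond_geometry(helix_model)
        names5 = [m.name for m in report.per_residue(12)[5]]
        assert "C-O" not in names5 and "CA-C-O" not in names5
        assert "N-CA" in names5

    @pytest.mark.parametrize("k", [-4.5, -4.0, 3.0])
    @pytest.mark.parametrize("measure", ["C-N-CA", "N-CA", "CA-C-N"])
    def test_z_linearity(self, k, measure):
        model = build_backbone(
            uniform_script(8, HELIX, distortions={(4, measure): k}))
        report = validate_bond_geometry(model)
        hits = [m for m in report.measures
                if m.name == measure and abs(m.z) > 0.5]
        assert len(hits) == 1
        assert hits[0].z == pytest.approx(k, abs=1e-3)


class TestRamachandran:
    def test_box_point_is_outlier(self):
        ev = evaluate_ramachandran(60.0, 120.0, "general")
        assert ev.status == "outlier"
        assert ev.in_signature_box
        assert ev.in_high_psi_band

    def test_alpha_helix_favored(self):
        ev = evaluate_ramachandran(-57.0, -47.0, "general")
        assert ev.status == "favored"
        assert not ev.in_signature_box and not ev.in_high_psi_band

    def test_band_without_box(self):
        ev = evaluate_ramachandran(-120.0, 100.0, "general")
        assert ev.in_high_psi_band and not ev.in_signature_box

    def test_undefined_unevaluable(self):
        ev = evaluate_ramachandran(None, 100.0)
        assert ev.status == "unevaluable"
        assert not ev.in_signature_box and not ev.in_high_psi_band

    def test_polyproline_not_outlier(self):
        assert evaluate_ramachandran(-75.0, 150.0, "proline").status == "favored"
        assert evaluate_ramachandran(-120.0, 120.0, "general").status == "favored"

    @pytest.mark.parametrize(
        "phi,psi,inside",
        [
            (-15.0, 100.0, False), (170.0, 100.0, False),   # phi edges open
            (0.0, 60.0, False), (0.0, 170.0, False),        # psi edges open
            (-14.999, 60.001, True), (169.999, 169.999, True),
            (0.0, 100.0, True),
        ],
    )
    def test_signature_box_edges_open(self, phi, psi, inside):
        assert evaluate_ramachandran(phi, psi).in_signature_box is inside

    def test_injected_status_overrides_table(self):
        ev = evaluate_ramachandran(-57.0, -47.0, "general",
                                   injected_status="outlier")
        assert ev.status == "outlier"

    def test_residue_class_assignment(self):
        assert residue_rama_class("GLY", "ALA") == "glycine"
        assert residue_rama_class("PRO", "ALA") == "proline"
        assert residue_rama_class("ALA", "PRO") == "pre_proline"
        assert residue_rama_class("LEU", None) == "general"


def ca_only_model(ca_positions):
    """Single-segment model from bare CA positions."""
    residues = []
    for i, pos in enumerate(ca_positions):
        atom = Atom("CA", "C", np.asarray(pos, float), 50.0, i + 1)
        residues.append(Residue("A", i + 1, "", "ALA", [atom], plddt=50.0))
    model = StructureModel(residues=residues)
    model.segments = [list(range(len(residues)))]
    return model


class TestCaGeometry:
    def test_ideal_helix_interior_clean(self, helix_model):
        assert not any(flag_ca_geometry(helix_model))

    def test_tight_virtual_angle_flagged(self):
        # 60-degree virtual angle at the middle residue, 3.8 A arms
        model = ca_only_model([
            (3.8 * math.cos(math.radians(60.0)),
             3.8 * math.sin(math.radians(60.0)), 0.0),
            (0.0, 0.0, 0.0),
            (3.8, 0.0, 0.0),
        ])
        assert flag_ca_geometry(model) == [False, True, False]

    def test_terminal_residues_never_flagged(self):
        model = ca_only_model([(0, 0, 0), (1.0, 0, 0), (1.5, 0.5, 0)])
        out = flag_ca_geometry(model)
        assert out[0] is False and out[-1] is False

    def test_short_ca_distance_flagged(self):
        model = ca_only_model([(0, 0, 0), (2.0, 0, 0), (2.0, 3.8, 0)])
        assert flag_ca_geometry(model)[1]

    def test_injected_list_overrides_proxy(self, helix_model):
        out = flag_ca_geometry(helix_model, injected_outliers={"A 5"})
        assert out == [r.rid == "A 5" for r in helix_model.residues]


def density_oracle(states, window_indices):
    """Independent re-statement of the two-of-four window rule."""
    out = []
    for idxs in window_indices:
        conds = 0
        conds += sum(states[j]["omega"] for j in idxs) >= 2
        conds += sum(states[j]["ca"] for j in idxs) >= 2
        conds += sum(states[j]["cov"] for j in idxs) >= 2
        conds += (len(idxs) == 3
                  and all(states[j]["band"] for j in idxs)
                  and any(states[j]["outlier"] for j in idxs))
        out.append(conds >= 2)
    return out


def make_flags(states):
    out = []
    for s in states:
        out.append(
            ResidueValidation(
                rama=rama("outlier" if s["outlier"] else "favored",
                          band=s["band"]),
                omega_attr=s["omega"],
                ca_geom_outlier=s["ca"],
                covalent_outlier=s["cov"],
            )
        )
    return out


class TestOutlierDensity:
    def test_two_conditions_high_density(self):
        states = [
            dict(omega=True, ca=False, cov=True, band=False, outlier=False),
            dict(omega=True, ca=False, cov=False, band=False, outlier=False),
            dict(omega=False, ca=False, cov=True, band=False, outlier=False),
        ]
        fl = make_flags(states)
        assert mark_outlier_density(fl, [[0, 1, 2]])[1] is True

    def test_c4_alone_insufficient(self):
        states = [dict(omega=False, ca=False, cov=False, band=True,
                       outlier=(i == 1)) for i in range(3)]
        fl = make_flags(states)
        assert mark_outlier_density(fl, [[0, 1, 2]]) == [False] * 3

    def test_truncated_terminal_window(self):
        fl = make_flags([dict(omega=False, ca=False, cov=False,
                              band=True, outlier=True)] * 2)
        assert mark_outlier_density(fl, [[0, 1]]) == [False, False]

    def test_truncated_window_can_satisfy_c1_to_c3(self):
        fl = make_flags([dict(omega=True, ca=True, cov=False,
                              band=False, outlier=False)] * 2)
        assert mark_outlier_density(fl, [[0, 1]]) == [True, True]

    def test_exhaustive_against_oracle(self):
        # all 2^12 combinations of the four evidence booleans over a
        # 3-residue window (rama outlier tied to band membership)
        for mask in range(4096):
            states = []
            for r in range(3):
                bits = (mask >> (4 * r)) & 0xF
                band = bool(bits & 8)
                states.append(dict(omega=bool(bits & 1), ca=bool(bits & 2),
                                   cov=bool(bits & 4), band=band,
                                   outlier=band))
            fl = make_flags(states)
            got = mark_outlier_density(fl, [[0, 1, 2]])
            want = density_oracle(states, [[0, 1], [0, 1, 2], [1, 2]])
            assert got == want, f"mismatch at mask {mask}"

    def test_band_outlier_decoupled_states(self):
        # tri-valued rama state: clear / band-only / band+outlier
        rstates = [dict(band=False, outlier=False),
                   dict(band=True, outlier=False),
                   dict(band=True, outlier=True)]
        for mask in range(512):
            for r0 in rstates:
                for r1 in rstates:
                    for r2 in rstates:
                        states = []
                        for r, rs in zip(range(3), (r0, r1, r2)):
                            bits = (mask >> (3 * r)) & 0x7
                            states.append(dict(omega=bool(bits & 1),
                                               ca=bool(bits & 2),
                                               cov=bool(bits & 4), **rs))
                        fl = make_flags(states)
                        got = mark_outlier_density(fl, [[0, 1, 2]])
                        want = density_oracle(
                            states, [[0, 1], [0, 1, 2], [1, 2]])
                        assert got == want


def plddt_model(plddts):
    residues = []
    for i, p in enumerate(plddts):
        atom = Atom("CA", "C", np.array([float(i) * 3.8, 0, 0]), p, i + 1)
        residues.append(Residue("A", i + 1, "", "ALA", [atom], plddt=p))
    model = StructureModel(residues=residues)
    model.segments = [list(range(len(residues)))]
    return model


class TestSignatureOutliers:
    def test_box_outlier_ignores_packing(self):
        model = plddt_model([65.0])
        fl = [ResidueValidation(rama=rama("outlier", box=True, band=True))]
        assert mark_signature_outliers(model, fl, [True]) == [True]

    def test_cis_nonpro_marks_both_sharers(self):
        model = build_backbone(uniform_script(
            6, HELIX, distortions={(2, "omega"): -170.0}))  # omega -> 10
        dihedrals = compute_backbone_dihedrals(model)
        fl = compute_validation_flags(model, dihedrals)
        assert fl[2].omega_attr and fl[3].omega_attr
        out = mark_signature_outliers(model, fl, [False] * 6)
        assert out[2] and out[3]
        assert not out[0]

    def test_cis_pro_permitted_when_predictive(self):
        script = uniform_script(6, HELIX, plddt=85.0)
        script.names[3] = "PRO"
        script.distortions = {(2, "omega"): -175.0}  # cis bond into the PRO
        model = build_backbone(script)
        dihedrals = compute_backbone_dihedrals(model)
        fl = compute_validation_flags(model, dihedrals)
        assert fl[2].cis_pro_attr and fl[3].cis_pro_attr
        out = mark_signature_outliers(model, fl, [True] * 6)
        assert not any(out)

    def test_cis_pro_signature_when_low_and_unpacked(self):
        script = uniform_script(6, HELIX, plddt=40.0)
        script.names[3] = "PRO"
        script.distortions = {(2, "omega"): -175.0}
        model = build_backbone(script)
        dihedrals = compute_backbone_dihedrals(model)
        fl = compute_validation_flags(model, dihedrals)
        out = mark_signature_outliers(model, fl, [False] * 6)
        assert out[2] and out[3]

    def test_ca_outlier_needs_low_unpacked(self):
        model = plddt_model([80.0, 40.0])
        base = dict(rama=rama())
        fl = [ResidueValidation(ca_geom_outlier=True, **base),
              ResidueValidation(ca_geom_outlier=True, **base)]
        assert mark_signature_outliers(model, fl, [False, False]) == [False, True]

    @settings(max_examples=200)
    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans(),
                              st.booleans(), st.booleans()),
                    min_size=1, max_size=6))
    def test_signature_monotone_in_evidence(self, rows):
        model = plddt_model([40.0] * len(rows))
        packed = [False] * len(rows)

        def build(rows):
            return [
                ResidueValidation(
                    rama=rama("outlier" if r[0] else "favored", box=r[0]),
                    omega_attr=r[1], cis_pro_attr=r[2], cnca_attr=r[3],
                    ca_geom_outlier=r[4])
                for r in rows
            ]

        base = mark_signature_outliers(model, build(rows), packed)
        more = [tuple(True for _ in r) for r in rows]
        boosted = mark_signature_outliers(model, build(more), packed)
        for b, m in zip(base, boosted):
            assert m or not b
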