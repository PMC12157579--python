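# afmodes

Per-residue triage of AlphaFold2 structure predictions into six
prediction modes — **predictive**, **unpacked high-pLDDT**,
**near-predictive**, **pseudostructure**, **barbed wire**, and
**unphysical** — from three lines of evidence:

1. **pLDDT**, read from the B-factor field of the CA atom (AlphaFold
   convention), thresholded at 70;
2. **tertiary-contact packing**: heavy-atom steric contacts per atom over
   a 5-residue window, excluding contacts internal to one
   secondary-structure element and contacts at chain sequence separation
   ≤ 4 (packed above 0.6 contacts/atom for helix/coil, 0.35 for strand);
3. **backbone-validation outliers**: Ramachandran status, cis/twisted
   peptide bonds, covalent bond-length/angle z-scores (|z| > 4),
   CA-geometry flags, plus the derived *outlier-density* and *signature
   outlier* booleans that distinguish barbed wire / unphysical from
   pseudostructure / near-predictive.

Low-pLDDT runs of 1–2 residues surrounded by an identical other category
are smoothed into their surroundings; pre-smoothing labels are kept for
survey-style pruning (drop 3 residues from each end of a run, keep ≥ 3).

The package also ships:

- a **synthetic decoy generator** (`afmodes.synthetic`) that builds
  backbones from torsion scripts with controlled geometric distortions
  and pLDDT profiles, covering every mode end-to-end without external
  data;
- a **disorder-annotation overlap stage** (`afmodes.overlap`) computing,
  per mode, the fraction of survey-pruned residues covered by each
  annotation range set (MobiDB-entry style JSON, supplied locally);
- output renderers: TSV/JSON annotation tables, kinemage markup with
  mode-colored CA balls and per-residue `Lprocg` labels, and
  mode-filtered PDB selection files.

## Command line

```sh
# TSV annotation table to stdout
afmodes model.pdb

# phenix-style flags
afmodes model.pdb output.type=kin --out model.kin
afmodes model.pdb output.type=selection_file modes=predictive,near_predictive --out trimmed.pdb

# conventional spellings work too
afmodes model.pdb --output-type json --out model.json
```

Options:

- `--config cfg.json` — override classifier thresholds (any
  `ClassifierConfig` field) and/or van der Waals radii
  (`{"radii": {"C": 1.7, ...}}`);
- `--inject flags.json` — supply externally computed validation evidence:
  `{"rama": {"A 15": "outlier", ...}, "cablam_outliers": ["A 16", ...]}`.
  Injected Ramachandran statuses and CA-geometry outlier lists override
  the bundled coarse Ramachandran table and the CA-virtual-geometry
  proxy, which are documented approximations of the MolProbity
  evaluators.

Note on packing scores: contacts are detected with a heavy-atom distance
criterion (vdW surface separation ≤ 0.25 Å), not a hydrogen-inclusive
dot-surface method, so absolute scores differ from tools built on
Reduce/Probe; the 0.6 / 0.35 cutoffs are configuration defaults
calibrated for this criterion.

## Library use

```python
from afmodes import read_structure, annotate_structure

model = read_structure("model.pdb")
result = annotate_structure(model)
for rec in result.records:
    print(rec.rid, rec.mode, rec.lprocg, rec.plddt, rec.packed)
```

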