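"""Curate a raw SMILES library: standardize, deduplicate, filter, split.

Builds a small library containing a salt, a duplicate (different SMILES
spelling of the same structure), an equivocal assay outcome and a label
conflict, then shows what curation keeps.
"""

from amesqsar.curation import (
    CurationLog,
    MoleculeRecord,
    curate,
    split_dataset,
    standardize_records,
)

raw = [
    MoleculeRecord(id="acetate-salt", smiles_raw="CC(=O)O.[Na+]", label=0),
    MoleculeRecord(id="benzene", smiles_raw="c1ccccc1", label=0),
    MoleculeRecord(id="benzene-kekule", smiles_raw="C1=CC=CC=C1", label=0),  # duplicate
    MoleculeRecord(id="nitrobenzene", smiles_raw="O=[N+]([O-])c1ccccc1", label=1),
    MoleculeRecord(id="maybe", smiles_raw="CCOCC", label="equivocal"),
    MoleculeRecord(id="conflict-a", smiles_raw="CCCl", label=1),
    MoleculeRecord(id="conflict-b", smiles_raw="ClCC", label=0),  # same structure, other label
    MoleculeRecord(id="broken", smiles_raw="C1CC", label=1),  # unparseable
]

log = CurationLog()
ds = curate(standardize_records(raw, log), log=log)
ds = split_dataset(ds, test_fraction=0.25, seed=0)

print(f"kept {len(ds)} of {len(raw)} records")
print(f"  rejected (unparseable): {[i for i, _ in log.rejected]}")
print(f"  duplicates collapsed:   {log.duplicates_removed}")
print(f"  equivocal removed:      {log.equivocal_removed}")
print(f"  label conflicts:        {log.conflicts}")
for rec in ds.records:
    print(f"  {rec.id:14s} {rec.smiles_std:24s} label={rec.label} "
          f"split={ds.split[rec.id]}")
# The salt was stripped to acetic acid, the two benzene spellings merged,
# and the chloroethane conflict was dropped entirely rather than guessing.
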