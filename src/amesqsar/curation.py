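"""Compound library curation: standardization, deduplication, splitting.

A raw SMILES library (e.g. Ames mutagenicity collections) is turned into
a :class:`CuratedDataset`: every structure is sanitized and reduced to its
largest connected component (salt/solvate stripping), canonical SMILES is
the deduplication key, equivocal assay outcomes are removed, and the
remaining compounds are split into train/test by a seeded permutation.

Labels: 1 = mutagen, 0 = nonmutagen, "equivocal" = inconclusive assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "EQUIVOCAL",
    "MoleculeRecord",
    "CuratedDataset",
    "CurationLog",
    "standardize_record",
    "standardize_records",
    "curate",
    "split_dataset",
    "pca_projection",
    "read_molecule_csv",
    "read_molecule_sdf",
    "write_curated_csv",
]

logger = logging.getLogger(__name__)

EQUIVOCAL = "equivocal"

_LABEL_ALIASES = {
    "1": 1,
    "0": 0,
    "mutagen": 1,
    "nonmutagen": 0,
    "non-mutagen": 0,
    "equivocal": EQUIVOCAL,
}


def parse_label(raw) -> int | str:
    """Map accepted label spellings onto {1, 0, 'equivocal'}."""
    key = str(raw).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unrecognized label {raw!r}")
    return _LABEL_ALIASES[key]


@dataclass(frozen=True)
class MoleculeRecord:
    id: str
    smiles_raw: str
    label: int | str
    smiles_std: str | None = None
    source: str = ""


@dataclass
class CurationLog:
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    duplicates_removed: int = 0
    equivocal_removed: int = 0
    conflicts: list[str] = field(default_factory=list)  # smiles_std with label conflict


@dataclass
class CuratedDataset:
    """Standardized, deduplicated compound collection with optional split."""

    records: list[MoleculeRecord]
    split: dict[str, str] = field(default_factory=dict)  # id -> "train" | "test"
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles_std for r in self.records]

    def labels(self) -> np.ndarray:
        return np.asarray([r.label for r in self.records], dtype=int)

    def subset(self, part: str) -> "CuratedDataset":
        if part not in {"train", "test"}:
            raise ValueError("part must be 'train' or 'test'")
        recs = [r for r in self.records if self.split.get(r.id) == part]
        return CuratedDataset(records=recs, split={r.id: part for r in recs}, seed=self.seed)


def standardize_record(raw: MoleculeRecord) -> MoleculeRecord:
    """Sanitize, keep the largest connected component, canonicalize.

    Stereochemistry is retained as supplied.  Raises ``ValueError`` for
    SMILES that RDKit cannot parse; the caller decides whether to abort
    or to log and drop the record.
    """
    if not raw.smiles_raw:
        raise ValueError(f"{raw.id}: empty SMILES")
    RDLogger.DisableLog("rdApp.error")
    try:
        mol = Chem.MolFromSmiles(raw.smiles_raw)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if mol is None:
        raise ValueError(f"{raw.id}: unparseable SMILES {raw.smiles_raw!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    largest = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    smiles_std = Chem.MolToSmiles(largest)  # canonical, aromatic form
    return replace(raw, smiles_std=smiles_std)


def standardize_records(
    records: list[MoleculeRecord], log: CurationLog | None = None
) -> list[MoleculeRecord]:
    """Standardize a batch, dropping and logging unparseable entries."""
    log = log if log is not None else CurationLog()
    out = []
    for rec in records:
        try:
            out.append(standardize_record(rec))
        except ValueError as exc:
            logger.warning("excluded %s: %s", rec.id, exc)
            log.rejected.append((rec.id, str(exc)))
    return out


def curate(
    records: list[MoleculeRecord],
    drop_equivocal: bool = True,
    log: CurationLog | None = None,
) -> CuratedDataset:
    """Deduplicate by canonical SMILES and filter equivocal outcomes.

    The first occurrence of a duplicated structure is kept when all its
    labels agree; structures carrying conflicting mutagen/nonmutagen
    labels are removed entirely and reported, since there is no defensible
    way to pick one.
    """
    log = log if log is not None else CurationLog()
    if any(r.smiles_std is None for r in records):
        raise ValueError("records must be standardized before curation")

    by_smiles: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.smiles_std not in by_smiles:
            order.append(rec.smiles_std)
        by_smiles.setdefault(rec.smiles_std, []).append(rec)

    kept: list[MoleculeRecord] = []
    for smi in order:
        group = by_smiles[smi]
        labels = {g.label for g in group}
        non_equiv = {l for l in labels if l != EQUIVOCAL}
        if len(non_equiv) > 1:
            log.conflicts.append(smi)
            logger.warning(
                "conflicting labels for %s (%s); all %d records dropped",
                smi, sorted(map(str, labels)), len(group),
            )
            continue
        first = group[0]
        log.duplicates_removed += len(group) - 1
        if drop_equivocal and first.label == EQUIVOCAL:
            log.equivocal_removed += 1
            continue
        kept.append(first)
    return CuratedDataset(records=kept)


def split_dataset(
    ds: CuratedDataset, test_fraction: float = 0.1, seed: int = 0
) -> CuratedDataset:
    """Assign train/test by a seeded uniform permutation.

    The test size is ``n - floor((1 - test_fraction) * n)``, so a 90:10
    split of 5866 compounds yields 5279 train and 587 test.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(np.floor((1.0 - test_fraction) * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    split = {}
    for pos, idx in enumerate(perm):
        split[ds.records[idx].id] = "train" if pos < n_train else "test"
    return CuratedDataset(records=list(ds.records), split=split, seed=seed)


def pca_projection(X, k: int = 2):
    """Project a feature matrix onto its first k principal components.

    Returns ``(scores, explained_pct)`` where ``scores`` is n x k and
    ``explained_pct`` gives the percentage of variance per component.
    Used to check that train and test occupy the same chemical space.
    """
    from sklearn.decomposition import PCA

    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.where(~np.isfinite(values).all(axis=0))[0]
        names = (
            [X.column_names[i] for i in bad]
            if hasattr(X, "column_names")
            else bad.tolist()
        )
        raise ValueError(f"non-finite entries in columns: {names}")
    n, p = values.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k must be in [1, {min(n, p)}]")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(values)
    explained_pct = pca.explained_variance_ratio_ * 100.0
    return scores, explained_pct


# ---------------------------------------------------------------------------
# readers / writers


def read_molecule_csv(path, source: str = "") -> list[MoleculeRecord]:
    """Read a raw library from CSV with columns id, smiles, label."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "smiles", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"CSV is missing columns: {sorted(missing)}")
    return [
        MoleculeRecord(
            id=str(row.id), smiles_raw=str(row.smiles),
            label=parse_label(row.label), source=source,
        )
        for row in df.itertuples()
    ]


def read_molecule_sdf(path, label_field: str, source: str = "") -> list[MoleculeRecord]:
    """Read molecules from an SDF file, taking the label from a property."""
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            logger.warning("skipping unreadable SDF entry %d", i)
            continue
        if not mol.HasProp(label_field):
            raise ValueError(f"SDF entry {i} lacks property {label_field!r}")
        mol_id = mol.GetProp("_Name") or f"sdf{i}"
        records.append(
            MoleculeRecord(
                id=mol_id,
                smiles_raw=Chem.MolToSmiles(mol),
                label=parse_label(mol.GetProp(label_field)),
                source=source,
            )
        )
    return records


def write_curated_csv(ds: CuratedDataset, path) -> None:
    df = pd.DataFrame(
        {
            "id": ds.ids,
            "smiles_std": ds.smiles,
            "label": [r.label for r in ds.records],
            "split": [ds.split.get(r.id, "") for r in ds.records],
        }
    )
    df.to_csv(path, index=False)


def read_curated_csv(path) -> CuratedDataset:
    df = pd.read_csv(path, dtype={"id": str})
    records = [
        MoleculeRecord(
            id=str(r.id), smiles_raw=str(r.smiles_std),
            smiles_std=str(r.smiles_std), label=parse_label(r.label),
        )
        for r in df.itertuples()
    ]
    split = {}
    if "split" in df.columns:
        for r in df.itertuples():
            if isinstance(r.split, str) and r.split in {"train", "test"}:
                split[str(r.id)] = r.split
    return CuratedDataset(records=records, split=split)
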