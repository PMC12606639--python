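"""Molecular featurization and feature-hygiene transforms.

Ten feature families are built in, all computed locally with RDKit:

====================  ======================================================
MACCS                 167 substructure keys (presence/absence bits)
Avalon                Avalon fingerprint, 2048 bits
ECFP                  Morgan circular fingerprint, radius 2, 2048 bits
FCFP                  feature-class Morgan fingerprint, radius 2, 2048 bits
AtomPair              hashed atom-pair fingerprint, 2048 bits
Topological           hashed topological-torsion fingerprint, 2048 bits
RDKitFP               RDKit path-based fingerprint, 2048 bits
Layered               layered substructure fingerprint, 2048 bits
Pattern               pattern (substructure-screen) fingerprint, 2048 bits
Descriptors2D         RDKit's 2-D physicochemical/topological descriptor
                      set (~210 continuous values, may contain NaN before
                      hygiene)
====================  ======================================================

External embedding families (e.g. language-model fingerprints computed
elsewhere) plug in through :func:`register_external_family` as a
precomputed table keyed by molecule id; they are never computed
in-process.

Hygiene transforms: :func:`clean_matrix` (drop non-finite and optionally
constant columns), :func:`correlation_filter` (prune |Pearson r| above a
threshold keeping the larger-variance member) and :func:`x_randomize`
(the X-scrambling chance-correlation control).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

__all__ = [
    "FeatureFamily",
    "FeatureMatrix",
    "BUILTIN_FAMILY_NAMES",
    "compute_features",
    "clean_matrix",
    "correlation_filter",
    "x_randomize",
    "register_external_family",
    "write_feature_tsv",
    "read_feature_tsv",
]


@dataclass(frozen=True)
class FeatureFamily:
    name: str
    params: dict = field(default_factory=dict)


@dataclass
class FeatureMatrix:
    """One feature family evaluated over a molecule collection."""

    family: FeatureFamily
    values: np.ndarray  # n x p
    column_names: list[str]
    row_ids: list[str]
    dropped_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.row_ids) != n or len(self.column_names) != p:
            raise ValueError("row_ids/column_names do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# built-in families

_DEFAULT_NBITS = 2048
_DEFAULT_RADIUS = 2


def _bits_to_row(bv) -> np.ndarray:
    arr = np.zeros(bv.GetNumBits(), dtype=float)
    for b in bv.GetOnBits():
        arr[b] = 1.0
    return arr


def _maccs(mol, params):
    # RDKit emits 167 keys; bit 0 is unused padding in the original scheme
    # but is kept so that key numbers match the published MACCS indices.
    return _bits_to_row(MACCSkeys.GenMACCSKeys(mol))


def _avalon(mol, params):
    n_bits = params.get("n_bits", _DEFAULT_NBITS)
    return _bits_to_row(pyAvalonTools.GetAvalonFP(mol, nBits=n_bits))


def _morgan(mol, params, use_features=False):
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=params.get("radius", _DEFAULT_RADIUS),
        fpSize=params.get("n_bits", _DEFAULT_NBITS),
        atomInvariantsGenerator=(
            rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            if use_features
            else None
        ),
    )
    return _bits_to_row(gen.GetFingerprint(mol))


def _atom_pair(mol, params):
    gen = rdFingerprintGenerator.GetAtomPairGenerator(
        fpSize=params.get("n_bits", _DEFAULT_NBITS)
    )
    return _bits_to_row(gen.GetFingerprint(mol))


def _torsion(mol, params):
    gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(
        fpSize=params.get("n_bits", _DEFAULT_NBITS)
    )
    return _bits_to_row(gen.GetFingerprint(mol))


def _rdkit_fp(mol, params):
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        fpSize=params.get("n_bits", _DEFAULT_NBITS)
    )
    return _bits_to_row(gen.GetFingerprint(mol))


def _layered(mol, params):
    return _bits_to_row(
        Chem.LayeredFingerprint(mol, fpSize=params.get("n_bits", _DEFAULT_NBITS))
    )


def _pattern(mol, params):
    return _bits_to_row(
        Chem.PatternFingerprint(mol, fpSize=params.get("n_bits", _DEFAULT_NBITS))
    )


_DESC_NAMES = [name for name, _ in Descriptors.descList]


def _descriptors_2d(mol, params):
    vals = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
    return np.asarray([vals[name] for name in _DESC_NAMES], dtype=float)


def _fp_names(prefix: str, params: dict) -> Callable[[], list[str]]:
    def names():
        return [f"{prefix}{i}" for i in range(params.get("n_bits", _DEFAULT_NBITS))]

    return names


_BUILTINS: dict[str, tuple[Callable, Callable[[dict], list[str]]]] = {
    "MACCS": (_maccs, lambda p: [f"MACCS{i}" for i in range(167)]),
    "Avalon": (_avalon, lambda p: [f"Avalon{i}" for i in range(p.get("n_bits", _DEFAULT_NBITS))]),
    "ECFP": (
        lambda m, p: _morgan(m, p, use_features=False),
        lambda p: [f"ECFP{i}" for i in range(p.get("n_bits", _DEFAULT_NBITS))],
    ),
    "FCFP": (
        lambda m, p: _morgan(m, p, use_features=True),
        lambda p: [f"FCFP{i}" for i in range(p.get("n_bits", _DEFAULT_NBITS))],
    ),
    "AtomPair": (_atom_pair, lambda p: [f"AP{i}" for i in range(p.get("n_bits", _DEFAULT_NBITS))]),
    "Topological": (_torsion, lambda p: [f"TT{i}" for i in range(p.get("n_bits", _DEFAULT_NBITS))]),
    "RDKitFP": (_rdkit_fp, lambda p: [f"RDK{i}" for i in range(p.get("n_bits", _DEFAULT_NBITS))]),
    "Layered": (_layered, lambda p: [f"Layered{i}" for i in range(p.get("n_bits", _DEFAULT_NBITS))]),
    "Pattern": (_pattern, lambda p: [f"Pattern{i}" for i in range(p.get("n_bits", _DEFAULT_NBITS))]),
    "Descriptors2D": (_descriptors_2d, lambda p: list(_DESC_NAMES)),
}

BUILTIN_FAMILY_NAMES: tuple[str, ...] = tuple(_BUILTINS)

# id-keyed embedding tables supplied by the user (e.g. language-model
# fingerprints computed offline); never computed in-process.
_EXTERNAL: dict[str, tuple[dict[str, np.ndarray], list[str]]] = {}


def register_external_family(
    name: str, table: dict[str, np.ndarray], column_names: list[str] | None = None
) -> None:
    """Register a precomputed embedding table keyed by molecule id."""
    if name in _BUILTINS:
        raise ValueError(f"{name!r} clashes with a built-in family")
    widths = {len(np.atleast_1d(v)) for v in table.values()}
    if len(widths) != 1:
        raise ValueError("embedding table rows have inconsistent widths")
    (p,) = widths
    cols = column_names if column_names is not None else [f"{name}{i}" for i in range(p)]
    if len(cols) != p:
        raise ValueError("column_names length does not match embedding width")
    _EXTERNAL[name] = ({k: np.asarray(v, dtype=float) for k, v in table.items()}, cols)


def compute_features(ds, family: FeatureFamily | str) -> FeatureMatrix:
    """Featurize a curated dataset (or (ids, smiles) pair) with one family.

    Rows follow the input molecule order.  Fingerprint families yield
    {0,1} matrices; Descriptors2D yields continuous values that may
    contain NaN until :func:`clean_matrix` is applied.
    """
    if isinstance(family, str):
        family = FeatureFamily(name=family)
    if hasattr(ds, "records"):
        ids, smiles = ds.ids, ds.smiles
    else:
        ids, smiles = list(ds[0]), list(ds[1])

    if family.name in _EXTERNAL:
        table, cols = _EXTERNAL[family.name]
        rows = []
        for mol_id in ids:
            if mol_id not in table:
                raise ValueError(f"external family {family.name!r} has no row for id {mol_id!r}")
            rows.append(table[mol_id])
        return FeatureMatrix(family=family, values=np.vstack(rows),
                             column_names=list(cols), row_ids=list(ids))

    if family.name not in _BUILTINS:
        raise ValueError(
            f"unknown feature family {family.name!r}; built-ins: {sorted(_BUILTINS)}"
        )
    fn, name_fn = _BUILTINS[family.name]
    rows = []
    for mol_id, smi in zip(ids, smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"featurization failed for id {mol_id!r}: bad SMILES {smi!r}")
        rows.append(fn(mol, family.params))
    return FeatureMatrix(
        family=family,
        values=np.vstack(rows),
        column_names=name_fn(family.params),
        row_ids=list(ids),
    )


# ---------------------------------------------------------------------------
# hygiene transforms


def clean_matrix(X: FeatureMatrix, drop_constant: bool = False) -> FeatureMatrix:
    """Drop columns with non-finite entries; optionally drop constants.

    Constant removal is off for the main pipeline and switched on ahead
    of correlation-based feature selection.
    """
    finite = np.isfinite(X.values).all(axis=0)
    keep = finite.copy()
    if drop_constant:
        with np.errstate(invalid="ignore"):
            is_const = np.nanstd(X.values, axis=0) == 0
        keep &= ~is_const
    if not keep.any():
        raise ValueError("all columns dropped by hygiene")
    dropped = [c for c, k in zip(X.column_names, keep) if not k]
    return FeatureMatrix(
        family=X.family,
        values=X.values[:, keep],
        column_names=[c for c, k in zip(X.column_names, keep) if k],
        row_ids=list(X.row_ids),
        dropped_columns=X.dropped_columns + dropped,
    )


def correlation_filter(X: FeatureMatrix, threshold: float = 0.9) -> FeatureMatrix:
    """Prune highly correlated columns, keeping the larger-variance member.

    Offending pairs (|Pearson r| > threshold) are resolved greedily in
    order of descending |r| (ties by column index): the smaller-variance
    member is dropped; on equal variances the earlier column is kept.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    vals = X.values
    p = vals.shape[1]
    var = vals.var(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(p)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))

    pairs = [
        (abs(corr[i, j]), i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(corr[i, j]) > threshold and sd[i] > 0 and sd[j] > 0
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = np.ones(p, dtype=bool)
    for _, i, j in pairs:
        if alive[i] and alive[j]:
            drop = j if var[j] <= var[i] else i
            alive[drop] = False
    dropped = [c for c, a in zip(X.column_names, alive) if not a]
    return FeatureMatrix(
        family=X.family,
        values=vals[:, alive],
        column_names=[c for c, a in zip(X.column_names, alive) if a],
        row_ids=list(X.row_ids),
        dropped_columns=X.dropped_columns + dropped,
    )


def x_randomize(X: FeatureMatrix, seed: int, per_column: bool = False) -> FeatureMatrix:
    """Scramble the feature matrix against fixed labels (X-randomization).

    By default whole rows are permuted while ``row_ids`` (and hence the
    labels attached to them) keep their original order — the classical
    X-scrambling control.  ``per_column=True`` shuffles each column
    independently instead.
    """
    rng = np.random.default_rng(seed)
    if per_column:
        vals = np.column_stack(
            [rng.permutation(X.values[:, j]) for j in range(X.p)]
        )
    else:
        vals = X.values[rng.permutation(X.n), :]
    return replace(X, values=vals, row_ids=list(X.row_ids),
                   column_names=list(X.column_names),
                   dropped_columns=list(X.dropped_columns))


# ---------------------------------------------------------------------------
# serialization


def write_feature_tsv(X: FeatureMatrix, path) -> None:
    df = pd.DataFrame(X.values, columns=X.column_names)
    df.insert(0, "id", X.row_ids)
    df.to_csv(path, sep="\t", index=False)
    sidecar = str(path) + ".dropped.txt"
    with open(sidecar, "w") as fh:
        fh.write("\n".join(X.dropped_columns))


def read_feature_tsv(path, family: str = "external") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    ids = df.pop("id").tolist()
    return FeatureMatrix(
        family=FeatureFamily(name=family),
        values=df.to_numpy(dtype=float),
        column_names=list(df.columns),
        row_ids=ids,
    )
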