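"""Model interpretation: Shapley attributions and counterfactual analogs.

Feature importance uses permutation-sampling Shapley values: for each
explained compound, random feature orderings are drawn and each feature
is credited with the change in model output when its value is switched
from a background compound's value to the explained compound's value.
Along every sampled ordering the increments telescope, so the estimator
satisfies local accuracy (baseline + sum of attributions = model output)
up to the Monte-Carlo error of the background mean, and inherits the
null and symmetry axioms in expectation.

MACCS keys are grouped by the chemistry of their SMARTS definitions into
halogen, nitrogen-containing, oxygen-containing, ring-related and other,
the grouping used when summarizing which substructures drive predicted
mutagenicity.

Counterfactual search answers "what is the closest analog with the
opposite predicted label?": candidates are ranked by the Tanimoto
distance d = 1 - T(x, x') on circular fingerprints and the nearest
label-flipping candidate wins.  A deterministic single-edit analog
enumerator (add / remove / swap small substituents) supplies candidates
when no external list is given.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity

__all__ = [
    "AttributionSummary",
    "CounterfactualQuery",
    "shapley_attributions",
    "maccs_key_groups",
    "rank_and_group",
    "enumerate_analogs",
    "counterfactual_search",
    "tanimoto_distance",
]


# ---------------------------------------------------------------------------
# Shapley attribution


@dataclass
class AttributionSummary:
    feature_names: list[str]
    mean_abs: np.ndarray  # p
    mean_signed: np.ndarray  # p
    rank: np.ndarray  # p, 1 = most important by mean |value|
    baseline: float  # expected model output over the background
    attributions: np.ndarray  # n_explain x p, per-row signed values
    explained_outputs: np.ndarray  # n_explain model outputs f(x)

    def table(self, groups: dict[str, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean_abs_shap": self.mean_abs,
                "sign": np.sign(self.mean_signed).astype(int),
                "rank": self.rank,
            }
        ).sort_values("rank")
        if groups is not None:
            df.insert(1, "group", [groups.get(f, "other") for f in df["feature"]])
        return df.reset_index(drop=True)


def _as_predict_fn(model):
    if callable(model):
        return model
    if hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model.predict_proba(X)).ravel()
    raise TypeError("model must be callable or expose predict_proba")


def shapley_attributions(
    model,
    X_background,
    X_explain,
    n_samples: int = 2048,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> AttributionSummary:
    """Permutation-sampling Shapley attribution of model outputs.

    ``model`` is a trained network or any callable mapping an (m, p)
    array to m outputs.  ``n_samples`` random (permutation, background
    row) draws are used per explained row.  Deterministic given seed.
    """
    f = _as_predict_fn(model)
    bg = np.atleast_2d(np.asarray(
        X_background.values if hasattr(X_background, "values") else X_background,
        dtype=float))
    Xe = np.atleast_2d(np.asarray(
        X_explain.values if hasattr(X_explain, "values") else X_explain,
        dtype=float))
    if bg.shape[0] == 0:
        raise ValueError("background is empty")
    if bg.shape[1] != Xe.shape[1]:
        raise ValueError("background and explained widths differ")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p = bg.shape[1]
    if feature_names is None:
        feature_names = getattr(X_background, "column_names", None) or [
            f"f{i}" for i in range(p)
        ]

    rng = np.random.default_rng(seed)
    baseline = float(np.mean(f(bg)))
    explained_outputs = np.asarray(f(Xe), dtype=float)

    phi = np.zeros((Xe.shape[0], p))
    # evaluate whole permutation paths in chunks to keep memory bounded
    chunk = max(1, int(2_000_000 // max(1, (p + 1) * p)))
    steps = np.arange(p + 1)[:, None]
    for r, x in enumerate(Xe):
        done = 0
        while done < n_samples:
            nb = min(chunk, n_samples - done)
            done += nb
            for _ in range(nb):
                b = bg[rng.integers(bg.shape[0])]
                perm = rng.permutation(p)
                ranks = np.empty(p, dtype=int)
                ranks[perm] = np.arange(p)
                take = ranks[None, :] < steps  # (p+1, p): row t has first t features from x
                path = np.where(take, x[None, :], b[None, :])
                out = np.asarray(f(path), dtype=float).ravel()
                phi[r, perm] += np.diff(out)
        phi[r] /= n_samples

    mean_abs = np.mean(np.abs(phi), axis=0)
    mean_signed = np.mean(phi, axis=0)
    order = np.lexsort((np.arange(p), -mean_abs))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return AttributionSummary(
        feature_names=list(feature_names),
        mean_abs=mean_abs,
        mean_signed=mean_signed,
        rank=rank,
        baseline=baseline,
        attributions=phi,
        explained_outputs=explained_outputs,
    )


# ---------------------------------------------------------------------------
# MACCS key grouping

_HALOGEN_RE = re.compile(r"F|Cl|Br|I|#9\b|#17\b|#35\b|#53\b")
_NITROGEN_RE = re.compile(r"#7|N|n")
_OXYGEN_RE = re.compile(r"#8|O|o")
_RING_RE = re.compile(r"[Rr@]|\*\d|a")

# keys RDKit implements specially rather than by a single SMARTS
_SPECIAL_GROUPS = {1: "other", 125: "ring-related", 166: "other"}


def maccs_key_groups() -> dict[str, str]:
    """Assign each MACCS key to a structural group.

    Groups (first match wins): halogen, nitrogen-containing,
    oxygen-containing, ring-related, other — judged from the key's SMARTS
    definition.  E.g. MACCS134 [F,Cl,Br,I] is halogen, MACCS63 (N=O) is
    nitrogen-containing, MACCS125 (aromatic rings) is ring-related.
    """
    groups = {}
    for key, (smarts, _) in MACCSkeys.smartsPatts.items():
        name = f"MACCS{key}"
        if key in _SPECIAL_GROUPS:
            groups[name] = _SPECIAL_GROUPS[key]
        elif _HALOGEN_RE.search(smarts):
            groups[name] = "halogen"
        elif _NITROGEN_RE.search(smarts):
            groups[name] = "nitrogen-containing"
        elif _OXYGEN_RE.search(smarts):
            groups[name] = "oxygen-containing"
        elif _RING_RE.search(smarts):
            groups[name] = "ring-related"
        else:
            groups[name] = "other"
    groups["MACCS0"] = "other"  # RDKit's padding bit
    return groups


def rank_and_group(
    summary: AttributionSummary,
    groups: dict[str, str] | None = None,
    top_k: int = 20,
) -> pd.DataFrame:
    """Top-k positively contributing features with their group labels.

    "Positive contribution" means a positive mean signed Shapley value,
    i.e. the feature pushes predictions toward the mutagen class.
    """
    if groups is None:
        groups = maccs_key_groups()
    df = summary.table(groups=groups)
    pos = df[df["sign"] > 0]
    if top_k > len(pos):
        import warnings

        warnings.warn(
            f"top_k={top_k} exceeds the {len(pos)} positive features; clipping"
        )
        top_k = len(pos)
    return pos.head(top_k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# counterfactual analog search

# substituent fragments, attachment atom first
_SUBSTITUENTS = {
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "I": "I",
    "NO2": "[N+](=O)[O-]",
    "NH2": "N",
    "CH3": "C",
    "OH": "O",
}


@dataclass
class CounterfactualQuery:
    base_smiles: str
    analog_smiles: str
    distance: float  # 1 - Tanimoto, in [0, 1]
    label_base: int
    label_analog: int


def tanimoto_distance(
    smiles_a: str, smiles_b: str, radius: int = 2, n_bits: int = 2048
) -> float:
    """1 - Tanimoto similarity on circular fingerprints."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    mols = []
    for smi in (smiles_a, smiles_b):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"bad SMILES {smi!r}")
        mols.append(mol)
    fa, fb = (gen.GetFingerprint(m) for m in mols)
    return 1.0 - TanimotoSimilarity(fa, fb)


def _removable_matches(mol, frag_query):
    """Substituent matches attached to the rest of the molecule by one bond."""
    out = []
    for match in mol.GetSubstructMatches(frag_query):
        match_set = set(match)
        anchors = set()
        for idx in match:
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetIdx() not in match_set:
                    anchors.add(nb.GetIdx())
        if len(anchors) == 1:
            out.append((match, anchors.pop()))
    return out


def _canon(mol) -> str | None:
    try:
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return None


def _add_at(mol, atom_idx: int, frag_smiles: str):
    frag = Chem.MolFromSmiles(frag_smiles)
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    return _canon(combined.GetMol())


def _remove_match(mol, match):
    em = Chem.RWMol(mol)
    for idx in sorted(match, reverse=True):
        em.RemoveAtom(idx)
    return em


def enumerate_analogs(smiles: str, substituents: dict[str, str] | None = None) -> list[str]:
    """Deterministic single-edit analogs of a molecule.

    Edits: add a substituent from the small set {F, Cl, Br, I, NO2, NH2,
    CH3, OH} at any aromatic CH position, remove any such substituent,
    or swap one for another at the same position.  Returns unique
    canonical SMILES, excluding the input itself.
    """
    subs = substituents if substituents is not None else _SUBSTITUENTS
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad SMILES {smiles!r}")
    base_canon = Chem.MolToSmiles(mol)
    out: list[str] = []
    seen = {base_canon}

    def emit(smi):
        if smi is not None and smi not in seen:
            seen.add(smi)
            out.append(smi)

    # additions at aromatic carbons bearing a hydrogen
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic() and atom.GetSymbol() == "C" and atom.GetTotalNumHs() > 0:
            for frag in subs.values():
                emit(_add_at(mol, atom.GetIdx(), frag))

    # removals and swaps of existing substituent groups
    for name, frag in subs.items():
        query = Chem.MolFromSmiles(frag)
        for match, anchor in _removable_matches(mol, query):
            stripped = _remove_match(mol, match)
            emit(_canon(Chem.Mol(stripped.GetMol())))
            # swap: re-add a different substituent at the (re-indexed) anchor
            new_anchor = anchor - sum(1 for idx in match if idx < anchor)
            stripped_mol = stripped.GetMol()
            try:
                Chem.SanitizeMol(stripped_mol)
            except Exception:
                continue
            for other_name, other_frag in subs.items():
                if other_name != name:
                    emit(_add_at(stripped_mol, new_anchor, other_frag))
    return out


def counterfactual_search(
    base_smiles: str,
    candidates: list[str] | None,
    predictor,
    radius: int = 2,
    n_bits: int = 2048,
) -> CounterfactualQuery | None:
    """Closest candidate whose predicted label differs from the base.

    ``predictor`` maps a SMILES string to a binary label.  Distance is
    1 - Tanimoto on circular fingerprints; ties are broken by candidate
    order.  Returns None (with a warning) when no candidate flips the
    prediction or the candidate list is empty.
    """
    import warnings

    if candidates is None:
        candidates = enumerate_analogs(base_smiles)
    if not candidates:
        warnings.warn("empty candidate list; no counterfactual found")
        return None
    label_base = int(predictor(base_smiles))
    best: CounterfactualQuery | None = None
    for cand in candidates:
        label = int(predictor(cand))
        if label == label_base:
            continue
        d = tanimoto_distance(base_smiles, cand, radius=radius, n_bits=n_bits)
        if best is None or d < best.distance:
            best = CounterfactualQuery(
                base_smiles=base_smiles,
                analog_smiles=cand,
                distance=d,
                label_base=label_base,
                label_analog=label,
            )
    if best is None:
        warnings.warn("no candidate flips the prediction")
    return best
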