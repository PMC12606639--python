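"""Seeded synthetic SMILES libraries with a planted substructure rule.

Every pipeline stage needs realistic-looking molecular input that is
testable without downloading assay collections.  The generator builds
small aromatic/aliphatic molecules from a scaffold grammar (substituted
benzenes, naphthalenes, short alkyl chains) and plants a ground-truth
rule: a molecule is labeled mutagenic iff it carries a marker
substructure (a nitro group by default — a classic structural alert),
XOR a Bernoulli label-noise flip.  Class balance is exact by
construction and noise is applied per class, so a classifier's ceiling
performance is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import CuratedDataset, MoleculeRecord

__all__ = ["PlantedLibrarySpec", "generate_planted_dataset"]

NITRO_SMARTS = "[N+](=O)[O-]"

# substituent SMILES fragments used by the grammar (attachment point first)
_PLAIN_SUBS = ["F", "Cl", "Br", "N", "O", "C", "OC"]
_RULE_SUB = "[N+](=O)[O-]"

# templates; slots are filled with "(X)" for a substituent or "" for none
_SCAFFOLDS = [
    ("c1cc{0}ccc1{1}", 2),
    ("c1cc{0}cc{1}c1{2}", 3),
    ("c1ccc2ccc{0}cc2c1{1}", 2),
    ("C{0}CC{1}", 2),
    ("CC{0}CCC{1}", 2),
    ("c1cc{0}ccc1C{1}C{2}", 3),
]


@dataclass(frozen=True)
class PlantedLibrarySpec:
    n: int = 600
    positive_fraction: float = 0.5
    rule: str = NITRO_SMARTS
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("n must be at least 20")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


def _random_molecule(rng: np.random.Generator, with_rule: bool) -> str | None:
    template, slots = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
    subs = [str(rng.choice(_PLAIN_SUBS)) for _ in range(slots)]
    # a slot may stay empty, adding size diversity
    for i in range(slots):
        if rng.random() < 0.3:
            subs[i] = ""
    if with_rule:
        subs[rng.integers(slots)] = _RULE_SUB
    smi = template.format(*(f"({s})" if s else "" for s in subs))
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    canon = Chem.MolToSmiles(mol)
    if with_rule != mol.HasSubstructMatch(Chem.MolFromSmarts(NITRO_SMARTS)):
        return None
    return canon


def generate_planted_dataset(
    spec: PlantedLibrarySpec,
) -> tuple[CuratedDataset, pd.DataFrame]:
    """Generate the library plus a truth table.

    Returns ``(dataset, truth)`` where ``truth`` has columns id, smiles,
    rule_match, flipped, label and ``label = rule_match XOR flipped``.
    Molecules are unique by canonical SMILES and survive standardization
    unchanged (single component, already canonical).  Raises if the
    grammar cannot supply enough unique structures for the requested
    counts.
    """
    rng = np.random.default_rng(spec.seed)
    rule_query = Chem.MolFromSmarts(spec.rule)
    if rule_query is None:
        raise ValueError(f"bad rule SMARTS {spec.rule!r}")

    n_pos = int(round(spec.n * spec.positive_fraction))
    n_neg = spec.n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("positive_fraction unsatisfiable at this n")

    pools: dict[bool, list[str]] = {True: [], False: []}
    seen: set[str] = set()
    attempts, max_attempts = 0, 200 * spec.n
    while (len(pools[True]) < n_pos or len(pools[False]) < n_neg) and attempts < max_attempts:
        attempts += 1
        want_rule = len(pools[True]) < n_pos
        smi = _random_molecule(rng, with_rule=want_rule)
        if smi is None or smi in seen:
            continue
        # grammar molecules must match the planted rule iff marked
        has_rule = Chem.MolFromSmiles(smi).HasSubstructMatch(rule_query)
        if has_rule != want_rule:
            continue
        seen.add(smi)
        pools[want_rule].append(smi)
    if len(pools[True]) < n_pos or len(pools[False]) < n_neg:
        raise ValueError(
            f"grammar exhausted: generated {len(pools[True])}/{n_pos} rule-bearing "
            f"and {len(pools[False])}/{n_neg} plain molecules"
        )

    rows = []
    for rule_match, pool, count in ((True, pools[True], n_pos), (False, pools[False], n_neg)):
        # per-class noise keeps the overall class balance exact in expectation
        k_flip = int(round(spec.label_noise * count))
        flip_idx = set(rng.choice(count, size=k_flip, replace=False).tolist())
        for i in range(count):
            flipped = i in flip_idx
            rows.append(
                {
                    "smiles": pool[i],
                    "rule_match": rule_match,
                    "flipped": flipped,
                    "label": int(rule_match ^ flipped),
                }
            )
    order = rng.permutation(len(rows))
    truth = pd.DataFrame([rows[i] for i in order])
    truth.insert(0, "id", [f"syn{i:05d}" for i in range(len(truth))])

    records = [
        MoleculeRecord(
            id=row.id,
            smiles_raw=row.smiles,
            smiles_std=row.smiles,
            label=int(row.label),
            source="synthetic",
        )
        for row in truth.itertuples()
    ]
    return CuratedDataset(records=records), truth
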