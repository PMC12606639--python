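"""Counterfactual analog search: smallest edit that flips the prediction.

Uses a substructure-rule predictor as a stand-in for a trained network
(any SMILES -> label callable works) and searches single-edit analogs of
toluene for the nearest one predicted mutagenic.
"""

from rdkit import Chem

from amesqsar.interpret import counterfactual_search, enumerate_analogs

NITRO = Chem.MolFromSmarts("[N+](=O)[O-]")


def predictor(smiles: str) -> int:
    return int(Chem.MolFromSmiles(smiles).HasSubstructMatch(NITRO))


base = "Cc1ccccc1"  # toluene, predicted nonmutagenic
analogs = enumerate_analogs(base)
print(f"{len(analogs)} single-edit analogs of toluene, e.g. {analogs[:4]}")

result = counterfactual_search(base, analogs, predictor)
print(f"base   {result.base_smiles}  predicted {result.label_base}")
print(f"analog {result.analog_smiles}  predicted {result.label_analog}")
print(f"Tanimoto distance d = 1 - T = {result.distance:.3f}")
# The nearest flipping analog is a nitrotoluene: adding the nitro group
# is the smallest structural change that crosses the decision boundary.
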