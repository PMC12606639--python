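"""Leverage applicability domain: which queries can the model be trusted on?

Fits the hat-value machinery on a training matrix of continuous 2-D
descriptors and scores in-library molecules against a deliberately alien
query (a long perfluorinated sulfonic acid unlike anything in the
training set).  Descriptor space makes "alien" visible: extreme
descriptor values produce extreme leverage.
"""

import numpy as np

from amesqsar.applicability import ad_report, critical_hat, fit_leverage
from amesqsar.featurize import clean_matrix, compute_features
from amesqsar.synthetic import PlantedLibrarySpec, generate_planted_dataset

ds, _ = generate_planted_dataset(PlantedLibrarySpec(n=600, seed=3))
X = clean_matrix(compute_features(ds, "Descriptors2D"), drop_constant=True)

model = fit_leverage(X)
print(f"h* = 3(p+1)/n = 3({model.p}+1)/{model.n} = {model.h_star:.3f}")
print(f"(at the published scale, p=167 and n=5279 give "
      f"h* = {critical_hat(167, 5279):.3f})")

alien_smiles = "FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)S(=O)(=O)O"
alien = compute_features((["alien"], [alien_smiles]), "Descriptors2D")
cols = [alien.column_names.index(c) for c in X.column_names]
alien_row = np.nan_to_num(alien.values[:, cols])

queries = np.vstack([X.values[:5], alien_row])
report = ad_report(model, queries, ids=X.row_ids[:5] + ["alien"])
print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Training molecules have hat values far below h*; the perfluoro query's
# leverage is orders of magnitude above it, so its prediction would be
# flagged unreliable rather than silently returned.
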