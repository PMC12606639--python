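"""Compute feature matrices for several families and apply hygiene.

Generates a 60-molecule synthetic library, featurizes it with MACCS keys
and 2-D descriptors, and shows missing-value cleanup and the correlation
filter used for feature-selection comparisons.
"""

from amesqsar.featurize import clean_matrix, compute_features, correlation_filter
from amesqsar.synthetic import PlantedLibrarySpec, generate_planted_dataset

ds, _ = generate_planted_dataset(PlantedLibrarySpec(n=60, seed=0))

for family in ("MACCS", "ECFP", "Descriptors2D"):
    X = compute_features(ds, family)
    clean = clean_matrix(X, drop_constant=True)
    print(f"{family:14s} raw {X.n}x{X.p:5d} -> clean {clean.n}x{clean.p:5d} "
          f"(dropped {len(clean.dropped_columns)} columns)")

# correlation filtering keeps the larger-variance member of each
# highly correlated descriptor pair (|Pearson r| > 0.9)
desc = clean_matrix(compute_features(ds, "Descriptors2D"), drop_constant=True)
filtered = correlation_filter(desc, threshold=0.9)
print(f"correlation filter: {desc.p} -> {filtered.p} descriptors retained")
# Fingerprint bits are binary and rarely missing; the continuous 2-D
# descriptors lose a few columns to non-finite values and constants.
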