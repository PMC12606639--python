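"""Train the selected network architecture and cross-validate it.

Uses the planted-rule library (nitro group => mutagen, 5% label noise)
so the achievable ceiling is known: with 5% of labels flipped, balanced
accuracy tops out near 0.95.
"""

from amesqsar.featurize import compute_features
from amesqsar.neuralnet import NetworkConfig, cross_validate, grid_configs
from amesqsar.synthetic import PlantedLibrarySpec, generate_planted_dataset

ds, _ = generate_planted_dataset(
    PlantedLibrarySpec(n=300, label_noise=0.05, seed=1)
)
X = compute_features(ds, "MACCS")
y = ds.labels()

# the full hyperparameter sweep for one family: 3 depths x 2 optimizers
print(f"grid size for one family: {len(grid_configs(['MACCS']))} configurations")

cfg = NetworkConfig(hidden_sizes=(512, 128, 8), optimizer="Adamax", seed=0)
report = cross_validate(X, y, cfg, k=5, seed=0)
for key, (mean, sd) in report.mean_sd.items():
    print(f"  {key:18s} {mean:.3f} +/- {sd:.3f}")
# Balanced accuracy well above 0.9 shows the network recovered the
# planted substructure rule; it cannot exceed ~0.95 because of the noise.
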