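"""X-randomization: is the model learning chemistry or chance correlation?

Scrambles the rows of the feature matrix against fixed labels, retrains,
and checks that held-out performance collapses to coin-flipping while
the intact model stays strong.
"""

from amesqsar.featurize import compute_features, x_randomize
from amesqsar.metrics import compute_metrics, confusion_counts
from amesqsar.neuralnet import NetworkConfig, predict, train_network
from amesqsar.synthetic import PlantedLibrarySpec, generate_planted_dataset

ds, _ = generate_planted_dataset(PlantedLibrarySpec(n=400, label_noise=0.05, seed=6))
X = compute_features(ds, "MACCS")
y = ds.labels()
half = X.n // 2
cfg = NetworkConfig(hidden_sizes=(64,), epochs=60, seed=0)

for name, matrix in (("intact", X), ("scrambled", x_randomize(X, seed=9))):
    net = train_network(matrix.values[:half], y[:half], cfg)
    _, labels = predict(net, matrix.values[half:])
    bal = compute_metrics(confusion_counts(y[half:], labels)).balanced_accuracy
    print(f"{name:10s} held-out balanced accuracy: {bal:.3f}")
# The intact model scores ~0.9; the scrambled one hovers near 0.5,
# confirming the signal comes from structure-label association and not
# from chance correlation in a wide feature matrix.
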