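"""Pairwise OR-voting integration of two single-family models.

Trains MACCS and ECFP networks on the same library, combines their test
predictions with the any-positive vote, and compares the error structure:
the integrated model's recall can only improve on the members'.
"""

from amesqsar.curation import split_dataset
from amesqsar.ensemble import IntegratedModel, enumerate_pairs, or_vote, select_best
from amesqsar.featurize import compute_features
from amesqsar.metrics import compute_metrics, confusion_counts
from amesqsar.neuralnet import NetworkConfig, predict, train_network
from amesqsar.synthetic import PlantedLibrarySpec, generate_planted_dataset

ds, _ = generate_planted_dataset(PlantedLibrarySpec(n=300, label_noise=0.05, seed=2))
ds = split_dataset(ds, test_fraction=0.2, seed=2)
train, test = ds.subset("train"), ds.subset("test")

print(f"pairs from 13 families: {len(enumerate_pairs([f'f{i}' for i in range(13)]))}")

nets, labels = {}, {}
for fam in ("MACCS", "ECFP"):
    Xtr = compute_features(train, fam)
    Xte = compute_features(test, fam)
    nets[fam] = train_network(Xtr, train.labels(), NetworkConfig(epochs=60, seed=0))
    _, labels[fam] = predict(nets[fam], Xte.values)
    m = compute_metrics(confusion_counts(test.labels(), labels[fam]))
    print(f"  {fam:6s} recall {m.recall:.3f}  precision {m.precision:.3f}")

voted = or_vote(labels["MACCS"], labels["ECFP"])
m = compute_metrics(confusion_counts(test.labels(), voted))
print(f"  OR-vote recall {m.recall:.3f}  precision {m.precision:.3f}")

report = select_best({"MACCS-ECFP": (m.accuracy, m.balanced_accuracy, m.precision)})
print(f"selected pair: {report.winner}")
# The vote unions the members' positive calls: missed mutagens must be
# missed by BOTH members, so recall >= each member's recall.
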