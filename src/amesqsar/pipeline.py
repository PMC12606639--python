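"""End-to-end pipeline: curate -> featurize -> train -> integrate -> report.

One :class:`RunConfig` drives all stages; every source of randomness is
funneled through its master seed and each run directory gets a manifest
recording the seed, the stages executed and the artifacts written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import applicability, arka, curation, ensemble, featurize, interpret, metrics, neuralnet

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    families: list[str] = field(default_factory=lambda: ["MACCS", "Descriptors2D"])
    full_grid: bool = False  # sweep depths x optimizers instead of the selected config
    k_folds: int = 10
    test_fraction: float = 0.1
    seed: int = 0
    epochs: int = 100
    run_ad: bool = False
    run_shap: bool = False
    run_arka: bool = False
    run_counterfactual: bool = False
    run_xrand: bool = False
    shap_samples: int = 256
    shap_rows: int = 20

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Plain-text key=value config; list values are comma-separated."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "families":
                kwargs[key] = [v.strip() for v in value.split(",") if v.strip()]
            elif key in {"k_folds", "seed", "epochs", "shap_samples", "shap_rows"}:
                kwargs[key] = int(value)
            elif key == "test_fraction":
                kwargs[key] = float(value)
            elif key.startswith("run_") or key == "full_grid":
                kwargs[key] = value.lower() in {"1", "true", "yes", "on"}
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _write(path: Path, text: str, manifest: list[str]) -> None:
    path.write_text(text)
    manifest.append(path.name)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stage = "curate"
    try:
        records = curation.read_molecule_csv(cfg.input_path)
        log = curation.CurationLog()
        ds = curation.curate(curation.standardize_records(records, log), log=log)
        ds = curation.split_dataset(ds, test_fraction=cfg.test_fraction, seed=cfg.seed)
        curation.write_curated_csv(ds, out / "curated.csv")
        artifacts.append("curated.csv")
        train, test = ds.subset("train"), ds.subset("test")
        y_train, y_test = train.labels(), test.labels()

        stage = "featurize"
        feats_train, feats_test = {}, {}
        for fam in cfg.families:
            Xtr = featurize.clean_matrix(featurize.compute_features(train, fam))
            # apply the training drop mask to the test side
            keep = [c for c in Xtr.column_names]
            Xte_raw = featurize.compute_features(test, fam)
            col_idx = [Xte_raw.column_names.index(c) for c in keep]
            Xte = featurize.FeatureMatrix(
                family=Xte_raw.family,
                values=np.nan_to_num(Xte_raw.values[:, col_idx]),
                column_names=keep,
                row_ids=Xte_raw.row_ids,
            )
            feats_train[fam], feats_test[fam] = Xtr, Xte
            featurize.write_feature_tsv(Xtr, out / f"features_{fam}_train.tsv")
            artifacts.append(f"features_{fam}_train.tsv")

        stage = "train"
        if cfg.full_grid:
            grid = neuralnet.grid_configs(cfg.families, epochs=cfg.epochs, seed=cfg.seed)
        else:
            grid = [
                (fam, neuralnet.NetworkConfig(epochs=cfg.epochs, seed=cfg.seed))
                for fam in cfg.families
            ]
        cv_reports: dict[str, neuralnet.CVReport] = {}
        single_nets: dict[str, neuralnet.TrainedNetwork] = {}
        single_rows = []
        for fam, net_cfg in grid:
            report = neuralnet.cross_validate(
                feats_train[fam], y_train, net_cfg, k=cfg.k_folds, seed=cfg.seed
            )
            key = f"{fam}|{len(net_cfg.hidden_sizes)}hl|{net_cfg.optimizer}"
            single_rows.append({"model": key, **{m: report.mean(m) for m in report.mean_sd}})
            # the selected architecture carries the family's CV result forward
            if net_cfg.hidden_sizes == (512, 128, 8) and net_cfg.optimizer == "Adamax":
                cv_reports[fam] = report
                single_nets[fam] = neuralnet.train_network(feats_train[fam], y_train, net_cfg)
        _write(out / "single_models.json", json.dumps(single_rows, indent=2), artifacts)

        stage = "integrate"
        pairs = ensemble.enumerate_pairs(cfg.families)
        pair_rows = {}
        for fa, fb in pairs:
            # pair CV: OR-vote the members' out-of-fold labels fold by fold
            accs, bals, precs = [], [], []
            from sklearn.model_selection import StratifiedKFold

            skf = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed)
            for fold, (tr, te) in enumerate(skf.split(feats_train[fa].values, y_train)):
                fold_seed = (cfg.seed + fold) % 2**31
                la = neuralnet.predict(
                    neuralnet.train_network(
                        feats_train[fa].values[tr], y_train[tr],
                        neuralnet.NetworkConfig(epochs=cfg.epochs, seed=fold_seed)),
                    feats_train[fa].values[te])[1]
                lb = neuralnet.predict(
                    neuralnet.train_network(
                        feats_train[fb].values[tr], y_train[tr],
                        neuralnet.NetworkConfig(epochs=cfg.epochs, seed=fold_seed)),
                    feats_train[fb].values[te])[1]
                m = metrics.compute_metrics(
                    metrics.confusion_counts(y_train[te], ensemble.or_vote(la, lb)))
                accs.append(m.accuracy); bals.append(m.balanced_accuracy); precs.append(m.precision)
            pair_rows[f"{fa}-{fb}"] = (
                float(np.mean(accs)), float(np.mean(bals)), float(np.mean(precs)))
        selection = ensemble.select_best(pair_rows)
        _write(out / "selection.json", selection.to_json(), artifacts)

        stage = "evaluate"
        fa, fb = selection.winner.split("-", 1)
        best = ensemble.IntegratedModel(member_a=single_nets[fa], member_b=single_nets[fb])
        test_labels = best.predict_labels(feats_test[fa].values, feats_test[fb].values)
        test_metrics = metrics.compute_metrics(metrics.confusion_counts(y_test, test_labels))
        _write(out / "test_metrics.json",
               json.dumps(test_metrics.rounded().as_dict(), indent=2), artifacts)

        if cfg.run_ad:
            stage = "ad"
            for fam in (fa, fb):
                lev = applicability.fit_leverage(feats_train[fam])
                rep = applicability.ad_report(lev, feats_test[fam])
                rep.to_csv(out / f"ad_{fam}.tsv", sep="\t", index=False)
                artifacts.append(f"ad_{fam}.tsv")

        if cfg.run_shap:
            stage = "shap"
            rng = np.random.default_rng(cfg.seed)
            Xtr = feats_train[fa]
            bg = Xtr.values[rng.choice(Xtr.n, size=min(100, Xtr.n), replace=False)]
            explain = Xtr.values[rng.choice(Xtr.n, size=min(cfg.shap_rows, Xtr.n), replace=False)]
            summary = interpret.shapley_attributions(
                single_nets[fa], bg, explain, n_samples=cfg.shap_samples,
                seed=cfg.seed, feature_names=Xtr.column_names)
            groups = interpret.maccs_key_groups() if fa == "MACCS" else {}
            summary.table(groups=groups).to_csv(out / "shap.tsv", sep="\t", index=False)
            artifacts.append("shap.tsv")

        if cfg.run_arka:
            stage = "arka"
            model = arka.fit_arka(feats_train[fa], y_train)
            points = arka.arka_scores(model, feats_train[fa], y_train)
            arka.detect_cliffs(points)
            arka.arka_table(points).to_csv(out / "arka_train.tsv", sep="\t", index=False)
            artifacts.append("arka_train.tsv")

        if cfg.run_xrand:
            stage = "xrand"
            Xr = featurize.x_randomize(feats_train[fa], seed=cfg.seed)
            rep = neuralnet.cross_validate(
                Xr, y_train, neuralnet.NetworkConfig(epochs=cfg.epochs, seed=cfg.seed),
                k=cfg.k_folds, seed=cfg.seed)
            _write(out / "xrand_cv.json", rep.to_json(), artifacts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "n_single_models": len(grid),
        "n_pairs": len(pairs),
        "winner": selection.winner,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
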