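"""End-to-end orchestration of the six pipeline stages.

select -> fuse -> normalize -> balance -> split -> (5-fold early-stopped
CNN training, best model kept) -> feature extraction -> SVM fit -> test
metrics.

Two resampling orders are first-class. ``paper`` mode balances the whole
dataset before the train/test split — the order the reference protocol
describes — which leaks synthetic copies of test-set neighborhoods into
training. ``safe`` mode splits first and confines feature selection,
normalization fitting and resampling to the training partition. Both are
reported so the leakage gap is visible; every stage derives its seed from
the single pipeline seed, making a full run exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from .fusion import (FusedDataset, OmicsBlock, fuse_equal_weight,
                     minmax_apply, minmax_fit_transform, minmax_normalize,
                     rf_feature_importance, select_top_k)
from .network import ECNNConfig, ECNNModel
from .resample import SmoteParams, hybrid_balance
from .svm import SVMModel, fit_svm, svm_predict

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "repeated_runs"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults match the module-level defaults."""

    top_k: int = 64
    n_trees: int = 500
    criterion: str = "gini"
    smote_k: int = 5
    majority_only: bool = False
    mode: str = "paper"               # 'paper' | 'safe'
    ecnn: ECNNConfig = field(default_factory=ECNNConfig)
    svm_C: float = 0.9
    svm_delta: float | None = None
    seed: int = 0
    n_rounds: int = 10
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "safe"):
            raise ValueError("mode must be 'paper' or 'safe'")


@dataclass
class PipelineResult:
    """Everything one run produced, sufficient to audit every number."""

    report: ev.MetricsReport
    cm: ev.ConfusionMatrix
    resample_report: dict
    selection: pd.DataFrame
    model: ECNNModel
    svm: SVMModel
    fold_histories: list[list[dict]]
    best_fold: int
    provenance: dict
    test_set: FusedDataset

    def metrics_json(self) -> str:
        """Deterministic serialization of the run's metric report."""
        payload = {
            "confusion": self.cm.as_dict(),
            "metrics": self.report.as_dict(),
            "resample": self.resample_report,
            "best_fold": self.best_fold,
            "mode": self.provenance["mode"],
            "seed": self.provenance["seed"],
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Derive independent per-stage seeds (< 2^31) from the pipeline seed."""
    state = np.random.SeedSequence(seed).generate_state(12)
    ints = [int(s & 0x7FFFFFFF) for s in state]
    return {
        "rf": ints[0:4],
        "smote": ints[4],
        "split": ints[5],
        "fold": ints[6],
        "net": ints[7:12],
    }


def _select_and_fuse(blocks: Sequence[OmicsBlock], labels: np.ndarray,
                     cfg: PipelineConfig, rf_seeds: Sequence[int]
                     ) -> tuple[list, pd.DataFrame]:
    selected = []
    manifests = []
    for block, s in zip(blocks, rf_seeds):
        imp = rf_feature_importance(block, labels, n_trees=cfg.n_trees,
                                    criterion=cfg.criterion, seed=s)
        k = min(cfg.top_k, block.n_features)
        selected.append(select_top_k(imp, block, k))
        manifests.append(imp.manifest(block.feature_ids).head(k))
    return selected, pd.concat(manifests, ignore_index=True)


def run_pipeline(blocks: Sequence[OmicsBlock], labels,
                 config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline on four omics blocks plus survival labels.

    Returns the test-set metrics together with every intermediate artifact
    (selection manifest, resampling report, per-fold training logs, the
    best-fold network, the SVM, and sample-level provenance). Identical
    config and seed give an identical result, byte-for-byte in the
    serialized report.
    """
    labels = np.asarray(labels, dtype=int)
    seeds = _stage_seeds(config.seed)

    if config.mode == "paper":
        sel_ids = list(blocks[0].sample_ids)
        selected, manifest = _select_and_fuse(blocks, labels, config, seeds["rf"])
        fused = fuse_equal_weight(selected, labels)
        norm = minmax_normalize(fused)
        balanced, res_report = hybrid_balance(
            norm, SmoteParams(config.smote_k, None, seeds["smote"]),
            majority_only=config.majority_only)
        train, test = ev.split_8_2(balanced, seeds["split"])
    else:  # safe: split first, fit everything inside the training partition
        idx = np.arange(len(labels))
        from sklearn.model_selection import train_test_split
        tr_idx, te_idx = train_test_split(idx, test_size=0.2, stratify=labels,
                                          random_state=seeds["split"])
        tr_idx, te_idx = np.sort(tr_idx), np.sort(te_idx)
        train_blocks = [b.subset_samples(tr_idx) for b in blocks]
        sel_ids = list(train_blocks[0].sample_ids)
        selected, manifest = _select_and_fuse(train_blocks, labels[tr_idx],
                                              config, seeds["rf"])
        keep_ids = {b.source_tag: b.feature_ids for b in selected}
        test_blocks = []
        for b in blocks:
            cols = [b.feature_ids.index(f) for f in keep_ids[b.source_tag]]
            test_blocks.append(OmicsBlock(b.source_tag,
                                          b.values[np.ix_(te_idx, cols)],
                                          [b.sample_ids[i] for i in te_idx],
                                          list(keep_ids[b.source_tag])))
        fused_tr = fuse_equal_weight(selected, labels[tr_idx])
        fused_te = fuse_equal_weight(test_blocks, labels[te_idx])
        tr_values, mm = minmax_fit_transform(fused_tr.values)
        fused_tr = replace(fused_tr, values=tr_values)
        fused_te = replace(fused_te, values=minmax_apply(fused_te.values, mm))
        train, res_report = hybrid_balance(
            fused_tr, SmoteParams(config.smote_k, None, seeds["smote"]),
            majority_only=config.majority_only)
        test = fused_te
    res_report["mode"] = config.mode

    folds = ev.five_fold(train, seeds["fold"])
    models: list[ECNNModel] = []
    for i, (fit_part, val_part) in enumerate(folds):
        net_cfg = replace(config.ecnn, seed=seeds["net"][i])
        models.append(ECNNModel(net_cfg).fit(
            fit_part.values, fit_part.labels, val_part.values, val_part.labels))
    best_fold = int(np.argmin([m.best_val_loss for m in models]))
    best = models[best_fold]

    feats_train = best.extract(train.values)
    feats_test = best.extract(test.values)
    svm = fit_svm(feats_train, train.labels, C=config.svm_C,
                  delta=config.svm_delta)
    pred = svm_predict(svm, feats_test)
    cm = ev.confusion(test.labels, pred)
    report = ev.metrics(cm)

    result = PipelineResult(
        report=report, cm=cm, resample_report=res_report, selection=manifest,
        model=best, svm=svm,
        fold_histories=[m.history for m in models], best_fold=best_fold,
        provenance={
            "mode": config.mode, "seed": config.seed,
            "selection_sample_ids": sel_ids,
            "train_sample_ids": list(train.sample_ids),
            "test_sample_ids": list(test.sample_ids),
        },
        test_set=test,
    )
    if config.outdir is not None:
        _write_artifacts(result, Path(config.outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.selection.to_csv(outdir / "selection.tsv", sep="\t", index=False)
    (outdir / "resample.json").write_text(
        json.dumps(result.resample_report, sort_keys=True, indent=2))
    result.model.save(outdir / "ecnn.json")
    result.svm.save(outdir / "svm.json")
    (outdir / "metrics.json").write_text(result.metrics_json())
    rows = [dict(h, fold=i) for i, hist in enumerate(result.fold_histories)
            for h in hist]
    pd.DataFrame(rows).to_csv(outdir / "training_log.csv", index=False)
    test = result.test_set
    df = pd.DataFrame(test.values, index=test.sample_ids)
    df.insert(0, "label", test.labels)
    df.to_csv(outdir / "test_set.tsv", sep="\t")


def replay_checkpoint(outdir: str | Path) -> ev.MetricsReport:
    """Recompute test metrics from saved artifacts, skipping all training."""
    outdir = Path(outdir)
    model = ECNNModel.load(outdir / "ecnn.json")
    svm = SVMModel.load(outdir / "svm.json")
    df = pd.read_csv(outdir / "test_set.tsv", sep="\t", index_col=0)
    labels = df.pop("label").to_numpy(dtype=int)
    feats = model.extract(df.to_numpy(dtype=float))
    pred = svm_predict(svm, feats)
    return ev.metrics(ev.confusion(labels, pred))


def repeated_runs(blocks: Sequence[OmicsBlock], labels,
                  config: PipelineConfig, seeds: Sequence[int] | None = None
                  ) -> tuple[ev.MetricsReport, list[dict]]:
    """The repeated-experiment protocol: one full pipeline per seed.

    Aggregates per-round test metrics and the across-run accuracy variance.
    ``seeds`` defaults to ``config.seed + 0 .. n_rounds-1``.
    """
    if seeds is None:
        seeds = [config.seed + i for i in range(config.n_rounds)]

    def one_round(seed: int):
        result = run_pipeline(blocks, labels, replace(config, seed=seed,
                                                      outdir=None))
        return result.cm, {"resample": result.resample_report,
                           "best_fold": result.best_fold}

    return ev.repeated_experiment(one_round, seeds)
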