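"""End-to-end pipeline: rank → IFS curve → final model → optional test set.

One :class:`PipelineConfig` document carries every stage's settings and
is echoed into the header comments of each output file, so a run is
reproducible from its artifacts alone.  Outputs written to ``out_dir``:

    ranking.tsv             full mRMR ordering with scores
    ifs_curve.tsv           per-k CV metrics (one row per k)
    selected_features.txt   the optimal top-k feature names, one per line
    model.joblib            the final trained forest (with feature names)
    report.tsv / report.json  training-CV row and, if a test table was
                              given, an independent-test row
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .datasets import LabeledDataset
from .forest import RFConfig, predict, save_model
from .ifs import ifs_curve, select_final_model
from .io import read_dataset, write_ifs_curve, write_ranking
from .metrics import CVConfig, MetricSet, compute_metrics, confusion
from .mrmr import rank_features

log = logging.getLogger("editrf")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    label_column: str = "label"
    positive_label: str = "1"
    negative_label: str | None = None
    delimiter: str | None = None
    sample_id_column: str | None = None
    impute: str | None = None
    scheme: str = "MID"
    threshold_multiplier: float = 1.0
    passthrough_levels: int = 3
    n_trees: int = 10
    max_depth: int | None = None
    folds: int = 10
    stratified: bool = True
    pooled: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.scheme not in ("MID", "MIQ"):
            raise ValueError("scheme must be MID or MIQ")
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.impute not in (None, "median"):
            raise ValueError("impute must be 'median' or unset")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: ("" if v is None else v) for k, v in d.items()}

    def rf(self) -> RFConfig:
        return RFConfig(
            n_trees=self.n_trees, max_depth=self.max_depth, seed=self.seed
        )

    def cv(self) -> CVConfig:
        return CVConfig(
            folds=self.folds,
            seed=self.seed,
            stratified=self.stratified,
            pooled=self.pooled,
        )


def _metrics_row(dataset_name: str, k: int, m: MetricSet) -> dict:
    return {
        "dataset": dataset_name,
        "features": k,
        "Sn": m.sn,
        "Sp": m.sp,
        "Acc": m.acc,
        "MCC": m.mcc,
    }


def _load(path, cfg: PipelineConfig) -> LabeledDataset:
    return read_dataset(
        path,
        label_column=cfg.label_column,
        delimiter=cfg.delimiter,
        positive_label=cfg.positive_label,
        negative_label=cfg.negative_label,
        sample_id_column=cfg.sample_id_column,
        impute=cfg.impute,
    )


def run_pipeline(
    train_path: str | Path,
    test_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "editrf_out",
) -> dict:
    """Run the full workflow and write all artifacts; returns the report."""
    cfg = config or PipelineConfig()
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = cfg.echo()

    train_ds = _load(train_path, cfg)
    neg, pos = train_ds.class_counts
    log.info(
        "training table: %d samples (%d positive, %d negative), %d features",
        train_ds.n_samples, pos, neg, train_ds.n_features,
    )

    ranking = rank_features(
        train_ds,
        scheme=cfg.scheme,
        threshold_multiplier=cfg.threshold_multiplier,
        passthrough_levels=cfg.passthrough_levels,
    )
    write_ranking(ranking, out / "ranking.tsv", comments=echo)

    curve = ifs_curve(train_ds, ranking, cfg.rf(), cfg.cv())
    write_ifs_curve(curve, out / "ifs_curve.tsv", comments=echo)
    log.info(
        "IFS optimum: k=%d, MCC=%.4f", curve.optimal_k, curve.optimal_metrics.mcc
    )

    selected = ranking.top(curve.optimal_k)
    (out / "selected_features.txt").write_text(
        "\n".join(selected) + "\n", encoding="utf-8"
    )

    model = select_final_model(train_ds, curve, ranking, cfg.rf())
    save_model(model, out / "model.joblib")

    rows = [_metrics_row("training", curve.optimal_k, curve.optimal_metrics)]
    if test_path is not None:
        test_ds = _load(test_path, cfg)
        preds = predict(model, test_ds.table)
        test_m = compute_metrics(confusion(test_ds.labels, preds))
        rows.append(_metrics_row("testing", curve.optimal_k, test_m))
        log.info("testing: Acc=%.3f MCC=%.3f", test_m.acc, test_m.mcc)

    report = {"config": echo, "optimal_k": curve.optimal_k, "rows": rows}
    with open(out / "report.tsv", "w", encoding="utf-8") as fh:
        for key, val in echo.items():
            fh.write(f"# {key}={val}\n")
        fh.write("dataset\tfeatures\tSn\tSp\tAcc\tMCC\n")
        for r in rows:
            fh.write(
                f"{r['dataset']}\t{r['features']}\t{float(r['Sn'])!r}\t"
                f"{float(r['Sp'])!r}\t{float(r['Acc'])!r}\t{float(r['MCC'])!r}\n"
            )
    (out / "report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
    return report
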