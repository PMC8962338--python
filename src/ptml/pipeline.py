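"""End-to-end pipeline: curate -> describe -> deviate -> select -> train ->
evaluate -> interpret, with every stage logged and every artifact
reproducible from the resolved configuration echo."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import conditions_dataset as cd
from . import ptml_model as pm
from .descriptors import gti_table
from .interpret_design import class_propensities, sensitivity_values
from .specs import candidate_features, parse_feature_name

log = logging.getLogger("ptml")


@dataclass
class RunConfig:
    """Resolved settings for one modeling run."""

    input_csv: str
    out_dir: str
    model: int = 2
    cutoff_csv: str | None = None  # None -> bundled default roster
    test_fraction: float = 0.25
    split_seed: int = 7
    target_size: int | None = None  # None -> 15 (model 1) / 14 (model 2)
    pcc_bound: float = 0.7
    hidden_width: int = 45
    train_seed: int = 7
    bins: int = 24

    def resolved_target_size(self) -> int:
        if self.target_size is not None:
            return self.target_size
        return 15 if self.model == 1 else 14


@dataclass
class PipelineResult:
    config: RunConfig
    records: pd.DataFrame
    features: pd.DataFrame
    selected: list[str]
    stats: cd.BoxJenkinsStats
    mlp: pm.ClassifierBundle
    lda: pm.ClassifierBundle
    report: dict
    curation_log: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, *, write: bool = True) -> PipelineResult:
    """Execute every stage on a bioactivity table and (optionally) write
    the artifacts (features.csv, bj.json, model .json files, report.json,
    interpret.json, resolved config echo) to ``config.out_dir``."""
    cutoffs = (
        cd.CutoffTable.from_csv(config.cutoff_csv)
        if config.cutoff_csv
        else cd.CutoffTable.default()
    )
    records, curation = cd.load_bioactivity_table(config.input_csv)
    log.info("curation: %s", curation)
    records = cd.deduplicate(records)
    records = cd.annotate_activity(records, cutoffs)
    records = cd.split_dataset(records, config.test_fraction, config.split_seed)
    train = records[records["split"] == "train"]
    test = records[records["split"] == "test"]
    log.info(
        "split: %d train (%d active), %d test",
        len(train),
        int((train["label"] == 1).sum()),
        len(test),
    )

    gti = gti_table(sorted(set(records["smiles"])), model=config.model)
    stats = cd.fit_box_jenkins(train, gti)
    candidates = candidate_features(config.model)
    feats_train = cd.transform(train, gti, stats, candidates)
    feats_all = cd.transform(records, gti, stats, candidates)

    ranking = pm.rank_features(feats_train, train["label"], bins=config.bins)
    selected = pm.select_features(
        ranking,
        feats_train,
        pcc_bound=config.pcc_bound,
        target_size=config.resolved_target_size(),
    )
    log.info("selected %d features: %s", len(selected), selected)

    x_train = feats_train[selected]
    x_test = feats_all.loc[test.index, selected]
    mlp = pm.train_classifier(
        x_train,
        train["label"],
        "mlp",
        hidden_width=config.hidden_width,
        seed=config.train_seed,
    )
    lda = pm.train_classifier(x_train, train["label"], "lda", seed=config.train_seed)

    report: dict = {"topology": mlp.topology, "selected_features": selected}
    for name, bundle in (("mlp", mlp), ("lda", lda)):
        report[name] = {
            "train": pm.evaluate(
                bundle, x_train, train["label"], train[["ma", "tg", "ei"]]
            ).to_dict(),
            "test": pm.evaluate(
                bundle, x_test, test["label"], test[["ma", "tg", "ei"]]
            ).to_dict(),
        }
    report["ad"] = {
        "train_in_ad_fraction": float(mlp.in_ad(x_train).mean()),
        "test_in_ad_fraction": float(mlp.in_ad(x_test).mean()),
    }

    result = PipelineResult(
        config=config,
        records=records,
        features=feats_all,
        selected=selected,
        stats=stats,
        mlp=mlp,
        lda=lda,
        report=report,
        curation_log=curation,
    )
    if write:
        _write_artifacts(result, x_train, train)
    return result


def _write_artifacts(result: PipelineResult, x_train: pd.DataFrame, train: pd.DataFrame) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=1)
    result.records.to_csv(out / "records.csv", index=False)
    result.features.to_csv(out / "features.csv", index=False)
    result.stats.save(out / "bj.json")
    result.mlp.save(out / "model_mlp.json")
    result.lda.save(out / "model_lda.json")
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, default=float)
    prop = class_propensities(x_train, train["label"], result.selected)
    sv = sensitivity_values(result.mlp, x_train, train["label"])
    with open(out / "interpret.json", "w") as fh:
        json.dump(
            {
                "propensities": prop.reset_index().to_dict(orient="records"),
                "sensitivity": sv.reset_index().to_dict(orient="records"),
                "baseline_error": sv.attrs["baseline_error"],
            },
            fh,
            indent=1,
            default=float,
        )


def model_features_of(bundle: pm.ClassifierBundle) -> list[tuple[str, str]]:
    """The (raw spec, element kind) pairs behind a bundle's features."""
    return [parse_feature_name(n) for n in bundle.feature_names]
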