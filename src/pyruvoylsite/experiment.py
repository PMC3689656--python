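"""End-to-end experiment driver on synthetic corpora.

Wires the whole pipeline together the way a study run would: generate a
corpus, extract serine windows, build balanced datasets, split train/test,
fit the positional frequency table on the training positives, encode both
splits, rank + incrementally select features on the training split, and
evaluate the final forest on the held-out split. Used by the CLI and the
reproduction script; also the harness for planted-signal recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import build_catalog, encode_all, fit_frequency_table
from .metrics import MetricSet, confusion, metric_set, roc
from .pipeline import (
    IncrementalFeatureClassifier,
    build_datasets,
    split_train_test,
)
from .synthetic import FixtureBundle, SyntheticConfig, generate
from .windowing import WindowConfig, build_sample_set


@dataclass
class ExperimentResult:
    """One dataset's train/evaluate outcome."""

    window_length: int
    k: int
    selected_features: tuple[str, ...]
    train_cv: MetricSet
    test: MetricSet
    test_auc: float
    jaccard_vs_planted: float


def jaccard(a, b) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def run_synthetic_experiment(
    seed: int,
    window_length: int = 17,
    max_k: int | None = 30,
    dataset_index: int = 0,
    folds: int = 10,
    trees: int = 10,
    config: SyntheticConfig | None = None,
    bundle: FixtureBundle | None = None,
) -> ExperimentResult:
    """Run the full pipeline once on a synthetic corpus.

    ``seed`` drives corpus generation, negative partitioning, the
    train/test split, fold assignment and forest training. ``max_k``
    truncates the IFS scan; the default keeps the scan well past where
    the planted signal saturates.
    """
    wconf = WindowConfig.from_length(window_length)
    if bundle is None:
        if config is None:
            config = SyntheticConfig(seed=seed)
        bundle = generate(config)

    windows = build_sample_set(bundle.proteins, bundle.sites, wconf)
    datasets = build_datasets(windows, parts=4, seed=seed)
    dataset = datasets.datasets[dataset_index]

    split = split_train_test(dataset, fraction=0.8, seed=seed)
    train_windows = [dataset[i] for i in split.train]
    test_windows = [dataset[i] for i in split.test]

    freq = fit_frequency_table(train_windows, wconf, on="positives")
    catalog = build_catalog(wconf)
    train = encode_all(train_windows, bundle.annotations, freq, catalog)
    test = encode_all(test_windows, bundle.annotations, freq, catalog)

    model = IncrementalFeatureClassifier(
        folds=folds, trees=trees, max_k=max_k, random_state=seed
    )
    model.fit(train.values, train.labels)

    pred = model.predict(test.values)
    scores = model.vote_fraction(test.values)
    test_metrics = metric_set(confusion(test.labels, pred))
    test_auc = roc(test.labels, scores).auc

    selected = tuple(catalog[i].name for i in model.selected_)
    planted = bundle.planted_feature_names(wconf)
    best_idx = int(np.argmax(model.ifs_curve_.mcc()))
    return ExperimentResult(
        window_length=window_length,
        k=model.k_,
        selected_features=selected,
        train_cv=model.ifs_curve_.metrics[best_idx],
        test=test_metrics,
        test_auc=test_auc,
        jaccard_vs_planted=jaccard(selected, planted),
    )
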