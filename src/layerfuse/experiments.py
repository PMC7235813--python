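"""Experiment harnesses: assembling methods, layer subsets, data size.

Each harness trains the tagger over a grid of one varied factor on a
shared synthetic corpus, holding every non-varied setting (corpus,
split, encoder geometry, optimization, repeat seeds) identical across
cells — fairness is asserted by logging a configuration hash per cell.
Each cell is repeated ``repeats`` times with derived seeds and reported
as the run with the median test micro-F1 (for three repeats, the middle
of the ranking).

These harnesses reproduce an experiment *design* on synthetic data; no
claim is made that synthetic rankings transfer to real clinical text.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aggregate import AGGREGATE_METHODS, resolve_layer_subset
from .corpus import AnnotatedSentence, CorpusSpec, default_corpus_spec, generate_corpus, split_corpus
from .encoder import EncoderConfig, tiny_encoder_config
from .model import TrainConfig, evaluate_model, tiny_train_config, train

__all__ = [
    "ExperimentGrid",
    "run_single",
    "compare_assembling",
    "compare_layer_subsets",
    "learning_curve",
    "end_to_end_benchmark",
]

DEFAULT_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 1.0)
SUBSET_ORDER = ("all", "last6", "last4", "last2")


def end_to_end_benchmark(seed: int = 0, n_train: int = 2000,
                         n_valid: int = 500, n_test: int = 500,
                         epochs: int = 10) -> dict:
    """Reference end-to-end run: train the multi-head fusion tagger on
    the default separable synthetic corpus and score the held-out test
    split.

    Train/validation/test corpora are generated independently (i.i.d.
    sentences, disjoint derived seeds).  The desk-scale geometry is the
    4-layer, width-64 encoder with 4 encoder heads and 4 fusion heads,
    batch size 32, at most 10 epochs.  Returns the trained model, the
    training history (including the pre-training loss) and the test
    MetricReport.
    """
    train_set = generate_corpus(default_corpus_spec(n_sentences=n_train,
                                                    seed=seed + 11))
    valid_set = generate_corpus(default_corpus_spec(n_sentences=n_valid,
                                                    seed=seed + 12))
    test_set = generate_corpus(default_corpus_spec(n_sentences=n_test,
                                                   seed=seed + 13))
    cfg = tiny_encoder_config(seed=seed)
    model, history = train(
        train_set, valid_set, cfg,
        train_config=tiny_train_config(seed=seed, epochs=epochs),
        method="multihead", n_fusion_heads=4,
    )
    report = evaluate_model(model, test_set)
    return {
        "model": model,
        "history": history,
        "report": report,
        "n_train": len(train_set),
        "n_test": len(test_set),
    }


@dataclass(frozen=True)
class ExperimentGrid:
    """One experiment: a corpus recipe plus the factor levels to sweep."""

    corpus_spec: CorpusSpec
    seed: int = 0
    repeats: int = 3
    methods: Tuple[str, ...] = AGGREGATE_METHODS
    subsets: Tuple[str, ...] = ("all", "last2")
    fractions: Tuple[float, ...] = DEFAULT_FRACTIONS
    method: str = "multihead"
    layer_subset: str = "all"
    encoder_config: Optional[EncoderConfig] = None
    train_config: Optional[TrainConfig] = None
    n_fusion_heads: Optional[int] = None

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for m in self.methods:
            if m not in AGGREGATE_METHODS:
                raise ValueError(f"unknown aggregation method {m!r}")
        for f in self.fractions:
            if not (0.0 < f <= 1.0):
                raise ValueError(f"training fraction {f} outside (0, 1]")

    def resolved_encoder_config(self) -> EncoderConfig:
        return self.encoder_config or tiny_encoder_config(seed=self.seed)

    def resolved_train_config(self) -> TrainConfig:
        return self.train_config or tiny_train_config(seed=self.seed)


def _config_hash(grid: ExperimentGrid) -> str:
    """Hash of everything a cell must NOT vary (data + shared settings)."""
    import dataclasses

    shared = {
        "corpus_spec": {
            **dataclasses.asdict(grid.corpus_spec),
            "entity_lexicons": {k: list(v) for k, v in
                                grid.corpus_spec.entity_lexicons.items()},
        },
        "seed": grid.seed,
        "repeats": grid.repeats,
        "encoder_config": dataclasses.asdict(grid.resolved_encoder_config()),
        "train_config": dataclasses.asdict(grid.resolved_train_config()),
    }
    blob = json.dumps(shared, sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _data(grid: ExperimentGrid):
    corpus = generate_corpus(grid.corpus_spec)
    return split_corpus(corpus, (0.6, 0.2, 0.2), seed=grid.seed)


def run_single(train_set: Sequence[AnnotatedSentence],
               valid_set: Sequence[AnnotatedSentence],
               test_set: Sequence[AnnotatedSentence],
               grid: ExperimentGrid, method: str, layer_subset: str,
               repeat_seed: int) -> dict:
    """Train one cell-repeat and score it on the held-out test set."""
    cfg = grid.resolved_encoder_config()
    import dataclasses

    tcfg = dataclasses.replace(grid.resolved_train_config(), seed=repeat_seed)
    model, history = train(
        list(train_set), list(valid_set), cfg,
        train_config=tcfg, method=method, layer_subset=layer_subset,
        n_fusion_heads=grid.n_fusion_heads,
    )
    report = evaluate_model(model, test_set)
    return {
        "seed": repeat_seed,
        "history": history,
        "report": report,
        "precision": report.micro.precision,
        "recall": report.micro.recall,
        "f1": report.micro.f1,
    }


def _median_run(runs: List[dict]) -> dict:
    """The run in the middle of the F1 ranking (lower middle if even)."""
    ranked = sorted(runs, key=lambda r: r["f1"])
    return ranked[(len(ranked) - 1) // 2]


def _run_cell(data, grid: ExperimentGrid, method: str, layer_subset: str) -> Tuple[dict, List[dict]]:
    train_set, valid_set, test_set = data
    runs = [
        run_single(train_set, valid_set, test_set, grid, method,
                   layer_subset, repeat_seed=grid.seed + 101 * (r + 1))
        for r in range(grid.repeats)
    ]
    return _median_run(runs), runs


def _finish(rows: List[dict], all_runs: Dict, grid: ExperimentGrid) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.attrs["runs"] = all_runs
    df.attrs["config_hash"] = _config_hash(grid)
    return df


def compare_assembling(grid: ExperimentGrid) -> pd.DataFrame:
    """Sweep the assembling method; one row per method with the median
    run's P/R/F1 (percent)."""
    data = _data(grid)
    rows, all_runs = [], {}
    for method in grid.methods:
        picked, runs = _run_cell(data, grid, method, grid.layer_subset)
        all_runs[method] = runs
        rows.append({
            "method": method,
            "P": 100 * picked["precision"],
            "R": 100 * picked["recall"],
            "F1": 100 * picked["f1"],
        })
    return _finish(rows, all_runs, grid)


def compare_layer_subsets(grid: ExperimentGrid) -> pd.DataFrame:
    """Sweep the extracted layer subset for the multi-head method;
    rows follow the canonical order all, last6, last4, last2."""
    cfg = grid.resolved_encoder_config()
    for s in grid.subsets:
        resolve_layer_subset(s, cfg.n_layers)  # fail fast on subset > L
    ordered = [s for s in SUBSET_ORDER if s in grid.subsets]
    ordered += [s for s in grid.subsets if s not in ordered]
    data = _data(grid)
    rows, all_runs = [], {}
    for subset in ordered:
        picked, runs = _run_cell(data, grid, grid.method, subset)
        all_runs[subset] = runs
        rows.append({
            "subset": subset,
            "P": 100 * picked["precision"],
            "R": 100 * picked["recall"],
            "F1": 100 * picked["f1"],
        })
    return _finish(rows, all_runs, grid)


def training_subsets(train_set: Sequence[AnnotatedSentence],
                     fractions: Sequence[float], seed: int):
    """Nested training subsets: one shuffle, prefixes of growing size."""
    order = np.random.default_rng(seed).permutation(len(train_set))
    for f in fractions:
        k = max(1, math.ceil(f * len(train_set)))
        yield f, [train_set[i] for i in order[:k]]


def learning_curve(grid: ExperimentGrid) -> pd.DataFrame:
    """F1 as a function of training-set fraction (nested subsets)."""
    train_set, valid_set, test_set = _data(grid)
    rows, all_runs = [], {}
    for f, subset in training_subsets(train_set, sorted(grid.fractions),
                                      grid.seed + 7):
        picked, runs = _run_cell((subset, valid_set, test_set), grid,
                                 grid.method, grid.layer_subset)
        all_runs[f] = {"runs": runs, "n_train": len(subset)}
        rows.append({
            "fraction": f,
            "n_train": len(subset),
            "P": 100 * picked["precision"],
            "R": 100 * picked["recall"],
            "F1": 100 * picked["f1"],
        })
    return _finish(rows, all_runs, grid)
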