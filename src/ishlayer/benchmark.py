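"""End-to-end synthetic benchmark: generate, featurize, evaluate.

One call reproduces the full study design on synthetic data: a labeled
dataset of per-gene image sets, multi-scale LBP featurization, and nested
gene-grouped cross-validated evaluation of every layer detector under the
four pooling strategies, plus the single-factor resolution ablation and
selected one-vs-one confusions.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .datasets import FeaturizedDataset
from .evaluation import ALL_STRATEGIES, EvalConfig, EvalResult, evaluate_layer
from .gene_model import Strategy
from .preprocess import DEFAULT_FACTORS
from .synthetic_data import LayerClass, POSITIVE_LAYERS, generate_dataset

__all__ = ["BenchmarkResult", "run_synthetic_benchmark"]


@dataclass
class BenchmarkResult:
    """Everything the synthetic benchmark computes."""

    dataset: FeaturizedDataset
    #: layer -> strategy -> EvalResult (layer vs the shared negative set)
    strategies: dict[LayerClass, dict[Strategy, EvalResult]]
    #: layer -> {factor: EvalResult, "multi": EvalResult}
    ablation: dict[LayerClass, dict] = field(default_factory=dict)
    #: (layer_i, layer_j) -> EvalResult of the pairwise two-level classifier
    pairwise: dict[tuple[LayerClass, LayerClass], EvalResult] = field(
        default_factory=dict
    )

    def auc(self, layer: LayerClass, strategy: Strategy = Strategy.TWO_LEVEL) -> float:
        return self.strategies[LayerClass(layer)][Strategy(strategy)].mean_auc


def run_synthetic_benchmark(
    n_per_class: int = 40,
    n_negative: int = 120,
    seed: int = 1,
    factors: tuple[int, ...] = DEFAULT_FACTORS,
    strategies: tuple = ALL_STRATEGIES,
    run_ablation: bool = True,
    confusion_pairs: tuple = ((LayerClass.GRANULAR, LayerClass.MOLECULAR),),
    out_dir: str | Path | None = None,
    config: EvalConfig | None = None,
    verbose: bool = False,
) -> BenchmarkResult:
    """Run the full synthetic study and return every result.

    Images are written to ``out_dir`` (a temporary directory by default,
    removed afterwards) and read back through the standard loading path, so
    the disk round trip is part of what is being tested.
    """
    config = config or EvalConfig(seed=seed)

    def log(msg: str) -> None:
        if verbose:
            print(msg, flush=True)

    if out_dir is None:
        with tempfile.TemporaryDirectory(prefix="ishlayer_bench_") as tmp:
            log(f"generating dataset ({n_per_class}/class, {n_negative} negative)")
            manifest = generate_dataset(n_per_class, n_negative, seed, tmp)
            log("featurizing")
            dataset = FeaturizedDataset.from_manifest(manifest, factors)
    else:
        manifest = generate_dataset(n_per_class, n_negative, seed, out_dir)
        dataset = FeaturizedDataset.from_manifest(manifest, factors)

    result = BenchmarkResult(dataset=dataset, strategies={})
    for layer in POSITIVE_LAYERS:
        log(f"evaluating {layer.value} vs negative ({len(strategies)} strategies)")
        result.strategies[layer] = evaluate_layer(
            dataset, layer, strategies, config
        )

    if run_ablation:
        for layer in POSITIVE_LAYERS:
            log(f"resolution ablation: {layer.value}")
            abl = {}
            for f in factors:
                abl[f] = evaluate_layer(
                    dataset.select_levels((f,)), layer, Strategy.TWO_LEVEL, config
                )
            abl["multi"] = result.strategies[layer][Strategy.TWO_LEVEL]
            result.ablation[layer] = abl

    for li, lj in confusion_pairs:
        li, lj = LayerClass(li), LayerClass(lj)
        log(f"pairwise: {li.value} vs {lj.value}")
        result.pairwise[(li, lj)] = evaluate_layer(
            dataset, li, Strategy.TWO_LEVEL, config, versus=lj
        )
    return result
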