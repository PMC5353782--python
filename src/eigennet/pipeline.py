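"""One-step orchestration of the full eigengene-network workflow.

filter -> modules -> balanced eigengenes -> Bayesian-network consensus ->
disease-children feature selection -> decision tree -> projection onto an
optional test set -> confusion -> greedy gene-set compaction. All
randomness flows from one root seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import bayesnet, classifier, coexpression, eigengene, preprocess
from .dataset import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus optional input/output paths."""

    # input paths (unused when run_pipeline is called with in-memory data)
    train_expr: str | None = None
    train_labels: str | None = None
    test_expr: str | None = None
    test_labels: str | None = None
    delimiter: str = "\t"
    # preprocessing
    filter_fraction: float = 1.0 / 3.0
    # network construction
    candidate_powers: tuple = tuple(range(1, 13))
    r2_cut: float = 0.8
    fallback_power: int = 6  # pinned power when no candidate is scale-free
    cut_height: float = 0.95
    min_module_size: int = 20
    # eigengenes
    balance: bool = True
    balance_target: object = "auto"
    # Bayesian network
    use_bayesnet: bool = True
    n_levels: int = 3
    n_boot: int = 100
    strength_cut: float = 0.5
    bn_feature_cap: int = 8
    # classifier
    min_per_leaf_fraction: float = 0.10
    max_drop: float = 0.05
    min_genes: int = 1
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        if isinstance(cfg.candidate_powers, list):
            cfg.candidate_powers = tuple(cfg.candidate_powers)
        return cfg


@dataclass
class PipelineResult:
    """Everything the one-step run produced, plus a completeness manifest."""

    config: PipelineConfig
    gene_stats: list = None
    filtered: ExpressionDataset = None
    modules: coexpression.ModuleAssignment = None
    power: int = None
    model: eigengene.EigengeneModel = None
    eig_train: pd.DataFrame = None
    eig_test: pd.DataFrame = None
    net: bayesnet.BayesNet = None
    features: list = None
    tree: classifier.DecisionTree = None
    confusion_train: pd.DataFrame = None
    sensitivity_train: dict = None
    confusion_test: pd.DataFrame = None
    sensitivity_test: dict = None
    compaction: classifier.CompactionResult = None
    manifest: dict = field(default_factory=dict)
    log_lines: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.modules is not None:
            self.modules.to_tsv(out / "modules.tsv")
        if self.model is not None:
            self.model.to_json(out / "model.json")
        if self.eig_train is not None:
            self.eig_train.to_csv(out / "eig_train.tsv", sep="\t", index_label="sample_id")
        if self.eig_test is not None:
            self.eig_test.to_csv(out / "eig_test.tsv", sep="\t", index_label="sample_id")
        if self.net is not None:
            (out / "net.dot").write_text(self.net.to_dot())
            self.net.edge_frame().to_csv(out / "net_edges.tsv", sep="\t", index=False)
        if self.tree is not None:
            self.tree.to_json(out / "tree.json")
            (out / "tree.txt").write_text(self.tree.render())
        if self.confusion_train is not None:
            self.confusion_train.to_csv(out / "confusion_train.tsv", sep="\t")
        if self.confusion_test is not None:
            self.confusion_test.to_csv(out / "confusion_test.tsv", sep="\t")
        if self.compaction is not None:
            rows = [
                {"remaining_genes": n, **{f"acc_{c}": a for c, a in acc.items()}}
                for n, acc in self.compaction.trajectory
            ]
            pd.DataFrame(rows).to_csv(out / "compaction.tsv", sep="\t", index=False)
        (out / "run.log").write_text("\n".join(self.log_lines) + "\n")
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    train: ExpressionDataset,
    config: PipelineConfig | None = None,
    test: ExpressionDataset | None = None,
) -> PipelineResult:
    """Run the full workflow on in-memory datasets."""
    cfg = config or PipelineConfig()
    result = PipelineResult(config=cfg)
    result.log_lines.append(f"config: {asdict(cfg)}")

    def stage(name: str):
        result.manifest[name] = "failed"

        def done():
            result.manifest[name] = "complete"

        return done

    try:
        done = stage("filter")
        cond_a, cond_b = train.conditions()
        result.gene_stats = preprocess.welch_t_per_gene(train, cond_a, cond_b)
        result.filtered = preprocess.filter_top_fraction(
            train, result.gene_stats, cfg.filter_fraction
        )
        result.log_lines.append(
            f"filter: kept {result.filtered.n_genes}/{train.n_genes} genes "
            f"(fraction {cfg.filter_fraction:.4f})"
        )
        done()

        done = stage("modules")
        corr = coexpression.correlation_matrix(result.filtered)
        result.power = coexpression.pick_soft_threshold(
            corr, cfg.candidate_powers, cfg.r2_cut, fallback=cfg.fallback_power
        )
        adj = coexpression.adjacency(corr, result.power)
        dissim = coexpression.tom_dissimilarity(adj)
        result.modules = coexpression.detect_modules(
            dissim, cfg.min_module_size, cfg.cut_height
        )
        sizes = result.modules.module_sizes
        result.log_lines.append(
            f"modules: power {result.power}, "
            f"{len([m for m in sizes if m != 0])} modules, sizes {sizes}"
        )
        done()

        done = stage("eigengenes")
        result.model, result.eig_train = eigengene.compute_eigengenes(
            result.filtered, result.modules, cfg.balance, cfg.balance_target
        )
        result.log_lines.append(
            "eigengenes: replication factors "
            f"{result.model.metadata.get('replication_factors')}"
        )
        done()

        done = stage("feature_selection")
        all_modules = result.model.module_ids
        if cfg.use_bayesnet and len(all_modules) >= 2:
            table = bayesnet.discretize_eigengenes(
                result.eig_train, train.condition, cfg.n_levels
            )
            result.net = bayesnet.consensus_structure(
                table,
                n_boot=cfg.n_boot,
                strength_cut=cfg.strength_cut,
                seed=cfg.seed,
            )
            kids = bayesnet.disease_children(result.net)[: cfg.bn_feature_cap]
            result.features = kids if kids else all_modules
        else:
            result.features = all_modules
        result.log_lines.append(f"features: {result.features}")
        done()

        done = stage("tree")
        result.tree = classifier.fit_tree(
            result.eig_train,
            train.condition,
            result.features,
            cfg.min_per_leaf_fraction,
        )
        pred = classifier.predict(result.tree, result.eig_train)
        result.confusion_train, result.sensitivity_train = classifier.confusion(
            pred, train.condition
        )
        result.log_lines.append(
            f"tree: features {result.tree.features()}, "
            f"train sensitivity {result.sensitivity_train}"
        )
        done()

        if test is not None:
            done = stage("projection")
            result.eig_test = eigengene.project_eigengenes(result.model, test)
            if test.condition is not None:
                pred_t = classifier.predict(result.tree, result.eig_test)
                result.confusion_test, result.sensitivity_test = classifier.confusion(
                    pred_t, test.condition
                )
                result.log_lines.append(
                    f"projection: test sensitivity {result.sensitivity_test}"
                )
            done()

        done = stage("compaction")
        result.compaction = classifier.compact_tree(
            result.tree,
            result.model,
            result.filtered,
            train.condition,
            cfg.min_genes,
            cfg.max_drop,
        )
        n0 = result.compaction.trajectory[0][0]
        result.log_lines.append(
            f"compaction: {n0} -> {len(result.compaction.selected_genes)} genes"
        )
        done()
    except PipelineError:
        raise
    except Exception as exc:
        failed = [k for k, v in result.manifest.items() if v == "failed"]
        raise PipelineError(failed[-1] if failed else "unknown", exc) from exc
    return result


def one_step(config: PipelineConfig, out_dir) -> PipelineResult:
    """File-based entry point: read inputs per config, run, write the bundle."""
    from . import io as _io

    if config.train_expr is None or config.train_labels is None:
        raise ValueError("config must provide train_expr and train_labels paths")
    train = _io.read_expression_matrix(config.train_expr, config.delimiter)
    train = train.with_condition(_io.read_labels(config.train_labels, config.delimiter))
    test = None
    if config.test_expr is not None:
        test = _io.read_expression_matrix(config.test_expr, config.delimiter)
        if config.test_labels is not None:
            test = test.with_condition(
                _io.read_labels(config.test_labels, config.delimiter)
            )
    try:
        result = run_pipeline(train, config, test)
    except PipelineError as err:
        log.error("aborting: %s", err)
        raise
    result.write(out_dir)
    return result
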