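"""Validation protocol and the full factorial strategy comparison.

Per class, 10% of reports (floor) are frozen once as a held-out test set;
the remaining 90% supplies, for each repetition, a fresh random 80/10
train/validation draw. The frozen test ids never enter any base
classifier's training subset, which is what the shared-test-set design is
for. ``run_grid`` evaluates every valid (strategy, decision, algorithm,
weighting) combination — 18 one-vs-one rows plus 9 one-vs-all rows — on the
frozen test partition and on any external corpora, reproducibly from
config + seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import IncidentReport, read_corpus
from .ensemble import (
    VALID_DECISIONS,
    EnsembleModel,
    LabelScheme,
    check_decision,
    decompose_ovsa,
    decompose_ovso,
    train_ensemble,
)
from .evaluation import MetricsReport, average_metrics, confusion_matrix, select_best
from .features import FeaturePipeline, build_vocabulary, vectorize
from .preprocessing import PreprocessConfig, preprocess_corpus
from .synthetic import default_config, generate_corpus

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "ExperimentConfig",
    "GridRow",
    "make_split_plan",
    "run_grid",
    "evaluate_external",
]


@dataclass(frozen=True)
class SplitPlan:
    """Frozen per-class test ids plus repeated train/validation draws."""

    test_ids: frozenset[str]
    repetitions: tuple[tuple[frozenset[str], frozenset[str]], ...]  # (train, validation)
    n_repetitions: int
    seed: int

    def check_disjoint(self) -> None:
        for train, val in self.repetitions:
            assert not (self.test_ids & (train | val)), "test ids leaked into train/validation"
            assert not (train & val), "train/validation overlap"


def make_split_plan(
    corpus: Sequence[IncidentReport],
    scheme: LabelScheme,
    n_repetitions: int = 10,
    seed: int = 0,
    label_field: str = "incident_type",
) -> SplitPlan:
    """80/10/10 repeated random sub-sampling with a single frozen test set.

    Within each class of size n: test and validation each get floor(n/10)
    reports, the remainder trains. The test draw happens once; every
    repetition re-draws train/validation from the remaining 90%.
    """
    by_class: dict[str, list[str]] = {lab: [] for lab in scheme.labels}
    for r in corpus:
        lab = getattr(r, label_field)
        if lab in by_class:
            by_class[lab].append(r.report_id)
    for lab, ids in by_class.items():
        if len(ids) < 10:
            raise ValueError(f"class {lab!r} has only {len(ids)} reports; need >= 10")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    test: set[str] = set()
    remaining: dict[str, list[str]] = {}
    for lab in scheme.labels:
        ids = sorted(by_class[lab])
        k = len(ids) // 10
        pick = rng.choice(len(ids), size=k, replace=False)
        chosen = {ids[i] for i in pick}
        test |= chosen
        remaining[lab] = [i for i in ids if i not in chosen]

    reps = []
    for rep in range(n_repetitions):
        rep_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, rep)))
        train: set[str] = set()
        val: set[str] = set()
        for lab in scheme.labels:
            ids = remaining[lab]
            k = len(by_class[lab]) // 10
            pick = set(rep_rng.choice(len(ids), size=k, replace=False).tolist())
            val |= {ids[i] for i in pick}
            train |= {ids[i] for i in range(len(ids)) if i not in pick}
        reps.append((frozenset(train), frozenset(val)))

    plan = SplitPlan(
        test_ids=frozenset(test),
        repetitions=tuple(reps),
        n_repetitions=n_repetitions,
        seed=seed,
    )
    plan.check_disjoint()
    return plan


@dataclass(frozen=True)
class GridRow:
    strategy: str
    decision: str
    algorithm: str
    weighting: str

    def name(self) -> str:
        return f"{self.strategy}-{self.decision}-{self.algorithm}-{self.weighting}"


def grid_rows(
    strategies: Sequence[str] = ("ovso", "ovsa"),
    algorithms: Sequence[str] = ("logreg", "svm_linear", "svm_rbf"),
    weightings: Sequence[str] = ("binary", "tf", "tfidf"),
    decisions: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[GridRow]:
    rows = []
    for strat in strategies:
        if strat not in VALID_DECISIONS:
            raise ValueError(f"unknown strategy {strat!r}")
        for dec in (decisions or {}).get(strat) or VALID_DECISIONS[strat]:
            check_decision(strat, dec)
            for alg in algorithms:
                for w in weightings:
                    rows.append(GridRow(strat, dec, alg, w))
    return rows


@dataclass(frozen=True)
class ExperimentConfig:
    corpus_source: str = "balanced_type"  # preset name or path to a corpus file
    task: str = "type"  # 'type' or 'severity'
    strategies: tuple[str, ...] = ("ovso", "ovsa")
    algorithms: tuple[str, ...] = ("logreg", "svm_linear", "svm_rbf")
    weightings: tuple[str, ...] = ("binary", "tf", "tfidf")
    decisions: Optional[Mapping[str, tuple[str, ...]]] = None  # strategy -> decisions
    n_repetitions: int = 10
    seed: int = 0
    overlap: Optional[float] = None
    hyperparams: Mapping[str, float] = field(default_factory=lambda: {"C": 1.0})
    output_dir: Optional[str] = None
    external_corpora: Mapping[str, str] = field(default_factory=dict)  # name -> preset/path

    @property
    def label_field(self) -> str:
        return "severity" if self.task == "severity" else "incident_type"


def _load_or_generate(source: str, task: str, seed: int, overlap: Optional[float]):
    if Path(source).exists():
        return read_corpus(source)
    return generate_corpus(default_config(source, seed=seed, task=task, overlap=overlap))


def _scheme_from_corpus(corpus, label_field: str) -> LabelScheme:
    seen: dict[str, None] = {}
    for r in corpus:
        lab = getattr(r, label_field)
        if lab is not None:
            seen.setdefault(lab)
    return LabelScheme(tuple(seen))


def run_grid(config: ExperimentConfig):
    """Train and evaluate every requested configuration.

    Returns ``(results_df, reports)`` where ``reports`` maps
    ``(row_name, corpus_name)`` to a :class:`MetricsReport`; ``corpus_name``
    is ``"test"`` for the frozen partition plus one entry per external
    corpus. Writes results.csv and per-configuration confusion matrices when
    ``config.output_dir`` is set.
    """
    rows = grid_rows(config.strategies, config.algorithms, config.weightings, config.decisions)
    label_field = config.label_field

    corpus = _load_or_generate(config.corpus_source, config.task, config.seed, config.overlap)
    scheme = _scheme_from_corpus(corpus, label_field)
    plan = make_split_plan(corpus, scheme, config.n_repetitions, config.seed, label_field)

    test_reports = [r for r in corpus if r.report_id in plan.test_ids]
    pool_reports = [r for r in corpus if r.report_id not in plan.test_ids]

    pp_cfg = PreprocessConfig()
    preprocess = lambda reps: preprocess_corpus(reps, pp_cfg)  # noqa: E731
    pool_docs = preprocess(pool_reports)
    vocab = build_vocabulary(pool_docs)

    externals = {
        name: _load_or_generate(src, config.task, config.seed + 1, config.overlap)
        for name, src in config.external_corpora.items()
    }

    # the smallest class bounds the one-vs-all per-class subset size
    class_sizes = {}
    for r in pool_reports:
        lab = getattr(r, label_field)
        class_sizes[lab] = class_sizes.get(lab, 0) + 1
    per_class_n = min(class_sizes.values())

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    records = []
    reports: dict[tuple[str, str], MetricsReport] = {}
    for row in rows:
        t0 = time.perf_counter()
        pipeline = FeaturePipeline(vocab=vocab, weighting=row.weighting)
        if row.strategy == "ovso":
            subsets = decompose_ovso(scheme, pool_reports, label_field)
        else:
            subsets = decompose_ovsa(scheme, pool_reports, per_class_n, config.seed, label_field)
        ensemble = train_ensemble(
            subsets,
            algorithm=row.algorithm,
            hyperparams=dict(config.hyperparams),
            strategy=row.strategy,
            decision=row.decision,
            scheme=scheme,
            pipeline=pipeline,
            preprocess=preprocess,
            label_field=label_field,
        )

        eval_sets = {"test": test_reports, **externals}
        record = {
            "configuration": row.name(),
            "strategy": row.strategy,
            "decision": row.decision,
            "algorithm": row.algorithm,
            "weighting": row.weighting,
        }
        for cname, creports in eval_sets.items():
            report, cm = _evaluate(ensemble, creports)
            reports[(row.name(), cname)] = report
            prefix = "" if cname == "test" else f"{cname}_"
            record[f"{prefix}micro_f"] = report.micro_f
            record[f"{prefix}macro_f"] = report.macro_f
            if outdir:
                cm.save_csv(outdir / f"confusion_{row.name()}_{cname}.csv")
                report.save_csv(outdir / f"metrics_{row.name()}_{cname}.csv")
        record["seconds"] = round(time.perf_counter() - t0, 3)
        records.append(record)
        logger.info("evaluated %s in %.1fs", row.name(), record["seconds"])

    df = pd.DataFrame.from_records(records)
    if outdir:
        df.to_csv(outdir / "results.csv", index=False)
        manifest = {
            "seed": config.seed,
            "task": config.task,
            "corpus_source": config.corpus_source,
            "n_repetitions": config.n_repetitions,
            "n_configurations": len(rows),
        }
        pd.Series(manifest).to_json(outdir / "manifest.json")
    return df, reports


def _evaluate(ensemble: EnsembleModel, corpus: Sequence[IncidentReport]):
    label_field = ensemble.label_field
    if not corpus:
        raise ValueError("cannot evaluate on an empty corpus")
    gold = [getattr(r, label_field) for r in corpus]
    unseen = sorted({g for g in gold if g not in ensemble.scheme.labels})
    if unseen:
        raise ValueError(f"corpus contains labels outside the ensemble scheme: {unseen}")
    docs = preprocess_corpus(list(corpus))
    pred = ensemble.predict_docs(docs)
    cm = confusion_matrix(gold, pred, ensemble.scheme)
    return average_metrics(cm), cm


def evaluate_external(ensemble: EnsembleModel, corpus: Sequence[IncidentReport]) -> MetricsReport:
    """Score an external corpus with the training-time vocabulary unchanged."""
    report, _ = _evaluate(ensemble, corpus)
    return report


def best_configuration(df: pd.DataFrame, reports, corpus_name: str = "test") -> str:
    """Name of the configuration with the best micro-F on ``corpus_name``."""
    results = [
        (name, rep) for (name, cname), rep in reports.items() if cname == corpus_name
    ]
    return select_best(results)
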