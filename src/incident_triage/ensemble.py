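"""Multiclass reduction to binary ensembles and group decision schemes.

One-versus-one (``ovso``) trains l(l-1)/2 pairwise discriminators and
combines them by voting or by a tail-rejection decision DAG; one-versus-all
(``ovsa``) trains l one-vs-rest discriminators and predicts the label with
the highest calibrated probability. The DAG walks the ordered candidate
list from (first, last), rejecting the losing end label at each node, so any
prediction costs exactly l-1 classifier evaluations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from . import base as _base
from .base import BaseClassifierModel, OneVsRestTask, PairTask, Task, train_base
from .corpus import IncidentReport
from .features import FeaturePipeline
from .preprocessing import TokenDoc

__all__ = [
    "STRATEGIES",
    "DECISIONS",
    "VALID_DECISIONS",
    "LabelScheme",
    "EnsembleModel",
    "decompose_ovso",
    "decompose_ovsa",
    "train_ensemble",
    "predict_voting",
    "predict_dag",
    "predict_ovsa",
]

STRATEGIES = ("ovso", "ovsa")
DECISIONS = ("voting", "dag", "argmax_prob")
VALID_DECISIONS = {"ovso": ("voting", "dag"), "ovsa": ("argmax_prob",)}


@dataclass(frozen=True)
class LabelScheme:
    """Ordered class labels; the order is persisted and drives the DAG."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a label scheme needs at least 2 classes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("label scheme contains duplicates")

    @property
    def l(self) -> int:  # noqa: E743 - matches the l-class framing
        return len(self.labels)

    def pairs(self) -> list[PairTask]:
        """All unordered pairs, first-in-scheme-order label as positive."""
        labs = self.labels
        return [PairTask(labs[i], labs[j]) for i in range(len(labs)) for j in range(i + 1, len(labs))]


def check_decision(strategy: str, decision: str) -> None:
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; valid: {', '.join(STRATEGIES)}")
    if decision not in VALID_DECISIONS[strategy]:
        raise ValueError(
            f"decision {decision!r} is not valid for strategy {strategy!r} "
            f"(valid: {', '.join(VALID_DECISIONS[strategy])})"
        )


def _label_of(report: IncidentReport, label_field: str) -> Optional[str]:
    return getattr(report, label_field)


def _group_by_label(
    reports: Sequence[IncidentReport], scheme: LabelScheme, label_field: str
) -> dict[str, list[IncidentReport]]:
    groups: dict[str, list[IncidentReport]] = {lab: [] for lab in scheme.labels}
    for r in reports:
        lab = _label_of(r, label_field)
        if lab in groups:
            groups[lab].append(r)
    missing = [lab for lab in scheme.labels if not groups[lab]]
    if missing:
        raise ValueError(f"labels missing from the corpus: {', '.join(missing)}")
    return groups


def decompose_ovso(
    scheme: LabelScheme,
    corpus: Sequence[IncidentReport],
    label_field: str = "incident_type",
) -> list[tuple[PairTask, list[IncidentReport]]]:
    """One training subset per unordered label pair (l(l-1)/2 subsets)."""
    groups = _group_by_label(corpus, scheme, label_field)
    return [(pair, groups[pair.a] + groups[pair.b]) for pair in scheme.pairs()]


def decompose_ovsa(
    scheme: LabelScheme,
    corpus: Sequence[IncidentReport],
    per_class_n: int,
    seed: int = 0,
    label_field: str = "incident_type",
) -> list[tuple[OneVsRestTask, list[IncidentReport], list[IncidentReport]]]:
    """One (positives, sampled negatives) subset per label.

    Each subset holds ``per_class_n`` positives and ``per_class_n`` negatives
    spread as evenly as possible over the other l-1 labels: every rest label
    contributes ``per_class_n // (l-1)``, with the remainder assigned
    round-robin in scheme order. Sampling is seeded and deterministic.
    """
    groups = _group_by_label(corpus, scheme, label_field)
    l = scheme.l
    shortfall = {}
    for lab in scheme.labels:
        if len(groups[lab]) < per_class_n:
            shortfall[lab] = per_class_n - len(groups[lab])
    if shortfall:
        raise ValueError(f"insufficient reports for per_class_n={per_class_n}: short by {shortfall}")

    subsets = []
    for ti, target in enumerate(scheme.labels):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ti,)))
        pos_pool = groups[target]
        pos_idx = rng.choice(len(pos_pool), size=per_class_n, replace=False)
        positives = [pos_pool[i] for i in sorted(pos_idx)]

        rest = [lab for lab in scheme.labels if lab != target]
        quota = {lab: per_class_n // (l - 1) for lab in rest}
        for k in range(per_class_n % (l - 1)):
            quota[rest[k]] += 1
        negatives: list[IncidentReport] = []
        for lab in rest:
            pool = groups[lab]
            take = quota[lab]
            if take > len(pool):
                raise ValueError(
                    f"insufficient reports in class {lab!r} for negative quota "
                    f"{take} (have {len(pool)})"
                )
            idx = rng.choice(len(pool), size=take, replace=False)
            negatives.extend(pool[i] for i in sorted(idx))
        subsets.append((OneVsRestTask(target), positives, negatives))
    return subsets


@dataclass
class EnsembleModel:
    scheme: LabelScheme
    strategy: str
    decision: str
    base_models: Mapping[Task, BaseClassifierModel]
    pipeline: Optional[FeaturePipeline] = None
    label_field: str = "incident_type"
    #: incremented on every base-classifier evaluation made by predict_dag
    dag_eval_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        check_decision(self.strategy, self.decision)
        l = self.scheme.l
        expected = l * (l - 1) // 2 if self.strategy == "ovso" else l
        if len(self.base_models) != expected:
            raise ValueError(
                f"{self.strategy} over {l} classes needs {expected} base models, "
                f"got {len(self.base_models)}"
            )

    # -- convenience over raw feature matrices ------------------------------
    def predict(self, X) -> list[str]:
        if self.decision == "voting":
            return predict_voting(self, X)
        if self.decision == "dag":
            return predict_dag(self, X)
        return predict_ovsa(self, X)

    def predict_docs(self, docs: Sequence[TokenDoc]) -> list[str]:
        if self.pipeline is None:
            raise ValueError("ensemble has no feature pipeline attached")
        return self.predict(self.pipeline.transform(docs))


def train_ensemble(
    subsets,
    algorithm: str,
    hyperparams: Optional[Mapping] = None,
    strategy: str = "ovso",
    decision: str = "voting",
    scheme: Optional[LabelScheme] = None,
    pipeline: Optional[FeaturePipeline] = None,
    preprocess=None,
    label_field: str = "incident_type",
) -> EnsembleModel:
    """Fit one base model per decomposition subset.

    ``subsets`` comes from :func:`decompose_ovso` (``(task, reports)``) or
    :func:`decompose_ovsa` (``(task, positives, negatives)``). ``hyperparams``
    may be a single mapping applied to every task or a mapping keyed by task.
    ``preprocess`` maps a list of reports to TokenDocs; required together
    with ``pipeline`` to vectorize the subsets.
    """
    check_decision(strategy, decision)
    if scheme is None:
        raise ValueError("a LabelScheme is required")
    if pipeline is None or preprocess is None:
        raise ValueError("a feature pipeline and a preprocess function are required")

    per_task_hp = hyperparams if isinstance(hyperparams, dict) and any(
        isinstance(k, (PairTask, OneVsRestTask)) for k in hyperparams
    ) else None

    base_models: dict[Task, BaseClassifierModel] = {}
    for subset in subsets:
        task = subset[0]
        if isinstance(task, PairTask):
            reports = subset[1]
            y = [_label_of(r, label_field) for r in reports]
        else:
            _, positives, negatives = subset
            reports = list(positives) + list(negatives)
            y = [task.label] * len(positives) + [f"not_{task.label}"] * len(negatives)
        hp = per_task_hp.get(task) if per_task_hp else hyperparams
        X = pipeline.transform(preprocess(reports))
        try:
            base_models[task] = train_base(X, y, algorithm, hp, task=task)
        except Exception as exc:
            raise RuntimeError(f"training failed for task {task}: {exc}") from exc
    return EnsembleModel(
        scheme=scheme,
        strategy=strategy,
        decision=decision,
        base_models=base_models,
        pipeline=pipeline,
        label_field=label_field,
    )


def _require(ensemble: EnsembleModel, strategy: str, decision: str) -> None:
    if ensemble.strategy != strategy or ensemble.decision != decision:
        raise ValueError(
            f"prediction scheme ({strategy}, {decision}) does not match the "
            f"ensemble ({ensemble.strategy}, {ensemble.decision})"
        )
    if not ensemble.base_models:
        raise ValueError("ensemble has no fitted base models")


def _as_matrix(X):
    if sp.issparse(X):
        return X.tocsr()
    X = np.asarray(X, dtype=float)
    return X.reshape(1, -1) if X.ndim == 1 else X


def predict_voting(ensemble: EnsembleModel, X) -> list[str]:
    """Majority vote over all pairwise contests.

    Each pairwise model votes by decision-score sign (a score of exactly 0
    votes for the pair's first label). Ties break by the largest summed
    calibrated probability over the tied labels' contests, then scheme order.
    """
    _require(ensemble, "ovso", "voting")
    X = _as_matrix(X)
    n = X.shape[0]
    labels = ensemble.scheme.labels
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    votes = np.zeros((n, len(labels)), dtype=int)
    probsum = np.zeros((n, len(labels)))

    for pair in ensemble.scheme.pairs():
        model = ensemble.base_models[pair]
        s = model.decision_score(X)
        p = model.predict_prob(X)
        ia, ib = lab_idx[pair.a], lab_idx[pair.b]
        a_wins = s >= 0
        votes[a_wins, ia] += 1
        votes[~a_wins, ib] += 1
        probsum[:, ia] += p
        probsum[:, ib] += 1.0 - p

    out = []
    for i in range(n):
        top = votes[i].max()
        tied = np.flatnonzero(votes[i] == top)
        if len(tied) > 1:
            best_p = probsum[i, tied].max()
            tied = tied[probsum[i, tied] >= best_p - 1e-12]
        out.append(labels[int(tied[0])])
    return out


def predict_dag(ensemble: EnsembleModel, X) -> list[str]:
    """Tail-rejection DAG over the scheme order; exactly l-1 evaluations."""
    _require(ensemble, "ovso", "dag")
    X = _as_matrix(X)
    labels = ensemble.scheme.labels
    out = []
    for i in range(X.shape[0]):
        xi = X[i : i + 1]
        lo, hi = 0, len(labels) - 1
        while lo < hi:
            pair = PairTask(labels[lo], labels[hi])
            model = ensemble.base_models.get(pair)
            if model is None:
                raise ValueError(f"missing pairwise model for {pair}")
            ensemble.dag_eval_count += 1
            score = float(model.decision_score(xi)[0])
            if score >= 0:
                hi -= 1  # reject the later label
            else:
                lo += 1  # reject the earlier label
        out.append(labels[lo])
    return out


def predict_ovsa(ensemble: EnsembleModel, X) -> list[str]:
    """Label of the one-vs-rest model with the highest calibrated probability."""
    _require(ensemble, "ovsa", "argmax_prob")
    X = _as_matrix(X)
    labels = ensemble.scheme.labels
    probs = np.column_stack(
        [ensemble.base_models[OneVsRestTask(lab)].predict_prob(X) for lab in labels]
    )
    return [labels[int(j)] for j in np.argmax(probs, axis=1)]


# --- persistence -----------------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, directory: str | Path) -> None:
    """Directory bundle: manifest.json, vocabulary.tsv, per-task model files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    task_files = {}
    for k, (task, model) in enumerate(sorted(ensemble.base_models.items(), key=lambda kv: repr(kv[0]))):
        fname = f"task_{k:03d}.joblib"
        _base.save_model(model, directory / fname)
        if isinstance(task, PairTask):
            task_files[fname] = {"kind": "pair", "a": task.a, "b": task.b}
        else:
            task_files[fname] = {"kind": "one_vs_rest", "label": task.label}
    manifest = {
        "format_version": 1,
        "strategy": ensemble.strategy,
        "decision": ensemble.decision,
        "labels": list(ensemble.scheme.labels),
        "label_field": ensemble.label_field,
        "weighting": ensemble.pipeline.weighting if ensemble.pipeline else None,
        "tasks": task_files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    if ensemble.pipeline is not None:
        ensemble.pipeline.vocab.save_tsv(directory / "vocabulary.tsv")


def load_ensemble(directory: str | Path) -> EnsembleModel:
    from .features import Vocabulary

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    base_models: dict[Task, BaseClassifierModel] = {}
    for fname, meta in manifest["tasks"].items():
        task: Task = (
            PairTask(meta["a"], meta["b"])
            if meta["kind"] == "pair"
            else OneVsRestTask(meta["label"])
        )
        base_models[task] = _base.load_model(directory / fname)
    pipeline = None
    if (directory / "vocabulary.tsv").exists() and manifest.get("weighting"):
        pipeline = FeaturePipeline(
            vocab=Vocabulary.load_tsv(directory / "vocabulary.tsv"),
            weighting=manifest["weighting"],
        )
    return EnsembleModel(
        scheme=LabelScheme(tuple(manifest["labels"])),
        strategy=manifest["strategy"],
        decision=manifest["decision"],
        base_models=base_models,
        pipeline=pipeline,
        label_field=manifest.get("label_field", "incident_type"),
    )
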