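"""Synthetic labeled incident-report corpora.

Generates corpora whose gross statistics — class compositions, report length
moments, class-specific vocabulary with a tunable confusability (overlap)
knob, severity indicator phrases with adjacent-level blending, and
secondary-type term co-occurrence — match the structure the downstream
pipeline assumes, without any real clinical data.

Seeding: one master seed; each class draws from its own deterministic
substream (``SeedSequence(seed, spawn_key=(class_index,))``), so per-class
output is invariant to which other classes are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from ._pools import (
    POOLS_VERSION,
    SAC_KEYWORD_POOLS,
    SAC_LABELS,
    SAC_TERM_POOLS,
    SHARED_TERMS,
    TYPE_LABELS,
    TYPE_TERM_POOLS,
)
from .corpus import IncidentReport

__all__ = [
    "GeneratorConfig",
    "CorpusSummary",
    "default_config",
    "generate_corpus",
    "summarize_corpus",
    "PRESETS",
    "TYPE_LABELS",
    "SAC_LABELS",
]

# Length models reported for the two source systems: mean, sd, min, max words.
_AIMS_LENGTH = (78.5, 35.5, 5, 308)
_RISKMAN_LENGTH = (63.4, 31.6, 5, 404)

# Per-class counts of the stratified compositions (real-world ratios).
_STRATIFIED_ORIGINAL_TYPE = {
    "falls": 90, "medications": 68, "pressure_injury": 37, "aggression": 49,
    "documentation": 26, "blood_product": 5, "patient_identification": 7,
    "infection": 6, "clinical_handover": 7, "deteriorating_patient": 1,
    "others": 148,
}
_STRATIFIED_ORIGINAL_SEVERITY = {"SAC1": 25, "SAC2": 95, "SAC3": 2198, "SAC4": 2519}
_STRATIFIED_INDEPENDENT_TYPE = {
    "falls": 872, "medications": 1053, "pressure_injury": 190,
    "aggression": 487, "documentation": 252, "blood_product": 59,
    "patient_identification": 86, "infection": 22, "clinical_handover": 87,
    "deteriorating_patient": 14, "others": 2878,
}
_STRATIFIED_INDEPENDENT_SEVERITY = {"SAC1": 23, "SAC2": 105, "SAC3": 2609, "SAC4": 3213}

PRESETS = (
    "balanced_type",
    "balanced_severity",
    "stratified_original",
    "stratified_independent",
)

# Fraction of a non-overlap token drawn from the class pool (rest: shared pool).
_OWN_POOL_WEIGHT = 0.65


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of one synthetic corpus."""

    label_scheme: tuple[str, ...]
    per_class_counts: Mapping[str, int]
    class_term_pools: Mapping[str, Sequence[str]]
    shared_term_pool: Sequence[str]
    overlap: float = 0.15
    severity_keyword_pools: Optional[Mapping[str, Sequence[str]]] = None
    sac23_blend: float = 0.0
    cooccurrence_rate: float = 0.0
    length_mean: float = 78.5
    length_sd: float = 35.5
    length_min: int = 5
    length_max: int = 308
    seed: int = 0
    label_field: str = "incident_type"  # which IncidentReport field gets the label
    source: str = "synthetic"

    def validate(self) -> None:
        if len(self.label_scheme) != len(set(self.label_scheme)):
            raise ValueError("label_scheme contains duplicate labels")
        extra = set(self.per_class_counts) - set(self.label_scheme)
        if extra:
            raise ValueError(f"per_class_counts has labels outside the scheme: {sorted(extra)}")
        if any(c < 0 for c in self.per_class_counts.values()):
            raise ValueError("per_class_counts must be nonnegative")
        for knob, name in (
            (self.overlap, "overlap"),
            (self.sac23_blend, "sac23_blend"),
            (self.cooccurrence_rate, "cooccurrence_rate"),
        ):
            if not 0.0 <= knob <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {knob}")
        if self.length_min < 1:
            raise ValueError("length_min must be >= 1")
        if not self.length_min <= self.length_mean <= self.length_max:
            raise ValueError("require length_min <= length_mean <= length_max")
        if self.label_field not in ("incident_type", "severity"):
            raise ValueError("label_field must be 'incident_type' or 'severity'")
        for label, n in self.per_class_counts.items():
            if n > 0 and not self.class_term_pools.get(label):
                raise ValueError(f"class_term_pools is empty for requested label {label!r}")


def default_config(
    preset: str,
    seed: int = 0,
    task: Optional[str] = None,
    overlap: Optional[float] = None,
) -> GeneratorConfig:
    """Build a preset corpus configuration.

    ``preset`` is one of :data:`PRESETS`. The two balanced presets imply the
    task; for the stratified presets ``task`` selects ``"type"`` (default) or
    ``"severity"``. Balanced/original presets use the state-wide system's
    length model, the independent preset the independent hospital system's.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {', '.join(PRESETS)}")
    if preset == "balanced_type":
        task = "type"
    elif preset == "balanced_severity":
        task = "severity"
    elif task is None:
        task = "type"
    if task not in ("type", "severity"):
        raise ValueError(f"task must be 'type' or 'severity', got {task!r}")

    if task == "type":
        scheme, pools, label_field = TYPE_LABELS, TYPE_TERM_POOLS, "incident_type"
        kw_pools, blend, cooc = None, 0.0, 0.3
    else:
        scheme, pools, label_field = SAC_LABELS, SAC_TERM_POOLS, "severity"
        kw_pools, blend, cooc = SAC_KEYWORD_POOLS, 0.35, 0.0

    if preset == "balanced_type":
        counts = {lab: 260 for lab in TYPE_LABELS}
        length, source = _AIMS_LENGTH, "synthetic-balanced"
    elif preset == "balanced_severity":
        counts = {lab: 290 for lab in SAC_LABELS}
        length, source = _AIMS_LENGTH, "synthetic-balanced"
    elif preset == "stratified_original":
        counts = dict(
            _STRATIFIED_ORIGINAL_TYPE if task == "type" else _STRATIFIED_ORIGINAL_SEVERITY
        )
        length, source = _AIMS_LENGTH, "synthetic-stratified-original"
    else:
        counts = dict(
            _STRATIFIED_INDEPENDENT_TYPE if task == "type" else _STRATIFIED_INDEPENDENT_SEVERITY
        )
        length, source = _RISKMAN_LENGTH, "synthetic-stratified-independent"

    cfg = GeneratorConfig(
        label_scheme=tuple(scheme),
        per_class_counts=counts,
        class_term_pools={k: list(v) for k, v in pools.items()},
        shared_term_pool=list(SHARED_TERMS),
        severity_keyword_pools=(
            {k: list(v) for k, v in kw_pools.items()} if kw_pools else None
        ),
        sac23_blend=blend,
        cooccurrence_rate=cooc,
        length_mean=length[0],
        length_sd=length[1],
        length_min=length[2],
        length_max=length[3],
        seed=seed,
        label_field=label_field,
        source=source,
    )
    if overlap is not None:
        cfg = replace(cfg, overlap=overlap)
    cfg.validate()
    return cfg


def _class_rng(seed: int, class_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(class_index,)))


def _sample_lengths(rng: np.random.Generator, cfg: GeneratorConfig, n: int) -> np.ndarray:
    if cfg.length_sd <= 0:
        return np.full(n, int(round(cfg.length_mean)))
    a = (cfg.length_min - cfg.length_mean) / cfg.length_sd
    b = (cfg.length_max - cfg.length_mean) / cfg.length_sd
    raw = truncnorm.rvs(a, b, loc=cfg.length_mean, scale=cfg.length_sd, size=n, random_state=rng)
    return np.clip(np.rint(raw).astype(int), cfg.length_min, cfg.length_max)


def _keyword_chunks(rng: np.random.Generator, cfg: GeneratorConfig, label: str) -> list[list[str]]:
    """Severity indicator phrases for one report, with SAC2/SAC3 blending."""
    pools = cfg.severity_keyword_pools
    if not pools or label not in pools:
        return []
    chunks = []
    for _ in range(int(rng.integers(1, 3))):  # 1 or 2 phrases per report
        src = label
        if label in ("SAC2", "SAC3") and rng.random() < cfg.sac23_blend:
            src = "SAC3" if label == "SAC2" else "SAC2"
        pool = pools.get(src) or pools[label]
        chunks.append(str(rng.choice(pool)).split())
    return chunks


def _cooccurrence_chunks(
    rng: np.random.Generator, cfg: GeneratorConfig, label: str
) -> list[list[str]]:
    """Secondary-type terms injected into documentation reports (text only;
    the gold label stays single)."""
    if label != "documentation" or rng.random() >= cfg.cooccurrence_rate:
        return []
    partners = [p for p in ("patient_identification", "medications") if cfg.class_term_pools.get(p)]
    if not partners:
        return []
    pool = list(cfg.class_term_pools[partners[int(rng.integers(len(partners)))]])
    k = min(3, len(pool))
    return [[t] for t in rng.choice(pool, size=k, replace=False)]


def generate_corpus(config: GeneratorConfig) -> list[IncidentReport]:
    """Generate the corpus described by ``config`` (pure function of config)."""
    config.validate()
    reports: list[IncidentReport] = []
    pools = {k: list(v) for k, v in config.class_term_pools.items()}
    shared = list(config.shared_term_pool)

    for ci, label in enumerate(config.label_scheme):
        n = int(config.per_class_counts.get(label, 0))
        if n == 0:
            continue
        rng = _class_rng(config.seed, ci)
        own = pools[label]
        foreign = [t for lab in config.label_scheme if lab != label for t in pools.get(lab, [])]
        lengths = _sample_lengths(rng, config, n)

        for i in range(n):
            target = int(lengths[i])
            chunks: list[list[str]] = []
            if config.label_field == "severity":
                chunks += _keyword_chunks(rng, config, label)
            else:
                chunks += _cooccurrence_chunks(rng, config, label)
            n_injected = sum(len(c) for c in chunks)

            n_fill = max(target - n_injected, 0)
            if n_fill:
                u = rng.random(n_fill)
                for j in range(n_fill):
                    if foreign and u[j] < config.overlap:
                        chunks.append([foreign[int(rng.integers(len(foreign)))]])
                    elif shared and rng.random() >= _OWN_POOL_WEIGHT:
                        chunks.append([shared[int(rng.integers(len(shared)))]])
                    else:
                        chunks.append([own[int(rng.integers(len(own)))]])

            order = rng.permutation(len(chunks))
            tokens = [t for k in order for t in chunks[k]]
            if len(tokens) > config.length_max:
                tokens = tokens[: config.length_max]
            while len(tokens) < config.length_min:
                tokens.append(own[int(rng.integers(len(own)))])

            reports.append(
                IncidentReport(
                    report_id=f"{config.source}-{label}-{i:05d}",
                    narrative=" ".join(tokens),
                    incident_type=label if config.label_field == "incident_type" else None,
                    severity=label if config.label_field == "severity" else None,
                    source=config.source,
                )
            )
    return reports


@dataclass(frozen=True)
class CorpusSummary:
    total: int
    by_incident_type: dict[str, int]
    by_severity: dict[str, int]
    length_mean: Optional[float]
    length_sd: Optional[float]
    length_min: Optional[int]
    length_max: Optional[int]

    @property
    def lengths_defined(self) -> bool:
        return self.length_mean is not None


def summarize_corpus(reports: Sequence[IncidentReport]) -> CorpusSummary:
    """Composition and word-length summary (lengths over whitespace tokens)."""
    by_type: dict[str, int] = {}
    by_sev: dict[str, int] = {}
    lengths = []
    for r in reports:
        if r.incident_type is not None:
            by_type[r.incident_type] = by_type.get(r.incident_type, 0) + 1
        if r.severity is not None:
            by_sev[r.severity] = by_sev.get(r.severity, 0) + 1
        lengths.append(r.word_count())
    if lengths:
        arr = np.asarray(lengths, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=0))
        lo, hi = int(arr.min()), int(arr.max())
    else:
        mean = sd = lo = hi = None  # undefined for an empty corpus
    return CorpusSummary(
        total=len(reports),
        by_incident_type=by_type,
        by_severity=by_sev,
        length_mean=mean,
        length_sd=sd,
        length_min=lo,
        length_max=hi,
    )
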