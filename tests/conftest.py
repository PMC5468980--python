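import numpy as np
import pytest

from incident_triage.base import BaseClassifierModel, PairTask, PlattCalibrator
from incident_triage.corpus import IncidentReport
from incident_triage.ensemble import LabelScheme
from incident_triage.synthetic import GeneratorConfig


class FixedScoreEstimator:
    """Stand-in estimator emitting one constant decision score."""

    def __init__(self, score: float):
        self.score = float(score)
        self.classes_ = np.array([0, 1])

    def decision_function(self, X):
        n = X.shape[0] if hasattr(X, "shape") else len(X)
        return np.full(n, self.score)


def stub_pair_model(a: str, b: str, score: float) -> BaseClassifierModel:
    """Pairwise model voting for ``a`` iff ``score >= 0``."""
    return BaseClassifierModel(
        task=PairTask(a, b),
        algorithm="svm_linear",
        hyperparams={"C": 1.0},
        positive_label=a,
        negative_label=b,
        estimator=FixedScoreEstimator(score),
        calibrator=PlattCalibrator(1.0, 0.0),
    )


@pytest.fixture
def four_scheme() -> LabelScheme:
    return LabelScheme(("A", "B", "C", "D"))


@pytest.fixture
def sac_scheme() -> LabelScheme:
    return LabelScheme(("SAC1", "SAC2", "SAC3", "SAC4"))


@pytest.fixture
def tiny_config() -> GeneratorConfig:
    """Three small well-separated classes for fast end-to-end runs."""
    return GeneratorConfig(
        label_scheme=("alpha", "beta", "gamma"),
        per_class_counts={"alpha": 30, "beta": 30, "gamma": 30},
        class_term_pools={
            "alpha": ["apple", "apricot", "almond", "avocado"],
            "beta": ["banana", "berry", "broccoli", "bean"],
            "gamma": ["grape", "guava", "garlic", "ginger"],
        },
        shared_term_pool=["ward", "nurse", "patient", "bed"],
        overlap=0.0,
        length_mean=20.0,
        length_sd=5.0,
        length_min=5,
        length_max=40,
        seed=11,
    )


def make_reports(labels, label_field="incident_type", words_per_report=6, seed=0):
    """Deterministic labeled reports with class-specific narratives."""
    rng = np.random.default_rng(seed)
    reports = []
    for i, lab in enumerate(labels):
        toks = [f"term{lab}{rng.integers(3)}" for _ in range(words_per_report)]
        kwargs = {label_field: lab}
        reports.append(
            IncidentReport(report_id=f"r{i:04d}", narrative=" ".join(toks), **kwargs)
        )
    return reports
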