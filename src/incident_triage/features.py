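"""Bag-of-words vocabulary and the binary / tf / tf-idf weightings.

The vocabulary is always built from training-partition documents only;
idf(t) = ln(N / df(t)), unsmoothed, so a term present in every training
document gets weight 0. Out-of-vocabulary tokens at transform time are
dropped. Matrices are CSR sparse throughout; no vector normalization is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .preprocessing import TokenDoc

__all__ = [
    "Vocabulary",
    "FeatureMatrix",
    "FeaturePipeline",
    "WEIGHTINGS",
    "build_vocabulary",
    "compute_idf",
    "vectorize",
]

WEIGHTINGS = ("binary", "tf", "tfidf")


@dataclass(frozen=True)
class Vocabulary:
    terms: tuple[str, ...]
    index: Mapping[str, int]
    doc_freq: Mapping[str, int]
    n_train_docs: int

    def __len__(self) -> int:
        return len(self.terms)

    def save_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"#n_train_docs={self.n_train_docs}\n")
            fh.write("term\tindex\tdf\n")
            for t in self.terms:
                fh.write(f"{t}\t{self.index[t]}\t{self.doc_freq[t]}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        n = int(lines[0].split("=", 1)[1])
        terms, index, df = [], {}, {}
        for line in lines[2:]:
            term, idx, d = line.split("\t")
            terms.append(term)
            index[term] = int(idx)
            df[term] = int(d)
        return cls(terms=tuple(terms), index=index, doc_freq=df, n_train_docs=n)


@dataclass(frozen=True)
class FeatureMatrix:
    """Documents x vocabulary-terms weight matrix (CSR, never densified)."""

    X: sp.csr_matrix
    weighting: str
    report_ids: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def build_vocabulary(train_docs: Sequence[TokenDoc]) -> Vocabulary:
    """Sorted term union of the training docs with document frequencies."""
    if not train_docs:
        raise ValueError("cannot build a vocabulary from an empty document list")
    df: dict[str, int] = {}
    for doc in train_docs:
        for t in set(doc.tokens):
            df[t] = df.get(t, 0) + 1
    if not df:
        raise ValueError("all training documents are empty; no features available")
    terms = tuple(sorted(df))
    return Vocabulary(
        terms=terms,
        index={t: i for i, t in enumerate(terms)},
        doc_freq=df,
        n_train_docs=len(train_docs),
    )


def compute_idf(vocab: Vocabulary) -> dict[str, float]:
    """idf(t) = ln(N / df(t)); exactly 0 when df(t) = N."""
    n = vocab.n_train_docs
    return {t: math.log(n / d) for t, d in vocab.doc_freq.items()}


def _tf_matrix(docs: Sequence[TokenDoc], vocab: Vocabulary) -> sp.csr_matrix:
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for doc in docs:
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            j = vocab.index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j])
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(docs), len(vocab)),
    )


def vectorize(
    docs: Sequence[TokenDoc],
    vocab: Vocabulary,
    weighting: str,
    idf: Mapping[str, float] | None = None,
) -> FeatureMatrix:
    """Vectorize ``docs`` against ``vocab`` under one of the three weightings."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}; valid: {', '.join(WEIGHTINGS)}")
    X = _tf_matrix(docs, vocab)
    if weighting == "binary":
        X.data = np.ones_like(X.data)
    elif weighting == "tfidf":
        idf = idf if idf is not None else compute_idf(vocab)
        idf_vec = np.array([idf[t] for t in vocab.terms])
        X = X.multiply(sp.csr_matrix(idf_vec)).tocsr()
    return FeatureMatrix(X=X, weighting=weighting, report_ids=tuple(d.report_id for d in docs))


@dataclass(frozen=True)
class FeaturePipeline:
    """Frozen vocabulary + weighting used by a trained ensemble."""

    vocab: Vocabulary
    weighting: str

    def transform(self, docs: Sequence[TokenDoc]) -> sp.csr_matrix:
        return vectorize(docs, self.vocab, self.weighting).X
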