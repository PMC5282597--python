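"""K-mer frequency baseline and length-stratified evaluation.

K-mer frequencies (K = 1..max_k, overlapping occurrences, count divided by
the number of valid window positions) feed the same Welch selection and CV
machinery as transition frequencies — one code path, two feature spaces.
Length-stratified evaluation splits each class at its own median length
into a moderately-long and an extremely-long stratum and reports the AUC
within each.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._alphabet import encode, kmer_counts, code_to_kmer, valid_window_count
from .classify import roc_auc
from .seqio import SequenceRecord
from .transitions import FrequencyMatrix

DEFAULT_MAX_K = 6


def enumerate_kmers(max_k: int) -> list[str]:
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    out: list[str] = []
    for k in range(1, max_k + 1):
        out.extend(code_to_kmer(c, k) for c in range(4**k))
    return out


def _kmer_row(codes: np.ndarray, max_k: int) -> np.ndarray:
    parts: list[np.ndarray] = []
    for k in range(1, max_k + 1):
        counts = kmer_counts(codes, k).astype(float)
        denom = valid_window_count(codes, k)
        parts.append(counts / denom if denom else counts)
    return np.concatenate(parts)


def kmer_frequency_matrix(records: Sequence[SequenceRecord],
                          max_k: int = DEFAULT_MAX_K) -> FrequencyMatrix:
    """K-mer frequency matrix: freq(w) = N(w) / #valid positions.

    Windows containing N are excluded from both the count and the position
    total; for an N-free sequence the denominator is L - K + 1.
    """
    if not records:
        raise ValueError("need at least one sequence record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    names = enumerate_kmers(max_k)
    rows = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        rows[i] = _kmer_row(encode(rec.sequence), max_k)
    df = pd.DataFrame(rows, index=ids, columns=names)
    levels = np.array([len(w) for w in names])
    return FrequencyMatrix(df, [r.group_label for r in records], levels,
                           kind="kmer")


class KmerFrequencyEncoder(BaseEstimator, TransformerMixin):
    """scikit-learn transformer: DNA strings -> K-mer frequency features."""

    def __init__(self, max_k: int = DEFAULT_MAX_K) -> None:
        self.max_k = max_k

    def fit(self, X, y=None):
        self.feature_names_ = enumerate_kmers(self.max_k)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        out = np.empty((len(X), len(self.feature_names_)))
        for i, seq in enumerate(X):
            s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
            out[i] = _kmer_row(encode(s.upper()), self.max_k)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(self.feature_names_)


def length_strata(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Per-class median-length split: 0 = moderately long, 1 = extremely
    long, per record in input order.

    Each class is split into two equal-size halves by length (ties broken
    by input order; an odd class puts the extra record in the moderate
    half).
    """
    strata = np.zeros(len(records), dtype=int)
    labels = [r.group_label for r in records]
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        order = sorted(idx, key=lambda i: (len(records[i]), i))
        half = (len(order) + 1) // 2
        for i in order[half:]:
            strata[i] = 1
    return strata


def length_stratified_auc(records: Sequence[SequenceRecord],
                          scores: Sequence[float],
                          labels: Sequence[int] | None = None
                          ) -> dict[str, float | None]:
    """AUCs within the moderately- and extremely-long strata.

    Returns {"moderate": auc, "extreme": auc, "cutoffs": {label: length}};
    a stratum missing one of the classes gets None.
    """
    scores = np.asarray(scores, dtype=float)
    if labels is None:
        y = np.array([1 if r.group_label == "positive" else 0
                      for r in records])
    else:
        y = np.asarray(labels)
    strata = length_strata(records)
    out: dict[str, float | None] = {}
    for name, s in (("moderate", 0), ("extreme", 1)):
        mask = strata == s
        ys = y[mask]
        if (ys == 1).any() and (ys == 0).any():
            out[name], _ = roc_auc(scores[mask], ys)
        else:
            out[name] = None
    cutoffs: dict[str, float] = {}
    for lab in sorted({r.group_label for r in records}):
        lens = sorted(len(r) for r in records if r.group_label == lab)
        cutoffs[lab] = float(np.median(lens)) if lens else float("nan")
    out["cutoffs"] = cutoffs
    return out
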