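"""Decomposition of DNA sequences into Markov transition frequencies.

A transition of order k is the event of observing base b immediately after
a fixed k-mer prefix w.  Its frequency in a sequence is the conditional
frequency

    f(w -> b) = N(wb) / sum_b' N(wb')

where N(x) counts occurrences of the word x in the sequence (windows
containing N are excluded from all counts).  Enumerating all orders
0..m gives sum_{k=0..m} 4^(k+1) features; for the default m = 5 that is
5460.  An alternative per-length normalisation N(wb)/(L-k) is available
behind ``normalization="length"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._alphabet import (
    BASES,
    encode,
    kmer_counts,
    kmer_to_code,
    code_to_kmer,
    valid_window_count,
)
from .seqio import SequenceRecord

DEFAULT_MAX_ORDER = 5
_MAX_ORDER_BOUND = 12


@dataclass(frozen=True)
class Transition:
    """A Markov transition: ``prefix`` (k-mer, possibly empty) -> ``base``."""

    prefix: str
    base: str

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"transition base must be one of {BASES}")
        if any(c not in BASES for c in self.prefix):
            raise ValueError(
                f"transition prefix {self.prefix!r} not over {BASES}"
            )

    @property
    def order(self) -> int:
        return len(self.prefix)

    @property
    def level(self) -> int:
        """Level of the quad-tree edge this transition occupies (order+1)."""
        return self.order + 1

    @property
    def word(self) -> str:
        """The (prefix+base) word; also the tree node the edge points to."""
        return self.prefix + self.base

    def __str__(self) -> str:
        return f"{self.prefix}>{self.base}"

    @classmethod
    def from_string(cls, s: str) -> "Transition":
        if ">" in s:
            prefix, base = s.rsplit(">", 1)
        else:
            prefix, base = s[:-1], s[-1:]
        return cls(prefix, base)


def as_transition(t) -> Transition:
    return t if isinstance(t, Transition) else Transition.from_string(str(t))


def n_transitions(max_order: int) -> int:
    return sum(4 ** (k + 1) for k in range(max_order + 1))


@lru_cache(maxsize=None)
def _enumerate_cached(max_order: int) -> tuple[Transition, ...]:
    out: list[Transition] = []
    for k in range(max_order + 1):
        for code in range(4**k):
            prefix = code_to_kmer(code, k)
            for base in BASES:
                out.append(Transition(prefix, base))
    return tuple(out)


def enumerate_transitions(max_order: int) -> list[Transition]:
    """All transitions of order 0..max_order in (order, prefix, base) order."""
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if max_order > _MAX_ORDER_BOUND:
        raise ValueError(f"max_order > {_MAX_ORDER_BOUND} is impractical")
    return list(_enumerate_cached(max_order))


def transition_levels(max_order: int) -> np.ndarray:
    """Level (order+1) of each enumerated transition, in enumeration order."""
    return np.repeat(
        np.arange(1, max_order + 2), [4 ** (k + 1) for k in range(max_order + 1)]
    )


def _row_frequencies(codes: np.ndarray, max_order: int,
                     normalization: str) -> np.ndarray:
    """Frequency vector over all enumerated transitions for one sequence."""
    L = codes.size
    parts: list[np.ndarray] = []
    for k in range(max_order + 1):
        counts = kmer_counts(codes, k + 1).reshape(4**k, 4).astype(float)
        if normalization == "conditional":
            denom = counts.sum(axis=1, keepdims=True)
            freq = np.divide(counts, denom,
                             out=np.zeros_like(counts), where=denom > 0)
        elif normalization == "length":
            d = valid_window_count(codes, k + 1)
            freq = counts / d if d > 0 else np.zeros_like(counts)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        parts.append(freq.ravel())
    return np.concatenate(parts)


def transition_frequency(seq: SequenceRecord | str, t: Transition | str,
                         normalization: str = "conditional") -> float:
    """Frequency of a single transition in one sequence.

    Returns 0 when the prefix never occurs with a successor.
    """
    t = as_transition(t)
    s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq).upper()
    codes = encode(s)
    k = t.order
    counts = kmer_counts(codes, k + 1).reshape(4**k, 4)
    prefix_code = kmer_to_code(t.prefix) if k else 0
    base_code = kmer_to_code(t.base)
    row = counts[prefix_code]
    if normalization == "conditional":
        denom = int(row.sum())
    elif normalization == "length":
        denom = valid_window_count(codes, k + 1)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(row[base_code]) / denom if denom else 0.0


class FrequencyMatrix:
    """Sequences x features table of transition (or k-mer) frequencies.

    Wraps a pandas DataFrame (rows: sequence ids; columns: feature names
    like ``"CATG>A"`` or k-mer words) plus per-row group labels and the
    level (tree level for transitions, word length for k-mers) of each
    feature column.
    """

    def __init__(self, data: pd.DataFrame, labels: Sequence[str],
                 levels: np.ndarray, kind: str = "transition") -> None:
        labels = pd.Series(list(labels), index=data.index, name="label")
        if len(labels) != len(data):
            raise ValueError("labels length must match row count")
        if len(levels) != data.shape[1]:
            raise ValueError("levels length must match column count")
        self.data = data
        self.labels = labels
        self.levels = np.asarray(levels)
        self.kind = kind

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def y(self) -> np.ndarray:
        """Binary labels (positive=1, negative=0); unlabelled rows are -1."""
        mapping = {"positive": 1, "negative": 0, "unlabelled": -1}
        return self.labels.map(mapping).to_numpy()

    def subset_rows(self, index) -> "FrequencyMatrix":
        index = np.asarray(index)
        return FrequencyMatrix(self.data.iloc[index],
                               self.labels.iloc[index].tolist(),
                               self.levels, self.kind)

    def subset_columns(self, names: Sequence[str]) -> "FrequencyMatrix":
        cols = list(names)
        pos = [self.data.columns.get_loc(c) for c in cols]
        return FrequencyMatrix(self.data[cols], self.labels.tolist(),
                               self.levels[pos], self.kind)

    def with_labels(self, labels: Sequence[str]) -> "FrequencyMatrix":
        return FrequencyMatrix(self.data, list(labels), self.levels, self.kind)

    # -- persistence -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """TSV: row id, label, then one column per feature (gzip by name)."""
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "transition"
                 ) -> "FrequencyMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        labels = df.pop("label").tolist()
        if kind == "transition":
            levels = np.array([as_transition(c).level for c in df.columns])
        else:
            levels = np.array([len(c) for c in df.columns])
        return cls(df, labels, levels, kind)


def frequency_matrix(records: Sequence[SequenceRecord],
                     max_order: int = DEFAULT_MAX_ORDER,
                     normalization: str = "conditional") -> FrequencyMatrix:
    """Transition-frequency matrix for a set of sequences.

    One row per record, one column per enumerated transition of order
    0..max_order; duplicate sequence ids raise ValueError.
    """
    if not records:
        raise ValueError("need at least one sequence record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate sequence id {dup!r}")
    names = [str(t) for t in enumerate_transitions(max_order)]
    rows = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        rows[i] = _row_frequencies(encode(rec.sequence), max_order,
                                   normalization)
    df = pd.DataFrame(rows, index=ids, columns=names)
    return FrequencyMatrix(df, [r.group_label for r in records],
                           transition_levels(max_order), "transition")


class TransitionFrequencyEncoder(BaseEstimator, TransformerMixin):
    """Transform DNA sequences into transition-frequency features.

    scikit-learn transformer: ``X`` is a sequence of DNA strings or
    SequenceRecords; ``transform`` returns an (n_sequences, n_transitions)
    array in the fixed (order, prefix, base) enumeration order.

    Parameters
    ----------
    max_order : highest Markov order to enumerate (default 5 -> 5460 columns).
    normalization : "conditional" (Markov conditional frequency, default) or
        "length" (count over valid window positions).
    """

    def __init__(self, max_order: int = DEFAULT_MAX_ORDER,
                 normalization: str = "conditional") -> None:
        self.max_order = max_order
        self.normalization = normalization

    def fit(self, X, y=None):
        enumerate_transitions(self.max_order)  # validates max_order
        self.n_features_out_ = n_transitions(self.max_order)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_out_"):
            self.fit(X)
        out = np.empty((len(X), self.n_features_out_))
        for i, seq in enumerate(X):
            s = seq.sequence if isinstance(seq, SequenceRecord) else str(seq)
            out[i] = _row_frequencies(encode(s.upper()), self.max_order,
                                      self.normalization)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(
            [str(t) for t in enumerate_transitions(self.max_order)]
        )
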