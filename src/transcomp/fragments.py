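"""Sliding-window consistency scoring, fragment calling and conservation
tests.

The local consistency score of a window is the sum of favored-transition
frequencies minus the sum of disfavored ones, with all frequencies
computed on the window subsequence alone (transitions crossing the window
edge do not count).  The maximal- and minimal-scoring 500-bp windows of a
positive sequence are its favored and disfavored fragment.  Conservation
of called fragments is assessed with a paired t-test on per-fragment mean
conservation scores and with an element-overlap test against an empirical
null of uniformly placed random fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._alphabet import encode, window_codes, kmer_to_code
from .features import DEFAULT_ALPHA, welch_statistics
from .seqio import GenomicInterval, ScoreTrack, SequenceRecord
from .transitions import FrequencyMatrix, as_transition

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500


@dataclass
class ConsistencyProfile:
    """Per-window consistency scores for one sequence."""

    sequence_id: str
    window: int
    step: int
    starts: np.ndarray
    scores: np.ndarray

    def argmax_window(self) -> tuple[int, float]:
        """(start, score) of the highest-scoring window; leftmost on ties."""
        i = int(np.argmax(self.scores))
        return int(self.starts[i]), float(self.scores[i])

    def argmin_window(self) -> tuple[int, float]:
        i = int(np.argmin(self.scores))
        return int(self.starts[i]), float(self.scores[i])

    def to_bedgraph(self, path) -> None:
        """Write one bedGraph record per window start (step-wide bins)."""
        with open(path, "w") as fh:
            for s, v in zip(self.starts, self.scores):
                fh.write(f"{self.sequence_id}\t{s}\t{s + self.step}\t{v:.6g}\n")


@dataclass
class FragmentCall:
    """Favored (max-score) and disfavored (min-score) window of a sequence."""

    sequence_id: str
    favored: GenomicInterval
    disfavored: GenomicInterval
    favored_score: float
    disfavored_score: float


def _group_by_prefix(transitions: Iterable) -> dict[str, list[int]]:
    """Map prefix -> base codes of the selected transitions under it."""
    groups: dict[str, list[int]] = {}
    for t in transitions:
        t = as_transition(t)
        groups.setdefault(t.prefix, []).append(kmer_to_code(t.base))
    return groups


def consistency_profile(seq: SequenceRecord | str, favored: Iterable,
                        disfavored: Iterable, window: int = DEFAULT_WINDOW,
                        step: int = 1) -> ConsistencyProfile | None:
    """Sliding-window consistency score along one sequence.

    Windows start at 0, step, ... up to len(seq)-window.  Frequencies are
    the Markov conditional frequencies computed on the window subsequence.
    Sequences shorter than the window return None with a logged warning
    (batch callers skip them).
    """
    if isinstance(seq, SequenceRecord):
        sid, s = seq.id, seq.sequence
    else:
        sid, s = "seq", str(seq).upper()
    L = len(s)
    if L < window:
        logger.warning("sequence %s shorter than window (%d < %d); skipped",
                       sid, L, window)
        return None
    if step < 1:
        raise ValueError("step must be >= 1")
    codes = encode(s)
    starts = np.arange(0, L - window + 1, step)
    scores = np.zeros(len(starts))
    fav_groups = _group_by_prefix(favored)
    dis_groups = _group_by_prefix(disfavored)
    # occurrence positions per word length, shared across groups
    pos_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def word_positions(word_len: int):
        if word_len not in pos_cache:
            pos_cache[word_len] = window_codes(codes, word_len)
        return pos_cache[word_len]

    def window_counts(word: str) -> np.ndarray:
        """Count of ``word`` fully inside each window."""
        ell = len(word)
        vals, valid = word_positions(ell)
        occ = np.flatnonzero(valid & (vals == kmer_to_code(word)))
        hi = np.searchsorted(occ, starts + window - ell, side="right")
        lo = np.searchsorted(occ, starts, side="left")
        return (hi - lo).astype(float)

    for groups, sign in ((fav_groups, 1.0), (dis_groups, -1.0)):
        for prefix, base_codes in groups.items():
            sib = {b: window_counts(prefix + b) for b in "ACGT"}
            denom = sum(sib.values())
            for bc in base_codes:
                num = sib["ACGT"[bc]]
                with np.errstate(divide="ignore", invalid="ignore"):
                    freq = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
                scores += sign * freq
    return ConsistencyProfile(sid, window, step, starts, scores)


def call_fragments(records: Sequence[SequenceRecord], favored: Iterable,
                   disfavored: Iterable, window: int = DEFAULT_WINDOW,
                   step: int = 1) -> list[FragmentCall]:
    """Favored/disfavored fragment call per eligible sequence.

    Ties are broken leftmost; sequences shorter than the window are
    skipped (with a warning from the profile step).
    """
    favored = list(favored)
    disfavored = list(disfavored)
    calls: list[FragmentCall] = []
    for rec in records:
        prof = consistency_profile(rec, favored, disfavored, window, step)
        if prof is None:
            continue
        fs, fscore = prof.argmax_window()
        ds, dscore = prof.argmin_window()
        calls.append(
            FragmentCall(
                sequence_id=rec.id,
                favored=GenomicInterval(rec.id, fs, fs + window,
                                        score=fscore, name=rec.id),
                disfavored=GenomicInterval(rec.id, ds, ds + window,
                                           score=dscore, name=rec.id),
                favored_score=fscore,
                disfavored_score=dscore,
            )
        )
    return calls


@dataclass
class PairedTResult:
    t: float
    p: float
    df: int
    mean_diff: float
    degenerate: bool = False

    @property
    def direction(self) -> str:
        if self.mean_diff > 0:
            return "favored_higher"
        if self.mean_diff < 0:
            return "disfavored_higher"
        return "none"


def conservation_compare(fav_means: Sequence[float],
                         disfav_means: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on per-sequence conservation means.

    Zero-variance differences are flagged degenerate: p = 1 when the lists
    are identical, p = NaN for a nonzero constant shift (the statistic is
    undefined).
    """
    a = np.asarray(list(fav_means), dtype=float)
    b = np.asarray(list(disfav_means), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedTResult(t=np.nan, p=1.0 if md == 0.0 else np.nan,
                             df=n - 1, mean_diff=md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), p=p, df=n - 1, mean_diff=md)


def _overlap_ok_starts(length: int, window: int,
                       elements: Sequence[GenomicInterval]) -> np.ndarray:
    """Boolean over window starts: does a window at s overlap >=1 element
    by >=1 bp?"""
    ok = np.zeros(length - window + 1, dtype=bool)
    for el in elements:
        lo = max(0, el.start - window + 1)
        hi = min(length - window, el.end - 1)
        if lo <= hi:
            ok[lo:hi + 1] = True
    return ok


def element_overlap_test(fragments: Sequence[GenomicInterval],
                         elements: Sequence[GenomicInterval],
                         host_sequences: Sequence[SequenceRecord],
                         n_sim: int = 100_000, seed: int = 0,
                         window: int = DEFAULT_WINDOW,
                         add_one: bool = False) -> tuple[float, float]:
    """Observed element-overlap fraction of fragments vs a random-placement
    null.

    Observed: fraction of fragments overlapping >=1 element by >=1 bp.
    Null: each simulation draws one uniform random window per host
    sequence and records the overlap fraction; P is the fraction of
    simulations reaching an equal or higher fraction.  Hosts shorter than
    the window are excluded from both observed and null.
    """
    hosts = {r.id: len(r) for r in host_sequences}
    eligible = {h for h, L in hosts.items() if L >= window}
    for h, L in hosts.items():
        if L < window:
            logger.warning("host %s shorter than window; excluded", h)
    by_host: dict[str, list[GenomicInterval]] = {h: [] for h in eligible}
    for el in elements:
        if el.chrom in by_host:
            by_host[el.chrom].append(el)
    frags = [f for f in fragments if f.chrom in eligible]
    if not frags:
        raise ValueError("no fragments on eligible host sequences")
    for f in frags:
        if f.end > hosts[f.chrom]:
            raise ValueError(f"fragment {f} exceeds its host sequence")
    observed = float(
        np.mean([
            any(f.overlaps(el) for el in by_host[f.chrom]) for f in frags
        ])
    )
    rng = np.random.default_rng(seed)
    hit_counts = np.zeros(n_sim, dtype=np.int64)
    n_hosts = 0
    for h in sorted(eligible):
        L = hosts[h]
        ok = _overlap_ok_starts(L, window, by_host[h])
        draws = rng.integers(0, L - window + 1, size=n_sim)
        hit_counts += ok[draws]
        n_hosts += 1
    null_fracs = hit_counts / n_hosts
    r = int(np.sum(null_fracs >= observed))
    p = (r + 1) / (n_sim + 1) if add_one else r / n_sim
    return observed, p


@dataclass
class FprResult:
    observed_p: float
    null_ps: np.ndarray
    fpr: float
    n_sets: int
    seed: int


def randomized_fragment_fpr(mat: FrequencyMatrix,
                            records: Sequence[SequenceRecord],
                            track: ScoreTrack, n_sets: int = 1000,
                            alpha: float = DEFAULT_ALPHA,
                            window: int = DEFAULT_WINDOW, step: int = 1,
                            seed: int = 0) -> FprResult:
    """Empirical false-positive rate of the fragment-conservation test.

    The observed pipeline (select features -> call fragments on positive
    sequences -> paired conservation t-test) is rerun on ``n_sets``
    label-shuffled copies; the FPR estimate is the fraction of shuffled
    sets whose conservation p-value falls below the observed one.
    """
    rec_by_id = {r.id: r for r in records}

    def pipeline_p(labels: np.ndarray) -> float:
        X = mat.values
        t, df, p = welch_statistics(X[labels == 1], X[labels == 0])
        mean_diff = X[labels == 1].mean(axis=0) - X[labels == 0].mean(axis=0)
        sig = p < alpha
        names = np.asarray(mat.feature_names)
        favored = names[sig & (mean_diff > 0)]
        disfavored = names[sig & (mean_diff < 0)]
        pos_ids = [mat.ids[i] for i in np.flatnonzero(labels == 1)]
        calls = call_fragments([rec_by_id[i] for i in pos_ids], favored,
                               disfavored, window, step)
        if len(calls) < 2:
            return 1.0
        fav_means = [track.mean(c.sequence_id, c.favored.start,
                                c.favored.end) for c in calls]
        dis_means = [track.mean(c.sequence_id, c.disfavored.start,
                                c.disfavored.end) for c in calls]
        res = conservation_compare(fav_means, dis_means)
        return 1.0 if np.isnan(res.p) else res.p

    y = mat.y
    observed_p = pipeline_p(y)
    rng = np.random.default_rng(seed)
    null_ps = np.empty(n_sets)
    for s in range(n_sets):
        null_ps[s] = pipeline_p(y[rng.permutation(len(y))])
    fpr = float(np.mean(null_ps < observed_p))
    return FprResult(observed_p=observed_p, null_ps=null_ps, fpr=fpr,
                     n_sets=n_sets, seed=seed)
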