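"""Seeded synthetic two-group sequence benchmarks with known ground truth.

Sequences are drawn from a background Markov model with lognormal lengths
(defaults scaled down from the tens-of-kilobase regime of real lncRNA gene
bodies to a few kilobases).  The positive group carries signal in one of
two modes:

* global_shift — positive sequences are drawn throughout from a model in
  which a chosen set of transitions has boosted (or depressed) conditional
  probability;
* planted_fragment — positive sequences are background except for a fixed
  number of 500-bp fragments drawn from the boosted model at uniform
  random non-overlapping positions.

``balanced_signal_set`` builds a boost set whose lower-order conditionals
cancel exactly (boosts arranged in compensating context pairs), so the
planted transition set is also the mathematical truth set for feature
recovery.  ``cfp_signal_set`` builds one full-length root-to-leaf path
plus scattered deepest-level transitions, for quad-tree path
demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import BASES, kmer_to_code, code_to_kmer
from .seqio import ScoreTrack, SequenceRecord
from .transitions import Transition, as_transition

DEFAULT_FRAGMENT_LENGTH = 500


@dataclass(frozen=True)
class MarkovModel:
    """Order-k Markov model: ``probs[context_code, base]``.

    Context codes are base-4 encodings of the k-mer preceding the emitted
    base; every row must sum to 1.
    """

    order: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (4**self.order, 4):
            raise ValueError(
                f"probs must have shape ({4**self.order}, 4)"
            )
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each probability row must sum to 1")
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovModel":
        return cls(order, np.full((4**order, 4), 0.25))

    @classmethod
    def skewed(cls, at_frac: float = 0.58, cpg_prob: float = 0.10
               ) -> "MarkovModel":
        """Mildly AT-rich order-1 background with CpG depletion.

        ``at_frac`` is the combined A+T probability in a generic context;
        ``cpg_prob`` the probability of G after C.
        """
        at = at_frac / 2
        cg = (1 - at_frac) / 2
        base = np.array([at, cg, cg, at])
        probs = np.tile(base, (4, 1))
        # deplete G after C, redistribute to the other bases
        c_row = base.copy()
        deficit = c_row[2] - cpg_prob
        c_row[2] = cpg_prob
        others = [0, 1, 3]
        c_row[others] += deficit * c_row[others] / c_row[others].sum()
        probs[1] = c_row
        return cls(1, probs / probs.sum(axis=1, keepdims=True))

    def lifted(self, order: int) -> "MarkovModel":
        """The same process expressed with a longer context."""
        if order < self.order:
            raise ValueError("can only lift to a higher order")
        if order == self.order:
            return self
        # context code modulo 4**self.order keeps the trailing k bases
        probs = self.probs[np.arange(4**order) % (4**self.order)]
        return MarkovModel(order, probs)

    def with_boosts(self, boosts: Mapping) -> "MarkovModel":
        """Additive conditional-probability boosts for chosen transitions.

        ``boosts`` maps a Transition (or "prefix>base" string) to a delta;
        the model is lifted to the highest boost order and, for every
        context whose suffix matches a boost prefix, the target base
        probability is shifted by delta.  Any per-row surplus or deficit
        is redistributed proportionally over the unboosted bases of that
        row; rows whose deltas cancel are left exactly balanced.
        """
        items = [(as_transition(t), float(d)) for t, d in boosts.items()]
        if not items:
            return self
        order = max(self.order, max(t.order for t, _ in items))
        model = self.lifted(order)
        probs = model.probs.copy()
        touched = np.zeros_like(probs, dtype=bool)
        for t, delta in items:
            k = t.order
            base = kmer_to_code(t.base)
            if k == 0:
                rows = np.arange(4**order)
            else:
                suffix = kmer_to_code(t.prefix)
                rows = np.flatnonzero(np.arange(4**order) % (4**k) == suffix)
            probs[rows, base] += delta
            touched[rows, base] = True
        for r in np.flatnonzero(~np.isclose(probs.sum(axis=1), 1.0)):
            surplus = probs[r].sum() - 1.0
            free = ~touched[r]
            if not free.any() or probs[r, free].sum() <= 0:
                raise ValueError(f"cannot rebalance boosted row {r}")
            probs[r, free] -= surplus * probs[r, free] / probs[r, free].sum()
        if (probs <= 0).any() or (probs >= 1).any():
            raise ValueError("boosts push probabilities out of (0, 1)")
        return MarkovModel(order, probs)


def sample_sequence(model: MarkovModel, length: int,
                    rng: np.random.Generator | int = 0,
                    record_id: str = "seq",
                    group_label: str = "unlabelled") -> SequenceRecord:
    """Draw one sequence of the requested length from a Markov model.

    The first ``order`` bases are drawn from the model's mean conditional
    distribution (a detail that washes out for length >> order).
    Deterministic for a given seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = model.order
    if k == 0:
        draws = rng.choice(4, size=length, p=model.probs[0])
        seq = "".join(BASES[c] for c in draws)
        return SequenceRecord(record_id, seq, group_label)
    cum = np.cumsum(model.probs, axis=1)
    cum[:, -1] = 1.0
    mean_cum = np.cumsum(model.probs.mean(axis=0))
    mean_cum[-1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    mask = 4**k
    state = 0
    for i in range(length):
        if i < k:
            c = int(np.searchsorted(mean_cum, u[i], side="right"))
        else:
            c = int(np.searchsorted(cum[state], u[i], side="right"))
        out[i] = c
        state = (state * 4 + c) % mask
    seq = "".join(BASES[c] for c in out)
    return SequenceRecord(record_id, seq, group_label)


def _stationary_word_prob(background: MarkovModel, word: str) -> float:
    """Stationary probability of a word under an order-<=1 view of the
    background chain (the screening heuristic used when placing signal)."""
    P = background.lifted(1).probs if background.order <= 1 else \
        background.probs.reshape(-1, 4).mean(axis=0)[None, :].repeat(4, 0)
    evals, evecs = np.linalg.eig(P.T)
    v = np.real(evecs[:, int(np.argmax(np.real(evals)))])
    v = np.abs(v) / np.abs(v).sum()
    idx = [kmer_to_code(c) for c in word]
    p = float(v[idx[0]])
    for a, b in zip(idx, idx[1:]):
        p *= float(P[a, b])
    return p


def balanced_signal_set(n_pairs: int = 10, delta: float = 0.2,
                        core_length: int = 4,
                        background: MarkovModel | None = None,
                        seed: int = 0) -> dict[str, float]:
    """Boost set of order-(core_length+1) transitions whose lower-order
    conditionals cancel exactly.

    For each of ``n_pairs`` distinct core k-mers two sibling contexts
    (A+core and C+core) and two target bases (b, b') are chosen; b is
    boosted by +delta in the first context and depressed by -delta in the
    second, and b' the mirror image.  Aggregated over any shorter context
    suffix the shifts cancel, so exactly the 2*n_pairs boosted transitions
    are favored and the 2*n_pairs depressed ones disfavored — a clean
    truth set for recovery experiments.  Cores are screened for enough
    probability headroom for +-delta under ``background`` (uniform by
    default) and for at-least-uniform stationary context abundance, so the
    planted signal is observable at benchmark sequence lengths rather
    than hidden in contexts the background rarely visits.
    """
    rng = np.random.default_rng(seed)
    background = background or MarkovModel.uniform(0)
    boosts: dict[str, float] = {}
    cores: set[str] = set()
    order = core_length + 1
    lifted = background.lifted(order) if background.order <= order else None
    if lifted is None:
        raise ValueError("background order exceeds signal order")
    attempts = 0
    while len(cores) < n_pairs:
        attempts += 1
        if attempts > 1000 * n_pairs:
            raise RuntimeError("could not place the requested signal pairs")
        core = code_to_kmer(int(rng.integers(0, 4**core_length)), core_length)
        if core in cores:
            continue
        ctx_a, ctx_c = "A" + core, "C" + core
        floor = 0.999 * 0.25 ** (core_length + 1)  # tolerance for round-off
        if min(_stationary_word_prob(background, ctx_a),
               _stationary_word_prob(background, ctx_c)) < floor:
            continue
        row_a = lifted.probs[kmer_to_code(ctx_a)]
        row_c = lifted.probs[kmer_to_code(ctx_c)]
        ok = [
            b for b in range(4)
            if min(row_a[b], row_c[b]) > delta + 0.01
            and max(row_a[b], row_c[b]) < 1 - delta - 0.01
        ]
        if len(ok) < 2:
            continue
        b1, b2 = rng.choice(ok, size=2, replace=False)
        cores.add(core)
        boosts[f"{ctx_a}>{BASES[b1]}"] = +delta
        boosts[f"{ctx_a}>{BASES[b2]}"] = -delta
        boosts[f"{ctx_c}>{BASES[b1]}"] = -delta
        boosts[f"{ctx_c}>{BASES[b2]}"] = +delta
    return boosts


def cfp_signal_set(delta: float = 0.1, n_scattered: int = 14,
                   leaf: str = "CGCGTT", seed: int = 0) -> dict[str, float]:
    """One full-length root-to-leaf boost path plus scattered deepest-level
    boosts (mirrors the empirically observed deepest-level dominance)."""
    boosts: dict[str, float] = {}
    for i in range(len(leaf)):
        boosts[f"{leaf[:i]}>{leaf[i]}"] = delta
    rng = np.random.default_rng(seed)
    k = len(leaf) - 1
    placed = 0
    while placed < n_scattered:
        prefix = code_to_kmer(int(rng.integers(0, 4**k)), k)
        base = BASES[int(rng.integers(0, 4))]
        key = f"{prefix}>{base}"
        if key in boosts:
            continue
        boosts[key] = delta
        placed += 1
    return boosts


@dataclass
class BenchmarkConfig:
    """Study conditions for a synthetic two-group benchmark.

    Lengths are lognormal with the given median and log-sd, floored at
    ``min_length`` (a scaled-down version of real lncRNA gene-body length
    variation); ``signal`` maps transitions to conditional-probability
    deltas; ``pos_length_factor`` optionally makes positives longer, as
    real positive sets are.
    """

    n_pos: int = 100
    n_neg: int = 100
    length_median: float = 5000.0
    length_log_sd: float = 0.4
    min_length: int = 1500
    pos_length_factor: float = 1.0
    background: MarkovModel = field(default_factory=lambda: MarkovModel.skewed())
    signal_mode: str = "global_shift"
    signal: Mapping[str, float] = field(default_factory=dict)
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    fragments_per_seq: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both groups need at least one sequence")
        if self.signal_mode not in ("global_shift", "planted_fragment"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")


@dataclass
class BenchmarkTruth:
    """Ground truth of a generated benchmark."""

    favored: frozenset[str]
    disfavored: frozenset[str]
    fragments: dict[str, list[tuple[int, int]]]
    config: BenchmarkConfig

    @property
    def signal_transitions(self) -> frozenset[str]:
        return self.favored | self.disfavored


def _draw_length(rng: np.random.Generator, cfg: BenchmarkConfig,
                 factor: float = 1.0) -> int:
    L = int(round(np.exp(rng.normal(np.log(cfg.length_median * factor),
                                    cfg.length_log_sd))))
    return max(L, cfg.min_length)


def generate_benchmark(config: BenchmarkConfig
                       ) -> tuple[list[SequenceRecord], BenchmarkTruth]:
    """Generate a labelled two-group benchmark with known ground truth.

    Deterministic under ``config.seed``.  In planted_fragment mode each
    positive sequence carries ``fragments_per_seq`` non-overlapping
    boosted-model fragments at uniform random positions; in global_shift
    mode positive sequences are drawn from the boosted model throughout.
    """
    cfg = config
    if (cfg.signal_mode == "planted_fragment"
            and cfg.fragment_length * cfg.fragments_per_seq > cfg.min_length):
        raise ValueError(
            "fragment_length x fragments_per_seq exceeds min_length; "
            "fragments could not fit the shortest sequence"
        )
    rng = np.random.default_rng(cfg.seed)
    boosted = cfg.background.with_boosts(cfg.signal) if cfg.signal \
        else cfg.background
    favored = frozenset(
        str(as_transition(t)) for t, d in cfg.signal.items() if d > 0
    )
    disfavored = frozenset(
        str(as_transition(t)) for t, d in cfg.signal.items() if d < 0
    )
    records: list[SequenceRecord] = []
    fragments: dict[str, list[tuple[int, int]]] = {}
    for i in range(cfg.n_neg):
        L = _draw_length(rng, cfg)
        records.append(sample_sequence(cfg.background, L, rng,
                                       f"neg_{i:04d}", "negative"))
    for i in range(cfg.n_pos):
        L = _draw_length(rng, cfg, cfg.pos_length_factor)
        rid = f"pos_{i:04d}"
        if cfg.signal_mode == "global_shift" or not cfg.signal:
            records.append(sample_sequence(boosted, L, rng, rid, "positive"))
            continue
        w = cfg.fragment_length
        m = cfg.fragments_per_seq
        if w * m > L:
            raise ValueError(
                "fragment length exceeds available sequence; raise "
                "min_length or lower fragment_length/fragments_per_seq"
            )
        base = sample_sequence(cfg.background, L, rng, rid, "positive")
        seq = list(base.sequence)
        # non-overlapping uniform placement via the sorted-gap construction
        slack = np.sort(rng.integers(0, L - m * w + 1, size=m))
        placed = [(int(s + j * w), int(s + (j + 1) * w))
                  for j, s in enumerate(slack)]
        for s, e in placed:
            frag = sample_sequence(boosted, w, rng)
            seq[s:e] = frag.sequence
        records.append(SequenceRecord(rid, "".join(seq), "positive"))
        fragments[rid] = placed
    # interleave determinism note: negatives first, then positives, fixed ids
    truth = BenchmarkTruth(favored=favored, disfavored=disfavored,
                           fragments=fragments, config=cfg)
    return records, truth


def random_score_track(records: Sequence[SequenceRecord], seed: int = 0,
                       run_length: int = 50) -> ScoreTrack:
    """Sequence-independent random conservation-like track.

    Piecewise-constant runs of Beta(0.5, 1.5)-distributed scores keyed by
    sequence id; independent of sequence content by construction, for
    calibration tests.
    """
    rng = np.random.default_rng(seed)
    track = ScoreTrack()
    for rec in records:
        pos = 0
        L = len(rec)
        while pos < L:
            end = min(L, pos + run_length)
            track.add(rec.id, pos, end, float(rng.beta(0.5, 1.5)))
            pos = end
    return track
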