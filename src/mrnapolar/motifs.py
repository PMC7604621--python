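"""Position-weight-matrix scanning of 3'UTR sequences with exact p-values.

A PWM is a per-position nucleotide probability model of a short RNA motif.
Windows of a sequence are scored by the log2 likelihood ratio against a
0-order background model, and each score is assigned the exact p-value
P(score(W) >= s) for a random background word W, computed by dynamic
programming over integer-discretised scores (the FIMO approach). Scanning is
sense-strand only: the substrates are mRNA 3'UTRs, not double-stranded
genomic DNA.

The per-cluster motif statistic is the fraction of an mRNA cluster's genes
carrying at least ``min_count`` motif occurrences in their 3'UTR.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "PWM",
    "MotifHit",
    "PWMScanner",
    "estimate_pwm",
    "pwm_pvalue",
    "scan_sequence",
    "motif_cluster_frequency",
    "encode_sequence",
]

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
# score grid granularity: 1/1000 bit
EPS = 1e-3
# floor for log-odds of (near-)zero probabilities, in bits
_SCORE_FLOOR = -64.0


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an RNA/DNA string as indices into ACGT; U maps to T, N to 4.

    Mixed case is accepted. Any other letter raises ``ValueError``.
    """
    seq = sequence.upper().replace("U", "T")
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        if ch == "N":
            out[i] = 4
        else:
            try:
                out[i] = _INDEX[ch]
            except KeyError:
                raise ValueError(f"invalid letter {ch!r} at position {i}") from None
    return out


@dataclasses.dataclass
class PWM:
    """Position weight matrix over ACGT (U treated as T).

    ``probs`` has shape (4, width); every column sums to 1. ``background``
    is the 0-order background nucleotide distribution used for scoring.
    """

    probs: np.ndarray
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must have shape (4, width)")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        sums = self.probs.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if abs(self.background.sum() - 1) > 1e-9 or np.any(self.background <= 0):
            raise ValueError("background must be a positive distribution")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))

    def score_matrix(self) -> np.ndarray:
        """Log2 likelihood-ratio scores, shape (width, 4), floored in bits."""
        with np.errstate(divide="ignore"):
            s = np.log2(self.probs / self.background[:, None]).T
        return np.maximum(s, _SCORE_FLOOR)

    def int_score_matrix(self) -> np.ndarray:
        """Scores rounded to the EPS grid, shape (width, 4), dtype int64."""
        return np.rint(self.score_matrix() / EPS).astype(np.int64)


@dataclasses.dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence; 0-based half-open [start, end)."""

    sequence_id: str
    start: int
    end: int
    score: float  # log2 likelihood ratio, bits
    p_value: float


def estimate_pwm(
    instances: Sequence[str],
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
    name: str = "motif",
) -> PWM:
    """Estimate a PWM from aligned equal-length motif instances.

    Column probabilities are (count + pseudocount) / (n + 4 * pseudocount).
    """
    if len(instances) == 0:
        raise ValueError("need at least one instance")
    encoded = [encode_sequence(s) for s in instances]
    width = len(encoded[0])
    if any(len(e) != width for e in encoded):
        raise ValueError("instances must all have the same length")
    if any(np.any(e == 4) for e in encoded):
        raise ValueError("instances must not contain N")
    counts = np.zeros((4, width))
    for e in encoded:
        counts[e, np.arange(width)] += 1
    probs = (counts + pseudocount) / (len(encoded) + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(probs=probs, background=bg, name=name)


def _score_distribution(pwm: PWM) -> tuple[np.ndarray, int]:
    """Null distribution of the integer window score under the background.

    Returns ``(probs, offset)`` where ``probs[k]`` is the probability that a
    random background word has integer score ``k + offset``.
    """
    s_int = pwm.int_score_matrix()
    bg = pwm.background
    lo = int(s_int.min(axis=1).sum())
    hi = int(s_int.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    # start with an empty prefix: score 0 relative to the running minimum
    run_lo = 0
    dist[0] = 1.0
    size = 1
    for j in range(pwm.width):
        col = s_int[j]
        col_lo = int(col.min())
        new_lo = run_lo + col_lo
        new_size = size + int(col.max()) - col_lo
        new = np.zeros(new_size)
        for a in range(4):
            shift = int(col[a]) - col_lo
            new[shift : shift + size] += bg[a] * dist[:size]
        dist = new
        size = new_size
        run_lo = new_lo
    assert run_lo == lo and size == hi - lo + 1
    return dist, lo


def _tail_function(pwm: PWM) -> tuple[np.ndarray, int]:
    """Upper-tail P(S_int >= k) indexed by k - offset, plus the offset."""
    cached = getattr(pwm, "_tail_cache", None)
    if cached is not None:
        return cached
    dist, lo = _score_distribution(pwm)
    tail = np.cumsum(dist[::-1])[::-1]
    # guard against floating accumulation slightly above 1
    result = (np.minimum(tail, 1.0), lo)
    pwm._tail_cache = result
    return result


def pwm_pvalue(pwm: PWM, score: float) -> float:
    """Exact p-value P(score(W) >= score) for a background word W.

    Scores are discretised to the 1/1000-bit grid used by the scanner, so
    the result agrees with exhaustive enumeration to within the
    discretisation bound (EPS * width).
    """
    tail, lo = _tail_function(pwm)
    k = int(np.rint(score / EPS)) - lo
    if k <= 0:
        return 1.0
    if k >= len(tail):
        return 0.0
    return float(tail[k])


def _window_int_scores(pwm: PWM, encoded: np.ndarray) -> np.ndarray:
    """Integer score of every window; N contributes the background-expected
    score for its column."""
    s_int = pwm.int_score_matrix()
    expected = np.rint(
        (pwm.score_matrix() * pwm.background[None, :]).sum(axis=1) / EPS
    ).astype(np.int64)
    w = pwm.width
    n_windows = len(encoded) - w + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.int64)
    scores = np.zeros(n_windows, dtype=np.int64)
    for j in range(w):
        letters = encoded[j : j + n_windows]
        col = np.append(s_int[j], expected[j])  # index 4 = N
        scores += col[letters]
    return scores


def scan_sequence(
    pwm: PWM,
    sequence: str,
    p_max: float = 1e-5,
    sequence_id: str = "seq",
    no_overlap: bool = False,
) -> list[MotifHit]:
    """Report every window with match p-value below ``p_max``, sorted by start.

    Overlapping occurrences are all reported unless ``no_overlap`` is set, in
    which case a greedy left-to-right pass keeps only non-overlapping hits.
    A sequence shorter than the motif yields an empty list.
    """
    encoded = encode_sequence(sequence)
    scores = _window_int_scores(pwm, encoded)
    if scores.size == 0:
        return []
    tail, lo = _tail_function(pwm)
    idx = np.clip(scores - lo, 0, len(tail) - 1)
    pvals = tail[idx]
    pvals[scores - lo < 0] = 1.0
    hits = [
        MotifHit(
            sequence_id=sequence_id,
            start=int(i),
            end=int(i) + pwm.width,
            score=float(scores[i] * EPS),
            p_value=float(pvals[i]),
        )
        for i in np.nonzero(pvals < p_max)[0]
    ]
    if no_overlap:
        kept: list[MotifHit] = []
        for h in hits:
            if not kept or h.start >= kept[-1].end:
                kept.append(h)
        hits = kept
    return hits


class PWMScanner:
    """Estimator-style motif scanner: fit a PWM from instances, transform
    sequences into hit lists.

    ``fit(instances)`` estimates the PWM (or use ``pwm=`` to supply one);
    ``transform(sequences)`` returns a list of hit lists, one per input
    sequence. ``sequences`` may be a mapping id -> sequence or a plain list.
    """

    def __init__(
        self,
        p_max: float = 1e-5,
        pseudocount: float = 0.1,
        no_overlap: bool = False,
        pwm: PWM | None = None,
    ):
        self.p_max = p_max
        self.pseudocount = pseudocount
        self.no_overlap = no_overlap
        self.pwm = pwm

    def get_params(self, deep: bool = True) -> dict:
        return {
            "p_max": self.p_max,
            "pseudocount": self.pseudocount,
            "no_overlap": self.no_overlap,
            "pwm": self.pwm,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: Sequence[str], y=None) -> "PWMScanner":
        if self.pwm is not None:
            self.pwm_ = self.pwm
        else:
            self.pwm_ = estimate_pwm(X, pseudocount=self.pseudocount)
        return self

    def transform(self, X) -> list[list[MotifHit]]:
        if not hasattr(self, "pwm_"):
            raise ValueError("PWMScanner is not fitted")
        if isinstance(X, Mapping):
            items = list(X.items())
        else:
            items = [(f"seq{i}", s) for i, s in enumerate(X)]
        return [
            scan_sequence(self.pwm_, seq, self.p_max, sid, self.no_overlap)
            for sid, seq in items
        ]


def motif_cluster_frequency(
    hit_counts: Mapping[str, int],
    clusters: Mapping[str, int | str],
    min_count: int = 2,
) -> dict:
    """Fraction of each cluster's genes with at least ``min_count`` motif hits.

    Genes present in ``clusters`` but absent from ``hit_counts`` count as
    zero occurrences; a counted gene without a cluster label is an error.
    """
    unlabelled = set(hit_counts) - set(clusters)
    if unlabelled:
        raise ValueError(f"genes without cluster label: {sorted(unlabelled)[:5]}")
    totals: dict = {}
    positive: dict = {}
    for gene, label in clusters.items():
        totals[label] = totals.get(label, 0) + 1
        if hit_counts.get(gene, 0) >= min_count:
            positive[label] = positive.get(label, 0) + 1
    return {label: positive.get(label, 0) / n for label, n in totals.items()}
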