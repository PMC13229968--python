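"""Sequence- and distribution-level evaluation metrics.

Implements the evaluation suite for comparing token sequences and parameter
populations: teacher-forcing token accuracy and support-weighted F1, corpus
BLEU-4 with brevity penalty, ROUGE-L over the longest common subsequence,
the 1-D Wasserstein (earth mover's) distance with a range-normalized
variant, and R²/RMSE/MAPE regression metrics.

Two deliberate fidelity choices:

* ``rouge_l`` defaults to the orientation used by the plant-architecture
  evaluation it reproduces — recall as LCS/len(generated), precision as
  LCS/len(reference), β = P/R — which algebraically reduces the F-score to
  LCS/len(reference). ``standard=True`` gives the conventional ROUGE-L
  (R = LCS/len(reference), P = LCS/len(generated), F with β²-weighting).
* BLEU-4 uses clipped n-gram counts at corpus level with no smoothing: any
  empty n-gram precision yields a score of 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import exp, sqrt

import numpy as np
from scipy import stats

from .tokenizer import TokenSequence

__all__ = [
    "SeqEvalReport",
    "DistEvalReport",
    "token_accuracy",
    "weighted_f1",
    "per_token_scores",
    "bleu4",
    "rouge_l",
    "lcs_length",
    "wasserstein_1d",
    "normalized_wasserstein",
    "regression_metrics",
    "evaluate_sequences",
]


def _ids(seq) -> tuple[int, ...]:
    return tuple(seq.ids) if isinstance(seq, TokenSequence) else tuple(seq)


def _pairs(gen, ref) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Normalize (sequence, sequence) or (list, list) inputs to pairs."""
    if isinstance(gen, (TokenSequence, tuple)) or (
            isinstance(gen, list) and gen and isinstance(gen[0], int)):
        return [(_ids(gen), _ids(ref))]
    if len(gen) != len(ref):
        raise ValueError(f"corpus size mismatch: {len(gen)} generated vs {len(ref)} reference")
    return [(_ids(g), _ids(r)) for g, r in zip(gen, ref)]


# ---------------------------------------------------------------------------
# teacher-forcing (aligned) metrics
# ---------------------------------------------------------------------------

def token_accuracy(pred, ref) -> float:
    """Fraction of aligned positions where predicted == reference token."""
    p, r = _ids(pred), _ids(ref)
    if len(p) != len(r):
        raise ValueError(f"aligned metrics need equal lengths, got {len(p)} vs {len(r)}")
    if not r:
        raise ValueError("empty sequences")
    return sum(a == b for a, b in zip(p, r)) / len(r)


def per_token_scores(pred, ref) -> dict[int, dict[str, float]]:
    """Per-token-ID precision, recall, F1 and reference support.

    Covers every ID present in either sequence; one-vs-rest confusion counts
    over aligned positions. IDs absent from both sequences are omitted (they
    would carry zero support and contribute nothing to the weighted mean).
    """
    p, r = _ids(pred), _ids(ref)
    if len(p) != len(r):
        raise ValueError(f"aligned metrics need equal lengths, got {len(p)} vs {len(r)}")
    tp: Counter = Counter()
    fp: Counter = Counter()
    fn: Counter = Counter()
    support: Counter = Counter()
    for a, b in zip(p, r):
        support[b] += 1
        if a == b:
            tp[a] += 1
        else:
            fp[a] += 1
            fn[b] += 1
    out = {}
    for k in sorted(set(p) | set(r)):
        prec = tp[k] / (tp[k] + fp[k]) if tp[k] + fp[k] else 0.0
        rec = tp[k] / (tp[k] + fn[k]) if tp[k] + fn[k] else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[k] = {"precision": prec, "recall": rec, "f1": f1, "support": support[k]}
    return out


def weighted_f1(pred, ref) -> float:
    """F1 averaged over token IDs, weighted by reference support:
    Σₖ nₖ·F1ₖ / Σₖ nₖ."""
    scores = per_token_scores(pred, ref)
    total = sum(s["support"] for s in scores.values())
    if total == 0:
        raise ValueError("empty sequences")
    return sum(s["support"] * s["f1"] for s in scores.values()) / total


# ---------------------------------------------------------------------------
# generation (unaligned) metrics
# ---------------------------------------------------------------------------

def _ngrams(ids: tuple[int, ...], n: int) -> Counter:
    return Counter(ids[i:i + n] for i in range(len(ids) - n + 1))


def bleu4(gen, ref) -> float:
    """Corpus-level BLEU-4 in percent.

    Geometric mean of clipped 1–4-gram precisions, pooled over all sequence
    pairs, times the brevity penalty min(1, exp(1 − Σl_ref / Σl_gen)). No
    smoothing: a zero n-gram precision gives 0.
    """
    pairs = _pairs(gen, ref)
    if any(len(g) == 0 or len(r) == 0 for g, r in pairs):
        raise ValueError("BLEU-4 is undefined for empty sequences")
    l_gen = sum(len(g) for g, _ in pairs)
    l_ref = sum(len(r) for _, r in pairs)
    log_prec_sum = 0.0
    for n in range(1, 5):
        matched = 0
        total = 0
        for g, r in pairs:
            g_counts = _ngrams(g, n)
            r_counts = _ngrams(r, n)
            matched += sum(min(c, r_counts[ng]) for ng, c in g_counts.items())
            total += max(len(g) - n + 1, 0)
        if total == 0 or matched == 0:
            return 0.0
        log_prec_sum += np.log(matched / total)
    bp = min(1.0, exp(1.0 - l_ref / l_gen))
    return float(bp * exp(log_prec_sum / 4.0) * 100.0)


def lcs_length(a, b) -> int:
    """Longest common subsequence length by dynamic programming, O(|a|·|b|)."""
    a, b = _ids(a), _ids(b)
    if len(b) < len(a):
        a, b = b, a
    prev = np.zeros(len(a) + 1, dtype=np.int64)
    for y in b:
        curr = prev.copy()
        for i, x in enumerate(a, start=1):
            if x == y:
                curr[i] = prev[i - 1] + 1
            elif curr[i - 1] > curr[i]:
                curr[i] = curr[i - 1]
        np.maximum.accumulate(curr, out=curr)
        prev = curr
    return int(prev[-1])


def rouge_l(gen, ref, standard: bool = False) -> float:
    """ROUGE-L F-score, averaged over sequence pairs.

    Default orientation: R = LCS/len(gen), P = LCS/len(ref), β = P/R,
    F = (1+β²)·R·P / (R + β·P) — which simplifies to LCS/len(ref).
    With ``standard=True``: R = LCS/len(ref), P = LCS/len(gen),
    F = (1+β²)·R·P / (R + β²·P) with β = R/P.
    """
    pairs = _pairs(gen, ref)
    if any(len(g) == 0 or len(r) == 0 for g, r in pairs):
        raise ValueError("ROUGE-L is undefined for empty sequences")
    scores = []
    for g, r in pairs:
        lcs = lcs_length(g, r)
        if lcs == 0:
            scores.append(0.0)
            continue
        if standard:
            rec = lcs / len(r)
            prec = lcs / len(g)
            beta = rec / prec
            scores.append((1 + beta ** 2) * rec * prec / (rec + beta ** 2 * prec))
        else:
            rec = lcs / len(g)
            prec = lcs / len(r)
            beta = prec / rec
            scores.append((1 + beta ** 2) * rec * prec / (rec + beta * prec))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# distribution metrics
# ---------------------------------------------------------------------------

def wasserstein_1d(a, b, p: float = 1.0) -> float:
    """Order-``p`` Wasserstein distance between 1-D empirical samples.

    ``p = 1`` is the earth mover's distance (integrated |CDF difference|);
    general ``p`` integrates |quantile difference|^p exactly over the merged
    step quantile functions.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Wasserstein distance needs non-empty samples")
    if p == 1.0:
        return float(stats.wasserstein_distance(a, b))
    if p < 1:
        raise ValueError("order p must be >= 1")
    return _quantile_wasserstein(a, b, p)


def _quantile_wasserstein(a: np.ndarray, b: np.ndarray, p: float) -> float:
    """Exact piecewise integration of |F_a⁻¹(q) − F_b⁻¹(q)|^p over q ∈ (0, 1)
    for sorted samples (both empirical quantile functions are step functions)."""
    qs = np.union1d(np.arange(1, len(a)) / len(a), np.arange(1, len(b)) / len(b))
    qs = np.concatenate([[0.0], qs, [1.0]])
    mids = (qs[:-1] + qs[1:]) / 2.0
    ia = np.minimum((mids * len(a)).astype(int), len(a) - 1)
    ib = np.minimum((mids * len(b)).astype(int), len(b) - 1)
    diff = np.abs(a[ia] - b[ib]) ** p
    return float(np.sum(diff * np.diff(qs)) ** (1.0 / p))


def normalized_wasserstein(samples, reference, p: float = 1.0) -> float:
    """Wasserstein distance divided by the reference sample's value range.

    A constant (zero-range) reference gives 0 when the raw distance is ~0
    and +inf otherwise.
    """
    wd = wasserstein_1d(samples, reference, p)
    rng = float(np.max(reference) - np.min(reference))
    if rng == 0.0:
        return 0.0 if wd < 1e-12 else float("inf")
    return wd / rng


def regression_metrics(pred, true) -> dict[str, float]:
    """R², RMSE and MAPE (percent) with standard definitions.

    Zero true values are excluded from MAPE; their count is reported under
    ``mape_excluded``.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    if len(true) == 0:
        raise ValueError("empty series")
    resid = true - pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    rmse = sqrt(ss_res / len(true))
    nz = true != 0
    mape = (float(np.mean(np.abs(resid[nz] / true[nz]))) * 100.0
            if nz.any() else float("nan"))
    return {"r2": r2, "rmse": rmse, "mape": mape,
            "mape_excluded": int((~nz).sum())}


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class SeqEvalReport:
    """Sequence-evaluation summary over one corpus of (pred, ref) pairs."""

    bleu4_percent: float
    rouge_l: float
    accuracy: float | None = None           # aligned corpora only
    weighted_f1: float | None = None
    per_token: dict[int, dict[str, float]] | None = None

    def to_dict(self) -> dict:
        d = {"bleu4_percent": self.bleu4_percent, "rouge_l": self.rouge_l}
        if self.accuracy is not None:
            d["accuracy"] = self.accuracy
            d["weighted_f1"] = self.weighted_f1
        return d


@dataclass
class DistEvalReport:
    """Per-parameter distribution distances between two populations."""

    raw_wd: dict[str, float] = field(default_factory=dict)
    normalized_wd: dict[str, float] = field(default_factory=dict)
    normalization: dict[str, float] = field(default_factory=dict)   # reference range used


def evaluate_sequences(preds, refs, aligned: bool = False) -> SeqEvalReport:
    """Full sequence-evaluation report for a corpus of pairs.

    With ``aligned=True`` the pairs must be position-aligned (teacher
    forcing) and accuracy / weighted F1 are computed by pooling positions
    over the corpus; BLEU-4 and ROUGE-L are always computed.
    """
    pairs = _pairs(preds, refs)
    report = SeqEvalReport(bleu4_percent=bleu4(preds, refs), rouge_l=rouge_l(preds, refs))
    if aligned:
        flat_p = tuple(t for g, _ in pairs for t in g)
        flat_r = tuple(t for _, r in pairs for t in r)
        report.accuracy = token_accuracy(flat_p, flat_r)
        report.weighted_f1 = weighted_f1(flat_p, flat_r)
        report.per_token = per_token_scores(flat_p, flat_r)
    return report
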