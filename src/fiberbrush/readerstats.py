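"""Reader-study analytics for binary neoplasia calls.

Endoscopists read each image under two conditions (original HR vs
super-resolved SR) and call it neoplastic or non-neoplastic with high or low
confidence; biopsy histopathology is the gold standard.  This module
computes per-reader and pooled diagnostic performance (sensitivity,
specificity, accuracy), stratifies by confidence, compares HR against SR
with unpaired t-tests across readers, and sizes an equivalence study on
binary data.

The positive class is fixed to "neoplastic" (high-grade dysplasia / ESCC)
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist

__all__ = [
    "ReaderResponse",
    "GoldLabel",
    "PerformanceSummary",
    "confusion",
    "diagnostic_metrics",
    "unpaired_t_test",
    "equivalence_sample_size",
    "reader_study_report",
    "demo_gold_labels",
    "simulate_reader_responses",
]

POSITIVE = "neoplastic"
NEGATIVE = "non_neoplastic"
_CALLS = (POSITIVE, NEGATIVE)
_CONDITIONS = ("HR", "SR")
_CONFIDENCES = ("high", "low")


@dataclass(frozen=True)
class ReaderResponse:
    """One reader's call on one image under one viewing condition."""

    reader_id: str
    image_id: str
    condition: str
    call: str
    confidence: str

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")
        if self.call not in _CALLS:
            raise ValueError(f"call must be one of {_CALLS}")
        if self.confidence not in _CONFIDENCES:
            raise ValueError(f"confidence must be one of {_CONFIDENCES}")


@dataclass(frozen=True)
class GoldLabel:
    """Histopathology ground truth for one image."""

    image_id: str
    truth: str

    def __post_init__(self) -> None:
        if self.truth not in _CALLS:
            raise ValueError(f"truth must be one of {_CALLS}")


@dataclass(frozen=True)
class PerformanceSummary:
    """Diagnostic metrics derived from a 2x2 confusion table.

    Metrics with a zero denominator (e.g. sensitivity with no positive
    cases) are ``None`` — absent, never silently zero.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    stratum: str = "all"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def _gold_map(gold: list[GoldLabel]) -> dict[str, str]:
    out: dict[str, str] = {}
    for g in gold:
        if g.image_id in out and out[g.image_id] != g.truth:
            raise ValueError(f"conflicting gold labels for {g.image_id}")
        out[g.image_id] = g.truth
    return out


def confusion(
    responses: list[ReaderResponse],
    gold: list[GoldLabel],
    stratum: str = "all",
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over the responses, optionally filtered by
    confidence stratum ("all", "high_conf", or "low_conf")."""
    if stratum not in ("all", "high_conf", "low_conf"):
        raise ValueError(f"unknown stratum {stratum!r}")
    truth = _gold_map(gold)
    missing = sorted({r.image_id for r in responses} - set(truth))
    if missing:
        raise ValueError(f"responses without gold labels: {missing}")
    want = {"all": None, "high_conf": "high", "low_conf": "low"}[stratum]
    tp = fp = fn = tn = 0
    for r in responses:
        if want is not None and r.confidence != want:
            continue
        pos_truth = truth[r.image_id] == POSITIVE
        pos_call = r.call == POSITIVE
        if pos_call and pos_truth:
            tp += 1
        elif pos_call and not pos_truth:
            fp += 1
        elif not pos_call and pos_truth:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def diagnostic_metrics(
    counts: tuple[int, int, int, int], stratum: str = "all"
) -> PerformanceSummary:
    """Wrap (TP, FP, FN, TN) counts into a PerformanceSummary."""
    tp, fp, fn, tn = counts
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    return PerformanceSummary(tp=tp, fp=fp, fn=fn, tn=tn, stratum=stratum)


def unpaired_t_test(
    group_a: list[float], group_b: list[float], equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided unpaired two-sample t-test; returns (t, df, p).

    Pooled-variance (Student's) by default; ``equal_var=False`` gives the
    Welch form.  Degenerate zero-variance groups with equal means return
    (0, df, 1); with unequal means the statistic is undefined and an error
    is raised.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            df = float(a.size + b.size - 2)
            return 0.0, df, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    if equal_var:
        df = float(a.size + b.size - 2)
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    else:
        sa, sb = va / a.size, vb / b.size
        se = math.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (
            sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
        )
    t = diff / se
    p = 2.0 * float(_t_dist.sf(abs(t), df))
    return float(t), df, min(p, 1.0)


def equivalence_sample_size(
    p_assumed: float,
    limit: float,
    alpha: float = 0.05,
    power: float = 0.8,
) -> int:
    """Per-condition sample size for a binary equivalence comparison.

    Two-proportion, equal-variance normal approximation without continuity
    correction: the smallest integer n with

        n >= (z_{1-alpha/2} + z_{1-beta})^2 * 2 p (1 - p) / limit^2

    where p is the assumed common proportion and ``limit`` the equivalence
    margin.  The assumed proportion is an explicit argument because study
    reports rarely print the variance estimate behind their quoted n.
    """
    for name, v in (("p_assumed", p_assumed), ("limit", limit),
                    ("alpha", alpha), ("power", power)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    z_a = float(_norm.ppf(1.0 - alpha / 2.0))
    z_b = float(_norm.ppf(power))
    n = (z_a + z_b) ** 2 * 2.0 * p_assumed * (1.0 - p_assumed) / limit**2
    return int(math.ceil(n))


def _summaries_for(
    responses: list[ReaderResponse], gold: list[GoldLabel]
) -> dict[str, PerformanceSummary]:
    return {
        stratum: diagnostic_metrics(
            confusion(responses, gold, stratum), stratum
        )
        for stratum in ("all", "high_conf", "low_conf")
    }


def reader_study_report(
    responses: list[ReaderResponse], gold: list[GoldLabel]
) -> dict:
    """Full reader-study analysis.

    Returns a dict with:

    - ``per_reader``: DataFrame of per-reader, per-condition, per-stratum
      metrics and counts;
    - ``pooled``: the same with all readers' responses pooled;
    - ``t_tests``: per-metric unpaired t-tests of HR vs SR across readers
      (omitted with a notice when there is a single reader);
    - ``high_confidence_fraction``: per condition, mean over readers of the
      fraction of responses called with high confidence.
    """
    conditions = {r.condition for r in responses}
    if not conditions.issuperset(_CONDITIONS):
        raise ValueError("responses must cover both HR and SR conditions")
    readers = sorted({r.reader_id for r in responses})

    rows = []
    per_reader_metric: dict[tuple[str, str], dict[str, float]] = {}
    hc_frac: dict[str, list[float]] = {c: [] for c in _CONDITIONS}
    for cond in _CONDITIONS:
        for reader in readers:
            subset = [
                r for r in responses
                if r.condition == cond and r.reader_id == reader
            ]
            for stratum, summ in _summaries_for(subset, gold).items():
                rows.append(
                    {"reader_id": reader, "condition": cond,
                     **summ.as_dict()}
                )
                if stratum == "all":
                    per_reader_metric[(cond, reader)] = {
                        "sensitivity": summ.sensitivity,
                        "specificity": summ.specificity,
                        "accuracy": summ.accuracy,
                    }
            if subset:
                hc = sum(r.confidence == "high" for r in subset)
                hc_frac[cond].append(hc / len(subset))
        pooled_subset = [r for r in responses if r.condition == cond]
        for stratum, summ in _summaries_for(pooled_subset, gold).items():
            rows.append(
                {"reader_id": "pooled", "condition": cond, **summ.as_dict()}
            )
    per_reader = pd.DataFrame([r for r in rows if r["reader_id"] != "pooled"])
    pooled = pd.DataFrame([r for r in rows if r["reader_id"] == "pooled"])

    t_tests: dict | None
    if len(readers) < 2:
        t_tests = None
        notice = "t-tests omitted: fewer than two readers"
    else:
        notice = ""
        t_tests = {}
        for metric in ("sensitivity", "specificity", "accuracy"):
            hr_vals = [
                per_reader_metric[("HR", r)][metric] for r in readers
                if per_reader_metric[("HR", r)][metric] is not None
            ]
            sr_vals = [
                per_reader_metric[("SR", r)][metric] for r in readers
                if per_reader_metric[("SR", r)][metric] is not None
            ]
            if len(hr_vals) >= 2 and len(sr_vals) >= 2:
                t, df, p = unpaired_t_test(hr_vals, sr_vals)
                t_tests[metric] = {"t": t, "df": df, "p": p}
            else:
                t_tests[metric] = None

    return {
        "per_reader": per_reader,
        "pooled": pooled,
        "t_tests": t_tests,
        "notice": notice,
        "high_confidence_fraction": {
            c: (float(np.mean(v)) if v else None) for c, v in hc_frac.items()
        },
    }


def read_responses_csv(path) -> list[ReaderResponse]:
    """Read responses from CSV with columns reader_id, image_id, condition,
    call, confidence."""
    df = pd.read_csv(path, dtype=str)
    return [
        ReaderResponse(
            reader_id=row.reader_id, image_id=row.image_id,
            condition=row.condition, call=row.call,
            confidence=row.confidence,
        )
        for row in df.itertuples()
    ]


def read_gold_csv(path) -> list[GoldLabel]:
    """Read gold labels from CSV with columns image_id, truth."""
    df = pd.read_csv(path, dtype=str)
    return [
        GoldLabel(image_id=row.image_id, truth=row.truth)
        for row in df.itertuples()
    ]


def demo_gold_labels(
    n: int = 120, neoplastic: int = 78, seed: int = 0
) -> list[GoldLabel]:
    """A demonstration gold-standard set: 78/120 neoplastic by default,
    matching the published reader-study class mix, in seeded shuffled
    order."""
    if not 0 <= neoplastic <= n:
        raise ValueError("neoplastic count must lie in [0, n]")
    truths = [POSITIVE] * neoplastic + [NEGATIVE] * (n - neoplastic)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [
        GoldLabel(image_id=f"img_{i:04d}", truth=truths[j])
        for i, j in enumerate(order)
    ]


def simulate_reader_responses(
    gold: list[GoldLabel],
    reader_ids: list[str],
    accuracy: float = 0.70,
    high_conf_rate: float = 0.5,
    conditions: tuple[str, ...] = _CONDITIONS,
    seed: int = 0,
) -> list[ReaderResponse]:
    """Synthetic reader responses with a target per-call accuracy.

    Each call independently agrees with the gold label with probability
    ``accuracy`` and is flagged high-confidence with probability
    ``high_conf_rate``; a convenience for exercising the report pipeline.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for cond in conditions:
        for reader in reader_ids:
            for g in gold:
                correct = rng.random() < accuracy
                call = g.truth if correct else (
                    NEGATIVE if g.truth == POSITIVE else POSITIVE
                )
                conf = "high" if rng.random() < high_conf_rate else "low"
                out.append(
                    ReaderResponse(
                        reader_id=reader, image_id=g.image_id,
                        condition=cond, call=call, confidence=conf,
                    )
                )
    return out
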