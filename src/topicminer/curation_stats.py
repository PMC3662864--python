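"""Evaluation statistics for curated interaction data.

Covers the metrics used to validate a literature-derived interaction
catalogue: confusion-matrix metrics for the extraction components,
two-annotator Cohen's kappa for curation quality, Fisher's exact test for
gold-gene-set enrichment, precision stratified by extractor confidence and
document count, a binomial-GLM (logit link) triage model of curated
correctness on extractor confidence, and the top-k mention precision used to
gauge how many mentions a curator must read per group.

All percentage outputs are full precision; rounding is a presentation
concern.  Metrics whose denominators are unavailable are reported as None
(absent), never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "CurationRecord",
    "AgreementCounts",
    "confusion_metrics",
    "cohens_kappa",
    "fisher_enrichment",
    "gene_set_table",
    "precision_by_strata",
    "fit_triage_model",
    "top_mentions_precision",
    "TriageFitError",
    "load_curation_records",
]

#: Smallest p-value reported numerically; below this the text form is "<2.2e-16".
P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fp/tn/fn counts; tn and fn may be absent (None) when the evaluation
    design cannot observe them."""

    tp: int = 0
    fp: int = 0
    tn: int | None = None
    fn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CurationRecord:
    """A grouped interaction's curated label plus triage covariates."""

    signature: str
    label: str  # "tp" | "fp"
    confidence: float
    doc_count: int = 1

    def __post_init__(self) -> None:
        if self.label not in ("tp", "fp"):
            raise ValueError(f"label must be 'tp' or 'fp', got {self.label!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0,1]")
        if self.doc_count < 1:
            raise ValueError("doc_count must be >= 1")


@dataclass(frozen=True)
class AgreementCounts:
    """Label marginals of two curation rounds over the same items."""

    before: tuple[int, int]  # (tp, fp) of the original round
    after: tuple[int, int]   # (tp, fp) of the re-curation round
    agreed: int
    disagreed: int

    def __post_init__(self) -> None:
        total = self.agreed + self.disagreed
        if sum(self.before) != total or sum(self.after) != total:
            raise ValueError(
                "before/after marginals must each sum to agreed + disagreed"
            )


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Precision, recall, F score, accuracy and true-negative rate (percent).

    Metrics whose denominators are zero or whose inputs are absent come back
    as None.
    """
    def ratio(num: int, den: int | None) -> float | None:
        if den is None or den == 0:
            return None
        return 100.0 * num / den

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn) if c.fn is not None else None
    f_score = None
    if precision is not None and recall is not None and precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    accuracy = None
    if c.tn is not None and c.fn is not None:
        accuracy = ratio(c.tp + c.tn, c.tp + c.fp + c.tn + c.fn)
    tn_rate = ratio(c.tn, (c.tn + c.fp) if c.tn is not None else None) \
        if c.tn is not None else None
    return {
        "precision": precision,
        "recall": recall,
        "f_score": f_score,
        "accuracy": accuracy,
        "tn_rate": tn_rate,
    }


def cohens_kappa(a: AgreementCounts) -> dict[str, float]:
    """Two-category Cohen's kappa from round marginals.

    p_a = agreed/total; p_e = p(tp before)p(tp after) + p(fp before)p(fp after);
    kappa = (p_a - p_e) / (1 - p_e).  p_e == 1 (degenerate marginals) is an
    error because kappa is then undefined.
    """
    total = a.agreed + a.disagreed
    if total == 0:
        raise ValueError("no items")
    p_a = a.agreed / total
    p_e = (a.before[0] / total) * (a.after[0] / total) + \
          (a.before[1] / total) * (a.after[1] / total)
    if p_e >= 1.0:
        raise ZeroDivisionError("expected agreement p_e == 1; kappa undefined")
    return {"p_a": p_a, "p_e": p_e, "kappa": (p_a - p_e) / (1.0 - p_e)}


def fisher_enrichment(a: int, b: int, c: int, d: int) -> dict:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns the sample odds ratio (a*d)/(b*c) -- "inf"/0 reported when a
    margin cell is zero -- the two-sided exact p-value, and a display string
    that switches to "<2.2e-16" when the p underflows the double floor.
    The conditional-MLE odds ratio is included for small tables.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"count {name} must be non-negative")
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if b * c == 0:
        odds_ratio: float = math.nan if a * d == 0 else math.inf
    else:
        odds_ratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    p = float(p)
    p_text = f"{p:.4g}" if p >= P_FLOOR else "<2.2e-16"
    cmle = None
    if a + b + c + d <= 10_000:
        cmle = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    return {
        "odds_ratio": odds_ratio,
        "odds_ratio_cmle": cmle,
        "p_value": max(p, 0.0),
        "p_text": p_text,
    }


def gene_set_table(
    chains_focus: Sequence,
    chains_background: Sequence,
    gene_set: set[int],
) -> dict:
    """2x2 gold-gene enrichment table over mention-level event chains.

    A chain "mentions a gold gene" iff any participant's Entrez ID is in the
    set.  Accepts either EventChainMention objects or pre-extracted iterables
    of Entrez IDs per chain.  Returns the table cells, per-corpus percentages
    and the Fisher enrichment result.
    """
    from .events import EventChainMention, iter_participants

    def hits(chains: Sequence) -> tuple[int, int]:
        n_hit = 0
        n_total = 0
        for chain in chains:
            if isinstance(chain, EventChainMention):
                ids = {p.entrez_id for p in iter_participants(chain.root)
                       if p.entrez_id is not None}
            else:
                ids = set(chain)
            n_total += 1
            if ids & gene_set:
                n_hit += 1
        return n_hit, n_total

    a, n_f = hits(chains_focus)
    c, n_b = hits(chains_background)
    b, d = n_f - a, n_b - c
    return {
        "table": (a, b, c, d),
        "pct_focus": 100.0 * a / n_f if n_f else 0.0,
        "pct_background": 100.0 * c / n_b if n_b else 0.0,
        "fisher": fisher_enrichment(a, b, c, d) if min(n_f, n_b) > 0 else None,
    }


def _precision(records: Sequence[CurationRecord]) -> float | None:
    if not records:
        return None
    tp = sum(1 for r in records if r.label == "tp")
    return 100.0 * tp / len(records)


def precision_by_strata(
    records: Sequence[CurationRecord], confidence_cutoff: float = 0.5
) -> dict[str, float | None]:
    """Curation precision overall and within confidence / document strata."""
    if not records:
        raise ValueError("no curation records")
    return {
        "overall": _precision(records),
        "above_cutoff": _precision([r for r in records if r.confidence > confidence_cutoff]),
        "below_cutoff": _precision([r for r in records if r.confidence <= confidence_cutoff]),
        "multi_doc": _precision([r for r in records if r.doc_count > 1]),
        "single_doc": _precision([r for r in records if r.doc_count == 1]),
    }


def load_curation_records(path) -> list[CurationRecord]:
    """Read curation labels from TSV (signature, label, confidence, doc_count)."""
    import csv

    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                CurationRecord(
                    signature=row["signature"],
                    label=row["label"],
                    confidence=float(row["confidence"]),
                    doc_count=int(row.get("doc_count", 1)),
                )
            )
    return records


class TriageFitError(RuntimeError):
    """The logistic triage model could not be fit meaningfully."""


def fit_triage_model(records: Sequence[CurationRecord]) -> dict:
    """Binomial GLM (logit link) of curated correctness on extractor confidence.

    Returns intercept, slope, the confidence threshold at which the predicted
    probability of being a true positive crosses 0.5 (None when the slope is
    not positive or not distinguishable from zero), and per-record fitted
    probabilities.  Single-label input and complete separation raise
    :class:`TriageFitError` -- never a silent fit.
    """
    import statsmodels.api as sm

    y = np.array([1.0 if r.label == "tp" else 0.0 for r in records])
    x = np.array([r.confidence for r in records])
    if len(set(y)) < 2:
        raise TriageFitError("both labels must be present to fit the triage model")
    # complete separation: some confidence value splits the labels perfectly
    if x[y == 1].min() > x[y == 0].max() or x[y == 0].min() > x[y == 1].max():
        raise TriageFitError("labels are completely separated by confidence")
    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        fit = model.fit()
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise TriageFitError(f"GLM fit failed: {exc}") from exc
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    slope_se = float(fit.bse[1])
    slope_significant = slope_se > 0 and abs(slope / slope_se) > 1.959963984540054
    threshold = -intercept / slope if slope > 0 and slope_significant else None
    return {
        "intercept": intercept,
        "slope": slope,
        "slope_se": slope_se,
        "threshold": threshold,
        "probabilities": np.asarray(fit.fittedvalues),
    }


def top_mentions_precision(
    groups: Sequence[tuple[Sequence[tuple[float, bool]], ...]] | Sequence,
    k: int = 5,
) -> dict:
    """Mean number of correct mentions among the k highest-confidence mentions.

    Each group is a sequence of (confidence, correct) pairs for its labeled
    mentions.  Groups with fewer than k labeled mentions are excluded (and
    counted in the report).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    per_group: list[int] = []
    excluded = 0
    for mentions in groups:
        pairs = list(mentions)
        if len(pairs) < k:
            excluded += 1
            continue
        top = sorted(pairs, key=lambda p: -p[0])[:k]
        per_group.append(sum(1 for _, correct in top if correct))
    mean = float(np.mean(per_group)) if per_group else None
    return {
        "mean_correct": mean,
        "n_groups": len(per_group),
        "excluded": excluded,
        "total_correct": int(np.sum(per_group)) if per_group else 0,
    }
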