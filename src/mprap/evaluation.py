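"""Evaluation: confusion metrics, region-stratified reports, structure QA
and interface detection.

Buried is the positive class throughout: a buried residue predicted buried
is a true positive, predicted exposed a false negative; an exposed residue
predicted exposed is a true negative, predicted buried a false positive.
Binary quality is summarised by accuracy, sensitivity (buried recall),
specificity and the Matthews correlation coefficient (MCC); real-valued
predictions additionally by mean absolute error (percent RSA) and the
Pearson correlation coefficient.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accessibility import BurialState
from .errors import DomainError, MissingDataError
from .structio import Region, classify_region

QA_SUSPICION_MCC = 0.3  # between known-bad (<=0.26) and known-good (>=0.64)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float


def _as_buried_bool(states) -> np.ndarray:
    out = np.empty(len(states), dtype=bool)
    for i, s in enumerate(states):
        v = s.value if isinstance(s, BurialState) else str(s)
        if v not in ("buried", "exposed"):
            raise DomainError(f"state must be buried/exposed, got {v!r}")
        out[i] = v == "buried"
    return out


def confusion(pred_states, true_states) -> ConfusionCounts:
    """Tally predictions against truth with buried as positive."""
    if len(pred_states) != len(true_states):
        raise DomainError("prediction/truth length mismatch")
    p = _as_buried_bool(pred_states)
    t = _as_buried_bool(true_states)
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity, MCC from confusion counts.

    A zero denominator yields 0 (with a warning for sensitivity and
    specificity, where it means an empty truth class).
    """
    if c.total == 0:
        raise DomainError("cannot compute metrics on zero residues")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fn == 0:
        warnings.warn("no buried residues in truth; sensitivity undefined -> 0",
                      stacklevel=2)
        sensitivity = 0.0
    else:
        sensitivity = c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        warnings.warn("no exposed residues in truth; specificity undefined -> 0",
                      stacklevel=2)
        specificity = 0.0
    else:
        specificity = c.tn / (c.tn + c.fp)
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return Metrics(accuracy, sensitivity, specificity, mcc)


def real_metrics(pred_rsa, true_rsa) -> tuple[float, float]:
    """MAE (percent RSA) and Pearson correlation of real-valued output."""
    pred = np.asarray(pred_rsa, dtype=float)
    true = np.asarray(true_rsa, dtype=float)
    if len(pred) != len(true):
        raise DomainError("prediction/truth length mismatch")
    if len(pred) < 2:
        raise DomainError("need at least 2 residues for real-value metrics")
    if np.std(true) == 0:
        raise DomainError("truth has zero variance; Pearson Cc undefined")
    mae = float(np.abs(pred - true).mean())
    cc = float(stats.pearsonr(pred, true).statistic)
    return mae, cc


@dataclass
class StratumReport:
    n: int
    counts: ConfusionCounts | None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    mcc: float | None = None
    mae: float | None = None
    cc: float | None = None


@dataclass
class EvalReport:
    """Per-stratum and overall performance summary."""

    strata: dict = field(default_factory=dict)  # name -> StratumReport

    def to_json(self) -> str:
        payload = {}
        for name, s in self.strata.items():
            payload[name] = {
                "n": s.n,
                "counts": None if s.counts is None else vars(s.counts),
                "accuracy": s.accuracy, "sensitivity": s.sensitivity,
                "specificity": s.specificity, "mcc": s.mcc,
                "mae": s.mae, "cc": s.cc,
            }
        return json.dumps(payload, indent=2)

    def to_table(self) -> str:
        """Human-readable table, one column per membrane stratum."""
        order = [n for n in ("all", "core", "interface", "nonmembrane")
                 if n in self.strata]
        order += [n for n in self.strata if n not in order]
        lines = ["metric      " + "".join(f"{n:>14s}" for n in order)]
        for metric in ("n", "accuracy", "sensitivity", "specificity",
                       "mcc", "mae", "cc"):
            cells = []
            for name in order:
                v = getattr(self.strata[name], metric)
                if v is None:
                    cells.append(f"{'--':>14s}")
                elif metric == "n":
                    cells.append(f"{v:>14d}")
                else:
                    cells.append(f"{v:>14.3f}")
            lines.append(f"{metric:<12s}" + "".join(cells))
        return "\n".join(lines)


def _stratum(pred_states, true_states, pred_rsa, true_rsa, n) -> StratumReport:
    if n == 0:
        return StratumReport(n=0, counts=None)
    c = confusion(pred_states, true_states)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = metrics(c)
    rep = StratumReport(n=n, counts=c, accuracy=m.accuracy,
                        sensitivity=m.sensitivity,
                        specificity=m.specificity, mcc=m.mcc)
    if pred_rsa is not None and n >= 2 and np.std(true_rsa) > 0:
        rep.mae, rep.cc = real_metrics(pred_rsa, true_rsa)
    return rep


def stratified_report(pred_states, true_states, z=None,
                      pred_rsa=None, true_rsa=None) -> EvalReport:
    """Metrics overall and per membrane region (from |z|).

    Residues with missing z are kept in the "all" stratum but excluded
    from the regional ones.
    """
    n = len(pred_states)
    if len(true_states) != n or (z is not None and len(z) != n):
        raise DomainError("aligned inputs required")
    pred_states = list(pred_states)
    true_states = list(true_states)
    pr = None if pred_rsa is None else np.asarray(pred_rsa, float)
    tr = None if true_rsa is None else np.asarray(true_rsa, float)

    report = EvalReport()
    report.strata["all"] = _stratum(pred_states, true_states, pr, tr, n)
    if z is None:
        return report
    z = np.asarray(z, dtype=float)
    for region in Region:
        idx = [i for i in range(n)
               if np.isfinite(z[i]) and classify_region(z[i]) is region]
        report.strata[region.value] = _stratum(
            [pred_states[i] for i in idx], [true_states[i] for i in idx],
            None if pr is None else pr[idx],
            None if tr is None else tr[idx], len(idx))
    return report


@dataclass
class QaResult:
    accuracy: float
    mcc: float
    suspicious: bool
    n: int


def qa_structure(observed_states, predicted_states,
                 suspicion_mcc: float = QA_SUSPICION_MCC) -> QaResult:
    """Structure quality check: agreement between burial states derived
    from the structure and states predicted from sequence.

    Correct structures agree well with prediction; erroneous ones show
    near-random agreement, so a low MCC flags the model as suspicious.
    """
    c = confusion(predicted_states, observed_states)
    m = metrics(c)
    return QaResult(accuracy=m.accuracy, mcc=m.mcc,
                    suspicious=m.mcc < suspicion_mcc, n=c.total)


def interface_sweep(predicted_rsa, interface_truth,
                    cutoffs=None) -> pd.DataFrame:
    """Interface-detection trade-off among single-chain-exposed residues.

    For each predicted-RSA cutoff: the fraction of true interface residues
    predicted below it (detected), the fraction of non-interface residues
    above it (retained), and the precision among residues below it.
    Inputs must already be restricted to residues exposed in the single
    chain.
    """
    pred = np.asarray(predicted_rsa, dtype=float)
    truth = np.asarray(interface_truth, dtype=bool)
    if len(pred) != len(truth):
        raise DomainError("prediction/truth length mismatch")
    if truth.sum() == 0:
        raise MissingDataError("no interface residues in truth")
    if cutoffs is None:
        cutoffs = np.arange(0.0, 100.5, 2.5)
    rows = []
    n_if = truth.sum()
    n_not = (~truth).sum()
    for c in cutoffs:
        below = pred < c
        detected = (below & truth).sum() / n_if
        retained = ((~below) & (~truth)).sum() / n_not if n_not else np.nan
        precision = (truth[below].mean() if below.any() else np.nan)
        rows.append((float(c), float(detected), float(retained),
                     float(precision) if precision == precision else np.nan))
    return pd.DataFrame(rows, columns=["cutoff", "interface_fraction_below",
                                       "noninterface_fraction_above",
                                       "precision"])
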