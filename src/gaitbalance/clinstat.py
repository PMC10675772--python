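"""Discrete balance variables and between-group agreement statistics.

From each subject's normalized IA/RCIA curves, 48 discrete variables are
extracted: the value of each of the four curves (sagittal/frontal IA,
sagittal/frontal RCIA) at the four gait events (HS, CTO, CHS, TO), the
time-average of each curve over the four sub-phases (iDLS, SLS, tDLS, SW),
and the range (max - min) over the same sub-phases.  Numbering:

* 1-16   event values   (sag IA 1-4, fro IA 5-8, sag RCIA 9-12, fro RCIA 13-16)
* 17-32  sub-phase means (same plane/quantity blocks, iDLS/SLS/tDLS/SW)
* 33-48  sub-phase ranges

Between-group inference follows the matched-cohort protocol: per-subject
values are trial averages, groups are compared with pooled-variance
independent t-tests at alpha = 0.05 per variable (no multiplicity
correction by default), and effect sizes are absolute pooled-SD Cohen's d.
Model-vs-ground-truth agreement classifies each variable's significance
into true/false positives/negatives and summarizes sensitivity,
specificity, accuracy, and the Pearson correlation of the two 48-long
effect-size vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .balance import BalanceCurves, GaitEvents

__all__ = [
    "VARIABLE_INFO",
    "VariableTable",
    "GroupComparison",
    "AgreementReport",
    "extract_variables",
    "rmse_curves",
    "rrmse_curves",
    "cohens_d",
    "independent_t",
    "group_comparison",
    "agreement",
    "compare_models",
]

EVENTS = ("HS", "CTO", "CHS", "TO")
SUBPHASES = ("iDLS", "SLS", "tDLS", "SW")
_CURVES = (("sagittal", "IA"), ("frontal", "IA"),
           ("sagittal", "RCIA"), ("frontal", "RCIA"))


def _build_variable_info() -> pd.DataFrame:
    rows = []
    num = 1
    for kind, anchors in (("event", EVENTS), ("mean", SUBPHASES),
                          ("range", SUBPHASES)):
        for plane, quantity in _CURVES:
            for anchor in anchors:
                rows.append(dict(
                    number=num, plane=plane, quantity=quantity, kind=kind,
                    anchor=anchor, units="deg" if quantity == "IA" else "deg/s"))
                num += 1
    return pd.DataFrame(rows).set_index("number")


#: metadata for the 48 balance variables, indexed by variable number
VARIABLE_INFO = _build_variable_info()


def _event_grid_index(events: GaitEvents, name: str) -> int:
    pct = {"HS": 0.0, "CTO": events.cto_pct, "CHS": events.chs_pct,
           "TO": events.to_pct}[name]
    return int(round(pct))  # nearest 1 % grid point


def _window_slice(events: GaitEvents, name: str) -> slice:
    bounds = {"iDLS": (0.0, events.cto_pct),
              "SLS": (events.cto_pct, events.chs_pct),
              "tDLS": (events.chs_pct, events.to_pct),
              "SW": (events.to_pct, 100.0)}[name]
    lo, hi = int(round(bounds[0])), int(round(bounds[1]))
    if hi <= lo:
        raise ValueError(f"empty sub-phase window {name}: [{lo}, {hi}]")
    return slice(lo, hi + 1)


def extract_variables(curves: BalanceCurves, events: GaitEvents) -> np.ndarray:
    """The 48-vector of discrete balance variables for one cycle.

    Event values are read at the nearest 1 % grid point; sub-phase averages
    and ranges use the inclusive grid window between the bounding events.
    """
    if not (0 < events.cto_pct < events.chs_pct < events.to_pct < 100):
        raise ValueError("event percents must be strictly inside (0, 100)")
    series = {("sagittal", "IA"): curves.sagittal_ia,
              ("frontal", "IA"): curves.frontal_ia,
              ("sagittal", "RCIA"): curves.sagittal_rcia,
              ("frontal", "RCIA"): curves.frontal_rcia}
    out = np.empty(48)
    for num, row in VARIABLE_INFO.iterrows():
        y = series[(row.plane, row.quantity)]
        if row.kind == "event":
            out[num - 1] = y[_event_grid_index(events, row.anchor)]
        else:
            w = y[_window_slice(events, row.anchor)]
            out[num - 1] = w.mean() if row.kind == "mean" else w.max() - w.min()
    return out


@dataclass
class VariableTable:
    """Per-subject 48-variable values (trial-averaged), with group labels."""

    values: pd.DataFrame  # index: subject_id, columns: 1..48
    groups: pd.Series     # subject_id -> 'old' | 'young'

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(range(1, 49)):
            raise ValueError("columns must be variable numbers 1..48")
        if not self.values.index.equals(self.groups.index):
            raise ValueError("values and groups must share the subject index")

    @classmethod
    def from_subject_curves(
        cls,
        per_subject: dict[str, tuple[str, list[tuple[BalanceCurves, GaitEvents]]]],
    ) -> "VariableTable":
        """Build from {subject: (group, [(curves, events) per trial])}.

        Per-subject values are means across that subject's trials.
        """
        rows, groups = {}, {}
        for sid, (group, trials) in per_subject.items():
            vals = np.mean([extract_variables(c, e) for c, e in trials], axis=0)
            rows[sid] = vals
            groups[sid] = group
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=range(1, 49))
        return cls(values=df, groups=pd.Series(groups))

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values.loc[self.groups == group]


# ---------------------------------------------------------------------------
# curve error metrics
# ---------------------------------------------------------------------------

def rmse_curves(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-plane RMSE over the 101-point cycle; shapes (2, 101)."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    return np.sqrt(np.mean((pred - truth) ** 2, axis=-1))


def rrmse_curves(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Relative RMSE: 100 * RMSE / (max - min) of the ground-truth curve."""
    truth = np.asarray(truth, float)
    rng = truth.max(axis=-1) - truth.min(axis=-1)
    if np.any(rng <= 0):
        raise ValueError("rRMSE undefined for a flat ground-truth curve")
    return 100.0 * rmse_curves(pred, truth) / rng


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def cohens_d(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Absolute pooled-SD Cohen's d between two groups.

    pooled SD = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)), which
    reduces to sqrt((s1^2 + s2^2) / 2) for equal group sizes.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    return float(abs(m1 - m2) / pooled)


def independent_t(
    group1: np.ndarray | tuple[float, float, int],
    group2: np.ndarray | tuple[float, float, int],
) -> tuple[float, float]:
    """Pooled-variance Student t-test, two-sided.

    Each group is either a sample array or summary statistics
    ``(mean, sd, n)``; both paths agree.  Degenerate zero-variance input
    with equal means returns (0, 1).
    """
    def summarize(g):
        if isinstance(g, tuple):
            return float(g[0]), float(g[1]), int(g[2])
        a = np.asarray(g, float)
        return a.mean(), a.std(ddof=1), len(a)

    m1, s1, n1 = summarize(group1)
    m2, s2, n2 = summarize(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    if sp2 == 0:
        if m1 == m2:
            return 0.0, 1.0
        return float(np.sign(m1 - m2) * np.inf), 0.0
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass
class GroupComparison:
    """Per-variable between-group statistics (old vs young)."""

    table: pd.DataFrame  # index 1..48: old_mean, old_sd, young_mean, young_sd,
                         # t, p, d, significant
    alpha: float = 0.05

    @property
    def significant(self) -> pd.Series:
        return self.table["significant"]

    @property
    def effect_sizes(self) -> pd.Series:
        return self.table["d"]


def group_comparison(
    table: VariableTable,
    alpha: float = 0.05,
    correction: str | None = None,
) -> GroupComparison:
    """Independent t-test and Cohen's d for each of the 48 variables.

    ``correction="bonferroni"`` divides alpha by 48; the default (None)
    applies alpha per test, replicating the uncorrected published protocol.
    """
    old = table.group_values("old")
    young = table.group_values("young")
    rows = []
    thr = alpha / 48 if correction == "bonferroni" else alpha
    for num in range(1, 49):
        a, b = old[num].to_numpy(), young[num].to_numpy()
        t, p = independent_t(a, b)
        d = cohens_d(a.mean(), a.std(ddof=1), len(a),
                     b.mean(), b.std(ddof=1), len(b))
        rows.append(dict(number=num, old_mean=a.mean(), old_sd=a.std(ddof=1),
                         young_mean=b.mean(), young_sd=b.std(ddof=1),
                         t=t, p=p, d=d, significant=p < thr))
    df = pd.DataFrame(rows).set_index("number")
    return GroupComparison(table=df, alpha=alpha)


@dataclass
class AgreementReport:
    """Model-vs-ground-truth agreement on between-group significance."""

    false_negatives: list[int]
    false_positives: list[int]
    n_positives: int
    n_negatives: int
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    pearson_r_effect_sizes: float

    def to_dict(self) -> dict:
        return {
            "false_negatives": self.false_negatives,
            "false_positives": self.false_positives,
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "pearson_r_effect_sizes": self.pearson_r_effect_sizes,
        }


def agreement(
    model_cmp: GroupComparison,
    truth_cmp: GroupComparison,
) -> AgreementReport:
    """Classify each variable's significance (model vs ground truth).

    Positives are the variables significant in the ground truth; a false
    negative is a positive the model comparison misses, a false positive a
    ground-truth-negative the model flags.  Sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), accuracy = (TP+TN)/48, all in percent, and
    Pearson's r between the two 48-long effect-size vectors.
    """
    if not model_cmp.table.index.equals(truth_cmp.table.index):
        raise ValueError("variable sets differ between comparisons")
    truth_sig = truth_cmp.significant
    model_sig = model_cmp.significant
    positives = truth_sig[truth_sig].index
    negatives = truth_sig[~truth_sig].index
    fn = [int(v) for v in positives if not model_sig[v]]
    fp = [int(v) for v in negatives if model_sig[v]]
    tp = len(positives) - len(fn)
    tn = len(negatives) - len(fp)
    sens = 100.0 * tp / len(positives) if len(positives) else 100.0
    spec = 100.0 * tn / len(negatives) if len(negatives) else 100.0
    acc = 100.0 * (tp + tn) / len(truth_sig)
    d_model = np.asarray(model_cmp.effect_sizes, float)
    d_truth = np.asarray(truth_cmp.effect_sizes, float)
    if d_model.std() == 0 or d_truth.std() == 0:
        r = float("nan")  # correlation undefined for a constant vector
    else:
        r = float(np.corrcoef(d_model, d_truth)[0, 1])
    return AgreementReport(
        false_negatives=fn, false_positives=fp,
        n_positives=len(positives), n_negatives=len(negatives),
        sensitivity_pct=sens, specificity_pct=spec, accuracy_pct=acc,
        pearson_r_effect_sizes=r)


def agreement_from_counts(
    n_false_negative: int, n_positives: int,
    n_false_positive: int, n_negatives: int,
) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %) from confusion counts."""
    tp = n_positives - n_false_negative
    tn = n_negatives - n_false_positive
    sens = 100.0 * tp / n_positives if n_positives else 100.0
    spec = 100.0 * tn / n_negatives if n_negatives else 100.0
    acc = 100.0 * (tp + tn) / (n_positives + n_negatives)
    return sens, spec, acc


def compare_models(
    rmse_a: np.ndarray,
    rmse_b: np.ndarray,
) -> tuple[float, float]:
    """Paired two-sided t-test on per-subject RMSE vectors of two pipelines."""
    a = np.asarray(rmse_a, float)
    b = np.asarray(rmse_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length paired vectors")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
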