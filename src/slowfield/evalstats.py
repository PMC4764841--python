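"""Exact statistics for closed-loop performance tables.

The selectivity of onset detection and of movement-type inference is tested
with a one-tailed Fisher exact test on a 2x2 contingency table: the p-value
is the upper hypergeometric tail P(X >= a) under fixed margins, i.e. the
probability of an association at least as positive as observed.  Accuracy
is the diagonal fraction (a + d) / N in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells with the fixed role mapping row=condition, column=outcome.

    For type decoding: a=grasp/grasp, b=grasp/open, c=open/grasp,
    d=open/open.  For onset selectivity: a=TP, b=FP, c=FN, d=TN.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("cells must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_one_tailed(t: ContingencyTable2x2) -> float:
    """One-sided (positive association) Fisher exact p-value.

    p = sum_{k >= a} P_hypergeom(k | margins): the chance of drawing at
    least ``a`` first-row successes when ``a+c`` successes are allocated at
    random among ``N`` observations with ``a+b`` in the first row.
    """
    if t.n < 1:
        raise ValueError("table must contain at least one observation")
    return float(hypergeom.sf(t.a - 1, t.n, t.a + t.b, t.a + t.c))


def contingency_accuracy(t: ContingencyTable2x2) -> float:
    """Diagonal percent agreement, 100 (a + d) / N."""
    if t.n < 1:
        raise ValueError("table must contain at least one observation")
    return 100.0 * (t.a + t.d) / t.n


def type_table_from_log_score(score: dict) -> ContingencyTable2x2:
    """Movement-type contingency from ``movement_type_accuracy`` output."""
    from .simulate import GRASP, OPEN

    c = score["contingency"]
    return ContingencyTable2x2(
        a=c[(GRASP, GRASP)], b=c[(GRASP, OPEN)],
        c=c[(OPEN, GRASP)], d=c[(OPEN, OPEN)],
    )


def onset_table_from_counts(counts: dict) -> ContingencyTable2x2:
    """TP/FP/FN/TN counts from ``classify_sections`` as a 2x2 table."""
    return ContingencyTable2x2(
        a=counts["TP"], b=counts["FP"], c=counts["FN"], d=counts["TN"])


def build_report(scored_logs: dict) -> dict:
    """Assemble the two closed-loop summary tables.

    ``scored_logs`` maps subject id to a dict with keys ``type_score``
    (from movement_type_accuracy) and ``section_counts`` (from
    classify_sections).  Returns two DataFrames mirroring the published
    layouts: per-subject movement-type decoding (accuracy, four cells, p)
    and onset selectivity (accuracy, TP, FP, FN, TN, p).
    """
    type_rows, onset_rows = [], []
    for subject, scored in scored_logs.items():
        ts = scored["type_score"]
        tt = type_table_from_log_score(ts)
        if tt.n > 0:
            t_acc = round(contingency_accuracy(tt), 1)
            t_p = round(fisher_exact_one_tailed(tt), 3)
        else:
            t_acc, t_p = None, None
        type_rows.append({
            "subject": subject, "accuracy_percent": t_acc,
            "grasp_grasp": tt.a, "grasp_open": tt.b,
            "open_grasp": tt.c, "open_open": tt.d, "p": t_p,
        })
        ot = onset_table_from_counts(scored["section_counts"])
        onset_rows.append({
            "subject": subject,
            "accuracy_percent": round(contingency_accuracy(ot), 1),
            "TP": ot.a, "FP": ot.b, "FN": ot.c, "TN": ot.d,
            "p": round(fisher_exact_one_tailed(ot), 3),
        })
    type_cols = ["subject", "accuracy_percent", "grasp_grasp", "grasp_open",
                 "open_grasp", "open_open", "p"]
    onset_cols = ["subject", "accuracy_percent", "TP", "FP", "FN", "TN", "p"]
    return {
        "movement_type": pd.DataFrame(type_rows, columns=type_cols),
        "onset_selectivity": pd.DataFrame(onset_rows, columns=onset_cols),
    }
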