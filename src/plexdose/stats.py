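"""Cohort statistics and qPCR confirmation math.

* Fisher's exact test on 2x2 tables (two-sided by point-probability
  summation, plus one-sided variants) for carrier-frequency enrichment
  between phenotype groups.
* Group frequency tables (n, carriers, percent).
* Relative quantification of qPCR cycle thresholds by the 2^-ddCT method,
  converting target-vs-housekeeping CT differences between a case and a
  calibrator into an absolute copy-number estimate: N = 2 * 2^-ddCT, with
  N < 1.5 called deletion and N > 2.5 duplication.
* Sensitivity/specificity scoring of predicted carrier status against a
  simulation truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import round_half_away

#: relative slack on the "at most as probable as observed" comparison in the
#: two-sided summation, guarding against floating-point ties
_TWO_SIDED_REL_TOL = 1e-7

DELETION_MAX_COPIES = 1.5
DUPLICATION_MIN_COPIES = 2.5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = carrier/non-carrier."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValueError(f"count {name} must be a non-negative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


TableLike = Union[ContingencyTable2x2, Sequence[Sequence[int]]]


def _as_table(table: TableLike) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    (a, b), (c, d) = table
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def fisher_exact(table: TableLike, sided: str = "two-sided") -> float:
    """Fisher's exact test P value for a 2x2 table.

    With margins fixed, the count ``a`` follows a hypergeometric
    distribution.  The two-sided P sums the probabilities of all tables at
    most as probable as the observed one (with a small relative slack on the
    comparison); ``greater``/``less`` sum the upper/lower tail in ``a``.
    """
    t = _as_table(table)
    row1 = t.a + t.b
    col1 = t.a + t.c
    total = t.total
    # support of a given the margins
    k_min = max(0, col1 - (total - row1))
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    logpmf = sps.hypergeom.logpmf(support, total, col1, row1)
    log_obs = sps.hypergeom.logpmf(t.a, total, col1, row1)

    if sided in ("two-sided", "two"):
        keep = logpmf <= log_obs + math.log1p(_TWO_SIDED_REL_TOL)
        p = float(np.exp(logpmf[keep]).sum())
    elif sided == "greater":
        p = float(np.exp(logpmf[support >= t.a]).sum())
    elif sided == "less":
        p = float(np.exp(logpmf[support <= t.a]).sum())
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    if p > 1.0 - 1e-12:  # full-mass sums accumulate rounding; the exact answer is 1
        p = 1.0
    return max(p, math.ulp(0.0))


def group_frequency_table(carriers: Union[Mapping[str, bool], pd.Series],
                          groups: Union[Mapping[str, object], pd.Series]
                          ) -> pd.DataFrame:
    """Carrier frequency per phenotype group.

    ``carriers`` maps sample id -> carrier flag (non-"normal" labels also
    accepted); ``groups`` maps sample id -> group label.  Every sample must
    have a group.  Percent is 100 * carriers / n, rounded half away from
    zero to one decimal.
    """
    carriers = pd.Series(dict(carriers) if not isinstance(carriers, pd.Series)
                         else carriers)
    if carriers.dtype == object:
        carriers = carriers.map(lambda v: bool(v) if isinstance(v, (bool, np.bool_))
                                else str(v) != "normal")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = set(carriers.index) - set(groups.index)
    if missing:
        raise ValueError(f"no group for sample(s): {', '.join(sorted(map(str, missing)))}")

    rows = []
    for label in dict.fromkeys(groups.loc[carriers.index]):
        ids = [s for s in carriers.index if groups[s] == label]
        n = len(ids)
        k = int(carriers.loc[ids].sum())
        rows.append({"group": label, "n": n, "carriers": k,
                     "percent": round_half_away(100.0 * k / n, 1) if n else 0.0})
    return pd.DataFrame(rows, columns=["group", "n", "carriers", "percent"])


@dataclass(frozen=True)
class DdctResult:
    """Outcome of a 2^-ddCT relative-quantification comparison."""

    ddct: float               # cycles
    relative_quantity: float  # 2^-ddct, case vs calibrator
    copy_number: float        # 2 * relative_quantity (calibrator assumed diploid)
    classification: str       # deletion | normal | duplication


def ddct_copy_number(ct_target_case: float, ct_ref_case: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> DdctResult:
    """Copy number from qPCR cycle thresholds by the 2^-ddCT method.

    ddCT = (CT_target - CT_housekeeping) in the case minus the same
    difference in the calibrator.  One extra cycle (ddCT = +1) halves the
    relative quantity, i.e. a heterozygous deletion (N = 1).
    """
    values = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(v) for v in values):
        raise ValueError("CT values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    rq = 2.0 ** (-ddct)
    copies = 2.0 * rq
    if copies < DELETION_MAX_COPIES:
        cls = "deletion"
    elif copies > DUPLICATION_MIN_COPIES:
        cls = "duplication"
    else:
        cls = "normal"
    return DdctResult(ddct=ddct, relative_quantity=rq,
                      copy_number=copies, classification=cls)


def _carrier_map(values: Union[Mapping[str, object], pd.Series]) -> pd.Series:
    series = pd.Series(dict(values) if not isinstance(values, pd.Series) else values)
    return series.map(lambda v: bool(v) if isinstance(v, (bool, np.bool_))
                      else str(v) != "normal")


def sensitivity_specificity(predicted: Union[Mapping[str, object], pd.Series],
                            truth: Union[Mapping[str, object], pd.Series]
                            ) -> tuple[float, float]:
    """Carrier-level sensitivity and specificity, in percent.

    Both arguments map sample id -> carrier flag or class label (any label
    other than ``"normal"`` counts as carrier).  The sample sets must match
    exactly.
    """
    pred = _carrier_map(predicted)
    true = _carrier_map(truth)
    if set(pred.index) != set(true.index):
        raise ValueError("predicted and truth sample sets differ")
    pred = pred.reindex(true.index)
    tp = int((pred & true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    fp = int((pred & ~true).sum())
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec
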