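"""Assay reproducibility QC: per-probe coefficient of variation.

The assay's variability metric is CV = standard deviation / mean of the
normalized dosage ratio, computed per probe within groups of samples that
share a known copy state (mixing 2-copy and 1-copy samples would inflate the
CV mechanically).  A probe passes when its CV is at or below the threshold
(default 0.1) in every group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import pandas as pd

from ._util import atomic_write
from .normalize import RatioMatrix

DEFAULT_CV_THRESHOLD = 0.1

QC_COLUMNS = ["probe_id", "group", "n", "mean", "sd", "cv", "pass"]


@dataclass
class QcReport:
    """Per-(probe, group) CV table plus warnings for unusable groups."""

    table: pd.DataFrame            # columns QC_COLUMNS
    cv_threshold: float = DEFAULT_CV_THRESHOLD
    warnings: list[str] = field(default_factory=list)

    @property
    def max_cv(self) -> float:
        return float(self.table["cv"].max())

    @property
    def flagged_probes(self) -> list[str]:
        """Probes whose CV exceeds the threshold in at least one group."""
        bad = self.table.loc[~self.table["pass"], "probe_id"]
        return sorted(bad.unique())

    @property
    def all_pass(self) -> bool:
        return bool(self.table["pass"].all())

    def to_tsv(self, path) -> None:
        with atomic_write(path) as handle:
            self.table.to_csv(handle, sep="\t", index=False, float_format="%.6g")


def probe_cv(ratios: Union[RatioMatrix, pd.DataFrame],
             groups: Mapping[str, object] | pd.Series,
             cv_threshold: float = DEFAULT_CV_THRESHOLD) -> QcReport:
    """Per-probe CV of the dosage ratio within copy-state groups.

    ``groups`` maps each sample id to a group label (typically the known copy
    state or CNV class).  Within each group the sample standard deviation
    (n-1 denominator) is divided by the mean, per probe, over non-missing
    ratios; groups with fewer than two samples are skipped with a warning.
    """
    matrix = ratios.ratios if isinstance(ratios, RatioMatrix) else ratios
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = set(matrix.index) - set(groups.index)
    if missing:
        raise ValueError(f"no group for sample(s): {', '.join(sorted(map(str, missing)))}")

    rows = []
    warnings: list[str] = []
    for label, sample_ids in groups.groupby(groups).groups.items():
        sample_ids = [s for s in sample_ids if s in matrix.index]
        if len(sample_ids) < 2:
            warnings.append(f"group {label!r} has {len(sample_ids)} sample(s); skipped")
            continue
        sub = matrix.loc[sample_ids]
        n = sub.notna().sum(axis=0)
        mean = sub.mean(axis=0, skipna=True)
        sd = sub.std(axis=0, ddof=1, skipna=True)
        cv = sd / mean
        for pid in matrix.columns:
            if n[pid] < 2:
                continue
            rows.append({
                "probe_id": pid, "group": label, "n": int(n[pid]),
                "mean": float(mean[pid]), "sd": float(sd[pid]),
                "cv": float(cv[pid]),
                # tiny relative slack so a CV of exactly the threshold passes
                # despite floating-point accumulation
                "pass": bool(cv[pid] <= cv_threshold * (1 + 1e-9)),
            })

    table = pd.DataFrame(rows, columns=QC_COLUMNS)
    return QcReport(table=table, cv_threshold=cv_threshold, warnings=warnings)
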