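"""Raw peak areas -> dosage ratios.

Two-stage normalization, the standard practice for ligation-probe assays:

1. *Intra-sample scaling.*  Total fluorescence varies per sample (DNA input,
   ligation and PCR efficiency), so every area is divided by the sample's
   normalization factor — the median area of its reference probes, which
   target copy-stable loci.  The median is robust to a CNV overlapping a
   reference probe or to a probe dropout.

2. *Per-probe baseline.*  Probes differ in intrinsic efficiency, so each
   scaled value is divided by that probe's baseline — the median scaled value
   over a control cohort (``controls="self"`` uses the whole batch, valid
   whenever fewer than half the samples are aberrant at any one probe).

The resulting dosage ratio has diploid expectation 1.0; a heterozygous
deletion gives ~0.5, a single-copy gain ~1.5.  Missing cells propagate as
missing ratios and are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .panel import ProbePanel
from .signals_io import PeakTable

#: minimum usable reference probes for a per-sample factor
MIN_REFERENCES = 3
#: minimum batch size for self-normalization (controls="self")
MIN_SELF_BATCH = 8


class ConfigError(ValueError):
    """Raised on an unusable normalization configuration (e.g. empty controls)."""


class InsufficientReferencesError(ValueError):
    """Raised when a sample has too few reference-probe signals to scale."""


@dataclass
class RatioMatrix:
    """Samples x probes dosage ratios plus the normalization book-keeping."""

    ratios: pd.DataFrame          # diploid expectation 1.0; NaN = missing
    scaled: pd.DataFrame          # areas after intra-sample scaling
    sample_factor: pd.Series      # per-sample normalization factor
    baseline: pd.Series           # per-probe control baseline
    control_ids: tuple[str, ...]
    failed: dict[str, str] = field(default_factory=dict)  # sample -> reason

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratios.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.ratios.columns)


def normalize_sample(areas: pd.Series, panel: ProbePanel,
                     min_references: int = MIN_REFERENCES
                     ) -> tuple[pd.Series, float]:
    """Scale one sample's areas by the median of its reference-probe areas.

    Returns ``(scaled_areas, factor)``.  Raises
    :class:`InsufficientReferencesError` when fewer than ``min_references``
    reference probes carry signal, in which case the sample cannot be
    normalized and should be flagged failed.
    """
    ref_ids = [p.probe_id for p in panel.references]
    ref_vals = areas.reindex(ref_ids).dropna()
    if len(ref_vals) < min_references:
        raise InsufficientReferencesError(
            f"insufficient references: {len(ref_vals)} usable of "
            f"{len(ref_ids)} (need >= {min_references})")
    factor = float(np.median(ref_vals))
    if factor <= 0:
        raise InsufficientReferencesError("reference median is not positive")
    return areas / factor, factor


def compute_ratios(peaks: PeakTable,
                   controls: Union[str, Iterable[str]] = "self") -> RatioMatrix:
    """Convert a raw :class:`PeakTable` into a :class:`RatioMatrix`.

    ``controls`` is either ``"self"`` (per-probe baseline = median over the
    whole batch, requiring at least 8 samples) or an explicit collection of
    control sample ids present in the batch.  Samples already flagged failed
    on the peak table, or failing intra-sample scaling, get all-NaN ratio
    rows and an entry in ``failed``.
    """
    panel = peaks.panel
    areas = peaks.areas
    failed = dict(peaks.failed)

    scaled = pd.DataFrame(np.nan, index=areas.index, columns=areas.columns)
    factors = pd.Series(np.nan, index=areas.index, name="factor")
    for sid in areas.index:
        if sid in failed:
            continue
        try:
            scaled.loc[sid], factors.loc[sid] = normalize_sample(areas.loc[sid], panel)
        except InsufficientReferencesError as exc:
            failed[sid] = str(exc)

    usable = [sid for sid in areas.index if sid not in failed]
    if isinstance(controls, str) and controls == "self":
        if len(usable) < MIN_SELF_BATCH:
            raise ConfigError(
                f"self-normalization needs >= {MIN_SELF_BATCH} usable samples, "
                f"got {len(usable)}")
        control_ids = list(usable)
    else:
        control_ids = [str(c) for c in controls]
        if not control_ids:
            raise ConfigError("empty control set")
        unknown = set(control_ids) - set(areas.index)
        if unknown:
            raise ConfigError(f"unknown control sample(s): {', '.join(sorted(unknown))}")
        control_ids = [c for c in control_ids if c not in failed]
        if not control_ids:
            raise ConfigError("all control samples failed normalization")

    baseline = scaled.loc[control_ids].median(axis=0, skipna=True)
    baseline.name = "baseline"
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = scaled.div(baseline, axis=1)
    ratios[ratios <= 0] = np.nan  # a non-positive ratio is a data artifact
    ratios.loc[[sid for sid in failed if sid in ratios.index]] = np.nan

    return RatioMatrix(
        ratios=ratios, scaled=scaled, sample_factor=factors,
        baseline=baseline, control_ids=tuple(control_ids), failed=failed)
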