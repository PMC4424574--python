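"""Ratio-threshold CNV calling, segmentation, and LCR breakpoint classification.

Calling is a fixed-threshold rule on the dosage ratio.  Two threshold modes
are provided: the four-dye high-density assay calls loss below 0.75 and gain
above 1.25, while classic MLPA practice uses the wider 0.70/1.30 window.
Ratios exactly at a threshold are called normal in both modes.

Maximal runs of consecutive same-state aberrant probes on one chromosome are
merged into :class:`CnvSegment` objects.  Segment coordinates are the anchor
positions of the first and last aberrant probe (the inner bound); the true
breakpoints are only localized to the flanking inter-probe gaps, reported as
breakpoint-uncertainty intervals.  On 22q11.2 those intervals are matched
against the LCR22A-H map to name the rearrangement class ("A-D" for the
typical deletion, "A-B"/"A-C" for the nested ones, "E-H" for the distal
duplication); segments not flanked by LCRs on both sides are "atypical", and
segments outside the mapped region are "n/a".
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .normalize import RatioMatrix
from .panel import LcrMap, ProbePanel

LOSS, NORMAL, GAIN, MISSING = "loss", "normal", "gain", "missing"

_MODE_THRESHOLDS = {
    "cnvplex": (0.75, 1.25),
    "mlpa": (0.70, 1.30),
}


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds and segmentation policy for the CNV caller."""

    mode: str = "cnvplex"
    loss_threshold: Optional[float] = None
    gain_threshold: Optional[float] = None
    min_probes_per_segment: int = 2
    bridge_missing: bool = True  # missing probes inside a run neither break nor extend it

    def __post_init__(self) -> None:
        if self.mode not in _MODE_THRESHOLDS:
            raise ValueError(f"unknown caller mode {self.mode!r}")
        loss, gain = _MODE_THRESHOLDS[self.mode]
        if self.loss_threshold is None:
            object.__setattr__(self, "loss_threshold", loss)
        if self.gain_threshold is None:
            object.__setattr__(self, "gain_threshold", gain)
        if not (0 < self.loss_threshold < 1 < self.gain_threshold):
            raise ValueError("thresholds must satisfy 0 < loss < 1 < gain")
        if self.min_probes_per_segment < 1:
            raise ValueError("min_probes_per_segment must be >= 1")

    @classmethod
    def cnvplex(cls, **kwargs) -> "CallerConfig":
        return cls(mode="cnvplex", **kwargs)

    @classmethod
    def mlpa(cls, **kwargs) -> "CallerConfig":
        return cls(mode="mlpa", **kwargs)


@dataclass
class ProbeCalls:
    """Per-(sample, probe) state matrix alongside the underlying ratios."""

    states: pd.DataFrame  # values in {loss, normal, gain, missing}
    ratios: pd.DataFrame
    config: CallerConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states.index)

    def frame(self) -> pd.DataFrame:
        """Long-format (sample_id, probe_id, ratio, state) view."""
        long = self.states.stack(future_stack=True).rename("state").reset_index()
        long.columns = ["sample_id", "probe_id", "state"]
        long["ratio"] = self.ratios.stack(future_stack=True).reset_index(drop=True)
        return long[["sample_id", "probe_id", "ratio", "state"]]


@dataclass(frozen=True)
class CnvSegment:
    """A contiguous run of same-state aberrant probes in one sample."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive position of the first aberrant probe
    end: int    # position of the last aberrant probe
    state: str  # loss | gain
    n_probes: int
    mean_ratio: float
    probe_ids: tuple[str, ...] = ()
    # (last non-aberrant probe position or None, first aberrant probe position)
    proximal_uncertainty: tuple[Optional[int], int] = (None, 0)
    # (last aberrant probe position, next non-aberrant probe position or None)
    distal_uncertainty: tuple[int, Optional[int]] = (0, None)
    lcr_class: str = "n/a"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if self.state not in (LOSS, GAIN):
            raise ValueError("segment state must be loss or gain")
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")


@dataclass(frozen=True)
class SingleProbeFlag:
    """An isolated aberrant probe, reported for confirmation rather than called."""

    sample_id: str
    probe_id: str
    chrom: str
    position: int
    state: str
    ratio: float


@dataclass
class SegmentationResult:
    segments: list[CnvSegment]
    flags: list[SingleProbeFlag]

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def call_probes(ratios: Union[RatioMatrix, pd.DataFrame],
                config: CallerConfig = CallerConfig()) -> ProbeCalls:
    """Threshold every dosage ratio into loss/normal/gain (missing stays missing).

    Ratios strictly below the loss threshold are losses, strictly above the
    gain threshold gains; threshold values themselves are normal.
    """
    matrix = ratios.ratios if isinstance(ratios, RatioMatrix) else ratios
    values = matrix.to_numpy(dtype=float)
    states = np.full(values.shape, NORMAL, dtype=object)
    states[values < config.loss_threshold] = LOSS
    states[values > config.gain_threshold] = GAIN
    states[np.isnan(values)] = MISSING
    return ProbeCalls(
        states=pd.DataFrame(states, index=matrix.index, columns=matrix.columns),
        ratios=matrix, config=config)


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i, j) runs of identical values."""
    if len(states) == 0:
        return []
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    bounds = np.concatenate(([0], change, [len(states)]))
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def segment_calls(calls: ProbeCalls, panel: ProbePanel,
                  config: Optional[CallerConfig] = None) -> SegmentationResult:
    """Merge aberrant probe calls into CNV segments per sample.

    Maximal runs of consecutive same-chromosome, same-state aberrant probes
    become segments; a state change (e.g. loss directly followed by gain)
    breaks a run.  Runs shorter than ``min_probes_per_segment`` are emitted
    as :class:`SingleProbeFlag` entries instead of segments.  When
    ``bridge_missing`` is set (default), probes with no ratio neither break
    nor extend a run.
    """
    config = config or calls.config
    segments: list[CnvSegment] = []
    flags: list[SingleProbeFlag] = []

    by_chrom: dict[str, list] = {}
    for p in panel.probes:
        by_chrom.setdefault(p.chrom, []).append(p)

    for sid in calls.states.index:
        state_row = calls.states.loc[sid]
        ratio_row = calls.ratios.loc[sid]
        for chrom, probes in by_chrom.items():
            pids = [p.probe_id for p in probes]
            states = state_row.reindex(pids).to_numpy(dtype=object)
            states[pd.isna(states)] = MISSING
            positions = np.array([p.position for p in probes])
            rvals = ratio_row.reindex(pids).to_numpy(dtype=float)

            if config.bridge_missing:
                keep = states != MISSING
            else:
                keep = np.ones(len(states), dtype=bool)
            k_states = states[keep]
            k_pos = positions[keep]
            k_pids = np.array(pids, dtype=object)[keep]
            k_ratios = rvals[keep]

            for i, j in _runs(k_states):
                run_state = k_states[i]
                if run_state not in (LOSS, GAIN):
                    continue
                n = j - i
                if n < config.min_probes_per_segment:
                    for k in range(i, j):
                        flags.append(SingleProbeFlag(
                            sample_id=sid, probe_id=str(k_pids[k]), chrom=chrom,
                            position=int(k_pos[k]), state=str(run_state),
                            ratio=float(k_ratios[k])))
                    continue
                prox_flank = int(k_pos[i - 1]) if i > 0 else None
                dist_flank = int(k_pos[j]) if j < len(k_pos) else None
                segments.append(CnvSegment(
                    sample_id=sid, chrom=chrom,
                    start=int(k_pos[i]), end=int(k_pos[j - 1]),
                    state=str(run_state), n_probes=n,
                    mean_ratio=float(np.nanmean(k_ratios[i:j])),
                    probe_ids=tuple(str(x) for x in k_pids[i:j]),
                    proximal_uncertainty=(prox_flank, int(k_pos[i])),
                    distal_uncertainty=(int(k_pos[j - 1]), dist_flank)))

    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    flags.sort(key=lambda f: (f.sample_id, f.chrom, f.position))
    return SegmentationResult(segments=segments, flags=flags)


def _overlap_length(lo: float, hi: float, start: int, end: int, tol: int) -> float:
    """Overlap of the open interval (lo, hi) with [start - tol, end + tol]."""
    a, b = start - tol, end + tol
    return min(hi, b) - max(lo, a)


def classify_lcr(segment: CnvSegment, lcr: LcrMap) -> str:
    """Name the LCR architecture of a 22q11.2 segment.

    When both breakpoint-uncertainty intervals overlap an LCR block (each
    block widened by ``tolerance_bp``), the class is
    ``"<proximal>-<distal>"`` using the short block names; when several
    blocks overlap, the one with the largest overlap wins (ties to the more
    proximal block).  Segments whose flanks match no block — or the same
    block on both sides — are ``"atypical"``; segments outside the mapped
    region are ``"n/a"``.
    """
    region_lo, region_hi = lcr.region_bounds()
    if segment.chrom != lcr.chrom:
        return "n/a"
    if segment.start < region_lo or segment.end > region_hi:
        return "n/a"

    def best_block(lo: Optional[int], hi: Optional[int]) -> Optional[str]:
        lo_v = -math.inf if lo is None else float(lo)
        hi_v = math.inf if hi is None else float(hi)
        best_name, best_len = None, 0.0
        for name, start, end in lcr.boundaries:
            length = _overlap_length(lo_v, hi_v, start, end, lcr.tolerance_bp)
            if length > best_len:
                best_name, best_len = name, length
        return best_name

    proximal = best_block(*segment.proximal_uncertainty)
    distal = best_block(*segment.distal_uncertainty)
    if proximal is None or distal is None or proximal == distal:
        return "atypical"
    return f"{lcr.short_name(proximal)}-{lcr.short_name(distal)}"


def classify_segments(segments: Iterable[CnvSegment], lcr: LcrMap) -> list[CnvSegment]:
    """Return segments with ``lcr_class`` filled in."""
    return [dataclasses.replace(s, lcr_class=classify_lcr(s, lcr)) for s in segments]


def segment_length_mb(segment: CnvSegment) -> float:
    """Segment span in megabases, rounded half away from zero to 2 decimals."""
    span = (segment.end - segment.start) / 1e6
    return math.floor(span * 100 + 0.5) / 100
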