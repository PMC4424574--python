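"""One-call wiring of the analysis chain: peaks -> ratios -> calls -> segments."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import pandas as pd

from .caller import (CallerConfig, CnvSegment, ProbeCalls, SegmentationResult,
                     call_probes, classify_segments, segment_calls)
from .normalize import RatioMatrix, compute_ratios
from .panel import LcrMap, ProbePanel
from .signals_io import PeakTable


@dataclass
class CallingResult:
    """Everything produced by one pass of the calling pipeline."""

    ratios: RatioMatrix
    calls: ProbeCalls
    segmentation: SegmentationResult
    lcr_map: Optional[LcrMap]

    @property
    def segments(self) -> list[CnvSegment]:
        return self.segmentation.segments

    def predicted_carriers(self) -> pd.Series:
        """Per-sample carrier flag: at least one called segment."""
        carriers = {sid: False for sid in self.ratios.sample_ids}
        for seg in self.segments:
            carriers[seg.sample_id] = True
        return pd.Series(carriers, name="carrier")


def run_calling(peaks: PeakTable,
                config: CallerConfig = CallerConfig(),
                controls: Union[str, Iterable[str]] = "self",
                lcr_map: Optional[LcrMap] = None) -> CallingResult:
    """Normalize a peak table, call probes, segment, and classify LCR classes."""
    ratios = compute_ratios(peaks, controls=controls)
    calls = call_probes(ratios, config)
    segmentation = segment_calls(calls, peaks.panel, config)
    if lcr_map is not None:
        segmentation.segments = classify_segments(segmentation.segments, lcr_map)
    return CallingResult(ratios=ratios, calls=calls,
                         segmentation=segmentation, lcr_map=lcr_map)
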