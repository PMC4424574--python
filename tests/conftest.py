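import numpy as np
import pandas as pd
import pytest

from plexdose import (ProbeDef, ProbePanel, build_demo_lcr_map,
                      build_demo_panel)
from plexdose.signals_io import PeakRecord


@pytest.fixture(scope="session")
def demo_panel():
    return build_demo_panel()


@pytest.fixture(scope="session")
def lcr_map():
    return build_demo_lcr_map()


@pytest.fixture(scope="session")
def tiny_panel():
    """Eight probes on one chromosome: four targets, four references."""
    probes = (
        ProbeDef("T1", "GENE1", "chr1", 100, "FAM", 100.0, 1),
        ProbeDef("T2", "GENE1", "chr1", 200, "FAM", 120.0, 1),
        ProbeDef("T3", "GENE2", "chr1", 300, "HEX", 100.0, 1),
        ProbeDef("T4", "GENE2", "chr1", 400, "HEX", 120.0, 1),
        ProbeDef("R1", "REF1", "chr1", 1000, "FAM", 140.0, 1, "reference"),
        ProbeDef("R2", "REF2", "chr1", 1100, "HEX", 140.0, 1, "reference"),
        ProbeDef("R3", "REF3", "chr1", 1200, "TAMRA", 100.0, 1, "reference"),
        ProbeDef("R4", "REF4", "chr1", 1300, "ROX", 100.0, 1, "reference"),
    )
    return ProbePanel(name="tiny", probes=probes)


def records_from_table(peaks):
    """Regenerate fragment-dialect PeakRecords from a PeakTable."""
    by_id = peaks.panel.by_id
    records = []
    for sid in peaks.sample_ids:
        for pid, area in peaks.areas.loc[sid].dropna().items():
            probe = by_id[pid]
            records.append(PeakRecord(sample_id=sid, dye=probe.dye,
                                      size=probe.amplicon_size,
                                      area=float(area), probe_id=pid))
    return records


def flat_ratio_row(panel, value=1.0):
    """A single-sample ratio DataFrame with every probe at `value`."""
    return pd.DataFrame([np.full(len(panel), value)],
                        index=["s1"], columns=panel.probe_ids)
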