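"""Synthetic multiplex peak-signal generator.

Emulates the measurement process of a ligation-probe assay so the whole
analysis chain (matching, normalization, QC, calling, statistics) is testable
without any real capillary data.  The signal model for probe ``p`` in sample
``s`` is

    area(s, p) = base_area * eff_p * scale_s * (copy_state_p / 2) * exp(eps)

with ``eff_p`` a fixed per-probe efficiency (log-normal, sigma 0.25, frozen
per seed), ``scale_s`` a per-sample scale factor (log-normal, sigma 0.3,
modelling DNA input and overall PCR yield), and ``eps ~ Normal(0,
noise_sigma^2)`` multiplicative measurement noise (default sigma 0.04).
Copy state 0 emits no fragment at all, exercising the missing-cell path.
Fragment sizes are emitted at the expected amplicon size; apparent-size
error is not modelled.

A registry of named CNV profiles mirrors the recurrent 22q11.2
rearrangements (typical A-D deletion, nested A-B and A-C deletions, distal
E-H duplication), the two small variant regions (DGCR6/PRODH, TOP3B), and a
composite 8p23 deletion-plus-duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union
import zlib

import numpy as np
import pandas as pd

from .panel import ProbeDef, ProbePanel
from .signals_io import PeakRecord, PeakTable, peak_table_from_records


@dataclass(frozen=True)
class Alteration:
    """One altered genomic interval: every probe inside gets ``copy_state``."""

    chrom: str
    start: int
    end: int
    copy_state: int  # 0..4; 2 is diploid

    def __post_init__(self) -> None:
        if not (0 <= self.copy_state <= 4):
            raise ValueError("copy_state must be in 0..4")
        if self.start > self.end:
            raise ValueError("alteration start must be <= end")

    def covers(self, probe: ProbeDef) -> bool:
        return probe.chrom == self.chrom and self.start <= probe.position <= self.end


@dataclass(frozen=True)
class CnvSpec:
    """Ground-truth copy configuration for one simulated sample class.

    Probes may be affected by coordinate range (``alterations``) or by id
    (``probe_states``); everything else is diploid (copy state 2).
    """

    label: str
    alterations: tuple[Alteration, ...] = ()
    probe_states: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        # accept a mapping for convenience; store hashably
        if isinstance(self.probe_states, Mapping):
            object.__setattr__(
                self, "probe_states",
                tuple(sorted((str(k), int(v)) for k, v in self.probe_states.items())))
        object.__setattr__(self, "alterations", tuple(self.alterations))

    @property
    def _probe_state_map(self) -> dict[str, int]:
        return dict(self.probe_states)

    @property
    def is_normal(self) -> bool:
        return not self.alterations and not self.probe_states

    def copy_state_of(self, probe: ProbeDef) -> int:
        states = self._probe_state_map
        if probe.probe_id in states:
            return states[probe.probe_id]
        for alt in self.alterations:
            if alt.covers(probe):
                return alt.copy_state
        return 2

    def copy_states(self, panel: ProbePanel) -> pd.Series:
        return pd.Series({p.probe_id: self.copy_state_of(p) for p in panel.probes})

    def validate_against(self, panel: ProbePanel) -> None:
        unknown = set(self._probe_state_map) - set(panel.probe_ids)
        if unknown:
            raise ValueError(
                f"spec {self.label!r} references unknown probe(s): "
                f"{', '.join(sorted(unknown))}")
        for alt in self.alterations:
            if not any(alt.covers(p) for p in panel.probes):
                raise ValueError(
                    f"spec {self.label!r}: no panel probe inside "
                    f"{alt.chrom}:{alt.start}-{alt.end}")


@dataclass(frozen=True)
class SimConfig:
    """Noise model and seed for the signal simulator."""

    seed: int = 0
    noise_sigma: float = 0.04           # log-scale multiplicative measurement noise
    sample_scale_sigma: float = 0.3     # log-scale per-sample factor spread
    probe_efficiency_sigma: float = 0.25  # log-scale fixed per-probe factor spread
    base_area: float = 1000.0           # arbitrary fluorescence units

    def __post_init__(self) -> None:
        for name in ("noise_sigma", "sample_scale_sigma", "probe_efficiency_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.base_area <= 0:
            raise ValueError("base_area must be > 0")


def probe_efficiencies(panel: ProbePanel, sim: SimConfig) -> pd.Series:
    """Fixed per-probe efficiency factors, frozen per (panel, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence((int(sim.seed), 0xEFF)))
    eff = np.exp(rng.normal(0.0, sim.probe_efficiency_sigma, size=len(panel)))
    return pd.Series(eff, index=panel.probe_ids, name="efficiency")


def _sample_rng(sim: SimConfig, sample_id: str) -> np.random.Generator:
    tag = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(sim.seed), tag)))


def simulate_sample(panel: ProbePanel, spec: CnvSpec, sim: SimConfig,
                    sample_id: str,
                    efficiencies: Optional[pd.Series] = None,
                    rng: Optional[np.random.Generator] = None
                    ) -> list[PeakRecord]:
    """Simulate one sample's peak records under a copy configuration.

    ``efficiencies`` and ``rng`` may be supplied by a cohort driver; left at
    None they are derived deterministically from ``sim.seed`` (and the
    sample id), so the same inputs always give byte-identical output.
    """
    spec.validate_against(panel)
    if efficiencies is None:
        efficiencies = probe_efficiencies(panel, sim)
    if rng is None:
        rng = _sample_rng(sim, sample_id)

    scale = float(np.exp(rng.normal(0.0, sim.sample_scale_sigma)))
    noise = np.exp(rng.normal(0.0, sim.noise_sigma, size=len(panel)))

    records: list[PeakRecord] = []
    for probe, eps in zip(panel.probes, noise):
        copy_state = spec.copy_state_of(probe)
        if copy_state == 0:
            continue  # homozygous loss: no ligation product at all
        area = sim.base_area * float(efficiencies[probe.probe_id]) * scale \
            * (copy_state / 2.0) * float(eps)
        records.append(PeakRecord(
            sample_id=sample_id, dye=probe.dye, size=probe.amplicon_size,
            area=area, probe_id=probe.probe_id))
    return records


def simulate_cohort(panel: ProbePanel,
                    class_counts: Mapping[Union[str, CnvSpec], int],
                    sim: SimConfig,
                    specs: Optional[Mapping[str, CnvSpec]] = None,
                    id_prefix: str = "S",
                    size_tol: float = 0.5,
                    ) -> tuple[PeakTable, pd.DataFrame]:
    """Simulate a whole cohort with the given per-class sample counts.

    ``class_counts`` maps a :class:`CnvSpec` (or a label resolved through
    ``specs``, defaulting to :func:`known_cnv_specs`) to a sample count.
    Sample order is shuffled (seeded) and a truth table
    ``(sample_id, label, carrier)`` is returned alongside the peak table so
    downstream scoring never re-derives truth from identifiers.
    """
    if specs is None:
        specs = known_cnv_specs()
    resolved: list[CnvSpec] = []
    for key, count in class_counts.items():
        if count < 0:
            raise ValueError("class counts must be >= 0")
        spec = key if isinstance(key, CnvSpec) else specs[str(key)]
        resolved.extend([spec] * int(count))

    rng = np.random.default_rng(np.random.SeedSequence((int(sim.seed), 0xC0C0)))
    order = rng.permutation(len(resolved))
    efficiencies = probe_efficiencies(panel, sim)

    records: list[PeakRecord] = []
    truth_rows = []
    width = max(3, len(str(max(len(resolved), 1))))
    for rank, spec_idx in enumerate(order, start=1):
        spec = resolved[spec_idx]
        sample_id = f"{id_prefix}{rank:0{width}d}"
        records.extend(simulate_sample(
            panel, spec, sim, sample_id, efficiencies=efficiencies, rng=rng))
        truth_rows.append({
            "sample_id": sample_id, "label": spec.label,
            "carrier": not spec.is_normal})

    truth = pd.DataFrame(truth_rows, columns=["sample_id", "label", "carrier"])
    peaks = peak_table_from_records(records, panel, size_tol=size_tol,
                                    prematched=True)
    return peaks, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    from ._util import atomic_write
    with atomic_write(path) as handle:
        truth.to_csv(handle, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Named CNV profiles matching the demo panel geometry
# ---------------------------------------------------------------------------

# Coordinates match the demo panel anchors: the typical deletion runs from the
# DGCR6 probe to the LZTR1 probe, the nested deletions stop at RTN4R (B) and
# MED15 (C), the distal duplication spans RIMBP3C..ZNF280B, and the 8p23
# composite event is a four-probe loss followed by a two-probe gain.
_DELETION_START = 18_893_757

_KNOWN_SPECS: dict[str, tuple[Alteration, ...]] = {
    "normal": (),
    "A-D": (Alteration("chr22", _DELETION_START, 21_464_055, 1),),
    "A-B": (Alteration("chr22", _DELETION_START, 20_233_757, 1),),
    "A-C": (Alteration("chr22", _DELETION_START, 20_940_053, 1),),
    "dupE-H": (Alteration("chr22", 22_050_000, 23_200_000, 3),),
    "DGCR6/PRODH-del": (Alteration("chr22", _DELETION_START, 18_918_663, 1),),
    "DGCR6/PRODH-dup": (Alteration("chr22", _DELETION_START, 18_918_663, 3),),
    "TOP3B-dup": (Alteration("chr22", 22_312_856, 22_330_186, 3),),
    "8p-del+dup": (Alteration("chr8", 9_000_000, 10_000_000, 1),
                   Alteration("chr8", 11_560_000, 11_600_000, 3)),
    "A-D+TOP3B-dup": (Alteration("chr22", _DELETION_START, 21_464_055, 1),
                      Alteration("chr22", 22_312_856, 22_330_186, 3)),
}


def known_cnv_specs() -> dict[str, CnvSpec]:
    """Registry of named CNV profiles for the demo panel."""
    return {label: CnvSpec(label=label, alterations=alts)
            for label, alts in _KNOWN_SPECS.items()}


def demo_validation_specs() -> list[CnvSpec]:
    """The nine-carrier reference set used for sensitivity/specificity checks.

    Six typical A-D deletions, one TOP3B micro-duplication, one A-D deletion
    co-occurring with the TOP3B duplication, and one A-C nested deletion —
    the CNV composition of a fully pre-characterized validation series.
    """
    specs = known_cnv_specs()
    return ([specs["A-D"]] * 6
            + [specs["TOP3B-dup"], specs["A-D+TOP3B-dup"], specs["A-C"]])
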