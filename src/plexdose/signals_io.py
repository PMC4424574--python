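"""Read fragment-analysis peak tables and write calls/ratio matrices.

Capillary fragment analysis (GeneMapper-style) exports one row per detected
peak: sample, dye channel, apparent fragment size, and peak area (or height).
``read_peaks`` matches each fragment to the unique panel probe with the same
dye whose expected amplicon size lies within a size tolerance, producing a
samples x probes area matrix.  Two dialects are auto-detected by header:

1. fragment dialect — ``sample_id  dye  size  area`` (``height`` accepted via
   ``use_height=True``);
2. pre-matched dialect — ``sample_id  probe_id  area``, bypassing size
   matching entirely.

Matching is deliberately conservative: a fragment within tolerance of two
probes is rejected and flagged (a false assignment corrupts dosage ratios
silently), and a probe receiving two fragments for one sample is recorded as
a conflict with the cell left missing, never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import atomic_write, chrom_sort_key
from .panel import ProbePanel

#: a sample matching fewer than this fraction of panel probes is flagged failed
MIN_MATCH_FRACTION = 0.8


class PeakFileError(ValueError):
    """Raised when a peak table cannot be parsed."""


@dataclass
class PeakRecord:
    """One capillary-electrophoresis peak."""

    sample_id: str
    dye: str
    size: float      # apparent fragment length, bp
    area: float      # peak area, arbitrary fluorescence units
    probe_id: Optional[str] = None  # filled once matched to the panel

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be >= 0")
        if self.size <= 0:
            raise ValueError("fragment size must be > 0")


@dataclass
class PeakTable:
    """Per-sample raw peak areas keyed by panel probe.

    ``areas`` is a samples x probes DataFrame; NaN marks a missing cell
    (no fragment observed), which is distinct from an explicit zero area.
    """

    panel: ProbePanel
    areas: pd.DataFrame
    unmatched: list[PeakRecord] = field(default_factory=list)
    ambiguous: list[PeakRecord] = field(default_factory=list)
    conflicts: list[tuple[str, str]] = field(default_factory=list)  # (sample, probe)
    failed: dict[str, str] = field(default_factory=dict)            # sample -> reason

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def n_samples(self) -> int:
        return len(self.areas)

    def no_signal_probes(self, sample_id: str) -> list[str]:
        row = self.areas.loc[sample_id]
        return list(row.index[row.isna()])


def _match_fragments(frame: pd.DataFrame, panel: ProbePanel, size_tol: float
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assign probe_ids by (dye, size); returns (matched, unmatched, ambiguous)."""
    pieces_m, pieces_u, pieces_a = [], [], []
    probes_by_dye: dict[str, pd.DataFrame] = {}
    for p in panel.probes:
        probes_by_dye.setdefault(p.dye, []).append((p.amplicon_size, p.probe_id))
    for dye in probes_by_dye:
        arr = sorted(probes_by_dye[dye])
        probes_by_dye[dye] = (np.array([a for a, _ in arr]),
                              np.array([pid for _, pid in arr], dtype=object))

    for dye, sub in frame.groupby("dye", sort=False):
        if dye not in probes_by_dye:
            pieces_u.append(sub)
            continue
        sizes, pids = probes_by_dye[dye]
        frag = sub["size"].to_numpy(dtype=float)
        idx = np.searchsorted(sizes, frag)
        left = np.clip(idx - 1, 0, len(sizes) - 1)
        right = np.clip(idx, 0, len(sizes) - 1)
        d_left = np.abs(frag - sizes[left])
        d_right = np.abs(frag - sizes[right])
        best = np.where(d_left <= d_right, left, right)
        other = np.where(d_left <= d_right, right, left)
        d_best = np.minimum(d_left, d_right)
        d_other = np.maximum(d_left, d_right)
        within = d_best <= size_tol
        # same index means only one candidate exists on this dye
        ambiguous = within & (d_other <= size_tol) & (best != other)
        matched_mask = within & ~ambiguous
        matched = sub[matched_mask].copy()
        matched["probe_id"] = pids[best[matched_mask]]
        pieces_m.append(matched)
        pieces_u.append(sub[~within])
        pieces_a.append(sub[ambiguous])

    empty = frame.iloc[0:0]
    matched = pd.concat(pieces_m) if pieces_m else empty.assign(probe_id=None)
    unmatched = pd.concat(pieces_u) if pieces_u else empty
    ambiguous = pd.concat(pieces_a) if pieces_a else empty
    return matched, unmatched, ambiguous


def _records_from_frame(frame: pd.DataFrame) -> list[PeakRecord]:
    return [
        PeakRecord(sample_id=r.sample_id, dye=getattr(r, "dye", "FAM"),
                   size=float(getattr(r, "size", 1.0)), area=float(r.area),
                   probe_id=getattr(r, "probe_id", None))
        for r in frame.itertuples(index=False)
    ]


def peak_table_from_frame(frame: pd.DataFrame, panel: ProbePanel,
                          size_tol: float = 0.5) -> PeakTable:
    """Build a :class:`PeakTable` from a long-format fragment DataFrame.

    If the frame carries a ``probe_id`` column the fragments are taken as
    pre-matched; otherwise ``dye`` and ``size`` columns drive matching.
    """
    if size_tol <= 0:
        raise ValueError("size_tol must be > 0")
    frame = frame.copy()
    frame["sample_id"] = frame["sample_id"].astype(str)
    sample_order = list(dict.fromkeys(frame["sample_id"]))

    if "probe_id" in frame.columns:
        known = set(panel.probe_ids)
        good = frame["probe_id"].isin(known)
        matched = frame[good]
        unmatched = frame[~good]
        ambiguous = frame.iloc[0:0]
    else:
        matched, unmatched, ambiguous = _match_fragments(frame, panel, size_tol)

    conflicts: list[tuple[str, str]] = []
    dup_mask = matched.duplicated(subset=["sample_id", "probe_id"], keep=False)
    if dup_mask.any():
        dup = matched[dup_mask]
        conflicts = sorted({(r.sample_id, r.probe_id) for r in dup.itertuples()})
        matched = matched[~dup_mask]

    areas = (matched.pivot(index="sample_id", columns="probe_id", values="area")
             .reindex(index=sample_order, columns=panel.probe_ids))
    areas.index.name = "sample_id"

    failed: dict[str, str] = {}
    n_probes = len(panel)
    for sid, n_matched in areas.notna().sum(axis=1).items():
        if n_matched < MIN_MATCH_FRACTION * n_probes:
            failed[sid] = (f"matched only {int(n_matched)} of {n_probes} panel probes "
                           f"(<{MIN_MATCH_FRACTION:.0%})")

    return PeakTable(
        panel=panel, areas=areas,
        unmatched=_records_from_frame(unmatched),
        ambiguous=_records_from_frame(ambiguous),
        conflicts=conflicts, failed=failed)


def peak_table_from_records(records: Iterable[PeakRecord], panel: ProbePanel,
                            size_tol: float = 0.5,
                            prematched: bool = False) -> PeakTable:
    """Build a :class:`PeakTable` from :class:`PeakRecord` objects."""
    records = list(records)
    cols = {
        "sample_id": [r.sample_id for r in records],
        "dye": [r.dye for r in records],
        "size": [r.size for r in records],
        "area": [r.area for r in records],
    }
    if prematched:
        cols["probe_id"] = [r.probe_id for r in records]
    frame = pd.DataFrame(cols)
    return peak_table_from_frame(frame, panel, size_tol=size_tol)


def read_peaks(path, panel: ProbePanel, size_tol: float = 0.5,
               use_height: bool = False) -> PeakTable:
    """Read a peak-table TSV and match fragments to panel probes.

    The signal column is ``area`` by default; ``use_height=True`` reads a
    ``height`` column instead (both statistics behave identically downstream).
    """
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise PeakFileError(f"cannot parse peak file {path}: {exc}") from exc
    if frame.empty:
        raise PeakFileError(f"peak file {path} contains no samples")

    signal_col = "height" if use_height else "area"
    if signal_col not in frame.columns:
        raise PeakFileError(f"peak file {path} lacks a {signal_col!r} column")
    frame = frame.rename(columns={signal_col: "area"})

    if "probe_id" in frame.columns:
        required = {"sample_id", "probe_id"}
    else:
        required = {"sample_id", "dye", "size"}
    missing = required - set(frame.columns)
    if missing:
        raise PeakFileError(
            f"peak file {path} is missing column(s): {', '.join(sorted(missing))}")
    return peak_table_from_frame(frame, panel, size_tol=size_tol)


def write_peaks(records: Iterable[PeakRecord], path,
                dialect: str = "fragment") -> None:
    """Write peak records as a TSV in the fragment or pre-matched dialect."""
    records = list(records)
    with atomic_write(path) as handle:
        if dialect == "fragment":
            handle.write("sample_id\tdye\tsize\tarea\n")
            for r in records:
                handle.write(f"{r.sample_id}\t{r.dye}\t{r.size!r}\t{r.area!r}\n")
        elif dialect == "prematched":
            handle.write("sample_id\tprobe_id\tarea\n")
            for r in records:
                handle.write(f"{r.sample_id}\t{r.probe_id}\t{r.area!r}\n")
        else:
            raise ValueError(f"unknown peak dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Calls and ratio-matrix output
# ---------------------------------------------------------------------------

CALLS_COLUMNS = ["sample_id", "chrom", "start", "end", "state",
                 "n_probes", "lcr_class", "mean_ratio"]


def _sorted_segments(segments):
    return sorted(segments, key=lambda s: (s.sample_id, chrom_sort_key(s.chrom), s.start))


def write_calls(segments, path, format: str = "tsv") -> None:
    """Write CNV segments as a TSV (1-based inclusive) or BED (0-based half-open)."""
    segments = _sorted_segments(segments)
    with atomic_write(path) as handle:
        if format == "tsv":
            handle.write("\t".join(CALLS_COLUMNS) + "\n")
            for s in segments:
                handle.write(
                    f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t"
                    f"{s.n_probes}\t{s.lcr_class}\t{s.mean_ratio:.3f}\n")
        elif format == "bed":
            for s in segments:
                name = f"{s.sample_id}|{s.state}|{s.lcr_class}|n={s.n_probes}"
                handle.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{name}\n")
        else:
            raise ValueError(f"unknown calls format {format!r}")


def read_calls(path) -> pd.DataFrame:
    """Read a calls TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_ratio_matrix(ratios: pd.DataFrame, path) -> None:
    """Write a samples x probes ratio matrix TSV (``NA`` for missing cells)."""
    with atomic_write(path) as handle:
        ratios.to_csv(handle, sep="\t", na_rep="NA", index_label="sample_id")


def read_ratio_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA",
                       float_precision="round_trip")
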