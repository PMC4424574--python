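"""Probe-panel definition, loading, validation, and the bundled demo panel.

A multiplex ligation-probe assay interrogates up to ~two hundred genomic loci
at once.  Each probe pair ligates on its target locus and is amplified with one
of four dye-labelled universal primer sets; amplicons are resolved by capillary
electrophoresis, so within one PCR a (dye, fragment size) pair must identify a
unique probe.  This module models that physical layout:

* :class:`ProbeDef` — one probe: genomic anchor, dye channel, expected amplicon
  size, which of the two PCRs it is amplified in, and whether it is a *target*
  probe (copy-number readout) or a *reference* probe (assumed copy-stable,
  used for per-sample normalization).
* :class:`ProbePanel` — the ordered probe collection plus the multiplexing
  constraints (96 probes per PCR, minimum fragment-size separation per dye).
* :class:`LcrMap` — named low-copy-repeat blocks on 22q11.2 (LCR22A-H) used to
  classify deletion/duplication breakpoints.

The bundled demo panel reproduces the geometry of a 189-probe 22q11.2 assay:
157 target probes (115 across the 22q11 region, 42 on other susceptibility
loci) and 32 reference probes, split 96/93 over two PCRs with four dyes.
Coordinates are schematic — anchored to published deletion endpoints and
marker-gene order, with filler probes evenly spaced — so every ordering the
calling logic depends on is realistic even though individual probe positions
are synthetic.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from ._util import atomic_write, chrom_sort_key

DYES = ("FAM", "HEX", "TAMRA", "ROX")
ROLES = ("target", "reference")

#: maximum synthesizable probe-oligo length (bp) for the lengthening-ligation design
OLIGO_LEN_MAX = 72

MANIFEST_COLUMNS = [
    "probe_id", "gene", "chrom", "position", "dye",
    "amplicon_size", "pcr_group", "role",
]


class PanelFormatError(ValueError):
    """Raised when a panel manifest cannot be parsed into a valid panel."""


@dataclass(frozen=True)
class ProbeDef:
    """A single ligation probe of the multiplex panel."""

    probe_id: str
    gene: str
    chrom: str
    position: int          # 1-based genomic coordinate of the ligation site
    dye: str               # one of DYES
    amplicon_size: float   # expected fragment length in bp
    pcr_group: int         # which of the two PCRs amplifies this probe
    role: str = "target"
    oligo_len: Optional[int] = None  # total synthesized oligo length, bp

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1")
        if self.amplicon_size <= 0:
            raise ValueError(f"probe {self.probe_id}: amplicon_size must be > 0")
        if self.dye not in DYES:
            raise ValueError(f"probe {self.probe_id}: unknown dye {self.dye!r}")
        if self.role not in ROLES:
            raise ValueError(f"probe {self.probe_id}: role must be one of {ROLES}")
        if self.pcr_group < 1:
            raise ValueError(f"probe {self.probe_id}: pcr_group must be >= 1")

    @property
    def is_reference(self) -> bool:
        return self.role == "reference"


@dataclass(frozen=True)
class Violation:
    """One panel-design rule violation (data, not an exception)."""

    code: str
    message: str
    probe_ids: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ids = f" [{', '.join(self.probe_ids)}]" if self.probe_ids else ""
        return f"{self.code}: {self.message}{ids}"


def _sorted_probes(probes: Iterable[ProbeDef]) -> tuple[ProbeDef, ...]:
    return tuple(sorted(probes, key=lambda p: (chrom_sort_key(p.chrom), p.position)))


@dataclass(frozen=True)
class ProbePanel:
    """An ordered probe collection plus the physical multiplexing limits."""

    name: str
    probes: tuple[ProbeDef, ...]
    probes_per_pcr_limit: int = 96
    min_size_gap: float = 2.0  # bp; capillary size-resolution assumption

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", _sorted_probes(self.probes))

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def targets(self) -> list[ProbeDef]:
        return [p for p in self.probes if p.role == "target"]

    @property
    def references(self) -> list[ProbeDef]:
        return [p for p in self.probes if p.role == "reference"]

    @property
    def dye_count(self) -> int:
        return len({p.dye for p in self.probes})

    @property
    def by_id(self) -> dict[str, ProbeDef]:
        return {p.probe_id: p for p in self.probes}

    def probes_on(self, chrom: str) -> list[ProbeDef]:
        return [p for p in self.probes if p.chrom == chrom]

    def validate(self) -> list[Violation]:
        return validate_panel(self)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(p) for p in self.probes]
        df = pd.DataFrame(rows)
        if df["oligo_len"].isna().all():
            df = df.drop(columns=["oligo_len"])
        return df


def validate_panel(panel: ProbePanel) -> list[Violation]:
    """Check the panel against the multiplex-design rules.

    Returns a list of :class:`Violation` (empty means the panel is valid):

    * ``duplicate_id`` — a probe_id used more than once;
    * ``oligo_too_long`` — synthesized oligo exceeds 72 bp;
    * ``pcr_group_capacity`` — more than ``probes_per_pcr_limit`` probes in one PCR;
    * ``size_collision`` — two same-dye probes in one PCR closer than
      ``min_size_gap`` bp, which capillary electrophoresis cannot separate;
    * ``no_reference`` — no reference probe, so samples cannot be normalized.
    """
    violations: list[Violation] = []

    counts = Counter(p.probe_id for p in panel.probes)
    for pid, n in sorted(counts.items()):
        if n > 1:
            violations.append(Violation(
                "duplicate_id", f"probe_id {pid!r} occurs {n} times", (pid,)))

    for p in panel.probes:
        if p.oligo_len is not None and p.oligo_len > OLIGO_LEN_MAX:
            violations.append(Violation(
                "oligo_too_long",
                f"oligo length {p.oligo_len} bp exceeds the {OLIGO_LEN_MAX} bp synthesis limit",
                (p.probe_id,)))

    group_counts = Counter(p.pcr_group for p in panel.probes)
    for group, n in sorted(group_counts.items()):
        if n > panel.probes_per_pcr_limit:
            violations.append(Violation(
                "pcr_group_capacity",
                f"PCR group {group} holds {n} probes (limit {panel.probes_per_pcr_limit})"))

    by_channel: dict[tuple[int, str], list[ProbeDef]] = {}
    for p in panel.probes:
        by_channel.setdefault((p.pcr_group, p.dye), []).append(p)
    for (group, dye), probes in sorted(by_channel.items()):
        ordered = sorted(probes, key=lambda p: p.amplicon_size)
        for left, right in zip(ordered, ordered[1:]):
            gap = right.amplicon_size - left.amplicon_size
            if gap < panel.min_size_gap:
                violations.append(Violation(
                    "size_collision",
                    f"PCR group {group}, dye {dye}: amplicons {left.amplicon_size:g} and "
                    f"{right.amplicon_size:g} bp are {gap:g} bp apart "
                    f"(min gap {panel.min_size_gap:g})",
                    (left.probe_id, right.probe_id)))

    if not any(p.role == "reference" for p in panel.probes):
        violations.append(Violation(
            "no_reference", "panel has no reference probe; normalization is impossible"))

    return violations


def load_panel(path, name: str | None = None, **panel_kwargs) -> ProbePanel:
    """Load a tab-separated probe manifest.

    The manifest has a header row naming at least ``probe_id gene chrom
    position dye amplicon_size pcr_group role`` (``oligo_len`` optional);
    ``#``-prefixed lines are ignored.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise PanelFormatError(f"cannot parse panel manifest {path}: {exc}") from exc

    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(
            f"panel manifest {path} is missing column(s): {', '.join(missing)}")

    dup = df["probe_id"][df["probe_id"].duplicated()].unique().tolist()
    if dup:
        raise PanelFormatError(
            f"panel manifest {path} has duplicate probe_id(s): {', '.join(dup)}")

    probes = []
    for row in df.itertuples(index=False):
        oligo = getattr(row, "oligo_len", None)
        oligo_len = None if oligo in (None, "") or pd.isna(oligo) else int(float(oligo))
        probes.append(ProbeDef(
            probe_id=row.probe_id,
            gene=row.gene,
            chrom=row.chrom,
            position=int(row.position),
            dye=row.dye,
            amplicon_size=float(row.amplicon_size),
            pcr_group=int(row.pcr_group),
            role=row.role,
            oligo_len=oligo_len,
        ))
    panel_name = name if name is not None else str(path)
    return ProbePanel(name=panel_name, probes=tuple(probes), **panel_kwargs)


def write_manifest(panel: ProbePanel, path) -> None:
    """Write the panel back out as a loadable TSV manifest."""
    df = panel.to_dataframe()
    with atomic_write(path) as handle:
        handle.write(f"# panel: {panel.name}\n")
        df.to_csv(handle, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LCR map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LcrMap:
    """Named low-copy-repeat blocks used to classify 22q11.2 breakpoints.

    ``boundaries`` is an ordered tuple of ``(name, start, end)`` intervals on
    ``chrom``; ``tolerance_bp`` widens each block when matching a segment's
    breakpoint-uncertainty interval to it (LCR blocks themselves carry no
    probes, so breakpoints are localized only to the inter-probe gap).
    """

    boundaries: tuple[tuple[str, int, int], ...]
    tolerance_bp: int = 200_000
    chrom: str = "chr22"

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.boundaries, key=lambda b: b[1]))
        object.__setattr__(self, "boundaries", ordered)
        for (n1, s1, e1), (n2, s2, e2) in zip(ordered, ordered[1:]):
            if e1 >= s2:
                raise ValueError(f"LCR intervals {n1} and {n2} overlap")
        for name, start, end in ordered:
            if start > end:
                raise ValueError(f"LCR interval {name} has start > end")

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.boundaries]

    def short_name(self, name: str) -> str:
        """'LCR22A' -> 'A'; unknown prefixes pass through unchanged."""
        return name.removeprefix("LCR22") or name

    def region_bounds(self) -> tuple[int, int]:
        """Coordinate span covered by the map, widened by the tolerance."""
        starts = [b[1] for b in self.boundaries]
        ends = [b[2] for b in self.boundaries]
        return min(starts) - self.tolerance_bp, max(ends) + self.tolerance_bp

    @classmethod
    def from_yaml(cls, path) -> "LcrMap":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        tolerance = int(raw.pop("tolerance_bp", 200_000))
        chrom = str(raw.pop("chrom", "chr22"))
        boundaries = tuple(
            (str(name), int(iv[0]), int(iv[1])) for name, iv in raw.items())
        return cls(boundaries=boundaries, tolerance_bp=tolerance, chrom=chrom)

    def to_yaml(self, path) -> None:
        with atomic_write(path) as handle:
            handle.write(f"chrom: {self.chrom}\n")
            handle.write(f"tolerance_bp: {self.tolerance_bp}\n")
            for name, start, end in self.boundaries:
                handle.write(f"{name}: [{start}, {end}]\n")


def build_demo_lcr_map() -> LcrMap:
    """The bundled LCR22A-H map matching the demo panel geometry.

    The intervals are a schematic reconstruction: each block is placed in the
    probe-free gap where the corresponding recurrent breakpoints fall
    (proximal of DGCR6 for A, between RTN4R and ZNF74 for B, between MED15
    and PI4KA for C, distal of the typical-deletion endpoint for D, and so on
    distally for E-H).  Users with real LCR coordinates supply their own map.
    """
    return LcrMap(boundaries=(
        ("LCR22A", 18_860_000, 18_885_000),
        ("LCR22B", 20_250_000, 20_350_000),
        ("LCR22C", 20_980_000, 21_050_000),
        ("LCR22D", 21_470_000, 21_600_000),
        ("LCR22E", 21_900_000, 22_000_000),
        ("LCR22F", 22_650_000, 22_750_000),
        ("LCR22G", 22_900_000, 23_000_000),
        ("LCR22H", 23_250_000, 23_350_000),
    ))


# ---------------------------------------------------------------------------
# Demo panel
# ---------------------------------------------------------------------------

# 22q11/22q13 anchor probes whose relative order the calling logic depends on:
# the recurrent-deletion endpoints, the breakpoint marker genes, and the two
# small variant regions (DGCR6/PRODH, TOP3B).
_ANCHORS_22Q11: list[tuple[str, int]] = [
    ("USP18", 18_850_000),    # proximal flank, outside all recurrent deletions
    ("DGCR6", 18_893_757),    # first deleted probe of the A-D/A-B/A-C deletions
    ("PRODH", 18_918_663),
    ("RTN4R", 20_233_757),    # last deleted probe of the nested A-B deletion
    ("ZNF74", 20_748_405),
    ("MED15", 20_940_053),    # last deleted probe of the A-C deletion
    ("PI4KA", 21_061_518),
    ("LZTR1", 21_464_055),    # last deleted probe of the typical A-D deletion
    ("HIC2", 21_800_000),     # distal flank of the A-D deletion
    ("RIMBP3C", 22_050_000),  # first probe of the distal E-H duplication
    ("PPIL2", 22_250_000),
    ("TOP3B", 22_312_856),    # TOP3B micro-duplication region
    ("TOP3B", 22_330_186),
    ("VPREB1", 22_400_000),
    ("ZNF280B", 23_200_000),  # last probe of the E-H duplication
    ("PRAME", 23_500_000),    # distal flank of the E-H duplication
]

# (start, end, n) open intervals receiving evenly spaced filler probes; the
# gaps left empty correspond to the LCR blocks, which carry no unique sequence.
_FILL_22Q11: list[tuple[int, int, int]] = [
    (18_918_663, 20_233_757, 40),
    (20_748_405, 20_940_053, 4),
    (21_061_518, 21_464_055, 8),
    (22_050_000, 22_250_000, 3),
    (22_400_000, 23_200_000, 10),
    (23_500_000, 26_350_000, 34),
]

_FILL_GENES = [
    "CLTCL1", "HIRA", "MRPL40", "CDC45", "CLDN5", "SEPT5", "GP1BB", "TBX1",
    "GNB1L", "TXNRD2", "COMT", "ARVCF", "TANGO2", "DGCR8", "TRMT2A", "RANBP1",
    "ZDHHC8", "SCARF2", "KLHL22", "SERPIND1", "SNAP29", "CRKL", "AIFM3",
    "THAP7", "P2RX6", "SLC7A4", "BCR", "IGLL5", "GNAZ", "RAB36", "SMARCB1",
]

# 42 target probes on the other 22q11-deletion-syndrome-like susceptibility
# loci: 4 on 22q13, 8 on 4q35, 6 on chr8 (8p23), 6 on chr9 (9q34.3),
# 10 on chr10 (10p15), 8 on chr17 (17p13.3).
_OTHER_TARGETS: list[tuple[str, str, int]] = [
    ("CELSR1", "chr22", 46_770_000),
    ("ATXN10", "chr22", 46_270_000),
    ("ARSA", "chr22", 51_063_000),
    ("SHANK3", "chr22", 51_113_000),
    ("SORBS2", "chr4", 186_500_000),
    ("SORBS2", "chr4", 186_560_000),
    ("FAT1", "chr4", 187_510_000),
    ("FAT1", "chr4", 187_560_000),
    ("ZFP42", "chr4", 188_920_000),
    ("ZFP42", "chr4", 188_960_000),
    ("FRG1", "chr4", 190_860_000),
    ("FRG1", "chr4", 190_900_000),
    ("PPP1R3B", "chr8", 9_000_000),
    ("PPP1R3B", "chr8", 9_100_000),
    ("MSRA", "chr8", 9_900_000),
    ("MSRA", "chr8", 10_000_000),
    ("GATA4", "chr8", 11_560_000),
    ("GATA4", "chr8", 11_600_000),
    ("NOTCH1", "chr9", 139_390_000),
    ("NOTCH1", "chr9", 139_430_000),
    ("EHMT1", "chr9", 140_600_000),
    ("EHMT1", "chr9", 140_650_000),
    ("EHMT1", "chr9", 140_700_000),
    ("CACNA1B", "chr9", 140_770_000),
    ("ZMYND11", "chr10", 180_000),
    ("ZMYND11", "chr10", 220_000),
    ("DIP2C", "chr10", 500_000),
    ("DIP2C", "chr10", 540_000),
    ("ADARB2", "chr10", 1_230_000),
    ("ADARB2", "chr10", 1_270_000),
    ("KLF6", "chr10", 3_820_000),
    ("KLF6", "chr10", 3_860_000),
    ("GATA3", "chr10", 8_100_000),
    ("GATA3", "chr10", 8_140_000),
    ("YWHAE", "chr17", 1_250_000),
    ("YWHAE", "chr17", 1_290_000),
    ("CRK", "chr17", 1_330_000),
    ("CRK", "chr17", 1_370_000),
    ("HIC1", "chr17", 1_960_000),
    ("HIC1", "chr17", 2_000_000),
    ("PAFAH1B1", "chr17", 2_500_000),
    ("PAFAH1B1", "chr17", 2_540_000),
]

_REFERENCE_CHROMS = [
    "chr1", "chr2", "chr3", "chr5", "chr6", "chr7", "chr11", "chr12",
    "chr13", "chr14", "chr15", "chr16", "chr18", "chr19", "chr20", "chr21",
]


def _demo_probe_sites() -> list[tuple[str, str, int, str]]:
    """(gene, chrom, position, role) for all 189 demo probes, unsorted."""
    sites: list[tuple[str, str, int, str]] = []
    for gene, pos in _ANCHORS_22Q11:
        sites.append((gene, "chr22", pos, "target"))
    filler_index = 0
    total_fillers = sum(n for _, _, n in _FILL_22Q11)
    for start, end, n in _FILL_22Q11:
        step = (end - start) / (n + 1)
        for k in range(1, n + 1):
            gene = _FILL_GENES[(filler_index * len(_FILL_GENES)) // total_fillers]
            sites.append((gene, "chr22", int(round(start + k * step)), "target"))
            filler_index += 1
    for gene, chrom, pos in _OTHER_TARGETS:
        sites.append((gene, chrom, pos, "target"))
    for i in range(32):
        chrom = _REFERENCE_CHROMS[i % len(_REFERENCE_CHROMS)]
        pos = 50_000_000 + 30_000_000 * (i // len(_REFERENCE_CHROMS))
        sites.append((f"REF{i + 1:02d}", chrom, pos, "reference"))
    return sites


def build_demo_panel() -> ProbePanel:
    """Deterministically build the bundled 189-probe demo panel.

    157 target probes (115 across 22q11/22q13 proper, 42 on the other
    susceptibility loci) plus 32 reference probes, partitioned 96/93 over two
    PCRs.  Dyes rotate round-robin within each PCR and fragment sizes are
    assigned per dye with a 3 bp pitch, so every (PCR, dye, size) channel is
    collision-free and ``validate_panel`` returns an empty report.
    """
    sites = _demo_probe_sites()
    sites.sort(key=lambda s: (chrom_sort_key(s[1]), s[2]))

    dye_counter: Counter[str] = Counter()
    group_counter: Counter[int] = Counter()
    probes: list[ProbeDef] = []
    for i, (gene, chrom, pos, role) in enumerate(sites):
        group = 1 if (i % 2 == 0 or i == 1) else 2
        dye = DYES[group_counter[group] % len(DYES)]
        group_counter[group] += 1
        size = 80.0 + 3.0 * dye_counter[dye]
        dye_counter[dye] += 1
        probes.append(ProbeDef(
            probe_id=f"{gene}_{pos}",
            gene=gene,
            chrom=chrom,
            position=pos,
            dye=dye,
            amplicon_size=size,
            pcr_group=group,
            role=role,
            oligo_len=60 + (i % 12),
        ))
    return ProbePanel(name="demo-22q11-v1", probes=tuple(probes))
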