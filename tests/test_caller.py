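import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexdose.caller import (CallerConfig, CnvSegment, call_probes,
                             classify_lcr, segment_calls, segment_length_mb)
from plexdose.pipeline import run_calling
from plexdose.simulate import SimConfig, known_cnv_specs, simulate_cohort

from conftest import flat_ratio_row

CNVPLEX = CallerConfig.cnvplex()
MLPA = CallerConfig.mlpa()


class TestCallProbes:
    @pytest.mark.parametrize("ratio,config,expected", [
        (1.0, CNVPLEX, "normal"),
        (0.75, CNVPLEX, "normal"),   # boundary values call normal
        (1.25, CNVPLEX, "normal"),
        (0.7499, CNVPLEX, "loss"),
        (1.2501, CNVPLEX, "gain"),
        (1.285, CNVPLEX, "gain"),    # the borderline duplication signal
        (1.285, MLPA, "normal"),     # ... missed by the wider MLPA window
        (0.70, MLPA, "normal"),
        (0.6999, MLPA, "loss"),
        (1.30, MLPA, "normal"),
        (1.3001, MLPA, "gain"),
    ])
    def test_threshold_semantics(self, demo_panel, ratio, config, expected):
        row = flat_ratio_row(demo_panel)
        row.iloc[0, 0] = ratio
        calls = call_probes(row, config)
        assert calls.states.iloc[0, 0] == expected

    def test_missing_ratio_stays_missing(self, demo_panel):
        row = flat_ratio_row(demo_panel)
        row.iloc[0, 3] = np.nan
        calls = call_probes(row, CNVPLEX)
        assert calls.states.iloc[0, 3] == "missing"

    @settings(max_examples=50, derandomize=True)
    @given(milli=st.integers(min_value=10, max_value=1990),
           mode=st.sampled_from(["cnvplex", "mlpa"]))
    def test_threshold_duality(self, demo_panel, milli, mode):
        """Reflecting a ratio around 1 (r -> 2-r) swaps gain and loss:
        both threshold pairs (0.75/1.25 and 0.70/1.30) are symmetric
        about the diploid ratio."""
        config = CallerConfig(mode=mode)
        ratio = milli / 1000.0
        row = flat_ratio_row(demo_panel)
        row.iloc[0, 0] = ratio
        mirrored = flat_ratio_row(demo_panel)
        mirrored.iloc[0, 0] = (2000 - milli) / 1000.0
        swap = {"gain": "loss", "loss": "gain", "normal": "normal"}
        a = call_probes(row, config).states.iloc[0, 0]
        b = call_probes(mirrored, config).states.iloc[0, 0]
        assert swap[a] == b

    def test_asymmetric_thresholds_break_duality(self, demo_panel):
        # duality is a property of symmetric threshold pairs, not of the
        # caller: a skewed configuration loses it
        config = CallerConfig(mode="mlpa", loss_threshold=0.6)
        row = flat_ratio_row(demo_panel)
        row.iloc[0, 0] = 0.65
        mirrored = flat_ratio_row(demo_panel)
        mirrored.iloc[0, 0] = 1.35
        assert call_probes(row, config).states.iloc[0, 0] == "normal"
        assert call_probes(mirrored, config).states.iloc[0, 0] == "gain"

    def test_mlpa_aberrant_implies_cnvplex_aberrant(self, demo_panel):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.uniform(0.4, 1.6, size=(5, len(demo_panel))),
                             index=[f"s{i}" for i in range(5)],
                             columns=demo_panel.probe_ids)
        mlpa_states = call_probes(frame, MLPA).states
        cnvplex_states = call_probes(frame, CNVPLEX).states
        aberrant = mlpa_states.isin(["loss", "gain"])
        assert ((mlpa_states == cnvplex_states) | ~aberrant).all().all()


def chr8_pattern_row(panel, losses=4, gains=2):
    """Ratios emulating the composite 8p23 event: hemizygous loss over
    PPP1R3B/MSRA immediately followed by a GATA4 gain."""
    row = flat_ratio_row(panel)
    chr8 = [p.probe_id for p in panel.probes_on("chr8")]
    for pid in chr8[:losses]:
        row.loc["s1", pid] = 0.5
    for pid in chr8[losses:losses + gains]:
        row.loc["s1", pid] = 1.5
    return row


class TestSegmentCalls:
    def test_adjacent_loss_then_gain_not_merged(self, demo_panel):
        calls = call_probes(chr8_pattern_row(demo_panel), CNVPLEX)
        result = segment_calls(calls, demo_panel)
        chr8 = [s for s in result.segments if s.chrom == "chr8"]
        assert [(s.state, s.n_probes) for s in chr8] == [("loss", 4), ("gain", 2)]
        assert (chr8[0].start, chr8[0].end) == (9_000_000, 10_000_000)
        assert (chr8[1].start, chr8[1].end) == (11_560_000, 11_600_000)
        # the gain's proximal breakpoint lies between the last lost probe
        # and the first gained probe
        assert chr8[1].proximal_uncertainty == (10_000_000, 11_560_000)

    def test_all_normal_gives_no_segments(self, demo_panel):
        calls = call_probes(flat_ratio_row(demo_panel), CNVPLEX)
        result = segment_calls(calls, demo_panel)
        assert result.segments == [] and result.flags == []

    def test_isolated_probes_flagged_not_called(self, demo_panel):
        # N L N L N: two singletons, zero segments at min_probes_per_segment=2
        row = flat_ratio_row(demo_panel)
        chr22 = [p.probe_id for p in demo_panel.probes_on("chr22")]
        row.loc["s1", chr22[1]] = 0.5
        row.loc["s1", chr22[3]] = 0.5
        result = segment_calls(call_probes(row, CNVPLEX), demo_panel)
        assert result.segments == []
        assert [f.probe_id for f in result.flags] == [chr22[1], chr22[3]]

    def test_missing_probe_bridged_inside_run(self, demo_panel):
        row = flat_ratio_row(demo_panel)
        chr22 = [p.probe_id for p in demo_panel.probes_on("chr22")]
        for pid in chr22[1:6]:
            row.loc["s1", pid] = 0.5
        row.loc["s1", chr22[3]] = np.nan
        result = segment_calls(call_probes(row, CNVPLEX), demo_panel)
        assert len(result.segments) == 1
        seg = result.segments[0]
        assert seg.n_probes == 4  # the missing probe neither breaks nor extends
        assert chr22[3] not in seg.probe_ids

    def test_unbridged_mode_breaks_runs(self, demo_panel):
        config = CallerConfig(mode="cnvplex", bridge_missing=False)
        row = flat_ratio_row(demo_panel)
        chr22 = [p.probe_id for p in demo_panel.probes_on("chr22")]
        for pid in chr22[1:6]:
            row.loc["s1", pid] = 0.5
        row.loc["s1", chr22[3]] = np.nan
        result = segment_calls(call_probes(row, config), demo_panel, config)
        assert [s.n_probes for s in result.segments] == [2, 2]

    def test_independent_of_sample_order(self, demo_panel):
        row1 = chr8_pattern_row(demo_panel)
        row2 = flat_ratio_row(demo_panel)
        row2.index = ["s2"]
        forward = pd.concat([row1, row2])
        backward = forward.iloc[::-1]
        segs_f = segment_calls(call_probes(forward, CNVPLEX), demo_panel).segments
        segs_b = segment_calls(call_probes(backward, CNVPLEX), demo_panel).segments
        assert segs_f == segs_b


class TestClassifyLcr:
    def seg(self, start, end, state="loss", prox=None, dist=None, chrom="chr22"):
        return CnvSegment(
            sample_id="s", chrom=chrom, start=start, end=end, state=state,
            n_probes=2, mean_ratio=0.5 if state == "loss" else 1.5,
            proximal_uncertainty=(prox, start), distal_uncertainty=(end, dist))

    def test_typical_deletion_is_a_d(self, lcr_map):
        seg = self.seg(18_893_757, 21_464_055,
                       prox=18_850_000, dist=21_800_000)
        assert classify_lcr(seg, lcr_map) == "A-D"

    def test_med15_pi4ka_breakpoint_is_a_c(self, lcr_map):
        seg = self.seg(18_893_757, 20_940_053,
                       prox=18_850_000, dist=21_061_518)
        assert classify_lcr(seg, lcr_map) == "A-C"

    def test_distal_duplication_is_e_h(self, lcr_map):
        seg = self.seg(22_050_000, 23_200_000, state="gain",
                       prox=21_800_000, dist=23_500_000)
        assert classify_lcr(seg, lcr_map) == "E-H"

    def test_small_interstitial_variant_is_atypical(self, lcr_map):
        seg = self.seg(22_312_856, 22_330_186, state="gain",
                       prox=22_250_000, dist=22_400_000)
        assert classify_lcr(seg, lcr_map) == "atypical"

    def test_other_chromosome_is_na(self, lcr_map):
        seg = self.seg(9_000_000, 10_000_000, chrom="chr8",
                       prox=8_000_000, dist=11_560_000)
        assert classify_lcr(seg, lcr_map) == "n/a"

    def test_outside_mapped_region_is_na(self, lcr_map):
        seg = self.seg(46_270_000, 51_113_000,
                       prox=46_000_000, dist=51_200_000)
        assert classify_lcr(seg, lcr_map) == "n/a"


class TestSegmentLength:
    @pytest.mark.parametrize("start,end,expected", [
        (18_893_757, 21_464_055, 2.57),  # typical-deletion span
        (18_893_757, 20_940_053, 2.05),  # nested A-C span
        (18_893_757, 20_233_757, 1.34),  # nested A-B span
        (100, 100, 0.00),
    ])
    def test_span_in_mb(self, start, end, expected):
        seg = CnvSegment(sample_id="s", chrom="chr22", start=start, end=end,
                         state="loss", n_probes=1, mean_ratio=0.5)
        assert segment_length_mb(seg) == expected


class TestZeroNoiseRecovery:
    """With no noise the caller must recover every simulated CNV profile
    exactly: segment extent equals the affected probe extent, and the LCR
    class matches the generating class."""

    EXPECTED = {
        "A-D": [("chr22", 18_893_757, 21_464_055, "loss", "A-D")],
        "A-B": [("chr22", 18_893_757, 20_233_757, "loss", "A-B")],
        "A-C": [("chr22", 18_893_757, 20_940_053, "loss", "A-C")],
        "dupE-H": [("chr22", 22_050_000, 23_200_000, "gain", "E-H")],
        "DGCR6/PRODH-del": [("chr22", 18_893_757, 18_918_663, "loss", "atypical")],
        "DGCR6/PRODH-dup": [("chr22", 18_893_757, 18_918_663, "gain", "atypical")],
        "TOP3B-dup": [("chr22", 22_312_856, 22_330_186, "gain", "atypical")],
        "8p-del+dup": [("chr8", 9_000_000, 10_000_000, "loss", "n/a"),
                       ("chr8", 11_560_000, 11_600_000, "gain", "n/a")],
        "A-D+TOP3B-dup": [("chr22", 18_893_757, 21_464_055, "loss", "A-D"),
                          ("chr22", 22_312_856, 22_330_186, "gain", "atypical")],
        "normal": [],
    }

    @pytest.mark.parametrize("label", sorted(EXPECTED))
    def test_spec_recovered_exactly(self, demo_panel, lcr_map, label):
        reg = known_cnv_specs()
        sim = SimConfig(seed=3, noise_sigma=0.0, sample_scale_sigma=0.0,
                        probe_efficiency_sigma=0.0)
        counts = {reg[label]: 1}
        if label != "normal":
            counts[reg["normal"]] = 9
        else:
            counts = {reg["normal"]: 10}
        peaks, truth = simulate_cohort(demo_panel, counts, sim)
        result = run_calling(peaks, lcr_map=lcr_map)
        observed = [(s.chrom, s.start, s.end, s.state, s.lcr_class)
                    for s in result.segments]
        assert observed == self.EXPECTED[label]
        carrier_rows = truth.set_index("sample_id")["carrier"]
        assert set(s.sample_id for s in result.segments) == \
            set(carrier_rows.index[carrier_rows])
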