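"""Event calling: segmentation accuracy, MCF estimator closed forms and
round trips, WGD detection, detectability floor, matrix assembly."""

import numpy as np
import pytest

from cnaevo.arrays import emulate_sample, make_probe_map
from cnaevo.calling import (
    CalledSegment,
    CallThresholds,
    build_event_matrix,
    call_events,
    detect_wgd,
    estimate_mcf,
    refine_event_matrix,
    segment_signal,
)
from cnaevo.genome import (
    CNAEvent,
    GenomeBuild,
    GenomicSegment,
    reciprocal_overlap,
)
from cnaevo.simulate import (
    SimulationConfig,
    programmed_truth,
    simulate_lineage,
    tp53_like_regime,
)
from tests.test_arrays import diploid_truth, loss_truth, wgd_truth


def seg(call="loss", mean_logr=-1.0, bands=(0.0, 1.0), n_probes=100,
        n_het=30, chrom="chr1", start=0, end=5_000_000):
    return CalledSegment(
        segment=GenomicSegment(chrom, start, end), mean_logr=mean_logr,
        baf_bands=bands, n_probes=n_probes, n_het=n_het, call=call,
    )


class TestSegmentation:
    def test_constant_signal_one_segment_per_chromosome(self, two_chrom_genome):
        truth = diploid_truth(two_chrom_genome)
        pm = make_probe_map(two_chrom_genome, seed=0)
        segs = segment_signal(emulate_sample(truth, 0, pm, seed=1))
        assert len(segs) == 2
        assert {s.segment.chrom for s in segs} == {"chr1", "chr2"}
        assert all(abs(s.mean_logr) < 0.02 for s in segs)

    def test_step_breakpoints_within_two_probes(self):
        """A -1.0 logR step over 200 probes at sigma 0.1 is localized to
        within +/-2 probes of the true boundaries."""
        genome = GenomeBuild.from_pairs([("chr1", 30_000_000)])
        truth = loss_truth(genome, 1.0, start=10_000_000, end=20_000_000)
        pm = make_probe_map(genome, spacing=50_000, seed=2)
        sig = emulate_sample(truth, 1, pm, noise=(0.1, 0.02), seed=3)
        segs = segment_signal(sig)
        losses = [s for s in segs if s.mean_logr < -0.5]
        assert len(losses) == 1
        assert abs(losses[0].segment.start - 10_000_000) <= 2 * 50_000
        assert abs(losses[0].segment.end - 20_000_000) <= 2 * 50_000

    def test_degenerate_two_probe_chromosome(self):
        genome = GenomeBuild.from_pairs([("chr1", 100_000)])
        truth = diploid_truth(genome)
        pm = make_probe_map(genome, spacing=50_000, seed=0)
        segs = segment_signal(emulate_sample(truth, 0, pm, seed=1),
                              min_probes=10)
        assert len(segs) == 1

    def test_no_fragment_below_min_probes(self, two_chrom_genome):
        truth = loss_truth(two_chrom_genome, 0.6)
        pm = make_probe_map(two_chrom_genome, seed=3)
        segs = segment_signal(emulate_sample(truth, 1, pm, seed=4),
                              min_probes=10)
        assert all(s.n_probes >= 10 for s in segs)


class TestEstimateMcf:
    def test_clonal_loss_both_routes_agree(self):
        """Clonal one-copy loss: logR -1 and lower band 0 both invert to 1."""
        via_baf = estimate_mcf(seg(bands=(0.0, 1.0), n_het=30))
        via_logr = estimate_mcf(seg(bands=(0.5,), n_het=0))
        assert via_baf == pytest.approx(1.0, abs=1e-9)
        assert via_logr == pytest.approx(1.0, abs=1e-9)

    def test_half_loss_from_logr(self):
        """logR = log2(0.75) inverts to f = 0.5."""
        s = seg(mean_logr=np.log2(0.75), n_het=0, bands=(0.5,))
        assert estimate_mcf(s) == pytest.approx(0.5, abs=1e-9)

    def test_half_loss_from_baf_band(self):
        """Lower het band 1/3 inverts to f = 0.5."""
        s = seg(mean_logr=-0.4, bands=(1 / 3, 2 / 3), n_het=30)
        assert estimate_mcf(s) == pytest.approx(0.5, abs=1e-9)

    def test_half_gain_closed_form(self):
        """f = 0.5 gain: logR = log2(2.5/2), bands {0.4, 0.6}."""
        via_baf = estimate_mcf(seg("gain", np.log2(1.25), (0.4, 0.6)))
        via_logr = estimate_mcf(seg("gain", np.log2(1.25), (0.5,), n_het=0))
        assert via_baf == pytest.approx(0.5, abs=1e-9)
        assert via_logr == pytest.approx(0.5, abs=1e-9)

    def test_cnloh_band_identity(self):
        s = seg("cnloh", 0.0, (0.25, 0.75))
        assert estimate_mcf(s) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_logr_magnitude(self):
        losses = [estimate_mcf(seg(mean_logr=-x, bands=(0.5,), n_het=0))
                  for x in np.linspace(0.1, 1.0, 10)]
        gains = [estimate_mcf(seg("gain", x, (0.5,), n_het=0))
                 for x in np.linspace(0.1, 0.58, 10)]
        assert all(b > a for a, b in zip(losses, losses[1:]))
        assert all(b > a for a, b in zip(gains, gains[1:]))

    def test_undefined_for_neutral_and_complex(self):
        for call in ("neutral", "complex"):
            with pytest.raises(ValueError, match="undefined"):
                estimate_mcf(seg(call))

    def test_result_clipped(self):
        assert estimate_mcf(seg(mean_logr=-3.0, bands=(0.5,), n_het=0)) == 1.0


class TestCallEvents:
    def test_clonal_loss_called(self):
        s = seg(mean_logr=-0.9, bands=(0.02, 0.98))
        events = call_events([s])
        assert len(events) == 1 and events[0][0].kind == "loss"
        assert s.call == "loss"

    def test_neutral_segment_dropped(self):
        s = seg(mean_logr=0.0, bands=(0.5,), n_het=0)
        assert call_events([s]) == []
        assert s.call == "neutral"

    def test_below_floor_suppressed(self):
        """An event estimated below the 10% clone floor is not emitted."""
        b = (1 - 0.08) / (2 - 0.08)  # loss at f = 0.08
        s = seg(mean_logr=np.log2((2 - 0.08) / 2), bands=(b, 1 - b))
        assert call_events([s]) == []

    def test_inconsistent_routes_flagged_complex(self):
        # logR says strong gain, bands say balanced: contradictory state
        s = seg("neutral", mean_logr=0.8, bands=(0.5, 0.5), n_het=40)
        events = call_events([s])
        assert s.call == "complex"
        assert events[0][0].kind == "complex"
        assert np.isnan(events[0][1])

    def test_noiseless_roundtrip_recovers_events_exactly(self, two_chrom_genome):
        """Noiseless emulation -> calling recovers kind, boundaries, and MCF
        (within 1e-6) of every >= 1 Mbp event at MCF >= 0.2."""
        gain = CNAEvent("G", "gain", GenomicSegment("chr2", 10_000_000,
                                                    14_000_000), 1)
        loss = CNAEvent("L", "loss", GenomicSegment("chr1", 30_000_000,
                                                    36_000_000), -1)
        cnloh = CNAEvent("H", "cnloh", GenomicSegment("chr1", 50_000_000,
                                                      58_000_000), 0)
        truth = programmed_truth(
            two_chrom_genome,
            {"C0": (None, []), "C1": ("C0", [loss]), "C2": ("C1", [gain]),
             "C3": ("C2", [cnloh])},
            {0: {"C0": 1.0},
             1: {"C0": 0.2, "C1": 0.3, "C2": 0.3, "C3": 0.2}},
            sampled_passages=(1,),
        )
        pm = make_probe_map(two_chrom_genome, seed=11)
        sig = emulate_sample(truth, 1, pm, noise=(0.0, 0.0), seed=0)
        events = call_events(segment_signal(sig))
        true_mcf = {"L": 0.8, "G": 0.5, "H": 0.2}
        found = {}
        for ev, f in events:
            for eid, tev in truth.events.items():
                if ev.kind == tev.kind and \
                        reciprocal_overlap(ev.segment, tev.segment) > 0.9:
                    found[eid] = f
        assert set(found) == set(true_mcf)
        for eid, f in found.items():
            assert f == pytest.approx(true_mcf[eid], abs=1e-6)


class TestDetectWgd:
    def _segments(self, genome, truth, passage, seed, centering="diploid"):
        pm = make_probe_map(genome, seed=seed)
        sig = emulate_sample(truth, passage, pm, seed=seed + 1,
                             centering=centering)
        return segment_signal(sig)

    def test_diploid_fit(self, two_chrom_genome):
        segs = self._segments(two_chrom_genome,
                              diploid_truth(two_chrom_genome), 0, 21)
        pl = detect_wgd(segs, two_chrom_genome)
        assert pl.psi_hat == pytest.approx(2.0, abs=0.1)
        assert not pl.wgd_flag

    def test_clonal_wgd_diploid_centered(self, two_chrom_genome):
        """Genome-wide logR ~ 1 forces psi ~ 4 and the WGD flag."""
        segs = self._segments(two_chrom_genome, wgd_truth(two_chrom_genome),
                              1, 22)
        pl = detect_wgd(segs, two_chrom_genome)
        assert pl.psi_hat == pytest.approx(4.0, abs=0.1)
        assert pl.wgd_flag

    def test_wgd_with_segmentals_under_median_centering(self, two_chrom_genome):
        """After median centering, absolute ploidy comes from the grid fit;
        a WGD clone with a clonal loss (total 3 copies) identifies psi 4."""
        w = CNAEvent("W", "wgd")
        loss = CNAEvent("L", "loss",
                        GenomicSegment("chr1", 10_000_000, 40_000_000), -1)
        truth = programmed_truth(
            two_chrom_genome,
            {"C0": (None, []), "C1": ("C0", [w, loss])},
            {0: {"C0": 1.0}, 1: {"C1": 1.0}},
            sampled_passages=(1,),
        )
        segs = self._segments(two_chrom_genome, truth, 1, 23,
                              centering="median")
        pl = detect_wgd(segs, two_chrom_genome, centering="median")
        assert pl.psi_hat == pytest.approx(4.0, abs=0.15)
        assert pl.wgd_flag

    def test_simulated_unstable_sample_flagged(self, small_genome):
        """A simulated WGD lineage with extra segmental events is flagged."""
        cfg = SimulationConfig(
            genome=small_genome, regime=tp53_like_regime(), n_passages=24,
            bottleneck_size=300, sampled_passages=(24,), seed=1,
        )
        truth = simulate_lineage(cfg)
        wgd_mcf = max(
            (truth.true_mcf(e, 24) for e in truth.surviving_events()
             if truth.events[e].kind == "wgd"), default=0.0,
        )
        assert wgd_mcf > 0.9  # seed chosen for the regime's typical sweep
        segs = self._segments(small_genome, truth, 24, 24)
        assert detect_wgd(segs, small_genome).wgd_flag

    def test_insufficient_coverage_rejected(self, two_chrom_genome):
        with pytest.raises(ValueError, match="50%"):
            detect_wgd([seg(end=1_000_000)], two_chrom_genome)


class TestBuildEventMatrix:
    def _ev(self, kind="loss", chrom="chr1", start=0, end=5_000_000, i=0):
        delta = {"gain": 1, "loss": -1}.get(kind, 0)
        return CNAEvent(f"x{i}", kind, GenomicSegment(chrom, start, end), delta)

    def test_identical_events_unified(self):
        per_sample = {
            s: [(self._ev(i=i), 1.0)] for i, s in enumerate(["a", "b", "c"])
        }
        m = build_event_matrix(per_sample)
        assert m.mcf.shape == (1, 3)
        assert np.allclose(m.mcf, 1.0)

    def test_low_overlap_stays_separate(self):
        a = self._ev(start=0, end=10_000_000, i=0)
        b = self._ev(start=5_000_000, end=15_000_000, i=1)  # ro = 0.5 < 0.8
        m = build_event_matrix({"s1": [(a, 0.5)], "s2": [(b, 0.5)]})
        assert m.n_events == 2

    def test_kind_mismatch_stays_separate(self):
        a = self._ev("loss", i=0)
        b = self._ev("gain", i=1)
        m = build_event_matrix({"s1": [(a, 0.5)], "s2": [(b, 0.5)]})
        assert m.n_events == 2

    def test_absent_event_is_zero(self):
        m = build_event_matrix({"s1": [(self._ev(), 0.7)], "s2": []})
        assert m.mcf[0].tolist() == [0.7, 0.0]

    def test_unified_segment_is_intersection(self):
        a = self._ev(start=0, end=10_000_000, i=0)
        b = self._ev(start=500_000, end=10_000_000, i=1)  # ro = 0.95
        m = build_event_matrix({"s1": [(a, 1.0)], "s2": [(b, 1.0)]})
        assert m.n_events == 1
        assert m.events[0].segment == GenomicSegment("chr1", 500_000,
                                                     10_000_000)

    def test_rows_ordered_by_genome_position(self):
        per_sample = {"s": [
            (self._ev(chrom="chr2", i=0), 0.5),
            (self._ev(chrom="chr1", start=10_000_000, end=12_000_000, i=1), 0.5),
            (self._ev(chrom="chr1", i=2), 0.5),
            (CNAEvent("w", "wgd"), 1.0),
        ]}
        m = build_event_matrix(per_sample)
        assert [e.kind for e in m.events][0] == "wgd"
        segs = [e.segment for e in m.events[1:]]
        assert [(s.chrom, s.start) for s in segs] == [
            ("chr1", 0), ("chr1", 10_000_000), ("chr2", 0)
        ]

    def test_needs_one_sample(self):
        with pytest.raises(ValueError):
            build_event_matrix({})


class TestRefineMatrix:
    def test_recovers_presence_missed_by_unification(self, two_chrom_genome):
        """A clonal loss absent from one sample's rows (boundary jitter) is
        re-genotyped from that sample's probes; true absences stay zero."""
        truth = loss_truth(two_chrom_genome, 0.9)
        pm = make_probe_map(two_chrom_genome, seed=31)
        sig = emulate_sample(truth, 1, pm, seed=32, sample_id="mut")
        sig0 = emulate_sample(truth, 0, pm, seed=33, sample_id="ref")
        row = CNAEvent("r", "loss",
                       GenomicSegment("chr1", 20_000_000, 25_000_000), -1)
        from cnaevo.matrix import EventMatrix

        m = EventMatrix([row], ["mut", "ref"], np.array([[0.0, 0.0]]))
        refined = refine_event_matrix(m, {"mut": sig, "ref": sig0})
        assert refined.mcf[0, 0] == pytest.approx(0.9, abs=0.05)
        assert refined.mcf[0, 1] == 0.0
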