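"""Clonal-evolution simulator: determinism, perfect-phylogeny invariants,
regime contrast, and agreement with an independent re-implementation of the
mutation -> selection -> drift update."""

import numpy as np
import pytest

from cnaevo.genome import CNAEvent, GenomicSegment, event_length
from cnaevo.simulate import (
    CloneTruth,
    RegimeConfig,
    SimulationConfig,
    programmed_truth,
    rb1_like_regime,
    simulate_lineage,
    tp53_like_regime,
    true_mcf_matrix,
    wt_regime,
)


def neutral_regime(event_rate: float = 0.2) -> RegimeConfig:
    return RegimeConfig("neutral", event_rate=event_rate, fitness_mean=1.0,
                        fitness_sd=0.0)


class TestSimulateLineage:
    def test_no_mutation_single_founder(self, small_genome):
        cfg = SimulationConfig(
            genome=small_genome, regime=neutral_regime(0.0), n_passages=10,
            bottleneck_size=100, sampled_passages=(5, 10), seed=1,
        )
        truth = simulate_lineage(cfg)
        assert len(truth.clones) == 1
        assert truth.events == {}
        for p in range(11):
            assert truth.fractions[p] == {"C0": 1.0}

    def test_deterministic_given_seed(self, small_genome):
        cfg = SimulationConfig(
            genome=small_genome, regime=neutral_regime(), n_passages=15,
            bottleneck_size=200, sampled_passages=(15,), seed=42,
        )
        a, b = simulate_lineage(cfg), simulate_lineage(cfg)
        assert [c.clone_id for c in a.clones] == [c.clone_id for c in b.clones]
        assert a.fractions == b.fractions
        assert set(a.events) == set(b.events)

    def test_config_validation(self, small_genome):
        with pytest.raises(ValueError):
            SimulationConfig(genome=small_genome, regime=neutral_regime(),
                             bottleneck_size=0, sampled_passages=(1,))
        with pytest.raises(ValueError):
            SimulationConfig(genome=small_genome, regime=neutral_regime(),
                             n_passages=5, sampled_passages=(9,))

    def test_fractions_sum_to_one(self, small_genome):
        cfg = SimulationConfig(
            genome=small_genome, regime=neutral_regime(0.5), n_passages=20,
            bottleneck_size=100, sampled_passages=(20,), seed=7,
        )
        truth = simulate_lineage(cfg)
        for p, fr in truth.fractions.items():
            assert sum(fr.values()) == pytest.approx(1.0)

    def test_perfect_phylogeny_event_sets_nested(self, small_genome):
        cfg = SimulationConfig(
            genome=small_genome, regime=tp53_like_regime(), n_passages=20,
            bottleneck_size=300, sampled_passages=(10, 20), seed=5,
        )
        truth = simulate_lineage(cfg)
        for c in truth.clones:
            if c.parent_id is not None:
                parent_set = truth.events_carried(c.parent_id)
                assert parent_set <= truth.events_carried(c.clone_id)

    def test_mean_clone_count_matches_independent_oracle(self, small_genome):
        """Mean surviving-clone count under a neutral regime agrees with a
        straightforward re-implementation of the same update rules
        (separate code path, same model) within 2 combined standard errors.
        """
        n_reps, n_pass, bottleneck, rate = 120, 15, 200, 0.2

        def oracle(seed: int) -> int:
            # minimal independent rewrite: per passage, every surviving
            # clone spawns a 1-cell child if Poisson(rate) >= 1, then the
            # population is multinomially resampled (neutral fitness)
            r = np.random.default_rng(seed)
            counts = [bottleneck]
            for _ in range(n_pass):
                for i in range(len(counts)):
                    if counts[i] >= 1 and r.poisson(rate) >= 1:
                        counts[i] -= 1
                        counts.append(1)
                alive = [c for c in counts if c >= 1]
                probs = np.array(alive, dtype=float) / sum(alive)
                counts = list(r.multinomial(bottleneck, probs))
            return sum(1 for c in counts if c >= 1)

        ours = []
        for rep in range(n_reps):
            cfg = SimulationConfig(
                genome=small_genome, regime=neutral_regime(rate),
                n_passages=n_pass, bottleneck_size=bottleneck,
                sampled_passages=(n_pass,), seed=10_000 + rep,
            )
            truth = simulate_lineage(cfg)
            ours.append(len(truth.fractions[n_pass]))
        theirs = [oracle(20_000 + rep) for rep in range(n_reps)]
        se = np.sqrt(np.var(ours, ddof=1) / n_reps
                     + np.var(theirs, ddof=1) / n_reps)
        assert abs(np.mean(ours) - np.mean(theirs)) <= 2 * se


class TestTrueMcf:
    def _nested_truth(self, genome):
        founder_ev = CNAEvent("f", "loss",
                              GenomicSegment("chr1", 0, 2_000_000), -1)
        parent_ev = CNAEvent("p", "gain",
                             GenomicSegment("chr2", 0, 2_000_000), 1)
        child_ev = CNAEvent("c", "loss",
                            GenomicSegment("chr2", 10_000_000, 12_000_000), -1)
        return programmed_truth(
            genome,
            {"C0": (None, [founder_ev]), "C1": ("C0", [parent_ev]),
             "C2": ("C1", [child_ev])},
            {0: {"C0": 1.0}, 1: {"C0": 0.4, "C1": 0.4, "C2": 0.2}},
            sampled_passages=(1,),
        )

    def test_founder_event_mcf_one(self, small_genome):
        truth = self._nested_truth(small_genome)
        assert truth.true_mcf("f", 1) == pytest.approx(1.0)

    def test_private_event_equals_clone_fraction(self, small_genome):
        truth = self._nested_truth(small_genome)
        assert truth.true_mcf("c", 1) == pytest.approx(0.2)

    def test_nested_sum_over_carriers(self, small_genome):
        """Parent-branch event at 0.6 (incl. the 0.2 child), child at 0.2."""
        truth = self._nested_truth(small_genome)
        assert truth.true_mcf("p", 1) == pytest.approx(0.6)

    def test_unknown_passage_raises(self, small_genome):
        truth = self._nested_truth(small_genome)
        with pytest.raises(KeyError):
            truth.true_mcf("f", 99)

    def test_matrix_values_and_samples(self, small_genome):
        truth = self._nested_truth(small_genome)
        m = true_mcf_matrix(truth, (1,))
        assert m.samples == ["P1"]
        by_id = dict(zip([e.event_id for e in m.events], m.mcf[:, 0]))
        assert by_id == pytest.approx({"f": 1.0, "p": 0.6, "c": 0.2})

    def test_matrix_respects_phylogeny_invariants(self, small_genome):
        """Parent-branch MCF >= child-branch MCF and sibling sums bounded
        by the parent, in every sample of a simulated lineage."""
        cfg = SimulationConfig(
            genome=small_genome, regime=tp53_like_regime(), n_passages=24,
            bottleneck_size=300, sampled_passages=(8, 16, 24), seed=3,
        )
        truth = simulate_lineage(cfg)
        for c in truth.clones:
            if c.parent_id is None:
                continue
            for p in truth.sampled_passages:
                for eid in c.new_events:
                    child_mcf = truth.true_mcf(eid, p)
                    for up in truth.clone(c.parent_id).new_events:
                        assert truth.true_mcf(up, p) >= child_mcf - 1e-9
        # pigeonhole over sibling branches
        kids: dict[str, list[str]] = {}
        for c in truth.clones:
            if c.parent_id is not None and c.new_events:
                kids.setdefault(c.parent_id, []).append(c.clone_id)
        for parent, children in kids.items():
            for p in truth.sampled_passages:
                total = sum(
                    truth.true_mcf(truth.clone(k).new_events[0], p)
                    for k in children
                )
                parent_events = truth.clone(parent).new_events
                cap = (truth.true_mcf(parent_events[0], p)
                       if parent_events else 1.0)
                assert total <= cap + 1e-9


class TestRegimeContrast:
    def test_checkpoint_vs_unstable_large_event_burden(self, small_genome):
        """Stable knockouts yield (near) zero large detectable events;
        the unstable WGD-tolerant regime yields many (the qualitative
        contrast the regimes encode)."""

        def large_detectable(regime, seed):
            cfg = SimulationConfig(
                genome=small_genome, regime=regime, n_passages=24,
                bottleneck_size=300, sampled_passages=(8, 16, 24), seed=seed,
            )
            truth = simulate_lineage(cfg)
            n = 0
            for eid in truth.surviving_events():
                ev = truth.events[eid]
                if ev.segment is None or event_length(ev) < 1_000_000:
                    continue
                if max(truth.true_mcf(eid, p) for p in (8, 16, 24)) > 0.1:
                    n += 1
            return n

        stable = [large_detectable(rb1_like_regime(), s) for s in range(8)]
        unstable = [large_detectable(tp53_like_regime(), s) for s in range(8)]
        assert np.mean(stable) <= 0.5
        assert np.mean(unstable) >= 1.5
        assert np.mean(unstable) > np.mean(stable) + 1.0

    def test_tp53_like_regime_produces_wgd_sweeps(self, small_genome):
        wgd_seen = 0
        for seed in range(10):
            cfg = SimulationConfig(
                genome=small_genome, regime=tp53_like_regime(), n_passages=24,
                bottleneck_size=300, sampled_passages=(24,), seed=seed,
            )
            truth = simulate_lineage(cfg)
            for eid in truth.surviving_events():
                if truth.events[eid].kind == "wgd" \
                        and truth.true_mcf(eid, 24) > 0.5:
                    wgd_seen += 1
                    break
        assert wgd_seen >= 5

    def test_regime_validation(self):
        with pytest.raises(ValueError):
            RegimeConfig("bad", kind_weights=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            RegimeConfig("bad", wgd_prob=1.5)
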