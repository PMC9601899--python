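"""Adaptive mechanisms: mutation/remap proposals, accept-if-not-worse
selection and the concurrent epoch loop."""

import numpy as np
import pytest

from bnbot.adaptation import (
    accept,
    adapt,
    make_robot_config,
    mutate,
    propose,
)
from bnbot.arena import arena_task1, arena_task2, arena_task3
from bnbot.rbn import EnsembleSpec, generate_rbn

ARENAS = {1: arena_task1, 2: arena_task2, 3: arena_task3}


class TestMutate:
    def test_exact_counts_at_full_scale(self, rng):
        net = generate_rbn(EnsembleSpec(n=1000, k=3, p=0.5, seed=0))
        out = mutate(net, rng)
        assert int((out.truth_tables != net.truth_tables).sum()) == 80
        assert int((out.wiring != net.wiring).sum()) == 30

    def test_scaled_counts(self, rng):
        net = generate_rbn(EnsembleSpec(n=200, k=3, p=0.5, seed=1))
        out = mutate(net, rng)
        assert int((out.truth_tables != net.truth_tables).sum()) == round(
            0.01 * 200 * 8
        )
        assert int((out.wiring != net.wiring).sum()) == round(0.01 * 200 * 3)

    def test_structure_stays_valid(self, rng):
        net = generate_rbn(EnsembleSpec(n=50, k=3, p=0.5, seed=2))
        for _ in range(20):
            net = mutate(net, rng)
            assert not (net.wiring == np.arange(50)[:, None]).any()
            for row in net.wiring:
                assert len(set(row)) == 3

    def test_input_untouched(self, rng):
        net = generate_rbn(EnsembleSpec(n=100, k=3, p=0.5, seed=3))
        tables = net.truth_tables.copy()
        wiring = net.wiring.copy()
        mutate(net, rng)
        assert (net.truth_tables == tables).all()
        assert (net.wiring == wiring).all()

    def test_flip_is_involution_on_disjoint_draws(self, rng):
        net = generate_rbn(EnsembleSpec(n=1000, k=3, p=0.5, seed=4))
        once = mutate(net, rng, n_arcs=0)
        flipped = np.flatnonzero(
            (once.truth_tables != net.truth_tables).reshape(-1)
        )
        again = once.copy()
        again.truth_tables.reshape(-1)[flipped] ^= 1
        assert (again.truth_tables == net.truth_tables).all()


class TestPropose:
    def test_in_out_mapping_leaves_network_identical(self, rng):
        cfg = make_robot_config(EnsembleSpec(n=100, p=0.21), 1, rng)
        new = propose(cfg, "in-out-mapping", rng)
        assert (new.network.truth_tables == cfg.network.truth_tables).all()
        assert (new.network.wiring == cfg.network.wiring).all()
        assert new.coupling != cfg.coupling

    def test_mutation_leaves_coupling_identical(self, rng):
        cfg = make_robot_config(EnsembleSpec(n=100, p=0.21), 1, rng)
        new = propose(cfg, "mutation", rng)
        assert new.coupling == cfg.coupling
        assert (new.network.truth_tables != cfg.network.truth_tables).any()

    def test_hybrid_changes_both(self, rng):
        cfg = make_robot_config(EnsembleSpec(n=100, p=0.21), 1, rng)
        new = propose(cfg, "hybrid", rng)
        assert new.coupling != cfg.coupling
        assert (new.network.truth_tables != cfg.network.truth_tables).any()

    def test_unknown_mechanism(self, rng):
        cfg = make_robot_config(EnsembleSpec(n=100, p=0.21), 1, rng)
        with pytest.raises(ValueError):
            propose(cfg, "annealing", rng)


class TestAccept:
    @pytest.mark.parametrize("prev,new,ok", [
        (10.0, 10.0, True),   # sideways move
        (10.0, 9.999, False),
        (-5.0, 0.0, True),
    ])
    def test_rule(self, prev, new, ok):
        assert accept(prev, new) is ok

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            accept(float("nan"), 1.0)


class TestAdaptLoop:
    def _run(self, task=1, mechanism="io", epochs=5, robots=2, seed=0,
             n=60, steps=60, p=0.5):
        rng = np.random.default_rng(seed)
        spec = EnsembleSpec(n=n, k=3, p=p)
        cfgs = [make_robot_config(spec, task, rng) for _ in range(robots)]
        return adapt(ARENAS[task](), cfgs, task, mechanism, epochs=epochs,
                     steps=steps, seed=seed + 1)

    def test_single_epoch(self):
        recs = self._run(epochs=1)
        for r in recs:
            assert len(r.scores) == 1 and r.best_epoch == 0
            assert r.accepted[0]

    def test_cumulative_max_nondecreasing(self):
        for rec in self._run(epochs=15, mechanism="hyb"):
            cm = np.maximum.accumulate(rec.scores)
            assert (np.diff(cm) >= -1e-12).all()
            assert rec.scores[rec.best_epoch] == rec.best_score == cm[-1]

    def test_retained_scores_nondecreasing(self):
        for rec in self._run(epochs=15, mechanism="mut", task=2):
            retained = rec.scores[rec.accepted]
            assert (np.diff(retained) >= -1e-9).all()

    def test_in_out_mapping_preserves_network(self):
        rng = np.random.default_rng(9)
        spec = EnsembleSpec(n=60, k=3, p=0.21)
        cfgs = [make_robot_config(spec, 1, rng)]
        orig = cfgs[0].network.copy()
        recs = adapt(arena_task1(), cfgs, 1, "in-out-mapping", epochs=10,
                     steps=50, seed=5)
        final = recs[0].final_config.network
        assert (final.truth_tables == orig.truth_tables).all()
        assert (final.wiring == orig.wiring).all()

    def test_rejected_epochs_leave_retained_config_bit_identical(self):
        rng = np.random.default_rng(13)
        spec = EnsembleSpec(n=60, k=3, p=0.21)
        cfgs = [make_robot_config(spec, 1, rng)]
        recs = adapt(arena_task1(), cfgs, 1, "hybrid", epochs=20, steps=50,
                     seed=7)
        rec = recs[0]
        assert (~rec.accepted).any(), "expected at least one rejection"
        # the retained config's score equals the last accepted epoch's score
        last_acc = np.flatnonzero(rec.accepted)[-1]
        assert rec.scores[last_acc] >= rec.scores[~rec.accepted].max() - 1e-9

    def test_seed_determinism_end_to_end(self):
        a = self._run(task=3, mechanism="hyb", epochs=4, seed=21, steps=80)
        b = self._run(task=3, mechanism="hyb", epochs=4, seed=21, steps=80)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.scores, rb.scores)
            np.testing.assert_array_equal(ra.accepted, rb.accepted)
            np.testing.assert_array_equal(ra.best_states, rb.best_states)
            np.testing.assert_array_equal(
                ra.final_config.network.truth_tables,
                rb.final_config.network.truth_tables,
            )

    def test_best_states_shape(self):
        recs = self._run(epochs=3, steps=40, n=50)
        for r in recs:
            assert r.best_states.shape == (40, 50)
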