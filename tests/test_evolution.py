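"""Tests of the evolutionary operators, early stopping and the main loop."""


import numpy as np
import pytest
from scipy import stats

from evodecode.evolution import (
    EvolutionConfig,
    EvolutionTrace,
    Population,
    age_based_survival_selection,
    build_fully_connected,
    cluster_based_pruning,
    crossover,
    evolve,
    fitness_from_error,
    generalization_loss,
    init_network,
    init_population,
    make_variant,
    mutate,
    should_stop,
    tournament_select,
    training_progress,
)
from evodecode.netcore import TrainingConfig, count_metrics, validate_genome

from conftest import random_small_genome


def _error_reaches_output(genome) -> bool:
    """Graph search: does any path lead from the error input to the output?"""
    err = genome.error_input_id()
    adj: dict[int, set[int]] = {}
    for c in genome.connections:
        if c.source != c.target:
            adj.setdefault(c.source, set()).add(c.target)
    frontier, seen = {err}, set()
    while frontier:
        node = frontier.pop()
        seen.add(node)
        frontier |= adj.get(node, set()) - seen
    return genome.output_id() in seen


class TestInit:
    def test_minimal_construction_rules(self, rng):
        for _ in range(50):
            g = init_network(rng, 8)
            validate_genome(g, require_error_input=True)
            assert g.n_hidden == 1
            assert len(g.connections) in (3, 4)
            assert g.age == 0
            # error input always wired somewhere
            err = g.error_input_id()
            assert any(c.source == err for c in g.connections)

    def test_no_self_recurrence_when_disabled(self, rng):
        for _ in range(50):
            g = init_network(rng, 3, p_self_recurrent_init=0.0)
            assert all(c.kind != "self_recurrent" for c in g.connections)

    def test_population_all_minimal_and_partial(self, rng):
        cfg = EvolutionConfig(population_size=30, seed=0)
        pop = init_population(cfg, rng, 5)
        assert len(pop) == 30
        for g in pop.genomes:
            assert g.age == 0
            assert g.n_hidden == 1
            assert count_metrics(g).connection_ratio < 1.0


class TestTournament:
    def _pop(self, n):
        genomes = [init_network(np.random.default_rng(i), 2) for i in range(n)]
        fitness = [float(i) for i in range(n)]
        return Population(genomes=genomes, fitness=fitness)

    def test_full_size_returns_global_best(self, rng):
        pop = self._pop(10)
        g, f = tournament_select(pop, rng, 10)
        assert f == 9.0

    def test_size_one_is_uniform(self, rng):
        pop = self._pop(5)
        picks = [tournament_select(pop, rng, 1)[1] for _ in range(5000)]
        freq = np.bincount(np.array(picks, dtype=int), minlength=5) / 5000
        assert np.all(np.abs(freq - 0.2) < 0.03)

    def test_size_two_best_frequency_matches_combinatorics(self, rng):
        # the best genome wins iff it is drawn: P = 1 - C(n-1,2)/C(n,2) = 2/n
        n = 10
        pop = self._pop(n)
        wins = sum(tournament_select(pop, rng, 2)[1] == n - 1 for _ in range(10000))
        assert wins / 10000 == pytest.approx(2 / n, abs=0.015)

    def test_oversized_tournament_rejected(self, rng):
        with pytest.raises(ValueError):
            tournament_select(self._pop(3), rng, 4)


class TestCrossover:
    def test_no_crossover_copies_fitter_parent(self, rng):
        a, b = init_network(rng, 3), init_network(rng, 3)
        child = crossover(a, b, rng, p_c=0.0, fitness_a=0.9, fitness_b=0.1)
        assert [(c.source, c.target, c.weight) for c in child.connections] == [
            (c.source, c.target, c.weight) for c in a.connections
        ]

    def test_hidden_layers_concatenate(self, rng):
        a = init_network(rng, 3)
        b = mutate(init_network(rng, 3), rng, 1.0)
        b2 = crossover(b, b, rng, 1.0, 1.0, 1.0)  # 2 hidden via self-cross
        assert b2.n_hidden == 2
        child = crossover(a, b2, rng, 1.0, 1.0, 0.5)
        assert child.n_hidden == a.n_hidden + b2.n_hidden
        assert child.age == 0
        validate_genome(child, require_error_input=True)

    def test_every_offspring_connection_maps_to_a_parent(self, rng):
        for _ in range(20):
            a, b = random_small_genome(rng), random_small_genome(rng)
            child = crossover(a, b, rng, 1.0, 0.3, 0.7)
            parent_weights = {round(c.weight, 12) for c in a.connections} | {
                round(c.weight, 12) for c in b.connections
            }
            for c in child.connections:
                assert round(c.weight, 12) in parent_weights

    def test_duplicate_skip_keeps_fitter_parents_weight(self, rng):
        a, b = init_network(rng, 2), init_network(rng, 2)
        out = a.output_id()
        a.connections = [c for c in a.connections if c.target != out or c.source != 0]
        from evodecode.netcore import ConnectionGene

        a.connections.append(ConnectionGene(0, out, 0.111, "skip"))
        b.connections = [c for c in b.connections if not (c.source == 0 and c.target == out)]
        b.connections.append(ConnectionGene(0, out, 0.999, "skip"))
        child = crossover(a, b, rng, 1.0, fitness_a=0.2, fitness_b=0.8)  # b fitter
        w = [c.weight for c in child.connections if c.source == 0 and c.target == out]
        assert w == [0.999]


class TestMutation:
    def test_zero_probability_no_change(self, rng):
        g = random_small_genome(rng)
        g2 = mutate(g, rng, 0.0)
        assert len(g2.connections) == len(g.connections)

    def test_saturated_genome_unchanged(self, rng):
        g = build_fully_connected(2, 2, rng)
        g2 = mutate(g, rng, 1.0)
        assert len(g2.connections) == len(g.connections)

    def test_adds_exactly_one_connection(self, rng):
        for _ in range(30):
            g = init_network(rng, 3)
            g2 = mutate(g, rng, 1.0)
            assert len(g2.connections) == len(g.connections) + 1
            validate_genome(g2, require_error_input=True)

    def test_slot_choice_uniform_chi_square(self, rng):
        g = init_network(np.random.default_rng(0), 2, p_self_recurrent_init=0.0)
        from evodecode.evolution import _absent_slots

        slots = _absent_slots(g)
        counts = dict.fromkeys([(s, t) for s, t, _ in slots], 0)
        n_draws = 10000
        for _ in range(n_draws):
            g2 = mutate(g, rng, 1.0)
            added = [
                (c.source, c.target)
                for c in g2.connections
                if not g.has_connection(c.source, c.target)
            ]
            counts[added[0]] += 1
        observed = np.array(list(counts.values()))
        chi = stats.chisquare(observed)
        assert chi.pvalue > 0.01


class TestPruning:
    def _trained_genome_and_data(self, rng, n_extra_mutations=6):
        g = random_small_genome(rng)
        while g.n_hidden < 2:
            g = crossover(g, random_small_genome(rng), rng, 1.0, 1.0, 0.0)
        X = rng.normal(size=(5, 11, g.n_inputs))
        return g, X

    def test_single_hidden_neuron_untouched(self, rng):
        g = init_network(rng, 3)
        X = rng.normal(size=(3, 11, g.n_inputs))
        g2 = cluster_based_pruning(g, X, rng, removal_prob=1.0)
        assert g2.n_hidden == 1

    def test_zero_removal_prob_no_structure_change(self, rng):
        g, X = self._trained_genome_and_data(rng)
        g2 = cluster_based_pruning(g, X, rng, removal_prob=0.0)
        assert g2.n_hidden == g.n_hidden
        assert len(g2.connections) == len(g.connections)

    def test_dead_neuron_is_pruned(self, rng):
        # all hidden neurons drive the output except the silenced victim
        g = build_fully_connected(3, 3, rng)
        X = rng.normal(size=(5, 11, g.n_inputs))
        victim = g.hidden_ids()[0]
        for c in g.connections:
            if c.source == victim and c.target == g.output_id():
                c.weight = 0.0
        g2 = cluster_based_pruning(g, X, rng, removal_prob=1.0)
        assert victim not in g2.hidden_ids()
        assert g2.n_hidden >= 1

    def test_never_empties_hidden_layer_and_no_dangling(self, rng):
        for _ in range(20):
            g, X = self._trained_genome_and_data(rng)
            g2 = cluster_based_pruning(g, X, rng, removal_prob=1.0)
            assert g2.n_hidden >= 1
            ids = {n.id for n in g2.nodes}
            for c in g2.connections:
                assert c.source in ids and c.target in ids


class TestSurvival:
    def _pop_with_ages(self, ages, rng):
        genomes = []
        for a in ages:
            g = init_network(rng, 2)
            g.age = a
            genomes.append(g)
        return Population(genomes=genomes, fitness=[0.5] * len(ages))

    def test_young_population_only_ages(self, rng):
        cfg = EvolutionConfig(abss_age_onset=10, abss_replace_slope=0.1)
        pop = self._pop_with_ages([0, 0, 0, 0], rng)
        out = age_based_survival_selection(pop, rng, cfg, 2)
        assert [g.age for g in out.genomes] == [1, 1, 1, 1]
        assert len(out) == 4

    def test_certain_replacement_of_the_very_old(self, rng):
        cfg = EvolutionConfig(abss_age_onset=2, abss_replace_slope=1.0)
        pop = self._pop_with_ages([50, 50, 50], rng)
        out = age_based_survival_selection(pop, rng, cfg, 2)
        for g in out.genomes:
            assert g.age == 0 and g.n_hidden == 1

    def test_elite_protection_and_size_conservation(self, rng):
        cfg = EvolutionConfig(abss_age_onset=0, abss_replace_slope=1.0)
        for _ in range(50):
            pop = self._pop_with_ages([9, 9, 9, 9, 9], rng)
            marker = pop.genomes[2]
            out = age_based_survival_selection(pop, rng, cfg, 2, protect=2)
            assert len(out) == 5
            assert out.genomes[2].age == marker.age + 1  # survived, aged


class TestEarlyStopping:
    def test_gl_zero_at_running_minimum(self):
        assert generalization_loss([3.0, 2.0, 1.0], 3) == 0.0

    def test_gl_direct_formula(self):
        assert generalization_loss([1.0, 1.2], 2) == pytest.approx(0.2)

    def test_gl_nonnegative_on_random_series(self, rng):
        for _ in range(50):
            series = rng.uniform(0.1, 2.0, size=20)
            for tau in range(1, 21):
                assert generalization_loss(series, tau) >= 0.0

    def test_gl_zero_everywhere_on_decreasing_series(self, rng):
        series = np.sort(rng.uniform(0.1, 2.0, size=15))[::-1]
        for tau in range(1, 16):
            assert generalization_loss(series, tau) == pytest.approx(0.0)

    def test_pk_constant_strip_is_zero(self):
        assert training_progress([1.0] * 5, 5, 5) == pytest.approx(0.0)

    def test_pk_direct_formula(self):
        assert training_progress([2.0, 1.0, 1.0, 1.0, 1.0], 5, 5) == pytest.approx(0.2)

    def test_pk_nonnegative(self, rng):
        for _ in range(50):
            series = rng.uniform(0.05, 3.0, size=12)
            assert training_progress(series, 12, 5) >= 0.0

    def test_stop_requires_strict_inequality(self):
        cfg = EvolutionConfig(strip_length=5, max_generations=100)
        trace = EvolutionTrace()
        # flat errors: GL = 0, P_k = 0 -> keep going
        for _ in range(6):
            trace.e_tr.append(1.0)
            trace.e_va.append(1.0)
        assert not should_stop(trace, 6, cfg)

    def test_stop_when_gl_exceeds_pk(self):
        cfg = EvolutionConfig(strip_length=5, max_generations=100)
        trace = EvolutionTrace()
        trace.e_tr = [1.0] * 6          # flat strip: P_k = 0
        trace.e_va = [1.0] * 5 + [1.3]  # 30% above the minimum: GL = 0.3
        assert should_stop(trace, 6, cfg)

    def test_stop_at_generation_budget(self):
        cfg = EvolutionConfig(strip_length=5, max_generations=7)
        trace = EvolutionTrace()
        trace.e_tr = [1.0] * 7
        trace.e_va = [1.0] * 7
        assert should_stop(trace, 7, cfg)


class TestVariants:
    def test_variant_flags(self):
        base = EvolutionConfig()
        assert make_variant(base, "ECPNN-EFWC").use_abss is False
        assert make_variant(base, "ECPNN-EFWA").use_cbp is False
        assert make_variant(base, "ECPNN").use_error_input is False
        assert make_variant(base, "RNN-EF").evolve_structure is False

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            make_variant(EvolutionConfig(), "ESN")

    def test_ecpnn_feature_width(self, rng):
        g = init_network(rng, 8, include_error_input=False)
        assert g.n_inputs == 16
        assert g.error_input_id() is None

    def test_rnn_ef_is_fully_connected(self, rng):
        g = build_fully_connected(4, 4, rng)
        assert count_metrics(g).connection_ratio == 1.0


def _toy_sets(rng, k_units=3, n_train=12, n_val=6):
    """Linear-ish synthetic mapping inside the tanh range."""
    n_in = 2 * k_units + 1

    def make(n):
        X = rng.normal(size=(n, 11, n_in))
        X[:, :, -1] = 0.0
        V = np.tanh(0.6 * X[:, :, 0] - 0.4 * X[:, :, 1] + 0.2 * X[:, :, 2])
        return X, V

    return make(n_train), make(n_val)


class TestEvolve:
    def test_single_generation_trace(self, rng):
        train, val = _toy_sets(rng)
        cfg = EvolutionConfig(population_size=4, max_generations=1, seed=3)
        best, trace = evolve(train, val, cfg, 3, TrainingConfig(epochs=5))
        assert len(trace) == 1
        assert trace.termination_generation == 1

    def test_population_size_and_ages_conserved(self, rng):
        # structural bookkeeping exercised through the public loop
        train, val = _toy_sets(rng)
        cfg = EvolutionConfig(population_size=6, max_generations=4, seed=1)
        _, trace = evolve(train, val, cfg, 3, TrainingConfig(epochs=4))
        assert 1 <= len(trace) <= 4
        frame = trace.to_frame()
        assert set(frame.columns) >= {"generation", "E_tr", "E_va", "E_low", "GL", "P_k"}
        assert np.all(frame["E_low"].to_numpy() <= frame["E_va"].to_numpy() + 1e-15)

    def test_returned_genome_is_partially_connected(self, rng):
        train, val = _toy_sets(rng)
        hits = 0
        for seed in range(10):
            cfg = EvolutionConfig(population_size=6, max_generations=5, seed=seed)
            best, _ = evolve(train, val, cfg, 3, TrainingConfig(epochs=4))
            hits += count_metrics(best).connection_ratio < 1.0
        assert hits >= 9

    def test_crossover_improves_over_disabled_crossover(self):
        # crossover is the only source of hidden growth; with it disabled the
        # population is stuck at one hidden neuron, which should fit the
        # stationary spike-decoding task slightly worse (paired seeds, median)
        import warnings

        from evodecode.pipeline import (
            FeatureScaler,
            TargetScaler,
            _split_train_val,
            build_training_arrays,
        )
        from evodecode.synthetic import DriftConfig, SyntheticConfig, generate_dataset

        deltas = []
        for seed in range(5):
            cfg = SyntheticConfig(
                k_units=8, n_days=2, trials_per_day=25, drift=DriftConfig.stationary(), seed=seed
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds, _ = generate_dataset(cfg)
            tr, va = _split_train_val(ds.for_days([1, 2]), np.random.default_rng(seed + 50))
            fs = FeatureScaler.fit(tr)
            ts = TargetScaler.fit(np.concatenate([t.velocities[0] for t in tr]))
            train = build_training_arrays(tr, 0, fs, ts, True)
            val = build_training_arrays(va, 0, fs, ts, True)
            on = EvolutionConfig(population_size=10, max_generations=15, seed=seed)
            off = EvolutionConfig(
                population_size=10, max_generations=15, seed=seed, p_crossover=0.0
            )
            _, tr_on = evolve(train, val, on, 8, TrainingConfig(epochs=25))
            _, tr_off = evolve(train, val, off, 8, TrainingConfig(epochs=25))
            deltas.append(min(tr_off.e_va) - min(tr_on.e_va))
        assert np.median(deltas) > 0.0

    def test_evolution_is_deterministic(self, rng):
        train, val = _toy_sets(rng)
        runs = []
        for _ in range(2):
            cfg = EvolutionConfig(population_size=4, max_generations=3, seed=11)
            best, trace = evolve(
                (train[0].copy(), train[1].copy()),
                (val[0].copy(), val[1].copy()),
                cfg,
                3,
                TrainingConfig(epochs=4),
            )
            runs.append((best.weight_vector(), list(trace.e_va)))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_fitness_ordering(self):
        assert fitness_from_error(0.0) == 1.0
        assert fitness_from_error(1.0) < fitness_from_error(0.5)
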