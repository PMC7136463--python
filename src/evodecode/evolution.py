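"""Evolutionary structure search for partially connected recurrent decoders.

The search maintains a population of network genomes.  Each generation:

1. offspring are produced by tournament selection + structural crossover
   (concatenating the parents' hidden layers and uniting their connections)
   and structural mutation (adding one absent admissible connection);
2. every offspring is trained by BPTT, inheriting its parents' trained
   weights (Lamarckian inheritance);
3. cluster-based pruning (CBP) splits each offspring's hidden neurons into a
   "better" and a "worse" significance group and stochastically removes the
   worse group;
4. age-based survival selection (ABSS) stochastically replaces long-surviving
   genomes — which tend to have accreted toward full connectivity — with
   freshly initialized minimal networks.

Evolution stops early when the generalization loss GL(tau) (the relative
excess of the current validation error over its running minimum) exceeds the
training-progress statistic P_k(tau) computed over a strip of recent
generations, or when the generation budget is exhausted.  The decoder
returned is the genome with the lowest validation error seen at any point.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .netcore import (
    CompiledNetwork,
    ConnectionGene,
    NetworkGenome,
    NodeGene,
    TrainingConfig,
    bptt_train,
    count_metrics,
    random_weight,
)

__all__ = [
    "EvolutionConfig",
    "EvolutionTrace",
    "Population",
    "VARIANTS",
    "init_network",
    "init_population",
    "tournament_select",
    "crossover",
    "mutate",
    "hidden_significance",
    "cluster_based_pruning",
    "age_based_survival_selection",
    "generalization_loss",
    "training_progress",
    "should_stop",
    "evolve",
    "make_variant",
    "build_fully_connected",
    "fitness_from_error",
]

VARIANTS = ("ECPNN-EF", "ECPNN-EFWC", "ECPNN-EFWA", "ECPNN", "RNN-EF")


@dataclass
class EvolutionConfig:
    """Hyperparameters of the structure search.

    ``p_crossover``/``p_mutation`` are the structural operator probabilities;
    the 0.75 defaults are the values a 5-fold cross-validation over the
    0.6-0.9 grid typically selects.  ``strip_length`` is the
    length of the recent-generation strip used by the training-progress
    statistic P_k.  ``abss_age_onset``/``abss_replace_slope`` parameterize the
    replacement probability min(1, slope * max(0, age - onset)).  Variant
    flags switch off CBP/ABSS or the error input, or bypass evolution
    entirely (fully connected baseline).
    """

    p_crossover: float = 0.75
    p_mutation: float = 0.75
    population_size: int = 30
    tournament_size: int = 2
    max_generations: int = 100
    strip_length: int = 5
    p_self_recurrent_init: float = 0.5
    cbp_removal_prob: float = 0.5
    abss_age_onset: int = 10
    abss_replace_slope: float = 0.1
    seed: int = 0
    # variant switches
    use_cbp: bool = True
    use_abss: bool = True
    use_error_input: bool = True
    evolve_structure: bool = True
    rnn_hidden: int = 4  # hidden width of the non-evolved fully connected baseline

    def __post_init__(self) -> None:
        for name in ("p_crossover", "p_mutation", "p_self_recurrent_init", "cbp_removal_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.strip_length < 1:
            raise ValueError("strip_length must be >= 1")


@dataclass
class EvolutionTrace:
    """Per-generation record of the best-fitness genome's errors and structure."""

    e_tr: list[float] = field(default_factory=list)
    e_va: list[float] = field(default_factory=list)
    e_low: list[float] = field(default_factory=list)
    gl: list[float] = field(default_factory=list)
    p_k: list[float] = field(default_factory=list)
    best_n_hidden: list[int] = field(default_factory=list)
    best_n_connections: list[int] = field(default_factory=list)
    best_connection_ratio: list[float] = field(default_factory=list)
    termination_generation: int | None = None

    def record(self, e_tr: float, e_va: float, genome: NetworkGenome, strip_length: int) -> None:
        self.e_tr.append(e_tr)
        self.e_va.append(e_va)
        self.e_low.append(min(self.e_low[-1], e_va) if self.e_low else e_va)
        tau = len(self.e_tr)
        self.gl.append(generalization_loss(self.e_va, tau))
        self.p_k.append(
            training_progress(self.e_tr, tau, strip_length) if tau >= strip_length else math.nan
        )
        m = count_metrics(genome)
        self.best_n_hidden.append(m.n_hidden)
        self.best_n_connections.append(m.n_connections)
        self.best_connection_ratio.append(m.connection_ratio)

    def __len__(self) -> int:
        return len(self.e_tr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(1, len(self.e_tr) + 1),
                "E_tr": self.e_tr,
                "E_va": self.e_va,
                "E_low": self.e_low,
                "GL": self.gl,
                "P_k": self.p_k,
                "best_N_h": self.best_n_hidden,
                "best_N_c": self.best_n_connections,
                "best_R_c": self.best_connection_ratio,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Population:
    genomes: list[NetworkGenome]
    fitness: list[float]

    def __len__(self) -> int:
        return len(self.genomes)


def fitness_from_error(e_tr: float) -> float:
    """Fitness of a genome given its training error: 1 / (1 + E_tr)."""
    return 1.0 / (1.0 + e_tr)


# ---------------------------------------------------------------------------
# initialization


def _make_nodes(k_units: int, include_error_input: bool, n_hidden: int) -> list[NodeGene]:
    n_in = 2 * k_units + (1 if include_error_input else 0)
    nodes = [
        NodeGene(i, "input", "error_input" if include_error_input and i == n_in - 1 else "neuronal_input")
        for i in range(n_in)
    ]
    nodes.append(NodeGene(n_in, "output", "output"))
    nodes += [NodeGene(n_in + 1 + j, "hidden", "hidden") for j in range(n_hidden)]
    return nodes


def init_network(
    rng: np.random.Generator,
    k_units: int,
    p_self_recurrent_init: float = 0.5,
    include_error_input: bool = True,
) -> NetworkGenome:
    """Minimal partially connected starting genome.

    One hidden neuron; one connection from a random non-error input to the
    hidden neuron; one skip connection from a random non-error input to the
    output; the error input (when present) wired to the hidden neuron or the
    output with equal probability; a self-recurrence on the hidden neuron
    with probability ``p_self_recurrent_init``.
    """
    if k_units < 1:
        raise ValueError("k_units must be >= 1")
    nodes = _make_nodes(k_units, include_error_input, n_hidden=1)
    n_in = 2 * k_units + (1 if include_error_input else 0)
    out_id, hid_id = n_in, n_in + 1
    n_neuronal = 2 * k_units
    conns = [
        ConnectionGene(int(rng.integers(n_neuronal)), hid_id, random_weight(rng), "forward"),
        ConnectionGene(int(rng.integers(n_neuronal)), out_id, random_weight(rng), "skip"),
    ]
    if include_error_input:
        err_id = n_in - 1
        if rng.random() < 0.5:
            conns.append(ConnectionGene(err_id, hid_id, random_weight(rng), "forward"))
        else:
            conns.append(ConnectionGene(err_id, out_id, random_weight(rng), "skip"))
    # the two random non-error picks may coincide with an existing slot only
    # across different kinds, so no duplicate (source, target) can arise here
    if rng.random() < p_self_recurrent_init:
        conns.append(ConnectionGene(hid_id, hid_id, random_weight(rng), "self_recurrent"))
    return NetworkGenome(nodes=nodes, connections=conns, age=0)


def init_population(
    config: EvolutionConfig, rng: np.random.Generator, k_units: int
) -> Population:
    genomes = [
        init_network(
            rng,
            k_units,
            p_self_recurrent_init=config.p_self_recurrent_init,
            include_error_input=config.use_error_input,
        )
        for _ in range(config.population_size)
    ]
    return Population(genomes=genomes, fitness=[math.nan] * len(genomes))


# ---------------------------------------------------------------------------
# variation operators


def tournament_select(
    population: Population, rng: np.random.Generator, size: int
) -> tuple[NetworkGenome, float]:
    """Best-fitness genome among ``size`` draws without replacement."""
    if size < 1 or size > len(population):
        raise ValueError("tournament size must be in [1, population size]")
    idx = rng.choice(len(population), size=size, replace=False)
    best = max(idx, key=lambda i: population.fitness[i])
    return population.genomes[best], population.fitness[best]


def _remap_hidden(genome: NetworkGenome, n_in: int, out_id: int, next_hidden: int) -> tuple[list[NodeGene], list[ConnectionGene], int]:
    """Renumber a parent's hidden nodes into a fresh id range."""
    mapping = {}
    nodes = []
    for h in genome.hidden_ids():
        mapping[h] = next_hidden
        nodes.append(NodeGene(next_hidden, "hidden", "hidden"))
        next_hidden += 1
    conns = []
    for c in genome.connections:
        src = mapping.get(c.source, c.source)
        tgt = mapping.get(c.target, c.target)
        conns.append(ConnectionGene(src, tgt, c.weight, c.kind))
    return nodes, conns, next_hidden


def crossover(
    parent_a: NetworkGenome,
    parent_b: NetworkGenome,
    rng: np.random.Generator,
    p_c: float,
    fitness_a: float = 0.0,
    fitness_b: float = 0.0,
) -> NetworkGenome:
    """Structural crossover: concatenate hidden layers, unite connections.

    With probability ``p_c`` the offspring carries every hidden neuron of
    both parents (ids remapped) and the union of their connections; where the
    same (source, target) slot exists in both parents — possible only for
    input->output skips — the fitter parent's weight is kept.  Otherwise the
    offspring is a copy of the fitter parent, retaining its age so that
    long-surviving structures remain visible to age-based selection.
    A genuinely crossed-over offspring is a new structure and starts at age 0.
    """
    fitter, other = (
        (parent_a, parent_b) if fitness_a >= fitness_b else (parent_b, parent_a)
    )
    if rng.random() >= p_c:
        return fitter.copy()
    n_in = fitter.n_inputs
    if other.n_inputs != n_in:
        raise ValueError("parents must share the input layer")
    out_id = n_in
    base = [n for n in fitter.nodes if n.layer != "hidden"]
    nodes_f, conns_f, nxt = _remap_hidden(fitter, n_in, out_id, n_in + 1)
    nodes_o, conns_o, _ = _remap_hidden(other, n_in, out_id, nxt)
    seen = {(c.source, c.target) for c in conns_f}
    merged = conns_f + [c for c in conns_o if (c.source, c.target) not in seen]
    return NetworkGenome(nodes=base + nodes_f + nodes_o, connections=list(map(copy.copy, merged)), age=0)


def _absent_slots(genome: NetworkGenome) -> list[tuple[int, int, str]]:
    present = {(c.source, c.target) for c in genome.connections}
    out_id = genome.output_id()
    slots: list[tuple[int, int, str]] = []
    for i in genome.input_ids():
        for h in genome.hidden_ids():
            if (i, h) not in present:
                slots.append((i, h, "forward"))
        if (i, out_id) not in present:
            slots.append((i, out_id, "skip"))
    for h in genome.hidden_ids():
        if (h, out_id) not in present:
            slots.append((h, out_id, "forward"))
        if (h, h) not in present:
            slots.append((h, h, "self_recurrent"))
    return slots


def mutate(genome: NetworkGenome, rng: np.random.Generator, p_m: float) -> NetworkGenome:
    """With probability ``p_m`` add one absent admissible connection.

    The slot is drawn uniformly over all absent input->hidden, input->output,
    hidden->output and hidden-self slots and receives a fresh random weight.
    A saturated (fully connected) genome is returned unchanged.
    """
    child = genome.copy()
    if rng.random() >= p_m:
        return child
    slots = _absent_slots(child)
    if not slots:
        return child
    src, tgt, kind = slots[int(rng.integers(len(slots)))]
    child.connections.append(ConnectionGene(src, tgt, random_weight(rng), kind))
    return child


# ---------------------------------------------------------------------------
# cluster-based pruning


def hidden_significance(
    genome: NetworkGenome, features: np.ndarray, targets: np.ndarray | None = None
) -> np.ndarray:
    """Output-contribution variability score per hidden neuron.

    The score is the standard deviation, over all trial-bins, of the neuron's
    activation multiplied by the magnitude of its outgoing weight to the
    output.  A neuron whose activity never moves the output (constant
    activation or zero outgoing weight) scores 0.
    """
    net = CompiledNetwork(genome)
    X = np.asarray(features, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    _, H = net.forward(X.copy(), targets=targets, dynamic_feedback=targets is not None)
    contrib = H * np.abs(net.W_ho * net.M_ho)[None, None, :]
    return contrib.reshape(-1, net.n_h).std(axis=0)


def _two_means_split(scores: np.ndarray) -> np.ndarray:
    """Exact 1-D two-cluster partition minimizing within-cluster SSE.

    Returns a boolean mask marking the *worse* (lower-mean) cluster.  Both
    clusters are nonempty; ties in score are broken by sort order.
    """
    order = np.argsort(scores)
    s = scores[order]
    n = len(s)
    best_cut, best_sse = 1, np.inf
    for cut in range(1, n):
        lo, hi = s[:cut], s[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best_cut = sse, cut
    worse = np.zeros(n, dtype=bool)
    worse[order[:best_cut]] = True
    return worse


def cluster_based_pruning(
    genome: NetworkGenome,
    features: np.ndarray,
    rng: np.random.Generator,
    removal_prob: float,
    targets: np.ndarray | None = None,
) -> NetworkGenome:
    """Stochastically remove the less significant hidden-neuron cluster.

    Hidden neurons are scored by :func:`hidden_significance`, split into a
    better and a worse group by an exact two-means partition, and each member
    of the worse group is removed with probability ``removal_prob`` together
    with all its connections.  A genome with a single hidden neuron (or with
    indistinguishable scores) is returned unchanged; because both clusters
    are nonempty, at least one hidden neuron always survives.
    """
    if genome.n_hidden < 2 or removal_prob <= 0.0:
        return genome.copy()
    scores = hidden_significance(genome, features, targets=targets)
    if np.ptp(scores) < 1e-12:
        return genome.copy()
    worse = _two_means_split(scores)
    hid_ids = np.array(genome.hidden_ids())
    doomed = {
        int(h)
        for h, w in zip(hid_ids, worse)
        if w and rng.random() < removal_prob
    }
    if not doomed:
        return genome.copy()
    child = genome.copy()
    child.nodes = [n for n in child.nodes if n.id not in doomed]
    child.connections = [
        c for c in child.connections if c.source not in doomed and c.target not in doomed
    ]
    return child


# ---------------------------------------------------------------------------
# age-based survival selection


def age_based_survival_selection(
    population: Population,
    rng: np.random.Generator,
    config: EvolutionConfig,
    k_units: int,
    protect: int | None = None,
) -> Population:
    """Replace over-aged genomes with fresh minimal networks.

    Each genome is replaced with probability
    min(1, abss_replace_slope * max(0, age - abss_age_onset)); survivors age
    by one generation.  ``protect`` exempts one index (the current elite) so
    the best validation performer is never lost to replacement.  Fresh
    replacements carry NaN fitness until trained.  Population size is
    conserved.
    """
    genomes: list[NetworkGenome] = []
    fitness: list[float] = []
    for i, g in enumerate(population.genomes):
        p_replace = min(1.0, config.abss_replace_slope * max(0, g.age - config.abss_age_onset))
        if i != protect and rng.random() < p_replace:
            fresh = init_network(
                rng,
                k_units,
                p_self_recurrent_init=config.p_self_recurrent_init,
                include_error_input=config.use_error_input,
            )
            genomes.append(fresh)
            fitness.append(math.nan)
        else:
            survivor = g.copy()
            survivor.age += 1
            genomes.append(survivor)
            fitness.append(population.fitness[i])
    return Population(genomes=genomes, fitness=fitness)


# ---------------------------------------------------------------------------
# early stopping


def generalization_loss(e_va_series: list[float] | np.ndarray, tau: int) -> float:
    """GL(tau) = E_va(tau) / E_low(tau) - 1, with E_low the running minimum.

    ``tau`` is the 1-based generation index into the validation-error series.
    """
    if tau < 1 or tau > len(e_va_series):
        raise ValueError("tau out of range")
    e_low = float(np.min(np.asarray(e_va_series[:tau], dtype=float)))
    if e_low <= 0.0:
        raise ValueError("E_low is zero: generalization loss undefined (perfect fit)")
    return float(e_va_series[tau - 1]) / e_low - 1.0


def training_progress(e_tr_series: list[float] | np.ndarray, tau: int, strip_k: int) -> float:
    """P_k(tau): mean-over-minimum excess of the training error on a strip.

    The strip covers generations tau - k + 1 .. tau (1-based).  P_k is the
    strip's summed training error divided by (k times the strip minimum),
    minus 1; it is 0 for a flat strip and nonnegative always.
    """
    if tau < strip_k:
        raise ValueError("tau must be >= strip length")
    if tau > len(e_tr_series):
        raise ValueError("tau out of range")
    strip = np.asarray(e_tr_series[tau - strip_k : tau], dtype=float)
    m = float(strip.min())
    if m <= 0.0:
        raise ValueError("strip minimum is zero: training progress undefined")
    return float(strip.sum()) / (strip_k * m) - 1.0


def should_stop(trace: EvolutionTrace, tau: int, config: EvolutionConfig) -> bool:
    """Stop when GL(tau) strictly exceeds P_k(tau), or the budget runs out."""
    if tau >= config.max_generations:
        return True
    if tau < config.strip_length:
        return False
    gl = generalization_loss(trace.e_va, tau)
    pk = training_progress(trace.e_tr, tau, config.strip_length)
    return gl > pk


# ---------------------------------------------------------------------------
# main loop


def _train_eval(
    genome: NetworkGenome,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    training: TrainingConfig,
    dynamic_feedback: bool,
) -> tuple[float, float]:
    """BPTT-train in place; return (E_tr, E_va) as mean per-bin errors."""
    _, e_tr = bptt_train(genome, train, training, dynamic_feedback=dynamic_feedback)
    e_va = _evaluate(genome, val, dynamic_feedback)
    return e_tr, e_va


def _evaluate(
    genome: NetworkGenome, data: tuple[np.ndarray, np.ndarray], dynamic_feedback: bool
) -> float:
    X, V = data
    net = CompiledNetwork(genome)
    Y, _ = net.forward(np.array(X, dtype=float), targets=V, dynamic_feedback=dynamic_feedback)
    return float(np.mean((Y - V) ** 2))


def evolve(
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: EvolutionConfig,
    k_units: int,
    training: TrainingConfig | None = None,
) -> tuple[NetworkGenome, EvolutionTrace]:
    """Run the full structure search and return the selected decoder.

    ``train_set``/``val_set`` are pre-stacked ``(features (B, T, n_in),
    targets (B, T))`` arrays on the network's tanh scale.  The trace records,
    per generation, the training and validation error of the best-fitness
    genome, the running validation minimum, GL, P_k and the best genome's
    structure counts.  The returned genome is the one with the lowest
    validation error observed in any generation (not necessarily the last).

    With ``config.evolve_structure`` False, a fully connected recurrent
    baseline of width ``config.rnn_hidden`` is built and BPTT-trained once;
    the trace then has a single generation.
    """
    training = training or TrainingConfig()
    rng = np.random.default_rng(config.seed)
    feedback = config.use_error_input
    trace = EvolutionTrace()

    if not config.evolve_structure:
        genome = build_fully_connected(
            k_units, config.rnn_hidden, rng, include_error_input=config.use_error_input
        )
        e_tr, e_va = _train_eval(genome, train_set, val_set, training, feedback)
        trace.record(e_tr, e_va, genome, config.strip_length)
        trace.termination_generation = 1
        return genome, trace

    pop = init_population(config, rng, k_units)
    e_va_pop = [math.nan] * len(pop)
    for i, g in enumerate(pop.genomes):
        e_tr, e_va = _train_eval(g, train_set, val_set, training, feedback)
        pop.fitness[i] = fitness_from_error(e_tr)
        e_va_pop[i] = e_va

    best_genome = pop.genomes[int(np.argmin(e_va_pop))].copy()
    best_e_va = float(np.min(e_va_pop))

    for tau in range(1, config.max_generations + 1):
        offspring: list[NetworkGenome] = []
        for _ in range(len(pop)):
            a, fa = tournament_select(pop, rng, config.tournament_size)
            b, fb = tournament_select(pop, rng, config.tournament_size)
            child = crossover(a, b, rng, config.p_crossover, fa, fb)
            child = mutate(child, rng, config.p_mutation)
            offspring.append(child)

        e_tr_off, e_va_off = [], []
        for child in offspring:
            e_tr, e_va = _train_eval(child, train_set, val_set, training, feedback)
            e_tr_off.append(e_tr)
            e_va_off.append(e_va)

        if config.use_cbp:
            for i, child in enumerate(offspring):
                pruned = cluster_based_pruning(
                    child,
                    train_set[0],
                    rng,
                    config.cbp_removal_prob,
                    targets=train_set[1] if feedback else None,
                )
                if pruned.n_hidden != child.n_hidden:
                    offspring[i] = pruned
                    e_tr_off[i] = _evaluate(pruned, train_set, feedback)
                    e_va_off[i] = _evaluate(pruned, val_set, feedback)

        fits = [fitness_from_error(e) for e in e_tr_off]
        best_fit_idx = int(np.argmax(fits))
        trace.record(
            e_tr_off[best_fit_idx], e_va_off[best_fit_idx], offspring[best_fit_idx], config.strip_length
        )

        gen_best_va = int(np.argmin(e_va_off))
        if e_va_off[gen_best_va] < best_e_va:
            best_e_va = e_va_off[gen_best_va]
            best_genome = offspring[gen_best_va].copy()

        pop = Population(genomes=offspring, fitness=fits)
        if config.use_abss:
            pop = age_based_survival_selection(pop, rng, config, k_units, protect=gen_best_va)
            for i, g in enumerate(pop.genomes):
                if math.isnan(pop.fitness[i]):
                    e_tr, _ = _train_eval(g, train_set, val_set, training, feedback)
                    pop.fitness[i] = fitness_from_error(e_tr)
        else:
            for g in pop.genomes:
                g.age += 1

        if should_stop(trace, tau, config):
            break

    trace.termination_generation = len(trace)
    return best_genome, trace


# ---------------------------------------------------------------------------
# variants


def make_variant(config: EvolutionConfig, variant: str) -> EvolutionConfig:
    """Derive the configuration of a named decoder variant.

    ECPNN-EF is the full method; ECPNN-EFWC keeps only CBP (no ABSS);
    ECPNN-EFWA keeps only ABSS (no CBP); ECPNN drops the error input
    (no error-correction learning); RNN-EF bypasses evolution and trains a
    fully connected recurrent network with ``config.rnn_hidden`` hidden
    neurons, matched to the evolved decoder's width for fair comparison.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "ECPNN-EF":
        return replace(config, use_cbp=True, use_abss=True, use_error_input=True, evolve_structure=True)
    if variant == "ECPNN-EFWC":
        return replace(config, use_cbp=True, use_abss=False, use_error_input=True, evolve_structure=True)
    if variant == "ECPNN-EFWA":
        return replace(config, use_cbp=False, use_abss=True, use_error_input=True, evolve_structure=True)
    if variant == "ECPNN":
        return replace(config, use_cbp=True, use_abss=True, use_error_input=False, evolve_structure=True)
    return replace(config, use_error_input=True, evolve_structure=False)


def build_fully_connected(
    k_units: int,
    n_hidden: int,
    rng: np.random.Generator,
    include_error_input: bool = True,
) -> NetworkGenome:
    """Fully connected recurrent genome (R_c = 1) with random weights."""
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    nodes = _make_nodes(k_units, include_error_input, n_hidden)
    n_in = 2 * k_units + (1 if include_error_input else 0)
    out_id = n_in
    hid = [n.id for n in nodes if n.layer == "hidden"]
    conns = []
    for i in range(n_in):
        for h in hid:
            conns.append(ConnectionGene(i, h, random_weight(rng), "forward"))
        conns.append(ConnectionGene(i, out_id, random_weight(rng), "skip"))
    for h in hid:
        conns.append(ConnectionGene(h, out_id, random_weight(rng), "forward"))
        conns.append(ConnectionGene(h, h, random_weight(rng), "self_recurrent"))
    return NetworkGenome(nodes=nodes, connections=conns, age=0)
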