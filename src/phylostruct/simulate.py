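"""Stochastic birth-death(-migration) simulation of rooted phylogenies.

A structured host population is modelled as two demes S1, S2.  Each extant
lineage in deme i gives birth at rate ``lambda_i``, dies at rate ``mu_i`` and
migrates to the other deme at rate ``alpha_ij``.  The waiting time to the next
event in deme i is exponential with rate ``N_i(t) (lambda_i + mu_i +
alpha_ij)`` where ``N_i(t)`` is the number of extant lineages in the deme.

The simulation starts from a single lineage, draws which deme hosts the next
event, which lineage it hits (uniformly within the deme) and which event type
occurs, and stops once the configured number of extant lineages is reached.
Dead lineages are pruned from the returned tree; migration events remain as
unifurcating colour-change nodes.

Deme selection follows the sub-total-rate rule: deme i is chosen with
probability ``T_Si / (T_Si + T_Sj)`` where ``T_Si = lambda_i + mu_i +
alpha_ij``, restricted to demes that currently have extant lineages.  A
population-weighted alternative (weights ``N_i T_Si``, the classical Gillespie
choice) is available via ``SimulationConfig.deme_weighting = "population"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import Node, Phylogeny

__all__ = [
    "DemeParameters", "SimulationConfig", "SimulatorState", "SimulationError",
    "draw_waiting_time", "select_deme", "select_event",
    "simulate_structured_tree", "simulate_unstructured_tree",
    "prune_extinct_lineages", "simulate_dataset", "TreeDataset",
    "baseline_design", "varied_design", "dataset2_design",
    "DEFAULT_UNSTRUCTURED", "DEFAULT_STRUCTURED",
]

BIRTH, MIGRATION, DEATH = "birth", "migration", "death"


class SimulationError(RuntimeError):
    """Raised when a simulation cannot complete (extinction, runaway, ...)."""


@dataclass(frozen=True)
class DemeParameters:
    """Per-lineage rates of one sub-population (all in 1/time units)."""

    birth_rate: float
    death_rate: float = 0.0
    emigration_rate: float = 0.0

    def __post_init__(self):
        # birth_rate may be 0 for epidemic-model edge cases; the simulator
        # itself requires a positive birth rate.
        if self.birth_rate < 0 or self.death_rate < 0 or self.emigration_rate < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def subtotal_rate(self) -> float:
        """T_Si = lambda_i + mu_i + alpha_ij."""
        return self.birth_rate + self.death_rate + self.emigration_rate


@dataclass
class SimulatorState:
    """Extant lineage counts, elapsed time and per-deme sub-total rates."""

    extant_count_per_deme: list[int]
    current_time: float
    subtotal_rates: list[float]


@dataclass(frozen=True)
class SimulationConfig:
    """Target sizes and bookkeeping knobs for one simulated tree.

    ``n_tips`` is the per-deme target pair for a structured tree.  With the
    default ``termination="total"`` the run stops once the total number of
    extant lineages reaches ``sum(n_tips)`` (so every returned tree has
    exactly that many tips); ``termination="joint"`` instead stops the first
    time both demes simultaneously meet their per-deme targets, in which case
    the faster-growing deme may overshoot its quota.
    """

    n_tips: tuple[int, int]
    start_deme: int = 0  # 0-based index
    max_events: int = 5_000_000
    max_retries: int = 100
    termination: str = "total"  # or "joint"
    deme_weighting: str = "subtotal"  # or "population"

    def __post_init__(self):
        if sum(self.n_tips) < 2:
            raise ValueError("need at least two target tips")
        if any(n < 0 for n in self.n_tips):
            raise ValueError("negative tip target")
        if self.max_events <= 0:
            raise ValueError("max_events must be positive")
        if self.termination not in ("total", "joint"):
            raise ValueError("termination must be 'total' or 'joint'")
        if self.deme_weighting not in ("subtotal", "population"):
            raise ValueError("deme_weighting must be 'subtotal' or 'population'")


# ---------------------------------------------------------------------------
# Elementary draws (exposed for testing against their distributions)
# ---------------------------------------------------------------------------

def draw_waiting_time(state: SimulatorState, deme: int,
                      rng: np.random.Generator) -> float:
    """Exponential waiting time to the next event in ``deme``.

    Rate parameter is ``N_i(t) * T_Si``; raises ``SimulationError`` if the
    deme has no extant lineages or a zero sub-total rate.
    """
    rate = state.extant_count_per_deme[deme] * state.subtotal_rates[deme]
    if rate <= 0:
        raise SimulationError("deme inactive: no events possible")
    # inverse-CDF draw keeps the stream aligned with plain uniform draws
    return -math.log1p(-rng.random()) / rate


def select_deme(state: SimulatorState, u: float,
                weighting: str = "subtotal") -> int:
    """Deme hosting the next event, from a uniform draw ``u`` in [0, 1].

    Under ``"subtotal"`` weighting deme i is returned iff
    ``u <= T_Si / (T_Si + T_Sj)``; under ``"population"`` the weights are
    ``N_i T_Si``.  Demes without extant lineages are excluded.
    """
    counts = state.extant_count_per_deme
    if weighting == "subtotal":
        weights = [t if n > 0 else 0.0
                   for n, t in zip(counts, state.subtotal_rates)]
    else:
        weights = [n * t for n, t in zip(counts, state.subtotal_rates)]
    total = sum(weights)
    if total <= 0:
        raise SimulationError("population extinct")
    return 0 if u <= weights[0] / total else 1


def select_event(params: DemeParameters, sigma: float) -> str:
    """Event type from a uniform draw ``sigma``.

    birth iff sigma <= lambda/T; migration iff lambda/T < sigma <=
    (lambda + alpha)/T; death otherwise.
    """
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    t = params.subtotal_rate
    if sigma <= params.birth_rate / t:
        return BIRTH
    if sigma <= (params.birth_rate + params.emigration_rate) / t:
        return MIGRATION
    return DEATH


# ---------------------------------------------------------------------------
# Whole-tree simulation
# ---------------------------------------------------------------------------

def _attempt_tree(params: tuple[DemeParameters, DemeParameters],
                  config: SimulationConfig,
                  rng: np.random.Generator) -> Optional[Phylogeny]:
    """One simulation attempt; ``None`` signals extinction before the target."""
    subtotals = [p.subtotal_rate for p in params]
    target_total = sum(config.n_tips)
    root = Node(deme=config.start_deme + 1)
    root.t0 = 0.0
    extant: list[list[Node]] = [[], []]
    extant[config.start_deme].append(root)
    dead: list[Node] = []
    t = 0.0
    n_events = 0
    state = SimulatorState([0, 0], 0.0, subtotals)

    while True:
        n1, n2 = len(extant[0]), len(extant[1])
        if config.termination == "total":
            if n1 + n2 >= target_total:
                break
        else:
            if n1 >= config.n_tips[0] and n2 >= config.n_tips[1]:
                break
        if n1 + n2 == 0:
            return None  # extinct
        state.extant_count_per_deme[0] = n1
        state.extant_count_per_deme[1] = n2
        state.current_time = t

        i = select_deme(state, rng.random(), config.deme_weighting)
        t += draw_waiting_time(state, i, rng)
        lineages = extant[i]
        idx = int(rng.integers(len(lineages)))
        node = lineages[idx]
        event = select_event(params[i], rng.random())
        node.edge_length = t - node.t0

        if event == BIRTH:
            left = node.add_child(Node(deme=node.deme))
            right = node.add_child(Node(deme=node.deme))
            left.t0 = right.t0 = t
            lineages[idx] = left
            lineages.append(right)
        elif event == MIGRATION:
            j = 1 - i
            node.is_migration = True
            child = node.add_child(Node(deme=j + 1))
            child.t0 = t
            lineages[idx] = lineages[-1]
            lineages.pop()
            extant[j].append(child)
        else:  # DEATH
            node.alive = False
            dead.append(node)
            lineages[idx] = lineages[-1]
            lineages.pop()

        n_events += 1
        if n_events > config.max_events:
            raise SimulationError("runaway simulation: max event count exceeded")

    # close extant branches at the stopping time
    for lineages in extant:
        for node in lineages:
            node.edge_length = t - node.t0

    tree = Phylogeny(root, metadata={
        "termination": config.termination,
        "n_events": n_events,
        "t_end": t,
    })
    if dead:
        tree = prune_extinct_lineages(tree)
    for k, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = str(k)
    return tree


def simulate_structured_tree(params: Sequence[DemeParameters],
                             config: SimulationConfig,
                             rng: np.random.Generator) -> Phylogeny:
    """Simulate one structured tree; retries from scratch on extinction.

    Emits a ``UserWarning`` when the per-deme reproduction numbers are all
    subcritical (the process then rarely reaches the target size).
    """
    params = tuple(params)
    if len(params) != 2:
        raise ValueError("exactly two deme parameter sets required")
    if any(p.birth_rate <= 0 for p in params):
        raise ValueError("simulation requires positive birth rates")
    growth = [p.birth_rate - p.death_rate - p.emigration_rate for p in params]
    if all(g <= 0 for g in growth):
        import warnings
        warnings.warn("process is subcritical in both demes; the simulation "
                      "may fail to reach the target size", UserWarning)
    for _ in range(config.max_retries + 1):
        tree = _attempt_tree(params, config, rng)
        if tree is not None:
            tree.metadata["label"] = "structured"
            return tree
    raise SimulationError(
        f"simulation failed: extinction in all {config.max_retries + 1} attempts")


def simulate_unstructured_tree(birth_rate: float, death_rate: float,
                               n_tips: int,
                               rng: np.random.Generator,
                               max_retries: int = 100) -> Phylogeny:
    """Simulate a plain birth-death tree with exactly ``n_tips`` extant tips.

    The single-deme special case: no migration, constant deme label, binary
    tree with ``n_tips - 1`` internal nodes.
    """
    params = DemeParameters(birth_rate, death_rate, 0.0)
    config = SimulationConfig(n_tips=(n_tips, 0), start_deme=0,
                              max_retries=max_retries)
    tree = simulate_structured_tree((params, params), config, rng)
    tree.metadata["label"] = "non-structured"
    return tree


def prune_extinct_lineages(tree: Phylogeny) -> Phylogeny:
    """Remove dead tips and suppress the unifurcations pruning creates.

    Migration (colour-change) unifurcations are retained; unifurcations that
    arise because one side of a bifurcation went extinct are collapsed, with
    branch lengths summed.  Raises ``SimulationError`` if no tip survives.
    """
    dead = [n for n in tree.iter_preorder() if n.is_leaf and not n.alive]
    if not any(n.alive for n in tree.iter_preorder() if n.is_leaf):
        raise SimulationError("population extinct: no extant tips")

    # phase 1: delete dead tips and any internal node left childless
    for node in dead:
        parent = node.parent
        while parent is not None:
            parent.children.remove(node)
            if parent.children:
                break
            node, parent = parent, parent.parent
        # a childless root would mean no extant tips, excluded above

    # phase 2: collapse non-migration unifurcations (postorder: children first)
    for node in list(tree.iter_postorder()):
        if len(node.children) == 1 and not node.is_migration:
            child = node.children[0]
            child.edge_length += node.edge_length
            parent = node.parent
            if parent is None:
                child.parent = None
                tree.root = child
            else:
                parent.children[parent.children.index(node)] = child
                child.parent = parent
    return tree


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

# Default rates, motivated by HIV epidemiology in Uganda: adult death rate
# 0.014/yr (tripled in the high-risk deme), literature R0 estimates 4.99
# (general population) and 9.09 (high-risk), out-migration rates 0.3 and 0.2.
# Birth rates follow from lambda_i = R0_i (2 alpha_ij + mu_i).
DEFAULT_UNSTRUCTURED = {"r0": 4.99, "mu": 0.014, "n_tips": 350}
DEFAULT_STRUCTURED = {
    "r0_1": 4.99, "mu_1": 0.014, "alpha_12": 0.3, "n_tips_1": 350,
    "r0_2": 9.09, "mu_2": 0.042, "alpha_21": 0.2, "n_tips_2": 200,
}

_DESIGN_COLUMNS = ["replicate_id", "label", "seed",
                   "lambda_1", "mu_1", "alpha_12", "n_tips_1",
                   "lambda_2", "mu_2", "alpha_21", "n_tips_2"]


def _lambda(r0, mu, alpha=0.0):
    return r0 * (2 * alpha + mu)


def _derive_seed(base_seed: int, index: int) -> int:
    return (int(base_seed) + index) % (2 ** 31)


def baseline_design(seed: int, n_unstructured: int = 500,
                    n_structured: int = 500) -> pd.DataFrame:
    """Per-tree parameter table for the baseline dataset.

    Non-structured trees: mu = 0.014, R0 = 4.99 (lambda = 0.0699), 350 tips.
    Structured trees: deme 1 mu = 0.014, alpha = 0.3, R0 = 4.99 (lambda =
    3.0639), quota 350 tips; deme 2 mu = 0.042, alpha = 0.2, R0 = 9.09
    (lambda = 4.0178), quota 200 tips.
    """
    u, s = DEFAULT_UNSTRUCTURED, DEFAULT_STRUCTURED
    rows = []
    for i in range(n_unstructured):
        rows.append(("u%04d" % i, "non-structured", _derive_seed(seed, i),
                     _lambda(u["r0"], u["mu"]), u["mu"], 0.0, u["n_tips"],
                     np.nan, np.nan, np.nan, 0))
    for i in range(n_structured):
        rows.append(("s%04d" % i, "structured",
                     _derive_seed(seed, n_unstructured + i),
                     _lambda(s["r0_1"], s["mu_1"], s["alpha_12"]), s["mu_1"],
                     s["alpha_12"], s["n_tips_1"],
                     _lambda(s["r0_2"], s["mu_2"], s["alpha_21"]), s["mu_2"],
                     s["alpha_21"], s["n_tips_2"]))
    return pd.DataFrame(rows, columns=_DESIGN_COLUMNS)


def _stratified_uniform(interval, n, rng, sampler):
    lo, hi = interval
    if not hi > lo:
        raise ValueError("empty interval")
    if sampler == "uniform":
        return lo + (hi - lo) * rng.random(n)
    from .design import latin_hypercube_design
    design = latin_hypercube_design({"x": (lo, hi)}, n, rng)
    return design.samples["x"].to_numpy()


def varied_design(seed: int, mode: str,
                  n_unstructured: int = 250, n_structured: int = 250,
                  size_intervals=((300, 400), (250, 300)),
                  unstructured_size_interval=(300, 400),
                  r0_intervals=((0.45, 6.34), (4.18, 36.75)),
                  sampler: str = "lhs") -> pd.DataFrame:
    """Per-tree parameter table with tree sizes and/or R0 drawn from intervals.

    ``mode`` is one of ``"varied-size"``, ``"varied-parameters"`` or
    ``"both"``.  Sizes and R0 values are drawn by Latin hypercube sampling
    (default) or plain uniform sampling.  In the varied-parameters modes only
    the structured demes' R0 are varied; the stated interval for deme 1
    reaches below the R0 = 1 persistence threshold, which a structured tree
    tolerates (deme 2 remains strongly supercritical) but under which a
    non-structured tree could never reach its target size, so non-structured
    rates stay at baseline.
    """
    if mode not in ("varied-size", "varied-parameters", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    base = baseline_design(seed, n_unstructured, n_structured)
    rng = np.random.default_rng(_derive_seed(seed, 10_000))
    unstr = base["label"] == "non-structured"
    if mode in ("varied-size", "both"):
        base.loc[unstr, "n_tips_1"] = np.round(_stratified_uniform(
            unstructured_size_interval, n_unstructured, rng, sampler)).astype(int)
        base.loc[~unstr, "n_tips_1"] = np.round(_stratified_uniform(
            size_intervals[0], n_structured, rng, sampler)).astype(int)
        base.loc[~unstr, "n_tips_2"] = np.round(_stratified_uniform(
            size_intervals[1], n_structured, rng, sampler)).astype(int)
    if mode in ("varied-parameters", "both"):
        s = DEFAULT_STRUCTURED
        r0_1 = _stratified_uniform(r0_intervals[0], n_structured, rng, sampler)
        r0_2 = _stratified_uniform(r0_intervals[1], n_structured, rng, sampler)
        base.loc[~unstr, "lambda_1"] = _lambda(r0_1, s["mu_1"], s["alpha_12"])
        base.loc[~unstr, "lambda_2"] = _lambda(r0_2, s["mu_2"], s["alpha_21"])
    return base


def dataset2_design(seed: int, n_unstructured: int = 500,
                    n_structured: int = 500) -> pd.DataFrame:
    """Variant of the baseline with tip counts drawn uniformly per tree:
    non-structured in (300, 400); structured deme quotas in (300, 400) and
    (150, 250)."""
    return varied_design(seed, "varied-size", n_unstructured, n_structured,
                         size_intervals=((300, 400), (150, 250)),
                         unstructured_size_interval=(300, 400),
                         sampler="uniform")


@dataclass
class TreeDataset:
    """Simulated trees plus the per-tree design/manifest table."""

    trees: list[Phylogeny]
    manifest: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def labels(self) -> list[str]:
        return [t.metadata["label"] for t in self.trees]


def simulate_dataset(design: pd.DataFrame, *,
                     termination: str = "total",
                     progress: bool = False) -> TreeDataset:
    """Simulate every tree described by a design table.

    The design holds one row per replicate (see :func:`baseline_design`);
    each tree gets its own seeded generator, so generation is reproducible
    and order-independent.  A replicate that fails after all retries aborts
    the dataset with a report of the failing row.
    """
    trees = []
    iterator = design.itertuples()
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, total=len(design))
        except ImportError:
            pass
    for row in iterator:
        rng = np.random.default_rng(int(row.seed))
        try:
            if row.label == "non-structured":
                tree = simulate_unstructured_tree(
                    row.lambda_1, row.mu_1, int(row.n_tips_1), rng)
            else:
                params = (DemeParameters(row.lambda_1, row.mu_1, row.alpha_12),
                          DemeParameters(row.lambda_2, row.mu_2, row.alpha_21))
                config = SimulationConfig(
                    n_tips=(int(row.n_tips_1), int(row.n_tips_2)),
                    termination=termination)
                tree = simulate_structured_tree(params, config, rng)
        except SimulationError as err:
            raise SimulationError(
                f"replicate {row.replicate_id} failed: {err}") from err
        tree.metadata["replicate_id"] = row.replicate_id
        tree.metadata["seed"] = int(row.seed)
        trees.append(tree)
    return TreeDataset(trees, design.copy())
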