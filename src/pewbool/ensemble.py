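"""Ensemble simulation and summary statistics for PEW Boolean models.

The long-run behavior of a PEW model is summarized by ensemble averages of
node states over many independently seeded runs started from a common,
biologically meaningful initial condition.  Stochastic nodes then show up
as non-binary averages, akin to intermediate molecular concentrations.
This module provides the ensemble runner plus the derived summaries used in
the applications: time-window averages with their per-run distribution and
median, dose-response sweeps over an input pulse probability, event
propensity curves over a model parameter, and first-return times to a
target state pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import Perturbation, UpdateScheme, simulate
from .grammar import NetworkModel

__all__ = [
    "EnsembleResult",
    "WindowStatistic",
    "DoseResponseTable",
    "PropensityCurve",
    "derive_seed",
    "run_ensemble",
    "window_average",
    "dose_response",
    "propensity_sweep",
    "first_return_times",
]

_HIST_BIN_WIDTH = 0.05


def derive_seed(base_seed: int, k: int) -> int:
    """Stable, independent per-run seed for run ``k`` of an ensemble."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


@dataclass
class EnsembleResult:
    """Stack of independently seeded trajectories plus their average.

    ``average[t, i]`` is the ON-fraction of node i at time t over the runs;
    ``trajectories`` has shape (runs, steps+1, N).
    """

    trajectories: np.ndarray
    nodes: tuple[str, ...]
    scheme: UpdateScheme
    base_seed: int
    seeds: tuple[int, ...]

    @property
    def runs(self) -> int:
        return self.trajectories.shape[0]

    @property
    def steps(self) -> int:
        return self.trajectories.shape[1] - 1

    @property
    def average(self) -> np.ndarray:
        return self.trajectories.mean(axis=0)

    def node_runs(self, node: str) -> np.ndarray:
        """(runs, steps+1) series of one node across the ensemble."""
        return self.trajectories[:, :, self.nodes.index(node)]

    def average_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.average, columns=list(self.nodes))
        df.insert(0, "step", np.arange(self.steps + 1))
        return df

    def write_csv(self, path, metadata: Mapping[str, object] | None = None) -> None:
        with open(path, "w") as fh:
            for key, value in (metadata or {}).items():
                fh.write(f"# {key}: {value}\n")
            self.average_frame().to_csv(fh, index=False)


def run_ensemble(
    model: NetworkModel,
    initial: Mapping[str, int] | Iterable[str],
    scheme: UpdateScheme = UpdateScheme.RANDOM_ORDER_ASYNC,
    runs: int = 200,
    steps: int = 100,
    perturbations: Sequence[Perturbation] = (),
    base_seed: int = 0,
    normalize_gasync: bool = False,
) -> EnsembleResult:
    """Run ``runs`` independent trajectories; run k is seeded from
    (base_seed, k), so the whole ensemble is reproducible from base_seed."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    initial = list(initial) if not isinstance(initial, Mapping) else initial
    seeds = tuple(derive_seed(base_seed, k) for k in range(runs))
    stack = np.empty((runs, steps + 1, len(model.nodes)), dtype=np.uint8)
    for k, seed in enumerate(seeds):
        traj = simulate(
            model,
            initial,
            scheme=scheme,
            steps=steps,
            perturbations=perturbations,
            seed=seed,
            normalize_gasync=normalize_gasync,
        )
        stack[k] = traj.states
    return EnsembleResult(stack, model.nodes, UpdateScheme(scheme), base_seed, seeds)


@dataclass
class WindowStatistic:
    """Distribution of per-run time averages of one node over [t0, t1)."""

    node: str
    t0: int
    t1: int
    per_run_means: np.ndarray
    median: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def window_average(
    result: EnsembleResult, node: str, t0: int, t1: int
) -> WindowStatistic:
    """Per-run mean of ``node`` over recorded steps [t0, t1), with the
    across-run median and a fixed-bin histogram (bin width 0.05 on [0,1])."""
    if not (0 <= t0 < t1 <= result.steps + 1):
        raise ValueError(
            f"window [{t0}, {t1}) not within recorded steps [0, {result.steps}]"
        )
    means = result.node_runs(node)[:, t0:t1].mean(axis=1)
    edges = np.arange(0.0, 1.0 + _HIST_BIN_WIDTH, _HIST_BIN_WIDTH)
    counts, _ = np.histogram(means, bins=edges)
    return WindowStatistic(node, t0, t1, means, float(np.median(means)), counts, edges)


@dataclass
class DoseResponseTable:
    """Window statistics of a readout node across input pulse probabilities."""

    input_node: str
    readout: str
    levels: tuple[float, ...]
    stats: tuple[WindowStatistic, ...]

    @property
    def medians(self) -> np.ndarray:
        return np.array([s.median for s in self.stats])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "median": self.medians,
                "mean": [float(s.per_run_means.mean()) for s in self.stats],
            }
        )


def dose_response(
    model: NetworkModel | Callable[[], NetworkModel],
    input_node: str,
    levels: Sequence[float],
    readout: str,
    window: tuple[int, int],
    runs: int = 100,
    steps: int = 160,
    seed: int = 0,
    scheme: UpdateScheme = UpdateScheme.RANDOM_ORDER_ASYNC,
    initial: Mapping[str, int] | Iterable[str] = (),
    pulse_window: tuple[int, int] | None = None,
) -> DoseResponseTable:
    """Sweep the input pulse probability ("concentration") over ``levels``.

    For each level a fresh ensemble is run in which ``input_node`` is
    re-drawn each step with ON-probability equal to the level (sustained for
    the whole run unless ``pulse_window`` narrows it), and the per-run
    window average of ``readout`` is summarized.
    """
    levels = tuple(sorted(float(v) for v in levels))
    if any(not 0.0 <= v <= 1.0 for v in levels):
        raise ValueError("levels must lie in [0, 1]")
    t0, t1 = window
    p_start, p_end = pulse_window if pulse_window is not None else (0, steps + 1)
    stats = []
    for level in levels:
        m = model() if callable(model) else model
        pulse = Perturbation(
            input_node, 1, prob=level, t_start=p_start, t_end=p_end, after_value=0
        )
        result = run_ensemble(
            m,
            initial,
            scheme=scheme,
            runs=runs,
            steps=steps,
            perturbations=(pulse,),
            base_seed=seed,
        )
        stats.append(window_average(result, readout, t0, t1))
    return DoseResponseTable(input_node, readout, levels, tuple(stats))


@dataclass
class PropensityCurve:
    """Fraction of runs showing an event, across a model-parameter sweep."""

    values: tuple[float, ...]
    propensity: np.ndarray
    se: np.ndarray  # binomial standard error sqrt(f(1-f)/runs)
    runs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.values, "propensity": self.propensity, "se": self.se}
        )


def propensity_sweep(
    model_editor: Callable[[float], NetworkModel],
    values: Sequence[float],
    event: Callable[[dict[str, int]], bool],
    runs: int = 100,
    steps: int = 100,
    seed: int = 0,
    scheme: UpdateScheme = UpdateScheme.GENERAL_ASYNC,
    initial: Mapping[str, int] | Iterable[str] = (),
    perturbations: Sequence[Perturbation] = (),
) -> PropensityCurve:
    """For each parameter value, build the edited model and measure the
    fraction of runs whose final state satisfies ``event``."""
    values = tuple(float(v) for v in values)
    fractions = np.empty(len(values))
    for j, v in enumerate(values):
        m = model_editor(v)
        hits = 0
        for k in range(runs):
            traj = simulate(
                m,
                initial,
                scheme=scheme,
                steps=steps,
                perturbations=perturbations,
                seed=derive_seed(seed, j * runs + k),
            )
            hits += bool(event(traj.final_state()))
        fractions[j] = hits / runs
    se = np.sqrt(fractions * (1.0 - fractions) / runs)
    return PropensityCurve(values, fractions, se, runs)


def first_return_times(
    result: EnsembleResult,
    pattern: Mapping[str, int],
    start: int = 0,
    persistence: int = 10,
) -> np.ndarray:
    """Per-run first time t >= start at which ``pattern`` holds for
    ``persistence`` consecutive recorded steps.

    Returns the entry time t of the persistent window for each run, or NaN
    where the pattern never settles within the recording.  The persistence
    requirement avoids counting transient flickers through the pattern.
    """
    cols = [result.nodes.index(n) for n in pattern]
    want = np.array([int(v) for v in pattern.values()], dtype=np.uint8)
    match = (result.trajectories[:, :, cols] == want).all(axis=2)  # (runs, T)
    T = match.shape[1]
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    times = np.full(result.runs, np.nan)
    for k in range(result.runs):
        row = match[k]
        run_len = 0
        for t in range(start, T):
            run_len = run_len + 1 if row[t] else 0
            if run_len >= persistence:
                times[k] = t - persistence + 1
                break
    return times
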