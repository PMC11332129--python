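"""Run the latent-cause model over seeds and curricula.

One "seed" is a complete simulated session: a curriculum's 200 stories
are sampled (the 3-vs-4 branch of every story from the seed's own
stream), presented to a fresh model, and scored.  A story's accuracy is
the mean probability the model assigned to the true successor at the
two probed deterministic transitions (states 3/4 -> 5/6 and 5/6 ->
7/8), mirroring the human two-alternative measure; test accuracy is the
unweighted mean over the final 40 random-test stories.

`run_condition` repeats this over many seeds, optionally drawing one
model parameter per seed from a truncated normal distribution (the
individual-differences variant), and collects per-seed diagnostics:
the number of latent causes inferred, test accuracy and the final
schema libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ModelParams, SchemaLibrary, process_story
from .tasks import (AccuracyTrace, CHAIN, Curriculum, N_TRAIN, build_curriculum,
                    sample_story)

__all__ = [
    "RunConfig",
    "RunResult",
    "run_seed",
    "run_condition",
    "inserted_blocks_experiment",
    "diagnostics",
    "chain_transition_matrix",
]

_VARYABLE = {"none": None, "concentration": "alpha", "stickiness": "beta",
             "sparsity": "lam"}
#: lower truncation for per-seed parameter draws; matches the fitting
#: search-space lower bound so drawn values stay in the legal range.
PARAM_FLOOR = 0.001


@dataclass(frozen=True)
class RunConfig:
    """A batch of simulated sessions for one condition."""

    base_params: ModelParams
    condition_name: str
    n_seeds: int = 100
    vary_param: str = "none"
    vary_sd: float = 0.0
    master_seed: int = 0
    start_chain: str = "A"
    labels: Sequence[str] | None = None  # for condition_name == "custom"
    accuracy_probes: str = "deterministic"  # deterministic | all

    def __post_init__(self):
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.vary_sd < 0:
            raise ValueError("vary_sd must be >= 0")
        if self.vary_param not in _VARYABLE:
            raise ValueError(f"unknown vary_param {self.vary_param!r}")


@dataclass
class RunResult:
    config: RunConfig
    traces: list[AccuracyTrace]
    per_seed_params: list[ModelParams]
    n_causes: np.ndarray
    test_accuracy: np.ndarray
    final_libraries: list[SchemaLibrary]

    @property
    def mean_trace(self) -> np.ndarray:
        return np.mean([t.values for t in self.traces], axis=0)

    @property
    def mean_test_accuracy(self) -> float:
        return float(self.test_accuracy.mean())


def _story_accuracy(records, mode: str) -> float:
    if mode == "all":
        ps = [r.p_2afc for r in records if r.p_2afc is not None]
    else:
        ps = [r.p_2afc for r in records if r.probed]
    return float(np.mean(ps)) if ps else 0.5


def run_seed(params: ModelParams, curriculum: Curriculum, seed: int,
             accuracy_probes: str = "deterministic",
             ) -> tuple[AccuracyTrace, SchemaLibrary]:
    """Simulate one full session and return its trace and final library."""
    rng = np.random.default_rng(seed)
    library = SchemaLibrary(n_states=params.n_obs_states)
    values = np.empty(len(curriculum))
    for idx, label in enumerate(curriculum.labels):
        story = sample_story(label, rng, story_index=idx)
        records = process_story(library, story, params)
        values[idx] = _story_accuracy(records, accuracy_probes)
    trace = AccuracyTrace(values=values, condition_name=curriculum.condition_name,
                          seed=seed, source="model")
    return trace, library


def _spawn_params(cfg: RunConfig, rng: np.random.Generator) -> ModelParams:
    attr = _VARYABLE[cfg.vary_param]
    if attr is None or cfg.vary_sd == 0.0:
        return cfg.base_params
    base_value = getattr(cfg.base_params, attr)
    drawn = max(PARAM_FLOOR, rng.normal(base_value, cfg.vary_sd))
    return replace(cfg.base_params, **{attr: float(drawn)})


def _child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-seed integers below 2**31."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2 ** 31)


def run_condition(cfg: RunConfig) -> RunResult:
    """Run ``n_seeds`` independent sessions of one condition."""
    param_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.master_seed, 17]).generate_state(1)[0])
    curriculum_seeds = _child_seeds(cfg.master_seed, cfg.n_seeds)
    traces, libs, params_used = [], [], []
    for s in range(cfg.n_seeds):
        p = _spawn_params(cfg, param_rng)
        cur = build_curriculum(cfg.condition_name, int(curriculum_seeds[s]),
                               start_chain=cfg.start_chain, labels=cfg.labels)
        trace, lib = run_seed(p, cur, int(curriculum_seeds[s]),
                              accuracy_probes=cfg.accuracy_probes)
        traces.append(trace)
        libs.append(lib)
        params_used.append(p)
    n_causes = np.array([l.n_schemas for l in libs])
    test_acc = np.array([t.test_accuracy for t in traces])
    return RunResult(config=cfg, traces=traces, per_seed_params=params_used,
                     n_causes=n_causes, test_accuracy=test_acc,
                     final_libraries=libs)


def inserted_blocks_experiment(base_params: ModelParams, master_seed: int,
                               n_seeds: int = 100,
                               vary_param: str = "concentration",
                               vary_sd: float = 0.3,
                               ) -> dict[str, RunResult]:
    """Early/middle/late inserted-block curricula under shared seeding.

    A pair of single-chain blocks is inserted at the beginning, middle
    or end of otherwise interleaved training; all three conditions use
    the same per-seed random streams so they differ only in curriculum.
    """
    out = {}
    for cond in ("early", "middle", "late"):
        cfg = RunConfig(base_params=base_params, condition_name=cond,
                        n_seeds=n_seeds, vary_param=vary_param,
                        vary_sd=vary_sd, master_seed=master_seed)
        out[cond] = run_condition(cfg)
    return out


# ---------------------------------------------------------------------------
# diagnostics


def chain_transition_matrix(chain_label: str, n_states: int = 9) -> np.ndarray:
    """Ground-truth row-stochastic transition matrix of one chain
    (restricted to the predictable states; terminal rows are zero)."""
    T = np.zeros((n_states, n_states))
    for path in CHAIN.paths(chain_label):
        for a, b in zip(path[:-1], path[1:]):
            if a < n_states and b < n_states:
                T[a, b] += 0.5  # each of the two branch paths has mass 1/2
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(T.sum(1, keepdims=True) > 0,
                     T / np.maximum(T.sum(1, keepdims=True), 1e-12), 0.0)
    return T


#: rows probed by the two-alternative questions (branch and post-branch states)
PROBED_ROWS = (3, 4, 5, 6)


def _matrix_match(lib: SchemaLibrary, rows=PROBED_ROWS) -> float | None:
    """Mean absolute deviation of a 2-cause library's learned matrices
    from the ground-truth chains, minimised over the 2 assignments."""
    if lib.n_schemas != 2:
        return None
    learned = []
    for k in range(2):
        M = lib.count_matrix(k)
        sums = M.sum(1, keepdims=True)
        learned.append(np.where(sums > 0, M / np.maximum(sums, 1e-12), 0.0))
    TA, TB = chain_transition_matrix("A"), chain_transition_matrix("B")
    devs = []
    for (x, y) in ((0, 1), (1, 0)):
        d = np.mean([np.abs(learned[x][r] - TA[r]).mean()
                     + np.abs(learned[y][r] - TB[r]).mean()
                     for r in rows]) / 2.0
        devs.append(d)
    return float(min(devs))


def diagnostics(result: RunResult) -> pd.DataFrame:
    """Per-seed summary: latent-cause count, test accuracy, varied
    parameter value and (for 2-cause seeds) the transition-matrix match."""
    attr = _VARYABLE[result.config.vary_param]
    rows = []
    for s, (lib, acc) in enumerate(zip(result.final_libraries,
                                       result.test_accuracy)):
        p = result.per_seed_params[s]
        rows.append({
            "seed": s,
            "n_causes": lib.n_schemas,
            "test_accuracy": float(acc),
            "alpha": p.alpha, "beta": p.beta, "lam": p.lam,
            "varied_value": getattr(p, attr) if attr else np.nan,
            "matrix_mad": _matrix_match(lib),
        })
    return pd.DataFrame(rows)


def n_causes_histogram(result: RunResult) -> dict[int, int]:
    vals, counts = np.unique(result.n_causes, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}
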