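"""Random-search parameter fitting against reference accuracy curves.

Candidate parameter triples (alpha, beta, lambda) are drawn uniformly
from a box (alpha, beta in [0.001, 100], lambda in [0.001, 1.2]); each
candidate is scored by simulating the model on the blocked and
interleaved curricula, averaging the per-story accuracy trace over
seeds, and measuring the squared deviation from a reference trace at
every one of the 200 stories.  The blocked and interleaved scores are
averaged into the final objective and the best-scoring candidate is
returned.

Evaluation uses common random numbers: every candidate sees the same
seed stream, so differences in score reflect parameters rather than
simulation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .model import ModelParams
from .runner import RunConfig, run_condition
from .tasks import AccuracyTrace

__all__ = ["SearchSpace", "FitResult", "trace_mse", "evaluate_params",
           "evaluation_seed", "random_search"]


def evaluation_seed(master_seed: int) -> int:
    """The common-random-numbers seed `random_search` evaluates with.

    Exposed so an externally supplied candidate (e.g. the parameters a
    reference was generated from) can be scored on exactly the same
    seed stream as the search's own candidates.
    """
    return int(np.random.SeedSequence([master_seed, 202])
               .generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class SearchSpace:
    alpha_range: tuple = (0.001, 100.0)
    beta_range: tuple = (0.001, 100.0)
    lam_range: tuple = (0.001, 1.2)
    n_samples: int = 200
    seeds_per_eval: int = 100
    mse_mode: str = "sum"  # sum | mean

    def __post_init__(self):
        for name in ("alpha_range", "beta_range", "lam_range"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.seeds_per_eval < 1:
            raise ValueError("seeds_per_eval must be >= 1")
        if self.mse_mode not in ("sum", "mean"):
            raise ValueError(f"unknown mse_mode {self.mse_mode!r}")


@dataclass
class FitResult:
    best_params: ModelParams
    best_score: float
    all_samples: list[tuple[ModelParams, float]]

    def __post_init__(self):
        scores = [s for _, s in self.all_samples]
        assert not scores or np.isclose(self.best_score, min(scores))


def trace_mse(model_trace, reference_trace, mode: str = "sum") -> float:
    """Squared deviation between two per-story accuracy traces.

    mode="sum" is sum_t (model_t - reference_t)^2 over the stories;
    mode="mean" divides by the trace length.
    """
    m = np.asarray(getattr(model_trace, "values", model_trace), dtype=float)
    r = np.asarray(getattr(reference_trace, "values", reference_trace),
                   dtype=float)
    if m.shape != r.shape:
        raise ValueError(f"trace length mismatch: {m.shape} vs {r.shape}")
    sq = float(np.sum((m - r) ** 2))
    if mode == "mean":
        return sq / m.size
    if mode != "sum":
        raise ValueError(f"unknown mode {mode!r}")
    return sq


def evaluate_params(params: ModelParams,
                    reference_traces: Mapping[str, AccuracyTrace],
                    seeds_per_eval: int, master_seed: int,
                    mse_mode: str = "sum",
                    vary_param: str = "none", vary_sd: float = 0.0) -> float:
    """Mean of the per-condition trace MSEs for one parameter triple."""
    for cond in ("blocked", "interleaved"):
        if cond not in reference_traces:
            raise ValueError(f"missing reference trace for {cond!r}")
    scores = []
    for cond in sorted(reference_traces):
        cfg = RunConfig(base_params=params, condition_name=cond,
                        n_seeds=seeds_per_eval, master_seed=master_seed,
                        vary_param=vary_param, vary_sd=vary_sd)
        result = run_condition(cfg)
        scores.append(trace_mse(result.mean_trace,
                                reference_traces[cond], mse_mode))
    return float(np.mean(scores))


def random_search(space: SearchSpace,
                  reference_traces: Mapping[str, AccuracyTrace],
                  master_seed: int,
                  template: ModelParams | None = None,
                  vary_param: str = "none", vary_sd: float = 0.0) -> FitResult:
    """Uniform random search over the (alpha, beta, lambda) box.

    `template` carries every non-searched parameter (temperature,
    variant flags); the searched triple replaces its alpha/beta/lam.
    For the individual-differences variant the searched alpha is the
    mean of the per-seed distribution (`vary_param`/`vary_sd`).
    All candidates share one evaluation seed stream (common random
    numbers), and draws are generated sequentially from a stream that
    depends only on `master_seed`, so enlarging n_samples keeps the
    earlier candidates unchanged.
    """
    if template is None:
        template = ModelParams(alpha=1.0, beta=1.0, lam=0.5)
    draw_rng = np.random.default_rng(
        np.random.SeedSequence([master_seed, 101]).generate_state(1)[0])
    eval_seed = evaluation_seed(master_seed)
    samples: list[tuple[ModelParams, float]] = []
    best: tuple[ModelParams, float] | None = None
    for _ in range(space.n_samples):
        a = draw_rng.uniform(*space.alpha_range)
        b = draw_rng.uniform(*space.beta_range)
        l = draw_rng.uniform(*space.lam_range)
        cand = replace(template, alpha=float(a), beta=float(b), lam=float(l))
        score = evaluate_params(cand, reference_traces, space.seeds_per_eval,
                                eval_seed, mse_mode=space.mse_mode,
                                vary_param=vary_param, vary_sd=vary_sd)
        samples.append((cand, score))
        if best is None or score < best[1]:
            best = (cand, score)
    return FitResult(best_params=best[0], best_score=best[1],
                     all_samples=samples)
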