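"""Pipeline configuration and report serialization.

Configurations are plain YAML/JSON mappings with one section per
pipeline stage; unknown keys are rejected with the offending key named,
and every section validates against the corresponding dataclass.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fitting import SearchSpace
from .model import ModelParams
from .rnn import RnnConfig

__all__ = ["PipelineConfig", "load_config", "dump_config", "write_report"]

_MODEL_DEFAULTS = {"tau": 4.0}
_RUN_DEFAULTS = {"condition": "blocked", "n_seeds": 100, "vary_param": "none",
                 "vary_sd": 0.0}


@dataclass
class PipelineConfig:
    """Validated sections for task, model, run, fit and rnn stages."""

    condition: str = "blocked"
    seed: int = 0
    model: ModelParams | None = None
    n_seeds: int = 100
    vary_param: str = "none"
    vary_sd: float = 0.0
    fit: SearchSpace = field(default_factory=SearchSpace)
    rnn: RnnConfig = field(default_factory=RnnConfig)
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = {"task": {"condition": self.condition, "seed": self.seed},
             "run": {"n_seeds": self.n_seeds, "vary_param": self.vary_param,
                     "vary_sd": self.vary_sd},
             "fit": dataclasses.asdict(self.fit),
             "rnn": dataclasses.asdict(self.rnn),
             "out_dir": self.out_dir}
        if self.model is not None:
            d["model"] = dataclasses.asdict(self.model)
        return d


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown key {sorted(unknown)[0]!r} in section {section!r}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid {section!r} section: {err}") from err


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    known = {"task", "model", "run", "fit", "rnn", "out_dir"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level key {sorted(unknown)[0]!r}")

    task = dict(data.get("task", {}))
    bad = set(task) - {"condition", "seed"}
    if bad:
        raise ValueError(f"unknown key {sorted(bad)[0]!r} in section 'task'")
    run = dict(_RUN_DEFAULTS)
    run_in = dict(data.get("run", {}))
    bad = set(run_in) - {"n_seeds", "vary_param", "vary_sd"}
    if bad:
        raise ValueError(f"unknown key {sorted(bad)[0]!r} in section 'run'")
    run.update(run_in)

    model = None
    if "model" in data:
        mdata = dict(_MODEL_DEFAULTS)
        mdata.update(data["model"])
        model = _build_section(ModelParams, mdata, "model")

    fit = _build_section(SearchSpace, dict(data.get("fit", {})), "fit")
    rnn = _build_section(RnnConfig, dict(data.get("rnn", {})), "rnn")

    return PipelineConfig(
        condition=task.get("condition", "blocked"),
        seed=int(task.get("seed", 0)),
        model=model,
        n_seeds=int(run["n_seeds"]),
        vary_param=str(run["vary_param"]),
        vary_sd=float(run["vary_sd"]),
        fit=fit, rnn=rnn,
        out_dir=str(data.get("out_dir", ".")),
    )


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True),
                          encoding="utf-8")


def write_report(run_results: dict | None, fit_results=None, out_dir=".",
                 ) -> tuple[Path, Path]:
    """Write summary.json and a markdown table for a set of results.

    `run_results` maps condition name -> RunResult; `fit_results` is an
    optional FitResult.  Regeneration from the same inputs is
    byte-identical.
    """
    from .runner import n_causes_histogram  # local import to avoid cycle

    if not run_results and fit_results is None:
        raise ValueError("nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"conditions": {}}
    lines = ["| condition | seeds | mean test accuracy | latent causes |",
             "|---|---|---|---|"]
    for cond, res in sorted((run_results or {}).items()):
        hist = n_causes_histogram(res)
        summary["conditions"][cond] = {
            "n_seeds": int(res.config.n_seeds),
            "mean_test_accuracy": round(res.mean_test_accuracy, 6),
            "n_causes_histogram": hist,
        }
        lines.append(f"| {cond} | {res.config.n_seeds} "
                     f"| {res.mean_test_accuracy:.3f} "
                     f"| {dict(sorted(hist.items()))} |")
    if fit_results is not None:
        bp = fit_results.best_params
        summary["fit"] = {"best_params": {"alpha": bp.alpha, "beta": bp.beta,
                                          "lam": bp.lam},
                          "best_score": round(fit_results.best_score, 6),
                          "n_samples": len(fit_results.all_samples)}
        lines.append(f"| fit | {len(fit_results.all_samples)} samples "
                     f"| score {fit_results.best_score:.4g} "
                     f"| a={bp.alpha:.3g} b={bp.beta:.3g} l={bp.lam:.3g} |")
    json_path = out_dir / "summary.json"
    md_path = out_dir / "summary.md"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                         encoding="utf-8")
    md_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return json_path, md_path
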