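"""Two-chain story task and training curricula.

The environment generates "stories": short Markov-chain state sequences
over ten observable states (0-9).  Two chains, A and B, share all of
their states except one schema-identifying state (1 for chain A, 2 for
chain B).  Both chains branch 50/50 into state 3 or 4 and from there
follow deterministic, mirror-opposite paths:

    chain A:  0-1-3-5-7-9   or  0-1-4-6-8-9
    chain B:  0-2-3-6-7-9   or  0-2-4-5-8-9

Because states 0 and 3-8 are aliased between the chains, an observer
must use the single identifying state (and the learned transition
structure) to predict what happens next.  A curriculum is the ordered
list of chain labels for 200 stories; the last 40 stories always form a
random test phase in which each story's chain is drawn with probability
one half.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChainSpec",
    "StorySequence",
    "Curriculum",
    "AccuracyTrace",
    "CHAIN",
    "sample_story",
    "build_curriculum",
    "generate_pseudo_human_traces",
    "stories_to_jsonl",
    "stories_from_jsonl",
    "trace_to_csv",
    "traces_to_csv",
    "trace_from_csv",
]

N_STORIES = 200
N_TRAIN = 160
BLOCK = 40


@dataclass(frozen=True)
class ChainSpec:
    """The two-chain generative process."""

    n_states: int = 10
    paths_A: tuple = ((0, 1, 3, 5, 7, 9), (0, 1, 4, 6, 8, 9))
    paths_B: tuple = ((0, 2, 3, 6, 7, 9), (0, 2, 4, 5, 8, 9))
    branch_prob: float = 0.5

    def paths(self, chain_label: str) -> tuple:
        if chain_label == "A":
            return self.paths_A
        if chain_label == "B":
            return self.paths_B
        raise ValueError(f"unknown chain label: {chain_label!r}")

    def successors(self, chain_label: str, state: int) -> list[int]:
        """States that can follow `state` under the given chain."""
        nxt = []
        for path in self.paths(chain_label):
            for a, b in zip(path[:-1], path[1:]):
                if a == state and b not in nxt:
                    nxt.append(b)
        return nxt


CHAIN = ChainSpec()

#: two admissible successors at the probed (deterministic) transitions,
#: pooled over both chains: states 3/4 lead to 5 or 6, states 5/6 to 7 or 8.
PROBE_OPTIONS = {3: (5, 6), 4: (5, 6), 5: (7, 8), 6: (7, 8)}


@dataclass(frozen=True)
class StorySequence:
    """One story: an ordered state path plus its generating chain."""

    states: tuple
    chain_label: str
    story_index: int = -1

    def __post_init__(self):
        legal = CHAIN.paths(self.chain_label)
        if tuple(self.states) not in legal:
            raise ValueError(
                f"{list(self.states)} is not a legal chain-{self.chain_label} path"
            )


def sample_story(chain_label: str, rng: np.random.Generator,
                 story_index: int = -1) -> StorySequence:
    """Draw one story from the given chain.

    The only stochastic step is the 50/50 branch into state 3 versus 4;
    every transition after the branch is deterministic.
    """
    paths = CHAIN.paths(chain_label)  # validates the label
    path = paths[0] if rng.random() < CHAIN.branch_prob else paths[1]
    return StorySequence(states=path, chain_label=chain_label,
                         story_index=story_index)


_CONDITIONS = ("blocked", "interleaved", "early", "middle", "late", "custom")


@dataclass(frozen=True)
class Curriculum:
    """Ordered chain labels for one 200-story session."""

    labels: tuple
    condition_name: str
    segments: tuple  # (start, end, kind) with end exclusive
    seed: int

    def __len__(self) -> int:
        return len(self.labels)


def _interleaved(n: int, start_chain: str) -> list[str]:
    other = "B" if start_chain == "A" else "A"
    return [start_chain if i % 2 == 0 else other for i in range(n)]


def build_curriculum(condition_name: str, seed: int, *,
                     start_chain: str = "A",
                     labels: Sequence[str] | None = None) -> Curriculum:
    """Assemble the label sequence for one curriculum condition.

    blocked      40xA 40xB 40xA 40xB | 40 random-test
    interleaved  ABAB... for 160     | 40 random-test
    early        40xA 40xB 80 interleaved | 40 random-test
    middle       40 interleaved 40xA 40xB 40 interleaved | 40 random-test
    late         80 interleaved 40xA 40xB | 40 random-test
    custom       explicit `labels` (random test appended only if the
                 provided list has 160 entries)

    The final 40 stories are always drawn A/B with probability 0.5 from
    the seeded RNG, so all conditions share the same test-phase contract.
    """
    if condition_name not in _CONDITIONS:
        raise ValueError(
            f"unknown condition {condition_name!r}; expected one of {_CONDITIONS}"
        )
    rng = np.random.default_rng(seed)
    A, B = ["A"] * BLOCK, ["B"] * BLOCK
    segs: list[tuple]
    if condition_name == "blocked":
        train = A + B + A + B
        segs = [(0, 40, "A-block"), (40, 80, "B-block"),
                (80, 120, "A-block"), (120, 160, "B-block")]
    elif condition_name == "interleaved":
        train = _interleaved(160, start_chain)
        segs = [(0, 160, "interleaved")]
    elif condition_name == "early":
        train = A + B + _interleaved(80, start_chain)
        segs = [(0, 40, "A-block"), (40, 80, "B-block"), (80, 160, "interleaved")]
    elif condition_name == "middle":
        train = _interleaved(40, start_chain) + A + B + _interleaved(40, start_chain)
        segs = [(0, 40, "interleaved"), (40, 80, "A-block"),
                (80, 120, "B-block"), (120, 160, "interleaved")]
    elif condition_name == "late":
        train = _interleaved(80, start_chain) + A + B
        segs = [(0, 80, "interleaved"), (80, 120, "A-block"), (120, 160, "B-block")]
    else:  # custom
        if labels is None:
            raise ValueError("custom condition requires an explicit label list")
        train = [str(l) for l in labels]
        bad = set(train) - {"A", "B"}
        if bad:
            raise ValueError(f"labels must be 'A' or 'B'; got {sorted(bad)}")
        segs = [(0, len(train), "custom")]
    if condition_name == "custom" and len(train) != N_TRAIN:
        all_labels = train
        segments = tuple(segs)
    else:
        test = ["A" if rng.random() < 0.5 else "B" for _ in range(BLOCK)]
        all_labels = train + test
        segments = tuple(segs + [(len(train), len(train) + BLOCK, "random-test")])
    return Curriculum(labels=tuple(all_labels), condition_name=condition_name,
                      segments=segments, seed=seed)


def sample_stories(curriculum: Curriculum,
                   rng: np.random.Generator) -> list[StorySequence]:
    """Draw the branch of every story in a curriculum from one RNG stream."""
    return [sample_story(lab, rng, story_index=i)
            for i, lab in enumerate(curriculum.labels)]


@dataclass
class AccuracyTrace:
    """Per-story scalar accuracy over one session."""

    values: np.ndarray
    condition_name: str
    seed: int = -1
    source: str = "model"  # model | pseudo_human | external

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def test_accuracy(self) -> float:
        """Mean accuracy over the final 40 (random-test) stories."""
        return float(np.mean(self.values[N_TRAIN:]))


def generate_pseudo_human_traces(params, condition_names: Iterable[str],
                                 n_seeds: int, master_seed: int,
                                 vary_param: str = "none",
                                 vary_sd: float = 0.0,
                                 ) -> list[AccuracyTrace]:
    """Stand-in reference curves for the fitting stage.

    Runs the latent-cause model at known parameters and returns one
    mean-over-seeds trace per condition, labelled ``source="pseudo_human"``.
    These play the role of empirical accuracy curves so that parameter
    fitting can be exercised end to end without any external data.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    from .runner import RunConfig, run_condition  # deferred: runner imports tasks

    traces = []
    for cond in condition_names:
        cfg = RunConfig(base_params=params, condition_name=cond,
                        n_seeds=n_seeds, master_seed=master_seed,
                        vary_param=vary_param, vary_sd=vary_sd)
        result = run_condition(cfg)
        traces.append(AccuracyTrace(values=result.mean_trace,
                                    condition_name=cond, seed=master_seed,
                                    source="pseudo_human"))
    return traces


# ---------------------------------------------------------------------------
# serialization

def stories_to_jsonl(stories: Iterable[StorySequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in stories:
            fh.write(json.dumps({"story_index": s.story_index,
                                 "chain_label": s.chain_label,
                                 "states": list(s.states)}) + "\n")


def stories_from_jsonl(path) -> list[StorySequence]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(StorySequence(states=tuple(d["states"]),
                                     chain_label=d["chain_label"],
                                     story_index=d["story_index"]))
    return out


def trace_to_csv(trace: AccuracyTrace, path) -> None:
    traces_to_csv([trace], path)


def traces_to_csv(traces: Iterable[AccuracyTrace], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["story", "accuracy", "condition", "seed", "source"])
        for tr in traces:
            for i, v in enumerate(tr.values):
                w.writerow([i + 1, f"{v:.6g}", tr.condition_name, tr.seed,
                            tr.source])


def trace_from_csv(path, condition_name: str | None = None) -> AccuracyTrace:
    """Read one accuracy trace from CSV.

    Accepts either the two-column (story, accuracy) layout or the full
    layout written by :func:`traces_to_csv`; with the latter,
    `condition_name` selects which condition to load.
    """
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "accuracy" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header with an 'accuracy' column")
        for row in reader:
            if condition_name is not None and "condition" in row \
                    and row["condition"] != condition_name:
                continue
            rows.append((int(row["story"]), float(row["accuracy"])))
    if not rows:
        raise ValueError(f"{path}: no rows matched")
    rows.sort()
    cond = condition_name or "external"
    return AccuracyTrace(values=np.array([v for _, v in rows]),
                         condition_name=cond, source="external")
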