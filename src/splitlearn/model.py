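"""Sticky-CRP latent-cause model of event schema learning.

The learner maintains a growing library of *schemas* (latent causes),
each holding a table M_k of observed state-to-state transition counts.
A sticky Chinese Restaurant Process supplies the prior over which
schema generated the current observations,

    P(z = k) propto  N_k + beta * delta[k, z_prev]   for an existing schema
    P(z = new) propto  alpha,

where N_k is how often schema k has been used before, alpha >= 0 is the
concentration parameter and beta >= 0 the stickiness bonus for the
previously active schema.  Only the *next unused* schema is scored as
"new"; schemas beyond it have prior zero.

The likelihood of observing the transition i -> j under schema k
marginalises a symmetric Dirichlet(lambda) prior over each row of the
transition matrix:

    P(j | i, k) = (lambda + M_k[i, j]) / (S * lambda + sum_j' M_k[i, j'])

with S = 9 predictable states (the terminal state of each story is
never shown to the learner).  Exact inference over schema histories is
intractable, so the history is frozen to its local MAP ("active
schema") after every inference step.

Two granularities of the local-MAP commitment are implemented:

``inference_unit="story"`` (default)
    One latent cause per story.  The posterior over the story's cause
    is updated incrementally within the story from the running product
    of per-transition likelihoods; the model tracks the running MAP
    among existing schemas for prediction, decides between "existing"
    and "new" when the story is complete, and then credits all of the
    story's transitions to the committed schema.  Usage counts N_k
    count stories.

``inference_unit="transition"``
    One inference step per observed transition: the posterior combines
    the sticky-CRP prior with the single current transition likelihood,
    the argmax is committed immediately and the transition credited to
    it.  Usage counts N_k count transitions.

Predictions use the active schema's count row passed through a softmax
with temperature tau (default 4); two-alternative probes renormalise
the predictive mass over the two admissible successors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .tasks import PROBE_OPTIONS

__all__ = [
    "ModelParams",
    "SchemaLibrary",
    "PosteriorSnapshot",
    "TransitionRecord",
    "crp_prior",
    "transition_likelihood",
    "infer_step",
    "predict_distribution",
    "predict_2afc",
    "process_story",
]

S_OBS = 9  # predictable states 0..8; the terminal state is dropped


@dataclass(frozen=True)
class ModelParams:
    """Parameters and variant switches of the latent-cause learner.

    alpha, beta, lam are the concentration, stickiness and Dirichlet
    sparsity parameters; tau the prediction softmax temperature.
    ``skip_unpredictable`` switches off schema inference at the
    irreducibly unpredictable transitions into states 3/4 (the
    second/third simulation variants); ``skip_after_first_block`` delays
    that switch until a run of 40 same-chain stories has been observed.
    """

    alpha: float
    beta: float
    lam: float
    tau: float = 4.0
    skip_unpredictable: bool = False
    skip_after_first_block: bool = False
    predict_mode: str = "active_only"  # active_only | marginal
    inference_unit: str = "story"      # story | transition
    sticky_across_stories: bool = True
    credit_skipped: bool = True
    n_obs_states: int = S_OBS

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0 (a zero sparsity makes unseen "
                             "transitions impossible)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.predict_mode not in ("active_only", "marginal"):
            raise ValueError(f"unknown predict_mode {self.predict_mode!r}")
        if self.inference_unit not in ("story", "transition"):
            raise ValueError(f"unknown inference_unit {self.inference_unit!r}")
        if self.n_obs_states != S_OBS:
            raise ValueError("the task exposes exactly 9 predictable states")


class SchemaLibrary:
    """The learner's evolving state: schemas, usage counts, active pointer."""

    def __init__(self, n_states: int = S_OBS):
        self.n_states = n_states
        self.counts: list[list[list[int]]] = []   # per schema: S x S table
        self.row_sums: list[list[int]] = []
        self.usage: list[float] = []              # N_k
        self.active: int = -1                     # current MAP schema
        self.prev_story_cause: int = -1           # committed cause of last story
        self.history: list[int] = []              # MAP assignment per inference step
        self.same_chain_run: int = 0              # bookkeeping for delayed skipping
        self._last_start_state: int | None = None
        self.skip_enabled: bool = False

    # -- basic queries ----------------------------------------------------

    @property
    def n_schemas(self) -> int:
        return len(self.counts)

    def count_matrix(self, k: int) -> np.ndarray:
        return np.array(self.counts[k], dtype=float)

    def total_inference_steps(self) -> int:
        return len(self.history)

    # -- mutation ---------------------------------------------------------

    def spawn(self) -> int:
        S = self.n_states
        self.counts.append([[0] * S for _ in range(S)])
        self.row_sums.append([0] * S)
        self.usage.append(0.0)
        return len(self.counts) - 1

    def credit(self, k: int, i: int, j: int) -> None:
        self.counts[k][i][j] += 1
        self.row_sums[k][i] += 1

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "n_states": self.n_states,
            "schemas": [{"usage": n, "counts": c}
                        for n, c in zip(self.usage, self.counts)],
            "active": self.active,
            "prev_story_cause": self.prev_story_cause,
            "history": self.history,
        })

    @classmethod
    def from_json(cls, text: str) -> "SchemaLibrary":
        d = json.loads(text)
        lib = cls(n_states=d["n_states"])
        for s in d["schemas"]:
            k = lib.spawn()
            lib.usage[k] = s["usage"]
            lib.counts[k] = [list(row) for row in s["counts"]]
            lib.row_sums[k] = [sum(row) for row in s["counts"]]
        lib.active = d["active"]
        lib.prev_story_cause = d.get("prev_story_cause", d["active"])
        lib.history = list(d["history"])
        return lib


@dataclass(frozen=True)
class PosteriorSnapshot:
    """Normalized posterior over {existing schemas, next-unused schema}."""

    probabilities: np.ndarray  # length n_schemas + 1; last entry = "new"
    selected: int
    switched: bool
    split: bool


@dataclass(frozen=True)
class TransitionRecord:
    """What happened at one observed transition of a story."""

    from_state: int
    to_state: int
    probed: bool
    p_2afc: float | None        # probability assigned to the true successor
    skipped: bool
    snapshot: PosteriorSnapshot | None


# ---------------------------------------------------------------------------
# core quantities


def crp_prior(library: SchemaLibrary, params: ModelParams,
              sticky_target: int | None = None) -> np.ndarray:
    """Sticky-CRP prior over {existing schemas, one "new" slot}.

    Unnormalized weights are N_k + beta for the sticky target (by
    default the active schema) and alpha for the next unused schema;
    the returned vector is normalized.  With an empty library the new
    slot has probability one regardless of alpha.
    """
    K = library.n_schemas
    if sticky_target is None:
        sticky_target = library.active
    w = np.empty(K + 1)
    for k in range(K):
        w[k] = library.usage[k] + (params.beta if k == sticky_target else 0.0)
    w[K] = params.alpha
    tot = w.sum()
    if tot <= 0.0:
        out = np.zeros(K + 1)
        out[K] = 1.0
        return out
    return w / tot


def transition_likelihood(library: SchemaLibrary, schema_k: int,
                          from_state_i: int, to_state_j: int,
                          params: ModelParams) -> float:
    """Dirichlet-multinomial predictive probability of i -> j under schema k.

    `schema_k` equal to the library size addresses the "new" slot
    (all-zero counts), which yields the uniform value 1/S.
    """
    S = params.n_obs_states
    if not (0 <= from_state_i < S and 0 <= to_state_j < S):
        raise ValueError("states must lie in [0, n_obs_states)")
    if schema_k == library.n_schemas:  # the unused "new" schema
        return 1.0 / S
    m = library.counts[schema_k][from_state_i][to_state_j]
    row = library.row_sums[schema_k][from_state_i]
    return (params.lam + m) / (S * params.lam + row)


def _posterior(library: SchemaLibrary, params: ModelParams,
               lik: list[float], lik_new: float,
               sticky_target: int) -> PosteriorSnapshot:
    """Combine likelihoods with the sticky-CRP prior and take the argmax.

    Ties favour the currently active schema, then the lowest index;
    the "new" slot wins only on a strict maximum.
    """
    K = library.n_schemas
    w = np.empty(K + 1)
    for k in range(K):
        w[k] = (library.usage[k]
                + (params.beta if k == sticky_target else 0.0)) * lik[k]
    w[K] = params.alpha * lik_new
    tot = w.sum()
    if tot <= 0.0:
        probs = np.zeros(K + 1)
        probs[K] = 1.0
        sel = K
    else:
        probs = w / tot
        best = probs.max()
        if K and library.active >= 0 and probs[library.active] == best:
            sel = library.active
        else:
            sel = int(np.argmax(probs))
    switched = sel != library.active
    split = sel == K
    return PosteriorSnapshot(probabilities=probs, selected=sel,
                             switched=switched, split=split)


def infer_step(library: SchemaLibrary, observed_transition: tuple[int, int],
               params: ModelParams) -> PosteriorSnapshot:
    """One per-transition local-MAP inference step (transition unit).

    Posterior propto transition likelihood x sticky-CRP prior; the
    argmax is committed: a new schema is spawned if the "new" slot won,
    its usage count is incremented, and the observed transition is
    credited to its table.
    """
    i, j = observed_transition
    K = library.n_schemas
    lik = [transition_likelihood(library, k, i, j, params) for k in range(K)]
    lik_new = transition_likelihood(library, K, i, j, params)
    snap = _posterior(library, params, lik, lik_new, library.active)
    sel = snap.selected
    if snap.split:
        sel = library.spawn()
    library.usage[sel] += 1.0
    library.credit(sel, i, j)
    library.active = sel
    library.history.append(sel)
    return snap


# ---------------------------------------------------------------------------
# prediction


def predict_distribution(library: SchemaLibrary, from_state_i: int,
                         params: ModelParams) -> np.ndarray:
    """Predictive distribution over the S next states.

    In ``active_only`` mode the active schema's count row is passed
    through softmax(x / tau).  In ``marginal`` mode each schema's
    temperature-transformed row is mixed under the sticky-CRP prior
    (the Bayes-optimal variant), including the uniform "new" slot.
    """
    S = params.n_obs_states
    if library.active < 0:
        return np.full(S, 1.0 / S)
    if params.predict_mode == "active_only":
        row = np.array(library.counts[library.active][from_state_i], dtype=float)
        z = row / params.tau
        z -= z.max()
        e = np.exp(z)
        return e / e.sum()
    prior = crp_prior(library, params)
    out = np.zeros(S)
    for k in range(library.n_schemas):
        row = np.array(library.counts[k][from_state_i], dtype=float)
        z = row / params.tau
        z -= z.max()
        e = np.exp(z)
        out += prior[k] * e / e.sum()
    out += prior[-1] / S
    return out / out.sum()


def predict_2afc(library: SchemaLibrary, from_state_i: int,
                 option_j1: int, option_j2: int,
                 params: ModelParams) -> float:
    """Probability assigned to option j1 in a two-alternative probe."""
    if option_j1 == option_j2:
        raise ValueError("the two options must differ")
    if library.active >= 0 and params.predict_mode == "active_only":
        # closed form: softmax restricted to two entries is a logistic
        row = library.counts[library.active][from_state_i]
        return 1.0 / (1.0 + math.exp((row[option_j2] - row[option_j1])
                                     / params.tau))
    d = predict_distribution(library, from_state_i, params)
    return float(d[option_j1] / (d[option_j1] + d[option_j2]))


# ---------------------------------------------------------------------------
# story processing


def _skip_active(params: ModelParams, library: SchemaLibrary) -> bool:
    if not params.skip_unpredictable:
        return False
    if params.skip_after_first_block:
        return library.skip_enabled
    return True


def _note_story_label(library: SchemaLibrary, first_transition_target: int):
    """Track runs of same-chain stories for the delayed-skip variant."""
    if library._last_start_state == first_transition_target:
        library.same_chain_run += 1
    else:
        library.same_chain_run = 1
        library._last_start_state = first_transition_target
    if library.same_chain_run >= 40:
        library.skip_enabled = True


def process_story(library: SchemaLibrary, story, params: ModelParams
                  ) -> list[TransitionRecord]:
    """Observe one story and update the library in place.

    The story's terminal state (9) is never shown to the model, so the
    processed transitions are 0->{1,2}, {1,2}->{3,4}, {3,4}->{5,6} and
    {5,6}->{7,8}.  At the two probed deterministic transitions the
    two-alternative prediction is recorded *before* inference sees the
    outcome.  When skipping is active, transitions into states 3/4 do
    not drive inference (they are still credited to the active schema's
    table so later predictions from 3/4 remain informed).
    """
    states = list(getattr(story, "states", story))
    if states[-1] >= params.n_obs_states:
        states = states[:-1]
    trans = list(zip(states[:-1], states[1:]))
    if not trans:
        raise ValueError("story too short")
    skipping = _skip_active(params, library)
    _note_story_label(library, trans[0][1])

    if params.inference_unit == "transition":
        return _process_transition_unit(library, trans, params, skipping)
    return _process_story_unit(library, trans, params, skipping)


#: admissible successor pairs at every non-terminal state (pooled chains);
#: states 3-6 are the probed deterministic transitions.
_ALL_OPTIONS = {0: (1, 2), 1: (3, 4), 2: (3, 4), **PROBE_OPTIONS}


def _record_probe(library, params, i, j):
    options = _ALL_OPTIONS.get(i)
    if options is None:
        return False, None
    other = options[0] if options[1] == j else options[1]
    return i in PROBE_OPTIONS, predict_2afc(library, i, j, other, params)


def _process_transition_unit(library, trans, params, skipping):
    records = []
    for i, j in trans:
        probed, p = _record_probe(library, params, i, j)
        if skipping and j in (3, 4):
            if params.credit_skipped and library.active >= 0:
                library.credit(library.active, i, j)
            records.append(TransitionRecord(i, j, probed, p, True, None))
            continue
        snap = infer_step(library, (i, j), params)
        records.append(TransitionRecord(i, j, probed, p, False, snap))
    library.prev_story_cause = library.active
    return records


def _process_story_unit(library, trans, params, skipping):
    """Story-level local MAP: incremental posterior, end-of-story commit."""
    S = params.n_obs_states
    lam, SL = params.lam, params.n_obs_states * params.lam
    K = library.n_schemas
    logL = [0.0] * K
    n_terms = 0
    records = []
    pending = []  # (index into records, i, j) for snapshot back-fill
    sticky = library.prev_story_cause if params.sticky_across_stories \
        else -2
    if not params.sticky_across_stories:
        # within-story stickiness still follows the running MAP
        sticky = -2

    counts, row_sums, usage = library.counts, library.row_sums, library.usage
    for i, j in trans:
        probed, p = _record_probe(library, params, i, j)
        skipped = skipping and j in (3, 4)
        records.append(TransitionRecord(i, j, probed, p, skipped, None))
        if skipped:
            continue
        for k in range(K):
            logL[k] += math.log((lam + counts[k][i][j]) / (SL + row_sums[k][i]))
        n_terms += 1
        if K:
            # running MAP among existing schemas, used for prediction
            best, bw = -1, -math.inf
            act = library.active
            for k in range(K):
                w = math.log(usage[k] + (params.beta if k == sticky else 0.0)) \
                    + logL[k] if usage[k] > 0 or k == sticky else -math.inf
                if w > bw + 1e-15 or (abs(w - bw) <= 1e-15 and k == act):
                    best, bw = k, w
            if best >= 0 and best != act:
                library.active = best
            if not params.sticky_across_stories:
                sticky = library.active

    # end-of-story commitment, now including the "new" hypothesis
    lik = [math.exp(v) for v in logL]
    lik_new = (1.0 / S) ** n_terms
    snap = _posterior(library, params, lik, lik_new,
                      sticky if sticky >= 0 else -1)
    sel = snap.selected
    if snap.split:
        sel = library.spawn()
    for i, j in trans:
        if (skipping and j in (3, 4)) and not params.credit_skipped:
            continue
        library.credit(sel, i, j)
    library.usage[sel] += 1.0
    library.history.append(sel)
    library.active = sel
    library.prev_story_cause = sel
    # expose the commitment decision on the story's last record
    records[-1] = replace(records[-1], snapshot=snap)
    return records
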