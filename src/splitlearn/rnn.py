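"""Non-splitting LSTM comparator for the two-chain task.

A single recurrent network — an embedding layer, one LSTM cell and a
softmax readout over the 9 predictable states — is trained by
backpropagation (Adam) to predict the next state of each story.  All
knowledge lives in one set of shared weights, so the network has no
splitting mechanism: under blocked training, learning chain B
overwrites chain A (catastrophic interference), which is the behaviour
this module quantifies.

After every training story the weights are frozen and the network is
probed with one fresh sequence from each chain; at the two
chain-disambiguating steps (inputs 3/4 and 5/6) the softmax mass on the
chain-A-consistent and chain-B-consistent successor is recorded.

The network and its gradients are implemented directly in NumPy
(standard LSTM cell equations, softmax cross-entropy, truncated BPTT
over the story), with Adam updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tasks import CHAIN, build_curriculum, sample_story

__all__ = ["RnnConfig", "EvalRecord", "LstmNet", "train_and_probe",
           "interference_index"]

N_IO = 9  # one-hot size over predictable states 0..8

#: chain-consistent successor at each probed (disambiguating) input state
_SUCCESSOR = {"A": {3: 5, 4: 6, 5: 7, 6: 8},
              "B": {3: 6, 4: 5, 5: 8, 6: 7}}


@dataclass(frozen=True)
class RnnConfig:
    condition_name: str = "blocked"
    embed_dim: int = 16
    hidden_dim: int = 32
    learning_rate: float = 0.06
    n_nets: int = 10
    master_seed: int = 0
    n_io: int = N_IO
    passes_per_story: int = 1

    def __post_init__(self):
        if self.n_io != N_IO:
            raise ValueError("the task one-hot covers exactly 9 states")
        if self.n_nets < 1:
            raise ValueError("n_nets must be >= 1")


@dataclass(frozen=True)
class EvalRecord:
    epoch: int          # story index just trained on
    eval_chain: str     # chain of the frozen-weight probe sequence
    p_chainA_next: float
    p_chainB_next: float
    net: int = 0
    condition: str = ""


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LstmNet:
    """Embedding -> LSTM cell -> linear softmax readout, with manual BPTT."""

    def __init__(self, embed_dim: int, hidden_dim: int, lr: float,
                 rng: np.random.Generator, n_io: int = N_IO):
        E, H, V = embed_dim, hidden_dim, n_io
        self.E, self.H, self.V, self.lr = E, H, V, lr

        def init(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

        self.params = {
            "We": init((E, V), V), "be": np.zeros(E),
            "Wg": init((4 * H, E + H), E + H), "bg": np.zeros(4 * H),
            "Wy": init((V, H), H), "by": np.zeros(V),
        }
        self.params["bg"][H:2 * H] = 1.0  # forget-gate bias
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    # -- forward ----------------------------------------------------------

    def forward(self, inputs: Sequence[int]):
        """Run the sequence; returns softmax outputs and a BPTT cache."""
        H = self.H
        p = self.params
        h = np.zeros(H)
        c = np.zeros(H)
        cache, probs = [], []
        for s in inputs:
            x = np.zeros(self.V)
            x[s] = 1.0
            e = p["We"] @ x + p["be"]
            z = np.concatenate([e, h])
            gates = p["Wg"] @ z + p["bg"]
            i_g = _sigmoid(gates[:H])
            f_g = _sigmoid(gates[H:2 * H])
            o_g = _sigmoid(gates[2 * H:3 * H])
            g_g = np.tanh(gates[3 * H:])
            c_new = f_g * c + i_g * g_g
            tc = np.tanh(c_new)
            h_new = o_g * tc
            logits = p["Wy"] @ h_new + p["by"]
            ex = np.exp(logits - logits.max())
            prob = ex / ex.sum()
            cache.append((x, z, i_g, f_g, o_g, g_g, c, c_new, tc, h_new))
            probs.append(prob)
            h, c = h_new, c_new
        return probs, cache

    def predict_sequence(self, inputs: Sequence[int]) -> list[np.ndarray]:
        """Frozen-weight forward pass (softmax outputs per step)."""
        probs, _ = self.forward(inputs)
        return probs

    # -- backward / update -------------------------------------------------

    def train_story(self, inputs: Sequence[int], targets: Sequence[int]
                    ) -> float:
        """One gradient pass on (current state -> next state) pairs.

        Returns the mean cross-entropy loss; raises on non-finite loss.
        """
        loss, grads = self.loss_and_grads(inputs, targets)
        self._adam(grads)
        return loss

    def loss_and_grads(self, inputs: Sequence[int], targets: Sequence[int]
                       ) -> tuple[float, dict]:
        """Mean cross-entropy over the sequence and its parameter gradients."""
        H = self.H
        p = self.params
        probs, cache = self.forward(inputs)
        T = len(inputs)
        loss = -np.mean([np.log(probs[t][targets[t]] + 1e-300)
                         for t in range(T)])
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged (non-finite)")
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in reversed(range(T)):
            x, z, i_g, f_g, o_g, g_g, c_prev, c_new, tc, h_new = cache[t]
            dlogits = probs[t].copy()
            dlogits[targets[t]] -= 1.0
            dlogits /= T
            grads["Wy"] += np.outer(dlogits, h_new)
            grads["by"] += dlogits
            dh = p["Wy"].T @ dlogits + dh_next
            do = dh * tc
            dc = dh * o_g * (1.0 - tc ** 2) + dc_next
            di = dc * g_g
            df = dc * c_prev
            dg = dc * i_g
            dgates = np.concatenate([
                di * i_g * (1 - i_g),
                df * f_g * (1 - f_g),
                do * o_g * (1 - o_g),
                dg * (1.0 - g_g ** 2),
            ])
            grads["Wg"] += np.outer(dgates, z)
            grads["bg"] += dgates
            dz = p["Wg"].T @ dgates
            de = dz[:self.E]
            dh_next = dz[self.E:]
            dc_next = dc * f_g
            grads["We"] += np.outer(de, x)
            grads["be"] += de
        return float(loss), grads

    def _adam(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        lr_t = self.lr * np.sqrt(1 - beta2 ** self._t) / (1 - beta1 ** self._t)
        for k in self.params:
            self._m[k] = beta1 * self._m[k] + (1 - beta1) * grads[k]
            self._v[k] = beta2 * self._v[k] + (1 - beta2) * grads[k] ** 2
            self.params[k] -= lr_t * self._m[k] / (np.sqrt(self._v[k]) + eps)


def _training_pairs(story) -> tuple[list[int], list[int]]:
    """(input, target) pairs from every story element except the last.

    The terminal state lies outside the 9-unit code and is dropped, so
    a story contributes four pairs: 0->1/2, 1/2->3/4, 3/4->5/6, 5/6->7/8.
    """
    states = [s for s in story.states if s < N_IO]
    return states[:-1], states[1:]


def _probe(net: LstmNet, story, eval_chain: str, epoch: int, net_idx: int,
           condition: str) -> EvalRecord:
    inputs, _ = _training_pairs(story)
    probs = net.predict_sequence(inputs)
    pa, pb = [], []
    for t, s in enumerate(inputs):
        if s in _SUCCESSOR["A"]:
            pa.append(probs[t][_SUCCESSOR["A"][s]])
            pb.append(probs[t][_SUCCESSOR["B"][s]])
    return EvalRecord(epoch=epoch, eval_chain=eval_chain,
                      p_chainA_next=float(np.mean(pa)),
                      p_chainB_next=float(np.mean(pb)),
                      net=net_idx, condition=condition)


def train_and_probe(config: RnnConfig) -> list[list[EvalRecord]]:
    """Train ``n_nets`` networks; probe both chains after every story.

    Returns one record list per network, two records (one per eval
    chain) per training story.
    """
    ss = np.random.SeedSequence(config.master_seed)
    net_seeds = ss.generate_state(config.n_nets) % (2 ** 31)
    all_records = []
    for n in range(config.n_nets):
        rng = np.random.default_rng(int(net_seeds[n]))
        net = LstmNet(config.embed_dim, config.hidden_dim,
                      config.learning_rate, rng)
        curriculum = build_curriculum(config.condition_name,
                                      int(net_seeds[n]))
        records = []
        for idx, label in enumerate(curriculum.labels):
            story = sample_story(label, rng, story_index=idx)
            inputs, targets = _training_pairs(story)
            for _ in range(config.passes_per_story):
                net.train_story(inputs, targets)
            for chain in ("A", "B"):
                probe_story = sample_story(chain, rng)
                records.append(_probe(net, probe_story, chain, idx, n,
                                      config.condition_name))
        all_records.append(records)
    return all_records


def interference_index(records: list[EvalRecord],
                       curriculum_labels: Sequence[str],
                       epochs: Sequence[int] | None = None) -> float:
    """Scalar summary of the blocked flip-flop signature.

    For evaluations whose chain differs from the chain currently being
    trained, the index averages (softmax mass on the trained chain's
    successor) minus (mass on the evaluated chain's successor).
    Positive values mean the network answers with the trained chain
    regardless of the probe — interference; values near zero or below
    mean the network respects the probe.  By default the block-final
    epochs 39/79/119/159 are used.
    """
    if not records:
        raise ValueError("no evaluation records")
    if epochs is None:
        epochs = (39, 79, 119, 159)
    gaps = []
    for r in records:
        if r.epoch not in epochs:
            continue
        trained = curriculum_labels[r.epoch]
        if trained == r.eval_chain:
            continue
        p = {"A": r.p_chainA_next, "B": r.p_chainB_next}
        gaps.append(p[trained] - p[r.eval_chain])
    if not gaps:
        raise ValueError("no mismatched evaluations at the requested epochs")
    return float(np.mean(gaps))
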