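"""GRU encoder–decoder with dot-product (Luong) attention for free recall.

The encoder reads the studied list one item at a time, storing every hidden
state h_1..h_L.  The decoder starts from h_L, is prompted with a
start-of-sequence token, and feeds each output back as its next input.  At
each decoding step the attention mechanism weights the stored encoder states
by softmax of their dot product with the current decoder state and returns
their weighted sum — the exact analogue of context reinstatement in the CMR
model (the correspondence is checked numerically by
:func:`attention_equivalence_check`).

The retrieval rule scores studied items by the dot product between the
post-attention state ĥ_j and each stored encoder state h_i (a pointer-style,
context-match rule mirroring CMR's retrieval), plus a learned
end-of-sequence logit.  Two output modes:

* ``in-list`` — softmax over the L studied items + EOS; unstudied items get
  probability exactly 0.
* ``full-vocab`` — studied items keep their context-match scores while the
  remaining vocabulary is scored by learned output embeddings; needed
  whenever incorrect (extra-list) recalls must be expressible, e.g. under
  reinforcement learning where they are penalized.

The no-attention ablation removes α_j: ĥ_j = tanh(W_c' h_j) with a mixing
layer of matched per-layer shape.  In in-list mode the ablated model still
scores against encoder states (it has no other way to name studied items);
in full-vocab mode it loses that route entirely and must recall from what
its hidden state retains, which is what makes the ablation a model of lost
episodic reinstatement.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cmr import CMRParams, CMRState, expected_reinstatement
from .data import Dataset, RecallSequence, StudyList, Trial, Wordpool
from .nn import Adam, GRUCell, Linear, ParamStore, uniform_init


@dataclass(frozen=True)
class Seq2SeqConfig:
    hidden_dim: int = 64
    vocab_size: int = 16
    embed_dim: int = 50
    attention: bool = True
    embedding_source: Literal["random", "learned", "pretrained"] = "random"
    output_mode: Literal["in-list", "full-vocab"] = "in-list"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if self.embedding_source not in ("random", "learned", "pretrained"):
            raise ValueError(f"unknown embedding source {self.embedding_source!r}")
        if self.output_mode not in ("in-list", "full-vocab"):
            raise ValueError(f"unknown output mode {self.output_mode!r}")


@dataclass
class EncoderTrace:
    """Stored encoder states for one list (numpy view).

    ``H`` holds h_1..h_L (what attention consults); ``H_pre`` holds the
    states just before each item was read, h_0..h_{L-1} (what the retrieval
    rule consults — each item's study cue, as in the temporal-context
    model's pre-item contexts).
    """

    H: np.ndarray  # (L, d)
    H_pre: np.ndarray | None = None  # (L, d)

    @property
    def L(self) -> int:
        return self.H.shape[0]

    @property
    def final_state(self) -> np.ndarray:
        return self.H[-1]


@dataclass
class EncoderStates:
    """Batched encoder memory: post-item states, pre-item states, final."""

    H: Tensor  # (B, L, d)
    Hpre: Tensor  # (B, L, d)
    final: Tensor  # (B, d)


@dataclass
class AttentionRecord:
    """Per-decoding-step attention weights over encoder positions."""

    weights: np.ndarray  # (steps, L); empty (0, L) when attention is off


@dataclass
class DecodeResult:
    recall: RecallSequence
    terminated: bool
    attention: AttentionRecord
    step_distributions: np.ndarray  # (steps, n_outcomes)
    step_values: np.ndarray  # (steps,)
    tokens: np.ndarray  # raw emitted tokens incl. possible EOS index


def pointer_scores(h_j: Tensor, Hmat: Tensor) -> Tensor:
    """Dot products of a probe (B, d) against stored states (B, L, d) -> (B, L)."""
    B, L, d = Hmat.shape
    return ad.reshape(ad.matmul(Hmat, ad.reshape(h_j, (B, d, 1))), (B, L))


def attend_core(h_j: Tensor, Hmat: Tensor) -> tuple[Tensor, Tensor]:
    """Dot-product attention: softmax over scores h_j . h_i, weighted sum.

    ``h_j``: (B, d); ``Hmat``: (B, L, d) stored encoder states.  Returns
    weights (B, L) on the simplex and the attention context (B, d).
    """
    B, L, d = Hmat.shape
    weights = ad.softmax(pointer_scores(h_j, Hmat), axis=1)
    alpha = ad.reshape(ad.matmul(ad.reshape(weights, (B, 1, L)), Hmat), (B, d))
    return weights, alpha


class Seq2SeqModel:
    """Encoder–decoder with optional attention; see module docstring."""

    def __init__(self, config: Seq2SeqConfig, wordpool: Wordpool | None = None):
        self.config = config
        N, d, de = config.vocab_size, config.hidden_dim, config.embed_dim
        self.N = N
        self.sos = N
        self.eos = N + 1
        rng = np.random.default_rng(config.seed)
        store = ParamStore()
        self.params = store

        if config.embedding_source == "pretrained":
            if wordpool is None or wordpool.embeddings is None:
                raise ValueError(
                    "embedding_source='pretrained' requires a word pool with embeddings"
                )
            if wordpool.N != N:
                raise ValueError("word pool size does not match vocab_size")
            native = wordpool.embeddings.shape[1]
            store.add("emb.items", wordpool.embeddings, trainable=False)
            self.emb_proj = Linear(store, "emb.proj", native, de, rng)
            store.add(
                "emb.special", uniform_init(rng, (2, de), 1.0 / np.sqrt(de))
            )
        else:
            trainable = config.embedding_source == "learned"
            store.add(
                "emb.items",
                rng.normal(0.0, 1.0 / np.sqrt(de), size=(N, de)),
                trainable=trainable,
            )
            self.emb_proj = None
            store.add(
                "emb.special", uniform_init(rng, (2, de), 1.0 / np.sqrt(de))
            )

        self.encoder = GRUCell(store, "enc", de, d, rng)
        store.add("enc.h0", uniform_init(rng, (d,), 1.0 / np.sqrt(d)))
        self.decoder = GRUCell(store, "dec", de, d, rng)
        mix_in = 2 * d if config.attention else d
        self.mix = Linear(store, "mix", mix_in, d, rng, bias=False)
        self.eos_head = Linear(store, "eos", d, 1, rng)
        store.add("out.emb", uniform_init(rng, (N, d), 1.0 / np.sqrt(d)))
        self.value_head = Linear(store, "value", d, 1, rng)

    # -- embeddings ------------------------------------------------------
    def embed(self, tokens: np.ndarray) -> Tensor:
        """Embed token indices (items 0..N-1, SOS=N, EOS=N+1) -> (B, d_emb)."""
        tokens = np.asarray(tokens)
        items = self.params["emb.items"]
        special = self.params["emb.special"]
        if self.emb_proj is not None:
            items = self.emb_proj(items)
        is_special = tokens >= self.N
        if not is_special.any():
            return ad.getitem(items, tokens)
        if is_special.all():
            return ad.getitem(special, tokens - self.N)
        item_rows = ad.getitem(items, np.where(is_special, 0, tokens))
        special_rows = ad.getitem(
            special, np.where(is_special, tokens - self.N, 0)
        )
        mask = Tensor(is_special.astype(float)[:, None])
        return item_rows * (1.0 - mask.data) + special_rows * mask.data

    # -- encoding --------------------------------------------------------
    def encode_batch(self, lists: np.ndarray) -> "EncoderStates":
        """Encode (B, L) item lists.

        Returns the stored per-step states H (B, L, d), the pre-item states
        Hpre (the state just *before* each item was read, with the learned
        initial state in row 0 — the analogue of CMR's start context), and
        the final state h_L.
        """
        lists = np.asarray(lists)
        if lists.ndim != 2 or lists.shape[1] == 0:
            raise ValueError("encode_batch requires a nonempty (B, L) array")
        B, L = lists.shape
        d = self.config.hidden_dim
        h = self.params["enc.h0"] * Tensor(np.ones((B, 1)))
        H: list[Tensor] = []
        Hpre: list[Tensor] = []
        for i in range(L):
            Hpre.append(ad.reshape(h, (B, 1, d)))
            x = self.embed(lists[:, i])
            h = self.encoder(x, h)
            H.append(ad.reshape(h, (B, 1, d)))
        return EncoderStates(
            H=ad.concat(H, axis=1), Hpre=ad.concat(Hpre, axis=1), final=h
        )

    def encode_sequence(self, study: StudyList) -> EncoderTrace:
        """Encoder trace for a single study list (deterministic forward)."""
        if study.L == 0:
            raise ValueError("cannot encode an empty list")
        with ad.no_grad():
            enc = self.encode_batch(np.asarray(study.positions)[None, :])
        return EncoderTrace(H=enc.H.data[0].copy(), H_pre=enc.Hpre.data[0].copy())

    # -- decoding --------------------------------------------------------
    def attend(self, h_j: Tensor, Hmat: Tensor) -> tuple[Tensor, Tensor]:
        if not self.config.attention:
            raise ValueError("attend() called on a no-attention model")
        return attend_core(h_j, Hmat)

    def decode_step(
        self, prev_tokens: np.ndarray, h_prev: Tensor, enc: "EncoderStates"
    ) -> tuple[Tensor, Tensor, Tensor | None]:
        """One decoder step: returns (ĥ_j, h_j, attention weights or None)."""
        x = self.embed(prev_tokens)
        h_j = self.decoder(x, h_prev)
        if self.config.attention:
            weights, alpha = self.attend(h_j, enc.H)
            hhat = ad.tanh(self.mix(ad.concat([h_j, alpha], axis=1)))
        else:
            weights = None
            hhat = ad.tanh(self.mix(h_j))
        return hhat, h_j, weights

    def output_logits(
        self, hhat: Tensor, enc: "EncoderStates", lists: np.ndarray
    ) -> Tensor:
        """Retrieval-rule logits.

        in-list: (B, L+1) — pointer scores for studied items, then EOS.
        full-vocab: (B, N+1) — output-embedding scores for every item with
        pointer scores added at studied columns, then EOS.
        """
        eos = self.eos_head(hhat)  # (B, 1)
        if self.config.output_mode == "in-list":
            # the ablated model keeps these scores here out of necessity:
            # with no other item channel it could not name studied items
            pointer = pointer_scores(hhat, enc.H)  # (B, L)
            return ad.concat([pointer, eos], axis=1)
        base = hhat @ ad.transpose(self.params["out.emb"])  # (B, N)
        if self.config.attention:
            # studied items are scored purely by the context match (as in
            # the in-list rule); output embeddings only carry off-list
            # (intrusion) competition
            pointer = pointer_scores(hhat, enc.H)
            base = ad.scatter_set_cols(base, np.asarray(lists), pointer)
        # without attention there is no episodic route back to the encoder
        # states: recall must come from what the hidden state retains
        return ad.concat([base, eos], axis=1)

    def value(self, hhat: Tensor) -> Tensor:
        return self.value_head(hhat)[:, 0]

    # -- generation ------------------------------------------------------
    def rollout_batch(
        self,
        lists: np.ndarray,
        rng: np.random.Generator | None = None,
        mode: Literal["sample", "greedy"] = "sample",
        max_steps: int | None = None,
        record_attention: bool = False,
    ) -> dict:
        """Decode a batch of lists without gradients.

        Returns a record with tokens, per-step log-probs of the taken
        actions, value estimates, an alive mask (steps at or before EOS),
        and optionally the attention weights.
        """
        lists = np.asarray(lists)
        B, L = lists.shape
        if max_steps is None:
            max_steps = 2 * L
        if max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if mode == "sample" and rng is None:
            raise ValueError("sample mode needs a random generator")
        with ad.no_grad():
            enc = self.encode_batch(lists)
            h = enc.final
            prev = np.full(B, self.sos, dtype=int)
            alive = np.ones(B, dtype=bool)
            tokens, logps, values, masks, dists, attn = [], [], [], [], [], []
            for _ in range(max_steps):
                hhat, h, weights = self.decode_step(prev, h, enc)
                logits = self.output_logits(hhat, enc, lists)
                logp = ad.log_softmax(logits, axis=1).data
                probs = np.exp(logp)
                if mode == "greedy":
                    choice = probs.argmax(axis=1)
                else:
                    u = rng.random(B)
                    cdf = probs.cumsum(axis=1)
                    choice = (u[:, None] > cdf).sum(axis=1)
                emitted = self._outcome_to_token(choice, lists)
                tokens.append(emitted)
                logps.append(logp[np.arange(B), choice])
                values.append(self.value(hhat).data)
                masks.append(alive.copy())
                dists.append(probs)
                if record_attention:
                    attn.append(
                        weights.data if weights is not None else np.zeros((B, 0))
                    )
                alive = alive & (emitted != self.eos)
                prev = emitted
                if not alive.any():
                    break
        record = {
            "lists": lists,
            "tokens": np.stack(tokens, axis=1),  # (B, T)
            "logp": np.stack(logps, axis=1),
            "values": np.stack(values, axis=1),
            "mask": np.stack(masks, axis=1),
            "dists": np.stack(dists, axis=1),  # (B, T, n_outcomes)
        }
        if record_attention:
            record["attention"] = np.stack(attn, axis=1)  # (B, T, L)
        return record

    def _outcome_to_token(self, choice: np.ndarray, lists: np.ndarray) -> np.ndarray:
        """Map an outcome index of the output softmax to a token index."""
        B, L = lists.shape
        if self.config.output_mode == "in-list":
            emitted = np.where(
                choice < L, lists[np.arange(B), np.minimum(choice, L - 1)], self.eos
            )
        else:
            emitted = np.where(choice < self.N, choice, self.eos)
        return emitted.astype(int)

    def token_to_outcome(self, tokens: np.ndarray, lists: np.ndarray) -> np.ndarray:
        """Inverse of ``_outcome_to_token`` (teacher forcing targets)."""
        tokens = np.asarray(tokens)
        B, L = lists.shape
        if self.config.output_mode == "in-list":
            # match tokens (B, T) against each studied column; EOS -> index L
            out = np.full(tokens.shape, L, dtype=int)
            for i in range(L):
                out = np.where(tokens == lists[:, i][:, None], i, out)
            return out
        out = np.where(tokens >= self.N, self.N, tokens)
        return out.astype(int)

    def generate_recall(
        self,
        study: StudyList,
        mode: Literal["sample", "greedy"] = "greedy",
        max_steps: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> DecodeResult:
        """Decode one list, feeding each output back, until EOS or max_steps."""
        rec = self.rollout_batch(
            np.asarray(study.positions)[None, :],
            rng=rng,
            mode=mode,
            max_steps=max_steps,
            record_attention=self.config.attention,
        )
        tokens = rec["tokens"][0]
        mask = rec["mask"][0]
        valid = tokens[mask]
        terminated = bool((valid == self.eos).any())
        outputs = tuple(int(t) for t in valid if t != self.eos)
        n_steps = int(mask.sum())
        attention = (
            rec["attention"][0][:n_steps]
            if self.config.attention
            else np.zeros((0, study.L))
        )
        return DecodeResult(
            recall=RecallSequence(outputs),
            terminated=terminated,
            attention=AttentionRecord(weights=attention),
            step_distributions=rec["dists"][0][:n_steps],
            step_values=rec["values"][0][:n_steps],
            tokens=tokens[:n_steps],
        )

    # -- persistence -----------------------------------------------------
    def save_checkpoint(self, directory: str | Path, provenance: dict | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params.state_dict())
        sidecar = {"config": asdict(self.config), "provenance": provenance or {}}
        (directory / "config.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load_checkpoint(
        cls, directory: str | Path, wordpool: Wordpool | None = None
    ) -> "Seq2SeqModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "config.json").read_text())
        config = Seq2SeqConfig(**sidecar["config"])
        model = cls(config, wordpool=wordpool)
        with np.load(directory / "params.npz") as archive:
            model.params.load_state_dict({k: archive[k] for k in archive.files})
        return model


def build_model(config: Seq2SeqConfig, wordpool: Wordpool | None = None) -> Seq2SeqModel:
    """Construct a seq2seq model; seeded so equal configs give equal weights."""
    return Seq2SeqModel(config, wordpool=wordpool)


def attention_equivalence_check(cmr_state: CMRState, k: float) -> float:
    """Numerically check attention == CMR context reinstatement.

    Builds an encoder trace whose rows are the stored pre-item contexts
    c_{i-1} and probes the attention mechanism with h_j = k * c_{j-1}; the
    attention context is compared elementwise against the expectation of the
    reinstated context under the CMR recall distribution at inverse
    temperature k.  Returns the max absolute discrepancy.
    """
    C = cmr_state.pre_item_contexts()  # (L, N)
    c_prev = cmr_state.c
    probe = Tensor((k * c_prev)[None, :])  # (1, N)
    _, alpha = attend_core(probe, Tensor(C[None, :, :]))
    via_attention = alpha.data[0]
    via_cmr = expected_reinstatement(cmr_state, c_prev, CMRParams(k=k))
    return float(np.max(np.abs(via_attention - via_cmr)))
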