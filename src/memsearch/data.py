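"""Core domain types for free-recall behavioral data.

The atom of behavioral data is a :class:`Trial`: one studied list paired with
one recall sequence.  Items are referenced by integer index into a shared
:class:`Wordpool`; serial positions are 0-based internally and reported
1-based by the analysis code.

Trial files are a line-oriented TSV format (one trial per line)::

    #memsearch-trials v1
    participant_id <TAB> session_id <TAB> w0001,w0002,... <TAB> w0002,w0009,...

The recall field may be empty and may contain repeats or intrusions
(pool tokens not on the studied list).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

TRIALS_HEADER = "#memsearch-trials v1"

#: Special tokens live outside the N item slots of a word pool.
SOS_TOKEN = "<sos>"
EOS_TOKEN = "<eos>"


class TrialFormatError(ValueError):
    """Raised when a trial file violates the documented grammar."""


@dataclass(frozen=True)
class Wordpool:
    """An experimental word pool of N unique tokens, optionally embedded.

    Parameters
    ----------
    items
        Ordered unique tokens.  ``N = len(items)``.
    embeddings
        Optional ``(N, d_emb)`` float matrix, one row per item.
    """

    items: tuple[str, ...]
    embeddings: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(set(self.items)) != len(self.items):
            raise ValueError("word pool tokens must be unique")
        if self.N < 2:
            raise ValueError("word pool needs at least 2 items")
        if self.embeddings is not None:
            emb = np.asarray(self.embeddings, dtype=float)
            if emb.ndim != 2 or emb.shape[0] != self.N:
                raise ValueError(
                    f"embeddings must be (N, d_emb) with N={self.N}, got {emb.shape}"
                )
            object.__setattr__(self, "embeddings", emb)

    @property
    def N(self) -> int:
        return len(self.items)

    @property
    def d_emb(self) -> int | None:
        return None if self.embeddings is None else self.embeddings.shape[1]

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except AttributeError:
            object.__setattr__(
                self, "_index", {t: i for i, t in enumerate(self.items)}
            )
            return self._index[token]

    def __contains__(self, token: str) -> bool:
        try:
            self.index(token)
            return True
        except KeyError:
            return False

    def __eq__(self, other) -> bool:
        if not isinstance(other, Wordpool):
            return NotImplemented
        if self.items != other.items:
            return False
        if (self.embeddings is None) != (other.embeddings is None):
            return False
        return self.embeddings is None or np.array_equal(
            self.embeddings, other.embeddings
        )

    __hash__ = None


@dataclass(frozen=True)
class StudyList:
    """An ordered studied list of item indices (no within-list repeats)."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        object.__setattr__(self, "positions", pos)
        if len(set(pos)) != len(pos):
            raise ValueError(f"study list repeats an item: {pos}")
        if any(p < 0 for p in pos):
            raise ValueError("item indices must be nonnegative")

    @property
    def L(self) -> int:
        return len(self.positions)

    def serial_position(self, item: int) -> int:
        """0-based study position of ``item``; raises if not studied."""
        return self.positions.index(item)


@dataclass(frozen=True)
class RecallSequence:
    """An ordered recall output: item indices, possibly with repeats and
    intrusions relative to a study list."""

    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        out = tuple(int(o) for o in self.outputs)
        if any(o < 0 for o in out):
            raise ValueError("recall indices must be nonnegative")
        object.__setattr__(self, "outputs", out)

    def __len__(self) -> int:
        return len(self.outputs)


@dataclass(frozen=True)
class Trial:
    study: StudyList
    recall: RecallSequence
    participant_id: str = "p0"
    session_id: str = "s0"


@dataclass(frozen=True)
class Dataset:
    """A collection of trials sharing one word pool and one list length."""

    trials: tuple[Trial, ...]
    wordpool: Wordpool

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def L(self) -> int:
        if not self.trials:
            raise ValueError("empty dataset has no list length")
        return self.trials[0].study.L


def validate_dataset(dataset: Dataset) -> list[str]:
    """Return a list of invariant violations; empty iff the dataset is valid.

    Checks: uniform list length, indices within the pool, no within-list
    repeats (repeats inside a *recall* sequence are legitimate data).
    """
    report: list[str] = []
    N = dataset.wordpool.N
    L0 = dataset.trials[0].study.L if dataset.trials else None
    for t, trial in enumerate(dataset.trials):
        if trial.study.L != L0:
            report.append(
                f"trial {t}: list length {trial.study.L} differs from {L0} (mixed L)"
            )
        seen: set[int] = set()
        for p in trial.study.positions:
            if not 0 <= p < N:
                report.append(f"trial {t}: study index {p} outside pool of size {N}")
            if p in seen:
                report.append(f"trial {t}: study list repeats item {p}")
            seen.add(p)
        for o in trial.recall.outputs:
            if not 0 <= o < N:
                report.append(f"trial {t}: recall index {o} outside pool of size {N}")
    return report


def _parse_tokens(fieldstr: str, pool: Wordpool, lineno: int, what: str) -> list[int]:
    if fieldstr == "":
        return []
    idx = []
    for tok in fieldstr.split(","):
        try:
            idx.append(pool.index(tok))
        except KeyError:
            raise TrialFormatError(
                f"line {lineno}: {what} token {tok!r} not in word pool"
            ) from None
    return idx


def read_trials(path: str | Path, wordpool: Wordpool) -> Dataset:
    """Parse a trial TSV file against ``wordpool``.

    Malformed lines raise :class:`TrialFormatError` naming the line number.
    """
    path = Path(path)
    trials: list[Trial] = []
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != TRIALS_HEADER:
            raise TrialFormatError(
                f"line 1: expected header {TRIALS_HEADER!r}, got {first!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise TrialFormatError(
                    f"line {lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            pid, sid, study_s, recall_s = parts
            study_idx = _parse_tokens(study_s, wordpool, lineno, "study")
            recall_idx = _parse_tokens(recall_s, wordpool, lineno, "recall")
            try:
                study = StudyList(tuple(study_idx))
            except ValueError as exc:
                raise TrialFormatError(f"line {lineno}: {exc}") from None
            trials.append(
                Trial(
                    study=study,
                    recall=RecallSequence(tuple(recall_idx)),
                    participant_id=pid,
                    session_id=sid,
                )
            )
    return Dataset(trials=tuple(trials), wordpool=wordpool)


def write_trials(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset so that :func:`read_trials` round-trips it exactly."""
    path = Path(path)
    items = dataset.wordpool.items
    with path.open("w", encoding="utf-8") as fh:
        fh.write(TRIALS_HEADER + "\n")
        for trial in dataset.trials:
            study_s = ",".join(items[p] for p in trial.study.positions)
            recall_s = ",".join(items[o] for o in trial.recall.outputs)
            fh.write(
                f"{trial.participant_id}\t{trial.session_id}\t{study_s}\t{recall_s}\n"
            )


def load_word_vectors(path: str | Path, pool: Wordpool) -> Wordpool:
    """Attach word vectors from a text file (token + floats per line).

    Every pool item must be covered; a missing item is an error (there is no
    silent random fill).  The vector dimension is inferred from the first
    line and enforced thereafter.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    d_emb: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            tok, vals = parts[0], parts[1:]
            if d_emb is None:
                d_emb = len(vals)
                if d_emb == 0:
                    raise ValueError(f"line {lineno}: no vector components")
            elif len(vals) != d_emb:
                raise ValueError(
                    f"line {lineno}: vector length {len(vals)} != {d_emb}"
                )
            if tok in pool:
                vectors[tok] = np.array([float(v) for v in vals])
    missing = [t for t in pool.items if t not in vectors]
    if missing:
        raise ValueError(f"word-vector file missing pool tokens: {missing}")
    emb = np.stack([vectors[t] for t in pool.items])
    return replace(pool, embeddings=emb)
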