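import numpy as np
import pytest

from memsearch import StudyList, Trial, RecallSequence, Wordpool, Dataset
from memsearch.synth import make_wordpool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pool5():
    return Wordpool(items=("cat", "dog", "tree", "rock", "bird"))


@pytest.fixture
def pool16(rng):
    return make_wordpool(16, d_emb=8, rng=rng)


def make_trial(study, recall, pid="p0", sid="s0"):
    return Trial(
        study=StudyList(tuple(study)),
        recall=RecallSequence(tuple(recall)),
        participant_id=pid,
        session_id=sid,
    )


@pytest.fixture
def tiny_dataset(pool5):
    trials = (
        make_trial([0, 1, 2], [1, 2]),
        make_trial([3, 4, 0], [0, 4, 1]),  # includes an intrusion (item 1)
        make_trial([2, 3, 4], []),
    )
    return Dataset(trials=trials, wordpool=pool5)
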