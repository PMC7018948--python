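from __future__ import annotations

import numpy as np
import pytest

from mirsnp.seed_scan import MatureMiRNA, UTRSequence

LET7A_LIKE = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture(scope="session")
def let7a() -> MatureMiRNA:
    return MatureMiRNA("sim-let-7a-5p", LET7A_LIKE)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def make_utr(sequence: str, tid: str = "T1", gene: str = "G1",
             biotype: str = "protein_coding", **offsets: int) -> UTRSequence:
    return UTRSequence(tid, gene, sequence, biotype, snp_offsets=dict(offsets))


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
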