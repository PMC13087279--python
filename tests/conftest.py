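import numpy as np
import pytest

from mscorrect import SketchParams


BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_substitutions(rng: np.random.Generator, sequence: str, rate: float) -> str:
    lut = {b: i for i, b in enumerate("ACGT")}
    codes = np.array([lut[b] for b in sequence], dtype=np.int64)
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=codes.size)
    codes[hit] = (codes[hit] + shift[hit]) % 4
    return BASES[codes].tobytes().decode()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def params() -> SketchParams:
    return SketchParams()
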