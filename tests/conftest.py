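import numpy as np
import pytest

from mepcal.codec_profile import CodecProfile, make_profile, wc53_profile
from mepcal.dna_codec import encode
from mepcal.error_model import make_fixtures


@pytest.fixture(scope="session")
def tables():
    return make_fixtures(11)


@pytest.fixture(scope="session")
def wc53_payload():
    rng = np.random.default_rng(12345)
    return rng.integers(0, 256, 5564, dtype=np.uint8).tobytes()


@pytest.fixture(scope="session")
def wc53_encoded(wc53_payload):
    """The default-configuration encoding used by many tests (pre-compressed
    payload, so the emitted length is the canonical 50,540 bp)."""
    return encode(wc53_payload, profile=wc53_profile(), seed=7,
                  compress=False)


@pytest.fixture(scope="session")
def toy_profile():
    return CodecProfile(S=5, R=4, E=10, M=10, N=2, G=1, packets_kept=2,
                        fountain_expansion=64)


@pytest.fixture(scope="session")
def toy_encoded(toy_profile):
    rng = np.random.default_rng(99)
    payload = rng.integers(0, 256, toy_profile.payload_capacity,
                           dtype=np.uint8).tobytes()
    return payload, encode(payload, profile=toy_profile, seed=3,
                           compress=False)


def random_small_profile(rng):
    """A random valid profile for property tests."""
    S = int(rng.choice([2, 4, 5, 8, 10]))
    R = int(rng.choice([4, 8]))
    u = R // 4
    kept = int(rng.integers(2, 6))
    E = kept * S * u
    extra_sets = int(rng.integers(1, 4))
    M = extra_sets * S * u
    while E + M > 255:
        kept -= 1
        E = kept * S * u
    N = int(rng.integers(1, 6))
    G = int(rng.integers(1, 3))
    return CodecProfile(S=S, R=R, E=E, M=M, N=N, G=G, packets_kept=kept,
                        fountain_expansion=max(32, 8 * kept),
                        set_index_len=int(rng.integers(4, 7)),
                        group_index_len=int(rng.integers(8, 12)))
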