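import numpy as np
import pytest

from ppdedup.bloom import BloomParams, KeyedHasher
from ppdedup.protocol import ProtocolConfig, Record, VirtualDataset


@pytest.fixture
def toy_params() -> BloomParams:
    return BloomParams(m=64, k=3, c=8, n=10, p_target=0.1)


@pytest.fixture
def toy_hasher(toy_params) -> KeyedHasher:
    return KeyedHasher(b"session-key-1", toy_params.k, toy_params.m)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def _rec(cid: str, rid: str, pid: str, **attrs) -> Record:
    base = {"agent": "influenza A", "result": "positive", "sex": "F",
            "age": "34", "area": "9001", "date": "2015-03-02",
            "first_name": "Anna", "last_name": "Berg", "dob": "1981-02-01"}
    base.update(attrs)
    return Record(custodian_id=cid, record_id=rid, patient_id=pid,
                  attributes=base)


@pytest.fixture
def fig1_vd() -> VirtualDataset:
    """Three laboratories; patient P1 tested at D1 and D3, P3 at D1 and D2,
    all other patients unique."""
    return VirtualDataset({
        "D1": [_rec("D1", "D1-r0", "10000000001"),
               _rec("D1", "D1-r1", "10000000003"),
               _rec("D1", "D1-r2", "10000000005")],
        "D2": [_rec("D2", "D2-r0", "10000000003"),
               _rec("D2", "D2-r1", "10000000006")],
        "D3": [_rec("D3", "D3-r0", "10000000001"),
               _rec("D3", "D3-r1", "10000000007")],
    })


P1 = "10000000001"
P3 = "10000000003"


@pytest.fixture
def strict_config() -> ProtocolConfig:
    """Config with a false-positive probability small enough that Bloom
    false positives are effectively impossible at test sizes."""
    return ProtocolConfig(p_target=1e-6)


def group_member_sets(groups) -> set:
    return {frozenset(map(tuple, g["members"])) for g in groups}
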