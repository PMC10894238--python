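import pytest

from beprofiler.library_design import ContextLibrarySpec, enumerate_context_library


@pytest.fixture(scope="session")
def lib32():
    spec = ContextLibrarySpec(target_bases=("A", "C"), positions=(6,))
    return enumerate_context_library(spec, seed=7)


@pytest.fixture(scope="session")
def lib448():
    spec = ContextLibrarySpec(target_bases=("A", "C"), positions=tuple(range(1, 15)))
    return enumerate_context_library(spec, seed=7)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))
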