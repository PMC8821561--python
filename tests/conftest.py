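import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnvensemble import (
    CallSet,
    CnvCall,
    GenomicInterval,
    SimulationConfig,
    SvType,
    default_caller_models,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def mk(chrom, start, end, svtype="DEL", sample="s1", caller="test", **kw) -> CnvCall:
    return CnvCall(
        GenomicInterval(str(chrom), start, end), SvType(svtype), caller, sample, **kw
    )


def mkset(calls, origin="test", sample="s1") -> CallSet:
    return CallSet.build(sample, origin, calls)


def random_callset(
    rng: np.random.Generator,
    n: int,
    origin: str = "rand",
    sample: str = "s1",
    n_chroms: int = 2,
    span: int = 500_000,
    size_range: tuple[int, int] = (100, 20_000),
) -> CallSet:
    """Random (possibly overlapping) call set for oracle comparisons."""
    calls = []
    for i in range(n):
        chrom = str(rng.integers(1, n_chroms + 1))
        size = int(rng.integers(size_range[0], size_range[1]))
        start = int(rng.integers(0, span))
        svtype = "DEL" if rng.random() < 0.6 else "DUP"
        calls.append(
            mk(chrom, start, start + size, svtype, sample=sample, caller=origin,
               id=f"{origin}_{i}")
        )
    return mkset(calls, origin=origin, sample=sample)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim_cfg() -> SimulationConfig:
    """A light cohort configuration for fast end-to-end tests."""
    return SimulationConfig(
        contigs=(("1", 30_000_000), ("2", 20_000_000)),
        n_truth=40,
        size_range=(1_000, 100_000),
        callers=default_caller_models(fp_rate_per_mb=2.0),
        seed=7,
    )
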