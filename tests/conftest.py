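import numpy as np
import pytest

from haplomark.metrics import METRICS, MetricMatrix
from haplomark.store import HaplotypeCount, RegionDef


def make_region(n_cpgs: int, region_id: str = "r1", chrom: str = "chr1",
                start: int = 100) -> RegionDef:
    """A region with evenly spaced CpGs, convenient for hand-built reads."""
    positions = tuple(start + 10 * i for i in range(n_cpgs))
    return RegionDef(region_id, chrom, start - 2, positions[-1] + 3, positions)


def make_haps(region_id, specs):
    """specs: iterable of (first_cpg_index, pattern, count)."""
    return [HaplotypeCount(region_id, o, p, c) for o, p, c in specs]


def matrix_from_values(values: np.ndarray, sample_ids=None, region_ids=None,
                       depth: float = 100.0) -> MetricMatrix:
    """Wrap one samples x regions array as a MetricMatrix (all metrics equal)."""
    values = np.asarray(values, dtype=float)
    n_s, n_r = values.shape
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(n_s)]
    region_ids = region_ids or [f"r{j:03d}" for j in range(n_r)]
    metric_values = {m: values.copy() for m in METRICS}
    return MetricMatrix(sample_ids, region_ids, metric_values,
                        np.full((n_s, n_r), depth))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
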