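import pytest
from hypothesis import HealthCheck, settings

from ripchip.array_io import (
    ArrayScan,
    GeneAnnotation,
    PLATFORMS,
    SpotRecord,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def pcr():
    return PLATFORMS["pcr"]


@pytest.fixture
def agilent():
    return PLATFORMS["agilent"]


def make_spot(
    probe_id="p1",
    ip=100.0,
    ref=100.0,
    ip_frac=0.95,
    ref_frac=0.95,
    flag=0,
):
    return SpotRecord(probe_id, ip, ref, ip_frac, ref_frac, flag)


def make_scan(spots, *, experiment_id="exp1", bait="geneB", platform="pcr",
              dye_swapped=False, condition="control"):
    return ArrayScan(
        experiment_id=experiment_id,
        bait_gene=bait,
        platform=platform,
        dye_swapped=dye_swapped,
        condition=condition,
        spots=tuple(spots),
    )


@pytest.fixture
def simple_annotation():
    """Three coding genes with two probes each plus one non-coding probe."""
    anns = []
    for gene in ("geneA", "geneB", "geneC"):
        for j in (1, 2):
            anns.append(GeneAnnotation(f"{gene}.p{j}", gene, True))
    anns.append(GeneAnnotation("ncX.p1", "ncX", False))
    return anns
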