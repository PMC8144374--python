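import numpy as np
import pytest

from bbsplice.events import EventCountTable, Junction, SpliceEvent
from bbsplice.simulate import SUPPORTED_CATALOG, make_toy_annotation


def make_es_event(k: int = 0, contig: str = "chr1", strand: str = "+") -> SpliceEvent:
    base = 1000 + 10_000 * k
    return SpliceEvent(
        event_id=f"es{k}", gene_id=f"G{k}", contig=contig, strand=strand,
        event_type="ES",
        iso1_junctions=(Junction(base, base + 100), Junction(base + 200, base + 300)),
        iso2_junctions=(Junction(base, base + 300),),
    )


@pytest.fixture
def small_table() -> EventCountTable:
    events = [make_es_event(k) for k in range(2)]
    return EventCountTable(
        events=events,
        samples=["s1", "s2", "s3"],
        iso1_counts=np.array([[5, 0, 7], [3, 10, 0]], dtype=np.int64),
        iso2_counts=np.array([[5, 0, 0], [9, 40, 0]], dtype=np.int64),
    )


@pytest.fixture(scope="session")
def toy_fixture(tmp_path_factory):
    """Full-catalog toy genome/GTF fixture, generated once per session."""
    outdir = tmp_path_factory.mktemp("toyfx")
    return make_toy_annotation(SUPPORTED_CATALOG, outdir)


@pytest.fixture(scope="session")
def toy_annotation(toy_fixture):
    from bbsplice.annotation import Annotation

    return Annotation(toy_fixture["gtf"], toy_fixture["genome"])
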