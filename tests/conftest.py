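import pytest

from acanthoflux.qc import QCConfig
from acanthoflux.taxonomy import (
    ReferenceRecord,
    ReferenceSet,
    TaxonomicLineage,
)

# short concrete primers keep hand-built QC fixtures readable
FWD = "ACGT"
REV = "TTCC"  # reverse complement GGAA appears at the 3' end of reads
REV_RC = "GGAA"


@pytest.fixture
def qc_cfg() -> QCConfig:
    return QCConfig(fwd_primer=FWD, rev_primer=REV, window_length=50,
                    max_window_error=0.01)


def make_ref(ref_id: str, sequence: str, lineage: str) -> ReferenceRecord:
    return ReferenceRecord(
        id=ref_id, sequence=sequence,
        lineage=TaxonomicLineage.from_string(lineage),
    )


@pytest.fixture
def small_refs() -> ReferenceSet:
    """Three clades, conflict-free lineages, distinctive sequences."""
    return ReferenceSet(
        records=[
            make_ref("refA1", "ACGTACGTACGTACGTACGT", "Acantharea;CladeA;A1"),
            make_ref("refA2", "ACGTACGTACGTACGTACCT", "Acantharea;CladeA;A2"),
            make_ref("refB1", "TTTTGGGGCCCCAAAATTTT", "Acantharea;CladeB;B1"),
        ],
        name="small",
    )
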