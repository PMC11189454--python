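import numpy as np
import pandas as pd
import pytest

import roicrosstalk as rc
from roicrosstalk import core_model as cm


@pytest.fixture(scope="session")
def fixture_bundle():
    """The deterministic miniature dataset (counts, annot, profiles, prior,
    network, centroids, truth)."""
    return rc.small_fixture()


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        [[10, 20], [0, 5], [3, 0]],
        index=["MMP2", "TNC", "THBS2"],
        columns=["roi1", "roi2"],
    )
    return cm.CountMatrix(df)


def make_annotation(rows):
    """Build a RoiAnnotation from (roi_id, core, compartment) triples with
    passing QC metrics unless overridden via dict entries."""
    recs = []
    for row in rows:
        if isinstance(row, dict):
            rec = {
                "donor_id": "d0",
                "raw_reads": 5000,
                "saturation": 75.0,
                "pct_aligned": 90.0,
                "pct_trimmed": 90.0,
                "pct_stitched": 90.0,
            }
            rec.update(row)
        else:
            rid, core, comp = row
            rec = {
                "roi_id": rid,
                "core_id": core,
                "donor_id": "d0",
                "compartment": comp,
                "raw_reads": 5000,
                "saturation": 75.0,
                "pct_aligned": 90.0,
                "pct_trimmed": 90.0,
                "pct_stitched": 90.0,
            }
        recs.append(rec)
    return cm.RoiAnnotation(pd.DataFrame(recs))


@pytest.fixture()
def make_annot():
    return make_annotation


def log2_expr(df):
    return cm.ExpressionMatrix(df.astype(float), "log2")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
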