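import numpy as np
import pandas as pd
import pytest

import csslmap as cm
from csslmap.datatypes import GenotypeData
from csslmap.pipeline import StudyConfig, run_pipeline


@pytest.fixture(scope="session")
def small_study():
    """A quick synthetic study for unit-level checks."""
    return cm.default_study(seed=7, n_lines=120, markers_per_chrom=60)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One full-pipeline run on the default study shape, shared across the
    recovery / pyramiding / colocalization checks."""
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(StudyConfig(seed=1), out)


def make_geno(matrix, chrom="A01", spacing=1000, line_prefix="L"):
    """Hand-built GenotypeData from a dosage matrix (lines x markers)."""
    matrix = np.asarray(matrix, dtype=np.int8)
    n_lines, n_markers = matrix.shape
    info = pd.DataFrame(
        {
            "marker_id": [f"{chrom}_{(j + 1) * spacing}" for j in range(n_markers)],
            "chromosome": [chrom] * n_markers,
            "position_bp": [(j + 1) * spacing for j in range(n_markers)],
        }
    )
    from csslmap.datatypes import recompute_marker_stats

    maf, miss = recompute_marker_stats(matrix)
    info["maf"] = maf
    info["missing_rate"] = miss
    return GenotypeData(matrix, info, [f"{line_prefix}{i + 1}" for i in range(n_lines)])
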