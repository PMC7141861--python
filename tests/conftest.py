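import numpy as np
import pandas as pd
import pytest

from strpop import simdata
from strpop.markers import MarkerDef


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ac_marker():
    """Dinucleotide marker with 10 reference copies on a toy contig."""
    start = simdata.FLANK_LEN + 1
    return MarkerDef.create("simAC", start, start + 20 - 1, "AC", 10,
                            marker_id="mAC")


@pytest.fixture
def small_catalog(rng):
    return simdata.make_marker_catalog(5, rng)


def cohort_genotypes(markers, n_samples, freqs, rng, prefix="S"):
    """Genotype table for a cohort drawn from per-marker allele spectra."""
    rows = []
    for i in range(n_samples):
        sid = f"{prefix}{i:04d}"
        for m in markers:
            g = simdata.draw_genotype(freqs[m.marker_id], rng)
            rows.append((sid, m.marker_id, *g))
    return pd.DataFrame(rows, columns=simdata.TRUTH_COLUMNS)
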