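import numpy as np
import pandas as pd
import pytest

from epioutlier.core_io import BetaCohort, classify_chrom


def make_cohort(beta_rows, positions, samples=None, chrom="chr1", detection_p=None):
    """Build a small BetaCohort from explicit beta rows.

    ``beta_rows``: dict probe_id -> list of beta values.
    ``positions``: dict probe_id -> (chrom, pos) or pos (chrom defaults).
    """
    probe_ids = list(beta_rows)
    n = len(next(iter(beta_rows.values())))
    sample_ids = samples or [f"s{i + 1}" for i in range(n)]
    beta = pd.DataFrame(
        {s: [beta_rows[p][i] for p in probe_ids] for i, s in enumerate(sample_ids)},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    rows = []
    for p in probe_ids:
        loc = positions[p]
        c, pos = loc if isinstance(loc, tuple) else (chrom, loc)
        rows.append((c, pos, classify_chrom(c)))
    manifest = pd.DataFrame(rows, columns=["chrom", "pos", "chrom_class"],
                            index=pd.Index(probe_ids, name="probe_id"))
    sheet = pd.DataFrame(
        {"reported_sex": "female", "batch": "b1", "group": "control", "age": 30},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    detp = None
    if detection_p is not None:
        detp = pd.DataFrame(
            {s: [detection_p[p][i] for p in probe_ids] for i, s in enumerate(sample_ids)},
            index=beta.index,
        )
    return BetaCohort(beta=beta, manifest=manifest, samples=sheet, detection_p=detp)


@pytest.fixture
def tiny_cohort():
    """3 probes x 2 samples, plain values."""
    return make_cohort(
        {"cg1": [0.1, 0.2], "cg2": [0.5, 0.6], "cg3": [0.9, 0.8]},
        {"cg1": 100, "cg2": 200, "cg3": 300},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
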