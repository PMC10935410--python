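import pandas as pd
import pytest

from lithnet.io import EXPRESSION_COLUMNS, ExpressionTable
from lithnet.synthetic import CohortConfig, apply_treatment_effect, generate_cohort


def make_table(rows, panel=None) -> ExpressionTable:
    """Build a validated ExpressionTable from (subject, group, timepoint,
    cell_type, analyte, mfr) tuples."""
    df = pd.DataFrame(rows, columns=EXPRESSION_COLUMNS)
    return ExpressionTable.from_frame(df, panel=panel)


def two_group_rows(resp: dict, nonresp: dict, analyte="A", cell_type="CD4",
                   timepoint="baseline"):
    """One analyte, one cell type: subject -> mfr per group."""
    rows = []
    for sid, v in resp.items():
        rows.append((sid, "responder", timepoint, cell_type, analyte, v))
    for sid, v in nonresp.items():
        rows.append((sid, "nonresponder", timepoint, cell_type, analyte, v))
    return rows


@pytest.fixture(scope="session")
def small_cohort() -> ExpressionTable:
    """A compact synthetic cohort with both timepoints (one cell type)."""
    cfg = CohortConfig(
        n_responders=6, n_nonresponders=5, n_analytes=6, cell_types=("CD4",),
        n_post_responders=5, n_post_nonresponders=2, rng_seed=7,
    )
    return apply_treatment_effect(generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def study_cohort() -> ExpressionTable:
    """Default study-scale cohort (28 analytes, two cell types, 12/11, 9/4 paired)."""
    cfg = CohortConfig(rng_seed=3)
    return apply_treatment_effect(generate_cohort(cfg), cfg)
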