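import numpy as np
import pandas as pd
import pytest

from pairedcoda import (AbundanceTable, StudyDesign, generate_study,
                        preset_paper_like)


@pytest.fixture
def tiny_table() -> AbundanceTable:
    counts = pd.DataFrame(
        {"s1": [3, 5, 10], "s2": [4, 6, 0]},
        index=["gA", "gB", "gC"],
    )
    lineages = pd.Series(
        {
            "gA": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                  "f__X;g__gA",
            "gB": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                  "f__X;g__gB",
            "gC": "k__Bacteria;p__Tenericutes;c__Mollicutes;o__ML615J-28;"
                  "f__;g__",
        },
        name="lineage",
    )
    return AbundanceTable(counts, lineages)


@pytest.fixture(scope="session")
def small_study():
    """A small paper-like paired study (8 subjects per group)."""
    config = preset_paper_like(seed=202, n_subjects_per_group=8)
    return generate_study(config)


def make_paired_design(n_per_group: int) -> StudyDesign:
    """Minimal paired two-group metadata with deterministic covariates."""
    rows = []
    for i in range(2 * n_per_group):
        subj = f"S{i:03d}"
        group = "intervention" if i < n_per_group else "control"
        for tp in ("before", "after"):
            rows.append({
                "sample_id": f"{subj}_{tp}", "subject_id": subj,
                "group": group, "timepoint": tp,
                "age": 30 + (i % 10), "gender": ["female", "male"][i % 2],
                "bmi": 22 + (i % 5), "weight": 60 + i,
                "meals_per_week": 5.0,
            })
    return StudyDesign(pd.DataFrame(rows))
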