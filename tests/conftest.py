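"""Shared fixtures: tiny hand-built LFQ matrices and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtri.bayes import make_default_bin_specs
from mtri.lfq import LfqMatrix, fold_change_table
from mtri.pipeline import build_evidence
from mtri.simulate import generate_study, scaled_config


def make_matrix(values: dict[str, list], samples: list[dict], **kwargs) -> LfqMatrix:
    """Build an LfqMatrix from {gene: [v1, v2, ...]} and sample-sheet dicts."""
    sheet = pd.DataFrame(samples)
    intensities = pd.DataFrame.from_dict(values, orient="index", columns=list(sheet["sample_id"]))
    intensities.index.name = "gene_id"
    return LfqMatrix(intensities=intensities, samples=sheet, **kwargs)


def sample_row(sid: str, approach="MXL", condition="crosslinked", b=1, t=1) -> dict:
    return {
        "sample_id": sid,
        "approach": approach,
        "condition": condition,
        "biological_rep": b,
        "technical_rep": t,
    }


@pytest.fixture(scope="session")
def small_study():
    """2000-gene synthetic study at the default signal strengths, seed 1."""
    return generate_study(scaled_config(2000, seed=1))


@pytest.fixture(scope="session")
def small_study_parts(small_study):
    """(study, fold-change table, evidence frame, bin specs) for the small study."""
    fc = fold_change_table(small_study.lfq)
    evidence = build_evidence(fc["combined_log2_fc"], small_study.annotations)
    specs = make_default_bin_specs(evidence)
    return small_study, fc, evidence, specs
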