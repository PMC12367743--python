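import numpy as np
import pandas as pd
import pytest

from ifnsig.io_formats import ExpressionMatrix, SampleMetadata
from ifnsig.synthetic_data import (
    CohortDesign,
    ModuleSpec,
    PatientSpec,
    default_study_design,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_study_design(seed=7))


@pytest.fixture()
def zero_noise_design():
    """Small deterministic design: no noise, one 10-gene module at -2 for survivors."""
    patients = (
        PatientSpec("P1", "BRT", "survivor", "b0"),
        PatientSpec("P2", "BRT", "survivor", "b0"),
        PatientSpec("P3", "TC", "deceased", "b0"),
    )
    return CohortDesign(
        patients=patients,
        n_genes=30,
        module_specs={"mod": ModuleSpec(10)},
        effect_sizes={("mod", "survivor"): -2.0},
        noise_sd=0.0,
        seed=11,
    )


def make_expression(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(values.shape[0]))
    if sample_ids is None:
        sample_ids = tuple(f"s{j}" for j in range(values.shape[1]))
    return ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)


def make_metadata(rows) -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            rows,
            columns=["sample_id", "patient_id", "timepoint", "arm", "outcome", "batch"],
        )
    )


def paired_metadata(patients) -> SampleMetadata:
    """patients: iterable of (patient_id, arm, outcome, batch)."""
    rows = []
    for pid, arm, outcome, batch in patients:
        for tp in ("pre", "post"):
            rows.append([f"{pid}_{tp}", pid, tp, arm, outcome, batch])
    return make_metadata(rows)


def swap_timepoints(meta: SampleMetadata) -> SampleMetadata:
    table = meta.table.copy()
    table["timepoint"] = table["timepoint"].map({"pre": "post", "post": "pre"})
    return SampleMetadata(table)
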