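"""Synthetic paired pre/post cohort generator with planted expression modules.

The generative model works directly on the log2 scale. For gene ``g`` and
sample ``s``::

    x[g, s] = baseline[g] + batch_offset[batch(s)]
              + 1{s is post and module(g) is active for outcome(s)}
                * sign[g] * effect(module(g), outcome(s))
              + eps,   eps ~ Normal(0, noise_sd)

Modules occupy disjoint, consecutive gene-index ranges. Effects are keyed
by ``(module_name, outcome)``; per-patient exemptions allow a module shift
to be withheld from individual patients (used to model a module that rises
in only a subset of an outcome group). Everything is driven by a single
``numpy`` generator seeded from the design, so identical designs produce
bit-identical cohorts.

An optional count-emission helper (``to_counts``) rounds ``2**x`` for I/O
tests; no sequencing-read or library-size modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ifnsig.io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    write_expression,
    write_gmt,
    write_metadata,
    write_survival,
)

__all__ = [
    "PatientSpec",
    "ModuleSpec",
    "CohortDesign",
    "SyntheticCohort",
    "generate_cohort",
    "default_study_design",
    "to_counts",
    "write_cohort",
]

ARMS = ("BRT", "TC")
OUTCOMES = ("survivor", "deceased")

#: Gene-set names used by the default design.
TYPE_I = "ifn_type_I"
TYPE_II = "ifn_type_II"
TYPE_III = "ifn_type_III"
B_CELL = "b_cell"
COAGULATION = "coagulation"


@dataclass(frozen=True)
class PatientSpec:
    patient_id: str
    arm: str
    outcome: str
    batch: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted module: ``size`` consecutive genes with per-gene signs.

    ``signs`` is either ``None`` (all +1) or a tuple of ``size`` values in
    {+1, -1}; a -1 gene responds in the opposite direction to the module's
    effect and carries coefficient -1 in the emitted gene-set collection.
    """

    size: int
    signs: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if self.signs is not None:
            if len(self.signs) != self.size:
                raise ValueError("signs length must equal module size")
            if not set(self.signs) <= {1, -1}:
                raise ValueError("signs must be +1 or -1")

    def sign_vector(self) -> np.ndarray:
        if self.signs is None:
            return np.ones(self.size)
        return np.asarray(self.signs, dtype=float)


@dataclass(frozen=True)
class CohortDesign:
    """Full specification of a synthetic cohort.

    ``effect_sizes`` maps ``(module_name, outcome)`` to the log2-scale shift
    added to *post* samples of patients with that outcome;
    ``effect_exemptions`` lists ``(patient_id, module_name)`` pairs whose
    shift is withheld.
    """

    patients: tuple[PatientSpec, ...]
    n_genes: int
    module_specs: Mapping[str, ModuleSpec]
    effect_sizes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    batch_offsets: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.25
    baseline_mean_sd: tuple[float, float] = (8.0, 2.0)
    effect_exemptions: frozenset[tuple[str, str]] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))
        object.__setattr__(self, "module_specs", dict(self.module_specs))
        object.__setattr__(self, "effect_sizes", dict(self.effect_sizes))
        object.__setattr__(self, "batch_offsets", dict(self.batch_offsets))
        object.__setattr__(self, "effect_exemptions", frozenset(self.effect_exemptions))
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id: {dup}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        total = sum(m.size for m in self.module_specs.values())
        if total > self.n_genes:
            raise ValueError(
                f"module gene counts sum to {total} > n_genes = {self.n_genes} "
                "(modules must be disjoint gene ranges)"
            )
        for (mod, outcome) in self.effect_sizes:
            if mod not in self.module_specs:
                raise ValueError(f"effect for unknown module {mod!r}")
            if outcome not in OUTCOMES:
                raise ValueError(f"effect for unknown outcome {outcome!r}")
        for (pid, mod) in self.effect_exemptions:
            if pid not in ids:
                raise ValueError(f"exemption for unknown patient {pid!r}")
            if mod not in self.module_specs:
                raise ValueError(f"exemption for unknown module {mod!r}")

    def module_ranges(self) -> dict[str, range]:
        """Disjoint consecutive gene-index ranges, in declaration order."""
        out: dict[str, range] = {}
        start = 0
        for name, spec in self.module_specs.items():
            out[name] = range(start, start + spec.size)
            start += spec.size
        return out


@dataclass(frozen=True)
class SyntheticCohort:
    expression: ExpressionMatrix
    metadata: SampleMetadata
    gene_sets: GeneSetCollection
    clinical: pd.DataFrame
    survival: pd.DataFrame
    design: CohortDesign


def _gene_ids(n_genes: int) -> tuple[str, ...]:
    width = max(4, len(str(n_genes)))
    return tuple(f"G{i + 1:0{width}d}" for i in range(n_genes))


def generate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Generate a cohort realising *design*; deterministic in ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    n_genes = design.n_genes
    gene_ids = _gene_ids(n_genes)
    ranges = design.module_ranges()

    mu0, sigma0 = design.baseline_mean_sd
    baseline = rng.normal(mu0, sigma0, size=n_genes)

    sample_rows = []
    columns = []
    col_ids = []
    for patient in design.patients:
        for timepoint in ("pre", "post"):
            sid = f"{patient.patient_id}_{timepoint}"
            col = baseline + design.batch_offsets.get(patient.batch, 0.0)
            if timepoint == "post":
                col = col.copy()
                for name, spec in design.module_specs.items():
                    effect = design.effect_sizes.get((name, patient.outcome), 0.0)
                    if effect == 0.0:
                        continue
                    if (patient.patient_id, name) in design.effect_exemptions:
                        continue
                    idx = ranges[name]
                    col[idx.start : idx.stop] = (
                        col[idx.start : idx.stop] + spec.sign_vector() * effect
                    )
            noise = rng.normal(0.0, design.noise_sd, size=n_genes) if design.noise_sd else 0.0
            columns.append(col + noise)
            col_ids.append(sid)
            sample_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": patient.patient_id,
                    "timepoint": timepoint,
                    "arm": patient.arm,
                    "outcome": patient.outcome,
                    "batch": patient.batch,
                }
            )

    expression = ExpressionMatrix(
        gene_ids, tuple(col_ids), np.column_stack(columns)
    )
    metadata = SampleMetadata(pd.DataFrame(sample_rows))
    metadata.bind(expression)

    sets: dict[str, tuple[str, ...]] = {}
    signs: dict[str, int] = {}
    for name, spec in design.module_specs.items():
        members = tuple(gene_ids[i] for i in ranges[name])
        sets[name] = members
        if spec.signs is not None:
            for g, s in zip(members, spec.signs):
                if s == -1:
                    signs[g] = -1
    gene_sets = GeneSetCollection(sets=sets, signs=signs)

    clinical = _synthesize_clinical(design, rng)
    survival = _synthesize_survival(design, rng)
    return SyntheticCohort(expression, metadata, gene_sets, clinical, survival, design)


def _synthesize_clinical(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Patient-level clinical table with continuous and categorical variables."""
    rows = []
    for p in design.patients:
        deceased = p.outcome == "deceased"
        rows.append(
            {
                "patient_id": p.patient_id,
                "arm": p.arm,
                "outcome": p.outcome,
                "age_years": round(float(rng.normal(66 if deceased else 50, 8)), 1),
                "ferritin_ng_ml": round(float(rng.lognormal(6.5, 0.6)), 1),
                "n_risk_factors": int(rng.integers(3, 7)),
                "sex": "M" if rng.random() < 0.2 else "F",
                "heliotrope_rash": int(rng.random() < 0.4),
                "arthritis": int(rng.random() < 0.3),
                "ssa_ro52_positive": int(rng.random() < (0.5 if deceased else 0.15)),
            }
        )
    return pd.DataFrame(rows)


def _synthesize_survival(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Deceased patients: event uniform on (2, 3) months; survivors: censored at 12."""
    rows = []
    for p in design.patients:
        if p.outcome == "deceased":
            time, event = float(rng.uniform(2.0, 3.0)), 1
        else:
            time, event = 12.0, 0
        rows.append(
            {
                "patient_id": p.patient_id,
                "group": p.arm,
                "time_months": round(time, 3),
                "event": event,
            }
        )
    return pd.DataFrame(rows)


#: Default log2-scale post-treatment shifts. Free parameters, not estimates
#: of any real cohort: survivors suppress the interferon modules strongly
#: and B-cell genes moderately; the deceased raise the interferon modules
#: (type I in only a subset, see the exemption in
#: :func:`default_study_design`) and coagulation genes while dipping B-cell
#: genes slightly. The IFN-vs-B-cell contrast is deliberately opposite
#: between outcomes so correlation-based clustering sees anti-aligned
#: relative profiles, not just opposite absolute shifts.
DEFAULT_EFFECT_SIZES: dict[tuple[str, str], float] = {
    (TYPE_I, "survivor"): -2.5,
    (TYPE_I, "deceased"): 1.5,
    (TYPE_II, "survivor"): -2.5,
    (TYPE_II, "deceased"): 1.5,
    (TYPE_III, "survivor"): -2.5,
    (TYPE_III, "deceased"): 1.5,
    (B_CELL, "survivor"): -1.2,
    (B_CELL, "deceased"): -0.5,
    (COAGULATION, "deceased"): 2.0,
}

DEFAULT_MODULE_SIZES: dict[str, int] = {
    TYPE_I: 73,
    TYPE_II: 94,
    TYPE_III: 10,
    B_CELL: 100,
    COAGULATION: 50,
}


def default_study_design(
    n_genes: int = 500,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> CohortDesign:
    """The default 6-patient, 2-arm design.

    Three BRT survivors and three TC patients of whom two are deceased;
    one batch per arm; interferon modules of 73/94/10 genes plus B-cell
    (100) and coagulation (50) modules. One of the two deceased patients
    is exempt from the type I interferon rise.
    """
    patients = (
        PatientSpec("TC-1", "TC", "deceased", "batch_TC"),
        PatientSpec("TC-2", "TC", "survivor", "batch_TC"),
        PatientSpec("TC-3", "TC", "deceased", "batch_TC"),
        PatientSpec("BRT-1", "BRT", "survivor", "batch_BRT"),
        PatientSpec("BRT-2", "BRT", "survivor", "batch_BRT"),
        PatientSpec("BRT-3", "BRT", "survivor", "batch_BRT"),
    )
    modules = {name: ModuleSpec(size) for name, size in DEFAULT_MODULE_SIZES.items()}
    return CohortDesign(
        patients=patients,
        n_genes=n_genes,
        module_specs=modules,
        effect_sizes=dict(DEFAULT_EFFECT_SIZES),
        batch_offsets={"batch_TC": 0.8, "batch_BRT": 0.0},
        noise_sd=noise_sd,
        baseline_mean_sd=(8.0, 2.0),
        effect_exemptions=frozenset({("TC-3", TYPE_I)}),
        seed=seed,
    )


def to_counts(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Emit a pseudo-count matrix (``round(2**x)``) for I/O testing only."""
    return ExpressionMatrix(
        expr.gene_ids, expr.sample_ids, np.rint(np.exp2(expr.values))
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort tables under *outdir*; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "gene_signs": outdir / "gene_signs.tsv",
        "clinical": outdir / "clinical.tsv",
        "survival": outdir / "survival.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_metadata(cohort.metadata, paths["metadata"])
    write_gmt(cohort.gene_sets, paths["gene_sets"], paths["gene_signs"])
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    write_survival(cohort.survival, paths["survival"])
    return paths
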