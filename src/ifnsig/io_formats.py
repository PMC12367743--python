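"""Readers/writers for expression matrices, sample metadata, gene sets and
clinical tables, with strict validation.

All tabular formats are plain TSV: tab-separated, UTF-8, ``.`` decimal
point, no quoting. Gene sets use the GMT convention (one set per line:
name, description, then member gene ids) with an optional two-column
sidecar TSV assigning a ``+1``/``-1`` sign to individual genes.

Validation is all-or-nothing: a reader either returns a fully validated
object or raises :class:`FormatError` without partially loaded state.
Gene identifiers are opaque strings; no symbol mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
]

TIMEPOINTS = ("pre", "post")


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Row identifiers, unique, order preserved.
    sample_ids : sequence of str
        Column identifiers, unique, order preserved.
    values : ndarray of shape (n_genes, n_samples)
        Finite log2-scale expression values.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if values.ndim != 2:
            raise FormatError(f"expression values must be 2-D, got {values.ndim}-D")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(frame.index), tuple(frame.columns), frame.to_numpy(dtype=float))

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index()
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, tuple(sample_ids), self.values[:, cols])


_META_COLUMNS = ("sample_id", "patient_id", "timepoint", "arm", "outcome", "batch")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations binding samples to patients and groups.

    The underlying table has columns ``sample_id``, ``patient_id``,
    ``timepoint`` (``pre``/``post``), ``arm``, ``outcome`` and ``batch``.
    Each patient may contribute at most one sample per timepoint.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        table = self.table.reset_index(drop=True).copy()
        missing = [c for c in _META_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        table = table[list(_META_COLUMNS)].astype(str)
        _check_unique(table["sample_id"].tolist(), "sample")
        bad_tp = sorted(set(table["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise FormatError(f"invalid timepoint values: {bad_tp}")
        dup = table.groupby(["patient_id", "timepoint"]).size()
        offenders = dup[dup > 1]
        if len(offenders):
            pid, tp = offenders.index[0]
            raise FormatError(f"patient {pid!r} has multiple {tp!r} samples")
        object.__setattr__(self, "table", table)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table["sample_id"])

    @property
    def patient_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.table["patient_id"]:
            seen.setdefault(p, None)
        return tuple(seen)

    def sample_for(self, patient_id: str, timepoint: str) -> str | None:
        rows = self.table[
            (self.table["patient_id"] == patient_id)
            & (self.table["timepoint"] == timepoint)
        ]
        if rows.empty:
            return None
        return str(rows["sample_id"].iloc[0])

    def patient_attr(self, attr: str) -> dict[str, str]:
        """Map patient_id -> value of a patient-level column (arm/outcome/batch)."""
        out: dict[str, str] = {}
        for _, row in self.table.iterrows():
            pid = row["patient_id"]
            if pid in out and out[pid] != row[attr]:
                raise FormatError(
                    f"patient {pid!r} has inconsistent {attr!r} across samples"
                )
            out[pid] = row[attr]
        return out

    def attr_of_sample(self, attr: str) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table[attr]))

    def paired_patients(self) -> tuple[str, ...]:
        """Patients having both a pre and a post sample, in first-seen order."""
        return tuple(
            p
            for p in self.patient_ids
            if self.sample_for(p, "pre") is not None
            and self.sample_for(p, "post") is not None
        )

    def bind(self, expr: ExpressionMatrix) -> None:
        """Check every metadata sample is present in *expr*."""
        have = set(expr.sample_ids)
        missing = [s for s in self.sample_ids if s not in have]
        if missing:
            raise FormatError(f"samples absent from expression matrix: {missing}")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with an optional per-gene sign coefficient.

    ``signs`` maps gene id -> +1 or -1; genes absent from the map carry
    the default coefficient +1.
    """

    sets: dict[str, tuple[str, ...]]
    signs: dict[str, int] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for name, genes in self.sets.items():
            genes = tuple(str(g) for g in genes)
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate members")
            clean[str(name)] = genes
        object.__setattr__(self, "sets", clean)
        for g, s in self.signs.items():
            if s not in (1, -1):
                raise FormatError(f"sign for gene {g!r} must be +1 or -1, got {s!r}")
        object.__setattr__(self, "signs", {str(g): int(s) for g, s in self.signs.items()})

    def sign_of(self, gene: str) -> int:
        return self.signs.get(gene, 1)

    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene ids, header = samples).

    Raises :class:`FormatError` with row/column coordinates for duplicate
    ids, ragged rows or non-numeric cells.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        if not sample_ids:
            raise FormatError(f"{path}: header has no sample columns")
        _check_unique(sample_ids, "sample")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {len(cols)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError:
                for j, x in enumerate(fields[1:], start=1):
                    try:
                        float(x)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric value {x!r} at line {lineno}, "
                            f"column {cols[j]!r}"
                        ) from None
                raise
    _check_unique(gene_ids, "gene")
    if not gene_ids:
        raise FormatError(f"{path}: no gene rows")
    return ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), np.asarray(rows))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# metadata TSV


def read_metadata(path: str | Path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(table)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets + sign sidecar


def read_gmt(path: str | Path, signs_path: str | Path | None = None) -> GeneSetCollection:
    """Read a GMT file; optionally attach a gene->sign sidecar TSV.

    Each GMT line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.
    Sets with zero genes are rejected. Sidecar sign values outside
    ``{+1, -1}`` are rejected.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: gene set {fields[0]!r} has no genes"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(
                    f"{path}: line {lineno}: gene set {name!r} has no genes"
                )
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = tuple(genes)
            descriptions[name] = desc
    signs: dict[str, int] = {}
    if signs_path is not None:
        signs_path = Path(signs_path)
        with signs_path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FormatError(
                        f"{signs_path}: line {lineno}: expected 2 columns, "
                        f"got {len(fields)}"
                    )
                gene, raw = fields
                if raw.lstrip("+") not in ("1", "-1") and raw not in ("+1", "-1", "1"):
                    raise FormatError(
                        f"{signs_path}: line {lineno}: sign must be +1 or -1, "
                        f"got {raw!r}"
                    )
                signs[gene] = int(raw)
    return GeneSetCollection(sets=sets, signs=signs, descriptions=descriptions)


def write_gmt(
    collection: GeneSetCollection,
    path: str | Path,
    signs_path: str | Path | None = None,
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    if signs_path is not None:
        with Path(signs_path).open("w", encoding="utf-8") as fh:
            for gene, sign in collection.signs.items():
                fh.write(f"{gene}\t{sign:+d}\n")


# ---------------------------------------------------------------------------
# survival TSV


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV with columns patient_id, time_months, event."""
    table = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in ("patient_id", "time_months", "event") if c not in table.columns]
    if missing:
        raise FormatError(f"survival table missing columns: {missing}")
    times = table["time_months"].to_numpy(dtype=float)
    if not np.all(np.isfinite(times)) or np.any(times <= 0):
        raise FormatError("survival times must be finite and > 0")
    events = table["event"].to_numpy()
    if not set(np.unique(events)) <= {0, 1}:
        raise FormatError("event must be 0 (censored) or 1 (death)")
    return table


def write_survival(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
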