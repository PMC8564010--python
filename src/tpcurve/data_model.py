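"""Domain types, CSV I/O, and validation for individual-level survival tables.

A survival table holds one row per assayed individual: the block and vial it
was reared in, the two prior-environment treatment temperatures (fertilization
and embryogenesis), the assay temperature, and a binary survival outcome.
Treatment temperatures are treated as unordered categorical factors
downstream; assay temperature is the continuous axis of the performance
curve.  Temperatures are plain decimal degrees Celsius throughout — no unit
conversion happens anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ValidationError",
    "SurvivalRecord",
    "ExperimentDesign",
    "SurvivalTable",
    "CSV_COLUMNS",
    "read_survival_csv",
    "write_survival_csv",
]

#: Canonical CSV header, in order.
CSV_COLUMNS = ("block", "vial", "fert_temp", "embryo_temp", "assay_temp", "outcome")


class ValidationError(ValueError):
    """Raised when a record, design, or file violates a declared invariant."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One assayed individual: design covariates plus a binary outcome."""

    block_id: str
    vial_id: str
    fert_temp: float
    embryo_temp: float
    assay_temp: float
    outcome: int

    def validate(self) -> None:
        if self.outcome not in (0, 1):
            raise ValidationError(f"outcome must be 0 or 1, got {self.outcome!r}")
        for name in ("fert_temp", "embryo_temp", "assay_temp"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout constants: treatment levels, assay grid, replication.

    ``replicates_per_combo`` maps each assay temperature to the number of
    replicate vials per fertilization x embryogenesis combination;
    ``temps_per_block`` is the (min, max) number of assay temperatures a
    single block may receive in the incomplete-block allocation.
    """

    fert_temps: tuple[float, ...] = (18.0, 22.0)
    embryo_temps: tuple[float, ...] = (18.0, 20.0, 22.0)
    assay_temps: tuple[float, ...] = (10.0, 13.0, 16.0, 18.0, 20.0, 22.0, 24.0, 26.0, 27.0, 28.0)
    n_per_vial: int = 30
    replicates_per_combo: Mapping[float, int] = field(
        default_factory=lambda: {t: (2 if t == 27.0 else 4)
                                 for t in (10.0, 13.0, 16.0, 18.0, 20.0, 22.0, 24.0, 26.0, 27.0, 28.0)}
    )
    n_blocks: int = 10
    temps_per_block: tuple[int, int] = (2, 5)

    def validate(self) -> None:
        if self.n_per_vial < 1 or self.n_blocks < 1:
            raise ValidationError("n_per_vial and n_blocks must be >= 1")
        if not self.fert_temps or not self.embryo_temps or not self.assay_temps:
            raise ValidationError("all temperature level lists must be non-empty")
        for t in self.assay_temps:
            if t not in self.replicates_per_combo:
                raise ValidationError(f"assay temperature {t} has no replicate count")
            if self.replicates_per_combo[t] < 1:
                raise ValidationError(f"replicate count for {t} must be >= 1")
        lo, hi = self.temps_per_block
        if not (1 <= lo <= hi):
            raise ValidationError("temps_per_block must satisfy 1 <= min <= max")

    @property
    def assay_range(self) -> tuple[float, float]:
        return (min(self.assay_temps), max(self.assay_temps))

    def n_vials(self) -> int:
        """Total vials across the full factorial."""
        per_combo = sum(self.replicates_per_combo[t] for t in self.assay_temps)
        return len(self.fert_temps) * len(self.embryo_temps) * per_combo

    def n_individuals(self) -> int:
        return self.n_vials() * self.n_per_vial


def default_design() -> ExperimentDesign:
    """The study layout: 2 fert x 3 embryo x 10 assay temperatures, 30 per
    vial, 4 replicate vials per combination (2 at 27 degC), 10 blocks."""
    return ExperimentDesign()


@dataclass
class SurvivalTable:
    """Ordered collection of :class:`SurvivalRecord` plus its declared design."""

    records: list[SurvivalRecord]
    design: ExperimentDesign = field(default_factory=default_design)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self, *, min_distinct_temps: int = 2) -> None:
        if not self.records:
            raise ValidationError("survival table is empty")
        self.design.validate()
        lo, hi = self.design.assay_range
        vial_key: dict[tuple[str, str], tuple[float, float, float]] = {}
        for i, rec in enumerate(self.records):
            try:
                rec.validate()
            except ValidationError as exc:
                raise ValidationError(f"record {i}: {exc}") from exc
            if not (lo <= rec.assay_temp <= hi):
                raise ValidationError(
                    f"record {i}: assay_temp {rec.assay_temp} outside declared range [{lo}, {hi}]"
                )
            key = (rec.block_id, rec.vial_id)
            cell = (rec.fert_temp, rec.embryo_temp, rec.assay_temp)
            if vial_key.setdefault(key, cell) != cell:
                raise ValidationError(
                    f"record {i}: vial {rec.vial_id!r} in block {rec.block_id!r} "
                    "appears in more than one treatment cell"
                )
        if len({r.assay_temp for r in self.records}) < min_distinct_temps:
            raise ValidationError(
                f"need at least {min_distinct_temps} distinct assay temperatures"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [r.block_id for r in self.records],
                "vial": [r.vial_id for r in self.records],
                "fert_temp": [r.fert_temp for r in self.records],
                "embryo_temp": [r.embryo_temp for r in self.records],
                "assay_temp": [r.assay_temp for r in self.records],
                "outcome": [r.outcome for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, design: ExperimentDesign | None = None) -> "SurvivalTable":
        records = [
            SurvivalRecord(
                block_id=str(row.block),
                vial_id=str(row.vial),
                fert_temp=float(row.fert_temp),
                embryo_temp=float(row.embryo_temp),
                assay_temp=float(row.assay_temp),
                outcome=int(row.outcome),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records=records, design=design or default_design())


def read_survival_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    design: ExperimentDesign | None = None,
    validate: bool = True,
) -> SurvivalTable:
    """Read a survival table from CSV.

    Parameters
    ----------
    path
        CSV file with a mandatory header row (comma separator, UTF-8,
        ``.`` decimal mark). Lines starting with ``#`` are ignored.
    schema
        Optional map from canonical column names (``block``, ``vial``,
        ``fert_temp``, ``embryo_temp``, ``assay_temp``, ``outcome``) to the
        names used in the file.
    design
        Declared design; defaults to the study layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in CSV_COLUMNS}
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s) {missing} in {path}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[list(CSV_COLUMNS)]

    records: list[SurvivalRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = {}
        for col in ("fert_temp", "embryo_temp", "assay_temp"):
            raw = getattr(row, col)
            try:
                values[col] = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {i + 1}, column {colmap[col]!r}: unparseable temperature {raw!r}"
                ) from None
        raw = row.outcome
        try:
            outcome = int(raw)
            if outcome not in (0, 1):
                raise ValueError
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {i + 1}, column {colmap['outcome']!r}: outcome must be 0 or 1, got {raw!r}"
            ) from None
        records.append(
            SurvivalRecord(
                block_id=str(row.block),
                vial_id=str(row.vial),
                outcome=outcome,
                **values,
            )
        )
    table = SurvivalTable(records=records, design=design or default_design())
    if validate:
        table.validate()
    return table


def write_survival_csv(table: SurvivalTable, path: str | Path) -> Path:
    """Write a survival table to CSV with the canonical header.

    Temperatures are written with up to 10 significant digits so the
    read/write round trip is exact to well beyond 6 significant digits.
    """
    path = Path(path)
    if str(path) == "" or path.is_dir():
        raise OSError(f"cannot write survival table to {path!r}")
    lines = [",".join(CSV_COLUMNS)]
    for r in table.records:
        lines.append(
            f"{r.block_id},{r.vial_id},{r.fert_temp:.10g},{r.embryo_temp:.10g},"
            f"{r.assay_temp:.10g},{r.outcome}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
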