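"""Data model and I/O for balanced multi-trait multi-environment trials.

A trial is a randomized complete block design replicated across environments:
every genotype appears once per block, every block is present in every
environment, and the same traits are measured on every plot.  The container
here is deliberately strict — all downstream statistics (the closed-form
MANOVA decomposition, contrast standard errors) assume full balance, so
validation rejects anything with missing or duplicated cells rather than
silently imputing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitSpec",
    "TrialDataset",
    "MeanTable",
    "Defect",
    "MetDataError",
    "FormatError",
    "DuplicateError",
    "BalanceError",
    "ParseError",
    "read_met_csv",
    "write_met_csv",
    "validate_balanced",
    "read_trait_specs",
    "write_trait_specs",
]

#: column names reserved for the design factors in trial CSV files
ENV_COL, GEN_COL, REP_COL = "ENV", "GEN", "REP"


class MetDataError(ValueError):
    """Base class for trial-data errors."""


class FormatError(MetDataError):
    """A required column is missing or the file layout is wrong."""


class DuplicateError(MetDataError):
    """The same (environment, genotype, block) cell appears more than once."""


class BalanceError(MetDataError):
    """The design is not a complete (environment x genotype x block) grid."""


class ParseError(MetDataError):
    """A trait cell could not be parsed as a finite number."""


@dataclass(frozen=True)
class TraitSpec:
    """One measured trait: its short code, selection direction and weight.

    ``direction`` states which end of the trait's scale the ideal genotype
    sits at: ``"maximize"`` (e.g. grain yield) or ``"minimize"`` (e.g.
    lodging).  ``weight`` is a non-negative prior importance used by the
    MGIDI weighting scheme (1.0 = neutral).
    """

    code: str
    direction: str = "maximize"
    weight: float = 1.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise MetDataError(
                f"trait {self.code!r}: direction must be 'maximize' or "
                f"'minimize', got {self.direction!r}"
            )
        if not (self.weight >= 0):
            raise MetDataError(f"trait {self.code!r}: weight must be >= 0")


@dataclass
class TrialDataset:
    """Balanced multi-trait trial observations.

    ``values`` has shape ``(e, v, r, p)`` indexed by (environment, genotype,
    block, trait); axes follow the declared label orders.
    """

    environments: list[str]
    genotypes: list[str]
    blocks: list[str]
    traits: list[TraitSpec]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        e, v, r, p = self.shape
        if self.values.shape != (e, v, r, p):
            raise MetDataError(
                f"values shape {self.values.shape} does not match labels "
                f"({e}, {v}, {r}, {p})"
            )
        for name, labels in (
            ("environments", self.environments),
            ("genotypes", self.genotypes),
            ("blocks", self.blocks),
        ):
            if len(set(labels)) != len(labels):
                raise MetDataError(f"duplicate labels in {name}")
        codes = [t.code for t in self.traits]
        if len(set(codes)) != len(codes):
            raise MetDataError("duplicate trait codes")
        if e < 2 or v < 2 or r < 2 or p < 1:
            raise MetDataError(
                "design too small: need >=2 environments, >=2 genotypes, "
                ">=2 blocks, >=1 trait"
            )
        if not np.all(np.isfinite(self.values)):
            raise MetDataError("non-finite trait values present")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (
            len(self.environments),
            len(self.genotypes),
            len(self.blocks),
            len(self.traits),
        )

    @property
    def trait_codes(self) -> list[str]:
        return [t.code for t in self.traits]

    def trait_index(self, code: str) -> int:
        try:
            return self.trait_codes.index(code)
        except ValueError:
            raise MetDataError(f"unknown trait code {code!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per plot, ENV/GEN/REP + trait columns."""
        e, v, r, p = self.shape
        idx = pd.MultiIndex.from_product(
            [self.environments, self.genotypes, self.blocks],
            names=[ENV_COL, GEN_COL, REP_COL],
        )
        flat = self.values.reshape(e * v * r, p)
        return pd.DataFrame(flat, columns=self.trait_codes, index=idx).reset_index()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return (
            self.environments == other.environments
            and self.genotypes == other.genotypes
            and self.blocks == other.blocks
            and self.traits == other.traits
            and np.array_equal(self.values, other.values)
        )


@dataclass
class MeanTable:
    """Two-way means: rows are genotypes or (environment, genotype) pairs,
    columns are traits."""

    row_labels: list  # str for by_genotype, (env, gen) tuples otherwise
    trait_codes: list[str]
    values: np.ndarray
    kind: str  # "by_genotype" | "by_genotype_environment"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("by_genotype", "by_genotype_environment"):
            raise MetDataError(f"unknown MeanTable kind {self.kind!r}")
        if self.values.shape != (len(self.row_labels), len(self.trait_codes)):
            raise MetDataError("MeanTable shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "by_genotype":
            index = pd.Index(self.row_labels, name=GEN_COL)
        else:
            index = pd.MultiIndex.from_tuples(
                self.row_labels, names=[ENV_COL, GEN_COL]
            )
        return pd.DataFrame(self.values, index=index, columns=self.trait_codes)

    def column(self, code: str) -> np.ndarray:
        try:
            j = self.trait_codes.index(code)
        except ValueError:
            raise MetDataError(f"unknown trait code {code!r}") from None
        return self.values[:, j]


@dataclass(frozen=True)
class Defect:
    """One validation finding. ``kind`` is 'missing', 'duplicate' or
    'nonfinite'."""

    kind: str
    env: str
    gen: str
    rep: str
    trait: str = ""
    message: str = ""


def _first_appearance(series: pd.Series) -> list[str]:
    return list(pd.unique(series))


def validate_balanced(data: TrialDataset | pd.DataFrame,
                      trait_codes: Sequence[str] | None = None) -> list[Defect]:
    """Check complete balance: every (env, gen, rep) cell exactly once with
    all traits finite.  Returns a list of defects (empty = valid); never
    raises.

    Accepts either a constructed :class:`TrialDataset` (which can only
    violate finiteness if mutated in place) or a long-format frame as read
    from CSV, where duplicates and missing cells are still representable.
    """
    if isinstance(data, TrialDataset):
        frame = data.to_frame()
        trait_codes = data.trait_codes
    else:
        frame = data
        if trait_codes is None:
            trait_codes = [
                c for c in frame.columns if c not in (ENV_COL, GEN_COL, REP_COL)
            ]

    defects: list[Defect] = []
    envs = _first_appearance(frame[ENV_COL])
    gens = _first_appearance(frame[GEN_COL])
    reps = _first_appearance(frame[REP_COL])

    counts: dict[tuple[str, str, str], int] = {}
    for env, gen, rep in zip(frame[ENV_COL], frame[GEN_COL], frame[REP_COL]):
        counts[(env, gen, rep)] = counts.get((env, gen, rep), 0) + 1

    for key, n in counts.items():
        if n > 1:
            defects.append(
                Defect(
                    "duplicate", *key,
                    message=f"cell {key} observed {n} times",
                )
            )
    for env in envs:
        for gen in gens:
            for rep in reps:
                if (env, gen, rep) not in counts:
                    defects.append(
                        Defect(
                            "missing", env, gen, rep,
                            message=f"cell ({env}, {gen}, {rep}) absent",
                        )
                    )

    for code in trait_codes:
        col = pd.to_numeric(frame[code], errors="coerce").to_numpy()
        bad = ~np.isfinite(col)
        for i in np.flatnonzero(bad):
            defects.append(
                Defect(
                    "nonfinite",
                    frame[ENV_COL].iat[i],
                    frame[GEN_COL].iat[i],
                    frame[REP_COL].iat[i],
                    trait=code,
                    message=f"non-finite value for trait {code} at data row {i}",
                )
            )
    return defects


def read_met_csv(path: str | Path, trait_specs: Sequence[TraitSpec]) -> TrialDataset:
    """Read a long-format trial CSV into a validated :class:`TrialDataset`.

    The file must have a header with ``ENV``, ``GEN``, ``REP`` columns plus
    one numeric column per trait code.  Label order is first-appearance
    order.  Raises :class:`FormatError`, :class:`DuplicateError`,
    :class:`BalanceError` or :class:`ParseError` on defects.
    """
    traits = list(trait_specs)
    frame = pd.read_csv(
        path, dtype={ENV_COL: str, GEN_COL: str, REP_COL: str},
        encoding="utf-8", float_precision="round_trip",
    )
    needed = [ENV_COL, GEN_COL, REP_COL] + [t.code for t in traits]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    for t in traits:
        col = pd.to_numeric(frame[t.code], errors="coerce")
        bad = col.isna() & frame[t.code].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {frame[t.code].iat[i]!r} in "
                f"column {t.code!r} at data row {i + 1}"
            )
        frame[t.code] = col

    defects = validate_balanced(frame, [t.code for t in traits])
    dups = [d for d in defects if d.kind == "duplicate"]
    if dups:
        raise DuplicateError(f"{path}: {dups[0].message}")
    holes = [d for d in defects if d.kind == "missing"]
    if holes:
        listed = "; ".join(d.message for d in holes[:5])
        raise BalanceError(f"{path}: unbalanced design — {listed}")
    nonfinite = [d for d in defects if d.kind == "nonfinite"]
    if nonfinite:
        raise ParseError(f"{path}: {nonfinite[0].message}")

    envs = _first_appearance(frame[ENV_COL])
    gens = _first_appearance(frame[GEN_COL])
    reps = _first_appearance(frame[REP_COL])
    e, v, r, p = len(envs), len(gens), len(reps), len(traits)

    ei = {lab: i for i, lab in enumerate(envs)}
    gi = {lab: i for i, lab in enumerate(gens)}
    ri = {lab: i for i, lab in enumerate(reps)}
    values = np.empty((e, v, r, p), dtype=float)
    trait_mat = frame[[t.code for t in traits]].to_numpy(dtype=float)
    for row, (env, gen, rep) in enumerate(
        zip(frame[ENV_COL], frame[GEN_COL], frame[REP_COL])
    ):
        values[ei[env], gi[gen], ri[rep], :] = trait_mat[row]

    return TrialDataset(envs, gens, reps, traits, values)


def write_met_csv(dataset: TrialDataset, path: str | Path) -> Path:
    """Write a dataset to CSV with deterministic (env, gen, rep) row order
    and full float precision; returns the path."""
    path = Path(path)
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    return path


def read_trait_specs(path: str | Path) -> list[TraitSpec]:
    """Load trait specifications from a YAML file.

    Layout: a list of mappings with keys ``code`` (required), ``direction``,
    ``weight``, ``units``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise FormatError(f"{path}: trait spec file must contain a list")
    specs = []
    for entry in raw:
        if "code" not in entry:
            raise FormatError(f"{path}: trait entry without 'code': {entry}")
        specs.append(
            TraitSpec(
                code=str(entry["code"]),
                direction=entry.get("direction", "maximize"),
                weight=float(entry.get("weight", 1.0)),
                units=str(entry.get("units", "")),
            )
        )
    codes = [s.code for s in specs]
    if len(set(codes)) != len(codes):
        raise FormatError(f"{path}: duplicate trait codes")
    return specs


def write_trait_specs(specs: Iterable[TraitSpec], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump([dataclasses.asdict(s) for s in specs], fh, sort_keys=False)
    return path
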