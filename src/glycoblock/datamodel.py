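"""Core tabular data types for glycan peak matrices, sample metadata and
derived-trait definitions.

A UPLC total-plasma-N-glycome run integrates each chromatogram into a fixed
panel of glycan peaks (GP1..GP39 by default), each expressed as a percentage
of the total integrated area, so every sample row is compositional: it sums
to 100.  Preprocessing steps (batch correction, rank transformation) destroy
that closure, which the :class:`GlycanPeakMatrix` tracks with its
``compositional`` flag.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glycoblock.errors import FormulaError, IntegrityError, ValidationError

#: The conventional 39-peak total plasma N-glycome panel.
DEFAULT_PEAK_PANEL = tuple(f"GP{i}" for i in range(1, 40))

#: The six structural trait families used to organise derived traits.
TRAIT_FAMILIES = (
    "branching",
    "degree of branching",
    "galactosylation",
    "sialylation",
    "sialylation of biantennary",
    "fucose position",
)


def default_peak_panel(n_peaks: int = 39) -> tuple[str, ...]:
    """Return the default peak panel ``('GP1', ..., 'GP<n_peaks>')``."""
    return tuple(f"GP{i}" for i in range(1, n_peaks + 1))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dups:
        raise IntegrityError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class GlycanPeakMatrix:
    """Samples x peaks relative-abundance matrix.

    Parameters
    ----------
    values
        2-D array, rows are samples, columns are peaks, percent of total
        integrated area when ``compositional``.
    sample_ids, peak_ids
        Ordered unique identifiers for rows and columns.
    compositional
        When true every row must sum to 100 within ``row_sum_rtol``
        (relative tolerance).  Batch correction and rank transformation
        clear the flag.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    peak_ids: tuple[str, ...]
    compositional: bool = True
    row_sum_rtol: float = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.peak_ids = tuple(str(p) for p in self.peak_ids)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.peak_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {len(self.peak_ids)} peak ids"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.peak_ids, "peak ids")
        if np.isnan(self.values).any():
            bad = [self.sample_ids[i] for i in sorted(set(np.where(np.isnan(self.values))[0]))]
            raise ValidationError(f"missing values are not supported; NA in samples {bad}")
        if self.compositional:
            if (self.values < 0).any():
                raise ValidationError("compositional matrix has negative entries")
            sums = self.values.sum(axis=1)
            bad_rows = np.where(np.abs(sums - 100.0) > self.row_sum_rtol * 100.0)[0]
            if bad_rows.size:
                offenders = {self.sample_ids[i]: float(sums[i]) for i in bad_rows[:10]}
                raise ValidationError(
                    f"rows do not sum to 100 within tolerance {self.row_sum_rtol}: {offenders}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.peak_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, compositional: bool = True,
                   row_sum_rtol: float = 1e-6) -> "GlycanPeakMatrix":
        return cls(df.to_numpy(dtype=float), tuple(df.index.astype(str)),
                   tuple(df.columns.astype(str)), compositional=compositional,
                   row_sum_rtol=row_sum_rtol)

    def with_values(self, values: np.ndarray, compositional: bool | None = None) -> "GlycanPeakMatrix":
        """Copy with replaced values (and optionally a new compositional flag)."""
        comp = self.compositional if compositional is None else compositional
        return replace(self, values=np.asarray(values, dtype=float), compositional=comp)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GlycanPeakMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise IntegrityError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in sample_ids]
        return replace(self, values=self.values[rows], sample_ids=tuple(sample_ids))


@dataclass
class SampleMetadata:
    """Per-sample grouping, batch and covariate information.

    ``table`` is indexed by sample id and carries at least ``group`` (two
    levels for the discriminant stages, conventionally control/case) and
    ``batch`` (plate identifier); any further columns are covariates.
    """

    table: pd.DataFrame
    group_col: str = "group"
    batch_col: str = "batch"

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate sample ids in metadata: {dups}")
        for col in (self.group_col, self.batch_col):
            if col not in self.table.columns:
                raise ValidationError(f"metadata is missing required column {col!r}")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def groups_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.aligned(sample_ids)[self.group_col].to_numpy()

    def batches_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.aligned(sample_ids)[self.batch_col].to_numpy()

    def aligned(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise IntegrityError(f"samples without metadata: {missing[:10]}")
        return self.table.loc[list(sample_ids)]

    def check_two_groups(self) -> tuple[str, str]:
        levels = sorted(pd.unique(self.table[self.group_col]).tolist())
        if len(levels) != 2:
            raise ValidationError(
                f"discriminant stages need exactly two group levels, got {levels}"
            )
        return levels[0], levels[1]


# ---------------------------------------------------------------------------
# Trait formulas
# ---------------------------------------------------------------------------

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)


@dataclass(frozen=True)
class TraitFormula:
    """A parsed derived-trait formula.

    The grammar is deliberately small: sums and differences of peaks,
    scalar multiples, and a single ratio of two such linear forms.  The
    pseudo-peak ``TOTAL`` denotes the sum of every peak in the panel.
    """

    trait_id: str
    family: str
    source: str
    tree: ast.expression = field(repr=False, compare=False)

    def peaks(self) -> set[str]:
        names = {n.id for n in ast.walk(self.tree) if isinstance(n, ast.Name)}
        return names

    def evaluate(self, env: Mapping[str, np.ndarray]) -> np.ndarray:
        return _eval_node(self.tree.body, env, self.trait_id)


def _eval_node(node: ast.AST, env: Mapping[str, np.ndarray], trait_id: str) -> np.ndarray:
    if isinstance(node, ast.Name):
        return env[node.id]
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise FormulaError(f"{trait_id}: non-numeric constant {node.value!r}")
        return np.asarray(float(node.value))
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        v = _eval_node(node.operand, env, trait_id)
        return -v if isinstance(node.op, ast.USub) else v
    if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
        left = _eval_node(node.left, env, trait_id)
        right = _eval_node(node.right, env, trait_id)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        if isinstance(node.op, ast.Mult):
            return left * right
        denom = np.asarray(right, dtype=float)
        if np.any(denom == 0):
            raise FormulaError(f"{trait_id}: division by zero in ratio denominator")
        return left / denom
    raise FormulaError(f"{trait_id}: unsupported expression element {ast.dump(node)[:60]}")


def parse_formula(trait_id: str, family: str, source: str,
                  panel: Sequence[str]) -> TraitFormula:
    """Parse a formula string into a validated :class:`TraitFormula`.

    Raises :class:`FormulaError` on syntax errors, unknown peak tokens or
    disallowed constructs (function calls, comparisons, ...).
    """
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise FormulaError(f"{trait_id}: cannot parse formula {source!r}: {exc.msg}") from exc
    allowed = set(panel) | {"TOTAL"}
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            if node.id not in allowed:
                raise FormulaError(f"{trait_id}: unknown peak token {node.id!r}")
        elif isinstance(node, (ast.Expression, ast.Constant, ast.Load)):
            continue
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
            continue
        elif isinstance(node, (ast.USub, ast.UAdd)):
            continue
        elif isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            continue
        elif isinstance(node, _ALLOWED_BINOPS):
            continue
        else:
            raise FormulaError(
                f"{trait_id}: disallowed construct {type(node).__name__} in {source!r}"
            )
    return TraitFormula(trait_id=trait_id, family=family, source=source, tree=tree)


@dataclass
class TraitDefinitionTable:
    """Ordered collection of derived-trait formulas over a peak panel."""

    formulas: tuple[TraitFormula, ...]
    panel: tuple[str, ...] = DEFAULT_PEAK_PANEL

    def __post_init__(self) -> None:
        _check_unique([f.trait_id for f in self.formulas], "trait ids")
        for f in self.formulas:
            unknown = f.peaks() - set(self.panel) - {"TOTAL"}
            if unknown:
                raise FormulaError(f"{f.trait_id}: peaks not in panel: {sorted(unknown)}")
            if f.family not in TRAIT_FAMILIES:
                raise ValidationError(
                    f"{f.trait_id}: unknown family {f.family!r}; expected one of {TRAIT_FAMILIES}"
                )

    @property
    def trait_ids(self) -> tuple[str, ...]:
        return tuple(f.trait_id for f in self.formulas)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f.family for f in self.formulas)

    def __len__(self) -> int:
        return len(self.formulas)

    def __iter__(self):
        return iter(self.formulas)


@dataclass
class DerivedTraitMatrix:
    """Samples x derived-trait values with provenance."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    trait_ids: tuple[str, ...]
    provenance: TraitDefinitionTable | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.trait_ids))
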