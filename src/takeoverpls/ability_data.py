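"""Data model and I/O for the abilities matrix and the binary take-over outcome.

The analysis operates on a participants x predictors table of ability scores
("abilities matrix") paired with a binary success vector (1 = the take-over
manoeuvre was completed without collision, 0 = collision).  Each predictor
carries an *orientation* flag: raw scores for which a larger value means a
*lower* ability (reaction times, time differences, error counts) are
multiplied by -1 so that, after :func:`orient`, a larger value always means a
higher ability.  Standardization to zero mean / unit sample SD puts all
predictors on a common "1 SD" scale, which is the scale on which the model's
per-predictor coefficients are interpreted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataFormatError, ValidationError, ZeroVarianceError

#: Name of the outcome column in delimited-text inputs.
OUTCOME_COLUMN = "success"

#: Name of the optional participant-identifier column.
PARTICIPANT_COLUMN = "participant"


@dataclass(frozen=True)
class AbilityVariable:
    """One predictor of the abilities matrix.

    Parameters
    ----------
    name:
        Short unique identifier (column name in tabular files).
    task:
        Source test the score comes from (e.g. ``"corsi"``, ``"stop_signal"``).
    description:
        Free-text description of the measure.
    unit:
        Measurement unit of the raw score.
    orientation:
        ``+1`` if a larger raw value already means higher ability, ``-1`` if a
        larger raw value means lower ability (the column is negated by
        :func:`orient`).
    """

    name: str
    task: str = ""
    description: str = ""
    unit: str = ""
    orientation: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in (1, -1):
            raise ValidationError(
                f"orientation of variable {self.name!r} must be +1 or -1, "
                f"got {self.orientation!r}"
            )
        if not self.name:
            raise ValidationError("variable name must be non-empty")


def _check_unique_names(variables: Sequence[AbilityVariable]) -> None:
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate variable names in catalogue: {dupes}")


@dataclass(frozen=True)
class SuccessVector:
    """Binary take-over outcome, one entry per participant (1 = no collision)."""

    participant_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValidationError("success values must be one-dimensional")
        if len(self.participant_ids) != values.shape[0]:
            raise ValidationError(
                f"{len(self.participant_ids)} participant ids but "
                f"{values.shape[0]} outcome values"
            )
        if not np.all(np.isin(values, (0.0, 1.0))):
            bad = np.where(~np.isin(values, (0.0, 1.0)))[0][0]
            raise ValidationError(
                f"outcome for participant {self.participant_ids[bad]!r} is "
                f"{values[bad]!r}; must be 0 or 1"
            )
        object.__setattr__(self, "values", values.astype(np.int64))
        object.__setattr__(self, "participant_ids", tuple(self.participant_ids))

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def success_rate(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class AbilitiesMatrix:
    """Participants x predictors matrix of ability scores.

    ``values`` holds raw units before :func:`orient` and ability-oriented
    units after it; :func:`standardize` further rescales each column to zero
    mean and unit sample SD.
    """

    participant_ids: tuple[str, ...]
    variables: tuple[AbilityVariable, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("abilities values must be a 2-D matrix")
        n, p = values.shape
        if len(self.participant_ids) != n:
            raise ValidationError(
                f"{len(self.participant_ids)} participant ids but {n} rows"
            )
        if len(self.variables) != p:
            raise ValidationError(f"{len(self.variables)} variables but {p} columns")
        _check_unique_names(self.variables)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at participant {self.participant_ids[i]!r}, "
                f"column {self.variables[j].name!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "participant_ids", tuple(self.participant_ids))
        object.__setattr__(self, "variables", tuple(self.variables))

    # -- convenience -------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def column_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"no variable named {name!r}") from None

    def restrict(self, subset: Sequence[int | str]) -> "AbilitiesMatrix":
        """Return the matrix restricted to the given columns (by index or name)."""
        idx = [self.column_index(s) if isinstance(s, str) else int(s) for s in subset]
        if not idx:
            raise ValidationError("subset must be non-empty")
        if any(i < 0 or i >= self.n_variables for i in idx):
            raise ValidationError(f"subset indices out of range: {idx}")
        return AbilitiesMatrix(
            participant_ids=self.participant_ids,
            variables=tuple(self.variables[i] for i in idx),
            values=self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.participant_ids), columns=list(self.names)
        )


@dataclass(frozen=True)
class StandardizationParams:
    """Per-variable mean and sample SD (the "1 SD" units of the coefficient
    table), retained so held-out rows can be standardized with training-fold
    statistics."""

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != sd.shape or mean.ndim != 1 or mean.shape[0] != len(self.names):
            raise ValidationError("standardization params shape mismatch")
        if np.any(sd <= 0):
            j = int(np.argmax(sd <= 0))
            raise ZeroVarianceError(
                f"standard deviation of {self.names[j]!r} is not strictly positive",
                column=self.names[j],
            )
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "names", tuple(self.names))

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Standardize rows (given in oriented raw units) with these params."""
        values = np.asarray(values, dtype=float)
        return (values - self.mean) / self.sd


def orient(matrix: AbilitiesMatrix) -> AbilitiesMatrix:
    """Multiply each column by its orientation so larger = higher ability.

    Applying :func:`orient` twice returns the original values (involution).
    """
    signs = np.array([v.orientation for v in matrix.variables], dtype=float)
    return dataclasses.replace(matrix, values=matrix.values * signs)


def standardize(matrix: AbilitiesMatrix) -> tuple[AbilitiesMatrix, StandardizationParams]:
    """Center and scale each column to mean 0 and sample SD 1 (divisor n-1)."""
    if matrix.n_participants < 2:
        raise ValidationError("standardization requires at least two participants")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        j = int(np.argmax(sd <= 0))
        raise ZeroVarianceError(
            f"column {matrix.variables[j].name!r} has zero variance",
            column=matrix.variables[j].name,
        )
    params = StandardizationParams(names=matrix.names, mean=mean, sd=sd)
    return dataclasses.replace(matrix, values=params.apply(matrix.values)), params


# ---------------------------------------------------------------------------
# Variable catalogue
# ---------------------------------------------------------------------------

def default_catalogue() -> tuple[AbilityVariable, ...]:
    """The 15-variable reference catalogue of the take-over study design.

    Orientation is -1 for every measure where a larger raw value reflects a
    lower ability (times, reaction-time differences, superfluous moves).
    """
    V = AbilityVariable
    return (
        V("age", "biographical", "Age", "year", 1),
        V("km_per_year", "biographical", "Annual mileage", "1,000 km/year", 1),
        V("years_licensed", "biographical", "Years since licensure", "year", 1),
        V("vmc_time_close", "visuomanual_coordination",
          "Percent of time spent within 0.5 cm of the moving target", "percent", 1),
        V("moa_mean_time", "multiple_object_avoidance",
          "Mean time to collision over trials", "s", 1),
        V("mot_speed", "multiple_object_tracking",
          "Visual tracking speed threshold", "a.u.", 1),
        V("nback_accuracy_diff", "n_back",
          "Accuracy difference, 3-back minus 1-back", "percent", 1),
        V("nback_rt_diff", "n_back",
          "Mean RT difference, 3-back minus 1-back", "ms", -1),
        V("corsi_span", "corsi", "Highest level reached", "n.a.", 1),
        V("ssrt", "stop_signal", "Stop-signal reaction time", "ms", -1),
        V("flanker_accuracy", "flanker", "Percent successful trials", "percent", 1),
        V("flanker_rt_diff", "flanker",
          "Mean RT difference, incongruent minus congruent", "ms", -1),
        V("tmt_b_minus_a", "trail_making", "Time difference, TMT-B minus TMT-A", "s", -1),
        V("tol_n_solved", "tower_of_london", "Number of models solved", "n.a.", 1),
        V("tol_extra_moves", "tower_of_london",
          "Superfluous moves on solved models", "n.a.", -1),
    )


def load_catalogue(path: str | Path) -> tuple[AbilityVariable, ...]:
    """Read a variable catalogue from a YAML (or JSON) file.

    The file holds a list of mappings with keys ``name``, ``task``,
    ``description``, ``unit`` and ``orientation``; it may also be a mapping
    with a top-level ``catalogue`` key (the CLI config format).
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("catalogue")
    if not isinstance(data, list) or not data:
        raise DataFormatError(f"{path}: expected a non-empty list of variables")
    variables = []
    for i, entry in enumerate(data):
        if not isinstance(entry, dict) or "name" not in entry:
            raise DataFormatError(f"{path}: catalogue entry {i} lacks a 'name'", row=i)
        variables.append(AbilityVariable(
            name=str(entry["name"]),
            task=str(entry.get("task", "")),
            description=str(entry.get("description", "")),
            unit=str(entry.get("unit", "")),
            orientation=int(entry.get("orientation", 1)),
        ))
    _check_unique_names(variables)
    return tuple(variables)


def catalogue_to_dicts(variables: Iterable[AbilityVariable]) -> list[dict]:
    return [dataclasses.asdict(v) for v in variables]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    # comma default, tab accepted: let the python engine sniff the delimiter
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       skipinitialspace=True)


def load_abilities(
    path: str | Path,
    catalogue: Sequence[AbilityVariable],
    outcome_column: str = OUTCOME_COLUMN,
) -> tuple[AbilitiesMatrix, SuccessVector]:
    """Load a delimited-text abilities table paired with its outcome column.

    The file must have a header row containing every catalogue variable name
    plus ``outcome_column``; an optional ``participant`` column supplies
    identifiers.  Values are returned in raw units, column order follows the
    catalogue (so subset bitmasks are stable regardless of file column order).
    """
    catalogue = tuple(catalogue)
    _check_unique_names(catalogue)
    frame = _read_table(path)
    missing = [v.name for v in catalogue if v.name not in frame.columns]
    if outcome_column not in frame.columns:
        missing.append(outcome_column)
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s): {missing}", column=missing[0]
        )
    if PARTICIPANT_COLUMN in frame.columns:
        ids = tuple(str(x) for x in frame[PARTICIPANT_COLUMN])
    else:
        ids = tuple(f"P{i + 1:03d}" for i in range(len(frame)))

    names = [v.name for v in catalogue]
    numeric = frame[names + [outcome_column]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | frame[names + [outcome_column]].isna()
    if bad.to_numpy().any():
        i = int(np.argwhere(bad.to_numpy())[0][0])
        j = bad.columns[int(np.argwhere(bad.to_numpy())[0][1])]
        raise DataFormatError(
            f"{path}: non-numeric or missing value at data row {i + 1}, "
            f"column {j!r}", row=i + 1, column=str(j)
        )
    outcome = frame[outcome_column].to_numpy(dtype="U32").astype(np.float64)
    if not np.all(np.isin(outcome, (0.0, 1.0))):
        i = int(np.argmax(~np.isin(outcome, (0.0, 1.0))))
        raise ValidationError(
            f"{path}: outcome {outcome_column!r} must be 0 or 1 "
            f"(data row {i + 1} has {outcome[i]!r})"
        )
    # numpy's string parser is correctly rounded (full round-trip precision);
    # the pandas to_numeric pass above only locates unparseable cells
    values = frame[names].to_numpy(dtype="U64").astype(np.float64)
    matrix = AbilitiesMatrix(ids, catalogue, values)
    success = SuccessVector(ids, outcome)
    return matrix, success


def write_abilities(
    path: str | Path,
    matrix: AbilitiesMatrix,
    success: SuccessVector | None = None,
    delimiter: str = ",",
) -> None:
    """Write the matrix (and outcome, if given) as delimited text.

    Floats are printed with 17 significant digits so a load/write round trip
    preserves values exactly.
    """
    if success is not None and success.participant_ids != matrix.participant_ids:
        raise ValidationError("matrix and success vector participants differ")
    frame = matrix.to_frame()
    frame.insert(0, PARTICIPANT_COLUMN, list(matrix.participant_ids))
    if success is not None:
        frame[OUTCOME_COLUMN] = success.values
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
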