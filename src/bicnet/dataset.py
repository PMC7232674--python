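"""The sample-by-variable data container used by scoring and search."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, InvalidValueError
from .network import VariableSpec


@dataclass(frozen=True)
class Dataset:
    """N samples x p typed columns.

    ``frame`` holds the observations (column order is preserved as given —
    learning results never depend on it); ``variables`` declares each
    column's kind and, for discrete columns, the number of levels.  Discrete
    values are integer codes in ``[0, levels)``; missing values are rejected.
    """

    frame: pd.DataFrame
    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if sorted(self.frame.columns) != sorted(names):
            raise InvalidArgumentError("frame columns do not match variable specs")
        if len(set(names)) != len(names):
            raise InvalidArgumentError("duplicate variable names")
        if self.frame.isna().any().any():
            raise InvalidValueError("missing values are not supported")
        for spec in self.variables:
            col = self.frame[spec.name]
            if spec.is_discrete:
                values = col.to_numpy()
                if not np.issubdtype(values.dtype, np.integer):
                    if not np.all(np.asarray(values, dtype=float) % 1 == 0):
                        raise InvalidValueError(
                            f"discrete column {spec.name!r} has non-integer values"
                        )
                    values = values.astype(np.int64)
                if values.size and (values.min() < 0 or values.max() >= spec.levels):
                    raise InvalidValueError(
                        f"discrete column {spec.name!r} outside [0, {spec.levels})"
                    )
            else:
                if not np.issubdtype(col.to_numpy().dtype, np.number):
                    raise InvalidValueError(
                        f"continuous column {spec.name!r} is not numeric"
                    )

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def kind(self, name: str) -> str:
        return self.spec(name).kind

    def column(self, name: str) -> np.ndarray:
        if self.spec(name).is_discrete:
            return self.frame[name].to_numpy().astype(np.int64)
        return self.frame[name].to_numpy().astype(np.float64)

    @property
    def continuous_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if not v.is_discrete)

    @property
    def discrete_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.is_discrete)

    def select_columns(self, order: Sequence[str]) -> "Dataset":
        """Reorder/subset columns by name (used to undo a column shuffle)."""
        spec_by_name = {v.name: v for v in self.variables}
        return Dataset(
            self.frame.loc[:, list(order)].copy(),
            tuple(spec_by_name[n] for n in order),
        )
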