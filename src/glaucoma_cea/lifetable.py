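"""Age/sex life tables for background mortality.

The model draws its all-cause death risk from an age-specific and
sex-specific life table: rows of (age, sex, qx) where qx is the annual
probability of dying between age x and x+1.  The table must be contiguous in
age over its supported range and must close with qx = 1 at a terminal age for
both sexes — that closure is what guarantees a "lifetime" horizon terminates.

No national life table is bundled; :func:`make_gompertz_life_table` builds a
synthetic one with a Gompertz mortality curve, adequate for simulation
studies and fully declared as synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import SEX_FEMALE, SEX_MALE

COLUMNS = ["age", "sex", "qx"]


@dataclass(frozen=True)
class LifeTable:
    """Wrapper over a (age, sex, qx) table with validated closure.

    Attributes
    ----------
    table
        DataFrame with columns ``age`` (int years), ``sex`` ('male'/'female')
        and ``qx`` (annual death probability in [0, 1]).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"life table missing columns {missing}")
        if ((df["qx"] < 0) | (df["qx"] > 1)).any():
            raise ValueError("life table qx outside [0, 1]")
        for sex in (SEX_MALE, SEX_FEMALE):
            sub = df[df["sex"] == sex].sort_values("age")
            if sub.empty:
                raise ValueError(f"life table has no rows for sex {sex!r}")
            ages = sub["age"].to_numpy()
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise ValueError(f"life table ages not contiguous for sex {sex!r}")
            if sub["qx"].iloc[-1] != 1.0:
                raise ValueError(
                    f"life table must close with qx=1 at its terminal age (sex {sex!r})"
                )

    @property
    def min_age(self) -> int:
        return int(self.table["age"].min())

    @property
    def terminal_age(self) -> int:
        """First age at which qx = 1 for both sexes (guaranteed to exist)."""
        ages = []
        for sex in (SEX_MALE, SEX_FEMALE):
            sub = self.table[(self.table["sex"] == sex) & (self.table["qx"] == 1.0)]
            ages.append(int(sub["age"].min()))
        return max(ages)

    def qx(self, age: int, sex: str) -> float:
        """Annual death probability at ``age`` for ``sex`` (1.0 past the table)."""
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise KeyError(f"unknown sex {sex!r}")
        if age > int(sub["age"].max()):
            return 1.0
        row = sub[sub["age"] == age]
        if row.empty:
            raise KeyError(f"age {age} below life table range (min {self.min_age})")
        return float(row["qx"].iloc[0])

    def mixed_qx(self, age: int, female_fraction: float) -> float:
        """Sex-averaged annual death probability for a mixed cohort."""
        if not 0.0 <= female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        return female_fraction * self.qx(age, SEX_FEMALE) + (1.0 - female_fraction) * self.qx(
            age, SEX_MALE
        )

    def mixed_qx_path(self, start_age: int, n_years: int, female_fraction: float) -> np.ndarray:
        """Vector of sex-averaged qx for ages start_age .. start_age+n_years-1
        (1.0 past the terminal age)."""
        if not 0.0 <= female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        ages = np.arange(start_age, start_age + n_years)
        if n_years and ages[0] < self.min_age:
            raise KeyError(f"ages below life table range (min {self.min_age})")
        male = (
            self.table[self.table["sex"] == SEX_MALE]
            .set_index("age")["qx"]
            .reindex(ages)
            .fillna(1.0)
            .to_numpy()
        )
        female = (
            self.table[self.table["sex"] == SEX_FEMALE]
            .set_index("age")["qx"]
            .reindex(ages)
            .fillna(1.0)
            .to_numpy()
        )
        return (1.0 - female_fraction) * male + female_fraction * female

    def write(self, path) -> None:
        self.table[COLUMNS].to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path, dtype={"age": int, "sex": str, "qx": float}))


def make_gompertz_life_table(
    modal_coefficient: float = 1.159e-5,
    slope: float = 0.10397,
    female_factor: float = 0.75,
    min_age: int = 40,
    terminal_age: int = 110,
) -> LifeTable:
    """Synthetic Gompertz life table: qx = min(1, a * exp(b * age)).

    Defaults give qx(65) near 1% and qx(85) near 8% for males, with female
    mortality scaled by ``female_factor``; qx is forced to 1 at
    ``terminal_age``.  A synthetic stand-in for a national life table,
    intended for simulation studies.
    """
    ages = np.arange(min_age, terminal_age + 1)
    q_male = np.minimum(1.0, modal_coefficient * np.exp(slope * ages))
    q_female = np.minimum(1.0, female_factor * q_male)
    q_male[-1] = 1.0
    q_female[-1] = 1.0
    rows = []
    for sex, q in ((SEX_MALE, q_male), (SEX_FEMALE, q_female)):
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": q}))
    return LifeTable(pd.concat(rows, ignore_index=True))
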