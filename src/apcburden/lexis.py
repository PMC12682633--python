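"""Lexis grids: age x period arrays of event counts and person-years.

A Lexis grid holds Poisson event counts ``y[a, t]`` and exposures
``n[a, t]`` over ``A`` age groups (index 0 = youngest) and ``T`` periods,
with age groups ``M`` periods wide (M = 5 for five-year groups over annual
periods).  Diagonals of the grid are birth cohorts: the cell (a, t) belongs
to cohort ``c = M * (A - 1 - a) + t`` (0-based), so the oldest age group at
the first period is cohort 0 and the youngest at the last period carries the
largest index.  Cohorts sharing an index share one effect value when M > 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["build_cohort_index", "n_cohorts", "LexisGrid"]


def build_cohort_index(A: int, T: int, M: int = 1) -> np.ndarray:
    """Cohort index map c[a, t] = M*(A-1-a) + t as an (A, T) integer array.

    Indices are 0-based: the oldest age group at the first period maps to
    cohort 0, the youngest at the last period to ``M*(A-1) + T - 1``.
    """
    if A < 1 or T < 1 or M < 1:
        raise ValueError("A, T and M must all be >= 1")
    a = np.arange(A)[:, None]
    t = np.arange(T)[None, :]
    return M * (A - 1 - a) + t


def n_cohorts(A: int, T: int, M: int = 1) -> int:
    """Number of distinct cohort indices on an A x T grid with age width M."""
    return M * (A - 1) + T


@dataclasses.dataclass
class LexisGrid:
    """Event counts and person-years on an age x period grid.

    Parameters
    ----------
    counts
        (A, T) array of nonnegative event counts.
    person_years
        (A, T) array of strictly positive exposures.
    age_groups
        A age-group labels, youngest first (e.g. ``"0 to 4" ... "85 plus"``).
    years
        T calendar years, consecutive and increasing.
    age_width
        Width of an age group in period units (M); 5 for five-year groups.
    """

    counts: np.ndarray
    person_years: np.ndarray
    age_groups: list[str]
    years: np.ndarray
    age_width: int = 5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.counts.shape != self.person_years.shape:
            raise ValueError("counts and person_years must have the same shape")
        A, T = self.counts.shape
        if len(self.age_groups) != A:
            raise ValueError("age_groups length must match counts rows")
        if self.years.shape != (T,):
            raise ValueError("years length must match counts columns")
        if T > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive calendar years")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and nonnegative")
        if np.any(~np.isfinite(self.person_years)) or np.any(self.person_years <= 0):
            raise ValueError("person_years must be finite and strictly positive")

    @property
    def A(self) -> int:
        return self.counts.shape[0]

    @property
    def T(self) -> int:
        return self.counts.shape[1]

    @property
    def cohort_index(self) -> np.ndarray:
        return build_cohort_index(self.A, self.T, self.age_width)

    @property
    def n_cohorts(self) -> int:
        return n_cohorts(self.A, self.T, self.age_width)

    def rates(self) -> np.ndarray:
        """Observed age-specific rates per person-year, y / n."""
        return self.counts / self.person_years

    def slice_years(self, first: int, last: int) -> "LexisGrid":
        """Sub-grid covering calendar years ``first..last`` inclusive."""
        mask = (self.years >= first) & (self.years <= last)
        if not mask.any():
            raise ValueError(f"no years in [{first}, {last}]")
        return LexisGrid(
            counts=self.counts[:, mask],
            person_years=self.person_years[:, mask],
            age_groups=list(self.age_groups),
            years=self.years[mask],
            age_width=self.age_width,
        )
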