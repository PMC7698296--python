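"""Six-month analysis periods.

Each calendar year splits into two semesters; the first (January-June)
is the breeding season.  Semester labels look like ``"2014-S1"``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

__all__ = ["Semester", "semester_of", "semester_range"]


@dataclass(frozen=True, order=True)
class Semester:
    year: int
    half: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.half not in (1, 2):
            raise ValueError("half must be 1 or 2")

    @property
    def breeding(self) -> int:
        return 1 if self.half == 1 else 0

    @property
    def label(self) -> str:
        return f"{self.year}-S{self.half}"

    @property
    def start(self) -> dt.date:
        return dt.date(self.year, 1 if self.half == 1 else 7, 1)

    @property
    def end(self) -> dt.date:
        """Last day of the semester (inclusive)."""
        if self.half == 1:
            return dt.date(self.year, 6, 30)
        return dt.date(self.year, 12, 31)

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def months(self) -> list[tuple[int, int]]:
        first = 1 if self.half == 1 else 7
        return [(self.year, m) for m in range(first, first + 6)]

    @classmethod
    def from_label(cls, label: str) -> "Semester":
        year, half = label.split("-S")
        return cls(int(year), int(half))


def semester_of(date: dt.date) -> Semester:
    return Semester(date.year, 1 if date.month <= 6 else 2)


def semester_range(first: Semester, n: int) -> list[Semester]:
    """``n`` consecutive semesters starting at ``first``."""
    out = []
    year, half = first.year, first.half
    for _ in range(n):
        out.append(Semester(year, half))
        if half == 1:
            half = 2
        else:
            year, half = year + 1, 1
    return out
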