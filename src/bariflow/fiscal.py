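"""Australian financial years (July–June), the time axis of every schedule.

A fiscal year is keyed by its starting calendar year: ``FiscalYear(2019)``
denotes 2019–20. All tables and CSV output render the "YYYY–YY" label;
internal indexing uses the integer start year.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

EN_DASH = "–"

_LABEL_RE = re.compile(r"^(\d{4})\s*[-–—/]\s*(\d{2}|\d{4})$")


@dataclass(frozen=True, order=True)
class FiscalYear:
    """One Australian financial year, e.g. ``FiscalYear(2019)`` → "2019–20"."""

    start: int

    def __post_init__(self) -> None:
        if not isinstance(self.start, int):
            raise TypeError(f"FiscalYear start must be an integer, got {self.start!r}")
        if not 1900 <= self.start <= 2200:
            raise ValueError(f"implausible fiscal year start {self.start}")

    @property
    def label(self) -> str:
        return f"{self.start}{EN_DASH}{(self.start + 1) % 100:02d}"

    @property
    def end(self) -> int:
        """Calendar year in which the fiscal year ends."""
        return self.start + 1

    def __add__(self, n: int) -> "FiscalYear":
        return FiscalYear(self.start + int(n))

    def __sub__(self, other: "FiscalYear | int"):
        if isinstance(other, FiscalYear):
            return self.start - other.start
        return FiscalYear(self.start - int(other))

    def __str__(self) -> str:
        return self.label

    @classmethod
    def parse(cls, value: "FiscalYear | int | str") -> "FiscalYear":
        """Accept 2019, "2019", "2019-20", "2019–20" or "2019/2020"."""
        if isinstance(value, FiscalYear):
            return value
        if isinstance(value, int):
            return cls(value)
        text = str(value).strip()
        m = _LABEL_RE.match(text)
        if m:
            start = int(m.group(1))
            tail = m.group(2)
            end = int(tail) if len(tail) == 4 else (start // 100) * 100 + int(tail)
            if end % 100 != (start + 1) % 100:
                raise ValueError(f"fiscal year label {value!r} does not span consecutive years")
            return cls(start)
        if text.isdigit():
            return cls(int(text))
        raise ValueError(f"cannot parse fiscal year from {value!r}")


def fiscal_range(start: FiscalYear | int, end: FiscalYear | int) -> list[FiscalYear]:
    """Inclusive, contiguous run of fiscal years from ``start`` to ``end``."""
    s, e = FiscalYear.parse(start), FiscalYear.parse(end)
    if e < s:
        raise ValueError(f"fiscal range end {e} precedes start {s}")
    return [FiscalYear(y) for y in range(s.start, e.start + 1)]


def year_labels(years: Iterator[int]) -> list[str]:
    return [FiscalYear(int(y)).label for y in years]
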