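"""Hourly daylight time grid and training/testing window definitions.

Top-view captures run once per hour during the photoperiod (12 captures per
day, 08:00-19:00), from 10 to 23 days after sowing (DAS).  A step index is
1-based over the whole cycle; decimal DAS appends the capture hour divided by
24 (23 DAS at 17:00 -> 23.71).

The six canonical training/testing windows (named T1..T6) are stored verbatim
as step anchors: published anchor tables of this kind are not always exactly
reconstructible from a uniform grid formula, so anchors are constants and the
grid formula is used only to timestamp synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TimeGrid:
    """Uniform daylight sampling grid.

    Parameters
    ----------
    first_das : first day after sowing covered by the grid.
    steps_per_day : hourly captures per photoperiod.
    first_hour : clock hour of the first daily capture.
    total_steps : number of steps in the whole cycle.
    """

    first_das: int = 10
    steps_per_day: int = 12
    first_hour: int = 8
    total_steps: int = 165

    def _check(self, step: int) -> None:
        if not 1 <= step <= self.total_steps:
            raise ValueError(
                f"step {step} outside grid range [1, {self.total_steps}]"
            )

    def das_of(self, step: int) -> float:
        """Decimal DAS of a 1-based step (day + capture-hour/24)."""
        self._check(step)
        day, idx = divmod(step - 1, self.steps_per_day)
        return self.first_das + day + (self.first_hour + idx) / 24.0

    def display_das(self, step: int) -> float:
        """Decimal DAS rounded to two decimals, the conventional display form."""
        return round(self.das_of(step), 2)

    def hour_of(self, step: int) -> int:
        self._check(step)
        return self.first_hour + (step - 1) % self.steps_per_day

    def step_of(self, das: float) -> int:
        """Left inverse of :meth:`das_of` on grid points (display rounding ok)."""
        day = int(das + 1e-9)
        idx = round((das - day) * 24.0) - self.first_hour
        step = (day - self.first_das) * self.steps_per_day + idx + 1
        self._check(step)
        if abs(self.das_of(step) - das) > 0.51 / 24.0:
            raise ValueError(f"das {das} does not lie on the grid")
        return step


def decimal_das(das: int, hour: int) -> float:
    """Decimal-DAS display convention: day + hour/24, two decimals."""
    return round(das + hour / 24.0, 2)


@dataclass(frozen=True)
class WindowSpec:
    """One training/testing split, all bounds 1-based inclusive steps."""

    name: str
    train_start: int
    train_end: int
    test_start: int
    test_end: int

    def __post_init__(self) -> None:
        if not (self.train_start <= self.train_end < self.test_start <= self.test_end):
            raise ValueError(f"invalid window ordering in {self!r}")

    @property
    def train_steps(self) -> range:
        return range(self.train_start, self.train_end + 1)

    @property
    def test_steps(self) -> range:
        return range(self.test_start, self.test_end + 1)

    @property
    def n_train(self) -> int:
        return self.train_end - self.train_start + 1

    @property
    def n_test(self) -> int:
        return self.test_end - self.test_start + 1


#: The six canonical training/testing windows.  T1-T4 train to 21 DAS and test 21-23 DAS;
#: T5-T6 train only to 20 DAS and must forecast further ahead.
CANONICAL_WINDOWS: dict[str, WindowSpec] = {
    "T1": WindowSpec("T1", 60, 140, 141, 165),
    "T2": WindowSpec("T2", 72, 140, 141, 165),
    "T3": WindowSpec("T3", 84, 140, 141, 165),
    "T4": WindowSpec("T4", 96, 140, 141, 165),
    "T5": WindowSpec("T5", 72, 127, 128, 165),
    "T6": WindowSpec("T6", 84, 127, 128, 165),
}

#: Forecast horizons in measured (daylight) hours; 12 measured hours = 1 day.
DEFAULT_HORIZONS: tuple[int, ...] = (1, 6, 12, 24, 36, 42, 48)
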