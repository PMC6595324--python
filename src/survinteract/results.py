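"""Common result record returned by every interaction test."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["TestResult"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one biomarker-treatment interaction test.

    ``extras`` carries method-specific detail: chosen cutpoint (optimal
    split), selected fractional-polynomial powers (MFPI), per-window
    estimates (STEPP), the local effect curve (LPLB), and a ``failed`` flag
    when a model fit did not converge (in which case ``p_value`` is 1,
    a deliberately conservative convention).
    """

    method: str
    statistic: float
    p_value: float
    df: int | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def failed(self) -> bool:
        return bool(self.extras.get("failed", False))

    def to_record(self) -> dict[str, Any]:
        rec = {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }
        rec.update(
            {
                k: v
                for k, v in self.extras.items()
                if isinstance(v, (int, float, str, bool))
            }
        )
        return rec
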