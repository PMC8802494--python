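"""Result containers shared by every test in the battery."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample survival test.

    ``statistic`` is the test's own scale (chi-square, z, maximum, area...);
    ``p_value`` is two-sided. ``metadata`` carries resampling iterations,
    seed, tau, the deciding stage of the two-stage procedure, and similar
    method-specific context.
    """

    method: str
    statistic: float
    p_value: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        p = self.p_value
        if not (p != p or 0.0 <= p <= 1.0):  # NaN allowed for failed tests
            raise ValueError(f"p-value {p} outside [0, 1]")
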