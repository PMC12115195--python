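"""Complexity accounting: structural parameter counts and MAC-based FLOPs.

The FLOP convention throughout the package counts one multiply-accumulate
as one FLOP (the convention under which a convolution's FLOPs equal its
weight count times the output grid size), and ``GFLOPs`` is that count
divided by 1e9.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ComplexityReport:
    """Parameter and FLOP tallies with a per-component breakdown.

    Invariant: the totals equal the sums over the breakdown entries
    (checked at construction when a breakdown is given).
    """

    parameter_count: int
    flop_count: int
    breakdown: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.parameter_count < 0 or self.flop_count < 0:
            raise ValueError("counts must be non-negative")
        if self.breakdown:
            ps = sum(p for _, p, _ in self.breakdown)
            fs = sum(f for _, _, f in self.breakdown)
            if ps != self.parameter_count or fs != self.flop_count:
                raise ValueError(
                    f"breakdown does not sum to totals: {ps} vs {self.parameter_count}, "
                    f"{fs} vs {self.flop_count}"
                )

    @property
    def params_millions(self) -> float:
        return self.parameter_count / 1e6

    @property
    def gflops(self) -> float:
        return self.flop_count / 1e9

    def summary(self) -> str:
        lines = [f"{'component':<24}{'params':>12}{'MACs':>16}"]
        for name, p, f in self.breakdown:
            lines.append(f"{name:<24}{p:>12,}{f:>16,}")
        lines.append(f"{'total':<24}{self.parameter_count:>12,}{self.flop_count:>16,}")
        lines.append(f"= {self.params_millions:.2f} M params, {self.gflops:.2f} GFLOPs")
        return "\n".join(lines)
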