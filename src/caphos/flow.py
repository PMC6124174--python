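"""Participant-flow accounting in the style of a STARD flow diagram.

Every filtering stage of either pipeline records (name, n_in, n_excluded,
reason, n_out); the report validates conservation — nothing enters a stage
without leaving it as either retained or excluded, and consecutive stages
chain exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FlowStage:
    name: str
    n_in: int
    n_excluded: int
    reason: str
    n_out: int

    def __post_init__(self) -> None:
        if self.n_in < 0 or self.n_excluded < 0:
            raise ValueError("stage counts must be non-negative")
        if self.n_out != self.n_in - self.n_excluded:
            raise ValueError(
                f"stage {self.name!r}: n_out {self.n_out} != n_in {self.n_in} - "
                f"n_excluded {self.n_excluded}"
            )


@dataclass
class FlowReport:
    stages: list[FlowStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_excluded: int, reason: str) -> None:
        stage = FlowStage(name, n_in, n_excluded, reason, n_in - n_excluded)
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {name!r} starts with {stage.n_in} records but the previous "
                f"stage ended with {self.stages[-1].n_out}"
            )
        self.stages.append(stage)

    @property
    def n_in(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_out(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    @property
    def n_excluded(self) -> int:
        return sum(s.n_excluded for s in self.stages)

    def counts(self) -> list[int]:
        """Record counts along the cascade: [n_in, after stage 1, ...]."""
        return [self.n_in] + [s.n_out for s in self.stages]

    def to_text(self) -> str:
        lines = [f"records in: {self.n_in}"]
        for s in self.stages:
            lines.append(f"  {s.name}: excluded {s.n_excluded} ({s.reason}) -> {s.n_out} remain")
        lines.append(f"records analysed: {self.n_out}")
        return "\n".join(lines)
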