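"""Eligibility cascade and auditable exclusion ledger.

The analytic sample is built by sequentially dropping: age under 20; age
80+ (ages are top-coded at 80, so exact age is unknown there); pregnancy;
no actigraphy; fewer than 4 valid actigraphy days; and participants missing
all six liver biomarkers.  The ledger records, stage by stage, how many
were excluded and how many remain, STROBE-flow style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ExclusionLedger", "apply_exclusions", "ledger_report", "EXCLUSION_STAGES"]

#: stage label -> predicate marking rows to EXCLUDE
EXCLUSION_STAGES = [
    ("age < 20", lambda df: df["age"] < 20),
    ("age 80+ (top-coded)", lambda df: df["age"] >= 80),
    ("pregnant", lambda df: df["pregnant"].astype(bool)),
    ("no actigraphy data", lambda df: ~df["has_actigraphy"].astype(bool)),
    ("< 4 valid actigraphy days", lambda df: df["n_valid_days"] < 4),
    ("no liver biomarker measures", lambda df: ~df["has_biomarkers"].astype(bool)),
]

REQUIRED_COLUMNS = ["age", "pregnant", "has_actigraphy", "n_valid_days",
                    "has_biomarkers"]


@dataclass
class ExclusionLedger:
    """Ordered exclusion stages: (label, n excluded, n remaining)."""

    initial: int
    stages: list = field(default_factory=list)  # (label, excluded, remaining)

    def add(self, label: str, excluded: int) -> None:
        remaining = self.remaining - int(excluded)
        self.stages.append((label, int(excluded), remaining))
        self.validate()

    @property
    def remaining(self) -> int:
        return self.stages[-1][2] if self.stages else self.initial

    def validate(self) -> None:
        prev = self.initial
        for label, excluded, remaining in self.stages:
            if excluded < 0 or remaining < 0:
                raise ValueError(f"negative count at stage {label!r}")
            if remaining != prev - excluded:
                raise ValueError(
                    f"inconsistent ledger at stage {label!r}: "
                    f"{prev} - {excluded} != {remaining}")
            prev = remaining

    @classmethod
    def from_counts(cls, initial: int, stage_counts) -> "ExclusionLedger":
        """Build from an iterable of (label, n excluded) pairs."""
        ledger = cls(initial=int(initial))
        for label, excluded in stage_counts:
            ledger.add(label, excluded)
        return ledger

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages,
                            columns=["stage", "excluded", "remaining"])


def apply_exclusions(table: pd.DataFrame):
    """Apply the eligibility cascade; return (analytic table, ledger).

    The table must carry age, pregnancy, actigraphy availability, valid-day
    count and biomarker availability; a missing column is reported by name.
    Attribution of an exclusion to a stage depends on the stage order, but
    the final analytic set is simply the intersection of all inclusion
    predicates.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    ledger = ExclusionLedger(initial=len(table))
    current = table
    for label, predicate in EXCLUSION_STAGES:
        drop = predicate(current)
        ledger.add(label, int(drop.sum()))
        current = current.loc[~drop]
    return current.reset_index(drop=True), ledger


def ledger_report(ledger: ExclusionLedger) -> str:
    """Human-readable STROBE-style flow summary of the exclusion cascade."""
    ledger.validate()
    lines = [f"{'stage':<32} {'excluded':>9} {'remaining':>10}",
             "-" * 53,
             f"{'initial sample':<32} {'':>9} {ledger.initial:>10}"]
    for label, excluded, remaining in ledger.stages:
        lines.append(f"{label:<32} {excluded:>9} {remaining:>10}")
    lines.append("-" * 53)
    lines.append(f"final analytic sample: {ledger.remaining}")
    return "\n".join(lines)
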