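"""Literature-derived effect sizes for the three disease-progression transitions.

The natural-history model is parameterised entirely from published effect
sizes: rate ratios for betel-quid chewing and smoking on the two
pre-malignant transitions, and odds ratios for HPV, miRNA aberrations and
risk genotypes. This module loads those constants from the packaged
delimited-text table, converts effect sizes to log-hazard coefficients, and
audits the printed equation coefficients against the printed effect sizes
(the source article contains a handful of internal discrepancies, which are
reported rather than silently corrected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import CoefficientSet

#: The three transitions of the progressive four-state model.
TRANSITIONS = ("N->L", "L->E", "E->C")


@dataclass(frozen=True)
class EvidenceEntry:
    """One published effect: a factor level acting on one transition."""

    factor_id: str
    level_label: str
    transition: str
    measure: str  # "rate_ratio" or "odds_ratio"
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    #: 2x2 counts (case-exposed, case-unexposed, control-exposed, control-unexposed)
    counts: tuple[int, int, int, int] | None = None
    control_prevalence: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.transition not in TRANSITIONS:
            raise ValueError(f"unknown transition {self.transition!r}")
        if self.measure not in ("rate_ratio", "odds_ratio"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if not self.estimate > 0:
            raise ValueError("effect estimate must be positive")
        if self.counts is not None and any(c < 0 for c in self.counts):
            raise ValueError("2x2 counts must be nonnegative")
        if self.control_prevalence is not None and not 0 <= self.control_prevalence <= 1:
            raise ValueError("control prevalence must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.factor_id, self.level_label, self.transition)

    def ci_anomaly(self) -> str | None:
        """Report an estimate falling outside its own printed CI, if any."""
        if self.ci_low is None or self.ci_high is None:
            return None
        if not (self.ci_low <= self.estimate <= self.ci_high):
            return (
                f"{self.factor_id} ({self.level_label}, {self.transition}): "
                f"estimate {self.estimate} outside CI {self.ci_low}-{self.ci_high}"
            )
        return None


class EvidenceTable:
    """All published effects, keyed by (factor_id, level_label, transition)."""

    def __init__(self, entries: list[EvidenceEntry]):
        self._entries: dict[tuple[str, str, str], EvidenceEntry] = {}
        for entry in entries:
            if entry.key in self._entries:
                raise ValueError(f"duplicate evidence key {entry.key}")
            self._entries[entry.key] = entry
        # The source tables contain one CI printed inconsistently with its
        # estimate; such rows are kept verbatim and listed here.
        self.anomalies: list[str] = [
            a for e in self._entries.values() if (a := e.ci_anomaly()) is not None
        ]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def query(self, factor_id: str, level_label: str, transition: str) -> EvidenceEntry:
        return self._entries[(factor_id, level_label, transition)]

    def get(self, key: tuple[str, str, str]) -> EvidenceEntry | None:
        return self._entries.get(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self._entries.values()])


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("oralsim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_evidence() -> EvidenceTable:
    """Load the packaged literature evidence table."""
    raw = _read_packaged_tsv("evidence.tsv")
    entries = []
    for row in raw.itertuples(index=False):
        count_cells = (
            row.case_exposed,
            row.case_unexposed,
            row.control_exposed,
            row.control_unexposed,
        )
        counts = None
        if all(pd.notna(c) for c in count_cells):
            counts = tuple(int(c) for c in count_cells)
        entries.append(
            EvidenceEntry(
                factor_id=row.factor_id,
                level_label=row.level_label,
                transition=row.transition,
                measure=row.measure,
                estimate=float(row.estimate),
                ci_low=float(row.ci_low) if pd.notna(row.ci_low) else None,
                ci_high=float(row.ci_high) if pd.notna(row.ci_high) else None,
                counts=counts,
                control_prevalence=(
                    float(row.control_prevalence)
                    if pd.notna(row.control_prevalence)
                    else None
                ),
                source=row.source,
            )
        )
    return EvidenceTable(entries)


def log_effect(estimate: float) -> float:
    """Natural log of a positive effect size (its log-hazard coefficient)."""
    if not estimate > 0:
        raise ValueError(f"effect estimate must be positive, got {estimate}")
    return math.log(estimate)


def crude_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Crude odds ratio (a*d)/(b*c) from a 2x2 table.

    Arguments follow the (case-exposed, case-unexposed, control-exposed,
    control-unexposed) convention. A zero cell in the denominator makes the
    crude OR incomputable and raises rather than returning infinity.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ValueError(f"count {name} must be nonnegative, got {v}")
    if b == 0 or c == 0:
        raise ZeroDivisionError("crude odds ratio incomputable: zero denominator cell")
    return (a * d) / (b * c)


@dataclass(frozen=True)
class CoefficientMismatch:
    """An equation coefficient that disagrees with ln(published effect size)."""

    factor_id: str
    level_label: str
    transition: str
    printed_coefficient: float
    log_effect_size: float

    @property
    def difference(self) -> float:
        return self.printed_coefficient - self.log_effect_size


def consistency_report(
    evidence: EvidenceTable,
    printed: "CoefficientSet",
    tol: float = 5e-3,
) -> list[CoefficientMismatch]:
    """Compare printed equation coefficients with ln(published effect sizes).

    Each term of the three transition equations is matched with its evidence
    entry; terms whose printed coefficient differs from ln(estimate) by more
    than ``tol`` (absolute) are returned. The source article contains a few
    such internal discrepancies, so a non-empty report is expected.
    """
    mismatches = []
    for (transition, factor_id, level_label), coef in printed.items():
        entry = evidence.get((factor_id, level_label, transition))
        if entry is None:
            raise KeyError(
                f"equation term ({factor_id}, {level_label}, {transition}) "
                "has no evidence entry"
            )
        derived = log_effect(entry.estimate)
        if abs(coef - derived) > tol:
            mismatches.append(
                CoefficientMismatch(
                    factor_id=factor_id,
                    level_label=level_label,
                    transition=transition,
                    printed_coefficient=coef,
                    log_effect_size=derived,
                )
            )
    return mismatches
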