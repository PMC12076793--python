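"""Empiric-regimen coverage from an antibiogram-style susceptibility table.

Coverage is the isolate-count-weighted probability that the local causative
organism is susceptible to the empiric regimen: under the default
``any_agent`` rule a combination covers an isolate if at least one component
is active; under ``all_agents`` every component must be active.  Rows with
an indeterminate status (unknown result that could flip the verdict) are
excluded from numerator and denominator, with the excluded count logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

RULES = ("any_agent", "all_agents")
STATUSES = ("S", "R", "U")


class AntibiogramError(ValueError):
    """Empty table, missing antibiotic column, or malformed input."""


@dataclass
class SusceptibilityTable:
    """Rows of (organism, isolate count, per-antibiotic S/R/U status)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if "organism" not in f.columns or "isolates" not in f.columns:
            raise AntibiogramError("table needs 'organism' and 'isolates' columns")
        if len(f) == 0:
            raise AntibiogramError("table is empty")
        if len(self.antibiotics) == 0:
            raise AntibiogramError("table has no antibiotic columns")
        if f["organism"].duplicated().any():
            dups = sorted(f.loc[f["organism"].duplicated(), "organism"])
            raise AntibiogramError(f"duplicate organism labels: {dups}")
        counts = f["isolates"]
        if not ((counts > 0) & (counts == counts.astype(int))).all():
            raise AntibiogramError("isolate counts must be positive integers")
        bad = set(f[self.antibiotics].to_numpy().ravel()) - set(STATUSES)
        if bad:
            raise AntibiogramError(f"unexpected susceptibility statuses: {sorted(bad)}")

    @property
    def antibiotics(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("organism", "isolates")]

    @property
    def total_isolates(self) -> int:
        return int(self.frame["isolates"].sum())


def read_antibiogram(path: str | Path, intermediate_as: str = "R") -> SusceptibilityTable:
    """Read a CSV antibiogram (UTF-8, comma, header row of antibiotic names).

    Intermediate ("I") results are mapped to ``intermediate_as`` (default
    "R", the conservative choice); blank cells become unknown ("U").
    """
    if intermediate_as not in ("S", "R"):
        raise AntibiogramError(f"intermediate_as must be 'S' or 'R', got {intermediate_as!r}")
    frame = pd.read_csv(path, dtype={"organism": str})
    agents = [c for c in frame.columns if c not in ("organism", "isolates")]
    frame[agents] = (
        frame[agents].fillna("U").astype(str).apply(lambda s: s.str.strip().str.upper())
    )
    frame[agents] = frame[agents].replace({"I": intermediate_as, "": "U", "NAN": "U"})
    return SusceptibilityTable(frame)


def coverage(table: SusceptibilityTable, antibiotics: list[str], rule: str = "any_agent") -> float:
    """Isolate-weighted probability that the regimen covers the organism."""
    if rule not in RULES:
        raise AntibiogramError(f"rule must be one of {RULES}, got {rule!r}")
    if not antibiotics:
        raise AntibiogramError("regimen has no antibiotics")
    missing = sorted(set(antibiotics) - set(table.antibiotics))
    if missing:
        raise AntibiogramError(f"antibiotic column(s) not in table: {missing}")

    covered_weight = 0.0
    determinate_weight = 0.0
    excluded = 0
    for _, row in table.frame.iterrows():
        statuses = [row[a] for a in antibiotics]
        n = int(row["isolates"])
        if rule == "any_agent":
            if "S" in statuses:
                verdict = True
            elif "U" in statuses:
                verdict = None  # no S seen, an unknown could still cover
            else:
                verdict = False
        else:  # all_agents
            if "R" in statuses:
                verdict = False
            elif "U" in statuses:
                verdict = None
            else:
                verdict = True
        if verdict is None:
            excluded += n
            continue
        determinate_weight += n
        if verdict:
            covered_weight += n
    if excluded:
        logger.info("coverage: excluded %d isolate(s) with indeterminate status", excluded)
    if determinate_weight == 0:
        raise AntibiogramError("no isolates with a determinate coverage verdict")
    return covered_weight / determinate_weight
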