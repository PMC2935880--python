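"""Replication sample-size calculations for reported associations.

Given a reported association (risk allele, odds ratio taken as the GRR of
a multiplicative model), this module computes the smallest total sample
size (cases + controls at a 1:1 ratio) that replicates the effect at a
target power under a nominal significance threshold, separately for every
population panel of a frequency table.  Because the allele-count NCP is
linear in sample size at fixed frequencies, the analytic power function
is monotone in N and the minimal even N is found by bisection with local
integer refinement.

Panels where the risk allele is fixed (frequency 0 or 1) can never
replicate and are reported NA; panels where even a capped sample size
(default 150,000) is insufficient are reported as capped, carrying the
power attained at the cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlleleMismatchError, MissingPanelError, ParseError
from .freq_data import FrequencyTable
from .power import NOMINAL, CohortArm, EffectModel, SignificanceRule, ncp_single, power_from_ncp

__all__ = [
    "AssociationRecord",
    "SampleSizeResult",
    "ReplicationReport",
    "required_sample_size",
    "replication_report",
    "read_associations",
    "write_associations",
]


@dataclass(frozen=True)
class AssociationRecord:
    """A reported GWAS hit used as a replication hypothesis."""

    snp_id: str
    risk_allele: str
    odds_ratio: float
    trait: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ValueError(f"{self.snp_id}: odds ratio must be positive")


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a required-sample-size calculation for one (SNP, panel).

    ``status`` is ``"ok"`` (``n`` is the minimal even total), ``"capped"``
    (target unreachable below the cap; ``power_at_cap`` reports the power
    at the cap) or ``"monomorphic"`` (the risk allele is fixed, so no
    sample size suffices).
    """

    status: str
    n: int | None = None
    power_at_cap: float | None = None

    def cell(self) -> str:
        """Compact cell text for tabular output."""
        if self.status == "ok":
            return str(self.n)
        if self.status == "capped":
            return f"cap:{self.power_at_cap:.4f}"
        return "NA"


def _power_at_total(n_total: int, p: float, model: EffectModel,
                    rule: SignificanceRule) -> float:
    half = n_total // 2
    arm = CohortArm(n_cases=half, n_controls=n_total - half, p=p)
    return power_from_ncp(ncp_single(arm, model), rule)


def required_sample_size(
    p: float,
    model: EffectModel,
    rule: SignificanceRule = NOMINAL,
    target: float = 0.80,
    n_cap: int = 150_000,
) -> SampleSizeResult:
    """Smallest even total N (cases = controls = N/2) with power >= target.

    ``p`` is the risk-allele frequency in the panel where replication is
    attempted.  Monomorphic frequencies return NA; if even ``n_cap``
    samples cannot reach the target the result is capped and carries the
    power at the cap.  The returned N brackets the target:
    ``power(N) >= target > power(N - 2)``.
    """
    if not 0 < target < 1:
        raise ValueError(f"target power must lie in (0, 1), got {target}")
    if not 0 <= p <= 1:
        raise ValueError(f"allele frequency must lie in [0, 1], got {p}")
    if p in (0.0, 1.0):
        return SampleSizeResult(status="monomorphic")
    cap_even = n_cap - (n_cap % 2)
    if _power_at_total(cap_even, p, model, rule) < target:
        return SampleSizeResult(
            status="capped", power_at_cap=_power_at_total(cap_even, p, model, rule)
        )
    lo, hi = 0, cap_even  # invariant: power(lo) < target <= power(hi)
    while hi - lo > 2:
        mid = (lo + hi) // 2
        mid -= mid % 2
        if mid <= lo:
            mid = lo + 2
        if _power_at_total(mid, p, model, rule) >= target:
            hi = mid
        else:
            lo = mid
    return SampleSizeResult(status="ok", n=hi)


@dataclass
class ReplicationReport:
    """Per-panel required sample sizes for a list of associations.

    ``table``: DataFrame with one row per association and one
    :class:`SampleSizeResult` column per panel.  ``summary`` counts, over
    the associations where the reference panel yields a finite N, how many
    could be replicated with fewer samples in some other panel
    (``efficiency_gain``), how many need more everywhere else
    (``efficiency_loss``), and how many need at least ``large_n_threshold``
    samples in the reference panel itself (``large_in_reference``).
    """

    reference_panel: str
    table: pd.DataFrame
    summary: dict[str, int | float]

    def cells(self) -> pd.DataFrame:
        """The table with results rendered as compact strings."""
        out = self.table.copy()
        for col in out.columns:
            if col not in ("snp_id", "trait", "odds_ratio", "risk_allele"):
                out[col] = out[col].map(lambda r: r.cell())
        return out


def replication_report(
    associations: Sequence[AssociationRecord],
    table: FrequencyTable,
    panels: Sequence[str] | None = None,
    reference_panel: str = "CEU",
    rule: SignificanceRule = NOMINAL,
    target: float = 0.80,
    n_cap: int = 150_000,
    large_n_threshold: int = 2_500,
) -> ReplicationReport:
    """Required replication N for every (association, panel) pair.

    The risk allele of each record is matched against the table's alleles
    to orient the frequency; a mismatch raises.  Associations whose
    reference-panel status is not ``"ok"`` are left out of the
    gain/loss comparison; capped and monomorphic cells in other panels are
    treated as "no smaller N available there".
    """
    if panels is None:
        panels = list(table.panels)
    if reference_panel not in panels:
        raise MissingPanelError(f"reference panel {reference_panel!r} not among panels")
    for panel in panels:
        if panel not in table.panels:
            raise MissingPanelError(f"panel {panel!r} not in frequency table")
    frame = table.frame.set_index("snp_id")

    rows = []
    for assoc in associations:
        if assoc.snp_id not in frame.index:
            raise MissingPanelError(f"association SNP {assoc.snp_id!r} not in table")
        site = frame.loc[assoc.snp_id]
        if assoc.risk_allele == site["allele_a"]:
            orient = 1.0
        elif assoc.risk_allele == site["allele_b"]:
            orient = -1.0
        else:
            raise AlleleMismatchError(
                f"{assoc.snp_id}: risk allele {assoc.risk_allele!r} matches neither "
                f"{site['allele_a']!r} nor {site['allele_b']!r}"
            )
        model = EffectModel(grr=assoc.odds_ratio)
        row: dict[str, object] = {
            "snp_id": assoc.snp_id,
            "trait": assoc.trait,
            "risk_allele": assoc.risk_allele,
            "odds_ratio": assoc.odds_ratio,
        }
        for panel in panels:
            f = float(site[panel])
            p_risk = f if orient > 0 else 1.0 - f
            row[panel] = required_sample_size(
                p_risk, model, rule=rule, target=target, n_cap=n_cap
            )
        rows.append(row)
    report = pd.DataFrame(rows)

    n_gain = n_loss = n_large_ref = n_compared = 0
    for _, row in report.iterrows():
        ref: SampleSizeResult = row[reference_panel]
        if ref.status != "ok":
            continue
        n_compared += 1
        if ref.n >= large_n_threshold:
            n_large_ref += 1
        others = [
            row[p].n
            for p in panels
            if p != reference_panel and row[p].status == "ok"
        ]
        if others and min(others) < ref.n:
            n_gain += 1
        elif others and min(others) > ref.n:
            n_loss += 1
    summary = {
        "n_associations": len(report),
        "n_compared": n_compared,
        "efficiency_gain": n_gain,
        "efficiency_loss": n_loss,
        "large_in_reference": n_large_ref,
        "large_n_threshold": large_n_threshold,
    }
    return ReplicationReport(
        reference_panel=reference_panel, table=report, summary=summary
    )


# ---------------------------------------------------------------------------
# Association list I/O
# ---------------------------------------------------------------------------

_ASSOC_COLUMNS = ["snp_id", "risk_allele", "odds_ratio", "trait"]


def read_associations(path: str | Path) -> list[AssociationRecord]:
    """Read an association TSV: snp_id, risk_allele, odds_ratio, trait."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _ASSOC_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: association table lacks columns {missing}")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                AssociationRecord(
                    snp_id=str(row["snp_id"]),
                    risk_allele=str(row["risk_allele"]),
                    odds_ratio=float(row["odds_ratio"]),
                    trait=str(row.get("trait", "")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def write_associations(records: Sequence[AssociationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "risk_allele": r.risk_allele,
                "odds_ratio": r.odds_ratio,
                "trait": r.trait,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
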