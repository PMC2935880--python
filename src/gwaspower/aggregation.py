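"""Genome-wide power aggregation and cross-population frequency analyses.

Per-SNP two-phase power is computed for every record of a frequency table
and summarized three ways:

* mean power stratified by minor-allele frequency (MAF) in a reference
  panel — the view that separates common from low-frequency variation;
* a four-way categorization of SNPs by whether they clear a power
  threshold under each of two competing scenarios;
* histograms of the cross-population allele-frequency difference, with
  the mean power change per difference bin — the view that exposes how
  genetic drift converts frequency elevation in one panel into power.

Allele anchoring: every cross-panel comparison fixes the allele that is
minor in the reference panel (ties at exactly 0.5 broken toward
``allele_a``) and follows that same allele's frequency into the other
panel.  Without a fixed anchor, allele flips (minor in one panel, major
in the other) would silently change the sign of a frequency difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, MissingPanelError
from .freq_data import FrequencyTable
from .power import GENOME_WIDE, EffectModel, SignificanceRule, ncp_values, power_from_ncp
from .scenarios import Scenario

__all__ = [
    "MafStrata",
    "PowerResult",
    "GainCategories",
    "FreqDifferenceCounts",
    "GainByDifference",
    "genome_power",
    "snp_powers",
    "gain_categories",
    "freq_difference_classes",
    "gain_by_difference",
]


@dataclass(frozen=True)
class MafStrata:
    """MAF bins in a reference panel.

    The default partition of [0, 0.5] is: monomorphic {0}; (0, 0.01);
    [0.01, 0.05] (the low-frequency band); (0.05, 0.10]; (0.10, 0.50].
    """

    reference_panel: str = "CEU"
    edges: tuple[float, ...] = (0.01, 0.05, 0.10, 0.50)

    @property
    def labels(self) -> tuple[str, ...]:
        e = self.edges
        return (
            "monomorphic",
            f"(0,{e[0]:g})",
            f"[{e[0]:g},{e[1]:g}]",
            *(f"({e[i]:g},{e[i + 1]:g}]" for i in range(1, len(e) - 1)),
        )

    def assign(self, maf: np.ndarray) -> np.ndarray:
        """Stratum label per SNP from its reference-panel MAF."""
        maf = np.asarray(maf, dtype=float)
        labels = np.array(self.labels, dtype=object)
        out = np.empty(maf.shape, dtype=object)
        out[maf == 0.0] = labels[0]
        out[(maf > 0.0) & (maf < self.edges[0])] = labels[1]
        out[(maf >= self.edges[0]) & (maf <= self.edges[1])] = labels[2]
        for i in range(1, len(self.edges) - 1):
            sel = (maf > self.edges[i]) & (maf <= self.edges[i + 1])
            out[sel] = labels[2 + i]
        return out


@dataclass
class PowerResult:
    """Per-SNP powers plus stratified and genome-wide means."""

    scenario: str
    grr: float
    per_snp: pd.DataFrame  # snp_id, stratum, ncp_a, ncp_b, power
    stratum_summary: pd.DataFrame  # stratum, n_snps, mean_power
    genome_mean: float

    @property
    def powers(self) -> pd.Series:
        """Per-SNP power indexed by snp_id."""
        return self.per_snp.set_index("snp_id")["power"]

    def stratum_mean(self, label: str) -> float:
        row = self.stratum_summary.loc[self.stratum_summary["stratum"] == label]
        if row.empty:
            raise KeyError(f"no stratum {label!r}")
        return float(row["mean_power"].iloc[0])


def snp_powers(
    table: FrequencyTable,
    scenario: Scenario,
    model: EffectModel,
    rule: SignificanceRule = GENOME_WIDE,
    risk_allele: str = "average",
) -> pd.DataFrame:
    """Vectorized per-SNP total NCP and power over all scenario arms.

    Returns a DataFrame with columns ``snp_id, ncp_a, ncp_b, power`` where
    the two NCP columns correspond to allele_a / allele_b as the risk
    allele and ``power`` follows ``risk_allele``.
    """
    arms = list(scenario.phase1.arms) + list(scenario.phase2.arms)
    for panel, _, _ in arms:
        if panel not in table.panels:
            raise MissingPanelError(f"scenario panel {panel!r} not in table panels")
    n = len(table)
    ncp_a = np.zeros(n)
    ncp_b = np.zeros(n)
    for panel, n_cases, n_controls in arms:
        p = table.freqs(panel)
        ncp_a += ncp_values(p, model.grr, n_cases, n_controls, model.prevalence)
        ncp_b += ncp_values(1.0 - p, model.grr, n_cases, n_controls, model.prevalence)
    if risk_allele == "a":
        power = power_from_ncp(ncp_a, rule)
    elif risk_allele == "b":
        power = power_from_ncp(ncp_b, rule)
    elif risk_allele == "average":
        power = 0.5 * (power_from_ncp(ncp_a, rule) + power_from_ncp(ncp_b, rule))
    else:
        raise ValueError(f"risk_allele must be 'a', 'b' or 'average', got {risk_allele!r}")
    return pd.DataFrame(
        {
            "snp_id": table.snp_ids.to_numpy(),
            "ncp_a": ncp_a,
            "ncp_b": ncp_b,
            "power": np.atleast_1d(power),
        }
    )


def genome_power(
    table: FrequencyTable,
    scenario: Scenario,
    model: EffectModel,
    rule: SignificanceRule = GENOME_WIDE,
    strata: MafStrata | None = None,
    risk_allele: str = "average",
) -> PowerResult:
    """Power for every SNP of a table, with MAF-stratified aggregates.

    Stratum means are unweighted means over the SNPs assigned to each
    reference-panel MAF bin; the genome-wide mean is the unweighted mean
    over all SNPs (equivalently the SNP-count-weighted mean of the stratum
    means).
    """
    if strata is None:
        strata = MafStrata()
    if strata.reference_panel not in table.panels:
        raise MissingPanelError(
            f"stratification panel {strata.reference_panel!r} not in table panels"
        )
    per_snp = snp_powers(table, scenario, model, rule, risk_allele)
    per_snp.insert(1, "stratum", strata.assign(table.maf(strata.reference_panel)))
    grouped = per_snp.groupby("stratum", sort=False)["power"].agg(["size", "mean"])
    grouped = grouped.reindex([l for l in strata.labels if l in grouped.index])
    summary = grouped.reset_index().rename(
        columns={"size": "n_snps", "mean": "mean_power"}
    )
    return PowerResult(
        scenario=scenario.name,
        grr=model.grr,
        per_snp=per_snp,
        stratum_summary=summary,
        genome_mean=float(per_snp["power"].mean()),
    )


# ---------------------------------------------------------------------------
# Scenario comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GainCategories:
    """SNP counts by threshold attainment under two scenarios."""

    threshold: float
    counts: dict[str, int]  # both / only_a / only_b / neither
    fractions: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _aligned(power_a: pd.Series, power_b: pd.Series) -> tuple[pd.Series, pd.Series]:
    if set(power_a.index) != set(power_b.index):
        raise AlignmentError("the two power series cover different SNP sets")
    return power_a, power_b.reindex(power_a.index)


def gain_categories(
    power_a: pd.Series, power_b: pd.Series, threshold: float = 0.80
) -> GainCategories:
    """Four-way classification of SNPs by power threshold attainment.

    ``both``: >= threshold under both scenarios; ``only_a`` / ``only_b``:
    under exactly one; ``neither``: under none.  Fractions sum to 1.
    """
    power_a, power_b = _aligned(power_a, power_b)
    hit_a = power_a.to_numpy() >= threshold
    hit_b = power_b.to_numpy() >= threshold
    counts = {
        "both": int(np.count_nonzero(hit_a & hit_b)),
        "only_a": int(np.count_nonzero(hit_a & ~hit_b)),
        "only_b": int(np.count_nonzero(~hit_a & hit_b)),
        "neither": int(np.count_nonzero(~hit_a & ~hit_b)),
    }
    total = len(power_a)
    fractions = {k: v / total for k, v in counts.items()}
    return GainCategories(threshold=threshold, counts=counts, fractions=fractions)


# ---------------------------------------------------------------------------
# Cross-population frequency differences
# ---------------------------------------------------------------------------


def _anchored_freqs(
    table: FrequencyTable, panel_ref: str, panel_alt: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(f_ref, f_alt, included) for the allele that is minor in the reference.

    Ties at exactly 0.5 anchor to allele_a.  SNPs monomorphic in both
    panels are flagged excluded.
    """
    fa_ref = table.freqs(panel_ref)
    fa_alt = table.freqs(panel_alt)
    anchor_is_a = fa_ref <= 0.5
    f_ref = np.where(anchor_is_a, fa_ref, 1.0 - fa_ref)
    f_alt = np.where(anchor_is_a, fa_alt, 1.0 - fa_alt)
    mono_ref = (fa_ref == 0.0) | (fa_ref == 1.0)
    mono_alt = (fa_alt == 0.0) | (fa_alt == 1.0)
    included = ~(mono_ref & mono_alt)
    return f_ref, f_alt, included


@dataclass(frozen=True)
class FreqDifferenceCounts:
    """Counts of SNPs by where the reference-minor allele is more common."""

    less_common_in_ref: int
    equal: int
    more_common_in_ref: int
    excluded: int  # monomorphic in both panels

    @property
    def included(self) -> int:
        return self.less_common_in_ref + self.equal + self.more_common_in_ref


def freq_difference_classes(
    table: FrequencyTable,
    panel_ref: str,
    panel_alt: str,
    tol: float = 0.0,
) -> FreqDifferenceCounts:
    """Classify each SNP by the anchored allele's frequency in the two panels.

    The compared allele is the reference panel's minor allele; its
    frequency in the alternative panel is compared against its frequency
    in the reference.  ``tol`` widens the "equal" class (default exact
    equality: finite-chromosome estimates are discrete, so ties occur).
    SNPs monomorphic in both panels are excluded.
    """
    f_ref, f_alt, included = _anchored_freqs(table, panel_ref, panel_alt)
    diff = f_alt[included] - f_ref[included]
    return FreqDifferenceCounts(
        less_common_in_ref=int(np.count_nonzero(diff > tol)),
        equal=int(np.count_nonzero(np.abs(diff) <= tol)),
        more_common_in_ref=int(np.count_nonzero(diff < -tol)),
        excluded=int(np.count_nonzero(~included)),
    )


@dataclass
class GainByDifference:
    """Histogram of SNPs by cross-panel frequency difference.

    ``bins``: per-bin SNP count and mean power change (scenario B minus
    scenario A); ``net_gain``: mean power change over all included SNPs;
    ``gain_positive_bins``: total power change contributed by bins of
    positive frequency difference, expressed per included SNP.
    """

    bin_width: float
    bins: pd.DataFrame  # bin_lo, bin_hi, count, mean_dpower
    net_gain: float
    gain_positive_bins: float


def gain_by_difference(
    table: FrequencyTable,
    power_a: pd.Series,
    power_b: pd.Series,
    panel_ref: str,
    panel_alt: str,
    bin_width: float = 0.05,
) -> GainByDifference:
    """Bin SNPs by anchored frequency difference and average the power change.

    The difference is ``freq_alt - freq_ref`` of the reference panel's
    minor allele; bins are half-open ``[lo, hi)`` multiples of
    ``bin_width``.  SNPs monomorphic in both panels are excluded.
    """
    power_a, power_b = _aligned(power_a, power_b)
    ids = table.snp_ids.to_numpy()
    if set(ids) != set(power_a.index):
        raise AlignmentError("power series do not cover the table's SNP set")
    f_ref, f_alt, included = _anchored_freqs(table, panel_ref, panel_alt)
    diff = (f_alt - f_ref)[included]
    dpower = (
        power_b.reindex(ids).to_numpy() - power_a.reindex(ids).to_numpy()
    )[included]
    idx = np.floor(diff / bin_width + 1e-12).astype(int)
    frame = (
        pd.DataFrame({"bin_idx": idx, "dpower": dpower})
        .groupby("bin_idx")
        .agg(count=("dpower", "size"), mean_dpower=("dpower", "mean"))
        .reset_index()
        .sort_values("bin_idx")
    )
    frame["bin_lo"] = frame["bin_idx"] * bin_width
    frame["bin_hi"] = frame["bin_lo"] + bin_width
    frame = frame[["bin_lo", "bin_hi", "count", "mean_dpower"]].reset_index(drop=True)
    n_included = int(np.count_nonzero(included))
    positive = frame["bin_lo"] > 0
    gain_pos = float(
        (frame.loc[positive, "count"] * frame.loc[positive, "mean_dpower"]).sum()
        / n_included
    )
    return GainByDifference(
        bin_width=bin_width,
        bins=frame,
        net_gain=float(dpower.mean()),
        gain_positive_bins=gain_pos,
    )
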