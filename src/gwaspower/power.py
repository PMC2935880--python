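"""Analytic power engine for case-control association under a multiplicative model.

A SNP's evidence for association is summarized by the non-centrality
parameter (NCP) of the 1-df allele-count chi-square comparing case and
control risk-allele frequencies.  Under a multiplicative (log-additive)
model with genotype relative risk GRR per copy of the risk allele, the
risk-allele frequency among cases is shifted upward relative to controls;
the NCP grows linearly with sample size at fixed frequencies, so evidence
from independent study arms (phases, population panels) adds on the NCP
scale.  Asymptotic power is the upper-tail mass of the noncentral
chi-square beyond the null critical value.

The rare-disease approximation (controls drawn from the general
population) is the default; supplying a disease prevalence switches to an
exact case/control genotype mixture under Hardy-Weinberg equilibrium.

A genotype-level Monte-Carlo simulator provides an independent check of
the analytic formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import MissingPanelError

__all__ = [
    "EffectModel",
    "CohortArm",
    "SignificanceRule",
    "GENOME_WIDE",
    "NOMINAL",
    "case_control_freqs",
    "ncp_single",
    "ncp_values",
    "power_from_ncp",
    "snp_power",
    "monte_carlo_power",
    "MonteCarloResult",
]


@dataclass(frozen=True)
class EffectModel:
    """Multiplicative disease model.

    Parameters
    ----------
    grr
        Genotype relative risk per copy of the risk allele.  Values below 1
        are accepted and are equivalent to re-orienting the risk allele.
    prevalence
        Optional disease prevalence K in (0, 1).  When absent, the
        rare-disease approximation is used: control allele frequencies equal
        population frequencies.
    """

    grr: float
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if not self.grr > 0:
            raise ValueError(f"grr must be positive, got {self.grr}")
        if self.prevalence is not None and not (0 < self.prevalence < 1):
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")


@dataclass(frozen=True)
class CohortArm:
    """One case-control arm drawn from a single source population."""

    n_cases: int
    n_controls: int
    p: float  # risk-allele frequency in the source population

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("sample counts must be non-negative")
        if not 0 <= self.p <= 1:
            raise ValueError(f"allele frequency must lie in [0, 1], got {self.p}")


@dataclass(frozen=True)
class SignificanceRule:
    """Significance threshold and test degrees of freedom."""

    alpha: float = 5e-8
    df: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.df < 1:
            raise ValueError("df must be a positive integer")

    @property
    def critical_value(self) -> float:
        """(1 - alpha) quantile of the central chi-square with ``df`` df."""
        return float(stats.chi2.isf(self.alpha, self.df))


#: Genome-wide discovery threshold used throughout GWAS practice.
GENOME_WIDE = SignificanceRule(alpha=5e-8)
#: Nominal threshold for replicating a pre-specified hypothesis.
NOMINAL = SignificanceRule(alpha=0.05)


def case_control_freqs(p, model: EffectModel):
    """Risk-allele frequencies among cases and controls.

    Under the rare-disease approximation,

        p_case = p * GRR / (p * GRR + (1 - p)),   p_control = p.

    With a prevalence K, genotype frequencies among cases are the HWE
    distribution reweighted by GRR**g, and controls are the population
    mixture with cases (at rate K) removed.

    Accepts scalars or numpy arrays; returns ``(p_case, p_control)`` with
    the same shape.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    grr = model.grr
    if model.prevalence is None:
        p_case = p * grr / (p * grr + (1.0 - p))
        p_control = p
    else:
        K = model.prevalence
        hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        weights = np.array([1.0, grr, grr**2])
        mean_risk = np.tensordot(weights, hwe, axes=1)
        f0 = K / mean_risk  # baseline penetrance
        if np.any(f0 * grr**2 > 1):
            raise ValueError(
                "prevalence/grr combination implies penetrance above 1"
            )
        f = np.multiply.outer(weights, f0)  # per-genotype penetrances
        case_geno = f * hwe / K
        ctrl_geno = (1 - f) * hwe / (1 - K)
        dose = np.array([0.0, 0.5, 1.0])
        p_case = np.tensordot(dose, case_geno, axes=1)
        p_control = np.tensordot(dose, ctrl_geno, axes=1)
    if p.ndim == 0:
        return float(p_case), float(p_control)
    return p_case, p_control


def ncp_values(p, grr: float, n_cases: float, n_controls: float,
               prevalence: float | None = None):
    """Vectorized NCP of the 1-df allele-count chi-square.

    ``ncp = (p_case - p_control)^2 / [pbar (1 - pbar) (1/(2 N_case) + 1/(2 N_control))]``

    where ``pbar`` is the sample-size-weighted pooled allele frequency under
    the alternative.  Monomorphic frequencies, a null effect (GRR = 1) and
    empty arms all yield 0.
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    out = np.zeros_like(p)
    if n_cases > 0 and n_controls > 0 and grr != 1.0:
        model = EffectModel(grr=grr, prevalence=prevalence)
        active = (p > 0) & (p < 1)
        if np.any(active):
            pc, pu = case_control_freqs(p[active], model)
            pc = np.atleast_1d(pc)
            pu = np.atleast_1d(pu)
            pbar = (n_cases * pc + n_controls * pu) / (n_cases + n_controls)
            denom = pbar * (1 - pbar) * (1 / (2 * n_cases) + 1 / (2 * n_controls))
            with np.errstate(divide="ignore", invalid="ignore"):
                ncp = (pc - pu) ** 2 / denom
            # subnormal p underflows the denominator; the true limit is 0
            out[active] = np.where(np.isfinite(ncp), ncp, 0.0)
    return float(out[0]) if scalar else out


def ncp_single(arm: CohortArm, model: EffectModel) -> float:
    """NCP contributed by a single case-control arm."""
    return float(
        ncp_values(arm.p, model.grr, arm.n_cases, arm.n_controls, model.prevalence)
    )


def power_from_ncp(ncp, rule: SignificanceRule):
    """Asymptotic power of a noncentral chi-square test.

    ``power = P[chi2(df, ncp) > q]`` with ``q`` the (1 - alpha) central
    quantile.  Computed through survival functions so that extreme tails
    (alpha = 5e-8) retain full precision.  ``ncp = 0`` returns exactly
    ``alpha``.
    """
    ncp_arr = np.asarray(ncp, dtype=float)
    if np.any(ncp_arr < 0):
        raise ValueError("ncp must be non-negative")
    q = rule.critical_value
    out = np.where(
        ncp_arr == 0.0,
        rule.alpha,
        stats.ncx2.sf(q, rule.df, np.where(ncp_arr == 0.0, 1.0, ncp_arr)),
    )
    # rounding at minuscule ncp can dip a hair below alpha; power is
    # mathematically confined to [alpha, 1]
    out = np.clip(out, rule.alpha, 1.0)
    return float(out) if ncp_arr.ndim == 0 else out


def snp_power(
    freqs: Mapping[str, float],
    scenario,
    model: EffectModel,
    rule: SignificanceRule = GENOME_WIDE,
    risk_allele: str = "average",
) -> float:
    """Two-phase power for one SNP given per-panel allele-a frequencies.

    Sums the NCP over every (phase, panel) arm of ``scenario`` and converts
    the total to power.  ``risk_allele`` selects which allele carries the
    risk: ``"a"``, ``"b"``, or ``"average"`` — the mean of the powers with
    either allele treated as risk-increasing, which makes the result
    orientation-free.
    """
    if risk_allele not in {"a", "b", "average"}:
        raise ValueError(f"risk_allele must be 'a', 'b' or 'average', got {risk_allele!r}")
    arms = list(scenario.phase1.arms) + list(scenario.phase2.arms)
    for panel, _, _ in arms:
        if panel not in freqs:
            raise MissingPanelError(f"panel {panel!r} has no frequency for this SNP")

    def total_power(orient_a: bool) -> float:
        total = 0.0
        for panel, n_cases, n_controls in arms:
            p = freqs[panel] if orient_a else 1.0 - freqs[panel]
            total += ncp_values(p, model.grr, n_cases, n_controls, model.prevalence)
        return power_from_ncp(total, rule)

    if risk_allele == "a":
        return total_power(True)
    if risk_allele == "b":
        return total_power(False)
    return 0.5 * (total_power(True) + total_power(False))


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical power estimate with its binomial standard error."""

    power: float
    se: float
    reps: int


def monte_carlo_power(
    arm: CohortArm,
    model: EffectModel,
    rule: SignificanceRule,
    reps: int = 50_000,
    seed: int = 0,
) -> MonteCarloResult:
    """Genotype-level Monte-Carlo estimate of power.

    Case genotypes are drawn from HWE(p) reweighted by GRR**g (rare-disease
    sampling); controls from HWE(p).  Each replicate is scored with the
    1-df allelic (2x2 allele-count) chi-square against the central critical
    value.  Deterministic for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = np.random.default_rng(seed)
    p = arm.p
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    w = np.array([1.0, model.grr, model.grr**2])
    case_probs = hwe * w
    case_probs /= case_probs.sum()

    case_geno = rng.multinomial(arm.n_cases, case_probs, size=reps)
    ctrl_geno = rng.multinomial(arm.n_controls, hwe, size=reps)
    a = case_geno[:, 1] + 2 * case_geno[:, 2]          # risk alleles, cases
    c = ctrl_geno[:, 1] + 2 * ctrl_geno[:, 2]          # risk alleles, controls
    b = 2 * arm.n_cases - a
    d = 2 * arm.n_controls - c
    n = 2 * (arm.n_cases + arm.n_controls)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (
            n
            * (a * d - b * c).astype(float) ** 2
            / ((a + b).astype(float) * (c + d) * (a + c) * (b + d))
        )
    stat = np.nan_to_num(stat)  # degenerate margins carry no evidence
    hits = int(np.count_nonzero(stat > rule.critical_value))
    phat = hits / reps
    se = float(np.sqrt(phat * (1 - phat) / reps))
    return MonteCarloResult(power=phat, se=se, reps=reps)
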