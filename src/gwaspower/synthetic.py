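"""Synthetic multi-population allele-frequency data.

Panels are related by genetic drift under the Balding-Nichols model: for
an ancestral allele frequency q and a panel-specific divergence F (an
F_ST analog), the panel's frequency is drawn from

    Beta( q (1 - F) / F,  (1 - q)(1 - F) / F ),

which has mean q and variance F q (1 - q).  Independent draws per panel
give a star topology around the ancestral pool.  On top of the drift
layer the generator reproduces two features of real frequency resources:
SNP-array ascertainment (keep only variants common in a reference panel)
and finite-founder estimation (frequencies observed as binomial counts
over a fixed number of chromosomes).

A companion generator fabricates lists of reported associations (risk
allele, odds ratio) with matching frequency-table rows for exercising the
replication calculator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .freq_data import SITE_COLUMNS, FrequencyTable
from .replication import AssociationRecord

__all__ = [
    "PanelModel",
    "AncestralSpectrum",
    "simulate_panels",
    "apply_ascertainment",
    "estimate_from_founders",
    "simulate_associations",
]


@dataclass(frozen=True)
class PanelModel:
    """Parameters of one synthetic population panel.

    ``divergence`` is the Balding-Nichols F in [0, 1) (0 = no drift:
    the panel frequency equals the ancestral draw).  ``chromosomes`` > 0
    replaces each true frequency with a binomial estimate over that many
    chromosomes; 0 keeps exact frequencies.
    """

    name: str
    divergence: float = 0.0
    chromosomes: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError(f"divergence must lie in [0, 1), got {self.divergence}")
        if self.chromosomes < 0:
            raise ValueError("chromosomes must be non-negative")


@dataclass(frozen=True)
class AncestralSpectrum:
    """Distribution of ancestral allele frequencies.

    ``neutral_1_over_x``: density proportional to 1/x on
    [min_freq, max_freq], the classic neutral site-frequency shape;
    sampled by exact inverse-CDF.  ``beta``: Beta(a, b) truncated to the
    bounds by rejection.  ``uniform``: flat on the bounds.
    """

    kind: str = "neutral_1_over_x"
    a: float = 1.0
    b: float = 1.0
    min_freq: float = 0.001
    max_freq: float = 0.999

    def __post_init__(self) -> None:
        if self.kind not in {"neutral_1_over_x", "beta", "uniform"}:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if not 0 < self.min_freq < self.max_freq < 1:
            raise ValueError("require 0 < min_freq < max_freq < 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.min_freq, self.max_freq, size=n)
        if self.kind == "neutral_1_over_x":
            # inverse CDF of density 1/(x log(max/min)) on [min, max]
            u = rng.uniform(size=n)
            return self.min_freq * (self.max_freq / self.min_freq) ** u
        out = np.empty(n)
        filled = 0
        while filled < n:  # rejection against the truncation bounds
            draw = rng.beta(self.a, self.b, size=2 * (n - filled))
            keep = draw[(draw >= self.min_freq) & (draw <= self.max_freq)]
            take = min(len(keep), n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
        return out


def _site_frame(n_snps: int) -> pd.DataFrame:
    width = max(6, len(str(n_snps)))
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i:0{width}d}" for i in range(1, n_snps + 1)],
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1, dtype=int),
            "allele_a": "A",
            "allele_b": "G",
        }
    )


def simulate_panels(
    n_snps: int,
    spectrum: AncestralSpectrum,
    panels: Sequence[PanelModel],
    seed: int,
) -> FrequencyTable:
    """Draw a frequency table of ``n_snps`` SNPs across drifted panels.

    Per SNP, an ancestral frequency q comes from ``spectrum``; each
    panel's frequency is an independent Balding-Nichols draw around q
    (F = 0 reproduces q exactly).  Panels with ``chromosomes`` > 0 then
    observe a binomial count over that many chromosomes.  Deterministic
    for a fixed seed.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be at least 1")
    if not panels:
        raise ValueError("need at least one panel")
    rng = np.random.default_rng(seed)
    q = spectrum.sample(n_snps, rng)
    frame = _site_frame(n_snps)
    chromosomes: dict[str, int] = {}
    for panel in panels:
        F = panel.divergence
        if F == 0.0:
            freq = q.copy()
        else:
            scale = (1.0 - F) / F
            freq = rng.beta(q * scale, (1.0 - q) * scale)
        if panel.chromosomes > 0:
            freq = rng.binomial(panel.chromosomes, freq) / panel.chromosomes
        frame[panel.name] = freq
        chromosomes[panel.name] = panel.chromosomes
    return FrequencyTable(
        frame=frame,
        panels=[p.name for p in panels],
        chromosomes=chromosomes,
        source="synthetic",
    )


def apply_ascertainment(
    table: FrequencyTable, reference_panel: str, min_maf: float
) -> FrequencyTable:
    """Keep SNPs whose reference-panel MAF is at least ``min_maf``.

    Models SNP-array ascertainment toward variants common in the
    reference population; ``min_maf = 0`` is the identity (sequencing-like
    input with no array filter).
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must lie in [0, 0.5], got {min_maf}")
    keep = table.maf(reference_panel) >= min_maf
    return table.subset(keep)


def estimate_from_founders(
    table: FrequencyTable, chromosomes: int, seed: int
) -> FrequencyTable:
    """Replace true frequencies with binomial finite-sample estimates.

    Each frequency p becomes X / chromosomes with X ~ Binomial(chromosomes,
    p): an unbiased estimate whose granularity (multiples of
    1/chromosomes) and sampling noise mimic frequency estimation from a
    fixed founder set.
    """
    if chromosomes < 2:
        raise ValueError("chromosomes must be at least 2")
    rng = np.random.default_rng(seed)
    frame = table.frame.copy()
    for panel in table.panels:
        p = table.freqs(panel)
        frame[panel] = rng.binomial(chromosomes, p) / chromosomes
    return FrequencyTable(
        frame=frame,
        panels=list(table.panels),
        chromosomes={p: chromosomes for p in table.panels},
        source="estimated",
    )


def simulate_associations(
    n: int,
    or_range: tuple[float, float],
    maf_range: tuple[float, float],
    panels: Sequence[PanelModel],
    seed: int,
    n_duplicate_snps: int = 0,
) -> tuple[list[AssociationRecord], FrequencyTable]:
    """Fabricate reported associations with matching frequency-table rows.

    Odds ratios are uniform on ``or_range`` and ancestral risk-allele
    frequencies uniform on ``maf_range``; per-panel frequencies then drift
    per the panel models.  ``n_duplicate_snps`` of the ``n`` records
    re-report an earlier SNP under a different trait, mimicking catalogs
    where one SNP is associated with several diseases.  The risk allele is
    always ``allele_a`` of the matching row.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0 <= n_duplicate_snps <= max(0, n - 1):
        raise ValueError("n_duplicate_snps must lie in [0, n-1]")
    lo_or, hi_or = or_range
    lo_f, hi_f = maf_range
    if not (0 < lo_or <= hi_or) or not (0 <= lo_f <= hi_f <= 1):
        raise ValueError("invalid or_range or maf_range")
    rng = np.random.default_rng(seed)
    n_unique = n - n_duplicate_snps
    if n == 0:
        empty = _site_frame(1).iloc[:0]
        for p in panels:
            empty[p.name] = np.array([], dtype=float)
        table = FrequencyTable(
            frame=empty, panels=[p.name for p in panels], source="synthetic"
        )
        return [], table

    q = rng.uniform(lo_f, hi_f, size=n_unique)
    frame = _site_frame(n_unique)
    frame["snp_id"] = [f"rs{i:06d}" for i in range(1, n_unique + 1)]
    for panel in panels:
        F = panel.divergence
        if F == 0.0:
            freq = q.copy()
        else:
            scale = (1.0 - F) / F
            freq = rng.beta(q * scale, (1.0 - q) * scale)
        if panel.chromosomes > 0:
            freq = rng.binomial(panel.chromosomes, freq) / panel.chromosomes
        frame[panel.name] = freq
    table = FrequencyTable(
        frame=frame, panels=[p.name for p in panels], source="synthetic"
    )

    odds = rng.uniform(lo_or, hi_or, size=n)
    snp_idx = list(range(n_unique))
    if n_duplicate_snps:
        snp_idx += list(rng.choice(n_unique, size=n_duplicate_snps, replace=True))
    records = [
        AssociationRecord(
            snp_id=frame.loc[j, "snp_id"],
            risk_allele=frame.loc[j, "allele_a"],
            odds_ratio=float(odds[i]),
            trait=f"trait{i + 1}",
            source="synthetic",
        )
        for i, j in enumerate(snp_idx)
    ]
    return records, table
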