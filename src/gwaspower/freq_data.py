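"""Per-SNP, per-panel allele-frequency tables.

The central container is :class:`FrequencyTable`: for every biallelic SNP
it stores the two allele identities and, for each population panel, the
frequency of ``allele_a``.  Anchoring every panel's frequency to the same
allele is what makes cross-population frequency differences well defined
(the frequency of ``allele_b`` is always the complement).

Tables can be read from a simple TSV dialect or derived from a VCF plus a
sample-to-panel map; founder subsampling reproduces the common practice of
equalizing panel sizes before comparing allele frequencies across panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientSampleError,
    PanelMappingError,
    ParseError,
    ValidationError,
)

__all__ = [
    "SNPRecord",
    "FrequencyTable",
    "GenotypeData",
    "SITE_COLUMNS",
    "read_frequency_table",
    "write_frequency_table",
    "read_genotypes_vcf",
    "subsample_founders",
    "annotate_monomorphic",
    "filter_polymorphic_any",
]

#: Fixed leading columns of the TSV dialect, in order.
SITE_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]

#: Decimal places used when printing frequencies.
FREQ_DECIMALS = 6


@dataclass(frozen=True)
class SNPRecord:
    """A single biallelic site with per-panel frequencies of ``allele_a``."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    freq_a: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValidationError(
                f"{self.snp_id}: allele_a and allele_b must differ"
            )

    def maf(self, panel: str) -> float:
        """Minor-allele frequency in ``panel``."""
        f = self.freq_a[panel]
        return min(f, 1.0 - f)


@dataclass
class FrequencyTable:
    """Ordered collection of SNPs with per-panel allele-a frequencies.

    Attributes
    ----------
    frame
        DataFrame with columns ``snp_id, chrom, pos, allele_a, allele_b``
        followed by one float column per panel (frequency of ``allele_a``;
        NaN marks an explicitly missing estimate).
    panels
        Panel names, in column order.
    chromosomes
        Chromosome count behind each panel's frequency estimates
        (0 = exact / unknown).
    source
        Provenance tag: ``observed``, ``estimated`` or ``synthetic``.
    """

    frame: pd.DataFrame
    panels: list[str]
    chromosomes: dict[str, int] = field(default_factory=dict)
    source: str = "observed"

    def __post_init__(self) -> None:
        self.validate()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield SNPRecord(
                snp_id=row.snp_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                allele_a=row.allele_a,
                allele_b=row.allele_b,
                freq_a={p: getattr(row, p) for p in self.panels},
            )

    # -- accessors ----------------------------------------------------------

    def freqs(self, panel: str) -> np.ndarray:
        """Allele-a frequency array for ``panel`` (aligned with ``frame``)."""
        if panel not in self.panels:
            raise KeyError(f"unknown panel {panel!r}")
        return self.frame[panel].to_numpy(dtype=float)

    def maf(self, panel: str) -> np.ndarray:
        """Minor-allele frequency array for ``panel``."""
        f = self.freqs(panel)
        return np.minimum(f, 1.0 - f)

    @property
    def snp_ids(self) -> pd.Series:
        return self.frame["snp_id"]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"missing site columns: {missing}")
        for panel in self.panels:
            if panel not in self.frame.columns:
                raise ValidationError(f"missing frequency column for panel {panel!r}")
            f = self.frame[panel].to_numpy(dtype=float)
            bad = (f < 0) | (f > 1)
            if np.any(bad & ~np.isnan(f)):
                snp = self.frame.loc[np.nonzero(bad)[0][0], "snp_id"]
                raise ValidationError(
                    f"frequency outside [0, 1] for SNP {snp} in panel {panel}"
                )
        if self.frame["snp_id"].duplicated().any():
            dup = self.frame.loc[self.frame["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValidationError(f"duplicate SNP id {dup!r}")
        same = self.frame["allele_a"].astype(str) == self.frame["allele_b"].astype(str)
        if same.any():
            snp = self.frame.loc[same, "snp_id"].iloc[0]
            raise ValidationError(f"{snp}: allele_a equals allele_b")

    def subset(self, mask: np.ndarray, **meta) -> "FrequencyTable":
        """New table with the rows selected by boolean ``mask``."""
        return FrequencyTable(
            frame=self.frame.loc[mask].reset_index(drop=True),
            panels=list(self.panels),
            chromosomes=dict(self.chromosomes),
            source=meta.get("source", self.source),
        )


# ---------------------------------------------------------------------------
# TSV input/output
# ---------------------------------------------------------------------------


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    """Write the TSV dialect: ``#``-prefixed metadata, header, one row per SNP.

    Frequencies are printed at 6 decimals; NaN as ``NA``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# source={table.source}\n")
        if table.chromosomes:
            pairs = ",".join(f"{p}:{table.chromosomes.get(p, 0)}" for p in table.panels)
            fh.write(f"# chromosomes={pairs}\n")
        out = table.frame[SITE_COLUMNS + table.panels].copy()
        for p in table.panels:
            out[p] = out[p].map(
                lambda x: "NA" if pd.isna(x) else f"{x:.{FREQ_DECIMALS}f}"
            )
        out.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: Path) -> FrequencyTable:
    source = "observed"
    chromosomes: dict[str, int] = {}
    header_line = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_line += 1
            body = line[1:].strip()
            if body.startswith("source="):
                source = body.split("=", 1)[1]
            elif body.startswith("chromosomes="):
                for pair in body.split("=", 1)[1].split(","):
                    name, _, count = pair.partition(":")
                    chromosomes[name] = int(count)

    try:
        frame = pd.read_csv(
            path, sep="\t", comment="#", na_values=["NA"], dtype={"chrom": str}
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in SITE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: header lacks required columns {missing}")
    panels = [c for c in frame.columns if c not in SITE_COLUMNS]
    if not panels:
        raise ParseError(f"{path}: no panel frequency columns found")
    for i, panel in enumerate(panels):
        col = pd.to_numeric(frame[panel], errors="coerce")
        bad = col.isna() & frame[panel].notna()
        if bad.any():
            # +2: header plus 1-based numbering; metadata lines precede it
            line_no = int(bad.idxmax()) + 2 + header_line
            raise ParseError(
                f"{path}: line {line_no}: non-numeric frequency "
                f"{frame.loc[bad.idxmax(), panel]!r} in column {panel}"
            )
        frame[panel] = col
    return FrequencyTable(
        frame=frame, panels=panels, chromosomes=chromosomes, source=source
    )


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


@dataclass
class GenotypeData:
    """Diploid genotypes as allele-a dosages (rows = sites, cols = samples).

    ``dosage[i, j]`` counts copies of ``allele_a`` (the REF allele when read
    from VCF) carried by sample ``j`` at site ``i``; -1 marks a missing call.
    """

    sites: pd.DataFrame  # SITE_COLUMNS
    dosage: np.ndarray  # int8, shape (n_sites, n_samples)
    samples: list[str]

    def panel_samples(self, panel_map: Mapping[str, str]) -> dict[str, list[int]]:
        """Column indices per panel; raises if a sample is unmapped."""
        unmapped = [s for s in self.samples if s not in panel_map]
        if unmapped:
            raise PanelMappingError(
                f"samples absent from panel map: {', '.join(unmapped[:5])}"
            )
        panels: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            panels.setdefault(panel_map[s], []).append(j)
        return panels


def read_genotypes_vcf(path: str | Path) -> GenotypeData:
    """Read biallelic SNP genotypes from a VCF (v4.x) file.

    Multi-allelic records are rejected with a counted warning rather than
    split: the analyses downstream assume a strictly two-allele model.
    """
    from cyvcf2 import VCF  # deferred: optional at import time

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        rows.append(
            (snp_id, str(variant.CHROM), int(variant.POS), variant.REF, variant.ALT[0])
        )
        dos = np.full(len(samples), -1, dtype=np.int8)
        for j, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                dos[j] = sum(1 for a in alleles if a == 0)  # REF = allele_a
        dosages.append(dos)
    if n_multi:
        warnings.warn(
            f"rejected {n_multi} multi-allelic record(s); the model is biallelic",
            stacklevel=2,
        )
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosage = (
        np.array(dosages, dtype=np.int8)
        if dosages
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeData(sites=sites, dosage=dosage, samples=samples)


def _freqs_from_genotypes(
    geno: GenotypeData, panel_idx: dict[str, list[int]]
) -> FrequencyTable:
    frame = geno.sites.copy()
    panels = list(panel_idx)
    chromosomes: dict[str, int] = {}
    for panel, idx in panel_idx.items():
        sub = geno.dosage[:, idx].astype(float)
        sub[sub < 0] = np.nan
        called = 2.0 * np.sum(~np.isnan(sub), axis=1)  # non-missing chromosomes
        with np.errstate(invalid="ignore"):
            frame[panel] = np.nansum(sub, axis=1) / np.where(called > 0, called, np.nan)
        chromosomes[panel] = 2 * len(idx)
    return FrequencyTable(
        frame=frame, panels=panels, chromosomes=chromosomes, source="observed"
    )


def read_panel_map(path: str | Path) -> dict[str, str]:
    """Two-column (sample, panel) TSV, no header required."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {i}: expected 2 columns, got {len(parts)}")
            if parts[0] == "sample" and parts[1] == "panel":
                continue  # optional header
            mapping[parts[0]] = parts[1]
    return mapping


def read_frequency_table(
    path: str | Path,
    format: str = "tsv",
    panel_map: Mapping[str, str] | str | Path | None = None,
) -> FrequencyTable:
    """Read a frequency table from TSV, or derive one from a VCF.

    For ``format="vcf"`` a ``panel_map`` covering every sample is required;
    per-panel frequencies are allele counts over non-missing called
    chromosomes in that panel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        if panel_map is None:
            raise PanelMappingError("vcf input requires a sample-to-panel map")
        if isinstance(panel_map, (str, Path)):
            panel_map = read_panel_map(panel_map)
        geno = read_genotypes_vcf(path)
        return _freqs_from_genotypes(geno, geno.panel_samples(panel_map))
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Founder subsampling
# ---------------------------------------------------------------------------


def subsample_founders(
    genotypes: GenotypeData,
    panel_map: Mapping[str, str],
    n_founders: int,
    seed: int,
) -> FrequencyTable:
    """Frequencies from a random subset of ``n_founders`` samples per panel.

    Equalizes the number of chromosomes (2 per founder) behind every
    panel's estimate, so that estimation noise is identical across panels.
    Deterministic for a fixed seed.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be positive")
    rng = np.random.default_rng(seed)
    panel_idx = genotypes.panel_samples(panel_map)
    chosen: dict[str, list[int]] = {}
    for panel in sorted(panel_idx):  # sorted: seed-stable regardless of map order
        idx = panel_idx[panel]
        if len(idx) < n_founders:
            raise InsufficientSampleError(
                f"panel {panel!r} has {len(idx)} samples, fewer than "
                f"n_founders={n_founders}"
            )
        pick = rng.choice(len(idx), size=n_founders, replace=False)
        chosen[panel] = [idx[k] for k in sorted(pick)]
    table = _freqs_from_genotypes(genotypes, chosen)
    table.source = "estimated"
    return table


# ---------------------------------------------------------------------------
# Monomorphism annotation and filtering
# ---------------------------------------------------------------------------


def annotate_monomorphic(
    table: FrequencyTable,
    reference_panel: str | None = None,
    strata=None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Flag fixed (frequency 0 or 1) sites per panel.

    Returns ``(flags, counts)``: ``flags`` is a boolean DataFrame (rows =
    SNPs, columns = panels).  When ``reference_panel`` is given, ``counts``
    tabulates monomorphic SNPs per panel stratified by the reference
    panel's MAF bin — the structure behind per-panel monomorphism
    summaries; otherwise ``counts`` is None.
    """
    flags = pd.DataFrame(index=table.frame.index)
    for panel in table.panels:
        f = table.freqs(panel)
        flags[panel] = (f == 0.0) | (f == 1.0)
    counts = None
    if reference_panel is not None:
        from .aggregation import MafStrata  # deferred to avoid an import cycle

        if strata is None:
            strata = MafStrata(reference_panel=reference_panel)
        labels = strata.assign(table.maf(reference_panel))
        counts = pd.DataFrame(
            {
                panel: pd.Series(labels[flags[panel].to_numpy()])
                .value_counts()
                .reindex(strata.labels, fill_value=0)
                for panel in table.panels
            }
        ).T
        counts.index.name = "panel"
    return flags, counts


def filter_polymorphic_any(table: FrequencyTable) -> FrequencyTable:
    """Keep SNPs with at least one panel frequency strictly inside (0, 1)."""
    keep = np.zeros(len(table), dtype=bool)
    for panel in table.panels:
        f = table.freqs(panel)
        keep |= (f > 0.0) & (f < 1.0)
    return table.subset(keep)
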