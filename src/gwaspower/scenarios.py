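"""Two-phase study designs.

A :class:`Scenario` is a pair of phases, each a list of case-control arms
drawn from named population panels.  Phase 1 mimics an initial genome-wide
scan (conventionally in a European panel); phase 2 adds samples from any
panel or mixture of panels.  Evidence is pooled by summing per-SNP NCPs
over every arm of both phases, so a scenario is fully described by its
(panel, n_cases, n_controls) triples.

Three presets cover the classic total sample sizes 10,000 / 20,000 /
80,000 with phase 1 fixed to CEU; multiethnic phase-2 designs split their
totals equally across panels, with remainders assigned deterministically
to the earliest panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from .exceptions import ConfigError

__all__ = [
    "PhaseDesign",
    "Scenario",
    "split_equal",
    "build_scenario",
    "preset_scenario",
    "load_scenario",
    "PRESET_TOTALS",
]

#: total sample size -> ((phase1 cases, controls), (phase2 cases, controls))
PRESET_TOTALS = {
    10_000: ((2_500, 2_500), (2_500, 2_500)),
    20_000: ((5_000, 5_000), (5_000, 5_000)),
    80_000: ((10_000, 10_000), (30_000, 30_000)),
}


@dataclass(frozen=True)
class PhaseDesign:
    """One phase: a tuple of (panel, n_cases, n_controls) arms."""

    arms: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for panel, n_cases, n_controls in self.arms:
            if n_cases < 0 or n_controls < 0:
                raise ConfigError(
                    f"negative sample count in arm for panel {panel!r}"
                )

    @property
    def total(self) -> int:
        return sum(nca + nco for _, nca, nco in self.arms)

    @property
    def panels(self) -> tuple[str, ...]:
        return tuple(panel for panel, _, _ in self.arms)


@dataclass(frozen=True)
class Scenario:
    """A named two-phase design."""

    name: str
    phase1: PhaseDesign
    phase2: PhaseDesign

    @property
    def total_samples(self) -> int:
        return self.phase1.total + self.phase2.total

    @property
    def panels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for panel in self.phase1.panels + self.phase2.panels:
            seen.setdefault(panel)
        return tuple(seen)


def split_equal(
    n_cases: int, n_controls: int, panels: Sequence[str]
) -> PhaseDesign:
    """Divide cases and controls as evenly as integers allow across panels.

    Remainders go to the earliest panels in list order, so totals are
    conserved exactly and the split is reproducible.
    """
    if not panels:
        raise ConfigError("cannot split samples across an empty panel list")
    if n_cases < 0 or n_controls < 0:
        raise ConfigError("sample counts must be non-negative")
    k = len(panels)
    arms = []
    for i, panel in enumerate(panels):
        extra_ca = 1 if i < n_cases % k else 0
        extra_co = 1 if i < n_controls % k else 0
        arms.append((panel, n_cases // k + extra_ca, n_controls // k + extra_co))
    return PhaseDesign(arms=tuple(arms))


def _phase_from_config(cfg: dict | None, what: str) -> PhaseDesign:
    if cfg is None:
        return PhaseDesign(arms=())
    if "arms" in cfg:  # explicit arms: list of {panel, cases, controls}
        arms = tuple(
            (a["panel"], int(a["cases"]), int(a["controls"])) for a in cfg["arms"]
        )
        return PhaseDesign(arms=arms)
    panels = cfg.get("panels") or ([cfg["panel"]] if "panel" in cfg else [])
    if not panels:
        raise ConfigError(f"{what}: no panel(s) specified")
    cases = int(cfg.get("cases", 0))
    controls = int(cfg.get("controls", 0))
    split = cfg.get("split", "equal")
    if split != "equal":
        raise ConfigError(f"{what}: unknown split rule {split!r}")
    return split_equal(cases, controls, panels)


def build_scenario(config: dict) -> Scenario:
    """Build a scenario from a declarative config.

    Keys: ``name``; ``phase1`` / ``phase2`` each either
    ``{panel | panels, cases, controls, split: equal}`` or
    ``{arms: [{panel, cases, controls}, ...]}``.  A missing or zero-size
    phase 2 yields a scenario equal to phase 1 alone.
    """
    if "phase1" not in config:
        raise ConfigError("scenario config requires a phase1 section")
    phase1 = _phase_from_config(config["phase1"], "phase1")
    if not phase1.arms:
        raise ConfigError("phase1 must contain at least one arm")
    phase2 = _phase_from_config(config.get("phase2"), "phase2")
    return Scenario(
        name=str(config.get("name", "scenario")), phase1=phase1, phase2=phase2
    )


def preset_scenario(
    total: int, phase2_panels: Sequence[str] | str, phase1_panel: str = "CEU"
) -> Scenario:
    """One of the three standard designs, phase 1 in ``phase1_panel``.

    ``total`` must be 10,000, 20,000 or 80,000; multiethnic phase-2 panels
    share the phase-2 totals equally.
    """
    if total not in PRESET_TOTALS:
        raise ConfigError(
            f"no preset for total={total}; choose from {sorted(PRESET_TOTALS)}"
        )
    if isinstance(phase2_panels, str):
        phase2_panels = [p for p in phase2_panels.replace("+", ",").split(",") if p]
    (ca1, co1), (ca2, co2) = PRESET_TOTALS[total]
    name = f"{total // 1000}k-{'+'.join(phase2_panels)}"
    return Scenario(
        name=name,
        phase1=PhaseDesign(arms=((phase1_panel, ca1, co1),)),
        phase2=split_equal(ca2, co2, list(phase2_panels)),
    )


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML (or JSON) config file."""
    with Path(path).open() as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return build_scenario(config)
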