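"""Declarative metabolite panel: spin-system definitions and config loading.

A panel is a list of spin systems, each describing one first-order
multiplet of one metabolite: where to look (coarse ppm window), what shape
to expect (multiplicity and J), how to assign it (``pattern`` matching
under J constraints, ``correlation``-narrowed singlet windows, or a fixed
``narrow_window``), and which matched components are integrated.

The shipped default panel covers 22 serum/plasma metabolites through 24
spin systems; creatinine (CH3 + CH2, intramolecular cross-check) and
valine (two CH3 doublets) contribute two systems each.  Windows and J
values follow standard serum NMR assignment tables and every field is
user-editable YAML — nothing about the panel is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "SpinSystemDef",
    "MetabolitePanel",
    "load_panel",
    "MULTIPLET_SIZE",
    "MULTIPLET_WEIGHTS",
    "PanelConfigError",
]

MULTIPLET_SIZE = {"singlet": 1, "doublet": 2, "triplet": 3, "quartet": 4}
#: first-order (binomial) component intensity weights, low-field to high-field
MULTIPLET_WEIGHTS = {
    "singlet": (1.0,),
    "doublet": (1.0, 1.0),
    "triplet": (1.0, 2.0, 1.0),
    "quartet": (1.0, 3.0, 3.0, 1.0),
}

STRATEGIES = ("pattern", "correlation", "narrow_window")
INTEGRATION_MODES = ("all", "outer", "tallest", "leftmost", "rightmost")


class PanelConfigError(ValueError):
    """Raised when a panel file violates the schema."""


@dataclass
class SpinSystemDef:
    """One target spin system of the panel."""

    metabolite: str
    system_id: str
    multiplicity: str
    delta: float                     # nominal chemical shift of the centre (ppm)
    window: tuple[float, float]      # coarse search window (ppm)
    n_protons: int
    strategy: str
    j_hz: float | None = None
    correlation_refs: tuple[str, ...] = ()
    integration: str = "all"
    crosscheck: str | None = None
    primary: bool = True             # reports the metabolite's concentration
    bootstrap_halfwidth: float = 0.005  # training-only seed window (ppm)

    def __post_init__(self):
        self.window = (float(min(self.window)), float(max(self.window)))
        if self.multiplicity not in MULTIPLET_SIZE:
            raise PanelConfigError(
                f"{self.system_id}: unknown multiplicity {self.multiplicity!r}"
            )
        if self.strategy not in STRATEGIES:
            raise PanelConfigError(
                f"{self.system_id}: unknown strategy {self.strategy!r}"
            )
        if self.integration not in INTEGRATION_MODES:
            raise PanelConfigError(
                f"{self.system_id}: unknown integration mode "
                f"{self.integration!r}"
            )
        if self.window[1] <= self.window[0]:
            raise PanelConfigError(f"{self.system_id}: empty window")
        if self.n_protons < 1:
            raise PanelConfigError(f"{self.system_id}: n_protons must be >= 1")
        if self.n_components > 1:
            if self.j_hz is None or self.j_hz <= 0:
                raise PanelConfigError(
                    f"{self.system_id}: multiplet needs a positive j_hz"
                )
        if self.strategy == "correlation":
            if not self.correlation_refs:
                raise PanelConfigError(
                    f"{self.system_id}: correlation strategy needs "
                    "correlation_refs"
                )
            if self.multiplicity != "singlet":
                raise PanelConfigError(
                    f"{self.system_id}: correlation strategy is for singlets "
                    "(or near-degenerate multiplets modelled as such)"
                )
        if not (self.window[0] <= self.delta <= self.window[1]):
            raise PanelConfigError(
                f"{self.system_id}: nominal delta {self.delta} outside window "
                f"{self.window}"
            )

    @property
    def n_components(self) -> int:
        return MULTIPLET_SIZE[self.multiplicity]

    @property
    def weights(self) -> tuple[float, ...]:
        return MULTIPLET_WEIGHTS[self.multiplicity]


@dataclass
class MetabolitePanel:
    systems: list[SpinSystemDef]
    by_id: dict = field(init=False)

    def __post_init__(self):
        ids = [s.system_id for s in self.systems]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise PanelConfigError(f"duplicate system_id(s): {sorted(dup)}")
        self.by_id = {s.system_id: s for s in self.systems}
        for s in self.systems:
            for ref in s.correlation_refs:
                if ref not in self.by_id:
                    raise PanelConfigError(
                        f"{s.system_id}: unknown correlation ref {ref!r}"
                    )
            if s.crosscheck is not None and s.crosscheck not in self.by_id:
                raise PanelConfigError(
                    f"{s.system_id}: unknown crosscheck partner "
                    f"{s.crosscheck!r}"
                )
        for m in self.metabolites:
            prim = [s for s in self.systems
                    if s.metabolite == m and s.primary]
            if len(prim) != 1:
                raise PanelConfigError(
                    f"metabolite {m!r} must have exactly one primary spin "
                    f"system, found {len(prim)}"
                )

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.systems:
            seen.setdefault(s.metabolite, None)
        return list(seen)

    @property
    def n_systems(self) -> int:
        return len(self.systems)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def primary_system(self, metabolite: str) -> SpinSystemDef:
        for s in self.systems:
            if s.metabolite == metabolite and s.primary:
                return s
        raise KeyError(metabolite)

    def systems_of(self, metabolite: str) -> list[SpinSystemDef]:
        return [s for s in self.systems if s.metabolite == metabolite]


def load_panel(path=None) -> MetabolitePanel:
    """Load a panel YAML file; with no path, the shipped default panel."""
    if path is None:
        text = (resources.files("smolesy") / "data" / "panel_default.yml"
                ).read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "panel" not in doc:
        raise PanelConfigError("panel file must contain a top-level 'panel' list")
    systems = []
    for entry in doc["panel"]:
        entry = dict(entry)
        entry["window"] = tuple(entry["window"])
        entry["correlation_refs"] = tuple(entry.get("correlation_refs", ()))
        try:
            systems.append(SpinSystemDef(**entry))
        except TypeError as exc:
            raise PanelConfigError(f"bad panel entry {entry!r}: {exc}") from exc
    return MetabolitePanel(systems)
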