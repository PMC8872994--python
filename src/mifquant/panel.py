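"""Marker panel: the configuration linking markers to fluorophores.

Each marker (CD8, CD68, CD3, FOXP3, CD56, PD-1) is disclosed by one
fluorophore, is scored in one primary cellular compartment (in this panel all
markers are cytoplasmic or membranous, so the compartment is the cytoplasm
ring), and carries dataset-wide rescale bounds (1st/99th percentile) and a
single positivity threshold on the rescaled [0, 1] intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError

COMPARTMENTS = ("ring", "nucleus")


@dataclass
class MarkerDef:
    """One marker's scoring configuration."""

    name: str
    fluorophore: str
    primary_compartment: str = "ring"
    p1: float | None = None
    p99: float | None = None
    threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.primary_compartment not in COMPARTMENTS:
            raise InvalidParameterError(
                f"primary_compartment must be one of {COMPARTMENTS}, "
                f"got {self.primary_compartment!r}"
            )
        if not 0 < self.threshold < 1:
            raise InvalidParameterError("threshold must lie strictly in (0, 1)")
        if self.p1 is not None and self.p99 is not None and not self.p1 < self.p99:
            raise InvalidParameterError("p1 must be < p99")

    @property
    def fitted(self) -> bool:
        return self.p1 is not None and self.p99 is not None


@dataclass
class MarkerPanel:
    """Ordered collection of marker definitions."""

    markers: list[MarkerDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise InvalidParameterError(f"duplicate marker names in panel: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def get(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"no marker named {name!r} in panel")

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {
                "marker": m.name,
                "fluorophore": m.fluorophore,
                "compartment": m.primary_compartment,
                "p1": m.p1,
                "p99": m.p99,
                "threshold": m.threshold,
            }
            for m in self.markers
        ]
        Path(path).write_text(yaml.safe_dump({"panel": data}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            [
                MarkerDef(
                    name=entry["marker"],
                    fluorophore=entry["fluorophore"],
                    primary_compartment=entry.get("compartment", "ring"),
                    p1=entry.get("p1"),
                    p99=entry.get("p99"),
                    threshold=entry.get("threshold", 0.3),
                )
                for entry in raw["panel"]
            ]
        )


def default_panel() -> MarkerPanel:
    """The six-marker immune panel with its fluorophore assignment.

    All six markers are cytoplasmic/membranous, so every primary compartment
    is the 2 um cytoplasm ring.
    """
    assignment = [
        ("CD8", "Opal520"),
        ("CD68", "Opal540"),
        ("CD3", "Opal570"),
        ("FOXP3", "Opal620"),
        ("CD56", "Opal650"),
        ("PD-1", "Opal690"),
    ]
    return MarkerPanel([MarkerDef(name, fluo, "ring") for name, fluo in assignment])
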