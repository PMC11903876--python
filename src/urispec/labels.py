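"""Dichotomization of laboratory marker values into healthy/pathological labels.

Clinical convention decides the direction of each cut-off: elevated
bilirubin, erythrocytes, ketones, leukocytes, nitrite, protein or
urobilinogen is pathological; pH and specific gravity are pathological
outside their reference range ([5, 7.5] and [1.002, 1.04]).  A literal
"pathological if value <= cutoff" rule is available as an override for
parity with tabulations that use that phrasing.  Boundary values count
as healthy.  pH is additionally bifurcated into an acidic and a basic
outcome, pH 7 being neutral (label 0) in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class MarkerDefinition:
    name: str
    scale: str = "quantitative"  # quantitative | ordinal
    cutoff: float | None = None
    range_bounds: tuple[float, float] | None = None
    direction: str = "high_is_pathological"
    source: str = "lab_reference"
    ordinal_levels: tuple[str, ...] = ()
    pathological_levels: frozenset = frozenset()
    caption_rule: bool = False  # literal "pathological iff value <= cutoff"

    def __post_init__(self):
        if (self.cutoff is None) == (self.range_bounds is None):
            raise ConfigurationError(
                f"marker {self.name}: exactly one of cutoff/range_bounds must be set")
        if self.direction == "range":
            if self.range_bounds is None or not self.range_bounds[0] < self.range_bounds[1]:
                raise ConfigurationError(f"marker {self.name}: range needs low < high")
        elif self.range_bounds is not None:
            raise ConfigurationError(
                f"marker {self.name}: range_bounds requires direction='range'")


def dichotomize(values, definition: MarkerDefinition) -> np.ndarray:
    """Binary labels (1 = pathological) aligned to the input order."""
    if definition.scale == "ordinal":
        vals = np.asarray(values, dtype=object)
        known = set(definition.ordinal_levels)
        unknown = sorted({str(v) for v in vals} - {str(k) for k in known})
        if unknown:
            raise ValueError(
                f"marker {definition.name}: unknown ordinal level(s) "
                + ", ".join(unknown))
        patho = {str(p) for p in definition.pathological_levels}
        return np.array([1 if str(v) in patho else 0 for v in vals], dtype=int)

    x = np.asarray(values, dtype=float)
    if definition.caption_rule:
        return (x <= definition.cutoff).astype(int)
    if definition.direction == "high_is_pathological":
        return (x > definition.cutoff).astype(int)
    if definition.direction == "low_is_pathological":
        return (x < definition.cutoff).astype(int)
    if definition.direction == "range":
        lo, hi = definition.range_bounds
        return ((x < lo) | (x > hi)).astype(int)
    raise ConfigurationError(f"marker {definition.name}: unknown direction "
                             f"{definition.direction!r}")


def split_ph(values) -> tuple[np.ndarray, np.ndarray]:
    """Bifurcate pH into acidic (pH < 7) and basic (pH > 7) outcomes.

    pH 7 is neutral: label 0 in both.
    """
    x = np.asarray(values, dtype=float)
    return (x < 7.0).astype(int), (x > 7.0).astype(int)


def _definition_from_dict(name: str, d: dict) -> MarkerDefinition:
    rb = d.get("range_bounds")
    return MarkerDefinition(
        name=name,
        scale=d.get("scale", "quantitative"),
        cutoff=d.get("cutoff"),
        range_bounds=tuple(rb) if rb else None,
        direction=d.get("direction", "high_is_pathological"),
        source=d.get("source", "lab_reference"),
        ordinal_levels=tuple(d.get("ordinal_levels", ())),
        pathological_levels=frozenset(d.get("pathological_levels", ())),
        caption_rule=bool(d.get("caption_rule", False)))


def load_marker_definitions(path=None) -> dict[str, MarkerDefinition]:
    """Marker definitions from YAML; package defaults when no path given."""
    if path is None:
        text = resources.files("urispec").joinpath("data/markers.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _definition_from_dict(name, d) for name, d in raw.items()}
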