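"""The eight schematic trajectory archetypes used by the simulator.

Each archetype is a piecewise-linear template over the differentiation
day grid (−2, 0, 2, 4, 6, 8), normalized so its values span one unit
(the all-constant shape is identically zero).  The canonical ``name`` of
an archetype is exactly what the slope-pattern grammar produces from its
central-difference slope vector; ``figure_label`` carries the looser
descriptive label used when presenting clusters (e.g. "drop-constant").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import label_pattern

__all__ = ["ArchetypeShape", "ARCHETYPES", "DEFAULT_DAYS", "archetype_names"]

DEFAULT_DAYS: tuple[int, ...] = (-2, 0, 2, 4, 6, 8)


@dataclass(frozen=True)
class ArchetypeShape:
    """A unit-amplitude schematic expression trajectory."""

    name: str
    figure_label: str
    template: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        tpl = np.asarray(self.template, dtype=float)
        if tpl.shape != (len(DEFAULT_DAYS),):
            raise ValueError("template must have one value per day of the grid")
        object.__setattr__(self, "template", tpl)
        rng = tpl.max() - tpl.min()
        if rng > 0 and not np.isclose(rng, 1.0):
            raise ValueError("template must be normalized to unit amplitude")
        if self.slope_pattern() != self.name:
            raise ValueError(
                f"template slopes spell {self.slope_pattern()!r}, not {self.name!r}"
            )

    def slopes(self, days: np.ndarray | None = None) -> np.ndarray:
        days = np.asarray(DEFAULT_DAYS if days is None else days, dtype=float)
        return np.gradient(self.template, days)

    def slope_pattern(self, epsilon: float = 1e-6) -> str:
        return label_pattern(self.slopes(), epsilon)

    def values(self, days: np.ndarray) -> np.ndarray:
        """Template evaluated at arbitrary days by linear interpolation."""
        return np.interp(np.asarray(days, dtype=float), DEFAULT_DAYS, self.template)


def _normalized(knots: tuple[float, ...]) -> np.ndarray:
    arr = np.asarray(knots, dtype=float)
    rng = arr.max() - arr.min()
    if rng == 0:
        return np.zeros_like(arr)
    return (arr - arr.min()) / rng


ARCHETYPES: tuple[ArchetypeShape, ...] = (
    ArchetypeShape(
        "rise-fall-rise-fall", "rise-fall-rise-fall", _normalized((0, 1, -0.5, 0.5, 1, 0))
    ),
    ArchetypeShape(
        "rise-constant", "rise-constant/slight decline", _normalized((0, 1, 1, 1, 1, 1))
    ),
    ArchetypeShape("rise", "rise", _normalized((0, 0.2, 0.4, 0.6, 0.8, 1))),
    ArchetypeShape(
        "constant-fall-constant", "constant-fall-constant", _normalized((1, 1, 1, 0, 0, 0))
    ),
    ArchetypeShape("constant", "constant", _normalized((0, 0, 0, 0, 0, 0))),
    ArchetypeShape("fall-constant", "drop-constant", _normalized((1, 0, 0, 0, 0, 0))),
    ArchetypeShape(
        "rise-fall-constant-fall",
        "rise-fall-constant-fall",
        _normalized((0, 1, 0.5, 0.5, 0.5, 0)),
    ),
    ArchetypeShape(
        "rise-constant-fall", "rise-constant-fall", _normalized((0, 1, 1, 1, 1, 0))
    ),
)


def archetype_names() -> list[str]:
    return [a.name for a in ARCHETYPES]


_BY_NAME = {a.name: a for a in ARCHETYPES}


def get_archetype(name: str) -> ArchetypeShape:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown archetype {name!r}; choose from {sorted(_BY_NAME)}")
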