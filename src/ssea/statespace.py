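"""State-space decomposition of 2x2 factorial responses.

A 2x2 sub-design with a shared reference treatment R(0,0) is decomposed into
three coordinates:

* ``f1 = D1(a) = R(a,0) - R(0,0)`` — isolated effect of driver 1,
* ``f2 = D2(b) = R(0,b) - R(0,0)`` — isolated effect of driver 2,
* ``g  = G(a,b) = R(a,b) - A(a,b) - R(0,0)`` with ``A = f1 + f2`` — the
  interactive deviation from the additive expectation.

``g`` is algebraically the interaction contrast of the 2x2 table,
``r11 - r10 - r01 + r00``, and equals four times the interaction coefficient
of a saturated two-way linear model with sum-to-zero coding.  A collection of
experimental units (genotypes, species, females...) then becomes a cloud of
points in the (f1, f2, g) space; responses classified as additive lie on the
g = 0 plane, synergistic and antagonistic responses depart from it in a
direction that depends on the sign of the single-driver effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (
    FactorialDataset,
    MissingCellError,
    ScaleSpec,
    SSEAError,
    transform_scale,
)

__all__ = [
    "CellMeans",
    "StateSpacePoint",
    "ResponseClass",
    "Group2x2",
    "enumerate_2x2_groups",
    "cell_means",
    "decompose",
    "classify_response",
    "statespace_table",
    "points_to_frame",
]


@dataclass(frozen=True)
class Group2x2:
    """One 2x2 sub-design of a multi-level factorial.

    Holds the reference level pair (0,0) and the non-reference pair (a,b);
    the four cells of the group are (0,0), (a,0), (0,b), (a,b).
    """

    reference: tuple[str, str]
    levels: tuple[str, str]

    @property
    def group_id(self) -> str:
        return f"{self.levels[0]}|{self.levels[1]}"

    @property
    def cells(self) -> tuple[tuple[str, str], ...]:
        (r1, r2), (a, b) = self.reference, self.levels
        return ((r1, r2), (a, r2), (r1, b), (a, b))


@dataclass(frozen=True)
class CellMeans:
    """Per-cell mean responses of one 2x2 group on the analysis scale."""

    r00: float
    r10: float
    r01: float
    r11: float
    n00: int = 1
    n10: int = 1
    n01: int = 1
    n11: int = 1
    se00: float = 0.0
    se10: float = 0.0
    se01: float = 0.0
    se11: float = 0.0

    def __post_init__(self) -> None:
        means = (self.r00, self.r10, self.r01, self.r11)
        if not np.all(np.isfinite(means)):
            raise SSEAError(f"non-finite cell mean in {means}")
        if min(self.n00, self.n10, self.n01, self.n11) < 1:
            raise SSEAError("every cell needs at least one replicate")


@dataclass(frozen=True)
class StateSpacePoint:
    """Coordinates of one unit x context x 2x2 group in the state space."""

    f1: float
    f2: float
    g: float
    additive: float
    r00: float
    se_g: float = 0.0
    unit_id: str = ""
    context_id: str = ""
    group_id: str = ""

    @property
    def combined(self) -> float:
        """Combined-treatment effect relative to the reference, r11 - r00."""
        return self.additive + self.g


@dataclass(frozen=True)
class ResponseClass:
    """Categorical response label with the direction metadata behind it."""

    label: str  # additive | synergistic | antagonistic | indeterminate
    single_effect_signs: tuple[str, str]
    g_sign: str
    decision_basis: str
    criterion: float


def enumerate_2x2_groups(
    driver1_levels: Sequence[str],
    driver2_levels: Sequence[str],
    reference: tuple[str, str] | None = None,
) -> list[Group2x2]:
    """Enumerate the 2x2 groups of an m x n design sharing one reference pair.

    Returns ``(m-1)*(n-1)`` groups in driver1-major order.  By default the
    reference is the first declared level of each driver.
    """
    d1 = [str(x) for x in driver1_levels]
    d2 = [str(x) for x in driver2_levels]
    if len(d1) < 2 or len(d2) < 2:
        raise SSEAError("need at least two levels per driver")
    if len(set(d1)) != len(d1) or len(set(d2)) != len(d2):
        raise SSEAError("driver levels must be unique")
    if reference is None:
        reference = (d1[0], d2[0])
    ref1, ref2 = str(reference[0]), str(reference[1])
    if ref1 not in d1:
        raise SSEAError(f"reference level {ref1!r} not among driver-1 levels {d1}")
    if ref2 not in d2:
        raise SSEAError(f"reference level {ref2!r} not among driver-2 levels {d2}")
    return [
        Group2x2(reference=(ref1, ref2), levels=(a, b))
        for a in d1
        if a != ref1
        for b in d2
        if b != ref2
    ]


def cell_means(
    data: FactorialDataset,
    group: Group2x2,
    spec: ScaleSpec = ScaleSpec("raw"),
    unit: str | None = None,
    context: str | None = None,
) -> CellMeans:
    """Mean and standard error of transformed replicate responses per cell.

    Replicate responses are transformed to the analysis scale first and then
    averaged, so the cell means agree with the linear models fitted on
    transformed replicates.  A single-replicate cell gets ``se = 0`` with a
    warning.
    """
    stats = []
    for d1, d2 in group.cells:
        rows = data.cell(d1, d2, unit=unit, context=context)
        if len(rows) == 0:
            where = f" for unit={unit!r}" if unit is not None else ""
            where += f", context={context!r}" if context is not None else ""
            raise MissingCellError(
                f"no replicates in cell (driver1={d1!r}, driver2={d2!r}){where}"
            )
        nt = rows["n_trials"].to_numpy() if "n_trials" in rows.columns else None
        y = transform_scale(rows["response"].to_numpy(), spec, n_trials=nt)
        n = len(y)
        if n == 1:
            warnings.warn(
                f"single replicate in cell ({d1!r}, {d2!r}); standard error set to 0",
                stacklevel=2,
            )
            stats.append((float(y[0]), 1, 0.0))
        else:
            stats.append((float(np.mean(y)), n, float(np.std(y, ddof=1) / np.sqrt(n))))
    (m00, n00, s00), (m10, n10, s10), (m01, n01, s01), (m11, n11, s11) = stats
    return CellMeans(
        r00=m00, r10=m10, r01=m01, r11=m11,
        n00=n00, n10=n10, n01=n01, n11=n11,
        se00=s00, se10=s10, se01=s01, se11=s11,
    )


def decompose(
    means: CellMeans,
    unit_id: str = "",
    context_id: str = "",
    group_id: str = "",
) -> StateSpacePoint:
    """Decompose one 2x2 cell-mean table into state-space coordinates.

    The standard error of g is propagated from the per-cell standard errors
    in quadrature, which assumes the four cells are estimated independently.
    """
    f1 = means.r10 - means.r00
    f2 = means.r01 - means.r00
    additive = f1 + f2
    g = means.r11 - additive - means.r00
    se_g = float(
        np.sqrt(means.se00**2 + means.se10**2 + means.se01**2 + means.se11**2)
    )
    return StateSpacePoint(
        f1=f1, f2=f2, g=g, additive=additive, r00=means.r00, se_g=se_g,
        unit_id=unit_id, context_id=context_id, group_id=group_id,
    )


def _sign(x: float) -> str:
    return "0" if x == 0 else ("+" if x > 0 else "-")


def classify_response(
    point: StateSpacePoint,
    k: float = 1.96,
    p_value: float | None = None,
    alpha: float = 0.05,
) -> ResponseClass:
    """Classify a state-space point as additive, synergistic or antagonistic.

    By default the interval criterion ``|g| <= k * se_g`` decides additivity;
    an externally computed interaction-test p-value (with ``alpha``) can be
    supplied instead.  For non-additive points the label is direction-aware:
    with both single-driver effects positive, g > 0 amplifies the response
    (synergistic) and g < 0 dampens it (antagonistic); with both negative the
    roles reverse (g < 0 amplifies harm).  When the single effects point in
    opposite directions there is no canonical amplification direction, so the
    label compares the magnitude of the combined effect |r11 - r00| with the
    additive expectation |f1 + f2| and the decision basis records the rule.
    """
    signs = (_sign(point.f1), _sign(point.f2))
    g_sign = _sign(point.g)
    if p_value is not None:
        basis, crit = "test", float(alpha)
        is_additive = p_value >= alpha
    else:
        if not np.isfinite(point.se_g):
            raise SSEAError("se_g must be finite for the interval criterion")
        basis, crit = "interval", float(k)
        is_additive = abs(point.g) <= k * point.se_g
    if is_additive or g_sign == "0":
        return ResponseClass("additive", signs, g_sign, basis, crit)
    if "0" in signs:
        return ResponseClass("indeterminate", signs, g_sign, basis, crit)
    if signs[0] == signs[1]:
        if signs[0] == "+":
            label = "synergistic" if point.g > 0 else "antagonistic"
        else:
            label = "synergistic" if point.g < 0 else "antagonistic"
    else:
        label = (
            "synergistic"
            if abs(point.combined) > abs(point.additive)
            else "antagonistic"
        )
        basis += ";opposite-sign-magnitude-rule"
    return ResponseClass(label, signs, g_sign, basis, crit)


def statespace_table(
    data: FactorialDataset,
    spec: ScaleSpec = ScaleSpec("raw"),
    reference: tuple[str, str] | None = None,
) -> list[StateSpacePoint]:
    """Decompose a whole dataset: one point per unit x context x 2x2 group.

    Units and contexts are traversed in order of first appearance and groups
    in driver1-major order, so the output order is deterministic.  Errors for
    missing cells carry the unit and context they occurred in.
    """
    if len(data) == 0:
        return []
    groups = enumerate_2x2_groups(
        data.driver1_levels, data.driver2_levels, reference=reference
    )
    points: list[StateSpacePoint] = []
    for unit in data.units:
        udata = data.subset(unit=unit)
        for context in udata.contexts:
            for grp in groups:
                means = cell_means(data, grp, spec, unit=unit, context=context)
                points.append(
                    decompose(means, unit_id=unit, context_id=context,
                              group_id=grp.group_id)
                )
    return points


def points_to_frame(
    points: Sequence[StateSpacePoint],
    spec: ScaleSpec = ScaleSpec("raw"),
    reference: tuple[str, str] | None = None,
    classify: bool = True,
    k: float = 1.96,
) -> pd.DataFrame:
    """Tabulate state-space points in the exportable CSV layout."""
    ref = "|".join(reference) if reference else ""
    rows = []
    for p in points:
        row = {
            "unit_id": p.unit_id,
            "context_id": p.context_id,
            "group_id": p.group_id,
            "f1": p.f1,
            "f2": p.f2,
            "g": p.g,
            "additive": p.additive,
            "r00": p.r00,
            "se_g": p.se_g,
            "class_label": classify_response(p, k=k).label if classify else "",
            "scale": spec.name,
            "reference": ref,
        }
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "context_id", "group_id", "f1", "f2", "g",
            "additive", "r00", "se_g", "class_label", "scale", "reference",
        ],
    )
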