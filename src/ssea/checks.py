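"""Artifact checks for state-space patterns.

Apparent interactive structure in a state-space plot can be an estimation
artifact: a bounded response analysed on the wrong scale, or noise shared
through the common reference treatment.  Two checks guard against this:

1. test the significance of the 2x2 interaction term directly, and
2. refit the cell means with a sum-to-zero ("zero-sum") coded linear model,
   dropping the interaction when it is not retained — in which case the
   refitted interactive deviation g collapses to 0 exactly and the original
   pattern is flagged as a suspected artifact.

A third screen quantifies the spurious g-vs-f correlations that shared
reference-treatment noise induces even under purely additive truth (with
i.i.d. cell noise and no true effect variation the expected correlation is
-1/sqrt(2), not 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import FactorialDataset, ScaleSpec, SSEAError, transform_scale
from .statespace import (
    CellMeans,
    Group2x2,
    StateSpacePoint,
    cell_means,
    decompose,
    enumerate_2x2_groups,
)

__all__ = [
    "InteractionTestResult",
    "RefitResult",
    "CorrelationScreen",
    "interaction_test",
    "zero_sum_refit",
    "spurious_correlation_screen",
    "artifact_report",
]

_RESID_TOL = 1e-12


@dataclass(frozen=True)
class InteractionTestResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class RefitResult:
    refit_cell_means: CellMeans
    interaction_retained: bool
    recomputed_point: StateSpacePoint
    test: InteractionTestResult
    g_before: float
    artifact_suspected: bool


@dataclass(frozen=True)
class CorrelationScreen:
    corr_g_f1: float
    corr_g_f2: float
    permutation_p_g_f1: float | None
    permutation_p_g_f2: float | None
    n_points: int
    n_permutations: int
    seed: int


def _design_2x2(
    data: FactorialDataset,
    spec: ScaleSpec,
    reference: tuple[str, str] | None = None,
):
    """Transformed responses and +-1 sum-coded design of one 2x2 group.

    The reference levels are coded -1 (defaulting to the first-appearing
    level of each driver), so the coefficient order is intercept, driver1,
    driver2, interaction.
    """
    d1 = data.driver1_levels
    d2 = data.driver2_levels
    if len(d1) != 2 or len(d2) != 2:
        raise SSEAError(
            f"interaction test needs a 2x2 group; got {len(d1)}x{len(d2)} levels"
        )
    if reference is None:
        ref1, ref2 = d1[0], d2[0]
    else:
        ref1, ref2 = str(reference[0]), str(reference[1])
        if ref1 not in d1 or ref2 not in d2:
            raise SSEAError(f"reference {reference!r} not among levels {d1} x {d2}")
    alt1 = next(lv for lv in d1 if lv != ref1)
    alt2 = next(lv for lv in d2 if lv != ref2)
    df = data.df
    nt = df["n_trials"].to_numpy() if "n_trials" in df.columns else None
    y = transform_scale(df["response"].to_numpy(), spec, n_trials=nt)
    x1 = np.where(df["driver1"].to_numpy() == ref1, -1.0, 1.0)
    x2 = np.where(df["driver2"].to_numpy() == ref2, -1.0, 1.0)
    X = np.column_stack([np.ones_like(x1), x1, x2, x1 * x2])
    return y, X, ((ref1, alt1), (ref2, alt2))


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def interaction_test(
    data: FactorialDataset,
    spec: ScaleSpec = ScaleSpec("raw"),
    alpha: float = 0.05,
) -> InteractionTestResult:
    """F-test of the interaction term in one 2x2 group.

    Fits the two-way fixed-effects linear model with interaction on the
    transformed replicate responses and tests the interaction by the Type II
    sum of squares (residual improvement over the main-effects model), which
    is invariant to factor order also in unbalanced designs.  Data with zero
    residual variance return F = 0, p = 1 with a warning.
    """
    y, X, _ = _design_2x2(data, spec)
    n = len(y)
    df_den = n - 4
    if df_den < 1:
        raise SSEAError(
            "zero residual degrees of freedom: the interaction test needs "
            "more than one replicate in at least one cell"
        )
    sse_full = _sse(X, y)
    sse_main = _sse(X[:, :3], y)
    ss_int = max(sse_main - sse_full, 0.0)
    scale = max(float(np.mean(y**2)), 1.0)
    if sse_full <= _RESID_TOL * scale:
        if ss_int <= _RESID_TOL * scale:
            warnings.warn(
                "no residual variance and no interaction signal; "
                "returning F = 0, p = 1",
                stacklevel=2,
            )
            return InteractionTestResult(0.0, 1, df_den, 1.0, alpha)
        warnings.warn(
            "zero residual variance with a nonzero interaction contrast; "
            "returning F = inf, p = 0",
            stacklevel=2,
        )
        return InteractionTestResult(float("inf"), 1, df_den, 0.0, alpha)
    f = (ss_int / 1.0) / (sse_full / df_den)
    p = float(stats.f.sf(f, 1, df_den))
    return InteractionTestResult(float(f), 1, df_den, p, alpha)


def zero_sum_refit(
    data: FactorialDataset,
    spec: ScaleSpec = ScaleSpec("raw"),
    alpha: float = 0.05,
    reference: tuple[str, str] | None = None,
    unit_id: str = "",
    context_id: str = "",
    group_id: str = "",
) -> RefitResult:
    """Zero-sum recode and model-based recomputation of the cell means.

    The saturated two-way model with sum-to-zero (+-1) coding is fitted to
    the replicate data.  If the interaction term fails the alpha-level test
    it is dropped and the cell means are recomputed from the main-effects
    fit; the state-space point rebuilt from those fitted means then has g = 0
    exactly (the main-effects model has no interaction contrast), and the
    original pattern is flagged as a suspected artifact.
    """
    test = interaction_test(data, spec, alpha=alpha)
    y, X, ((ref1, alt1), (ref2, alt2)) = _design_2x2(data, spec, reference=reference)
    grp = Group2x2(reference=(ref1, ref2), levels=(alt1, alt2))
    observed = cell_means(data, grp, spec)
    before = decompose(observed, unit_id, context_id, group_id or grp.group_id)

    if test.significant:
        point = decompose(observed, unit_id, context_id, group_id or grp.group_id)
        return RefitResult(
            refit_cell_means=observed,
            interaction_retained=True,
            recomputed_point=point,
            test=test,
            g_before=before.g,
            artifact_suspected=False,
        )

    Xm = X[:, :3]
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    n = len(y)
    sigma2 = _sse(Xm, y) / max(n - 3, 1)
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    # cell rows in (0,0), (a,0), (0,b), (a,b) order with -1 = reference coding
    cell_rows = np.array(
        [[1, -1, -1], [1, 1, -1], [1, -1, 1], [1, 1, 1]], dtype=float
    )
    fitted = cell_rows @ beta
    ses = np.sqrt(np.einsum("ij,jk,ik->i", cell_rows, xtx_inv, cell_rows) * sigma2)
    refit = CellMeans(
        r00=float(fitted[0]), r10=float(fitted[1]),
        r01=float(fitted[2]), r11=float(fitted[3]),
        n00=observed.n00, n10=observed.n10, n01=observed.n01, n11=observed.n11,
        se00=float(ses[0]), se10=float(ses[1]),
        se01=float(ses[2]), se11=float(ses[3]),
    )
    point = decompose(refit, unit_id, context_id, group_id or grp.group_id)
    if abs(point.g) > 1e-10 * max(1.0, abs(refit.r00)):
        raise AssertionError("main-effects refit produced a nonzero g")
    # g is structurally zero under the main-effects model; remove float dust
    point = StateSpacePoint(
        f1=point.f1, f2=point.f2, g=0.0, additive=point.additive,
        r00=point.r00, se_g=0.0, unit_id=point.unit_id,
        context_id=point.context_id, group_id=point.group_id,
    )
    return RefitResult(
        refit_cell_means=refit,
        interaction_retained=False,
        recomputed_point=point,
        test=test,
        g_before=before.g,
        artifact_suspected=True,
    )


def spurious_correlation_screen(
    points: Sequence[StateSpacePoint],
    n_permutations: int = 999,
    seed: int = 0,
) -> CorrelationScreen:
    """Screen a point collection for g-vs-f correlations.

    Pearson correlations of g with f1 and with f2 across points, with
    two-sided permutation p-values obtained by shuffling g against the
    (f1, f2) pairs using a seeded generator.  Degenerate (zero-variance)
    coordinates yield a correlation of 0 with a warning.  With
    ``n_permutations = 0`` only the correlations are computed.
    """
    if len(points) < 3:
        raise SSEAError("need at least 3 points for the correlation screen")
    g = np.array([p.g for p in points])
    f1 = np.array([p.f1 for p in points])
    f2 = np.array([p.f2 for p in points])

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(
                "zero variance in a screened coordinate; correlation set to 0",
                stacklevel=3,
            )
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r1, r2 = corr(g, f1), corr(g, f2)
    p1 = p2 = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits1 = hits2 = 0
        for _ in range(n_permutations):
            gp = rng.permutation(g)
            if abs(corr(gp, f1)) >= abs(r1) - 1e-12:
                hits1 += 1
            if abs(corr(gp, f2)) >= abs(r2) - 1e-12:
                hits2 += 1
        p1 = (1 + hits1) / (1 + n_permutations)
        p2 = (1 + hits2) / (1 + n_permutations)
    return CorrelationScreen(
        corr_g_f1=r1, corr_g_f2=r2,
        permutation_p_g_f1=p1, permutation_p_g_f2=p2,
        n_points=len(points), n_permutations=n_permutations, seed=seed,
    )


def artifact_report(
    data: FactorialDataset,
    spec: ScaleSpec = ScaleSpec("raw"),
    alpha: float = 0.05,
    reference: tuple[str, str] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Run interaction test + zero-sum refit per unit x context x 2x2 group.

    Returns one row per group with the F statistic, p-value, whether the
    interaction was retained, and g before/after the refit.  With
    ``bh_adjust`` a Benjamini-Hochberg flag column across all groups is
    appended (off by default; the per-group decisions are not corrected).
    """
    groups = enumerate_2x2_groups(
        data.driver1_levels, data.driver2_levels, reference=reference
    )
    rows = []
    for unit in data.units:
        udata = data.subset(unit=unit)
        for context in udata.contexts:
            cdata = udata.subset(context=context)
            for grp in groups:
                sub = cdata.subset(
                    driver_levels=(
                        {grp.reference[0], grp.levels[0]},
                        {grp.reference[1], grp.levels[1]},
                    )
                )
                res = zero_sum_refit(
                    sub, spec, alpha=alpha, reference=grp.reference,
                    unit_id=unit, context_id=context, group_id=grp.group_id,
                )
                rows.append(
                    {
                        "unit_id": unit,
                        "context_id": context,
                        "group_id": grp.group_id,
                        "f_statistic": res.test.f_statistic,
                        "p_value": res.test.p_value,
                        "interaction_retained": res.interaction_retained,
                        "g_before": res.g_before,
                        "g_after": res.recomputed_point.g,
                        "artifact_suspected": res.artifact_suspected,
                    }
                )
    report = pd.DataFrame(rows)
    if bh_adjust and len(report):
        from statsmodels.stats.multitest import multipletests

        flag, p_adj, *_ = multipletests(
            report["p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        report["p_value_bh"] = p_adj
        report["significant_bh"] = flag
    return report
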