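"""Backward model selection over factorial fixed-effects models.

Models are Gaussian linear models on the transformed response, fitted by
maximum likelihood over sets of categorical factor terms (main effects and
interactions, respecting marginality).  Selection walks backwards from a full
model: each removable highest-order term is tried, and a simpler model is
retained against the current one by a hybrid rule — the simple model wins
outright when its small-sample-corrected AIC (AICc) is lowest; otherwise the
complex model wins when its AICc advantage exceeds 3, and a likelihood-ratio
test at the 0.05 level decides the remaining close calls.

The module also implements the two-criterion detector for a "heatwave
effect" in a temperature-regime x temperature-level design: (1) the
regime-by-level interaction is retained and the sharp-increase/high-mean
treatment (T4) differs from both the gradual-increase (T2) and the
constant-high (T3) treatments; (2) mortality is concentrated after the
temperature increase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .dataset import FactorialDataset, ScaleSpec, SSEAError, transform_scale

__all__ = [
    "Term",
    "ModelSpec",
    "FitResult",
    "StepRecord",
    "SelectionTrace",
    "HeatwaveVerdict",
    "aicc",
    "fit_linear_model",
    "compare_pair",
    "backward_select",
    "detect_heatwave_effect",
]

#: a model term is a frozenset of factor names, e.g. {"regime", "level"}
Term = frozenset


def _term_label(term: Term, order: Sequence[str]) -> str:
    names = sorted(term, key=lambda f: (order.index(f) if f in order else 99, f))
    return ":".join(names)


@dataclass(frozen=True)
class ModelSpec:
    """A set of factor terms plus the analysis scale.

    ``factors`` fixes a deterministic factor order for labels and formulas;
    ``terms`` must respect marginality (every margin of an included
    interaction is itself included).
    """

    factors: tuple[str, ...]
    terms: frozenset[Term]
    scale: ScaleSpec = ScaleSpec("raw")

    def __post_init__(self) -> None:
        for t in self.terms:
            if not t or not t <= set(self.factors):
                raise SSEAError(f"term {set(t)} uses undeclared factors")
            for f in t:
                for sub in (t - {f},):
                    if sub and sub not in self.terms:
                        raise SSEAError(
                            f"model hierarchy violated: {set(t)} present "
                            f"without its margin {set(sub)}"
                        )

    @classmethod
    def full_factorial(
        cls, factors: Sequence[str], scale: ScaleSpec = ScaleSpec("raw"),
        max_order: int | None = None,
    ) -> "ModelSpec":
        """All main effects and interactions up to ``max_order``."""
        from itertools import combinations

        factors = tuple(factors)
        hi = max_order or len(factors)
        terms = frozenset(
            Term(c) for r in range(1, hi + 1) for c in combinations(factors, r)
        )
        return cls(factors=factors, terms=terms, scale=scale)

    def drop(self, term: Term) -> "ModelSpec":
        return ModelSpec(self.factors, frozenset(self.terms - {term}), self.scale)

    def removable_terms(self) -> list[Term]:
        """Terms that are not a margin of any other included term."""
        out = [
            t for t in self.terms
            if not any(t < other for other in self.terms)
        ]
        return sorted(out, key=lambda t: _term_label(t, self.factors))

    def formula(self, response: str = "_y") -> str:
        if not self.terms:
            return f"{response} ~ 1"
        labels = [
            ":".join(f"C({f})" for f in sorted(
                t, key=lambda f: self.factors.index(f)))
            for t in sorted(self.terms, key=lambda t: (len(t), _term_label(t, self.factors)))
        ]
        return f"{response} ~ " + " + ".join(labels)

    def term_labels(self) -> list[str]:
        return sorted(
            (_term_label(t, self.factors) for t in self.terms),
            key=lambda s: (s.count(":"), s),
        )


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood Gaussian fit of one model."""

    model: ModelSpec
    loglik: float
    k: int  # mean parameters + 1 for the residual variance
    n: int
    fitted: np.ndarray
    aicc: float


@dataclass(frozen=True)
class StepRecord:
    simple_terms: tuple[str, ...]
    complex_terms: tuple[str, ...]
    aicc_simple: float
    aicc_complex: float
    delta_aicc: float
    lrt_p: float | None
    retained: str  # "simple" | "complex"


@dataclass
class SelectionTrace:
    steps: list[StepRecord] = field(default_factory=list)
    final_terms: frozenset[Term] = frozenset()
    final_model: ModelSpec | None = None
    final_aicc: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "simple": " + ".join(s.simple_terms) or "1",
                    "complex": " + ".join(s.complex_terms),
                    "aicc_simple": s.aicc_simple,
                    "aicc_complex": s.aicc_complex,
                    "delta_aicc": s.delta_aicc,
                    "lrt_p": s.lrt_p,
                    "retained": s.retained,
                }
                for s in self.steps
            ]
        )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1)``; undefined for ``n <= k+1``.
    """
    if k < 1 or n < 1:
        raise SSEAError("k and n must be positive")
    if n <= k + 1:
        raise SSEAError(
            f"AICc undefined for n={n} <= k+1={k + 1} (too few observations)"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_linear_model(
    data: FactorialDataset | pd.DataFrame,
    model: ModelSpec,
    response: str = "response",
) -> FitResult:
    """Fit a fixed-effects Gaussian linear model by maximum likelihood.

    The response is transformed to ``model.scale`` first (using a per-row
    ``n_trials`` column when present).  The reported log-likelihood uses the
    ML variance estimate, and ``k`` counts the mean parameters plus the
    residual variance, as required by the information criteria.
    """
    df = data.df if isinstance(data, FactorialDataset) else data
    df = df.copy()
    nt = df["n_trials"].to_numpy() if "n_trials" in df.columns else None
    df["_y"] = transform_scale(df[response].to_numpy(dtype=float), model.scale, nt)
    res = smf.ols(model.formula("_y"), data=df).fit()
    exog = res.model.exog
    rank = int(np.linalg.matrix_rank(exog))
    if rank < exog.shape[1]:
        raise SSEAError(
            f"rank-deficient design ({rank} < {exog.shape[1]} columns) for "
            f"terms {model.term_labels()}; some terms are confounded"
        )
    n = int(res.nobs)
    k = exog.shape[1] + 1
    return FitResult(
        model=model,
        loglik=float(res.llf),
        k=k,
        n=n,
        fitted=np.asarray(res.fittedvalues),
        aicc=aicc(float(res.llf), k, n),
    )


def compare_pair(
    simple: FitResult,
    complex: FitResult,
    delta_threshold: float = 3.0,
    alpha: float = 0.05,
) -> StepRecord:
    """Retain one of two nested models by the AICc / likelihood-ratio rule.

    The simple model is retained when its AICc is lowest.  Otherwise the
    AICc difference decides: above ``delta_threshold`` the complex model is
    retained outright; at or below it a chi-square likelihood-ratio test is
    run and the complex model is retained when p < ``alpha``.
    """
    if not simple.model.terms <= complex.model.terms or (
        simple.model.terms == complex.model.terms
    ):
        raise SSEAError("compare_pair requires simple strictly nested in complex")
    delta = simple.aicc - complex.aicc
    lrt_p: float | None = None
    if simple.aicc <= complex.aicc:
        retained = "simple"
    elif delta > delta_threshold:
        retained = "complex"
    else:
        lrt = max(2.0 * (complex.loglik - simple.loglik), 0.0)
        df = complex.k - simple.k
        if df < 1:
            raise SSEAError("complex model adds no parameters")
        lrt_p = float(stats.chi2.sf(lrt, df))
        retained = "complex" if lrt_p < alpha else "simple"
    order = simple.model.factors
    return StepRecord(
        simple_terms=tuple(simple.model.term_labels()),
        complex_terms=tuple(complex.model.term_labels()),
        aicc_simple=simple.aicc,
        aicc_complex=complex.aicc,
        delta_aicc=delta,
        lrt_p=lrt_p,
        retained=retained,
    )


def backward_select(
    data: FactorialDataset | pd.DataFrame,
    full_model: ModelSpec,
    response: str = "response",
    delta_threshold: float = 3.0,
    alpha: float = 0.05,
) -> SelectionTrace:
    """Backward elimination from a full factorial model.

    Each round proposes dropping every currently removable (highest-order,
    hierarchy-respecting) term, orders the candidates by the AICc of the
    reduced model (ties broken by term label), and adopts the first drop the
    AICc/LRT rule retains.  Selection stops when no drop is retained or only
    the intercept remains; every comparison is recorded in the trace.
    """
    trace = SelectionTrace()
    current = fit_linear_model(data, full_model, response=response)
    while True:
        candidates = []
        for term in current.model.removable_terms():
            reduced = fit_linear_model(data, current.model.drop(term), response=response)
            candidates.append((reduced.aicc, _term_label(term, full_model.factors), reduced))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        adopted = None
        for _, _, reduced in candidates:
            step = compare_pair(
                reduced, current, delta_threshold=delta_threshold, alpha=alpha
            )
            trace.steps.append(step)
            if step.retained == "simple":
                adopted = reduced
                break
        if adopted is None:
            break
        current = adopted
        if not current.model.terms:
            break
    trace.final_terms = current.model.terms
    trace.final_model = current.model
    trace.final_aicc = current.aicc
    return trace


@dataclass(frozen=True)
class HeatwaveVerdict:
    criterion1_met: bool
    criterion2_met: bool | None
    fraction_deaths_after_increase: float | None
    verdict: bool
    interaction_retained: bool
    p_t4_vs_t2: float
    p_t4_vs_t3: float


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        raise SSEAError("contrasts need at least two replicates per treatment")
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def detect_heatwave_effect(
    data: FactorialDataset,
    trace: SelectionTrace,
    timing: pd.DataFrame | None = None,
    increase_day: int = 2,
    threshold: float = 0.5,
    alpha: float = 0.05,
    scale: ScaleSpec | None = None,
    regime_factor: str = "regime",
    level_factor: str = "level",
    treatment_col: str = "treatment",
    heatwave_labels: tuple[str, str, str] = ("T4", "T2", "T3"),
) -> HeatwaveVerdict:
    """Apply the two-criterion heatwave-effect rule.

    Criterion 1: a retained term couples temperature regime and temperature
    level (the interaction defining the heatwave), and Welch t contrasts on
    transformed replicate responses show the heatwave treatment (T4)
    differing from both the gradual-increase (T2) and constant-high (T3)
    treatments at ``alpha``.  Criterion 2: the fraction of deaths occurring
    on or after ``increase_day`` (day the temperature step is applied)
    exceeds ``threshold`` ("primarily after the increase").  The verdict is
    true only when both criteria hold; missing timing records leave
    criterion 2 unknown and the verdict false, with a warning.
    """
    if scale is None:
        scale = trace.final_model.scale if trace.final_model else ScaleSpec("raw")
    pair = {regime_factor, level_factor}
    interaction_retained = any(pair <= set(t) for t in trace.final_terms)

    t4, t2, t3 = heatwave_labels
    df = data.df
    if treatment_col not in df.columns:
        raise SSEAError(f"column {treatment_col!r} not found in dataset")

    def _resp(label: str) -> np.ndarray:
        sub = df[df[treatment_col] == label]
        if len(sub) == 0:
            raise SSEAError(f"no rows for treatment {label!r}")
        nt = sub["n_trials"].to_numpy() if "n_trials" in sub.columns else None
        return transform_scale(sub["response"].to_numpy(), scale, nt)

    y4 = _resp(t4)
    p42 = _welch_p(y4, _resp(t2))
    p43 = _welch_p(y4, _resp(t3))
    criterion1 = bool(interaction_retained and p42 < alpha and p43 < alpha)

    criterion2: bool | None
    fraction: float | None
    if timing is None or len(timing) == 0:
        warnings.warn(
            "no death-timing records: criterion 2 unknown, verdict false",
            stacklevel=2,
        )
        criterion2, fraction = None, None
        verdict = False
    else:
        t = timing
        if treatment_col in t.columns:
            t = t[t[treatment_col] == t4]
        if len(t) == 0:
            warnings.warn(
                f"no deaths recorded for {t4!r}: criterion 2 unknown",
                stacklevel=2,
            )
            criterion2, fraction = None, None
            verdict = False
        else:
            days = t["death_day"].to_numpy(dtype=float)
            fraction = float(np.mean(days >= increase_day))
            criterion2 = bool(fraction > threshold)
            verdict = bool(criterion1 and criterion2)
    return HeatwaveVerdict(
        criterion1_met=criterion1,
        criterion2_met=criterion2,
        fraction_deaths_after_increase=fraction,
        verdict=verdict,
        interaction_retained=interaction_retained,
        p_t4_vs_t2=p42,
        p_t4_vs_t3=p43,
    )
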