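"""Scheffe mixture-polynomial modelling of solute-composition effects.

Each state-diagram quantity (Tgs, K, E, B, Tg', Tm', ws') is regressed
on the six dry-basis solute fractions with a Scheffe-type polynomial:
six linear blending terms plus up to fifteen pairwise blending
(interaction) products, and *no intercept* -- on the simplex the linear
terms absorb the constant, and a vertex prediction equals that
component's linear coefficient.

Model reduction is backward elimination: interaction terms whose
coefficient t-test p-value exceeds ``alpha`` (default 0.10) are dropped
one at a time, worst first, refitting after each drop.  Linear terms are
always retained.

Regression ANOVA is reported about the response mean even though the
model has no intercept (sd = sqrt(SSE/(n-p)); R^2 = 1 - SSE/SST;
CV% = 100*sd/|mean|; F with df (p-1, n-p)), which is how mixture-design
software conventionally summarises Scheffe fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr as scipy_qr

from .core_models import (
    ChenParams,
    Composition,
    DomainError,
    GordonTaylorParams,
    StateDiagram,
)
from .state_diagram import MFCC

__all__ = [
    "LINEAR_TERMS",
    "INTERACTION_TERMS",
    "ALL_TERMS",
    "RESPONSE_NAMES",
    "MixtureDesign",
    "AnovaStats",
    "MixtureModel",
    "design_matrix",
    "fit_mixture_model",
    "anova_stats",
    "prune_model",
    "predict_response",
    "predict_state_diagram",
]

_LETTER_TO_FIELD = {"F": "xf", "G": "xg", "S": "xs", "P": "xp", "A": "xa", "M": "xm"}

LINEAR_TERMS: tuple[str, ...] = ("XF", "XG", "XS", "XP", "XA", "XM")
#: Pairwise products in the canonical a7..a21 ordering.
INTERACTION_TERMS: tuple[str, ...] = (
    "XFXG", "XFXS", "XFXP", "XFXA", "XFXM",
    "XGXS", "XGXP", "XGXA", "XGXM",
    "XSXP", "XSXA", "XSXM",
    "XPXA", "XPXM", "XAXM",
)
ALL_TERMS: tuple[str, ...] = LINEAR_TERMS + INTERACTION_TERMS

RESPONSE_NAMES: tuple[str, ...] = ("tgs", "k", "e", "b", "tg_prime", "tm_prime", "ws_prime")


def _term_columns(term: str) -> tuple[str, ...]:
    """Composition field names entering a term ('XFXM' -> ('xf', 'xm'))."""
    if term in LINEAR_TERMS:
        return (_LETTER_TO_FIELD[term[1]],)
    if term in INTERACTION_TERMS:
        return (_LETTER_TO_FIELD[term[1]], _LETTER_TO_FIELD[term[3]])
    raise ValueError(f"unknown term label {term!r}; expected one of the 21 "
                     "Scheffe terms (XF..XM, XFXG..XAXM)")


@dataclass(frozen=True)
class MixtureDesign:
    """An experimental design over the six-component simplex."""

    runs: tuple[tuple[int, Composition], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "runs", tuple(self.runs))

    def __len__(self) -> int:
        return len(self.runs)

    def component_matrix(self) -> np.ndarray:
        """(n_runs x 6) array of fractions ordered XF, XG, XS, XP, XA, XM."""
        return np.array([comp.as_tuple() for _, comp in self.runs], dtype=float)


@dataclass(frozen=True)
class AnovaStats:
    """Regression ANOVA summary: F-test p, R^2, residual SD and CV%."""

    p_value: float
    r_squared: float
    sd: float
    cv_percent: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.cv_percent < 0:
            raise ValueError("sd and cv_percent must be non-negative")


@dataclass(frozen=True)
class MixtureModel:
    """A (possibly pruned) Scheffe polynomial for one response."""

    response_name: str
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    anova: Optional[AnovaStats] = None
    coef_pvalues: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.coefficients):
            raise ValueError("one coefficient per term is required")
        for t in self.terms:
            _term_columns(t)  # validates labels
        missing = [t for t in LINEAR_TERMS if t not in self.terms]
        if missing:
            raise ValueError(f"linear terms are always present; missing {missing}")

    def coef(self, term: str) -> float:
        return self.coefficients[self.terms.index(term)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coefficients))


def design_matrix(design: MixtureDesign, terms: Sequence[str]) -> np.ndarray:
    """(n_runs x n_terms) Scheffe design matrix; never an intercept column."""
    comp = design.component_matrix()
    cols = []
    field_idx = {f: i for i, f in enumerate(("xf", "xg", "xs", "xp", "xa", "xm"))}
    for term in terms:
        fields = _term_columns(term)
        col = np.ones(comp.shape[0])
        for f in fields:
            col = col * comp[:, field_idx[f]]
        cols.append(col)
    return np.column_stack(cols)


def anova_stats(
    fitted: np.ndarray, responses: Sequence[float], n_terms: int
) -> AnovaStats:
    """ANOVA of a no-intercept fit, with sums of squares about the mean."""
    y = np.asarray(responses, dtype=float)
    n, p = y.size, n_terms
    if n <= p:
        raise ValueError(f"need n > p for residual df; got n={n}, p={p}")
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("responses have zero variance; ANOVA undefined")
    sd = float(np.sqrt(sse / (n - p)))
    r2 = 1.0 - sse / sst
    cv = 100.0 * sd / abs(float(y.mean()))
    ssr = sst - sse
    if p > 1 and sse > 0.0:
        f_stat = (ssr / (p - 1)) / (sse / (n - p))
        p_value = float(stats.f.sf(f_stat, p - 1, n - p))
    else:
        p_value = 0.0  # saturated or perfect fit
    return AnovaStats(p_value=p_value, r_squared=r2, sd=sd, cv_percent=cv)


def fit_mixture_model(
    design: MixtureDesign,
    responses: Sequence[float],
    terms: Sequence[str] = ALL_TERMS,
    response_name: str = "response",
) -> MixtureModel:
    """No-intercept OLS of ``responses`` on the requested Scheffe terms."""
    y = np.asarray(responses, dtype=float)
    terms = tuple(terms)
    if y.size != len(design):
        raise ValueError("one response per design run is required")
    if y.size < len(terms):
        raise ValueError(
            f"underdetermined: {y.size} runs for {len(terms)} terms"
        )
    x = design_matrix(design, terms)
    rank = np.linalg.matrix_rank(x)
    if rank < len(terms):
        # pivoted QR puts the most nearly dependent columns last
        _, _, piv = scipy_qr(x, mode="economic", pivoting=True)
        dependent = [terms[i] for i in piv[rank:]]
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {len(terms)}); "
            f"collinear terms likely among {dependent}"
        )
    res = sm.OLS(y, x).fit()
    anova = anova_stats(np.asarray(res.fittedvalues), y, len(terms))
    return MixtureModel(
        response_name=response_name,
        terms=terms,
        coefficients=tuple(float(c) for c in res.params),
        anova=anova,
        coef_pvalues=tuple(float(p) for p in res.pvalues),
    )


def prune_model(
    design: MixtureDesign,
    responses: Sequence[float],
    alpha: float = 0.10,
    response_name: str = "response",
    terms: Sequence[str] = ALL_TERMS,
) -> MixtureModel:
    """Backward elimination of non-significant interaction terms.

    Repeatedly drops the interaction with the largest coefficient
    p-value above ``alpha`` and refits; linear blending terms are never
    candidates.  With ``alpha=1`` the full model is returned unchanged.
    """
    current = tuple(terms)
    model = fit_mixture_model(design, responses, current, response_name)
    while True:
        candidates = [
            (p, t)
            for t, p in zip(model.terms, model.coef_pvalues)
            if t in INTERACTION_TERMS and p > alpha
        ]
        if not candidates:
            return model
        _, worst = max(candidates)
        current = tuple(t for t in model.terms if t != worst)
        model = fit_mixture_model(design, responses, current, response_name)


def predict_response(
    model: MixtureModel, composition: Composition
) -> float:
    """Evaluate the Scheffe polynomial at one composition."""
    values = composition.as_dict()
    total = 0.0
    for term, coef in zip(model.terms, model.coefficients):
        v = 1.0
        for f in _term_columns(term):
            v *= values[f]
        total += coef * v
    return total


def _blend_with_maltodextrin(base: Composition, xm: float) -> Composition:
    """Scale the base (maltodextrin-free) fractions by (1-xm), set XM=xm."""
    if base.xm != 0.0:
        raise ValueError("base composition must have a zero maltodextrin fraction")
    if not (0.0 <= xm < 1.0):
        raise DomainError(f"maltodextrin fraction xm={xm!r} outside [0, 1)")
    s = 1.0 - xm
    return Composition(
        xf=base.xf * s, xg=base.xg * s, xs=base.xs * s,
        xp=base.xp * s, xa=base.xa * s, xm=xm,
        sum_tol=max(base.sum_tol, 1e-6),
    )


def predict_state_diagram(
    base: Composition,
    xm: float,
    models: Mapping[str, MixtureModel],
) -> StateDiagram:
    """Predict a full state diagram for a juice base blended with maltodextrin.

    ``base`` is a maltodextrin-free composition; its fractions are scaled
    by (1 - xm) -- the only convention that preserves the base solute
    ratios while keeping the fractions on the simplex -- and the seven
    composition models are evaluated to assemble Gordon--Taylor
    parameters, Chen parameters and the MFCC.  The MFCC here is a model
    prediction, not a curve intersection, so exact consistency between
    the predicted Tm' and the predicted freezing curve is not imposed.
    """
    missing = [r for r in RESPONSE_NAMES if r not in models]
    if missing:
        raise ValueError(f"models missing for responses: {missing}")
    comp = _blend_with_maltodextrin(base, xm)
    pred = {name: predict_response(models[name], comp) for name in RESPONSE_NAMES}
    return StateDiagram(
        composition=comp,
        gt=GordonTaylorParams(tgs=pred["tgs"], k=pred["k"]),
        chen=ChenParams(e=pred["e"], b=pred["b"]),
        mfcc=MFCC(
            tg_prime=pred["tg_prime"],
            tm_prime=pred["tm_prime"],
            ws_prime=pred["ws_prime"],
        ),
    )
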