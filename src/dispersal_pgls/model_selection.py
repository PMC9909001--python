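"""All-subsets PGLS model comparison and multimodel inference.

Candidate models are every subset of main effects up to a variable cap,
optionally augmented with pairwise interactions between continuous and
binary predictors (marginality enforced: an interaction enters only with
both main effects present).  Models are ranked by AICc; Akaike weights give
relative model probabilities, from which 95% confidence model sets,
per-variable importance (summed weights of models containing the variable)
and model-averaged coefficients follow.  Generalized variance inflation
factors diagnose predictor collinearity, with the Fox-Monette
dimensionality correction GVIF^(1/(2 df)) for multi-level predictors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import PGLSFit, pgls_ml

__all__ = [
    "PredictorSpec",
    "Design",
    "ModelFormula",
    "ModelSet",
    "GVIFReport",
    "prepare_design",
    "enumerate_models",
    "build_model_matrix",
    "fit_models",
    "rank_models",
    "confidence_set",
    "variable_importance",
    "model_average",
    "gvif",
]


@dataclass(frozen=True)
class PredictorSpec:
    """How one predictor enters the design.

    Continuous predictors may be natural-log transformed (for right-skewed
    quantities like population size or mass) and are z-scored by default so
    coefficients are comparable.  Categorical predictors expand to
    reference-coded indicators; the reference level is configurable (the
    habitat contrasts here use "coasts" as reference).
    """

    name: str
    role: str = "continuous"  # continuous | binary | categorical
    levels: tuple[str, ...] = ()
    log_transform: bool = False
    standardize: bool = True
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.role not in {"continuous", "binary", "categorical"}:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.role == "categorical" and len(self.levels) < 2:
            raise ValueError(f"{self.name}: categorical predictor needs >= 2 levels")
        if self.role != "continuous" and (self.log_transform or not self.standardize):
            if self.log_transform:
                raise ValueError(
                    f"{self.name}: transform flags apply to continuous predictors only"
                )

    @property
    def df(self) -> int:
        """Degrees of freedom (indicator columns) this predictor occupies."""
        return len(self.levels) - 1 if self.role == "categorical" else 1


@dataclass
class Design:
    """Prepared predictor matrix plus bookkeeping.

    ``X`` holds one column per continuous/binary predictor and one indicator
    column per non-reference categorical level; ``column_groups`` maps each
    predictor name to its columns; ``dropped`` lists row keys removed for
    missing values.
    """

    X: pd.DataFrame
    column_groups: dict[str, list[str]]
    specs: dict[str, PredictorSpec]
    dropped: list[str] = field(default_factory=list)

    @property
    def predictors(self) -> list[str]:
        return list(self.column_groups)


def prepare_design(
    trait_table: pd.DataFrame, specs: Sequence[PredictorSpec]
) -> Design:
    """Transform raw trait columns into a regression-ready design.

    Rows with missing values in any used column are dropped (and recorded),
    mirroring the attrition that occurs when trait coverage is incomplete.
    Continuous predictors are log-transformed where flagged and then
    standardized to mean 0, sd 1 (sample sd, n-1 denominator).
    """
    used = [s.name for s in specs]
    missing_cols = [c for c in used if c not in trait_table.columns]
    if missing_cols:
        raise ValueError(f"trait table missing predictor columns: {missing_cols}")

    mask = trait_table[used].notna().all(axis=1)
    dropped = list(trait_table.index[~mask].astype(str))
    table = trait_table.loc[mask]

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for spec in specs:
        raw = table[spec.name]
        if spec.role == "continuous":
            x = raw.to_numpy(dtype=float)
            if spec.log_transform:
                if (x <= 0).any():
                    raise ValueError(
                        f"{spec.name}: non-positive values under log transform"
                    )
                x = np.log(x)
            if spec.standardize:
                sd = x.std(ddof=1)
                if sd == 0:
                    raise ValueError(f"{spec.name}: zero variance")
                x = (x - x.mean()) / sd
            elif x.std(ddof=1) == 0:
                raise ValueError(f"{spec.name}: zero variance")
            cols[spec.name] = x
            groups[spec.name] = [spec.name]
        elif spec.role == "binary":
            x = raw.astype(bool).to_numpy(dtype=float)
            if x.std(ddof=1) == 0:
                raise ValueError(f"{spec.name}: zero variance")
            cols[spec.name] = x
            groups[spec.name] = [spec.name]
        else:
            observed = set(raw.astype(str))
            unknown = observed - set(spec.levels)
            if unknown:
                raise ValueError(f"{spec.name}: unknown levels {sorted(unknown)}")
            ref = spec.reference or sorted(spec.levels)[0]
            if ref not in spec.levels:
                raise ValueError(f"{spec.name}: reference {ref!r} not a level")
            group_cols = []
            for level in sorted(spec.levels):
                # unobserved levels would yield all-zero (aliased) columns
                if level == ref or level not in observed:
                    continue
                cname = f"{spec.name}[{level}]"
                cols[cname] = (raw.astype(str) == level).to_numpy(dtype=float)
                group_cols.append(cname)
            if not group_cols:
                raise ValueError(f"{spec.name}: only the reference level is observed")
            groups[spec.name] = group_cols
    X = pd.DataFrame(cols, index=table.index)
    return Design(
        X=X, column_groups=groups, specs={s.name: s for s in specs}, dropped=dropped
    )


# ---------------------------------------------------------------------------
# model enumeration


@dataclass(frozen=True)
class ModelFormula:
    """A candidate model: main-effect predictors plus interaction pairs."""

    mains: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    @property
    def n_variables(self) -> int:
        """Named variables counted toward the model-size cap.

        Each main effect counts once and each interaction counts as one
        additional variable.
        """
        return len(self.mains) + len(self.interactions)

    def contains(self, predictor: str) -> bool:
        return predictor in self.mains or any(
            predictor in pair for pair in self.interactions
        )

    def label(self) -> str:
        parts = list(self.mains) + [f"{a}:{b}" for a, b in self.interactions]
        return " + ".join(parts) if parts else "1"


def enumerate_models(
    specs: Sequence[PredictorSpec],
    max_terms: int = 5,
    interactions: bool = True,
) -> list[ModelFormula]:
    """All candidate models, deterministically ordered.

    Subsets of main effects with at most ``max_terms`` variables (the
    intercept-only model included), then, when ``interactions`` is on, every
    set of pairwise interactions between continuous and binary predictors
    whose main effects are present and that keeps the variable count within
    the cap.  Multi-level categorical predictors enter as main effects only.
    """
    names = [s.name for s in specs]
    inter_ok = {s.name for s in specs if s.role in {"continuous", "binary"}}
    models: list[ModelFormula] = []
    for r in range(0, min(max_terms, len(names)) + 1):
        for mains in itertools.combinations(names, r):
            models.append(ModelFormula(mains=mains))
            if not interactions:
                continue
            pairs = [
                (a, b)
                for a, b in itertools.combinations(mains, 2)
                if a in inter_ok and b in inter_ok
            ]
            budget = max_terms - len(mains)
            for k in range(1, min(budget, len(pairs)) + 1):
                for chosen in itertools.combinations(pairs, k):
                    models.append(ModelFormula(mains=mains, interactions=chosen))
    return models


def build_model_matrix(
    design: Design, formula: ModelFormula
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix (intercept first) for one candidate model."""
    cols: list[str] = ["Intercept"]
    data = [np.ones(len(design.X))]
    for name in formula.mains:
        for c in design.column_groups[name]:
            cols.append(c)
            data.append(design.X[c].to_numpy())
    for a, b in formula.interactions:
        (ca,), (cb,) = design.column_groups[a], design.column_groups[b]
        cols.append(f"{ca}:{cb}")
        data.append(design.X[ca].to_numpy() * design.X[cb].to_numpy())
    return np.column_stack(data), cols


def fit_models(
    design: Design,
    y: np.ndarray,
    C: np.ndarray,
    formulas: Iterable[ModelFormula],
) -> list[tuple[ModelFormula, PGLSFit]]:
    """Fit every candidate by ML, re-estimating lambda within each model."""
    out = []
    for f in formulas:
        X, cols = build_model_matrix(design, f)
        fit = pgls_ml(X, y, C, terms=cols)
        fit.formula = f.label()
        out.append((f, fit))
    return out


# ---------------------------------------------------------------------------
# ranking, weights, averaging


@dataclass
class ModelSet:
    """AICc-ranked candidate models with Akaike weights."""

    formulas: list[ModelFormula]
    fits: list[PGLSFit]
    delta_aicc: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.fits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "formula": [f.label() for f in self.formulas],
                "k": [fit.k for fit in self.fits],
                "loglik": [fit.loglik for fit in self.fits],
                "AICc": [fit.aicc for fit in self.fits],
                "delta_AICc": self.delta_aicc,
                "weight": self.weights,
                "lambda": [fit.lambda_ for fit in self.fits],
                "R2": [fit.r2 for fit in self.fits],
            }
        )


def rank_models(
    fitted: Sequence[tuple[ModelFormula, PGLSFit]]
) -> ModelSet:
    """Rank by AICc and attach Akaike weights.

    All fits must share one observation set (identical n) for their
    likelihoods to be comparable.  Ties break toward fewer parameters, then
    lexicographic formula label.
    """
    if not fitted:
        raise ValueError("no fitted models to rank")
    ns = {fit.n for _, fit in fitted}
    if len(ns) != 1:
        raise ValueError(f"fits use differing observation counts {sorted(ns)}; "
                         "likelihoods are not comparable")
    order = sorted(
        range(len(fitted)),
        key=lambda i: (fitted[i][1].aicc, fitted[i][1].k, fitted[i][0].label()),
    )
    formulas = [fitted[i][0] for i in order]
    fits = [fitted[i][1] for i in order]
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return ModelSet(formulas=formulas, fits=fits, delta_aicc=delta, weights=w)


def confidence_set(ms: ModelSet, level: float = 0.95) -> list[int]:
    """Indices (into the ranked set) of the smallest weight-ordered prefix
    whose cumulative Akaike weight reaches ``level``."""
    cum = np.cumsum(ms.weights)
    cutoff = int(np.searchsorted(cum, level - 1e-12)) + 1
    return list(range(min(cutoff, len(ms))))


def variable_importance(ms: ModelSet) -> dict[str, float]:
    """Summed Akaike weights of the models containing each predictor."""
    names: list[str] = []
    for f in ms.formulas:
        for m in f.mains:
            if m not in names:
                names.append(m)
    return {
        name: float(
            sum(w for f, w in zip(ms.formulas, ms.weights) if f.contains(name))
        )
        for name in names
    }


def model_average(ms: ModelSet) -> pd.DataFrame:
    """Model-averaged coefficients, both conditional and full flavors.

    Conditional averaging renormalizes weights over the models containing a
    term; full averaging sets the coefficient to zero where the term is
    absent (shrinking rarely selected terms toward zero).  Unconditional
    standard errors follow Burnham & Anderson:
    SE = sum_i w_i * sqrt(se_i^2 + (b_i - b_bar)^2); the 95% CI is the
    normal interval estimate +/- 1.96 SE.
    """
    terms: list[str] = []
    for fit in ms.fits:
        for t in fit.terms:
            if t not in terms:
                terms.append(t)
    rows = []
    for term in terms:
        present = [
            (w, fit) for w, fit in zip(ms.weights, ms.fits) if term in fit.terms
        ]
        w_present = sum(w for w, _ in present)
        betas = np.array([fit.coefficients()[term] for _, fit in present])
        ses = np.array(
            [dict(zip(fit.terms, fit.se))[term] for _, fit in present]
        )
        ws = np.array([w for w, _ in present])

        cond = float(np.sum(ws * betas) / w_present)
        cond_se = float(np.sum((ws / w_present) * np.sqrt(ses**2 + (betas - cond) ** 2)))
        full = float(np.sum(ws * betas))  # absent models contribute zero
        full_se = float(
            np.sum(ws * np.sqrt(ses**2 + (betas - full) ** 2))
            + (1.0 - w_present) * abs(0.0 - full)
        )
        rows.append(
            {
                "term": term,
                "weight_sum": w_present,
                "estimate_conditional": cond,
                "se_conditional": cond_se,
                "ci_lo_conditional": cond - 1.96 * cond_se,
                "ci_hi_conditional": cond + 1.96 * cond_se,
                "estimate_full": full,
                "se_full": full_se,
                "ci_lo_full": full - 1.96 * full_se,
                "ci_hi_full": full + 1.96 * full_se,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# collinearity


@dataclass
class GVIFReport:
    table: pd.DataFrame  # predictor, gvif, df, corrected, band

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)


def _band(corrected: float, df: int) -> str:
    vif_scale = corrected**2
    if vif_scale < 2.0:
        return "none"
    if vif_scale <= 5.0:
        return "moderate"
    return "high"


def gvif(design: Design, predictors: Sequence[str] | None = None) -> GVIFReport:
    """Generalized variance inflation factors per predictor group.

    Computed from determinant partitions of the predictor correlation
    matrix (intercept excluded): GVIF_g = det(R_gg) det(R_-g) / det(R).
    The corrected value GVIF^(1/(2 df)) puts multi-level predictors on the
    one-coefficient scale; its square is read against the usual VIF bands
    (< 2 no collinearity, > 5 high collinearity).
    """
    names = list(predictors) if predictors is not None else design.predictors
    if len(names) < 2:
        raise ValueError("GVIF needs at least two predictors")
    all_cols = [c for n in names for c in design.column_groups[n]]
    R = np.corrcoef(design.X[all_cols].to_numpy(), rowvar=False)
    det_R = np.linalg.det(R)
    if abs(det_R) < 1e-12:
        raise ValueError(
            f"singular predictor correlation matrix over columns {all_cols}; "
            "some predictors are aliased"
        )
    col_idx = {c: i for i, c in enumerate(all_cols)}
    rows = []
    for name in names:
        g = [col_idx[c] for c in design.column_groups[name]]
        rest = [i for i in range(len(all_cols)) if i not in g]
        det_g = np.linalg.det(R[np.ix_(g, g)])
        det_rest = np.linalg.det(R[np.ix_(rest, rest)])
        gv = float(det_g * det_rest / det_R)
        df = len(g)
        corrected = gv ** (1.0 / (2.0 * df))
        rows.append(
            {
                "predictor": name,
                "gvif": gv,
                "df": df,
                "corrected": corrected,
                "band": _band(corrected, df),
            }
        )
    return GVIFReport(table=pd.DataFrame(rows))
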