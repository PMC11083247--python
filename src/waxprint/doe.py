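"""Box-Behnken design and second-order response-surface modelling.

The headspace conditions (incubation temperature, agitation, sample
quantity) are optimized with a three-factor Box-Behnken design: 12 edge
midpoints — every factor pair at (+-1, +-1) with the third factor at its
center — plus replicated center runs. The response is the Euclidean
distance between the normalized total ion spectra of two odor grades, and
the model is the full 10-term quadratic

    Y = b0 + sum_i bi Xi + sum_i bii Xi^2 + sum_{i<j} bij Xi Xj + e

in coded units (each factor scaled affinely onto [-1, 1]).

Significance testing follows the replicated-center-point convention of
classical RSM software: every single-degree-of-freedom term is tested
against the pure-error mean square estimated from the center replicates,
and the lack-of-fit F compares the non-replication part of the residual
against the same pure error. Term sums of squares are partial (Type III),
``SS_j = b_j^2 / (X'X)^{-1}_{jj}``, which for the orthogonal linear columns
of this design reduces to ``8 b_j^2``.

Also here: the one-way ANOVA of the incubation-time kinetic study and the
coefficient-of-variation precision check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import stats

__all__ = [
    "FactorDef",
    "BbdStudy",
    "bbd_design",
    "ResponseSurfaceModel",
    "ResponseSurfaceResults",
    "Optimum",
    "grid_scan",
    "kinetic_anova",
    "KineticAnovaResult",
    "precision_cv",
    "PrecisionResult",
]

TERM_NAMES = ("b0", "b1", "b2", "b3", "b11", "b22", "b33", "b12", "b13", "b23")


@dataclass(frozen=True)
class FactorDef:
    """One design factor with its natural-unit low/mid/high levels."""

    name: str
    low: float
    mid: float
    high: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.mid < self.high:
            raise ValueError(f"{self.name}: need low < mid < high")
        if not np.isclose(self.mid, (self.low + self.high) / 2, rtol=1e-6):
            raise ValueError(f"{self.name}: mid level must be the midpoint")

    def code(self, value):
        """Natural units -> coded [-1, 1] (extrapolation allowed)."""
        coded = (np.asarray(value, dtype=float) - self.mid) / ((self.high - self.low) / 2)
        if np.any(np.abs(coded) > 1 + 1e-9):
            warnings.warn(f"{self.name}: value outside the design range", stacklevel=2)
        return coded if np.ndim(value) else float(coded)

    def uncode(self, coded):
        """Coded units -> natural units."""
        value = self.mid + np.asarray(coded, dtype=float) * (self.high - self.low) / 2
        return value if np.ndim(coded) else float(value)


@dataclass
class BbdStudy:
    """A three-factor Box-Behnken design with (optionally) its responses."""

    factors: tuple[FactorDef, FactorDef, FactorDef]
    design: pd.DataFrame  # coded columns X1, X2, X3
    responses: np.ndarray | None = None
    run_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.factors) != 3:
            raise ValueError("only the 3-factor Box-Behnken design is supported")
        if self.responses is not None:
            self.responses = np.asarray(self.responses, dtype=float)
            if self.responses.size != len(self.design):
                raise ValueError("responses must match design rows")

    @property
    def coded(self) -> np.ndarray:
        return self.design[["X1", "X2", "X3"]].to_numpy(dtype=float)

    @property
    def n_center(self) -> int:
        return int((np.all(self.coded == 0, axis=1)).sum())

    def natural_units(self) -> pd.DataFrame:
        out = {}
        for k, f in enumerate(self.factors):
            out[f.name] = f.uncode(self.coded[:, k])
        return pd.DataFrame(out)

    def with_responses(self, responses) -> "BbdStudy":
        return BbdStudy(self.factors, self.design.copy(), np.asarray(responses, float),
                        self.run_order)


def bbd_design(
    factors, n_center: int = 6, seed: int | None = None
) -> BbdStudy:
    """Construct the 3-factor Box-Behnken design (12 edge runs + centers).

    ``seed`` randomizes the execution order column only; the design rows
    themselves keep a fixed, reproducible ordering.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValueError("only the 3-factor Box-Behnken design is supported")
    if n_center < 1:
        raise ValueError("need at least one center run")
    rows = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for a, b in ((-1, -1), (1, -1), (-1, 1), (1, 1)):
            point = [0, 0, 0]
            point[i], point[j] = a, b
            rows.append(point)
    rows.extend([[0, 0, 0]] * n_center)
    design = pd.DataFrame(rows, columns=["X1", "X2", "X3"])
    design.index = pd.RangeIndex(1, len(design) + 1, name="run")
    order = np.arange(1, len(design) + 1)
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    return BbdStudy(factors=factors, design=design, run_order=order)


def _model_matrix(coded: np.ndarray) -> np.ndarray:
    x1, x2, x3 = coded.T
    return np.column_stack(
        [np.ones(len(coded)), x1, x2, x3, x1 * x1, x2 * x2, x3 * x3,
         x1 * x2, x1 * x3, x2 * x3]
    )


class ResponseSurfaceModel:
    """OLS fit of the full 10-term quadratic to a Box-Behnken study."""

    def __init__(self, study: BbdStudy):
        if study.responses is None:
            raise ValueError("study has no responses to fit")
        if not np.all(np.isfinite(study.responses)):
            raise ValueError("responses must be finite")
        self.study = study

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors, response: str = "response"):
        """Build from a table with coded columns X1..X3 and a response column."""
        design = df[["X1", "X2", "X3"]].reset_index(drop=True)
        design.index = pd.RangeIndex(1, len(design) + 1, name="run")
        study = BbdStudy(tuple(factors), design, df[response].to_numpy(dtype=float))
        return cls(study)

    def fit(self) -> "ResponseSurfaceResults":
        X = _model_matrix(self.study.coded)
        y = self.study.responses
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design is rank-deficient for the 10-term quadratic")
        params, *_ = np.linalg.lstsq(X, y, rcond=None)
        return ResponseSurfaceResults(self, X, y, params)


@dataclass
class Optimum:
    coded: np.ndarray
    natural: dict[str, float]
    predicted: float


class ResponseSurfaceResults:
    """Estimates, ANOVA and optimization for a fitted quadratic surface."""

    def __init__(self, model: ResponseSurfaceModel, X, y, params):
        self.model = model
        self.exog = X
        self.endog = y
        self.params = pd.Series(params, index=TERM_NAMES)
        self.fittedvalues = X @ params
        self.resid = y - self.fittedvalues
        self.ss_resid = float(self.resid @ self.resid)
        self.ss_total = float(((y - y.mean()) ** 2).sum())
        self.df_resid = len(y) - len(params)
        self._xtx_inv = np.linalg.inv(X.T @ X)

    # -- goodness of fit ---------------------------------------------------
    @property
    def rsquared(self) -> float:
        return 1.0 - self.ss_resid / self.ss_total

    # -- pure error from replicated center points --------------------------
    def _center_mask(self) -> np.ndarray:
        return np.all(self.model.study.coded == 0, axis=1)

    def pure_error(self) -> tuple[float, int]:
        """(pure-error SS, df) from the replicated center runs."""
        mask = self._center_mask()
        n_center = int(mask.sum())
        if n_center < 2:
            raise ValueError("pure error undefined: need replicated center runs")
        centers = self.endog[mask]
        return float(((centers - centers.mean()) ** 2).sum()), n_center - 1

    # -- inference ---------------------------------------------------------
    def anova(self) -> pd.DataFrame:
        """Per-term ANOVA with the pure-error mean square as denominator.

        Partial (Type III) single-df sums of squares; for this design's
        orthogonal linear and interaction columns SS reduces to b^2 * Sum x^2.
        """
        ss_pe, df_pe = self.pure_error()
        ms_pe = ss_pe / df_pe
        rows = []
        for j, term in enumerate(TERM_NAMES):
            if term == "b0":
                continue
            ss = float(self.params.iloc[j] ** 2 / self._xtx_inv[j, j])
            if ms_pe == 0:  # degenerate: no center-replicate variation
                f = 0.0 if ss == 0 else np.inf
            else:
                f = ss / ms_pe
            rows.append(
                {"term": term, "ss": ss, "df": 1, "ms": ss,
                 "f": f, "p": float(stats.f.sf(f, 1, df_pe))}
            )
        table = pd.DataFrame(rows).set_index("term")
        table.attrs["ms_pure_error"] = ms_pe
        table.attrs["df_pure_error"] = df_pe
        return table

    def lack_of_fit(self) -> tuple[float, float]:
        """Lack-of-fit F and p against pure error."""
        ss_pe, df_pe = self.pure_error()
        ss_lof = self.ss_resid - ss_pe
        df_lof = self.df_resid - df_pe
        if df_lof <= 0:
            raise ValueError("no degrees of freedom left for lack of fit")
        f = (ss_lof / df_lof) / (ss_pe / df_pe)
        return float(f), float(stats.f.sf(f, df_lof, df_pe))

    def standardized_effects(self, alpha: float = 0.05) -> pd.DataFrame:
        """Pareto-style |t| ranking of terms with pure-error standard errors."""
        ss_pe, df_pe = self.pure_error()
        ms_pe = ss_pe / df_pe
        rows = []
        for j, term in enumerate(TERM_NAMES):
            if term == "b0":
                continue
            se = np.sqrt(ms_pe * self._xtx_inv[j, j])
            t = float(self.params.iloc[j] / se) if se > 0 else 0.0
            rows.append({"term": term, "t": t})
        table = pd.DataFrame(rows).set_index("term")
        crit = stats.t.ppf(1 - alpha / 2, df_pe)
        table["significant"] = np.abs(table["t"]) > crit
        table.attrs["t_critical"] = float(crit)
        return table.reindex(table["t"].abs().sort_values(ascending=False).index)

    # -- prediction & optimization -----------------------------------------
    def predict(self, coded_points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        return _model_matrix(pts) @ self.params.to_numpy()

    def optimize(self, n_starts: int = 20, seed: int = 0, maximize: bool = True) -> Optimum:
        """Constrained optimum of the fitted surface over the coded cube.

        Multi-start L-BFGS-B from the cube corners, the center and random
        interior points; see :func:`grid_scan` for the independent check.
        """
        sign = -1.0 if maximize else 1.0

        def fun(x):
            return sign * float(self.predict(x)[0])

        corners = np.array(
            [[i, j, k] for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)], float
        )
        rng = np.random.default_rng(seed)
        starts = np.vstack(
            [corners, np.zeros((1, 3)), rng.uniform(-1, 1, size=(n_starts, 3))]
        )
        best_x, best_v = None, np.inf
        for x0 in starts:
            res = sp_optimize.minimize(
                fun, x0, method="L-BFGS-B", bounds=[(-1, 1)] * 3
            )
            if res.fun < best_v:
                best_v, best_x = res.fun, res.x
        coded = np.clip(best_x, -1, 1)
        natural = {
            f.name: f.uncode(coded[k]) for k, f in enumerate(self.model.study.factors)
        }
        return Optimum(coded=coded, natural=natural, predicted=sign * best_v)

    # -- reporting ---------------------------------------------------------
    def reduced_equation(self, alpha: float = 0.05) -> pd.Series:
        """Coefficients of the significant terms only (plus the intercept)."""
        effects = self.standardized_effects(alpha)
        keep = ["b0"] + [t for t in effects.index[effects["significant"]]]
        return self.params[[t for t in TERM_NAMES if t in keep]]

    def summary(self) -> str:
        lines = ["Second-order response surface (coded units)", "=" * 46]
        factor_names = ", ".join(f.name for f in self.model.study.factors)
        lines.append(f"Factors: {factor_names}")
        lines.append(f"Runs: {len(self.endog)}  (center: {int(self._center_mask().sum())})")
        lines.append(f"R-squared: {self.rsquared * 100:.2f}%")
        f_lof, p_lof = self.lack_of_fit()
        lines.append(f"Lack of fit: F = {f_lof:.3f}, p = {p_lof:.3f}")
        lines.append("")
        lines.append(f"{'term':<6}{'coef':>12}{'F':>10}{'p':>10}")
        anova = self.anova()
        lines.append(f"{'b0':<6}{self.params['b0']:>12.5f}{'':>10}{'':>10}")
        for term in anova.index:
            lines.append(
                f"{term:<6}{self.params[term]:>12.5f}"
                f"{anova.loc[term, 'f']:>10.2f}{anova.loc[term, 'p']:>10.4f}"
            )
        opt = self.optimize()
        nat = ", ".join(f"{k} = {v:.4g}" for k, v in opt.natural.items())
        lines.append("")
        lines.append(
            "Optimum (coded): "
            + ", ".join(f"{v:+.4f}" for v in opt.coded)
            + f"  ->  Y = {opt.predicted:.5f}"
        )
        lines.append(f"Optimum (natural): {nat}")
        return "\n".join(lines)


def grid_scan(
    predict, step: float = 0.001, coarse_step: float = 0.02
) -> tuple[np.ndarray, float]:
    """Maximize ``predict`` over the coded cube by coarse-to-fine grid scan.

    A full coarse grid locates the basin; a fine grid at ``step`` resolution
    refines within one coarse cell around it. Serves as the independent
    cross-check of :meth:`ResponseSurfaceResults.optimize`.
    """

    def eval_grid(axes):
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = np.asarray(predict(pts)).ravel()
        k = int(np.argmax(vals))
        return pts[k], float(vals[k])

    coarse_axis = np.arange(-1, 1 + coarse_step / 2, coarse_step)
    center, _ = eval_grid([coarse_axis] * 3)
    fine_axes = []
    for c in center:
        lo, hi = max(-1.0, c - coarse_step), min(1.0, c + coarse_step)
        fine_axes.append(np.arange(lo, hi + step / 2, step))
    return eval_grid(fine_axes)


@dataclass
class KineticAnovaResult:
    f: float
    p: float
    table: pd.DataFrame  # per-time mean, sd, n
    significant: bool


def kinetic_anova(groups: dict, alpha: float = 0.05) -> KineticAnovaResult:
    """One-way ANOVA of the response across incubation times.

    ``groups`` maps each incubation time to its replicate distances. A
    non-significant result supports fixing the shortest time for routine use.
    """
    if len(groups) < 2:
        raise ValueError("need at least two incubation-time groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least two replicates")
    values = list(arrays.values())
    if all(np.ptp(np.concatenate(values)) == 0 for _ in (0,)):
        f, p = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*values)
        if np.isnan(f):  # all groups constant and equal
            f, p = 0.0, 1.0
    table = pd.DataFrame(
        {
            "time": list(arrays.keys()),
            "mean": [v.mean() for v in arrays.values()],
            "sd": [v.std(ddof=1) for v in arrays.values()],
            "n": [v.size for v in arrays.values()],
        }
    ).set_index("time")
    return KineticAnovaResult(float(f), float(p), table, bool(p < alpha))


@dataclass
class PrecisionResult:
    distances: np.ndarray
    cv_percent: float
    within_limit: bool
    limit_percent: float


def precision_cv(distances, limit_percent: float = 10.0) -> PrecisionResult:
    """Coefficient of variation (%) of replicate Euclidean distances.

    Sample standard deviation over mean, times 100; checked against the
    acceptance limit used for repeatability / intermediate precision.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two replicate distances")
    mean = d.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean distances")
    cv = 100.0 * d.std(ddof=1) / mean
    return PrecisionResult(d, float(cv), bool(cv <= limit_percent), limit_percent)
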