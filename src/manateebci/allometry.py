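"""Robust nonlinear estimation of the allometric body-condition models.

Three power-law models relate a manatee's umbilical girth (UG), body mass
(W) and straight-line length (SL):

* ``bci1``:  UG = BCI1 * SL**b1        (geometric similarity: b1 = 1)
* ``bci2``:  W  = BCI2 * SL**b2        (geometric similarity: b2 = 3)
* ``bci3``:  W  = BCI3 * SL * UG**b3   (geometric similarity: b3 = 2)

The coefficient is the population body-condition level; the exponent
captures how shape changes with size.  Habitat (coastal vs riverine) and
sex (F vs M) may enter as additive offsets on both the coefficient and
the exponent, with female/coastal as the reference cell:

    UG = (BCI1 + r*Riverine + m*Male) * SL**(b1 + br*Riverine + bm*Male)

Fitting is M-estimation on raw-scale residuals by iteratively reweighted
nonlinear least squares (Huber weights by default), initialised from
ordinary least squares on the log-linearised model.  Usage follows the
Model/Results convention::

    res = AllometricModel(frame, index="bci1", factors=("habitat",)).fit()
    res.params, res.bse, res.similarity_test(), res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit, least_squares

from .records import MorphRecord, records_to_frame
from .robust import BISQUARE_C, HUBER_K, bisquare_weights, huber_weights, mad_scale

logger = logging.getLogger(__name__)

__all__ = [
    "AllometricModel",
    "AllometricResults",
    "ModelSpecificationError",
    "INDEX_INFO",
    "model_predict",
    "fit_robust_allometry",
    "fit_ols_allometry",
    "exponent_similarity_test",
]

#: Per-index structure: response column, geometric-similarity exponent k,
#: and the numeric suffix used in parameter names.
INDEX_INFO = {
    "bci1": {"response": "ug_m", "k": 1.0, "suffix": "1"},
    "bci2": {"response": "w_kg", "k": 3.0, "suffix": "2"},
    "bci3": {"response": "w_kg", "k": 2.0, "suffix": "3"},
}

VALID_FACTORS = ("habitat", "sex")


class ModelSpecificationError(ValueError):
    """The requested model cannot be identified from the data given."""


def _param_names(index: str, factors: Sequence[str]) -> list[str]:
    s = INDEX_INFO[index]["suffix"]
    names = [f"bci{s}"]
    if "habitat" in factors:
        names.append(f"r{s}")
    if "sex" in factors:
        names.append(f"m{s}")
    names.append(f"b{s}")
    if "habitat" in factors:
        names.append(f"br{s}")
    if "sex" in factors:
        names.append(f"bm{s}")
    return names


class AllometricModel:
    """Robust power-law model for one body-condition index.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``sl_m`` and the model's response (``ug_m`` for bci1,
        ``w_kg`` for bci2/bci3; bci3 additionally needs ``ug_m`` as a
        predictor), plus ``habitat`` / ``sex`` when used as factors.
        Rows missing a required measurement are dropped (counted in
        ``n_dropped``); records of unknown sex are dropped only when sex
        is a factor.
    index : {"bci1", "bci2", "bci3"}
    factors : iterable of {"habitat", "sex"}
        Strata entering Eq.-7-style coefficient and exponent offsets.
    """

    def __init__(self, data: pd.DataFrame, index: str = "bci1",
                 factors: Iterable[str] = ()):
        if index not in INDEX_INFO:
            raise ValueError(f"index must be one of {tuple(INDEX_INFO)}, got {index!r}")
        factors = tuple(factors)
        for f in factors:
            if f not in VALID_FACTORS:
                raise ValueError(f"unknown factor {f!r}; allowed: {VALID_FACTORS}")
        self.index = index
        self.factors = factors
        info = INDEX_INFO[index]
        self.response_name = info["response"]
        self.k_similarity = info["k"]
        self.param_names = _param_names(index, factors)

        needed = ["sl_m", self.response_name]
        if index == "bci3":
            needed = ["sl_m", "ug_m", "w_kg"]
        cols = set(needed) | set(factors)
        missing_cols = cols - set(data.columns)
        if missing_cols:
            raise ValueError(f"data lacks column(s): {sorted(missing_cols)}")

        mask = np.ones(len(data), dtype=bool)
        for c in needed:
            mask &= data[c].notna().to_numpy()
        self.n_dropped_missing = int(len(data) - mask.sum())
        self.n_dropped_unknown_sex = 0
        if "sex" in factors:
            known = (data["sex"] != "unknown").to_numpy()
            self.n_dropped_unknown_sex = int((mask & ~known).sum())
            mask &= known
        sub = data.loc[mask]
        if self.n_dropped_unknown_sex:
            logger.info("dropped %d unknown-sex record(s) from sex-factor fit",
                        self.n_dropped_unknown_sex)

        self.sl = sub["sl_m"].to_numpy(dtype=float)
        self.ug = sub["ug_m"].to_numpy(dtype=float) if "ug_m" in sub else None
        self.endog = sub[self.response_name].to_numpy(dtype=float)
        self.riverine = (
            (sub["habitat"] == "riverine").to_numpy(dtype=float)
            if "habitat" in factors else np.zeros(len(sub))
        )
        self.male = (
            (sub["sex"] == "M").to_numpy(dtype=float)
            if "sex" in factors else np.zeros(len(sub))
        )
        self.ids = sub["id"].to_numpy() if "id" in sub else np.arange(len(sub))

        if np.any(self.sl <= 0) or np.any(self.endog <= 0):
            raise ValueError("measurements must be strictly positive")
        if index == "bci3" and np.any(self.ug <= 0):
            raise ValueError("measurements must be strictly positive")

        if "habitat" in factors and len(np.unique(self.riverine)) < 2:
            raise ModelSpecificationError(
                "habitat factor requested but only one habitat present")
        if "sex" in factors and len(np.unique(self.male)) < 2:
            raise ModelSpecificationError(
                "sex factor requested but only one sex present")

    @classmethod
    def from_records(cls, records: Sequence[MorphRecord], index: str = "bci1",
                     factors: Iterable[str] = ()) -> "AllometricModel":
        return cls(records_to_frame(records), index=index, factors=factors)

    @property
    def nobs(self) -> int:
        return len(self.endog)

    # -- prediction ----------------------------------------------------

    def _coef_expo(self, params: np.ndarray, riverine: np.ndarray,
                   male: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        names = self.param_names
        p = dict(zip(names, params))
        s = INDEX_INFO[self.index]["suffix"]
        coef = np.full_like(riverine, p[f"bci{s}"], dtype=float)
        expo = np.full_like(riverine, p[f"b{s}"], dtype=float)
        if f"r{s}" in p:
            coef = coef + p[f"r{s}"] * riverine
            expo = expo + p[f"br{s}"] * riverine
        if f"m{s}" in p:
            coef = coef + p[f"m{s}"] * male
            expo = expo + p[f"bm{s}"] * male
        return coef, expo

    def _predict(self, params: np.ndarray, sl: np.ndarray,
                 ug: Optional[np.ndarray], riverine: np.ndarray,
                 male: np.ndarray) -> np.ndarray:
        coef, expo = self._coef_expo(params, riverine, male)
        if self.index == "bci3":
            return coef * sl * ug ** expo
        return coef * sl ** expo

    def _jacobian(self, params: np.ndarray, sl: np.ndarray,
                  ug: Optional[np.ndarray], riverine: np.ndarray,
                  male: np.ndarray) -> np.ndarray:
        """Analytic d(pred)/d(params), columns in param order."""
        coef, expo = self._coef_expo(params, riverine, male)
        if self.index == "bci3":
            base = sl * ug ** expo
            logx = np.log(ug)
        else:
            base = sl ** expo
            logx = np.log(sl)
        cols = []
        s = INDEX_INFO[self.index]["suffix"]
        for name in self.param_names:
            if name == f"bci{s}":
                cols.append(base)
            elif name == f"r{s}":
                cols.append(riverine * base)
            elif name == f"m{s}":
                cols.append(male * base)
            elif name == f"b{s}":
                cols.append(coef * base * logx)
            elif name == f"br{s}":
                cols.append(riverine * coef * base * logx)
            elif name == f"bm{s}":
                cols.append(male * coef * base * logx)
        return np.column_stack(cols)

    def predict(self, params, data: Optional[pd.DataFrame] = None) -> np.ndarray:
        """Model prediction at ``params`` for the fit data or new data."""
        p = self._params_to_vector(params)
        if data is None:
            return self._predict(p, self.sl, self.ug, self.riverine, self.male)
        sl = data["sl_m"].to_numpy(dtype=float)
        ug = data["ug_m"].to_numpy(dtype=float) if "ug_m" in data else None
        riv = ((data["habitat"] == "riverine").to_numpy(dtype=float)
               if "habitat" in self.factors else np.zeros(len(data)))
        male = ((data["sex"] == "M").to_numpy(dtype=float)
                if "sex" in self.factors else np.zeros(len(data)))
        return self._predict(p, sl, ug, riv, male)

    def _params_to_vector(self, params) -> np.ndarray:
        if isinstance(params, Mapping):
            return np.array([params[n] for n in self.param_names], dtype=float)
        return np.asarray(params, dtype=float)

    # -- fitting -------------------------------------------------------

    def _log_ols_start(self) -> np.ndarray:
        """OLS on the log-linearised model, always well-defined for
        positive data.

        Without factors: one pooled log-log regression.  With factors:
        a per-stratum log-log regression per cell, combined into
        reference values and offsets by least squares over the cell
        design — for additively generated noise-free data this start is
        already the solution.
        """
        if self.index == "bci3":
            y = np.log(self.endog) - np.log(self.sl)
            x = np.log(self.ug)
        else:
            y = np.log(self.endog)
            x = np.log(self.sl)
        s = INDEX_INFO[self.index]["suffix"]
        start = {n: 0.0 for n in self.param_names}

        slope, intercept = np.polyfit(x, y, 1)
        start[f"bci{s}"] = float(np.exp(intercept))
        start[f"b{s}"] = float(slope)

        if self.factors:
            rows, slopes, coefs = [], [], []
            for riv in np.unique(self.riverine):
                for male in np.unique(self.male):
                    sel = (self.riverine == riv) & (self.male == male)
                    if sel.sum() < 3 or np.ptp(x[sel]) == 0:
                        continue
                    sl_c, ic_c = np.polyfit(x[sel], y[sel], 1)
                    rows.append([1.0, riv, male])
                    slopes.append(sl_c)
                    coefs.append(np.exp(ic_c))
            if len(rows) >= 1 + len(self.factors):
                design = np.asarray(rows)
                cols = [0]
                names_c = [f"bci{s}"]
                names_e = [f"b{s}"]
                if "habitat" in self.factors:
                    cols.append(1)
                    names_c.append(f"r{s}")
                    names_e.append(f"br{s}")
                if "sex" in self.factors:
                    cols.append(2)
                    names_c.append(f"m{s}")
                    names_e.append(f"bm{s}")
                D = design[:, cols]
                sol_c = np.linalg.lstsq(D, np.asarray(coefs), rcond=None)[0]
                sol_e = np.linalg.lstsq(D, np.asarray(slopes), rcond=None)[0]
                for name, v in zip(names_c, sol_c):
                    start[name] = float(v)
                for name, v in zip(names_e, sol_e):
                    start[name] = float(v)
        return np.array([start[n] for n in self.param_names])

    def fit(self, loss: str = "huber", tuning: Optional[float] = None,
            tol: float = 1e-8, max_iter: int = 100) -> "AllometricResults":
        """Fit by robust IRLS.

        Each iteration recomputes raw-scale residuals, the rescaled-MAD
        robust scale, robustness weights (Huber k=1.345 by default,
        Tukey bisquare c=4.685 optional), and solves the weighted
        nonlinear least-squares step; convergence is relative parameter
        change below ``tol``.  Standard errors come from the asymptotic
        covariance of the final weighted fit.
        """
        n, p = self.nobs, len(self.param_names)
        if n < p + 3:
            raise ModelSpecificationError(
                f"need at least {p + 3} usable records for {p} parameters, have {n}")
        if np.ptp(self.sl) == 0 and self.index != "bci3":
            raise ModelSpecificationError(
                "all lengths identical: exponent unidentifiable")
        if self.index == "bci3" and np.ptp(self.ug) == 0:
            raise ModelSpecificationError(
                "all girths identical: exponent unidentifiable")

        if loss == "huber":
            wfun, k = huber_weights, (tuning if tuning is not None else HUBER_K)
        elif loss == "bisquare":
            wfun, k = bisquare_weights, (tuning if tuning is not None else BISQUARE_C)
        else:
            raise ValueError(f"loss must be 'huber' or 'bisquare', got {loss!r}")

        sl, ug, riv, male, y = self.sl, self.ug, self.riverine, self.male, self.endog
        scale_floor = 1e-10 * float(np.sqrt(np.mean(y * y)))

        def solve_weighted(x0: np.ndarray, w: np.ndarray) -> np.ndarray:
            sw = np.sqrt(w)

            def fun(q):
                return sw * (y - self._predict(q, sl, ug, riv, male))

            def jac(q):
                return -sw[:, None] * self._jacobian(q, sl, ug, riv, male)

            sol = least_squares(fun, x0, jac=jac, method="lm", xtol=1e-12, ftol=1e-12)
            return sol.x

        params = self._log_ols_start()
        weights = np.ones(n)
        converged = False
        n_iter = 0
        scale = 0.0
        for n_iter in range(1, max_iter + 1):
            resid = y - self._predict(params, sl, ug, riv, male)
            scale = mad_scale(resid)
            if scale <= scale_floor:
                if np.max(np.abs(resid)) <= 1e-8 * np.sqrt(np.mean(y * y)):
                    # exact (noise-free) fit: one plain refinement
                    weights = np.ones(n)
                    params = solve_weighted(params, weights)
                    converged = True
                    break
                # majority of residuals exactly zero but outliers remain:
                # fall back to a mean-|r| scale so downweighting still works
                scale = float(np.mean(np.abs(resid)))
            weights = wfun(resid / scale, k)
            new = solve_weighted(params, weights)
            delta = np.max(np.abs(new - params) / (np.abs(params) + 1e-8))
            params = new
            if delta < tol:
                converged = True
                break
        if not converged:
            import warnings
            warnings.warn(
                f"allometric IRLS did not converge in {max_iter} iterations",
                RuntimeWarning, stacklevel=2)

        resid = y - self._predict(params, sl, ug, riv, male)
        J = self._jacobian(params, sl, ug, riv, male)
        JW = J * weights[:, None]
        dof = max(n - p, 1)
        s2 = float(np.sum(weights * resid * resid)) / dof
        cov = s2 * np.linalg.pinv(J.T @ JW)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))

        return AllometricResults(
            model=self,
            params=pd.Series(params, index=self.param_names),
            bse=pd.Series(bse, index=self.param_names),
            cov_params=pd.DataFrame(cov, index=self.param_names,
                                    columns=self.param_names),
            scale=scale,
            weights=np.clip(weights, 0.0, 1.0),
            converged=converged,
            n_iter=n_iter,
            loss=loss,
            tuning=k,
        )


@dataclass
class AllometricResults:
    """Fitted allometric model: estimates, uncertainties, diagnostics."""

    model: AllometricModel
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    scale: float
    weights: np.ndarray
    converged: bool
    n_iter: int
    loss: str
    tuning: float
    _tests: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def index(self) -> str:
        return self.model.index

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_resid(self) -> int:
        return self.model.nobs - len(self.params)

    def predict(self, data: Optional[pd.DataFrame] = None) -> np.ndarray:
        return self.model.predict(self.params.to_numpy(), data)

    # -- parameter access by stratum ------------------------------------

    def coefficient_for(self, habitat: str = "coastal", sex: str = "F") -> float:
        s = INDEX_INFO[self.index]["suffix"]
        val = float(self.params[f"bci{s}"])
        if f"r{s}" in self.params and habitat == "riverine":
            val += float(self.params[f"r{s}"])
        if f"m{s}" in self.params and sex == "M":
            val += float(self.params[f"m{s}"])
        return val

    def exponent_for(self, habitat: str = "coastal", sex: str = "F") -> float:
        """Group-specific exponent: reference b plus applicable offsets."""
        s = INDEX_INFO[self.index]["suffix"]
        val = float(self.params[f"b{s}"])
        if f"br{s}" in self.params and habitat == "riverine":
            val += float(self.params[f"br{s}"])
        if f"bm{s}" in self.params and sex == "M":
            val += float(self.params[f"bm{s}"])
        return val

    # -- tests -----------------------------------------------------------

    @property
    def tvalues(self) -> pd.Series:
        """Offsets: test of zero.  Exponent: test of the geometric-
        similarity value via the (k - b) contrast.  Coefficients: NaN
        (levels, not contrasts)."""
        return self._test_table()["t"]

    @property
    def pvalues(self) -> pd.Series:
        return self._test_table()["p"]

    def _test_table(self) -> pd.DataFrame:
        s = INDEX_INFO[self.index]["suffix"]
        k = self.model.k_similarity
        rows = {}
        for name in self.params.index:
            est, se = float(self.params[name]), float(self.bse[name])
            if name == f"bci{s}":
                rows[name] = (np.nan, np.nan)
                continue
            stat = (k - est) if name == f"b{s}" else est
            if se == 0.0 or not np.isfinite(se):
                rows[name] = (np.nan, np.nan)
                continue
            t = stat / se
            p = 2.0 * stats.t.sf(abs(t), self.df_resid)
            rows[name] = (t, p)
        out = pd.DataFrame(rows, index=["t", "p"]).T
        out.index.name = "parameter"
        return out

    def similarity_test(self) -> pd.DataFrame:
        """Test of geometric similarity: the (k - b) contrast per stratum.

        k is 1 (bci1), 3 (bci2) or 2 (bci3).  The contrast shares the SE
        of the exponent estimate; with exponent offsets fitted the offsets
        themselves are reported as tests of zero (equal exponents across
        strata).  A zero SE (degenerate, e.g. noise-free data) yields an
        undefined test, not an infinite t.
        """
        s = INDEX_INFO[self.index]["suffix"]
        k = self.model.k_similarity
        rows = []
        labels = {
            f"b{s}": (f"{k:g}-b{s} (Female, Coastal)", lambda e: k - e),
            f"br{s}": (f"b{s} (Coastal-Riverine)", lambda e: -e),
            f"bm{s}": (f"b{s} (Female-Male)", lambda e: -e),
        }
        for name, (label, transform) in labels.items():
            if name not in self.params.index:
                continue
            est = transform(float(self.params[name]))
            se = float(self.bse[name])
            if se == 0.0 or not np.isfinite(se):
                t = p = np.nan
            else:
                t = est / se
                p = 2.0 * stats.t.sf(abs(t), self.df_resid)
            rows.append({"parameter": label, "estimate": est, "se": se,
                         "t": t, "p": p})
        return pd.DataFrame(rows)

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Robust allometric fit: {self.index}  "
            f"(loss={self.loss}, tuning={self.tuning:g})",
            f"n = {self.nobs}, iterations = {self.n_iter}, "
            f"converged = {self.converged}, robust scale = {self.scale:.6g}",
            "",
            f"{'parameter':<10}{'estimate':>12}{'SE':>12}{'t':>10}{'p':>10}",
        ]
        tests = self._test_table()
        for name in self.params.index:
            t, p = tests.loc[name, "t"], tests.loc[name, "p"]
            t_s = f"{t:.3f}" if np.isfinite(t) else "-"
            p_s = f"{p:.4f}" if np.isfinite(p) else "-"
            lines.append(
                f"{name:<10}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{t_s:>10}{p_s:>10}")
        sim = self.similarity_test()
        if len(sim):
            lines.append("")
            lines.append("Geometric-similarity contrasts:")
            for _, r in sim.iterrows():
                t_s = f"{r['t']:.3f}" if np.isfinite(r["t"]) else "-"
                p_s = f"{r['p']:.4f}" if np.isfinite(r["p"]) else "-"
                lines.append(
                    f"  {r['parameter']:<28}{r['estimate']:>10.4f}"
                    f"{r['se']:>10.4f}{t_s:>10}{p_s:>10}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "factors": list(self.model.factors),
            "params": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "n_used": int(self.nobs),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iter),
            "robust_scale": float(self.scale),
            "loss": self.loss,
            "tuning": float(self.tuning),
        }


class StoredAllometricFit:
    """A fit reloaded from its serialized form (params + factors only).

    Quacks like :class:`AllometricResults` as far as scoring needs:
    ``converged``, ``model.factors``, ``exponent_for``/``coefficient_for``.
    """

    def __init__(self, payload: Mapping):
        self.index = payload["index"]
        self.factors = tuple(payload.get("factors", ()))
        self.params = pd.Series({k: float(v) for k, v in payload["params"].items()})
        self.converged = bool(payload.get("converged", True))

    @property
    def model(self) -> "StoredAllometricFit":
        return self

    def _lookup(self, base: str, habitat: str, sex: str) -> float:
        s = INDEX_INFO[self.index]["suffix"]
        prefix = {"coef": ("bci", "r", "m"), "expo": ("b", "br", "bm")}[base]
        val = float(self.params[f"{prefix[0]}{s}"])
        if habitat == "riverine" and f"{prefix[1]}{s}" in self.params:
            val += float(self.params[f"{prefix[1]}{s}"])
        if sex == "M" and f"{prefix[2]}{s}" in self.params:
            val += float(self.params[f"{prefix[2]}{s}"])
        return val

    def coefficient_for(self, habitat: str = "coastal", sex: str = "F") -> float:
        return self._lookup("coef", habitat, sex)

    def exponent_for(self, habitat: str = "coastal", sex: str = "F") -> float:
        return self._lookup("expo", habitat, sex)


# ---------------------------------------------------------------------------
# functional surface


def fit_robust_allometry(records, model: str = "bci1",
                         factors: Iterable[str] = (),
                         **fit_kwargs) -> AllometricResults:
    """Robust IRLS fit of one allometric model from records or a frame."""
    if isinstance(records, pd.DataFrame):
        m = AllometricModel(records, index=model, factors=factors)
    else:
        m = AllometricModel.from_records(records, index=model, factors=factors)
    return m.fit(**fit_kwargs)


def exponent_similarity_test(fit: AllometricResults) -> pd.DataFrame:
    """Geometric-similarity contrast table for a converged fit."""
    if not fit.converged:
        raise ValueError("similarity test requires a converged fit")
    return fit.similarity_test()


def model_predict(model: str, params: Mapping[str, float], sl_m, ug_m=None,
                  habitat: str = "coastal", sex: str = "F"):
    """Predict the model response for given measurements and stratum.

    ``params`` holds the coefficient/exponent (and optional offsets) under
    their conventional names, e.g. ``{"bci1": 0.76, "b1": 1.0}`` with
    optional ``r1``/``m1``/``br1``/``bm1``.
    """
    if model not in INDEX_INFO:
        raise ValueError(f"model must be one of {tuple(INDEX_INFO)}")
    s = INDEX_INFO[model]["suffix"]
    sl = np.asarray(sl_m, dtype=float)
    if np.any(sl <= 0):
        raise ValueError("sl_m must be positive")
    coef = float(params[f"bci{s}"])
    expo = float(params[f"b{s}"])
    if habitat == "riverine":
        coef += float(params.get(f"r{s}", 0.0))
        expo += float(params.get(f"br{s}", 0.0))
    elif habitat != "coastal":
        raise ValueError(f"unknown habitat {habitat!r}")
    if sex == "M":
        coef += float(params.get(f"m{s}", 0.0))
        expo += float(params.get(f"bm{s}", 0.0))
    if model == "bci3":
        if ug_m is None:
            raise ValueError("bci3 prediction requires ug_m")
        ug = np.asarray(ug_m, dtype=float)
        if np.any(ug <= 0):
            raise ValueError("ug_m must be positive")
        out = coef * sl * ug ** expo
    else:
        out = coef * sl ** expo
    return float(out) if np.isscalar(sl_m) else out


def fit_ols_allometry(records, model: str = "bci1") -> dict[str, float]:
    """Plain (unweighted) nonlinear least-squares fit of one model.

    The non-robust comparison fit used by recovery experiments: ordinary
    nonlinear least squares via ``scipy.optimize.curve_fit``, initialised
    from the log-linearised OLS, no factors, no reweighting.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    m = AllometricModel(frame, index=model)
    x0 = m._log_ols_start()
    s = INDEX_INFO[model]["suffix"]
    if model == "bci3":
        xdata = np.vstack([m.sl, m.ug])

        def f(x, coef, expo):
            return coef * x[0] * x[1] ** expo
    else:
        xdata = m.sl

        def f(x, coef, expo):
            return coef * x ** expo

    popt, _ = curve_fit(f, xdata, m.endog, p0=[x0[0], x0[-1]], maxfev=20000)
    return {f"bci{s}": float(popt[0]), f"b{s}": float(popt[1])}
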