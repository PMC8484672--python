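"""Group inference on body-condition scores.

Two tools: a high-breakdown robust linear factor model for the score

    BCI = a + c*Country + h*Habitat + s*Sex + f*FieldCondition

estimated MM-style (subsampling S-estimate of coefficients and scale,
then a bisquare M-step at fixed scale — the behaviour of high-breakdown
linear fitting as used for these data), and pairwise two-group
Wilcoxon rank-sum comparisons between localities with Bonferroni
adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .robust import (
    BISQUARE_C,
    S_BISQUARE_C,
    bisquare_psi,
    bisquare_psi_prime,
    bisquare_weights,
    m_scale,
)
from .scoring import BCIScoreTable

__all__ = [
    "ConditionFactorModel",
    "ConditionFactorResults",
    "PairwiseComparison",
    "RankDeficientError",
    "fit_robust_linear",
    "pairwise_wilcoxon",
]

#: Reference levels for treatment coding (explicit in all output).
REFERENCE_LEVELS = {"habitat": "coastal", "sex": "F", "field_condition": "ideal"}

VALID_TERMS = ("country", "habitat", "sex", "field_condition")


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (aliased factor terms)."""


def _scores_frame(scores: Union[BCIScoreTable, pd.DataFrame],
                  index: Optional[str]) -> pd.DataFrame:
    frame = scores.data if isinstance(scores, BCIScoreTable) else scores
    if index is not None and "model" in frame.columns:
        frame = frame[frame["model"] == index]
    return frame.reset_index(drop=True)


class ConditionFactorModel:
    """Robust linear model of a BCI score on categorical factors.

    Parameters
    ----------
    scores : BCIScoreTable or DataFrame
        Needs a ``score`` column plus one column per included term
        (``country``/``location``, ``habitat``, ``sex``,
        ``condition_group``).
    index : str, optional
        Which index's rows to use when the table holds several.
    terms : iterable of {"country", "habitat", "sex", "field_condition"}

    Treatment (dummy) coding with explicit reference levels: coastal,
    female, ideal (C3) condition, and the largest-sample country.
    Records of unknown sex are dropped when sex is a term.
    """

    def __init__(self, scores, terms: Iterable[str] = ("habitat", "sex"),
                 index: Optional[str] = None):
        terms = tuple(terms)
        for t in terms:
            if t not in VALID_TERMS:
                raise ValueError(f"unknown term {t!r}; allowed: {VALID_TERMS}")
        if not terms:
            raise ValueError("at least one term required")
        frame = _scores_frame(scores, index)

        col_of = {"country": "country", "habitat": "habitat", "sex": "sex",
                  "field_condition": "condition_group"}
        keep = np.ones(len(frame), dtype=bool)
        if "sex" in terms:
            keep &= (frame["sex"] != "unknown").to_numpy()
        if "field_condition" in terms:
            keep &= frame["condition_group"].isin(("thin", "ideal", "obese")).to_numpy()
        frame = frame.loc[keep].reset_index(drop=True)

        names = ["intercept"]
        cols = [np.ones(len(frame))]
        self.reference_levels: dict[str, str] = {}
        for term in terms:
            col = frame[col_of[term]].astype(str)
            levels = sorted(col.unique())
            if len(levels) < 2:
                raise ValueError(
                    f"term {term!r} needs >= 2 observed levels, found {levels}")
            if term == "country":
                ref = col.value_counts().idxmax()  # largest sample
            else:
                ref = REFERENCE_LEVELS[term]
                if ref not in levels:
                    ref = levels[0]
            self.reference_levels[term] = ref
            for lev in levels:
                if lev == ref:
                    continue
                names.append(f"{term}[{lev}]")
                cols.append((col == lev).to_numpy(dtype=float))

        self.exog = np.column_stack(cols)
        self.endog = frame["score"].to_numpy(dtype=float)
        self.param_names = names
        self.terms = terms
        self.frame = frame

        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            aliased = self._find_aliased()
            raise RankDeficientError(
                "design matrix is rank deficient; aliased column(s): "
                + ", ".join(aliased))
        if len(self.endog) < self.exog.shape[1] + 5:
            raise ValueError(
                f"need at least {self.exog.shape[1] + 5} observations for "
                f"{self.exog.shape[1]} parameters, have {len(self.endog)}")

    def _find_aliased(self) -> list[str]:
        """Name columns linearly dependent on the preceding ones."""
        aliased = []
        X = self.exog
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                aliased.append(self.param_names[j])
        return aliased or ["<unidentified>"]

    @property
    def nobs(self) -> int:
        return len(self.endog)

    # -- estimation ------------------------------------------------------

    def _s_estimate(self, rng: np.random.Generator, n_subsamples: int,
                    n_refine: int) -> tuple[np.ndarray, float]:
        """Subsampling S-estimate: best M-scale over exact p-subset fits,
        each refined by a few bisquare I-steps at the 50%-breakdown
        tuning."""
        X, y = self.exog, self.endog
        n, p = X.shape
        best_beta = None
        best_s = np.inf
        n_found = 0
        attempts = 0
        while n_found < n_subsamples and attempts < 20 * n_subsamples:
            attempts += 1
            idx = rng.choice(n, size=p, replace=False)
            try:
                beta = np.linalg.solve(X[idx], y[idx])
            except np.linalg.LinAlgError:
                continue
            n_found += 1
            for _ in range(n_refine):
                r = y - X @ beta
                s = m_scale(r, c=S_BISQUARE_C)
                if s == 0.0:
                    return beta, 0.0
                w = bisquare_weights(r / s, c=S_BISQUARE_C)
                Xw = X * w[:, None]
                try:
                    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
                except np.linalg.LinAlgError:
                    break
            s = m_scale(y - X @ beta, c=S_BISQUARE_C)
            if s < best_s:
                best_s, best_beta = s, beta
        if best_beta is None:
            # fall back to least squares (should not happen for full-rank X)
            best_beta = np.linalg.lstsq(X, y, rcond=None)[0]
            best_s = m_scale(y - X @ best_beta, c=S_BISQUARE_C)
        return best_beta, best_s

    def fit(self, seed: int = 20140101, n_subsamples: int = 200,
            n_refine: int = 3, tol: float = 1e-10,
            max_iter: int = 200) -> "ConditionFactorResults":
        """MM estimate: S-start, then bisquare IRLS (c = 4.685) at the
        fixed S-scale until the coefficients stabilise.

        The subsampling S-stage is seeded (default fixed) so repeated
        fits are reproducible.  A zero S-scale (exact fit, e.g. all
        scores identical) short-circuits: coefficients from the exact
        fit, zero scale, undefined tests.
        """
        rng = np.random.default_rng(seed)
        beta, s = self._s_estimate(rng, n_subsamples, n_refine)
        X, y = self.exog, self.endog
        n, p = X.shape
        converged = True
        n_iter = 0
        if s > 0:
            converged = False
            for n_iter in range(1, max_iter + 1):
                r = y - X @ beta
                w = bisquare_weights(r / s, c=BISQUARE_C)
                Xw = X * w[:, None]
                new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
                delta = np.max(np.abs(new - beta) / (np.abs(beta) + 1e-10))
                beta = new
                if delta < tol:
                    converged = True
                    break
            if not converged:
                warnings.warn("MM IRLS did not converge", RuntimeWarning,
                              stacklevel=2)

        resid = y - X @ beta
        if s > 0:
            u = resid / s
            a = float(np.mean(bisquare_psi(u, BISQUARE_C) ** 2))
            b = float(np.mean(bisquare_psi_prime(u, BISQUARE_C)))
            if b <= 0:
                cov = np.full((p, p), np.nan)
            else:
                cov = (s * s) * (a / (b * b)) * np.linalg.inv(X.T @ X / n) / n
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            weights = bisquare_weights(u, BISQUARE_C)
        else:
            cov = np.zeros((p, p))
            bse = np.zeros(p)
            weights = np.ones(n)

        return ConditionFactorResults(
            model=self,
            params=pd.Series(beta, index=self.param_names),
            bse=pd.Series(bse, index=self.param_names),
            cov_params=pd.DataFrame(cov, index=self.param_names,
                                    columns=self.param_names),
            scale=float(s),
            weights=weights,
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class ConditionFactorResults:
    """MM-fit results: coefficients, robust SEs, t tests, diagnostics."""

    model: ConditionFactorModel
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    scale: float
    weights: np.ndarray
    converged: bool
    n_iter: int

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_resid(self) -> int:
        return self.model.nobs - len(self.params)

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.params / self.bse
        return t.where(self.bse > 0, np.nan)

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.Series(p, index=self.params.index).where(np.isfinite(t), np.nan)

    def cell_means(self) -> pd.DataFrame:
        """Arithmetic group means per included term (parameterization-proof
        companion to the coefficients)."""
        col_of = {"country": "country", "habitat": "habitat", "sex": "sex",
                  "field_condition": "condition_group"}
        out = []
        for term in self.model.terms:
            g = self.model.frame.groupby(col_of[term])["score"]
            for level, mean in g.mean().items():
                out.append({"term": term, "level": level, "mean": mean,
                            "n": int(g.count()[level])})
        return pd.DataFrame(out)

    def summary(self) -> str:
        lines = [
            "Robust linear factor model (MM: S-start + bisquare M-step)",
            f"n = {self.nobs}, scale = {self.scale:.6g}, "
            f"converged = {self.converged}",
            "reference levels: " + ", ".join(
                f"{t}={l}" for t, l in self.model.reference_levels.items()),
            "",
            f"{'term':<24}{'estimate':>12}{'SE':>10}{'t':>9}{'p':>9}",
        ]
        for name in self.params.index:
            t, p = self.tvalues[name], self.pvalues[name]
            t_s = f"{t:.3f}" if np.isfinite(t) else "-"
            p_s = f"{p:.4f}" if np.isfinite(p) else "-"
            lines.append(f"{name:<24}{self.params[name]:>12.4f}"
                         f"{self.bse[name]:>10.4f}{t_s:>9}{p_s:>9}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "terms": list(self.model.terms),
            "reference_levels": dict(self.model.reference_levels),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "p": {k: (None if not np.isfinite(v) else float(v))
                  for k, v in self.pvalues.items()},
            "n_used": int(self.nobs),
            "robust_scale": float(self.scale),
            "converged": bool(self.converged),
        }


def fit_robust_linear(scores, terms: Iterable[str] = ("habitat", "sex"),
                      index: Optional[str] = None,
                      **fit_kwargs) -> ConditionFactorResults:
    """Fit the robust linear factor model on a score table."""
    return ConditionFactorModel(scores, terms=terms, index=index).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# pairwise Wilcoxon


@dataclass
class PairwiseComparison:
    """All-pairs two-group rank-sum comparison.

    Symmetric matrices of raw and adjusted p-values and of the rank-sum
    statistic; per-pair method metadata records whether the exact or the
    normal-approximation path produced each p.
    """

    groups: list[str]
    raw_p: pd.DataFrame
    adjusted_p: pd.DataFrame
    statistic: pd.DataFrame
    n_per_group: dict[str, int]
    method: str
    pair_methods: dict[tuple[str, str], str] = field(default_factory=dict)
    n_pairs: int = 0
    excluded_groups: list[str] = field(default_factory=list)

    def lower_triangle(self, digits: int = 4) -> pd.DataFrame:
        """Adjusted p-values in the conventional lower-triangle layout."""
        g = self.groups
        out = pd.DataFrame("", index=g[1:], columns=g[:-1], dtype=object)
        for i, gi in enumerate(g):
            for gj in g[:i]:
                out.loc[gi, gj] = round(float(self.adjusted_p.loc[gi, gj]), digits)
        return out


def pairwise_wilcoxon(
    scores,
    group_by: str = "location",
    adjust: str = "bonferroni",
    index: Optional[str] = None,
    value_col: str = "score",
) -> PairwiseComparison:
    """All-pairs two-sided Wilcoxon rank-sum tests between localities.

    Uses the exact null distribution when both groups have at most 10
    observations and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.  Bonferroni
    multiplies each raw p by the number of pairs, capped at 1.  Groups
    with fewer than 2 observations are excluded with a warning.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    frame = _scores_frame(scores, index)
    values = {}
    excluded = []
    for g, sub in frame.groupby(group_by):
        v = sub[value_col].to_numpy(dtype=float)
        if len(v) < 2:
            excluded.append(str(g))
            continue
        values[str(g)] = v
    if excluded:
        warnings.warn(
            f"excluded group(s) with < 2 observations: {', '.join(excluded)}",
            UserWarning, stacklevel=2)
    groups = sorted(values)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")

    m = len(groups) * (len(groups) - 1) // 2
    raw = pd.DataFrame(np.nan, index=groups, columns=groups)
    stat = pd.DataFrame(np.nan, index=groups, columns=groups)
    pair_methods: dict[tuple[str, str], str] = {}
    for gi, gj in itertools.combinations(groups, 2):
        x, y = values[gi], values[gj]
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        use_exact = no_ties and len(x) <= 10 and len(y) <= 10
        if use_exact:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            pair_methods[(gi, gj)] = "exact"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", use_continuity=True)
            pair_methods[(gi, gj)] = "normal_approx"
        raw.loc[gi, gj] = raw.loc[gj, gi] = float(res.pvalue)
        stat.loc[gi, gj] = stat.loc[gj, gi] = float(res.statistic)
    np.fill_diagonal(raw.values, 1.0)
    np.fill_diagonal(stat.values, np.nan)

    if adjust == "bonferroni":
        adj = (raw * m).clip(upper=1.0)
        np.fill_diagonal(adj.values, 1.0)
    else:
        adj = raw.copy()

    return PairwiseComparison(
        groups=groups, raw_p=raw, adjusted_p=adj, statistic=stat,
        n_per_group={g: len(values[g]) for g in groups},
        method="wilcoxon rank-sum, two-sided; "
               "exact when both n<=10 and no ties, else normal approximation "
               "with tie and continuity corrections; adjust=" + adjust,
        pair_methods=pair_methods, n_pairs=m, excluded_groups=excluded,
    )
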