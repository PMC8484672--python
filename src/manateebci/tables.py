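"""Standard summary tables for a scored population.

Analogues of the study's report tables: per-country index means, fitted
parameters with similarity contrasts, per sex-by-habitat index summaries,
and the sex/age-class census.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .allometry import AllometricResults
from .records import MorphRecord
from .scoring import BCIScoreTable

__all__ = [
    "country_summary",
    "parameter_table",
    "cell_summary",
    "census_table",
    "summary_tables",
]


def country_summary(scores: BCIScoreTable) -> pd.DataFrame:
    """Per habitat and country: mean and standard error of each index."""
    frame = scores.data
    rows = []
    for (habitat, country, model), sub in frame.groupby(
            ["habitat", "country", "model"]):
        v = sub["score"].to_numpy(dtype=float)
        rows.append({
            "habitat": habitat, "country": country, "model": model,
            "n": len(v), "mean": float(np.mean(v)),
            "se": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
        })
    out = pd.DataFrame(rows).sort_values(["habitat", "country", "model"])
    return out.reset_index(drop=True)


def parameter_table(fits: Mapping[str, AllometricResults]) -> pd.DataFrame:
    """Fitted parameters and geometric-similarity contrasts for each model."""
    rows = []
    for model in sorted(fits):
        fit = fits[model]
        tests = fit._test_table()
        for name in fit.params.index:
            rows.append({
                "model": model, "parameter": name,
                "estimate": float(fit.params[name]), "se": float(fit.bse[name]),
                "t": float(tests.loc[name, "t"]), "p": float(tests.loc[name, "p"]),
            })
        for _, r in fit.similarity_test().iterrows():
            rows.append({
                "model": model, "parameter": r["parameter"],
                "estimate": r["estimate"], "se": r["se"], "t": r["t"], "p": r["p"],
            })
    return pd.DataFrame(rows)


def cell_summary(scores: BCIScoreTable) -> pd.DataFrame:
    """Per sex-by-habitat cell and index: n, exponent used, mean, SD, range."""
    rows = []
    for (habitat, sex, model), sub in scores.data.groupby(
            ["habitat", "sex", "model"]):
        v = sub["score"].to_numpy(dtype=float)
        b_used = sub["b_used"].unique()
        rows.append({
            "habitat": habitat, "sex": sex, "model": model, "n": len(v),
            "b": float(b_used[0]) if len(b_used) == 1 else np.nan,
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
            "min": float(np.min(v)), "max": float(np.max(v)),
        })
    out = pd.DataFrame(rows).sort_values(["habitat", "sex", "model"])
    return out.reset_index(drop=True)


def census_table(records: Sequence[MorphRecord]) -> pd.DataFrame:
    """Counts of sex and age class per country."""
    rows = []
    for rec in records:
        rows.append({"country": rec.country or "(unknown)", "sex": rec.sex,
                     "age_class": rec.age_class or "(no length)"})
    frame = pd.DataFrame(rows)
    out = []
    for country, sub in frame.groupby("country"):
        entry = {"country": country,
                 "females": int((sub["sex"] == "F").sum()),
                 "males": int((sub["sex"] == "M").sum()),
                 "adults": int((sub["age_class"] == "adult").sum()),
                 "subadults": int((sub["age_class"] == "subadult").sum()),
                 "calves": int((sub["age_class"] == "calf").sum()),
                 "total": len(sub)}
        out.append(entry)
    return pd.DataFrame(out).sort_values("country").reset_index(drop=True)


def summary_tables(
    scores: BCIScoreTable,
    fits: Mapping[str, AllometricResults],
    records: Optional[Sequence[MorphRecord]] = None,
) -> dict[str, pd.DataFrame]:
    """The full report bundle, keyed by table name."""
    bundle = {
        "country_summary": country_summary(scores),
        "parameters": parameter_table(fits),
        "cell_summary": cell_summary(scores),
    }
    if records is not None:
        bundle["census"] = census_table(records)
    return bundle
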