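"""Per-individual body-condition scores and allometric weight prediction.

With the exponents b1/b2/b3 estimated, each animal's indices are plain
ratios:

    BCI1 = UG / SL**b1        BCI2 = W / SL**b2        BCI3 = W / (SL * UG**b3)

and body mass can be predicted from length and girth by inverting the
third model, W = BCI3 * SL * UG**b3; the population-average constants are
BCI3 = 37.67 and b3 = 1.893 (SL and UG in meters, W in kilograms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .allometry import AllometricResults
from .records import MorphRecord, merge_field_scores

__all__ = [
    "DEFAULT_BCI3",
    "DEFAULT_B3",
    "BCIScoreTable",
    "compute_bci",
    "estimate_weight",
    "score_population",
]

#: Average-manatee weight-law constants (all habitats, both sexes).
DEFAULT_BCI3 = 37.67
DEFAULT_B3 = 1.893

_REQUIRES = {"bci1": ("sl_m", "ug_m"), "bci2": ("sl_m", "w_kg"),
             "bci3": ("sl_m", "ug_m", "w_kg")}


def compute_bci(record: MorphRecord, model: str, b: float) -> Optional[float]:
    """One animal's index under exponent ``b``; None if a measurement is missing.

    bci1 = UG/SL^b, bci2 = W/SL^b, bci3 = W/(SL*UG^b).
    """
    if model not in _REQUIRES:
        raise ValueError(f"model must be one of {tuple(_REQUIRES)}, got {model!r}")
    if b <= 0:
        raise ValueError(f"exponent must be positive, got {b}")
    vals = {name: getattr(record, name) for name in _REQUIRES[model]}
    if any(v is None for v in vals.values()):
        return None
    if any(v <= 0 for v in vals.values()):
        raise ValueError(f"measurements must be positive: {vals}")
    if model == "bci1":
        return vals["ug_m"] / vals["sl_m"] ** b
    if model == "bci2":
        return vals["w_kg"] / vals["sl_m"] ** b
    return vals["w_kg"] / (vals["sl_m"] * vals["ug_m"] ** b)


def estimate_weight(sl_m, ug_m, bci3: float = DEFAULT_BCI3,
                    b3: float = DEFAULT_B3):
    """Predicted body mass (kg) from length and girth (meters).

    W = bci3 * SL * UG**b3.  Defaults are the average-manatee constants;
    habitat/sex-specific values from an :class:`AllometricResults` may be
    substituted.  Accepts scalars or arrays.
    """
    sl = np.asarray(sl_m, dtype=float)
    ug = np.asarray(ug_m, dtype=float)
    if np.any(sl <= 0) or np.any(ug <= 0):
        raise ValueError("sl_m and ug_m must be strictly positive")
    w = bci3 * sl * ug ** b3
    return float(w) if np.isscalar(sl_m) and np.isscalar(ug_m) else w


@dataclass
class BCIScoreTable:
    """Per-individual index values with the exponent that produced each.

    ``data`` has one row per (record, model) pair: record id, model,
    b_used, score, habitat, sex, country, location, condition group, and
    a flag for records scored with the reference exponent because their
    stratum was absent from the fit.
    """

    data: pd.DataFrame

    def for_index(self, model: str) -> pd.DataFrame:
        return self.data[self.data["model"] == model].reset_index(drop=True)

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        """Display copy with scores at table precision (3 decimals);
        full precision is retained in ``data``."""
        out = self.data.copy()
        out["score"] = out["score"].round(decimals)
        out["b_used"] = out["b_used"].round(decimals)
        return out

    def __len__(self) -> int:
        return len(self.data)


def score_population(
    records: Sequence[MorphRecord],
    fits: Mapping[str, AllometricResults],
    use_offsets: bool = True,
) -> BCIScoreTable:
    """Score every record under every fitted index its measurements allow.

    Each record uses its group-specific exponent (reference b plus the
    habitat/sex offsets applicable to it) from the corresponding fit;
    with ``use_offsets=False`` the reference-cell b serves all records.
    Records whose stratum cannot be resolved (unknown sex under a
    sex-factor fit) are scored with the reference b and flagged.
    """
    rows = []
    for model, fit in fits.items():
        if not fit.converged:
            raise ValueError(f"fit for {model} did not converge; refusing to score")
        for rec in records:
            flagged = False
            habitat, sex = rec.habitat, rec.sex
            if use_offsets:
                if "sex" in fit.model.factors and sex == "unknown":
                    sex = "F"  # reference
                    flagged = True
                b_used = fit.exponent_for(habitat=habitat, sex=sex)
            else:
                b_used = fit.exponent_for()
            score = compute_bci(rec, model, b_used)
            if score is None:
                continue
            rows.append({
                "id": rec.id, "model": model, "b_used": b_used, "score": score,
                "habitat": rec.habitat, "sex": rec.sex, "country": rec.country,
                "location": rec.location,
                "condition_group": merge_field_scores(rec.field_score),
                "age_class": rec.age_class,
                "reference_b_fallback": flagged,
            })
    cols = ["id", "model", "b_used", "score", "habitat", "sex", "country",
            "location", "condition_group", "age_class", "reference_b_fallback"]
    return BCIScoreTable(pd.DataFrame(rows, columns=cols))
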