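"""Marginal means and corrector-treatment contrasts.

Both treatment arms must be levels of a single position fit so that the
fixed-effect covariance is available for error propagation. Marginal means
are evaluated on the link scale at random-effect mean zero and at the
average offset over all samples; that constant is identical in every
condition and cancels exactly in both contrasts.

defect  = marginal mean of the variant under the control condition
          minus the WT marginal mean under control
rescue  = marginal mean of the variant under corrector treatment
          minus its marginal mean under control

Wald statistics divide each estimate by its propagated SE; p-values come
from the standard normal and are BH-adjusted across variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import LN2, PositionFit, bh_adjust

RESCUE_CLASSES = ("no-defect", "defect-not-rescued", "defect-rescued", "NA")


def marginal_means(fit: PositionFit, treatment: str) -> pd.DataFrame:
    """log2-scaled marginal mean and SE per variant (including WT)."""
    if treatment not in fit.conditions:
        raise ValueError(f"condition {treatment!r} not in fit")
    rows = []
    for v in ["WT"] + fit.variants:
        coef = np.zeros(fit.n_fixed)
        coef[fit.param_index(None, treatment)] = 1.0
        if v != "WT":
            coef[fit.param_index(v, treatment)] = 1.0
        est, se = fit.contrast(coef)
        rows.append(
            {
                "variant": v,
                "treatment": treatment,
                "mm_log2": (est + fit.mean_offset) / LN2,
                "se_log2": se / LN2,
            }
        )
    return pd.DataFrame(rows)


def _contrast_row(fit: PositionFit, coef: np.ndarray) -> tuple[float, float, float]:
    est, se = fit.contrast(coef)
    est, se = est / LN2, se / LN2
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
    return est, se, p


def defect_contrast(fit: PositionFit, control: str) -> pd.DataFrame:
    """Variant-minus-WT difference under the control condition (log2).

    The condition intercept and offset cancel, leaving the variant's control
    deviation; the SE uses the full fixed-effect covariance. WT's defect is
    exactly zero.
    """
    rows = [{"variant": "WT", "defect": 0.0, "defect_se": 0.0, "defect_p": np.nan}]
    for v in fit.variants:
        coef = np.zeros(fit.n_fixed)
        coef[fit.param_index(v, control)] = 1.0
        est, se, p = _contrast_row(fit, coef)
        rows.append({"variant": v, "defect": est, "defect_se": se, "defect_p": p})
    return pd.DataFrame(rows)


def rescue_contrast(fit: PositionFit, control: str, treated: str) -> pd.DataFrame:
    """Within-variant treated-minus-control difference (log2)."""
    rows = []
    for v in ["WT"] + fit.variants:
        coef = np.zeros(fit.n_fixed)
        coef[fit.param_index(None, treated)] += 1.0
        coef[fit.param_index(None, control)] -= 1.0
        if v != "WT":
            coef[fit.param_index(v, treated)] += 1.0
            coef[fit.param_index(v, control)] -= 1.0
        est, se, p = _contrast_row(fit, coef)
        rows.append({"variant": v, "rescue": est, "rescue_se": se, "rescue_p": p})
    return pd.DataFrame(rows)


def contrast_table(
    fits: dict[int, PositionFit] | list[PositionFit],
    control: str,
    treated: str,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Defect and rescue contrasts with BH q-values and rescue classes.

    q-values are computed across all variants of all supplied fits; WT rows
    are excluded from testing.
    """
    fit_list = list(fits.values()) if isinstance(fits, dict) else list(fits)
    parts = []
    for fit in fit_list:
        d = defect_contrast(fit, control)
        r = rescue_contrast(fit, control, treated)
        t = d.merge(r, on="variant")
        t = t[t["variant"] != "WT"]
        t.insert(1, "position", [fit.variant_position.get(v, fit.position) for v in t["variant"]])
        parts.append(t)
    out = pd.concat(parts, ignore_index=True)
    out["defect_q"] = bh_adjust(out["defect_p"])
    out["rescue_q"] = bh_adjust(out["rescue_p"])
    out["rescue_class"] = classify_rescue(out, fdr=fdr)
    return out


def classify_rescue(contrasts: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Apply the compound defect/rescue rule.

    defect-rescued: defect significantly negative AND rescue significantly
    positive at the FDR; defect-not-rescued: only the defect test passes;
    otherwise no-defect. Non-estimable entries propagate NA.
    """
    labels = []
    for _, r in contrasts.iterrows():
        if not (np.isfinite(r["defect_q"]) and np.isfinite(r["defect"])):
            labels.append("NA")
            continue
        has_defect = r["defect_q"] < fdr and r["defect"] < 0
        rescued = (
            np.isfinite(r["rescue_q"]) and r["rescue_q"] < fdr and r["rescue"] > 0
        )
        if has_defect and rescued:
            labels.append("defect-rescued")
        elif has_defect:
            labels.append("defect-not-rescued")
        else:
            labels.append("no-defect")
    return pd.Series(labels, index=contrasts.index, name="rescue_class")
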