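"""Per-position negative-binomial mixed model with Laplace-approximated
barcode random intercepts.

For one protein position, counts of every variant's barcodes plus all
wild-type barcodes of the same subregion are modeled as

    count_{ijkm} ~ NB(mu_ij, theta),   Var = mu + mu^2/theta
    log mu_ij = beta_cond[i] + beta_var[j, i] + alpha_k + offset(gamma_m)
    alpha_k ~ N(0, sigma^2)

with the WT deviation fixed at zero by reference coding, a single theta and
sigma^2 shared across conditions, and alpha_k shared by every sample of
barcode k. The marginal likelihood integrates each scalar alpha_k out by a
Laplace approximation (inner per-barcode Newton optimization); the outer
problem maximizes over (beta, log sigma, log theta) by L-BFGS-B with an
analytic gradient obtained by implicit differentiation of the inner mode.
Standard errors come from the inverse observed information (finite
differences of the analytic gradient) at the optimum.

Everything internal is on the natural-log scale; fold changes are converted
to log2 only at the reporting boundary.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

LN2 = np.log(2.0)

_LOG_SIGMA_BOUNDS = (np.log(1e-4), np.log(10.0))
_LOG_THETA_BOUNDS = (np.log(1e-3), np.log(1e8))
_BETA_BOUND = 30.0
#: fitted deviations beyond this magnitude indicate separation (e.g. a
#: variant with all-zero counts in one condition) and are not estimable
_ESTIMABLE_LIMIT = 15.0


@dataclasses.dataclass
class PositionDataset:
    """Long-format data for one position fit.

    ``var_idx`` codes non-WT variants 0..V-1 and WT cells as -1; every
    barcode has one row per sample (zeros explicit).
    """

    position: int
    y: np.ndarray
    barcode_idx: np.ndarray
    cond_idx: np.ndarray
    var_idx: np.ndarray
    offset: np.ndarray
    barcodes: list[str]
    conditions: list[str]
    variants: list[str]
    variant_alt: dict[str, str]
    variant_position: dict[str, int]
    non_estimable: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclasses.dataclass
class PositionFit:
    """ML estimates for one position (natural-log scale)."""

    position: int
    conditions: list[str]
    variants: list[str]
    variant_alt: dict[str, str]
    variant_position: dict[str, int]
    beta_cond: np.ndarray          # (C,)
    beta_var: np.ndarray           # (V, C), deviations from WT
    sigma2: float
    theta: float
    cov_fixed: np.ndarray          # (C + V*C, C + V*C)
    loglik: float
    converged: bool
    mean_offset: float
    non_estimable: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_fixed(self) -> int:
        return len(self.conditions) * (1 + len(self.variants))

    def param_index(self, variant: str | None, condition: str) -> int:
        """Position of a coefficient in the fixed-effect vector.

        ``variant=None`` addresses the condition intercept.
        """
        C = len(self.conditions)
        ci = self.conditions.index(condition)
        if variant is None or variant == "WT":
            return ci
        return C + self.variants.index(variant) * C + ci

    def contrast(self, coef: np.ndarray) -> tuple[float, float]:
        """Estimate and SE of a linear combination of fixed effects."""
        full = np.concatenate([self.beta_cond, self.beta_var.ravel()])
        est = float(coef @ full)
        se = float(np.sqrt(max(coef @ self.cov_fixed @ coef, 0.0)))
        return est, se


# ---------------------------------------------------------------------------
# dataset construction


def build_position_dataset(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    position: int,
    subregion: str | None = None,
) -> PositionDataset:
    """Subset counts to one position's variants plus its subregion's WT.

    Variants with no barcodes or with all-zero counts are excluded from the
    design and recorded as non-estimable.
    """
    if "offset" not in sample_sheet.columns:
        raise ValueError("sample sheet has no offset column; run compute_offsets")
    is_wt = counts["variant"] == "WT"
    at_pos = (counts["position"] == position) & ~is_wt
    if not at_pos.any():
        raise ValueError(f"no variant barcodes at position {position}")
    if subregion is None and "subregion" in counts.columns:
        subregion = counts.loc[at_pos, "subregion"].iloc[0]
    wt_rows = is_wt & (
        (counts["subregion"] == subregion) if "subregion" in counts.columns else True
    )
    if not wt_rows.any():
        raise ValueError(f"no WT barcodes in subregion {subregion!r}")
    sub = counts[at_pos | wt_rows]

    sids = sample_sheet["sample_id"].tolist()
    conditions = list(dict.fromkeys(sample_sheet["condition"]))
    cond_of_sample = sample_sheet.set_index("sample_id")["condition"]
    offset_of_sample = sample_sheet.set_index("sample_id")["offset"]

    y_mat = sub[sids].to_numpy(dtype=np.float64)
    bc = sub["barcode"].tolist()
    var_labels = sub["variant"].to_numpy()

    totals = pd.Series(y_mat.sum(axis=1), index=var_labels).groupby(level=0).sum()
    dead = sorted(v for v, t in totals.items() if v != "WT" and t == 0)
    keep = ~np.isin(var_labels, dead)
    y_mat, var_labels = y_mat[keep], var_labels[keep]
    bc = [b for b, k in zip(bc, keep) if k]
    sub = sub[keep]

    variants = sorted(v for v in set(var_labels) if v != "WT")
    vmap = {v: i for i, v in enumerate(variants)}
    var_code_bc = np.array([vmap.get(v, -1) for v in var_labels])

    n_bc, n_s = y_mat.shape
    y = y_mat.ravel()
    barcode_idx = np.repeat(np.arange(n_bc), n_s)
    var_idx = np.repeat(var_code_bc, n_s)
    cond_per_sample = np.array([conditions.index(cond_of_sample[s]) for s in sids])
    off_per_sample = np.array([float(offset_of_sample[s]) for s in sids])
    cond_idx = np.tile(cond_per_sample, n_bc)
    offset = np.tile(off_per_sample, n_bc)

    alt = {}
    pos_of = {}
    for v, a, p in zip(sub["variant"], sub["alt_aa"], sub["position"]):
        if v != "WT":
            alt[v] = a
            pos_of[v] = int(p)
    return PositionDataset(
        position=int(position),
        y=y.astype(np.float64),
        barcode_idx=barcode_idx,
        cond_idx=cond_idx,
        var_idx=var_idx,
        offset=offset,
        barcodes=bc,
        conditions=conditions,
        variants=variants,
        variant_alt=alt,
        variant_position=pos_of,
        non_estimable=dead,
    )


def downsample_barcodes(
    data: PositionDataset, n_barcodes: int, seed: int
) -> PositionDataset:
    """Keep a uniform random subset of barcodes per variant (and for WT).

    Variants (or WT) with fewer than ``n_barcodes`` barcodes keep all of
    them. Sampling is without replacement and deterministic in ``seed``.
    """
    if n_barcodes < 2:
        raise ValueError("n_barcodes must be >= 2")
    rng = np.random.default_rng(seed)
    first_cell = np.flatnonzero(np.diff(data.barcode_idx, prepend=-1))
    bc_var = data.var_idx[first_cell]  # variant code per barcode
    chosen: list[np.ndarray] = []
    for code in sorted(set(bc_var)):
        members = np.flatnonzero(bc_var == code)
        if len(members) > n_barcodes:
            members = np.sort(rng.choice(members, size=n_barcodes, replace=False))
        chosen.append(members)
    keep_bc = np.sort(np.concatenate(chosen))
    remap = -np.ones(data.n_barcodes, dtype=int)
    remap[keep_bc] = np.arange(len(keep_bc))
    mask = np.isin(data.barcode_idx, keep_bc)
    return dataclasses.replace(
        data,
        y=data.y[mask],
        barcode_idx=remap[data.barcode_idx[mask]],
        cond_idx=data.cond_idx[mask],
        var_idx=data.var_idx[mask],
        offset=data.offset[mask],
        barcodes=[data.barcodes[i] for i in keep_bc],
    )


# ---------------------------------------------------------------------------
# Laplace marginal likelihood


class _LaplaceObjective:
    """Negative Laplace marginal log-likelihood and its analytic gradient.

    Parameter vector: [beta_cond (C), beta_var (V*C), log sigma, log theta].
    Inner per-barcode modes are warm-started across evaluations.
    """

    def __init__(self, data: PositionDataset):
        self.d = data
        self.C = data.n_conditions
        self.V = data.n_variants
        self.K = data.n_barcodes
        self.n_fixed = self.C + self.V * self.C
        self.mask_var = data.var_idx >= 0
        self.flat_idx = np.where(
            self.mask_var, data.var_idx * self.C + data.cond_idx, 0
        )
        self._alpha = np.zeros(self.K)
        self._lgamma_y1 = special.gammaln(data.y + 1.0)

    def eta(self, params: np.ndarray) -> np.ndarray:
        beta_c = params[: self.C]
        beta_v = params[self.C : self.n_fixed]
        eta = beta_c[self.d.cond_idx] + self.d.offset
        eta = eta + np.where(self.mask_var, beta_v[self.flat_idx], 0.0)
        return eta

    def _solve_modes(self, eta, sigma2, theta):
        """Newton iterations for all barcode modes simultaneously."""
        d = self.d
        alpha = self._alpha
        for _ in range(200):
            mu = np.exp(np.clip(eta + alpha[d.barcode_idx], -700, 700))
            frac = mu / (theta + mu)
            u = d.y - (d.y + theta) * frac
            w = (d.y + theta) * theta * frac / (theta + mu)
            g = np.bincount(d.barcode_idx, u, self.K) - alpha / sigma2
            H = np.bincount(d.barcode_idx, w, self.K) + 1.0 / sigma2
            if np.max(np.abs(g)) < 1e-9:
                break
            step = np.clip(g / H, -1.0, 1.0)
            alpha = alpha + step
        self._alpha = alpha
        return alpha

    def value_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.d
        sigma2 = np.exp(2.0 * params[-2])
        theta = np.exp(params[-1])
        eta = self.eta(params)
        alpha = self._solve_modes(eta, sigma2, theta)

        a_cell = alpha[d.barcode_idx]
        log_mu = np.clip(eta + a_cell, -700, 700)
        mu = np.exp(log_mu)
        tpm = theta + mu
        frac = mu / tpm

        lp = (
            special.gammaln(d.y + theta)
            - special.gammaln(theta)
            - self._lgamma_y1
            + theta * np.log(theta)
            + d.y * log_mu
            - (d.y + theta) * np.log(tpm)
        )
        u = d.y - (d.y + theta) * frac
        w = (d.y + theta) * theta * frac / tpm
        v3 = -(d.y + theta) * theta * mu * (theta - mu) / tpm**3

        sum_lp = np.bincount(d.barcode_idx, lp, self.K)
        H = np.bincount(d.barcode_idx, w, self.K) + 1.0 / sigma2
        Sv = np.bincount(d.barcode_idx, v3, self.K)
        h_k = sum_lp - alpha**2 / (2 * sigma2) - 0.5 * np.log(2 * np.pi * sigma2)
        ll = float(np.sum(h_k + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(H)))

        # fixed-effect gradient via per-cell adjusted scores
        Hc = H[d.barcode_idx]
        SvH2 = (Sv / H**2)[d.barcode_idx]
        s_cell = u + 0.5 * v3 / Hc - 0.5 * SvH2 * w
        grad = np.empty(self.n_fixed + 2)
        grad[: self.C] = np.bincount(d.cond_idx, s_cell, self.C)
        grad[self.C : self.n_fixed] = np.bincount(
            self.flat_idx[self.mask_var], s_cell[self.mask_var], self.V * self.C
        )

        # log sigma
        dadls = (2.0 * alpha / sigma2) / H
        dHdls = -2.0 / sigma2 - Sv * dadls
        grad[-2] = float(np.sum(alpha**2 / sigma2 - 1.0 - 0.5 * dHdls / H))

        # log theta
        dig = special.digamma(d.y + theta) - special.digamma(theta)
        dlp_dt = dig + np.log(theta) + 1.0 - np.log(tpm) - (d.y + theta) / tpm
        du_dt = mu * (d.y - mu) / tpm**2
        dw_dt = mu * (d.y * (mu - theta) + 2.0 * theta * mu) / tpm**3
        S_dlp = np.bincount(d.barcode_idx, dlp_dt, self.K)
        S_du = np.bincount(d.barcode_idx, du_dt, self.K)
        S_dw = np.bincount(d.barcode_idx, dw_dt, self.K)
        dadlt = theta * S_du / H
        dHdlt = theta * S_dw - Sv * dadlt
        grad[-1] = float(np.sum(theta * S_dlp - 0.5 * dHdlt / H))

        return -ll, -grad

    def loglik(self, params: np.ndarray) -> float:
        return -self.value_grad(params)[0]


def _start_values(data: PositionDataset) -> np.ndarray:
    """Moment-based starting point on the (beta, log sigma, log theta) scale."""
    C, V = data.n_conditions, data.n_variants
    adj = np.log(data.y + 0.5) - data.offset
    start = np.zeros(C + V * C + 2)
    for c in range(C):
        wt = (data.var_idx < 0) & (data.cond_idx == c)
        start[c] = adj[wt].mean() if wt.any() else 0.0
        for v in range(V):
            cell = (data.var_idx == v) & (data.cond_idx == c)
            if cell.any():
                start[C + v * C + c] = np.clip(adj[cell].mean() - start[c], -10, 10)
    start[-2] = np.log(0.5)
    start[-1] = np.log(5.0)
    return start


def fit_position_model(
    data: PositionDataset,
    *,
    max_restarts: int = 3,
    seed: int = 0,
    compute_cov: bool = True,
) -> PositionFit:
    """Maximize the Laplace marginal likelihood for one position.

    Restarts from jittered starting values on failure; a fit that never
    converges is returned with ``converged=False`` and its effects should
    be treated as non-estimable.
    """
    if data.n_barcodes < 2:
        raise ValueError("need at least 2 barcodes")
    obj = _LaplaceObjective(data)
    n_fixed = obj.n_fixed
    bounds = (
        [(-_BETA_BOUND, _BETA_BOUND)] * n_fixed
        + [_LOG_SIGMA_BOUNDS, _LOG_THETA_BOUNDS]
    )
    rng = np.random.default_rng(seed)
    base_start = _start_values(data)
    best = None
    for attempt in range(max_restarts + 1):
        start = base_start.copy()
        if attempt > 0:
            start[:n_fixed] += rng.normal(0, 0.3, n_fixed)
            start[-2:] += rng.normal(0, 0.5, 2)
            start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        obj._alpha = np.zeros(obj.K)
        res = optimize.minimize(
            obj.value_grad,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            best = res if res.fun <= best.fun else best
            break
    params = best.x
    converged = bool(best.success)

    C, V = data.n_conditions, data.n_variants
    cov_fixed = np.full((n_fixed, n_fixed), np.nan)
    if compute_cov:
        cov_fixed = _covariance(obj, params, bounds)

    beta_cond = params[:C].copy()
    beta_var = params[C:n_fixed].reshape(V, C).copy()
    fit = PositionFit(
        position=data.position,
        conditions=list(data.conditions),
        variants=list(data.variants),
        variant_alt=dict(data.variant_alt),
        variant_position=dict(data.variant_position),
        beta_cond=beta_cond,
        beta_var=beta_var,
        sigma2=float(np.exp(2 * params[-2])),
        theta=float(np.exp(params[-1])),
        cov_fixed=cov_fixed,
        loglik=float(-best.fun),
        converged=converged,
        mean_offset=float(np.mean(data.offset)),
        non_estimable=list(data.non_estimable),
    )
    return fit


def _covariance(obj: _LaplaceObjective, params: np.ndarray, bounds) -> np.ndarray:
    """Fixed-effect covariance from the observed information.

    The Hessian of the negative log-likelihood is built by central finite
    differences of the analytic gradient; parameters pinned at their box
    bounds (e.g. log sigma when the data carry no barcode variation) are
    profiled out before inversion.
    """
    n = len(params)
    n_fixed = obj.n_fixed
    free = [
        i
        for i in range(n)
        if i < n_fixed
        or (params[i] - bounds[i][0] > 1e-6 and bounds[i][1] - params[i] > 1e-6)
    ]
    h = 1e-5 * np.maximum(1.0, np.abs(params))
    Hess = np.zeros((len(free), len(free)))
    for a, i in enumerate(free):
        plus = params.copy()
        plus[i] += h[i]
        minus = params.copy()
        minus[i] -= h[i]
        gp = obj.value_grad(plus)[1]
        gm = obj.value_grad(minus)[1]
        Hess[a] = ((gp - gm) / (2 * h[i]))[free]
    Hess = 0.5 * (Hess + Hess.T)
    try:
        cov_free = np.linalg.inv(Hess)
    except np.linalg.LinAlgError:
        cov_free = np.linalg.pinv(Hess)
    if not np.all(np.isfinite(cov_free)) or np.any(np.diag(cov_free) < 0):
        cov_free = np.linalg.pinv(Hess)
    cov = np.zeros((n, n))
    for a, i in enumerate(free):
        cov[i, [j for j in free]] = cov_free[a]
    return cov[:n_fixed, :n_fixed]


# ---------------------------------------------------------------------------
# reporting


def effect_table(fit: PositionFit) -> pd.DataFrame:
    """Per-variant per-condition log2 fold changes with Wald inference.

    Natural-log deviations and SEs are divided by ln 2; z = estimate/SE and
    two-sided p-values come from the standard normal. BH q-values are added
    separately (see bh_adjust) at the chosen scope.
    """
    rows = []
    C = len(fit.conditions)
    for vi, v in enumerate(fit.variants):
        for ci, cond in enumerate(fit.conditions):
            est = fit.beta_var[vi, ci]
            idx = C + vi * C + ci
            var = fit.cov_fixed[idx, idx]
            se = np.sqrt(var) if np.isfinite(var) and var >= 0 else np.nan
            estimable = (
                fit.converged and np.isfinite(se) and se > 0
                and abs(est) < _ESTIMABLE_LIMIT
            )
            if estimable:
                z = est / se
                p = 2.0 * stats.norm.sf(abs(z))
            else:
                z = p = np.nan
            rows.append(
                {
                    "variant": v,
                    "position": fit.variant_position.get(v, fit.position),
                    "alt_aa": fit.variant_alt.get(v, ""),
                    "condition": cond,
                    "log2fc": est / LN2,
                    "se": se / LN2 if np.isfinite(se) else np.nan,
                    "z": z,
                    "p": p,
                    "estimable": estimable,
                }
            )
    for v in fit.non_estimable:
        for cond in fit.conditions:
            rows.append(
                {
                    "variant": v,
                    "position": fit.position,
                    "alt_aa": "",
                    "condition": cond,
                    "log2fc": np.nan,
                    "se": np.nan,
                    "z": np.nan,
                    "p": np.nan,
                    "estimable": False,
                }
            )
    return pd.DataFrame(rows)


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN entries are excluded from the denominator and returned as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def add_q_values(effects: pd.DataFrame, scope: str = "condition") -> pd.DataFrame:
    """Attach BH q-values; default scope is per condition across variants."""
    out = effects.copy()
    out["q"] = np.nan
    if scope == "condition":
        for _, idx in out.groupby("condition").groups.items():
            out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"])
    elif scope == "global":
        out["q"] = bh_adjust(out["p"])
    else:
        raise ValueError(f"unknown BH scope {scope!r}")
    return out


def classify_variants(effects: pd.DataFrame, fdr: float = 0.01) -> pd.Series:
    """Call LoF/GoF/WT-like per (variant, condition) at the given FDR."""
    if "q" not in effects.columns:
        raise ValueError("run add_q_values first")
    labels = []
    for _, r in effects.iterrows():
        if not r["estimable"] or not np.isfinite(r["q"]):
            labels.append("NA")
        elif r["q"] < fdr and r["log2fc"] < 0:
            labels.append("LoF")
        elif r["q"] < fdr and r["log2fc"] > 0:
            labels.append("GoF")
        else:
            labels.append("WT-like")
    return pd.Series(labels, index=effects.index, name="class")


def residue_sensitivity(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-position summary: mean log2FC over sqrt of summed squared SEs.

    Nonsense variants are excluded. Rows are (position, condition); NaN when
    no estimable missense variant remains.
    """
    miss = effects[(effects["alt_aa"] != "*") & effects["estimable"]]
    rows = []
    for (pos, cond), grp in effects.groupby(["position", "condition"]):
        g = miss[(miss["position"] == pos) & (miss["condition"] == cond)]
        if len(g) == 0:
            score = np.nan
        else:
            score = g["log2fc"].mean() / np.sqrt((g["se"] ** 2).sum())
        rows.append({"position": pos, "condition": cond, "sensitivity": score})
    return pd.DataFrame(rows).drop_duplicates(["position", "condition"]).reset_index(drop=True)


def fit_all_positions(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    *,
    positions: Sequence[int] | None = None,
    seed: int = 0,
    bh_scope: str = "condition",
    fdr: float = 0.01,
) -> tuple[pd.DataFrame, dict[int, PositionFit]]:
    """Fit every position independently and assemble the effect table."""
    if positions is None:
        positions = sorted(
            counts.loc[counts["variant"] != "WT", "position"].unique()
        )
    fits: dict[int, PositionFit] = {}
    tables = []
    for pos in positions:
        data = build_position_dataset(counts, sample_sheet, pos)
        fit = fit_position_model(data, seed=seed)
        fits[int(pos)] = fit
        tables.append(effect_table(fit))
    effects = pd.concat(tables, ignore_index=True)
    effects = add_q_values(effects, scope=bh_scope)
    effects["class"] = classify_variants(effects, fdr=fdr)
    return effects, fits
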