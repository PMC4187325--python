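"""Time-window censoring schemes and genome-scale Cox screening.

The screen distinguishes genes whose expression is associated with *early*
recurrence (events before a boundary, default five years) from genes
associated with *late* recurrence (events at or after the boundary, the
dormancy-escape window). Three constructions of the same survival data are
used:

``overall``
    events censored only at last follow-up;
``late``
    events occurring before the boundary are additionally censored at the
    event time, so only late events count;
``early``
    events occurring at or after the boundary are additionally censored, so
    only early events count.

Every event is retained by exactly one of the early/late transforms.

Univariable fits use a vectorized Newton–Raphson maximizer of the Cox
partial likelihood with Efron tie handling and Wald p-values, so a
genome-scale screen over thousands of probes is a single batched call.
Multivariable covariate-adjusted fits delegate to lifelines.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "censor_late",
    "censor_early",
    "apply_scheme",
    "cox_univariable",
    "cox_batch",
    "screen_genome",
    "cox_adjusted",
    "clinical_param_cox",
]

SCHEMES = ("overall", "early", "late")


# ---------------------------------------------------------------------------
# censoring constructions
# ---------------------------------------------------------------------------

def _check_times(time):
    time = np.asarray(time, dtype=float)
    if (time < 0).any():
        raise ValueError("negative survival times")
    return time


def censor_late(time, event, boundary: float = 5.0):
    """Keep only late events: events before ``boundary`` become censored."""
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    new_event = np.where((event == 1) & (time < boundary), 0, event)
    return time.copy(), new_event


def censor_early(time, event, boundary: float = 5.0):
    """Keep only early events: events at or after ``boundary`` censored."""
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    new_event = np.where((event == 1) & (time >= boundary), 0, event)
    return time.copy(), new_event


def apply_scheme(time, event, scheme: str, boundary: float = 5.0):
    if scheme == "overall":
        return _check_times(time).copy(), np.asarray(event, dtype=int).copy()
    if scheme == "late":
        return censor_late(time, event, boundary)
    if scheme == "early":
        return censor_early(time, event, boundary)
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# batched univariable Cox (Efron ties, Wald tests)
# ---------------------------------------------------------------------------

def cox_batch(X, time, event, max_iter: int = 60, tol: float = 1e-10):
    """Fit a univariable Cox model for every row of ``X`` simultaneously.

    Parameters
    ----------
    X
        (p, n) covariate matrix, one model per row.
    time, event
        Shared survival outcome of the n samples.

    Returns
    -------
    DataFrame with columns ``coef``, ``se``, ``p``, ``flag`` (empty string,
    ``zero_variance`` or ``nonconverged``). Rows flagged as degenerate carry
    NaN statistics rather than being dropped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    n = len(time)
    if X.shape[1] != n or len(event) != n:
        raise ValueError("covariates and outcomes must align")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the data")

    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    Xs = X[:, order]

    sd = Xs.std(axis=1)
    mean = Xs.mean(axis=1)
    ok = sd > 0
    flags = np.array([""] * X.shape[0], dtype=object)
    flags[~ok] = "zero_variance"

    Z = np.zeros_like(Xs)
    Z[ok] = (Xs[ok] - mean[ok, None]) / sd[ok, None]

    ev_idx = np.flatnonzero(es == 1)
    ev_times = ts[ev_idx]
    # distinct event times -> tie groups
    starts = np.r_[0, np.flatnonzero(np.diff(ev_times) != 0) + 1]
    d = np.diff(np.r_[starts, len(ev_idx)])
    group_time = ev_times[starts]
    first_at_risk = np.searchsorted(ts, group_time, side="left")
    g_idx = np.repeat(np.arange(len(d)), d)
    frac = np.concatenate([np.arange(dj) / dj for dj in d])

    Zev = Z[:, ev_idx]
    sum_x_events = Zev.sum(axis=1)

    beta = np.zeros(X.shape[0])
    active = ok.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active][:, None]
        Za = Z[active]
        eta = b * Za
        eta -= eta.max(axis=1, keepdims=True)  # row-wise stabilization
        w = np.exp(eta)
        wx = w * Za
        wxx = wx * Za
        R0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
        R1 = np.cumsum(wx[:, ::-1], axis=1)[:, ::-1]
        R2 = np.cumsum(wxx[:, ::-1], axis=1)[:, ::-1]
        S0 = R0[:, first_at_risk]
        S1 = R1[:, first_at_risk]
        S2 = R2[:, first_at_risk]
        D0 = np.add.reduceat(w[:, ev_idx], starts, axis=1)
        D1 = np.add.reduceat(wx[:, ev_idx], starts, axis=1)
        D2 = np.add.reduceat(wxx[:, ev_idx], starts, axis=1)
        phi = S0[:, g_idx] - frac * D0[:, g_idx]
        m1 = (S1[:, g_idx] - frac * D1[:, g_idx]) / phi
        m2 = (S2[:, g_idx] - frac * D2[:, g_idx]) / phi
        grad = sum_x_events[active] - m1.sum(axis=1)
        info = (m2 - m1**2).sum(axis=1)  # observed information (positive)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = grad / info
        delta = np.where(np.isfinite(delta), delta, 0.0)
        delta = np.clip(delta, -1.0, 1.0)  # damped Newton
        beta[active] = beta[active] + delta
        still = np.abs(delta) > tol
        idx_active = np.flatnonzero(active)
        active[idx_active[~still]] = False

    diverged = ok & (np.abs(beta) > 20)
    flags[diverged] = "nonconverged"
    flags[ok & active] = "nonconverged"

    # final information at the solution for standard errors
    se = np.full(X.shape[0], np.nan)
    good = ok & (flags == "")
    if good.any():
        b = beta[good][:, None]
        Zg = Z[good]
        eta = b * Zg
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        wx = w * Zg
        wxx = wx * Zg
        R0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
        R1 = np.cumsum(wx[:, ::-1], axis=1)[:, ::-1]
        R2 = np.cumsum(wxx[:, ::-1], axis=1)[:, ::-1]
        S0 = R0[:, first_at_risk]
        S1 = R1[:, first_at_risk]
        S2 = R2[:, first_at_risk]
        D0 = np.add.reduceat(w[:, ev_idx], starts, axis=1)
        D1 = np.add.reduceat(wx[:, ev_idx], starts, axis=1)
        D2 = np.add.reduceat(wxx[:, ev_idx], starts, axis=1)
        phi = S0[:, g_idx] - frac * D0[:, g_idx]
        m1 = (S1[:, g_idx] - frac * D1[:, g_idx]) / phi
        m2 = (S2[:, g_idx] - frac * D2[:, g_idx]) / phi
        info = (m2 - m1**2).sum(axis=1)
        with np.errstate(divide="ignore"):
            se[good] = 1.0 / np.sqrt(info)

    coef = np.full(X.shape[0], np.nan)
    coef[good] = beta[good] / sd[good]
    se_out = np.full(X.shape[0], np.nan)
    se_out[good] = se[good] / sd[good]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se_out
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"coef": coef, "se": se_out, "p": p, "flag": flags})


def cox_univariable(covariate, time, event):
    """Single-covariate Cox fit; returns ``(coef, se, p)``.

    Raises on zero events or a zero-variance covariate.
    """
    res = cox_batch(np.asarray(covariate, dtype=float)[None, :], time, event)
    row = res.iloc[0]
    if row["flag"] == "zero_variance":
        raise ValueError("covariate has zero variance")
    if row["flag"] == "nonconverged":
        raise ValueError("Cox fit failed to converge (monotone likelihood?)")
    return float(row["coef"]), float(row["se"]), float(row["p"])


# ---------------------------------------------------------------------------
# genome-scale screen
# ---------------------------------------------------------------------------

def screen_genome(
    x: ExpressionMatrix,
    clinical: pd.DataFrame,
    endpoint: str = "rfs",
    threshold: float = 0.001,
    boundary: float = 5.0,
) -> pd.DataFrame:
    """Run the three-scheme univariable Cox screen over all probes.

    Returns a DataFrame indexed by probe with per-scheme coefficients,
    p-values and BH q-values, an overall ``direction`` (direct = positive
    coefficient, overexpression associated with poor outcome), and a
    ``category`` in {early-associated, late-associated, both, neither}
    decided purely by the early/late scheme p-values at ``threshold``.
    Probes that fail (zero variance, non-convergence) are categorized
    ``neither`` with the reason in ``flag``.
    """
    tcol, ecol = f"{endpoint}_years", f"{endpoint}_event"
    common = x.sample_ids.intersection(clinical.index)
    clin = clinical.loc[common, [tcol, ecol]].dropna()
    if len(clin) == 0:
        raise ValueError("no overlapping samples with outcome data")
    samples = clin.index
    X = x.values[samples].to_numpy(dtype=float)
    time = clin[tcol].to_numpy(dtype=float)
    event = clin[ecol].to_numpy(dtype=int)

    out = pd.DataFrame(index=x.probe_ids.copy())
    flags = None
    for scheme in SCHEMES:
        t_s, e_s = apply_scheme(time, event, scheme, boundary)
        res = cox_batch(X, t_s, e_s)
        out[f"coef_{scheme}"] = res["coef"].to_numpy()
        out[f"p_{scheme}"] = res["p"].to_numpy()
        out[f"q_{scheme}"] = _bh(res["p"].to_numpy())
        flags = res["flag"].to_numpy() if flags is None else np.where(
            flags != "", flags, res["flag"].to_numpy()
        )
    out["flag"] = flags
    out["direction"] = np.where(out["coef_overall"] > 0, "direct", "inverse")
    out.loc[out["coef_overall"].isna(), "direction"] = "NA"
    early_hit = out["p_early"] < threshold
    late_hit = out["p_late"] < threshold
    category = np.full(len(out), "neither", dtype=object)
    category[early_hit & ~late_hit] = "early-associated"
    category[late_hit & ~early_hit] = "late-associated"
    category[early_hit & late_hit] = "both"
    category[out["flag"] != ""] = "neither"
    out["category"] = category
    out.index.name = "probe_id"
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    q = np.full_like(p, np.nan, dtype=float)
    valid = np.isfinite(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# covariate-adjusted confirmation and clinical-parameter models
# ---------------------------------------------------------------------------

def cox_adjusted(covariate, time, event, covariates: pd.DataFrame):
    """Multivariable Cox fit returning the expression term's statistics.

    Clinical covariates that are constant or collinear in the complete-case
    data are dropped with a warning; if every one is dropped the fit reduces
    exactly to the univariable model. Returns a dict with ``coef``, ``se``,
    ``p``, ``n``, ``n_events``, ``dropped`` and ``flagged`` (True when there
    are fewer than 10 complete cases per fitted covariate).
    """
    import lifelines

    if covariates is None or covariates.shape[1] == 0:
        raise ValueError("empty covariate table")
    covariate = np.asarray(covariate, dtype=float)
    df = covariates.copy().reset_index(drop=True)
    df["_expr"] = covariate
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    df = df.dropna()
    if df["_event"].sum() == 0:
        raise ValueError("no events among complete cases")

    dropped = []
    keep = []
    cols = [c for c in covariates.columns]
    for c in cols:
        if df[c].nunique() <= 1:
            dropped.append(c)
        else:
            keep.append(c)
    # collinearity among the kept covariates (with intercept-free design of
    # centered columns): drop columns that do not increase matrix rank
    if keep:
        mat = df[keep].to_numpy(dtype=float)
        mat = mat - mat.mean(axis=0)
        kept2 = []
        for j, c in enumerate(keep):
            trial = mat[:, [keep.index(k) for k in kept2] + [j]]
            if np.linalg.matrix_rank(trial) > len(kept2):
                kept2.append(c)
            else:
                dropped.append(c)
        keep = kept2
    if dropped:
        warnings.warn(f"dropped constant/collinear covariates: {dropped}")

    if not keep:
        coef, se, p = cox_univariable(
            df["_expr"].to_numpy(), df["_time"].to_numpy(), df["_event"].to_numpy()
        )
    else:
        cph = lifelines.CoxPHFitter()
        cph.fit(
            df[["_time", "_event", "_expr"] + keep],
            duration_col="_time",
            event_col="_event",
        )
        coef = float(cph.params_["_expr"])
        se = float(cph.standard_errors_["_expr"])
        p = float(cph.summary.loc["_expr", "p"])
    n = len(df)
    flagged = n < 10 * (len(keep) + 1)
    return {
        "coef": coef,
        "se": se,
        "p": p,
        "n": n,
        "n_events": int(df["_event"].sum()),
        "dropped": dropped,
        "flagged": flagged,
    }


#: Dichotomization conventions for clinical parameters.
_PARAM_RULES = {
    "her2": ("calls", "her2", "positive"),
    "er": ("calls", "er", "positive"),
    "pr": ("calls", "pr", "positive"),
    "tnbc": ("calls", "subtype", "TNBC"),
    "size": ("clinical", "size_cm", 2.0),  # >=2 cm vs <2 cm
    "grade": ("clinical", "grade", 3),  # grade 3 vs others
    "age": ("clinical", "age", 50.0),  # >=50 vs <50
}


def clinical_param_cox(
    clinical: pd.DataFrame,
    parameter: str,
    scheme: str = "overall",
    calls: pd.DataFrame = None,
    endpoint: str = "rfs",
    boundary: float = 5.0,
):
    """Binary-covariate Cox model for one clinical parameter.

    Dichotomizations: receptor calls positive-vs-negative, TNBC vs others,
    size >=2 cm vs <2 cm, grade 3 vs others, age >=50 vs <50. Returns a dict
    with ``hr``, ``ci_low``, ``ci_high`` (exp of the 95% Wald interval),
    ``p``, ``n`` and ``n_events`` under the requested censoring scheme.
    """
    if parameter not in _PARAM_RULES:
        raise KeyError(f"unknown clinical parameter {parameter!r}")
    source, col, cut = _PARAM_RULES[parameter]
    if source == "calls":
        if calls is None:
            raise ValueError(f"parameter {parameter!r} needs a receptor-calls table")
        series = calls[col].reindex(clinical.index)
        binary = series.eq(cut).astype(float)
        binary[series.isna()] = np.nan
    else:
        vals = clinical[col].astype(float)
        binary = (vals >= cut).astype(float)
        binary[vals.isna()] = np.nan

    tcol, ecol = f"{endpoint}_years", f"{endpoint}_event"
    df = pd.DataFrame(
        {"x": binary, "t": clinical[tcol], "e": clinical[ecol]}
    ).dropna()
    if df["x"].nunique() < 2:
        raise ValueError(f"parameter {parameter!r} has a single level")
    t_s, e_s = apply_scheme(df["t"].to_numpy(), df["e"].to_numpy(dtype=int), scheme, boundary)
    coef, se, p = cox_univariable(df["x"].to_numpy(), t_s, e_s)
    return {
        "hr": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
        "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
        "p": p,
        "n": int(len(df)),
        "n_events": int(e_s.sum()),
    }
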