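"""Estimation of the three life-table ingredients from a cohort.

A cohort of illness-death event histories is split into one-year
person-period episodes; from these we estimate

1. pooled age-specific one-year transition rates by Poisson regression
   with a log person-time offset (transitions 1: CVD-free -> CVD,
   2: CVD-free -> non-CVD death, 3: CVD -> death, the last indexed by
   current age so the Markov life table can consume it),
2. five-year age-specific prevalence of each risk category within the
   CVD-free and CVD states (person-year weighted), and
3. per-transition Cox hazard ratios of the risk categories, with age as
   the time axis and entry-age left truncation for transitions 1-2, and
   time since CVD onset as the time axis (age at onset adjusted) for
   transition 3.

An inverse-probability-weighting helper re-balances CVD cases to the
full cohort's covariate distribution for the transition-3 sensitivity
refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

__all__ = [
    "AgeBasis",
    "RateModel",
    "TransitionHRs",
    "split_person_time",
    "fit_rates",
    "compute_prevalence",
    "fit_hrs",
    "ipw_reweight",
    "STATE_OF_TRANSITION",
]

# state whose occupants are at risk of each transition
STATE_OF_TRANSITION = {1: "free", 2: "free", 3: "cvd"}


class AgeBasis:
    """Design-matrix builder for the log-rate age model.

    ``kind='loglinear'`` gives a Gompertz-type model (intercept and
    centred age); ``'quadratic'`` adds a squared term; ``'nspline'``
    uses a natural cubic spline with the given interior knots.  Ages are
    centred at `center` so intercepts are interpretable mid-table.
    """

    def __init__(self, kind: str = "loglinear", center: float = 60.0,
                 knots: Sequence[float] = (50.0, 60.0, 70.0, 80.0)):
        if kind not in ("loglinear", "quadratic", "nspline"):
            raise ValueError(f"unknown age basis: {kind!r}")
        self.kind = kind
        self.center = center
        self.knots = tuple(knots)

    def design(self, ages) -> np.ndarray:
        x = np.asarray(ages, dtype=float) - self.center
        if self.kind == "loglinear":
            return np.column_stack([np.ones_like(x), x])
        if self.kind == "quadratic":
            return np.column_stack([np.ones_like(x), x, x**2])
        # natural cubic spline (truncated-power representation with
        # linearity constraints beyond the boundary knots)
        k = np.asarray(self.knots, dtype=float) - self.center
        if len(k) < 3:
            raise ValueError("nspline needs >= 3 knots")

        def d(j, xv):
            num = np.maximum(xv - k[j], 0) ** 3 - np.maximum(xv - k[-1], 0) ** 3
            return num / (k[-1] - k[j])

        cols = [np.ones_like(x), x]
        for j in range(len(k) - 2):
            cols.append(d(j, x) - d(len(k) - 2, x))
        return np.column_stack(cols)

    def to_dict(self):
        return {"kind": self.kind, "center": self.center, "knots": list(self.knots)}

    @classmethod
    def from_dict(cls, d):
        return cls(d["kind"], d["center"], tuple(d.get("knots", ())))


@dataclass
class RateModel:
    """Fitted pooled transition-rate model lambda(x) = exp(basis(x) @ coef)."""

    transition: int
    basis: AgeBasis
    coef: np.ndarray
    cov: np.ndarray
    events: int = 0
    person_years: float = 0.0

    def rate(self, ages) -> np.ndarray:
        return np.exp(self.basis.design(ages) @ self.coef)


@dataclass
class TransitionHRs:
    """Cox log hazard ratios for one transition and exposure scheme.

    ``groups`` lists all category labels with the reference first;
    ``log_hr``/``se`` align with it (reference entries are 0)."""

    transition: int
    scheme: str
    groups: tuple[str, ...]
    log_hr: np.ndarray
    se: np.ndarray
    cov: np.ndarray | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.log_hr)


def _episode_bands(start, stop, ids):
    """Split [start, stop) intervals at integer ages, vectorised.

    Returns (row_index, band_start, exposure_time, is_last_band)."""
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    keep = stop > start
    idx = np.flatnonzero(keep)
    s, e = start[idx], stop[idx]
    f0 = np.floor(s).astype(int)
    f1 = np.ceil(e).astype(int)
    counts = f1 - f0
    rows = np.repeat(idx, counts)
    # offset of each band within its episode
    offsets = np.arange(counts.sum()) - np.repeat(
        np.concatenate(([0], np.cumsum(counts)[:-1])), counts
    )
    band = np.repeat(f0, counts) + offsets
    t0 = np.maximum(np.repeat(s, counts), band)
    t1 = np.minimum(np.repeat(e, counts), band + 1)
    last = offsets == np.repeat(counts - 1, counts)
    return rows, band, t1 - t0, last


def split_person_time(cohort: pd.DataFrame) -> pd.DataFrame:
    """Expand a cohort into one-year person-period episodes.

    Each individual contributes CVD-free time from entry to the first
    of CVD onset, death, or censoring; CVD cases then contribute
    CVD-state time from onset to death or censoring.  Episodes are
    split at integer ages; the band containing a transition carries its
    event code (1, 2 or 3; 0 otherwise).  Inconsistent rows (entry not
    before exit, death before onset) are dropped with a warning.

    Returns a table with columns ``id, state, age_band, time, event``
    plus every cohort column other than the timing/event fields.
    """
    c = cohort.reset_index(drop=True)
    age_cvd = c["age_cvd"].to_numpy(dtype=float)
    age_death = c["age_death"].to_numpy(dtype=float)
    censor = c["censor_age"].to_numpy(dtype=float)
    entry = c["entry_age"].to_numpy(dtype=float)

    exit_all = np.fmin(age_death, censor)
    exit_free = np.fmin(np.fmin(age_cvd, age_death), censor)

    bad = (entry >= exit_free) | (
        ~np.isnan(age_cvd) & ~np.isnan(age_death) & (age_death < age_cvd)
    )
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} cohort rows with inconsistent ages",
            stacklevel=2,
        )
        c = c.loc[~bad].reset_index(drop=True)
        age_cvd, age_death = age_cvd[~bad], age_death[~bad]
        censor, entry = censor[~bad], entry[~bad]
        exit_all, exit_free = exit_all[~bad], exit_free[~bad]

    has_cvd = ~np.isnan(age_cvd) & (age_cvd <= exit_free)
    died = ~np.isnan(age_death) & (age_death <= exit_all)

    carry_cols = [
        col
        for col in c.columns
        if col not in ("age_cvd", "age_death", "censor_age", "event_cvd", "event_death")
    ]

    pieces = []
    # free-state episodes
    rows, band, time, last = _episode_bands(entry, exit_free, c.index.to_numpy())
    ev = np.zeros(len(rows), dtype=int)
    ev[last & has_cvd[rows]] = 1
    ev[last & ~has_cvd[rows] & died[rows]] = 2
    free = c.loc[rows, carry_cols].reset_index(drop=True)
    free.insert(1, "state", "free")
    free.insert(2, "age_band", band)
    free.insert(3, "time", time)
    free.insert(4, "event", ev)
    pieces.append(free)

    # cvd-state episodes
    if has_cvd.any():
        sub = np.flatnonzero(has_cvd)
        rows, band, time, last = _episode_bands(
            age_cvd[sub], exit_all[sub], sub
        )
        rows = sub[rows]
        ev = np.zeros(len(rows), dtype=int)
        ev[last & died[rows]] = 3
        cvd = c.loc[rows, carry_cols].reset_index(drop=True)
        cvd.insert(1, "state", "cvd")
        cvd.insert(2, "age_band", band)
        cvd.insert(3, "time", time)
        cvd.insert(4, "event", ev)
        pieces.append(cvd)

    ppt = pd.concat(pieces, ignore_index=True)
    return ppt.sort_values(["id", "state", "age_band"], kind="stable").reset_index(
        drop=True
    )


def fit_rates(
    ppt: pd.DataFrame,
    transition: int,
    basis: AgeBasis | None = None,
    age_range: tuple[float, float] | None = None,
) -> RateModel:
    """Fit the pooled age-specific rate for one transition.

    Events and person-years are aggregated by one-year age band over
    all groups (the pooled population rate the life-table calibration
    requires) and modelled as Poisson counts with a log person-time
    offset on the age basis evaluated at band midpoints.
    """
    if basis is None:
        basis = AgeBasis()
    state = STATE_OF_TRANSITION[transition]
    rows = ppt[ppt["state"] == state]
    if age_range is not None:
        rows = rows[(rows["age_band"] >= age_range[0]) & (rows["age_band"] < age_range[1])]
    agg = rows.groupby("age_band").agg(
        events=("event", lambda e: int((e == transition).sum())),
        py=("time", "sum"),
    )
    agg = agg[agg["py"] > 0]
    n_events = int(agg["events"].sum())
    if n_events == 0:
        raise ValueError(f"no events for transition {transition}")
    X = basis.design(agg.index.to_numpy(dtype=float) + 0.5)
    model = sm.GLM(
        agg["events"].to_numpy(),
        X,
        family=sm.families.Poisson(),
        offset=np.log(agg["py"].to_numpy()),
    )
    res = model.fit()
    return RateModel(
        transition=transition,
        basis=basis,
        coef=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        events=n_events,
        person_years=float(agg["py"].sum()),
    )


def compute_prevalence(
    ppt: pd.DataFrame,
    group_col: str,
    age_range: tuple[int, int] = (40, 90),
    band_width: int = 5,
) -> pd.DataFrame:
    """Person-year-weighted prevalence of each category per state and
    5-year age band.

    Empty (band, state) cells inherit the nearest non-empty band's
    proportions (warned).  Returns a tidy frame with columns
    ``band_start, state, group, proportion, person_years``.
    """
    lo, hi = age_range
    rows = ppt[(ppt["age_band"] >= lo) & (ppt["age_band"] < hi)].copy()
    rows["band_start"] = lo + band_width * ((rows["age_band"] - lo) // band_width)
    py = (
        rows.groupby(["band_start", "state", group_col], observed=True)["time"]
        .sum()
        .rename("person_years")
        .reset_index()
        .rename(columns={group_col: "group"})
    )
    groups = sorted(rows[group_col].unique())
    bands = list(range(lo, hi, band_width))
    full = pd.MultiIndex.from_product(
        [bands, ["free", "cvd"], groups], names=["band_start", "state", "group"]
    )
    py = py.set_index(["band_start", "state", "group"]).reindex(full, fill_value=0.0)
    py = py.reset_index()

    out = []
    free_prop = None
    for state in ("free", "cvd"):
        st = py[py["state"] == state].pivot(
            index="band_start", columns="group", values="person_years"
        )
        totals = st.sum(axis=1)
        filled = set()
        prop = st.div(totals, axis=0)
        empty = totals[totals == 0].index
        nonempty = totals[totals > 0].index.to_numpy()
        if len(empty) and not len(nonempty):
            if state == "cvd" and free_prop is not None:
                # no diseased person-time anywhere (e.g. an event-free
                # cohort): carry the disease-free mix over
                warnings.warn(
                    "no person-time in state 'cvd'; using the free-state "
                    "prevalence",
                    stacklevel=2,
                )
                prop = free_prop.copy()
                nonempty = prop.index.to_numpy()
                empty = []
            else:
                raise ValueError(f"no person-time at all in state {state!r}")
        for b in empty:
            nearest = nonempty[np.argmin(np.abs(nonempty - b))]
            prop.loc[b] = prop.loc[nearest]
            filled.add(int(b))
        if filled:
            warnings.warn(
                f"state {state!r}: empty bands {sorted(filled)} filled from "
                "nearest non-empty band",
                stacklevel=2,
            )
        if state == "free":
            free_prop = prop
        long = prop.reset_index().melt(
            id_vars="band_start", var_name="group", value_name="proportion"
        )
        long["state"] = state
        long = long.merge(py[py["state"] == state], on=["band_start", "state", "group"])
        out.append(long)
    res = pd.concat(out, ignore_index=True)
    return res[["band_start", "state", "group", "proportion", "person_years"]]


def _cox_design(df: pd.DataFrame, group_col: str, groups, covariates):
    X = pd.DataFrame(index=df.index)
    for g in groups[1:]:
        X[f"{group_col}[{g}]"] = (df[group_col] == g).astype(float)
    for cov in covariates:
        X[cov] = pd.to_numeric(df[cov])
    return X


def fit_hrs(
    cohort: pd.DataFrame,
    transition: int,
    group_col: str,
    covariates: Sequence[str] = (),
    groups: Sequence[str] | None = None,
    weights: np.ndarray | None = None,
) -> TransitionHRs:
    """Cox hazard ratios of the risk categories for one transition.

    Transitions 1-2 use age as the time scale with left truncation at
    entry; transition 3 uses follow-up time since CVD onset with age at
    onset as an additional covariate (Efron tie handling throughout).
    ``groups`` fixes the category order (reference first); by default
    categories are taken in sorted order.

    Unweighted fits use statsmodels' partial-likelihood implementation;
    a weighted (IPW) refit goes through lifelines, which supports case
    weights with robust variance.
    """
    c = cohort.reset_index(drop=True)
    if groups is None:
        groups = sorted(c[group_col].unique())
    groups = tuple(groups)

    age_cvd = c["age_cvd"].to_numpy(dtype=float)
    age_death = c["age_death"].to_numpy(dtype=float)
    censor = c["censor_age"].to_numpy(dtype=float)
    exit_all = np.fmin(age_death, censor)
    exit_free = np.fmin(np.fmin(age_cvd, age_death), censor)
    has_cvd = ~np.isnan(age_cvd) & (age_cvd <= exit_free)
    died = ~np.isnan(age_death) & (age_death <= exit_all)

    covariates = list(covariates)
    if transition in (1, 2):
        df = _cox_design(c, group_col, groups, covariates)
        df["entry"] = c["entry_age"]
        df["duration"] = exit_free
        df["event"] = (has_cvd if transition == 1 else (~has_cvd & died)).astype(int)
        entry_col = "entry"
    elif transition == 3:
        mask = has_cvd
        sub = c.loc[mask]
        df = _cox_design(sub, group_col, groups, covariates)
        df["age_at_onset"] = age_cvd[mask]
        df["duration"] = exit_all[mask] - age_cvd[mask]
        df["event"] = died[mask].astype(int)
        if weights is not None:
            df["__w"] = np.asarray(weights, dtype=float)[mask]
        df = df[df["duration"] > 0]
        entry_col = None
    else:
        raise ValueError("transition must be 1, 2 or 3")

    if df["event"].sum() == 0:
        raise ValueError(f"no events for transition {transition}")

    names = [f"{group_col}[{g}]" for g in groups[1:]]
    if "__w" in df.columns:
        cph = CoxPHFitter()
        fit_kwargs = dict(
            duration_col="duration", event_col="event", weights_col="__w", robust=True
        )
        if entry_col:
            fit_kwargs["entry_col"] = entry_col
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, **fit_kwargs)
        params = cph.params_[names].to_numpy()
        bse = cph.standard_errors_[names].to_numpy()
        cov = cph.variance_matrix_.loc[names, names].to_numpy()
    else:
        exog_cols = [c for c in df.columns if c not in ("duration", "event", "entry")]
        model = sm.PHReg(
            df["duration"].to_numpy(),
            df[exog_cols].to_numpy(dtype=float),
            status=df["event"].to_numpy(),
            entry=df["entry"].to_numpy() if entry_col else None,
            ties="efron",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0)
        if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
            raise RuntimeError(
                f"Cox fit for transition {transition} did not converge "
                "(possible monotone likelihood)"
            )
        idx = [exog_cols.index(n) for n in names]
        params = res.params[idx]
        bse = res.bse[idx]
        cov = res.cov_params()[np.ix_(idx, idx)]

    log_hr = np.zeros(len(groups))
    se = np.zeros(len(groups))
    log_hr[1:] = params
    se[1:] = bse
    return TransitionHRs(
        transition=transition,
        scheme=group_col,
        groups=groups,
        log_hr=log_hr,
        se=se,
        cov=cov,
    )


def ipw_reweight(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    truncate: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Stabilised inverse-probability weights balancing CVD cases to the
    full cohort.

    A logistic model of case membership on the covariates gives fitted
    probabilities p_i; stabilised weights ``P(case) / p_i`` are
    truncated at the given percentiles (computed over cases).  Returns
    one weight per cohort row (non-cases get weight 1; they do not
    enter the transition-3 risk set)."""
    c = cohort.reset_index(drop=True)
    case = (
        (~c["age_cvd"].isna())
        & (c["age_cvd"] <= np.fmin(c["age_death"].fillna(np.inf), c["censor_age"]))
    ).astype(int)
    if case.sum() == 0:
        raise ValueError("no CVD cases to reweight")
    X = sm.add_constant(c[list(covariates)].apply(pd.to_numeric).to_numpy(dtype=float))
    res = sm.Logit(case.to_numpy(), X).fit(disp=0)
    p = np.clip(res.predict(X), 1e-12, 1 - 1e-12)
    w = np.ones(len(c))
    is_case = case.to_numpy().astype(bool)
    w[is_case] = case.mean() / p[is_case]
    lo, hi = np.percentile(w[is_case], truncate)
    n_trunc = int(((w[is_case] < lo) | (w[is_case] > hi)).sum())
    if n_trunc:
        warnings.warn(f"truncated {n_trunc} IPW weights to [{lo:.3g}, {hi:.3g}]",
                      stacklevel=2)
    w[is_case] = np.clip(w[is_case], lo, hi)
    return w
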