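"""File formats: cohort CSV, life-table input workbook, run configs.

The cohort CSV is the canonical individual-level interchange format
(comma-separated, UTF-8, decimal point, ages in decimal years):
``id, sex, entry_age, age_cvd, age_death, censor_age`` plus arbitrary
exposure/covariate columns; empty cells in the event-age columns mean
the event was not observed.

Life-table inputs travel either as a three-sheet xlsx workbook
(Poisson rate coefficients, group prevalences, Cox log hazard ratios
-- the supplementary-data layout of published multistate analyses) read
through a column-mapping config, or as a native JSON document.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .lifetable import LifeTableInputs
from .transitions import AgeBasis, RateModel, TransitionHRs

__all__ = [
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_lifetable_workbook",
    "write_lifetable_workbook",
    "lifetable_inputs_to_json",
    "lifetable_inputs_from_json",
    "load_run_config",
    "config_hash",
    "DEFAULT_WORKBOOK_MAPPING",
]

COHORT_REQUIRED = ("id", "sex", "entry_age", "age_cvd", "age_death", "censor_age")


class CohortValidationError(ValueError):
    """Raised when cohort rows violate the age-ordering contract.

    ``errors`` lists ``(line_number, message)`` pairs (1-based data
    line numbers, header excluded)."""

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"invalid cohort rows: {lines}{more}")


def _validate_cohort(df: pd.DataFrame) -> list[tuple[int, str]]:
    errors = []
    entry = df["entry_age"].to_numpy(dtype=float)
    cvd = df["age_cvd"].to_numpy(dtype=float)
    death = df["age_death"].to_numpy(dtype=float)
    censor = df["censor_age"].to_numpy(dtype=float)
    exit_free = np.fmin(np.fmin(cvd, death), censor)
    for i in range(len(df)):
        line = i + 1
        if not np.isfinite(entry[i]) or not np.isfinite(censor[i]):
            errors.append((line, "entry_age and censor_age must be finite"))
            continue
        if ~np.isnan(death[i]) and ~np.isnan(cvd[i]) and death[i] < cvd[i]:
            errors.append((line, f"age_death {death[i]:g} < age_cvd {cvd[i]:g}"))
        if entry[i] >= exit_free[i]:
            errors.append((line, "entry_age is not before first exit age"))
    return errors


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    All rows must satisfy the ordering contract (entry before any
    event, CVD onset not after death); violations are collected and
    raised together as :class:`CohortValidationError` with line
    numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    errors = _validate_cohort(df)
    if errors:
        raise CohortValidationError(errors)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# life-table input workbook
# ---------------------------------------------------------------------------

DEFAULT_WORKBOOK_MAPPING: dict = {
    "poisson_sheet": "Input 1. Poisson coefficients",
    "prevalence_sheet": "Input 2. Group prevalence",
    "cox_sheet": "Input 3. Cox coefficients",
    "poisson": {
        "transition_col": "transition",
        "term_col": "term",  # row order must match the basis columns
        "coef_col": "coef",
        "se_col": "se",  # optional
        "basis": {"kind": "loglinear", "center": 60.0},
    },
    "prevalence": {
        "band_col": "band_start",
        "state_col": "state",
        "group_col": "group",
        "proportion_col": "proportion",
        "py_col": "person_years",  # optional
    },
    "cox": {
        "transition_col": "transition",
        "group_col": "group",
        "loghr_col": "log_hr",
        "se_col": "se",  # optional
        "reference": None,  # default: first group per transition
    },
}


def _merge_mapping(mapping):
    merged = json.loads(json.dumps(DEFAULT_WORKBOOK_MAPPING))
    for k, v in (mapping or {}).items():
        if isinstance(v, dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def read_lifetable_workbook(path, mapping: Mapping | None = None) -> LifeTableInputs:
    """Read the three-sheet life-table input workbook.

    Sheet 1 holds the Poisson rate coefficients per transition (rows in
    basis-column order), sheet 2 the prevalence of each group per
    5-year band and state, sheet 3 the Cox log hazard ratios.  Missing
    SE columns degrade to point-estimate-only inputs (zero-width CIs);
    prevalence rows not summing to one are renormalized with a warning.
    """
    m = _merge_mapping(mapping)
    xls = pd.ExcelFile(path)
    for key in ("poisson_sheet", "prevalence_sheet", "cox_sheet"):
        if m[key] not in xls.sheet_names:
            raise ValueError(f"workbook is missing sheet {m[key]!r}")

    pm = m["poisson"]
    pdf = xls.parse(m["poisson_sheet"])
    basis = AgeBasis.from_dict({**{"knots": ()}, **pm["basis"]})
    rates = {}
    for t, sub in pdf.groupby(pm["transition_col"]):
        coef = sub[pm["coef_col"]].to_numpy(dtype=float)
        if pm.get("se_col") and pm["se_col"] in sub.columns:
            cov = np.diag(sub[pm["se_col"]].to_numpy(dtype=float) ** 2)
        else:
            cov = np.zeros((len(coef), len(coef)))
        rates[int(t)] = RateModel(
            transition=int(t), basis=basis, coef=coef, cov=cov
        )

    vm = m["prevalence"]
    vdf = xls.parse(m["prevalence_sheet"]).rename(
        columns={
            vm["band_col"]: "band_start",
            vm["state_col"]: "state",
            vm["group_col"]: "group",
            vm["proportion_col"]: "proportion",
        }
    )
    if vm.get("py_col") and vm["py_col"] in vdf.columns:
        vdf = vdf.rename(columns={vm["py_col"]: "person_years"})
    else:
        vdf["person_years"] = 0.0
    sums = vdf.groupby(["band_start", "state"])["proportion"].transform("sum")
    if (np.abs(sums - 1.0) > 1e-6).any():
        warnings.warn("prevalence rows do not sum to 1; renormalizing", stacklevel=2)
    vdf["proportion"] = vdf["proportion"] / sums

    cm = m["cox"]
    cdf = xls.parse(m["cox_sheet"])
    hrs = {}
    for t, sub in cdf.groupby(cm["transition_col"]):
        groups = list(sub[cm["group_col"]])
        ref = cm.get("reference")
        if ref is None:
            ref = groups[0]
        order = [ref] + [g for g in groups if g != ref]
        sub = sub.set_index(cm["group_col"]).loc[order]
        log_hr = sub[cm["loghr_col"]].to_numpy(dtype=float)
        if cm.get("se_col") and cm["se_col"] in sub.columns:
            se = sub[cm["se_col"]].to_numpy(dtype=float)
        else:
            se = np.zeros(len(order))
        hrs[int(t)] = TransitionHRs(
            transition=int(t),
            scheme="workbook",
            groups=tuple(order),
            log_hr=log_hr,
            se=se,
            cov=None,
        )

    return LifeTableInputs(
        rates=rates,
        prevalence=vdf[["band_start", "state", "group", "proportion", "person_years"]],
        hrs=hrs,
    )


def write_lifetable_workbook(inputs: LifeTableInputs, path,
                             mapping: Mapping | None = None) -> None:
    """Write LifeTableInputs in the three-sheet workbook layout."""
    m = _merge_mapping(mapping)
    pm, vm, cm = m["poisson"], m["prevalence"], m["cox"]
    with pd.ExcelWriter(path) as writer:
        rows = []
        for t, rm in sorted(inputs.rates.items()):
            se = np.sqrt(np.clip(np.diag(rm.cov), 0, None))
            for j, c in enumerate(rm.coef):
                rows.append(
                    {
                        pm["transition_col"]: t,
                        pm["term_col"]: f"b{j}",
                        pm["coef_col"]: c,
                        pm["se_col"]: se[j],
                    }
                )
        pd.DataFrame(rows).to_excel(writer, sheet_name=m["poisson_sheet"], index=False)

        vdf = inputs.prevalence.rename(
            columns={
                "band_start": vm["band_col"],
                "state": vm["state_col"],
                "group": vm["group_col"],
                "proportion": vm["proportion_col"],
                "person_years": vm["py_col"],
            }
        )
        vdf.to_excel(writer, sheet_name=m["prevalence_sheet"], index=False)

        rows = []
        for t, h in sorted(inputs.hrs.items()):
            for g, lh, se in zip(h.groups, h.log_hr, h.se):
                rows.append(
                    {
                        cm["transition_col"]: t,
                        cm["group_col"]: g,
                        cm["loghr_col"]: lh,
                        cm["se_col"]: se,
                    }
                )
        pd.DataFrame(rows).to_excel(writer, sheet_name=m["cox_sheet"], index=False)


# ---------------------------------------------------------------------------
# native JSON interchange for LifeTableInputs
# ---------------------------------------------------------------------------


def lifetable_inputs_to_json(inputs: LifeTableInputs) -> dict:
    return {
        "sex": inputs.sex,
        "index_age": inputs.index_age,
        "end_age": inputs.end_age,
        "rates": {
            str(t): {
                "basis": rm.basis.to_dict(),
                "coef": list(map(float, rm.coef)),
                "cov": np.asarray(rm.cov).tolist(),
            }
            for t, rm in inputs.rates.items()
        },
        "prevalence": inputs.prevalence.to_dict(orient="records"),
        "hrs": {
            str(t): {
                "scheme": h.scheme,
                "groups": list(h.groups),
                "log_hr": list(map(float, h.log_hr)),
                "se": list(map(float, h.se)),
                "cov": None if h.cov is None else np.asarray(h.cov).tolist(),
            }
            for t, h in inputs.hrs.items()
        },
    }


def lifetable_inputs_from_json(doc: Mapping) -> LifeTableInputs:
    rates = {
        int(t): RateModel(
            transition=int(t),
            basis=AgeBasis.from_dict(d["basis"]),
            coef=np.asarray(d["coef"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
        )
        for t, d in doc["rates"].items()
    }
    hrs = {
        int(t): TransitionHRs(
            transition=int(t),
            scheme=d["scheme"],
            groups=tuple(d["groups"]),
            log_hr=np.asarray(d["log_hr"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            cov=None if d["cov"] is None else np.asarray(d["cov"], dtype=float),
        )
        for t, d in doc["hrs"].items()
    }
    return LifeTableInputs(
        rates=rates,
        prevalence=pd.DataFrame(doc["prevalence"]),
        hrs=hrs,
        sex=doc.get("sex", "all"),
        index_age=doc.get("index_age", 40),
        end_age=doc.get("end_age", 90),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

RUN_CONFIG_KEYS = {
    "seed",
    "output_dir",
    "sex",
    "exposure_scheme",
    "cohort_path",
    "gwas_dir",
    "genotype_path",
    "workbook_path",
    "simulation",
    "bootstrap",
    "covariates",
}

SIMULATION_KEYS = {
    "n",
    "entry_age_range",
    "sex_ratio_male",
    "group_name",
    "group_labels",
    "group_prevalence",
    "baseline_hazards",
    "true_hr",
    "followup_years",
}

BOOTSTRAP_KEYS = {"n_runs", "reference"}


def load_run_config(path) -> dict:
    """Load and validate a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - RUN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("config must set a seed")
    for key, allowed in (("simulation", SIMULATION_KEYS), ("bootstrap", BOOTSTRAP_KEYS)):
        sub = cfg.get(key) or {}
        bad = set(sub) - allowed
        if bad:
            raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
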