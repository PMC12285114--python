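"""Estimate the three life-table ingredients from the cohort.

Splits the cohort into one-year person-period episodes, fits the
pooled Poisson transition rates (Gompertz-type log-linear age model),
the 5-year age-specific group prevalence in each state, and the
per-transition Cox hazard ratios (with an IPW sensitivity refit of the
post-CVD mortality model).  Writes results/lifetable_inputs.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cvdlife.io import lifetable_inputs_to_json, read_cohort
from cvdlife.lifetable import LifeTableInputs
from cvdlife.transitions import (
    compute_prevalence,
    fit_hrs,
    fit_rates,
    ipw_reweight,
    split_person_time,
)

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
parser.add_argument("--scheme", default="genetic_risk")
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = read_cohort(args.cohort)
groups = ("low", "intermediate", "high") if args.scheme == "genetic_risk" else None
ppt = split_person_time(cohort)
print(f"{len(cohort)} individuals -> {len(ppt)} person-period rows, "
      f"{ppt['time'].sum():.0f} person-years")

rates = {t: fit_rates(ppt, t) for t in (1, 2, 3)}
for t, label in ((1, "CVD incidence"), (2, "non-CVD death"), (3, "death after CVD")):
    lam = rates[t].rate(np.array([45.0, 60.0, 75.0]))
    print(f"  transition {t} ({label}): {rates[t].events} events, "
          f"rate at 45/60/75 = {lam[0]:.4f}/{lam[1]:.4f}/{lam[2]:.4f} per year")

prev = compute_prevalence(ppt, args.scheme)
hrs = {t: fit_hrs(cohort, t, args.scheme, groups=groups) for t in (1, 2, 3)}
for t in (1, 2, 3):
    hr_txt = ", ".join(
        f"{g}={hr:.2f}" for g, hr in zip(hrs[t].groups[1:], hrs[t].hr[1:])
    )
    print(f"  transition {t} Cox HRs vs {hrs[t].groups[0]}: {hr_txt}")

# IPW sensitivity for post-CVD mortality: balance cases to the cohort
weights = ipw_reweight(cohort, ["cov1"])
hr3_ipw = fit_hrs(cohort, 3, args.scheme, groups=groups, weights=weights)
print("  transition 3 after IPW:",
      ", ".join(f"{g}={hr:.2f}" for g, hr in zip(hr3_ipw.groups[1:], hr3_ipw.hr[1:])))

inputs = LifeTableInputs(rates=rates, prevalence=prev, hrs=hrs)
args.out.mkdir(parents=True, exist_ok=True)
(args.out / "lifetable_inputs.json").write_text(
    json.dumps(lifetable_inputs_to_json(inputs), indent=2)
)
print(f"wrote {args.out / 'lifetable_inputs.json'}")
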