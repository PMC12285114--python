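"""Meta-polygenic score construction for a composite outcome.

A meta-PRS is assembled in three stages from many GWAS summaries:

1. candidate scores per GWAS by clumping and thresholding (externally
   computed weight files, e.g. lassosum or PRS-CS output, enter as
   ``method='external'`` candidates);
2. per GWAS, the candidate most strongly associated with the training
   outcome is kept (largest absolute Wald z in a covariate-adjusted
   logistic model); for traits with separate European and East-Asian
   GWAS, an AIC comparison of the one-score and two-score logistic
   models decides whether to integrate the ancestries or keep one;
3. the trait-specific scores are stacked by an elastic-net logistic
   model with seeded ten-fold cross-validation; the penalized weights
   define the meta-score, which expands to a single per-variant weight
   vector.

Allele harmonization flips weight signs when the effect allele matches
the panel's other allele and drops strand-ambiguous (A/T, C/G)
variants, which cannot be oriented without strand information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "GenotypeMatrix",
    "CandidatePrs",
    "MetaPrsModel",
    "harmonize",
    "clump_and_threshold",
    "candidate_grid",
    "score_individuals",
    "raw_scores",
    "select_optimal_prs",
    "aic_integrate",
    "elasticnet_stack",
    "build_metaprs",
]

GWAS_COLUMNS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele",
                "beta", "p", "eaf")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_R2_GRID = (0.1, 0.2, 0.5)
DEFAULT_WINDOW_KB = 250.0
DEFAULT_P_THRESHOLDS = (5e-8, 1e-6, 1e-4, 1e-2, 0.1, 0.5, 1.0)


@dataclass
class GenotypeMatrix:
    """Dosage panel: ``dosages`` is n x m in [0, 2], column *j* counting
    ``variants.allele1[j]``; metadata columns: variant_id, chrom, pos,
    allele1, allele2."""

    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        if self.dosages.size and (
            self.dosages.min() < 0 or self.dosages.max() > 2
        ):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass
class CandidatePrs:
    """Per-variant weights from one construction method.

    ``weights`` columns: variant_id, effect_allele, weight."""

    source: str
    method: str  # 'clump_threshold' or 'external'
    hyperparams: dict = field(default_factory=dict)
    weights: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.weights)


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


def harmonize(table: pd.DataFrame, panel: GenotypeMatrix,
              effect_col: str = "beta") -> pd.DataFrame:
    """Align effect alleles to the panel's counted allele.

    `table` needs columns variant_id, effect_allele and `effect_col`
    (other_allele optional but recommended).  Weight signs are flipped
    where the effect allele is the panel's other allele; variants with
    mismatching alleles and strand-ambiguous A/T, C/G variants are
    dropped.  Returns columns ``variant_id, col, weight`` with ``col``
    the panel column index.
    """
    meta = panel.variants.reset_index(drop=True).reset_index(names="col")
    merged = table.merge(
        meta[["col", "variant_id", "allele1", "allele2"]], on="variant_id"
    )
    if merged.empty:
        return pd.DataFrame(columns=["variant_id", "col", "weight"])
    amb = _is_ambiguous(merged["allele1"], merged["allele2"])
    same = merged["effect_allele"] == merged["allele1"]
    flipped = merged["effect_allele"] == merged["allele2"]
    if "other_allele" in merged.columns:
        same &= merged["other_allele"] == merged["allele2"]
        flipped &= merged["other_allele"] == merged["allele1"]
    keep = ~amb & (same | flipped)
    out = merged.loc[keep, ["variant_id", "col"]].copy()
    sign = np.where(same[keep], 1.0, -1.0)
    out["weight"] = sign * merged.loc[keep, effect_col].to_numpy()
    return out.reset_index(drop=True)


def clump_and_threshold(
    gwas: pd.DataFrame,
    ld_ref: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_kb: float = DEFAULT_WINDOW_KB,
    p_thresholds: Sequence[float] = DEFAULT_P_THRESHOLDS,
    source: str = "gwas",
) -> list[CandidatePrs]:
    """Greedy LD clumping followed by p-value thresholding.

    Variants are visited in ascending p (ties by input order); a
    variant is retained iff its squared dosage correlation with every
    already-retained variant on the same chromosome within `window_kb`
    is below `r2_threshold`.  One candidate score is returned per
    p-value threshold, holding the retained variants with p <= the
    threshold, weighted by their GWAS beta.
    """
    if gwas.empty:
        raise ValueError("empty GWAS summary")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if any(not 0 < p <= 1 for p in p_thresholds):
        raise ValueError("p thresholds must lie in (0, 1]")

    aligned = harmonize(gwas, ld_ref)
    aligned = aligned.merge(
        gwas[["variant_id", "p", "effect_allele"]], on="variant_id"
    )
    meta = ld_ref.variants
    aligned["chrom"] = meta["chrom"].to_numpy()[aligned["col"]]
    aligned["pos"] = meta["pos"].to_numpy()[aligned["col"]]
    aligned = aligned.sort_values("p", kind="stable").reset_index(drop=True)

    dos = ld_ref.dosages
    std = dos - dos.mean(axis=0)
    norms = np.sqrt((std**2).sum(axis=0))
    norms[norms == 0] = np.inf  # monomorphic: zero correlation with anything

    retained: list[int] = []  # row positions into `aligned`
    window = window_kb * 1000.0
    for i in range(len(aligned)):
        ci = int(aligned.at[i, "col"])
        ok = True
        for j in retained:
            cj = int(aligned.at[j, "col"])
            if aligned.at[i, "chrom"] != aligned.at[j, "chrom"]:
                continue
            if abs(aligned.at[i, "pos"] - aligned.at[j, "pos"]) > window:
                continue
            r = std[:, ci] @ std[:, cj] / (norms[ci] * norms[cj])
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            retained.append(i)

    kept = aligned.iloc[retained]
    out = []
    for p_thr in p_thresholds:
        sel = kept[kept["p"] <= p_thr]
        # weights stay on the GWAS effect-allele orientation
        weights = pd.DataFrame(
            {
                "variant_id": sel["variant_id"].to_numpy(),
                "effect_allele": sel["effect_allele"].to_numpy(),
                "weight": sel.merge(
                    gwas[["variant_id", "beta"]], on="variant_id"
                )["beta"].to_numpy(),
            }
        )
        out.append(
            CandidatePrs(
                source=source,
                method="clump_threshold",
                hyperparams={
                    "r2_threshold": r2_threshold,
                    "window_kb": window_kb,
                    "p_threshold": p_thr,
                },
                weights=weights,
            )
        )
    return out


def candidate_grid(
    gwas: pd.DataFrame,
    ld_ref: GenotypeMatrix,
    r2_grid: Sequence[float] = DEFAULT_R2_GRID,
    window_kb: float = DEFAULT_WINDOW_KB,
    p_thresholds: Sequence[float] = DEFAULT_P_THRESHOLDS,
    source: str = "gwas",
) -> list[CandidatePrs]:
    """Candidates over the full clumping grid (one per r2 x p cell)."""
    out = []
    for r2 in r2_grid:
        out.extend(
            clump_and_threshold(gwas, ld_ref, r2, window_kb, p_thresholds, source)
        )
    return out


def raw_scores(prs: CandidatePrs, genotypes: GenotypeMatrix) -> np.ndarray:
    """Unstandardized additive score: sum of weight x dosage after
    harmonization."""
    aligned = harmonize(prs.weights, genotypes, effect_col="weight")
    if aligned.empty:
        raise ValueError("no overlapping variants between score and panel")
    return genotypes.dosages[:, aligned["col"].to_numpy()] @ aligned[
        "weight"
    ].to_numpy()


def score_individuals(
    prs: CandidatePrs, genotypes: GenotypeMatrix, return_stats: bool = False
):
    """Standardized additive score (mean 0, SD 1 over the scored set).

    A degenerate score (zero variance, e.g. all weights zero) is
    rejected explicitly rather than silently returning zeros."""
    raw = raw_scores(prs, genotypes)
    mean, sd = float(raw.mean()), float(raw.std())
    if sd == 0:
        raise ValueError("score has zero variance; cannot standardize")
    z = (raw - mean) / sd
    if return_stats:
        return z, mean, sd
    return z


def _logit_fit(outcome, X):
    model = sm.Logit(outcome, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(disp=0, maxiter=200)


def _covariate_matrix(n, covariates):
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    return np.column_stack([np.ones(n), cov])


def select_optimal_prs(
    candidates: Sequence[CandidatePrs],
    genotypes: GenotypeMatrix,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
) -> CandidatePrs:
    """Pick the candidate with the strongest outcome association.

    Each candidate is scored and entered into a logistic model of the
    outcome on score + covariates; the candidate with the largest
    absolute Wald z wins (ties and z within 1e-9: first by input
    order).  Candidates that cannot be scored or whose fit fails
    (separation, non-convergence) are skipped with a warning.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    outcome = np.asarray(outcome)
    if outcome.min() == outcome.max():
        raise ValueError("outcome must contain both classes")
    base = _covariate_matrix(len(outcome), covariates)
    best, best_z = None, -np.inf
    for cand in candidates:
        try:
            z = score_individuals(cand, genotypes)
            res = _logit_fit(outcome, np.column_stack([base, z]))
            wald = abs(res.params[-1] / res.bse[-1])
        except Exception as err:  # separation, zero variance, no overlap
            warnings.warn(f"candidate {cand.source}/{cand.hyperparams} skipped: {err}",
                          stacklevel=2)
            continue
        if np.isfinite(wald) and wald > best_z + 1e-9:
            best, best_z = cand, wald
    if best is None:
        raise RuntimeError("no candidate could be evaluated")
    return best


def aic_integrate(
    prs_eur: np.ndarray,
    prs_eas: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[str, np.ndarray]:
    """Choose between ancestry scores (or both) by logistic-model AIC.

    Fits outcome ~ covariates + {EUR}, {EAS}, {EUR, EAS} and returns
    ``('eur_only' | 'eas_only' | 'both', combined_score)`` where the
    combined score for 'both' is the AIC-winning model's linear
    combination of the two scores (standardized).  Near-collinear
    scores (|r| > 0.999) fall back to the better single-score model.
    """
    prs_eur = np.asarray(prs_eur, dtype=float)
    prs_eas = np.asarray(prs_eas, dtype=float)
    base = _covariate_matrix(len(outcome), covariates)
    res_eur = _logit_fit(outcome, np.column_stack([base, prs_eur]))
    res_eas = _logit_fit(outcome, np.column_stack([base, prs_eas]))
    r = np.corrcoef(prs_eur, prs_eas)[0, 1]
    options = {"eur_only": res_eur.aic, "eas_only": res_eas.aic}
    res_both = None
    if abs(r) <= 0.999:
        res_both = _logit_fit(outcome, np.column_stack([base, prs_eur, prs_eas]))
        options["both"] = res_both.aic
    choice = min(options, key=options.get)
    if choice == "eur_only":
        combined = prs_eur
    elif choice == "eas_only":
        combined = prs_eas
    else:
        w = res_both.params[-2:]
        combined = prs_eur * w[0] + prs_eas * w[1]
        sd = combined.std()
        if sd > 0:
            combined = (combined - combined.mean()) / sd
    return choice, combined


@dataclass
class MetaPrsModel:
    """Elastic-net stacking weights over trait scores.

    ``trait_weights`` holds the nonzero stacking coefficients;
    ``standardization`` maps trait -> (mean, sd) applied to the raw
    trait scores before stacking; ``variant_expansion`` (columns
    variant_id, effect_allele, weight) is the equivalent single
    per-variant weight vector, i.e.
    ``sum_t coef_t * w_{t,variant} / sd_t``.
    """

    trait_weights: dict[str, float]
    intercept: float
    standardization: dict[str, tuple[float, float]]
    variant_expansion: pd.DataFrame
    cv_deviance: pd.DataFrame | None = None
    l1_ratio: float = 0.5
    C: float = 1.0

    def score(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Apply the variant expansion and standardize over the panel."""
        prs = CandidatePrs("metaprs", "stacked", weights=self.variant_expansion)
        return score_individuals(prs, genotypes)


def elasticnet_stack(
    trait_scores: pd.DataFrame,
    outcome: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    l1_ratios: Sequence[float] = (0.1, 0.5, 0.9),
    Cs: Sequence[float] | None = None,
    trait_prs: Mapping[str, CandidatePrs] | None = None,
    trait_sds: Mapping[str, float] | None = None,
) -> MetaPrsModel:
    """Stack trait scores with a cross-validated elastic net.

    ``trait_scores``: n x T frame of raw or standardized trait scores
    (standardization is applied/recorded here).  Fold assignment is a
    seeded stratified K-fold; the (l1_ratio, C) pair minimising the
    mean cross-validated binomial deviance wins, with near-ties (within
    0.1% of the minimum) resolved toward the strongest penalty, so a
    signal-free outcome collapses to the all-zero solution.  The model
    is refit on the full data at the winning penalty.

    If ``trait_prs`` is given, per-variant weights are expanded into a
    single combined weight vector (variants shared by several traits
    are summed).
    """
    if trait_scores.shape[1] < 2:
        raise ValueError("need at least two trait scores to stack")
    outcome = np.asarray(outcome)
    X_raw = trait_scores.to_numpy(dtype=float)
    means = X_raw.mean(axis=0)
    sds = X_raw.std(axis=0)
    if (sds == 0).any():
        bad = list(trait_scores.columns[sds == 0])
        raise ValueError(f"zero-variance trait scores: {bad}")
    X = (X_raw - means) / sds

    if Cs is None:
        Cs = np.logspace(-3.5, 1, 10)
    grid = [(l1, C) for C in Cs for l1 in l1_ratios]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, outcome))

    def fit_one(l1, C, Xt, yt):
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=l1, C=C,
            max_iter=10_000, tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xt, yt)
        return clf

    records = []
    for l1, C in grid:
        losses = []
        for tr, va in splits:
            clf = fit_one(l1, C, X[tr], outcome[tr])
            p = clf.predict_proba(X[va])[:, 1]
            losses.append(2.0 * log_loss(outcome[va], p, labels=[0, 1]))
        records.append({"l1_ratio": l1, "C": C, "mean_deviance": np.mean(losses)})
    cv_dev = pd.DataFrame(records)

    best_dev = cv_dev["mean_deviance"].min()
    tol = 1e-3 * abs(best_dev)
    near = cv_dev[cv_dev["mean_deviance"] <= best_dev + tol]
    # strongest penalty first: smallest C, then largest l1 share
    near = near.sort_values(["C", "l1_ratio"], ascending=[True, False])
    l1_star = float(near.iloc[0]["l1_ratio"])
    C_star = float(near.iloc[0]["C"])

    final = fit_one(l1_star, C_star, X, outcome)
    coefs = final.coef_.ravel()
    if not coefs.any():
        warnings.warn("elastic net selected the all-zero solution", stacklevel=2)

    traits = list(trait_scores.columns)
    trait_weights = {t: float(c) for t, c in zip(traits, coefs) if c != 0.0}
    standardization = {
        t: (float(m), float(s)) for t, m, s in zip(traits, means, sds)
    }

    expansion = pd.DataFrame(columns=["variant_id", "effect_allele", "weight"])
    if trait_prs is not None:
        pieces = []
        for t, coef in trait_weights.items():
            w = trait_prs[t].weights.copy()
            sd_t = trait_sds[t] if trait_sds else standardization[t][1]
            w["weight"] = coef * w["weight"] / sd_t
            pieces.append(w)
        if pieces:
            expansion = (
                pd.concat(pieces, ignore_index=True)
                .groupby(["variant_id", "effect_allele"], as_index=False)["weight"]
                .sum()
            )

    return MetaPrsModel(
        trait_weights=trait_weights,
        intercept=float(final.intercept_[0]),
        standardization=standardization,
        variant_expansion=expansion,
        cv_deviance=cv_dev,
        l1_ratio=l1_star,
        C=C_star,
    )


def _linear_coefs(target, z1, z2):
    """Exact coefficients of `target` on [z1, z2, 1] (least squares)."""
    A = np.column_stack([z1, z2, np.ones_like(z1)])
    sol, *_ = np.linalg.lstsq(A, target, rcond=None)
    return sol[:2]


def build_metaprs(
    genotypes: GenotypeMatrix,
    summaries: Mapping[str, Mapping[str, pd.DataFrame]],
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    seed: int = 0,
    r2_grid: Sequence[float] = DEFAULT_R2_GRID,
    window_kb: float = DEFAULT_WINDOW_KB,
    p_thresholds: Sequence[float] = DEFAULT_P_THRESHOLDS,
    external_candidates: Mapping[str, Sequence[CandidatePrs]] | None = None,
    folds: int = 10,
) -> tuple[MetaPrsModel, pd.DataFrame]:
    """Run the full three-stage meta-score construction.

    ``summaries`` maps trait -> {ancestry: GWAS summary frame} with
    ancestry keys 'trans' or 'EUR'/'EAS'.  Externally built weight
    files (e.g. lassosum, PRS-CS) can be injected per trait via
    ``external_candidates``.  Returns the fitted model and the n x T
    frame of trait scores used for stacking.
    """
    trait_scores = {}
    trait_best: dict[str, CandidatePrs] = {}
    trait_sds: dict[str, float] = {}
    for trait, by_ancestry in summaries.items():
        per_ancestry_scores = {}
        for ancestry, gwas in by_ancestry.items():
            cands = candidate_grid(
                gwas, genotypes, r2_grid, window_kb, p_thresholds,
                source=f"{trait}/{ancestry}",
            )
            if external_candidates and trait in external_candidates:
                cands = list(cands) + list(external_candidates[trait])
            best = select_optimal_prs(cands, genotypes, outcome, covariates)
            z, _, sd = score_individuals(best, genotypes, return_stats=True)
            per_ancestry_scores[ancestry] = (best, z, sd)
        if "trans" in per_ancestry_scores:
            best, z, sd = per_ancestry_scores["trans"]
            trait_scores[trait] = z
            trait_best[trait], trait_sds[trait] = best, sd
        else:
            (b_eur, z_eur, sd_eur) = per_ancestry_scores["EUR"]
            (b_eas, z_eas, sd_eas) = per_ancestry_scores["EAS"]
            choice, combined = aic_integrate(z_eur, z_eas, outcome, covariates)
            trait_scores[trait] = combined
            if choice == "eur_only":
                trait_best[trait], trait_sds[trait] = b_eur, sd_eur
            elif choice == "eas_only":
                trait_best[trait], trait_sds[trait] = b_eas, sd_eas
            else:
                # the integrated score is a fixed linear combination of
                # the two ancestry files, so merge them into one weight
                # file whose raw score equals that combination
                w_eur = b_eur.weights.copy()
                w_eas = b_eas.weights.copy()
                coef = _linear_coefs(combined, z_eur, z_eas)
                w_eur["weight"] *= coef[0] / sd_eur
                w_eas["weight"] *= coef[1] / sd_eas
                merged = CandidatePrs(
                    source=f"{trait}/integrated",
                    method="integrated",
                    hyperparams={"ancestries": ("EUR", "EAS")},
                    weights=pd.concat([w_eur, w_eas], ignore_index=True),
                )
                raw = raw_scores(merged, genotypes)
                trait_best[trait] = merged
                trait_sds[trait] = float(raw.std())
        # raw scores are standardized again inside the stack
    scores = pd.DataFrame(trait_scores)
    model = elasticnet_stack(
        scores, outcome, folds=folds, seed=seed,
        trait_prs=trait_best, trait_sds=trait_sds,
    )
    return model, scores
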