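"""Phenotypic mixed-model analysis: BLUEs, variance components, heritability.

Trials are completely randomised designs; the across-trial model is

    y_ij = mu + g_i + t_j + e_ij

with fixed trial effects.  Genotypes are treated as fixed to obtain BLUEs and
as random (REML) to estimate the genetic variance.  Heritability uses the
mean variance of a difference (MVD) of the BLUEs:

    h2 = sigma_G^2 / (sigma_G^2 + MVD / 2)

which stays meaningful in severely unbalanced trial series where the
classical entry-mean formula does not apply.  The residual variance of the
across-trial model confounds the trial-by-line interaction with plot error;
both are estimable only through replicated entries (mostly checks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .containers import PhenotypeRecords

__all__ = [
    "TrialFit",
    "AcrossTrialResult",
    "heritability",
    "fit_trial",
    "filter_trials",
    "fit_across_trials",
    "two_stage_protein",
]


def heritability(sigma_G2: float, mvd: float) -> float:
    """Piepho-Moehring heritability h2 = sigma_G2 / (sigma_G2 + MVD/2), clamped to [0, 1]."""
    sigma_G2 = max(float(sigma_G2), 0.0)
    mvd = max(float(mvd), 0.0)
    denom = sigma_G2 + mvd / 2.0
    if denom <= 0.0:
        return 0.0
    return float(min(max(sigma_G2 / denom, 0.0), 1.0))


@dataclass
class TrialFit:
    trial: str
    trait: str
    blues: pd.Series
    sigma_G2: float
    mvd: float
    h2: float | None  # None when no line is replicated ("not estimable")

    @property
    def estimable(self) -> bool:
        return self.h2 is not None


@dataclass
class AcrossTrialResult:
    trait: str
    blues: pd.Series
    grand_mean: float
    trial_effects: pd.Series
    sigma_G2: float
    sigma_e2: float
    mvd: float
    h2: float | None
    n_trials: int = 1


def _reml_line_random(values: np.ndarray, lines: np.ndarray, X: np.ndarray):
    """REML variance components for y = X beta + g_line + e via MixedLM."""
    if np.ptp(values) < 1e-12:
        return 0.0, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.MixedLM(values, X, groups=lines)
        try:
            res = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError):
            try:
                res = model.fit(reml=True, method="powell", maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                return 0.0, float(np.var(values, ddof=1))
    sigma_G2 = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    sigma_e2 = max(float(res.scale), 0.0)
    return sigma_G2, sigma_e2


def _blue_fit(df: pd.DataFrame, seed: int = 0, max_pairs: int = 10_000):
    """Fixed-genotype fit: BLUEs, trial contrasts, and the MVD kernel.

    Design: one indicator column per line (no intercept) plus trial
    indicators with the first trial as reference; requires a connected
    design.  Returns BLUEs, trial effects, the residual mean square, and the
    mean of ``C_ii + C_jj - 2 C_ij`` over line pairs with C the unscaled
    covariance of the genotype estimates (multiply by sigma_e2 for the MVD).
    For panels over 500 lines a seeded random subsample of ``max_pairs``
    pairs is used.
    """
    lines = pd.Index(sorted(df["line"].unique()))
    trials = pd.Index(sorted(df["trial"].unique()))
    n, q = len(df), len(lines)
    L = pd.get_dummies(df["line"]).reindex(columns=lines, fill_value=0).to_numpy(float)
    X = L
    if len(trials) > 1:
        T = pd.get_dummies(df["trial"]).reindex(columns=trials, fill_value=0).to_numpy(float)
        X = np.hstack([L, T[:, 1:]])
    y = df["value"].to_numpy(float)
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - np.linalg.matrix_rank(XtX)
    mse = float(resid @ resid / dof) if dof > 0 else np.nan
    blues = pd.Series(beta[:q], index=lines, name="blue")
    trial_eff = pd.Series(0.0, index=trials)
    if len(trials) > 1:
        trial_eff.iloc[1:] = beta[q:]
    C = XtX_inv[:q, :q]
    if q > 500:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, q, size=max_pairs)
        jj = rng.integers(0, q, size=max_pairs)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
        kernel = float(np.mean(C[ii, ii] + C[jj, jj] - 2.0 * C[ii, jj]))
    else:
        tr = float(np.trace(C))
        kernel = float((2.0 * q * tr - 2.0 * C.sum()) / (q * (q - 1)))
    return blues, trial_eff, mse, kernel


def fit_trial(records: PhenotypeRecords | pd.DataFrame, trait: str) -> TrialFit:
    """Single-trial analysis: BLUEs, REML genetic variance, MVD heritability.

    With no replicated line the data quality cannot be assessed: the fit is
    returned with ``h2 = None`` (flagged not estimable) and the line means as
    BLUEs.
    """
    df = records.for_trait(trait) if isinstance(records, PhenotypeRecords) else records
    df = df[df["trait"] == trait] if "trait" in df.columns else df
    trials = df["trial"].unique()
    if len(trials) != 1:
        raise ValueError(f"fit_trial expects records from one trial, got {list(trials)}")
    if df["line"].nunique() < 2:
        raise ValueError("fit_trial needs at least two lines")
    trial = trials[0]
    blues = df.groupby("line")["value"].mean().rename("blue")
    reps = df.groupby("line").size()
    if (reps < 2).all():
        return TrialFit(trial, trait, blues, np.nan, np.nan, None)
    y = df["value"].to_numpy(float)
    sigma_G2, sigma_e2 = _reml_line_random(y, df["line"].to_numpy(), np.ones((len(df), 1)))
    # MVD for a CRD: mean over line pairs of sigma_e2 (1/r_i + 1/r_j)
    inv_r = (1.0 / reps).to_numpy()
    mvd = float(sigma_e2 * 2.0 * inv_r.mean())
    return TrialFit(trial, trait, blues, sigma_G2, mvd, heritability(sigma_G2, mvd))


def filter_trials(trial_fits, h2_min: float, strict: bool = False) -> list:
    """Trial ids passing the heritability filter.

    Trials with estimable h2 below ``h2_min`` (at or below when ``strict``)
    are dropped; trials whose h2 could not be estimated (no replication) are
    retained, matching the practice of keeping unreplicated trials in the
    across-trial analysis.
    """
    kept = []
    for fit in trial_fits:
        if fit.h2 is None:
            kept.append(fit.trial)
        elif (fit.h2 > h2_min) if strict else (fit.h2 >= h2_min):
            kept.append(fit.trial)
    return kept


def connectivity_components(df: pd.DataFrame) -> list[set]:
    """Connected components of the trial graph (trials linked by shared lines)."""
    g = nx.Graph()
    g.add_nodes_from(df["trial"].unique())
    for _, grp in df.groupby("line"):
        ts = grp["trial"].unique()
        g.add_edges_from(zip(ts[:-1], ts[1:]))
    return [set(c) for c in nx.connected_components(g)]


def fit_across_trials(
    records: PhenotypeRecords | pd.DataFrame,
    trait: str,
    seed: int = 0,
) -> AcrossTrialResult:
    """Across-trial mixed model y_ij = mu + g_i + t_j + e_ij.

    Trial effects are fixed; line BLUEs come from the fixed-genotype fit and
    sigma_G2 / sigma_e2 from the random-genotype REML fit.  Heritability uses
    the MVD of the across-trial BLUEs.  Raises on a disconnected design,
    naming the disconnected trial groups.
    """
    df = records.for_trait(trait) if isinstance(records, PhenotypeRecords) else records
    df = df[df["trait"] == trait] if "trait" in df.columns else df
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    comps = connectivity_components(df)
    if len(comps) > 1:
        raise ValueError(
            "trial design is disconnected; components: "
            + "; ".join(sorted(",".join(sorted(map(str, c))) for c in comps))
        )
    trials = sorted(df["trial"].unique())
    blues, trial_eff, _mse, kernel = _blue_fit(df, seed=seed)
    if len(trials) > 1:
        T = pd.get_dummies(df["trial"]).reindex(columns=trials, fill_value=0).to_numpy(float)
        X = np.hstack([np.ones((len(df), 1)), T[:, 1:]])
    else:
        X = np.ones((len(df), 1))
    sigma_G2, sigma_e2 = _reml_line_random(
        df["value"].to_numpy(float), df["line"].to_numpy(), X
    )
    replicated = (df.groupby("line").size() >= 2).any()
    if replicated:
        mvd = sigma_e2 * kernel
        h2 = heritability(sigma_G2, mvd)
    else:
        mvd, h2 = np.nan, None
    return AcrossTrialResult(
        trait=trait,
        blues=blues,
        grand_mean=float(blues.mean()),
        trial_effects=trial_eff,
        sigma_G2=sigma_G2,
        sigma_e2=sigma_e2,
        mvd=mvd,
        h2=h2,
        n_trials=len(trials),
    )


def two_stage_protein(
    records: PhenotypeRecords | pd.DataFrame,
    trait: str = "PROT",
    h2_stage1_min: float = 0.3,
) -> dict[int, AcrossTrialResult]:
    """Two-stage protein analysis: per-trial BLUEs, then per-year across-trial fit.

    Stage 1 fits every trial separately; only trials with heritability
    strictly above ``h2_stage1_min`` (non-estimable trials are kept) enter
    the stage-2 across-trial model within each year.  Years with no retained
    trial are skipped with a warning.
    """
    df = records.for_trait(trait) if isinstance(records, PhenotypeRecords) else records
    df = df[df["trait"] == trait] if "trait" in df.columns else df
    out: dict[int, AcrossTrialResult] = {}
    for year, ydf in df.groupby("year"):
        fits = [fit_trial(tdf, trait) for _, tdf in ydf.groupby("trial")]
        retained = set(filter_trials(fits, h2_stage1_min, strict=True))
        if not retained:
            warnings.warn(f"year {year}: no trial passed the stage-1 h2 filter; skipped")
            continue
        stage2_rows = []
        for fit in fits:
            if fit.trial not in retained:
                continue
            stage2_rows.append(
                pd.DataFrame(
                    {
                        "line": fit.blues.index,
                        "trial": fit.trial,
                        "year": year,
                        "rep": 0,
                        "trait": trait,
                        "value": fit.blues.to_numpy(),
                        "is_check": False,
                    }
                )
            )
        stage2 = pd.concat(stage2_rows, ignore_index=True)
        comps = connectivity_components(stage2)
        if len(comps) > 1:
            warnings.warn(f"year {year}: stage-2 design disconnected; skipped")
            continue
        out[int(year)] = fit_across_trials(stage2, trait)
    return out
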