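"""Genomic and marker-assisted prediction models.

All engines predict line-level breeding values from marker data and
across-trial BLUEs:

* ``fit_rrblup`` — ridge-regression BLUP: all markers random with a common
  variance, y = Xb + Zu + e.
* ``fit_gblup`` — the equivalent line-effect model y = Xb + Zg + e with
  g ~ N(0, K sigma_g2) and the genomic relationship matrix K; records the
  shrinkage ratio lambda^2 = sigma_e2/sigma_g2.
* W-BLUP — ``fit_rrblup`` with designated major-QTL markers moved from the
  random set into the fixed design matrix.
* ``gwas_scan`` — mixed-model association scan with the kinship covariance
  fixed at its null-model estimate (population parameters previously
  determined), Wald tests per marker.
* ``fit_mas`` — fixed-effects-only prediction from a handful of selected
  markers (marker-assisted selection).
* ``fit_multitrait`` — bivariate G-BLUP with unstructured 2x2 genetic and
  residual covariances, supporting lines phenotyped for only one trait.
* ``fit_selection_index`` — the model-based index: a correlated trait's
  GEBVs enter the target-trait model as a fixed covariate,
  GEBV_i = x_i b_prot + g_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import ConvergenceError, em_reml_bivariate, reml_kernel
from .containers import KinshipMatrix, MarkerMap, MarkerMatrix
from .qc import centered_markers

__all__ = [
    "VarianceComponents",
    "PredictionResult",
    "GwasResult",
    "fit_rrblup",
    "fit_gblup",
    "gwas_scan",
    "select_mas_markers",
    "fit_mas",
    "fit_multitrait",
    "fit_selection_index",
    "ConvergenceError",
]


@dataclass
class VarianceComponents:
    sigma_u2: float | None = None  # marker-effect variance (RR-BLUP)
    sigma_g2: float | None = None  # genetic variance (G-BLUP)
    sigma_e2: float | None = None
    lambda2: float | None = None  # shrinkage ratio sigma_e2 / sigma_g2
    Sigma_g: np.ndarray | None = None  # 2x2, bivariate model
    Sigma_e: np.ndarray | None = None

    @property
    def h2(self) -> float | None:
        if self.sigma_g2 is None or self.sigma_e2 is None:
            return None
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class PredictionResult:
    gebv: pd.Series | pd.DataFrame  # per line (column per trait when bivariate)
    model: str
    fixed_effects: dict = field(default_factory=dict)
    marker_effects: pd.Series | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class GwasResult:
    table: pd.DataFrame  # marker, chrom, pos_cM, effect, stat, pvalue
    mapped_only: bool = True

    def top_markers(self, k: int = 3) -> list[str]:
        tab = self.table.sort_values(["pvalue", "pos_cM", "marker"])
        return list(tab["marker"].head(k))


def _training_design(blues: pd.Series, markers: MarkerMatrix):
    lines = [l for l in blues.index if l in set(markers.line_ids)]
    if len(lines) < len(blues):
        missing = sorted(set(blues.index) - set(lines))
        raise KeyError(f"phenotyped lines missing from marker matrix: {missing[:5]}")
    return lines


def fit_rrblup(
    blues: pd.Series,
    markers: MarkerMatrix,
    fixed_marker_ids: list[str] | tuple = (),
    lambda_: float | None = None,
) -> tuple[PredictionResult, VarianceComponents]:
    """RR-BLUP marker-effect model, optionally with fixed major-QTL markers.

    Markers in ``fixed_marker_ids`` enter the fixed design (centred, next to
    the intercept) and are excluded from the random-effect matrix — the
    weighted BLUP (W-BLUP) construction.  ``lambda_`` fixes the ridge ratio
    sigma_e2/sigma_u2 instead of estimating it by REML.  GEBVs cover every
    line of the marker matrix, phenotyped or not.
    """
    train = _training_design(blues, markers)
    W, _p = centered_markers(markers)
    frame = pd.DataFrame(W, index=markers.line_ids, columns=markers.marker_ids)
    flags: list[str] = []
    fixed_ids = [m for m in dict.fromkeys(fixed_marker_ids)]
    unknown = [m for m in fixed_ids if m not in frame.columns]
    if unknown:
        raise KeyError(f"fixed markers absent from marker matrix: {unknown}")
    random_ids = [m for m in markers.marker_ids if m not in set(fixed_ids)]
    y = blues.loc[train].to_numpy(float)
    Wf_all = frame[fixed_ids].to_numpy(float) if fixed_ids else np.empty((len(frame), 0))
    Wr_all = frame[random_ids].to_numpy(float)
    tr_idx = [frame.index.get_loc(l) for l in train]
    Wf = Wf_all[tr_idx]
    Wr = Wr_all[tr_idx]

    X = np.ones((len(train), 1))
    kept_fixed = []
    for j, mid in enumerate(fixed_ids):
        cand = np.column_stack([X, Wf[:, j]])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            X = cand
            kept_fixed.append(mid)
        else:
            flags.append(f"fixed marker {mid} collinear with design; dropped")
            warnings.warn(flags[-1])
    keep_cols = [fixed_ids.index(m) for m in kept_fixed]
    Wf_all = Wf_all[:, keep_cols]

    Kw = Wr @ Wr.T
    fit = reml_kernel(y, X, Kw, lambda_=lambda_)
    u = Wr.T @ fit.alpha
    gebv_vals = Wr_all @ u
    fixed_effects = {"intercept": float(fit.beta[0])}
    for j, mid in enumerate(kept_fixed):
        fixed_effects[mid] = float(fit.beta[1 + j])
        gebv_vals = gebv_vals + Wf_all[:, j] * fit.beta[1 + j]
    result = PredictionResult(
        gebv=pd.Series(gebv_vals, index=frame.index, name="gebv"),
        model="wblup" if kept_fixed else "rrblup",
        fixed_effects=fixed_effects,
        marker_effects=pd.Series(u, index=random_ids, name="effect"),
        flags=flags,
    )
    comps = VarianceComponents(
        sigma_u2=fit.sigma_g2, sigma_e2=fit.sigma_e2,
        lambda2=fit.lambda_ if np.isfinite(fit.lambda_) else None,
    )
    return result, comps


def fit_gblup(
    blues: pd.Series,
    K: KinshipMatrix,
    covariates: pd.DataFrame | None = None,
) -> tuple[PredictionResult, VarianceComponents]:
    """Single-trait G-BLUP with REML variance components.

    Unphenotyped lines of K receive GEBVs through the kinship block
    regression implied by the joint BLUP system.  ``covariates`` (indexed by
    line, covering at least the training lines) enter the fixed design next
    to the intercept.
    """
    train = [l for l in blues.index if l in set(K.line_ids)]
    if len(train) < len(blues):
        missing = sorted(set(blues.index) - set(train))
        raise KeyError(f"phenotyped lines missing from kinship matrix: {missing[:5]}")
    y = blues.loc[train].to_numpy(float)
    X = np.ones((len(train), 1))
    flags: list[str] = []
    fixed_names = ["intercept"]
    if covariates is not None:
        cov = covariates.loc[train]
        for name in cov.columns:
            col = cov[name].to_numpy(float)
            if np.ptp(col) < 1e-12:
                flags.append(f"covariate {name} constant; dropped")
                warnings.warn(flags[-1])
                continue
            X = np.column_stack([X, col])
            fixed_names.append(str(name))
    Ktt = K.submatrix(train, train)
    fit = reml_kernel(y, X, Ktt)
    K_all_t = K.submatrix(K.line_ids, train)
    g_all = K_all_t @ fit.alpha
    result = PredictionResult(
        gebv=pd.Series(g_all, index=K.line_ids, name="gebv"),
        model="gblup",
        fixed_effects={n: float(b) for n, b in zip(fixed_names, fit.beta)},
        flags=flags,
    )
    comps = VarianceComponents(
        sigma_g2=fit.sigma_g2, sigma_e2=fit.sigma_e2,
        lambda2=fit.lambda_ if np.isfinite(fit.lambda_) else None,
    )
    return result, comps


def gwas_scan(
    blues: pd.Series,
    markers: MarkerMatrix,
    marker_map: MarkerMap,
    K: KinshipMatrix,
) -> GwasResult:
    """Mixed-model association scan (K model, population parameters fixed).

    Variance components are estimated once under the marker-free null model;
    each mapped marker is then tested as a fixed effect by generalised least
    squares under that covariance, with Wald p-values.  Only markers with a
    map position are scanned; monomorphic markers are skipped.
    """
    train = [l for l in blues.index if l in set(K.line_ids)]
    y = blues.loc[train].to_numpy(float)
    n = len(train)
    Ktt = K.submatrix(train, train)
    null = reml_kernel(y, np.ones((n, 1)), Ktt)
    s, U = np.linalg.eigh((Ktt + Ktt.T) / 2.0)
    s = np.clip(s, 0.0, None)
    v = null.sigma_g2 * s + null.sigma_e2
    v = np.clip(v, 1e-12, None)
    w = 1.0 / np.sqrt(v)

    pos = marker_map.positions()
    mapped = [m for m in markers.marker_ids if m in pos.index]
    sub = markers.subset(lines=train, markers=mapped)
    Z = sub.calls.to_numpy(float)
    Zc = Z - Z.mean(axis=0, keepdims=True)
    Zt = (U.T @ Zc) * w[:, None]
    yt = (U.T @ (y - y.mean())) * w
    ones_t = (U.T @ np.ones(n)) * w

    # per-marker GLS with intercept: project out the whitened intercept
    denom_1 = float(ones_t @ ones_t)
    y_r = yt - ones_t * float(ones_t @ yt) / denom_1
    Z_r = Zt - np.outer(ones_t, (ones_t @ Zt) / denom_1)
    szz = np.einsum("ij,ij->j", Z_r, Z_r)
    szy = Z_r.T @ y_r
    rows = []
    df = n - 2
    yss = float(y_r @ y_r)
    for j, mid in enumerate(mapped):
        if Z[:, j].std() < 1e-12:
            continue  # monomorphic in the training set
        bhat = szy[j] / szz[j]
        rss = yss - bhat * szy[j]
        sigma2 = max(rss / df, 1e-300)
        se = np.sqrt(sigma2 / szz[j])
        t = bhat / se
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append(
            {
                "marker": mid,
                "chrom": pos.loc[mid, "chrom"],
                "pos_cM": float(pos.loc[mid, "pos_cM"]),
                "effect": float(bhat),
                "stat": float(t),
                "pvalue": float(max(p, np.finfo(float).tiny)),
            }
        )
    return GwasResult(table=pd.DataFrame(rows), mapped_only=True)


def select_mas_markers(
    strategy: str,
    gwas: GwasResult | None = None,
    glu_ids: list[str] | tuple = (),
    n_top: int = 3,
) -> list[str]:
    """Marker sets for the three marker-assisted selection strategies.

    ``glu_only`` returns the designated major-locus markers regardless of
    p-values; ``denovo_top3`` the ``n_top`` most significant mapped markers
    (ties broken by map position then id); ``combined`` their union without
    duplicates.
    """
    if strategy not in {"glu_only", "denovo_top3", "combined"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    denovo: list[str] = []
    if strategy in {"denovo_top3", "combined"}:
        if gwas is None:
            raise ValueError(f"strategy {strategy!r} needs a GWAS result")
        if len(gwas.table) < n_top:
            warnings.warn(
                f"only {len(gwas.table)} mapped markers available; returning all"
            )
        denovo = gwas.top_markers(n_top)
    if strategy == "glu_only":
        return list(glu_ids)
    if strategy == "denovo_top3":
        return denovo
    return list(dict.fromkeys(list(glu_ids) + denovo))


def fit_mas(
    blues: pd.Series,
    markers: MarkerMatrix,
    selected_ids: list[str],
) -> PredictionResult:
    """Marker-assisted selection: ordinary least squares on selected markers.

    Collinear selections are handled by the pseudoinverse (flagged); an
    empty selection degenerates to the grand mean (GEBVs all zero, flagged).
    """
    train = _training_design(blues, markers)
    flags: list[str] = []
    if not selected_ids:
        flags.append("empty marker selection; GEBV is the grand mean")
        return PredictionResult(
            gebv=pd.Series(0.0, index=markers.line_ids, name="gebv"),
            model="mas", fixed_effects={}, flags=flags,
        )
    missing = [m for m in selected_ids if m not in set(markers.marker_ids)]
    if missing:
        raise KeyError(f"selected markers absent from matrix: {missing}")
    W, _ = centered_markers(markers)
    frame = pd.DataFrame(W, index=markers.line_ids, columns=markers.marker_ids)
    Zs_all = frame[list(selected_ids)].to_numpy(float)
    tr_idx = [frame.index.get_loc(l) for l in train]
    Zs = Zs_all[tr_idx]
    X = np.column_stack([np.ones(len(train)), Zs])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        flags.append("collinear selected markers; pseudoinverse solution")
        warnings.warn(flags[-1])
    beta = np.linalg.pinv(X) @ blues.loc[train].to_numpy(float)
    gebv = Zs_all @ beta[1:]
    fixed = {"intercept": float(beta[0])}
    fixed.update({m: float(b) for m, b in zip(selected_ids, beta[1:])})
    return PredictionResult(
        gebv=pd.Series(gebv, index=frame.index, name="gebv"),
        model="mas", fixed_effects=fixed, flags=flags,
    )


def fit_multitrait(
    blues_target: pd.Series,
    blues_second: pd.Series,
    K: KinshipMatrix,
    max_iter: int = 500,
    tol: float = 1e-6,
    on_nonconvergence: str = "raise",
) -> tuple[PredictionResult, VarianceComponents]:
    """Bivariate G-BLUP with unstructured genetic/residual covariances.

    Availability is taken from the two BLUE series: lines present in only
    one of them are handled by the missing-data EM; the residual covariance
    is fixed at zero when no line is observed for both traits.  Returns
    GEBVs for both traits for every line of K (trait order: target, second).
    """
    idx = {l: i for i, l in enumerate(K.line_ids)}
    series = [blues_target.dropna(), blues_second.dropna()]
    obs, ys = [], []
    for srs in series:
        lines = [l for l in srs.index if l in idx]
        if len(lines) < len(srs):
            missing = sorted(set(srs.index) - set(lines))
            raise KeyError(f"phenotyped lines missing from kinship matrix: {missing[:5]}")
        obs.append(np.array([idx[l] for l in lines], dtype=int))
        ys.append(srs.loc[lines].to_numpy(float))
    fit = em_reml_bivariate(
        ys, obs, K.values, max_iter=max_iter, tol=tol,
        on_nonconvergence=on_nonconvergence,
    )
    gebv = pd.DataFrame(
        fit.g_hat, index=K.line_ids, columns=["target", "second"]
    )
    result = PredictionResult(
        gebv=gebv, model="multitrait",
        fixed_effects={"mean_target": float(fit.beta[0]), "mean_second": float(fit.beta[1])},
        flags=[] if fit.converged else ["not converged"],
    )
    comps = VarianceComponents(Sigma_g=fit.sigma_g, Sigma_e=fit.sigma_e)
    return result, comps


def fit_selection_index(
    blues_target: pd.Series,
    blues_protein: pd.Series,
    K: KinshipMatrix,
    fixed_marker_calls: pd.DataFrame | None = None,
) -> tuple[PredictionResult, VarianceComponents]:
    """Model-based selection index: GEBV_i = x_i b_prot + g_i.

    Step 1 predicts the correlated trait (protein content) for every line by
    single-trait G-BLUP; step 2 fits the target trait with those predictions
    as a fixed covariate.  ``fixed_marker_calls`` (lines x markers, e.g. the
    major glutenin loci) may add fixed marker effects to step 2, giving the
    combined index/W-BLUP model; their contributions enter the final GEBV.
    When the protein covariate carries no variation it is dropped and the
    fit reduces to the remaining model (flagged).
    """
    prot_fit, _ = fit_gblup(blues_protein, K)
    x = prot_fit.gebv.rename("x_protein")
    covs = x.to_frame()
    if fixed_marker_calls is not None:
        centred = fixed_marker_calls - fixed_marker_calls.mean(axis=0)
        covs = covs.join(centred, how="left")
    target_fit, comps = fit_gblup(blues_target, K, covariates=covs)
    gebv = target_fit.gebv.copy()
    flags = list(target_fit.flags)
    for name in covs.columns:
        b = target_fit.fixed_effects.get(str(name))
        if b is None:
            continue
        gebv = gebv + covs[name].reindex(gebv.index).fillna(0.0) * b
    if target_fit.fixed_effects.get("x_protein") is None:
        flags.append("protein covariate dropped; index weight omitted")
    result = PredictionResult(
        gebv=gebv.rename("gebv"), model="index",
        fixed_effects=dict(target_fit.fixed_effects), flags=flags,
    )
    return result, comps
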