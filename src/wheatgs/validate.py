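"""Validation designs for the prediction models.

Three single-trait schemes are compared for every marker-selection strategy:

* scheme A ("inside trading", deliberately flawed): markers are selected by
  GWAS on the full estimation set, then accuracy is measured by fourfold
  cross-validation *within that same set*.  Selecting predictors before
  leaving observations out overstates accuracy — the scheme is implemented
  as a diagnostic, not a recommendation.
* scheme B (correct cross-validation): accuracy on the 20 % of lines left
  out *before* the GWAS.
* scheme C (forward prediction): accuracy on later, disjoint validation
  populations.

Also here: random 80/20 cross-validation, the cross-validated
explained-genetic-variance estimator for candidate major-QTL markers, the
W-BLUP inclusion-threshold sweep, and the four multi-trait information
scenarios (protein content available for training only, also for the
validation set, for additional lines, or for everyone).

Accuracy is always the Pearson correlation between GEBVs and observed BLUEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import KinshipMatrix, MarkerMap, MarkerMatrix
from .models import (
    fit_gblup,
    fit_mas,
    fit_multitrait,
    fit_rrblup,
    fit_selection_index,
    gwas_scan,
    select_mas_markers,
)

__all__ = [
    "AccuracyResult",
    "ExplainedVariance",
    "accuracy",
    "cv_random",
    "run_inside_trading_suite",
    "explained_variance_cv",
    "threshold_sweep",
    "run_multitrait_scenarios",
]

MULTITRAIT_SCENARIOS = ("BASE", "TP", "VP", "ADD", "FULL")


def accuracy(gebv: pd.Series, observed: pd.Series) -> float:
    """Pearson correlation between GEBVs and observed BLUEs.

    Returns NaN (flagged undefined) for fewer than 3 shared lines or a
    zero-variance input; NaNs are excluded from scheme means downstream.
    """
    shared = gebv.index.intersection(observed.index)
    a = gebv.loc[shared].to_numpy(float)
    b = observed.loc[shared].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or a.std() < 1e-12 or b.std() < 1e-12:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class AccuracyResult:
    accuracies: list[float]
    scheme: str = ""
    model: str = ""
    scenario: str = ""

    @property
    def mean(self) -> float:
        vals = np.asarray(self.accuracies, dtype=float)
        return float(np.nanmean(vals)) if vals.size else float("nan")


@dataclass
class ExplainedVariance:
    marker: str
    trait: str
    value: float  # fraction of genetic variance, clamped to [0, 1]
    n_folds_used: int = 0


def _splits(lines: list, frac_train: float, reps: int, rng: np.random.Generator):
    n = len(lines)
    n_train = int(round(frac_train * n))
    for _ in range(reps):
        perm = rng.permutation(n)
        yield [lines[i] for i in perm[:n_train]], [lines[i] for i in perm[n_train:]]


def cv_random(
    blues: pd.Series,
    predictor,
    frac_train: float = 0.8,
    reps: int = 100,
    seed: int = 0,
) -> AccuracyResult:
    """Random resampling validation: train on ``frac_train``, test on the rest.

    ``predictor(train_blues, test_ids) -> pd.Series`` may wrap any of the
    fit_* engines.  Sampling is simple (unstratified), without replacement.
    """
    lines = list(blues.index)
    if len(lines) < 10:
        raise ValueError("cv_random needs at least 10 lines")
    rng = np.random.default_rng(seed)
    accs = []
    for train, test in _splits(lines, frac_train, reps, rng):
        gebv = predictor(blues.loc[train], test)
        accs.append(accuracy(gebv.loc[test], blues.loc[test]))
    return AccuracyResult(accs, scheme="random_80_20")


def _kfold(ids: list, k: int, rng: np.random.Generator):
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)
    for f in folds:
        test = [ids[i] for i in f]
        train = [ids[i] for i in perm if ids[i] not in set(test)]
        yield train, test


def _default_predictors(markers: MarkerMatrix, glu_ids, gwas_result):
    """Per-strategy predictors given a (fixed) marker selection."""
    selections = {
        "glu": select_mas_markers("glu_only", glu_ids=glu_ids),
        "denovo": select_mas_markers("denovo_top3", gwas=gwas_result),
        "combined": select_mas_markers("combined", gwas=gwas_result, glu_ids=glu_ids),
    }
    preds = {}
    for name, sel in selections.items():
        preds[f"mas_{name}"] = (
            lambda tb, ids, sel=sel: fit_mas(tb, markers, sel).gebv
        )
        preds[f"wblup_{name}"] = (
            lambda tb, ids, sel=sel: fit_rrblup(tb, markers, fixed_marker_ids=sel)[0].gebv
        )
    preds["rrblup"] = lambda tb, ids: fit_rrblup(tb, markers)[0].gebv
    return preds


def run_inside_trading_suite(
    basis_blues: pd.Series,
    markers: MarkerMatrix,
    marker_map: MarkerMap,
    K: KinshipMatrix,
    forward_sets: dict[str, pd.Series],
    glu_ids: list[str],
    reps: int = 100,
    frac_est: float = 0.8,
    seed: int = 0,
    predictors: dict | None = None,
) -> pd.DataFrame:
    """All three validation schemes for every marker-selection strategy.

    Per replicate, 80 % of the basis lines form the estimation set on which
    the GWAS selects de novo markers.  Scheme A refits effects in a fourfold
    CV inside that same estimation set (selection held fixed — the flaw
    under study); scheme B predicts the 20 % left out before the GWAS;
    scheme C predicts the forward populations.  Returns a tidy frame
    (scheme, strategy, rep, subset, accuracy).

    ``predictors`` may override/extend the built-in strategies with
    ``name -> f(train_blues, predict_ids) -> gebv`` callables (selection-
    independent predictors such as oracles).
    """
    basis_lines = set(basis_blues.index)
    for name, srs in forward_sets.items():
        overlap = basis_lines & set(srs.index)
        if overlap:
            raise ValueError(
                f"forward set {name!r} overlaps the basis population: {sorted(overlap)[:5]}"
            )
    rng = np.random.default_rng(seed)
    rows = []
    lines = list(basis_blues.index)
    n_est = int(round(frac_est * len(lines)))
    for rep in range(reps):
        perm = rng.permutation(len(lines))
        est = [lines[i] for i in perm[:n_est]]
        left_out = [lines[i] for i in perm[n_est:]]
        est_blues = basis_blues.loc[est]
        gwas_result = gwas_scan(est_blues, markers, marker_map, K)
        preds = _default_predictors(markers, glu_ids, gwas_result)
        if predictors:
            preds.update(predictors)
        fold_rng = np.random.default_rng(rng.integers(0, 2**31))
        folds = list(_kfold(est, 4, fold_rng))
        for strat, predict in preds.items():
            for fi, (ftrain, ftest) in enumerate(folds):
                gebv = predict(basis_blues.loc[ftrain], ftest)
                rows.append(
                    dict(scheme="A_inside_cv", strategy=strat, rep=rep,
                         subset=f"fold{fi}",
                         accuracy=accuracy(gebv.loc[ftest], basis_blues.loc[ftest]))
                )
            gebv = predict(est_blues, left_out)
            rows.append(
                dict(scheme="B_leftout_vs", strategy=strat, rep=rep, subset="vs",
                     accuracy=accuracy(gebv.loc[left_out], basis_blues.loc[left_out]))
            )
            for name, srs in forward_sets.items():
                ids = list(srs.index)
                gebv = predict(est_blues, ids)
                rows.append(
                    dict(scheme="C_forward", strategy=strat, rep=rep, subset=name,
                         accuracy=accuracy(gebv.loc[ids], srs))
                )
    return pd.DataFrame(rows)


def explained_variance_cv(
    blues: pd.Series,
    marker_calls: pd.Series,
    h2: float,
    folds: int = 5,
    reps: int = 100,
    seed: int = 0,
) -> ExplainedVariance:
    """Explained genetic variance of one candidate marker by k-fold CV.

    Per fold a single-marker linear model is fitted on the estimation folds
    and the left-out fold is predicted; the adjusted squared correlation of
    predicted vs observed performance, averaged over folds and replicates
    and divided by the trait heritability, estimates the fraction of genetic
    variance the marker explains (clamped to [0, 1]).  Folds whose
    estimation set is monomorphic for the marker are skipped.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    shared = blues.index.intersection(marker_calls.index)
    y = blues.loc[shared].to_numpy(float)
    z = marker_calls.loc[shared].to_numpy(float)
    n = len(shared)
    rng = np.random.default_rng(seed)
    vals = []
    used = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        for f in np.array_split(perm, folds):
            test = np.zeros(n, dtype=bool)
            test[f] = True
            if z[~test].std() < 1e-12:
                continue  # monomorphic in the estimation folds
            b1, b0 = np.polyfit(z[~test], y[~test], 1)
            pred = b0 + b1 * z[test]
            if pred.std() < 1e-12 or y[test].std() < 1e-12 or test.sum() < 4:
                continue
            r2 = float(np.corrcoef(pred, y[test])[0, 1] ** 2)
            nt = int(test.sum())
            r2_adj = 1.0 - (1.0 - r2) * (nt - 1) / (nt - 2)  # one predictor
            vals.append(r2_adj)
            used += 1
    value = float(np.clip(np.mean(vals) / h2, 0.0, 1.0)) if vals else 0.0
    return ExplainedVariance(
        marker=str(marker_calls.name), trait=str(blues.name), value=value,
        n_folds_used=used,
    )


def threshold_sweep(
    basis_blues: pd.Series,
    markers: MarkerMatrix,
    candidate_ids: list[str],
    forward_sets: dict[str, pd.Series],
    h2: float,
    thresholds: np.ndarray | None = None,
    explained: dict[str, float] | None = None,
    seed: int = 0,
    ev_reps: int = 100,
) -> pd.DataFrame:
    """Forward accuracy of W-BLUP and MAS across inclusion thresholds.

    Candidate markers whose cross-validated explained genetic variance
    exceeds the threshold (in %) enter the W-BLUP model as fixed effects
    (and form the MAS model); with an empty set W-BLUP reduces exactly to
    the RR-BLUP baseline.  Returns a tidy frame (threshold_pct,
    n_markers_fixed, model, mean_accuracy) with the operating threshold
    recorded in ``frame.attrs['operating_threshold_pct']`` (5.0, a
    compromise between explained variance and marker number).
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 25.5, 0.5)
    if explained is None:
        explained = {}
        for mid in candidate_ids:
            ev = explained_variance_cv(
                basis_blues, markers.calls[mid], h2=h2, seed=seed, reps=ev_reps
            )
            explained[mid] = 100.0 * ev.value
    rows = []
    cache: dict[tuple, dict[str, float]] = {}
    for thr in thresholds:
        fixed = tuple(m for m in candidate_ids if explained[m] > thr)
        if fixed not in cache:
            wfit, _ = fit_rrblup(basis_blues, markers, fixed_marker_ids=list(fixed))
            accs_w = [accuracy(wfit.gebv.loc[s.index], s) for s in forward_sets.values()]
            entry = {"wblup": float(np.nanmean(accs_w))}
            if fixed:
                mfit = fit_mas(basis_blues, markers, list(fixed))
                accs_m = [accuracy(mfit.gebv.loc[s.index], s) for s in forward_sets.values()]
                entry["mas"] = float(np.nanmean(accs_m))
            else:
                entry["mas"] = float("nan")
            cache[fixed] = entry
        for model in ("wblup", "mas"):
            rows.append(
                dict(threshold_pct=float(thr), n_markers_fixed=len(fixed),
                     model=model, mean_accuracy=cache[fixed][model])
            )
    out = pd.DataFrame(rows)
    out.attrs["operating_threshold_pct"] = 5.0
    out.attrs["explained_pct"] = dict(explained)
    return out


def run_multitrait_scenarios(
    blues_target: pd.Series,
    blues_protein: pd.Series,
    K: KinshipMatrix,
    reps: int = 100,
    seed: int = 0,
    scenarios=MULTITRAIT_SCENARIOS,
    methods=("GBLUP", "MVM", "INDEX"),
    max_iter: int = 500,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Multi-trait information scenarios with thirds resampling.

    Per replicate the lines are split into validation (V), training (T) and
    additional (A) thirds.  The target trait is always observed on T only;
    protein-content availability depends on the scenario: TP = T, VP = T+V,
    ADD = T+A, FULL = everyone, BASE = single-trait G-BLUP without protein.
    Each scenario is evaluated for the full bivariate mixed model (MVM) and
    the model-based selection index (INDEX); accuracy is measured on V.
    ``tol`` relaxes the EM convergence tolerance relative to a single
    definitive fit: the replicate average is insensitive to the last
    likelihood digits while the runtime is not.
    """
    lines = [l for l in blues_target.index if l in set(blues_protein.index)]
    if len(lines) < 30:
        raise ValueError("multi-trait scenarios need at least 30 lines")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        perm = rng.permutation(len(lines))
        third = len(lines) // 3
        V = [lines[i] for i in perm[:third]]
        T = [lines[i] for i in perm[third : 2 * third]]
        A = [lines[i] for i in perm[2 * third :]]
        prot_sets = {"TP": T, "VP": T + V, "ADD": T + A, "FULL": T + V + A}
        target_train = blues_target.loc[T]
        observed_v = blues_target.loc[V]
        if "BASE" in scenarios:
            base_fit, _ = fit_gblup(target_train, K)
            rows.append(dict(scenario="BASE", method="GBLUP", rep=rep,
                             accuracy=accuracy(base_fit.gebv.loc[V], observed_v)))
        for scen, pset in prot_sets.items():
            if scen not in scenarios:
                continue
            prot = blues_protein.loc[pset]
            if "MVM" in methods:
                try:
                    mfit, _ = fit_multitrait(
                        target_train, prot, K, max_iter=max_iter, tol=tol,
                        on_nonconvergence="warn",
                    )
                    acc = accuracy(mfit.gebv["target"].loc[V], observed_v)
                except Exception as exc:  # pragma: no cover - defensive
                    warnings.warn(f"MVM failed in rep {rep} {scen}: {exc}")
                    acc = float("nan")
                rows.append(dict(scenario=scen, method="MVM", rep=rep, accuracy=acc))
            if "INDEX" in methods:
                ifit, _ = fit_selection_index(target_train, prot, K)
                rows.append(dict(scenario=scen, method="INDEX", rep=rep,
                                 accuracy=accuracy(ifit.gebv.loc[V], observed_v)))
    return pd.DataFrame(rows)
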