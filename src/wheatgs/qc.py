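"""Marker quality control, imputation, LD pruning, and the genomic
relationship matrix.

The QC rules mirror common GBS practice for breeding panels: markers need a
call rate of at least 90 %, a minor allele frequency of at least 0.05
(computed on non-missing calls), and at most 10 % missing data.  Remaining
missing calls are imputed by iterated conditional expectation under a
per-chromosome multivariate-normal model (an EM scheme).  Strongly
correlated markers are thinned by dropping one member of every pair with
r^2 above a threshold (0.8 by default) at random, and the genomic
relationship matrix is

    K = W W' / (2 sum_k p_k (1 - p_k)),   W_ik = Z_ik + 1 - 2 p_k,

with p_k the frequency of the +1-coded allele.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import KinshipMatrix, MarkerMap, MarkerMatrix

__all__ = [
    "filter_markers",
    "impute_missing",
    "ld_prune",
    "compute_kinship",
]


def filter_markers(
    raw: MarkerMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    missing_max: float = 0.10,
) -> tuple[MarkerMatrix, dict]:
    """Apply the call-rate / MAF / missingness filters.

    A marker fails on MAF only when its minor allele frequency is strictly
    below ``maf_min`` (a marker at exactly 0.05 is retained).  Returns the
    filtered matrix and a report with the count removed per rule (a marker
    may be counted under several rules).
    """
    call_rate = raw.call_rate()
    missing = raw.missingness()
    maf = raw.maf()
    fail_call = call_rate < call_rate_min
    fail_missing = missing > missing_max
    fail_maf = maf < maf_min
    keep = ~(fail_call | fail_missing | fail_maf)
    report = {
        "n_input": raw.n_markers,
        "n_fail_call_rate": int(fail_call.sum()),
        "n_fail_missing": int(fail_missing.sum()),
        "n_fail_maf": int(fail_maf.sum()),
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        raise ValueError(f"all {raw.n_markers} markers removed by QC filters: {report}")
    return MarkerMatrix(raw.calls.loc[:, keep].copy()), report


def _impute_group(block: np.ndarray, n_sweeps: int, tol: float) -> np.ndarray:
    """Iterated conditional-expectation imputation of one marker group."""
    missing = np.isnan(block)
    if not missing.any():
        return block
    col_means = np.nanmean(block, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    filled = np.where(missing, col_means[None, :], block)
    if block.shape[1] == 1:
        return filled
    for _ in range(n_sweeps):
        mu = filled.mean(axis=0)
        cov = np.cov(filled, rowvar=False, ddof=1)
        prev = filled.copy()
        for i in np.where(missing.any(axis=1))[0]:
            m = missing[i]
            o = ~m
            if not o.any():
                filled[i, m] = mu[m]
                continue
            coo = cov[np.ix_(o, o)] + 1e-8 * np.eye(int(o.sum()))
            com = cov[np.ix_(m, o)]
            filled[i, m] = mu[m] + com @ np.linalg.solve(coo, filled[i, o] - mu[o])
        if np.max(np.abs(filled - prev)) < tol:
            break
    return np.clip(filled, -1.0, 1.0)


def impute_missing(
    markers: MarkerMatrix,
    marker_map: MarkerMap | None = None,
    n_sweeps: int = 3,
    tol: float = 1e-4,
) -> MarkerMatrix:
    """EM-style imputation of missing calls, chromosome by chromosome.

    Missing entries are replaced by their conditional expectation under an
    iteratively re-estimated mean/covariance model of the markers on the
    same chromosome (the whole panel if no map is given), then clipped to
    [-1, +1].  Deterministic given its input.  A chromosome with a single
    marker falls back to the column mean.
    """
    if not markers.has_missing():
        return markers
    calls = markers.calls.to_numpy(dtype=float).copy()
    if marker_map is not None:
        pos = marker_map.positions()
        groups: dict = {}
        for j, mid in enumerate(markers.marker_ids):
            chrom = pos.loc[mid, "chrom"] if mid in pos.index else "_unmapped"
            groups.setdefault(chrom, []).append(j)
    else:
        groups = {"_all": list(range(markers.n_markers))}
    for cols in groups.values():
        idx = np.asarray(cols, dtype=int)
        calls[:, idx] = _impute_group(calls[:, idx], n_sweeps=n_sweeps, tol=tol)
    return MarkerMatrix(pd.DataFrame(calls, index=markers.line_ids, columns=markers.marker_ids))


def ld_prune(
    markers: MarkerMatrix,
    r2_max: float = 0.8,
    seed: int = 0,
    marker_map: MarkerMap | None = None,
) -> MarkerMatrix:
    """Drop one marker of every pair with squared correlation above ``r2_max``.

    Markers are scanned in map order (position within chromosome) when a map
    is given, otherwise in column order; for each offending pair one member
    is dropped by a seeded coin flip.  Constant markers are dropped with a
    warning.  After the scan no retained pair exceeds ``r2_max``.
    """
    if markers.has_missing():
        raise ValueError("ld_prune requires a complete (imputed) marker matrix")
    order = list(markers.marker_ids)
    if marker_map is not None:
        pos = marker_map.positions()
        mapped = [m for m in order if m in pos.index]
        unmapped = [m for m in order if m not in pos.index]
        mapped.sort(key=lambda m: (pos.loc[m, "chrom"], pos.loc[m, "pos_cM"], m))
        order = mapped + unmapped
    calls = markers.calls[order]
    X = calls.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    constant = sd < 1e-12
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant markers before LD pruning")
    keep = ~constant
    Xs = np.where(constant[None, :], 0.0, (X - X.mean(axis=0)) / np.where(constant, 1.0, sd))
    n = X.shape[0]
    corr = (Xs.T @ Xs) / (n - 1)
    r2 = corr**2
    rng = np.random.default_rng(seed)
    m = len(order)
    for i in range(m):
        if not keep[i]:
            continue
        over = np.where(keep & (r2[i] > r2_max))[0]
        for j in over:
            if j <= i or not keep[i]:
                continue
            if rng.random() < 0.5:
                keep[j] = False
            else:
                keep[i] = False
    kept_ids = [order[i] for i in range(m) if keep[i]]
    # restore the original column order of the input matrix
    kept_ids = [mid for mid in markers.marker_ids if mid in set(kept_ids)]
    return markers.subset(markers=kept_ids)


def compute_kinship(markers: MarkerMatrix, ridge: float = 1e-6) -> KinshipMatrix:
    """Genomic relationship matrix K = WW'/(2 sum p_k(1-p_k)) with a small ridge.

    ``W`` centres each marker at twice its +1-allele frequency; monomorphic
    markers contribute nothing (their centred column and their term in the
    denominator are both zero).  ``ridge * I`` is added for invertibility in
    downstream mixed-model solves; pass ``ridge=0`` for the raw matrix.
    """
    if markers.has_missing():
        raise ValueError("compute_kinship requires a complete (imputed) marker matrix")
    Z = markers.calls.to_numpy(dtype=float)
    p = (Z + 1.0).mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if poly.sum() < 1:
        raise ValueError("all markers are monomorphic; kinship undefined")
    W = Z + 1.0 - 2.0 * p[None, :]
    denominator = float(2.0 * np.sum(p * (1.0 - p)))
    K = (W @ W.T) / denominator
    if ridge:
        K = K + ridge * np.eye(K.shape[0])
    return KinshipMatrix(values=K, line_ids=markers.line_ids, denominator=denominator)


def centered_markers(markers: MarkerMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Centred marker matrix W and +1-allele frequencies p (helper for models)."""
    Z = markers.calls.to_numpy(dtype=float)
    p = (Z + 1.0).mean(axis=0) / 2.0
    return Z + 1.0 - 2.0 * p[None, :], p


def max_pairwise_r2(markers: MarkerMatrix) -> float:
    """Largest squared pairwise marker correlation (exhaustive; test sizes only)."""
    X = markers.calls.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    ok = sd > 1e-12
    Xs = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    corr = (Xs.T @ Xs) / (X.shape[0] - 1)
    np.fill_diagonal(corr, 0.0)
    return float((corr**2).max()) if corr.size else 0.0
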