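"""Synthetic breeding-program data: genomes, breeding values, and trials.

The generator emulates the data structure of a winter-wheat quality breeding
program: a few hundred near-inbred lines genotyped at 1000-5000 biallelic
markers with block-wise linkage disequilibrium, eight quality traits (protein
content plus seven dough rheological parameters) with a dense genetic
correlation network, one to three major glutenin-like loci per trait, and
highly unbalanced completely randomised trials connected only through
replicated check varieties.

Default trait means, variance components and correlations follow the
published quantitative-genetic parameters for such material (protein content
mean 13.16 %, heritabilities 0.40-0.66, genetic correlation up to 0.85
between protein and dough development, major-locus variance fractions up to
~34 %).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import PHENO_COLUMNS, MarkerMap, MarkerMatrix, PhenotypeRecords

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

TRAIT_NAMES = ["PROT", "WAT", "DEV", "STAB", "FQN", "EXT", "RES", "ENG"]

#: trait -> (mean, genetic variance, residual variance, across-trial h2)
TRAIT_TABLE: dict[str, tuple[float, float, float, float]] = {
    "PROT": (13.16, 0.41, 0.58, 0.48),  # protein content (%)
    "WAT": (59.16, 2.76, 2.27, 0.61),  # farinograph water uptake (%)
    "DEV": (4.10, 1.26, 2.44, 0.40),  # dough development time (min)
    "STAB": (14.26, 25.81, 38.92, 0.47),  # dough stability (min)
    "FQN": (137.86, 2634.16, 4010.98, 0.46),  # farino quality number (x10 min)
    "EXT": (172.00, 140.56, 177.74, 0.51),  # extensibility (mm)
    "RES": (393.00, 3001.35, 5565.03, 0.40),  # resistance to extension (EU)
    "ENG": (116.81, 515.45, 337.05, 0.66),  # dough energy (cm^2)
}

# Genetic correlations (lower triangle of the published trait-correlation
# table), order PROT WAT DEV STAB FQN EXT RES ENG.
GENETIC_CORR = np.array(
    [
        [1.00, 0.29, 0.85, 0.76, 0.86, 0.43, 0.20, 0.52],
        [0.29, 1.00, 0.20, 0.22, 0.36, -0.04, 0.15, 0.02],
        [0.85, 0.20, 1.00, 0.78, 0.97, 0.66, 0.15, 0.55],
        [0.76, 0.22, 0.78, 1.00, 0.99, 0.54, 0.55, 0.91],
        [0.86, 0.36, 0.97, 0.99, 1.00, 0.58, 0.56, 0.91],
        [0.43, -0.04, 0.66, 0.54, 0.58, 1.00, -0.20, 0.46],
        [0.20, 0.15, 0.15, 0.55, 0.56, -0.20, 1.00, 0.71],
        [0.52, 0.02, 0.55, 0.91, 0.91, 0.46, 0.71, 1.00],
    ]
)

# Phenotypic correlations (upper triangle of the same table).
PHENOTYPIC_CORR = np.array(
    [
        [1.00, 0.39, 0.45, 0.22, 0.26, 0.35, 0.02, 0.25],
        [0.39, 1.00, 0.24, 0.00, 0.09, -0.01, -0.01, -0.05],
        [0.45, 0.24, 1.00, 0.18, 0.24, 0.29, -0.02, 0.20],
        [0.22, 0.00, 0.18, 1.00, 0.97, 0.18, 0.33, 0.51],
        [0.26, 0.09, 0.24, 0.97, 1.00, 0.18, 0.21, 0.37],
        [0.35, -0.01, 0.29, 0.18, 0.18, 1.00, -0.39, 0.32],
        [0.02, -0.01, -0.02, 0.33, 0.21, -0.39, 1.00, 0.57],
        [0.25, -0.05, 0.20, 0.51, 0.37, 0.32, 0.57, 1.00],
    ]
)

# Major glutenin-subunit-like loci: fraction of genetic variance per trait
# (percentages / 100).  Keys are symbolic; marker ids are resolved against a
# concrete simulated genome by :func:`default_major_loci`.
GLU_VARIANCE_FRACTIONS: dict[str, dict[str, float]] = {
    "Glu-A1": {"WAT": 0.060, "DEV": 0.126, "STAB": 0.304, "FQN": 0.180,
               "RES": 0.024, "EXT": 0.015, "ENG": 0.063},
    "Glu-B1": {"DEV": 0.014, "STAB": 0.040, "FQN": 0.018, "RES": 0.006,
               "EXT": 0.000, "ENG": 0.000},
    "Glu-D1": {"DEV": 0.019, "STAB": 0.339, "FQN": 0.295, "RES": 0.073,
               "EXT": 0.003, "ENG": 0.127},
}


def nearest_correlation(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``floor`` and the result rescaled to unit
    diagonal.  Published trait-correlation tables are frequently slightly
    indefinite because entries are estimated pairwise.
    """
    corr = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(corr)
    if w.min() >= floor:
        return corr
    w = np.clip(w, floor, None)
    repaired = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(repaired))
    return repaired / np.outer(d, d)


def make_psd(cov: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Clip eigenvalues of a symmetric matrix at ``floor``."""
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    if w.min() >= floor:
        return cov
    return v @ np.diag(np.clip(w, floor, None)) @ v.T


def psd_with_fixed_diag(cov: np.ndarray, n_sweeps: int = 200) -> np.ndarray:
    """Nearest PSD matrix with the diagonal of ``cov`` held fixed.

    Dykstra's alternating projections between the PSD cone and the
    fixed-diagonal affine set, run on the correlation scale so traits with
    very different variances are treated evenly.  Used for the polygenic
    remainder, whose diagonal carries the targeted per-trait variances: if
    the requested covariance targets are mutually infeasible (which the
    published trait tables are, once major-locus variance is carved out),
    the off-diagonals move as little as possible while the variances stay
    exact.
    """
    d = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
    R = cov / np.outer(d, d)
    R = (R + R.T) / 2.0
    Y = R.copy()
    correction = np.zeros_like(R)
    for _ in range(n_sweeps):
        Rk = Y - correction
        w, v = np.linalg.eigh(Rk)
        X = v @ np.diag(np.clip(w, 0.0, None)) @ v.T
        correction = X - Rk
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if w.min() >= -1e-10 and np.abs(np.diag(X) - 1.0).max() < 1e-10:
            break
    out = Y * np.outer(d, d)
    return (out + out.T) / 2.0


def _is_psd(mat: np.ndarray, tol: float = 1e-8) -> bool:
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-8):
        return False
    return np.linalg.eigvalsh(mat).min() >= -tol


def default_genetic_cov(traits=TRAIT_NAMES) -> np.ndarray:
    idx = [TRAIT_NAMES.index(t) for t in traits]
    corr = nearest_correlation(GENETIC_CORR[np.ix_(idx, idx)])
    sd = np.array([np.sqrt(TRAIT_TABLE[t][1]) for t in traits])
    return corr * np.outer(sd, sd)


def default_residual_cov(traits=TRAIT_NAMES) -> np.ndarray:
    """Residual covariance backed out from phenotypic and genetic parameters.

    Sigma_e = Sigma_p - Sigma_g with Sigma_p built from the phenotypic
    correlations and total variances; diagonal pinned to the published
    residual variances, then PSD-repaired.
    """
    idx = [TRAIT_NAMES.index(t) for t in traits]
    g = default_genetic_cov(traits)
    sd_p = np.array([np.sqrt(TRAIT_TABLE[t][1] + TRAIT_TABLE[t][2]) for t in traits])
    p = nearest_correlation(PHENOTYPIC_CORR[np.ix_(idx, idx)]) * np.outer(sd_p, sd_p)
    e = p - g
    np.fill_diagonal(e, [TRAIT_TABLE[t][2] for t in traits])
    e = make_psd(e, floor=1e-8)
    np.fill_diagonal(e, [TRAIT_TABLE[t][2] for t in traits])
    return make_psd(e, floor=1e-8)


def default_trait_means(traits=TRAIT_NAMES) -> np.ndarray:
    return np.array([TRAIT_TABLE[t][0] for t in traits])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the simulated breeding program.

    ``major_loci`` is a list of ``(marker_id, trait, fraction)`` triples: the
    marker's targeted fraction of the genetic variance of that trait.  The
    per-trait fractions must sum to < 1; the remainder is polygenic.
    """

    n_lines: int = 400
    n_markers: int = 2000
    n_chromosomes: int = 21
    map_length_cM: float = 150.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_decay_cM: float = 5.0
    het_rate: float = 0.02
    trait_names: tuple[str, ...] = tuple(TRAIT_NAMES)
    genetic_cov: np.ndarray | None = None
    residual_cov: np.ndarray | None = None
    trait_means: np.ndarray | None = None
    major_loci: list[tuple[str, str, float]] = field(default_factory=list)
    n_trials: int = 20
    lines_per_trial: int = 40
    n_checks: int = 4
    check_reps_per_trial: int = 3
    entry_reps: int = 1  # replicates of non-check entries (2+ in yield trials)
    trial_effect_scale: float = 1.0
    n_years: int = 5
    first_year: int = 2009
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        if self.genetic_cov is None:
            self.genetic_cov = default_genetic_cov(self.trait_names)
        if self.residual_cov is None:
            self.residual_cov = default_residual_cov(self.trait_names)
        if self.trait_means is None:
            self.trait_means = default_trait_means(self.trait_names)
        self.genetic_cov = np.asarray(self.genetic_cov, dtype=float)
        self.residual_cov = np.asarray(self.residual_cov, dtype=float)
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        for name, mat in (("genetic_cov", self.genetic_cov), ("residual_cov", self.residual_cov)):
            if mat.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t} for {t} traits, got {mat.shape}")
            if not _is_psd(mat):
                raise ValueError(
                    f"{name} is not symmetric positive semidefinite "
                    f"(min eigenvalue {np.linalg.eigvalsh((mat + mat.T) / 2).min():.3g})"
                )
        if self.trait_means.shape != (t,):
            raise ValueError("trait_means length must match trait_names")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.het_rate < 1.0:
            raise ValueError("het_rate must be in [0, 1)")
        totals: dict[str, float] = {}
        for marker, trait, frac in self.major_loci:
            if trait not in self.trait_names:
                raise ValueError(f"major locus {marker!r} targets unknown trait {trait!r}")
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"major locus fraction must be in [0, 1), got {frac}")
            totals[trait] = totals.get(trait, 0.0) + frac
        for trait, tot in totals.items():
            if tot >= 1.0:
                raise ValueError(f"major-locus fractions for {trait} sum to {tot} >= 1")
        if self.n_checks < 1:
            raise ValueError("need at least one check variety")
        if self.n_checks >= self.n_lines:
            raise ValueError("n_checks must be smaller than n_lines")
        if self.lines_per_trial > self.n_lines:
            raise ValueError(
                f"lines_per_trial ({self.lines_per_trial}) exceeds n_lines ({self.n_lines})"
            )
        if self.n_trials < 1 or self.lines_per_trial < 1:
            raise ValueError("n_trials and lines_per_trial must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage random generator derived from the one seed."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode()) % (2**31)])
        return np.random.default_rng(ss)


def marker_id(chrom: int, index: int) -> str:
    return f"chr{chrom:02d}_m{index:04d}"


def default_major_loci(config: SimulationConfig) -> list[tuple[str, str, float]]:
    """Resolve the three glutenin-like loci to concrete simulated marker ids.

    One locus is placed mid-chromosome on each of the first three chromosomes
    (the 1A/1B/1D analogues) with the default per-trait variance fractions.
    """
    per_chrom = _markers_per_chromosome(config.n_markers, config.n_chromosomes)
    loci = []
    for chrom, symbol in zip((1, 2, 3), ("Glu-A1", "Glu-B1", "Glu-D1")):
        mid = per_chrom[chrom - 1] // 2
        mid_id = marker_id(chrom, mid)
        for trait, frac in GLU_VARIANCE_FRACTIONS[symbol].items():
            if frac > 0 and trait in config.trait_names:
                loci.append((mid_id, trait, frac))
    return loci


def glu_marker_ids(config: SimulationConfig) -> list[str]:
    """Marker ids of the three designated major loci on chromosomes 1-3."""
    per_chrom = _markers_per_chromosome(config.n_markers, config.n_chromosomes)
    return [marker_id(c, per_chrom[c - 1] // 2) for c in (1, 2, 3)]


def _markers_per_chromosome(n_markers: int, n_chrom: int) -> list[int]:
    base = n_markers // n_chrom
    counts = [base] * n_chrom
    for i in range(n_markers - base * n_chrom):
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> tuple[MarkerMatrix, MarkerMap]:
    """Simulate near-inbred line genotypes with block-wise LD.

    Within consecutive blocks of ``ld_block_size`` markers on a chromosome, a
    latent Gaussian with correlation exp(-d/ld_decay_cM) (d = map distance)
    is thresholded at each marker's allele frequency, so adjacent-marker r^2
    decays with distance.  A small fraction ``het_rate`` of calls is set
    heterozygous (0), matching advanced-generation inbred or DH material.
    """
    rng = config.rng("genome")
    per_chrom = _markers_per_chromosome(config.n_markers, config.n_chromosomes)
    lo, hi = config.maf_range

    ids: list[str] = []
    chroms: list[int] = []
    positions: list[float] = []
    calls = np.empty((config.n_lines, config.n_markers), dtype=float)
    col = 0
    for chrom in range(1, config.n_chromosomes + 1):
        m = per_chrom[chrom - 1]
        if m == 0:
            continue
        pos = np.sort(rng.uniform(0.0, config.map_length_cM, size=m))
        maf = rng.uniform(lo, hi, size=m)
        flip = rng.random(m) < 0.5
        p_plus = np.where(flip, maf, 1.0 - maf)  # frequency of the +1 allele
        start = 0
        while start < m:
            stop = min(start + config.ld_block_size, m)
            b = stop - start
            if b == 1 or config.ld_block_size == 1:
                z = rng.standard_normal((config.n_lines, b))
            else:
                d = np.abs(pos[start:stop, None] - pos[None, start:stop])
                corr = np.exp(-d / config.ld_decay_cM)
                chol = np.linalg.cholesky(corr + 1e-10 * np.eye(b))
                z = rng.standard_normal((config.n_lines, b)) @ chol.T
            u = norm.cdf(z)
            block = np.where(u < p_plus[None, start:stop], 1.0, -1.0)
            calls[:, col + start : col + stop] = block
            start = stop
        ids.extend(marker_id(chrom, i) for i in range(m))
        chroms.extend([chrom] * m)
        positions.extend(pos)
        col += m

    if config.het_rate > 0:
        het = rng.random(calls.shape) < config.het_rate
        calls[het] = 0.0

    lines = [f"L{i:04d}" for i in range(config.n_lines)]
    matrix = MarkerMatrix(pd.DataFrame(calls, index=lines, columns=ids))
    mmap = MarkerMap(pd.DataFrame({"marker": ids, "chrom": chroms, "pos_cM": positions}))
    return matrix, mmap


# ---------------------------------------------------------------------------
# True breeding values
# ---------------------------------------------------------------------------


@dataclass
class TrueValues:
    """Ground truth of a simulation: breeding values and major-locus effects.

    ``true_bv`` holds breeding values as deviations from the trait means
    (lines x traits); ``qtl_effects`` maps each major-locus marker id to its
    per-trait allele-substitution effects.
    """

    true_bv: pd.DataFrame
    qtl_effects: dict[str, dict[str, float]]


def simulate_traits(markers: MarkerMatrix, config: SimulationConfig) -> TrueValues:
    """Draw marker-determined breeding values matching the target covariance.

    Major-locus effects are scaled so each locus explains exactly its target
    fraction of that trait's genetic variance in the simulated panel; the
    polygenic background is a linear combination of the remaining markers,
    orthogonalised against the major loci and recoloured so the sample
    genetic covariance of the panel equals ``genetic_cov`` (up to the PSD
    repair of the polygenic remainder).
    """
    if markers.has_missing():
        raise ValueError("simulate_traits requires a complete marker matrix")
    rng = config.rng("traits")
    traits = list(config.trait_names)
    t = len(traits)
    n = markers.n_lines
    Z = markers.calls.to_numpy(dtype=float)
    W = Z - Z.mean(axis=0, keepdims=True)

    marker_index = {m: k for k, m in enumerate(markers.marker_ids)}
    major_ids: list[str] = []
    for mid, trait, frac in config.major_loci:
        if mid not in marker_index:
            raise KeyError(f"major locus marker {mid!r} absent from marker matrix")
        if mid not in major_ids:
            major_ids.append(mid)
        if W[:, marker_index[mid]].var(ddof=1) <= 1e-12:
            raise ValueError(f"major locus marker {mid!r} is monomorphic in the panel")

    # Each locus acts through its marker residualised on the other major
    # markers: sampling LD between loci then cannot leak into another locus's
    # single-marker explained variance, which becomes exact by construction.
    beta = {m: np.zeros(t) for m in major_ids}
    Wtil = np.zeros((n, len(major_ids)))
    if major_ids:
        Wmaj = W[:, [marker_index[m] for m in major_ids]]
        for k in range(len(major_ids)):
            others = np.column_stack(
                [np.ones(n)] + [Wmaj[:, j] for j in range(len(major_ids)) if j != k]
            )
            coef, *_ = np.linalg.lstsq(others, Wmaj[:, k], rcond=None)
            Wtil[:, k] = Wmaj[:, k] - others @ coef
    for mid, trait, frac in config.major_loci:
        k = major_ids.index(mid)
        var_k = W[:, marker_index[mid]].var(ddof=1)
        var_til = Wtil[:, k].var(ddof=1)
        ti = traits.index(trait)
        sigma_g2 = config.genetic_cov[ti, ti]
        # cov(bv, w_k) = beta var(w~_k); explained = frac requires:
        beta[mid][ti] = np.sqrt(frac * sigma_g2 * var_k) / var_til

    # realized covariance contributed by the major loci
    C_major = np.zeros((t, t))
    if major_ids:
        B = np.stack([beta[m] for m in major_ids])  # loci x traits
        C_major = B.T @ np.cov(Wtil, rowvar=False, ddof=1).reshape(len(major_ids), -1) @ B
    sigma_poly = psd_with_fixed_diag(config.genetic_cov - C_major)

    poly_cols = [k for m, k in marker_index.items() if m not in major_ids]
    A = rng.standard_normal((len(poly_cols), t))
    G0 = W[:, poly_cols] @ A
    if major_ids:
        # orthogonalise the polygenic part against the major-locus markers so
        # each locus's realised explained variance hits its target exactly
        X = np.column_stack([np.ones(n), W[:, [marker_index[m] for m in major_ids]]])
        G0 = G0 - X @ np.linalg.lstsq(X, G0, rcond=None)[0]
    else:
        G0 = G0 - G0.mean(axis=0, keepdims=True)

    # recolour so the sample covariance equals sigma_poly exactly
    C0 = np.cov(G0, rowvar=False, ddof=1).reshape(t, t)
    w0, v0 = np.linalg.eigh(C0)
    w0 = np.clip(w0, 1e-12, None)
    C0_isqrt = v0 @ np.diag(1.0 / np.sqrt(w0)) @ v0.T
    wp, vp = np.linalg.eigh(sigma_poly)
    sigma_sqrt = vp @ np.diag(np.sqrt(np.clip(wp, 0.0, None))) @ vp.T
    G = G0 @ C0_isqrt @ sigma_sqrt

    bv = G.copy()
    for k, m in enumerate(major_ids):
        bv += np.outer(Wtil[:, k], beta[m])
    true_bv = pd.DataFrame(bv, index=markers.line_ids, columns=traits)
    qtl_effects = {
        m: {traits[i]: float(beta[m][i]) for i in range(t) if beta[m][i] != 0.0}
        for m in major_ids
    }
    return TrueValues(true_bv=true_bv, qtl_effects=qtl_effects)


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


def simulate_trials(true_values: TrueValues, config: SimulationConfig) -> PhenotypeRecords:
    """Generate an unbalanced multi-trial phenotype table.

    The first ``n_checks`` lines act as check varieties, replicated
    ``check_reps_per_trial`` times in every trial; the remaining lines are
    each assigned (unreplicated) to at least one trial.  An observation is
    trait mean + breeding value + trial effect + plot residual, with the
    residual vector for a plot drawn from ``residual_cov`` so that residual
    correlations between traits are preserved.  Trial effects have standard
    deviation ``trial_effect_scale`` times the genetic standard deviation,
    emulating confounded trial and genotype-by-environment variation.
    """
    rng = config.rng("trials")
    traits = list(config.trait_names)
    lines = list(true_values.true_bv.index)
    if config.lines_per_trial > len(lines):
        raise ValueError("lines_per_trial exceeds the number of simulated lines")
    checks = lines[: config.n_checks]
    entries = lines[config.n_checks :]
    capacity = config.n_trials * config.lines_per_trial
    if capacity < len(entries):
        raise ValueError(
            f"trial capacity {capacity} cannot place all {len(entries)} non-check lines; "
            "increase n_trials or lines_per_trial"
        )

    order = list(rng.permutation(entries))
    assignments: list[list[str]] = []
    cursor = 0
    for _ in range(config.n_trials):
        chosen: list[str] = []
        while len(chosen) < min(config.lines_per_trial, len(entries)):
            if cursor >= len(order):
                order = list(rng.permutation(entries))
                cursor = 0
            cand = order[cursor]
            cursor += 1
            if cand not in chosen:
                chosen.append(cand)
        assignments.append(chosen)

    g_sd = np.sqrt(np.diag(config.genetic_cov))
    bv = true_values.true_bv
    rows: dict[str, list] = {c: [] for c in PHENO_COLUMNS}
    year_of = [
        config.first_year + (j * config.n_years) // config.n_trials
        for j in range(config.n_trials)
    ]
    for j in range(config.n_trials):
        trial = f"T{j:03d}"
        trial_eff = rng.standard_normal(len(traits)) * config.trial_effect_scale * g_sd
        plot_plan = [(line, r) for line in checks for r in range(config.check_reps_per_trial)]
        plot_plan += [(line, r) for line in assignments[j] for r in range(config.entry_reps)]
        for line, rep in plot_plan:
            resid = rng.multivariate_normal(np.zeros(len(traits)), config.residual_cov)
            values = config.trait_means + bv.loc[line].to_numpy() + trial_eff + resid
            for ti, trait in enumerate(traits):
                rows["line"].append(line)
                rows["trial"].append(trial)
                rows["year"].append(year_of[j])
                rows["rep"].append(rep)
                rows["trait"].append(trait)
                rows["value"].append(float(values[ti]))
                rows["is_check"].append(line in checks)
    return PhenotypeRecords(pd.DataFrame(rows))


def degrade_markers(
    markers: MarkerMatrix,
    missing_rate: float = 0.0,
    low_maf_fraction: float = 0.0,
    seed: int = 0,
) -> MarkerMatrix:
    """Synthetic QC fixture: knock out calls and create rare-allele markers.

    ``missing_rate`` of entries are set missing uniformly at random and a
    ``low_maf_fraction`` of markers are regenerated with minor allele
    frequency below 0.05 so they fail the downstream MAF filter.
    """
    for name, rate in (("missing_rate", missing_rate), ("low_maf_fraction", low_maf_fraction)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    calls = markers.calls.to_numpy(dtype=float).copy()
    n, m = calls.shape
    if low_maf_fraction > 0:
        k = int(round(low_maf_fraction * m))
        cols = rng.choice(m, size=k, replace=False)
        for c in cols:
            p = rng.uniform(0.005, 0.045)
            calls[:, c] = np.where(rng.random(n) < p, 1.0, -1.0)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = np.nan
    return MarkerMatrix(pd.DataFrame(calls, index=markers.line_ids, columns=markers.marker_ids))


def simulate_study_population(config: SimulationConfig):
    """Convenience wrapper: genome, truth, and trials in one seeded call."""
    markers, mmap = simulate_genome(config)
    truth = simulate_traits(markers, config)
    pheno = simulate_trials(truth, config)
    return markers, mmap, truth, pheno
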