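"""Response to selection: direct, indirect, marker-assisted, and genomic.

When the predicted best fraction of a validation population is selected, the
expected performance of the selected group is

    mu_hat_sel = mu + h2 (mu_sel - mu)

with mu the population mean of the observed trait, mu_sel the observed mean
of the selected lines, and h2 = 1 for marker-assisted and genomic selection
(the observed BLUEs already estimate genetic merit of the *selected-on*
criterion) or the trait heritability for direct/indirect phenotypic
selection.  The relative superiority is

    rho_rel = (mu_hat_sel - mu) / mu,

which requires a positive trait mean (all traits here are positive-valued).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SelectionOutcome",
    "estimate_response",
    "proportion_correct",
    "compare_strategies",
]

PHENOTYPIC_STRATEGIES = {"direct_pheno", "indirect_protein"}


@dataclass
class SelectionOutcome:
    trait: str
    strategy: str
    fraction: float
    mu: float
    mu_sel: float
    mu_hat_sel: float
    rho_rel: float
    prop_correct: float
    n_selected: int


def _top_fraction(ranking: pd.Series, fraction: float, higher_is_better: bool = True):
    """Ids of the top ``fraction`` of lines by ranking; ties broken by line id."""
    k = int(np.ceil(fraction * len(ranking)))
    if k == 0:
        raise ValueError(f"fraction {fraction} selects zero lines")
    srt = ranking.sort_index().sort_values(ascending=not higher_is_better, kind="stable")
    return list(srt.index[:k])


def estimate_response(
    ranking: pd.Series,
    observed: pd.Series,
    h2: float,
    fraction: float,
    trait: str = "",
    strategy: str = "",
    higher_is_better: bool = True,
) -> SelectionOutcome:
    """Selection response when keeping the top ``fraction`` by ``ranking``.

    ``h2`` is the heritability used to shrink the observed superiority
    (pass 1 for marker-based strategies); ``observed`` must cover every
    ranked line and have a positive mean.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    missing = ranking.index.difference(observed.index)
    if len(missing):
        raise KeyError(f"ranked lines without observations: {list(missing[:5])}")
    observed = observed.loc[ranking.index]
    mu = float(observed.mean())
    if mu <= 0:
        raise ValueError(
            f"relative superiority is undefined for non-positive trait mean ({mu:.3g})"
        )
    selected = _top_fraction(ranking, fraction, higher_is_better)
    mu_sel = float(observed.loc[selected].mean())
    mu_hat_sel = mu + h2 * (mu_sel - mu)
    rho_rel = (mu_hat_sel - mu) / mu
    truly_top = set(_top_fraction(observed, fraction, higher_is_better))
    prop = len(truly_top & set(selected)) / len(truly_top)
    return SelectionOutcome(
        trait=trait, strategy=strategy, fraction=fraction, mu=mu, mu_sel=mu_sel,
        mu_hat_sel=float(mu_hat_sel), rho_rel=float(rho_rel),
        prop_correct=float(prop), n_selected=len(selected),
    )


def proportion_correct(
    predicted_ranking: pd.Series,
    reference_ranking: pd.Series,
    fraction: float,
    higher_is_better: bool = True,
) -> float:
    """Fraction of the true top-``fraction`` recovered by the predicted ranking."""
    if set(predicted_ranking.index) != set(reference_ranking.index):
        raise ValueError("rankings must cover the same line set")
    top_pred = set(_top_fraction(predicted_ranking, fraction, higher_is_better))
    top_ref = _top_fraction(reference_ranking, fraction, higher_is_better)
    return len(top_pred & set(top_ref)) / len(top_ref)


def compare_strategies(
    blues_validation: pd.DataFrame,
    gebv_sets: dict[str, pd.DataFrame | pd.Series],
    protein_blues: pd.Series,
    h2_table: dict[str, float],
    fractions=(0.10, 0.20, 0.30, 0.40, 0.50),
    higher_is_better: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Tidy response table across strategies, traits, and selected fractions.

    ``blues_validation`` holds the observed BLUEs (lines x traits);
    ``gebv_sets`` maps marker-based strategy names (e.g. ``mas``,
    ``gs_baseline``, ``gs_enhanced``) to GEBV frames over the same lines.
    Built-in phenotypic strategies: ``direct_pheno`` ranks by the observed
    trait itself and ``indirect_protein`` by the protein BLUEs; both shrink
    the observed superiority by the evaluated trait's heritability from
    ``h2_table``.  Strategies whose inputs are missing are omitted with a
    warning.  Selection direction defaults to "higher is better" for every
    trait; override per trait via ``higher_is_better``.
    """
    higher = higher_is_better or {}
    rows = []
    for trait in blues_validation.columns:
        observed = blues_validation[trait].dropna()
        hib = higher.get(trait, True)
        rankings: dict[str, tuple[pd.Series, float]] = {
            "direct_pheno": (observed, h2_table.get(trait, 1.0)),
        }
        if protein_blues is not None and trait != "PROT":
            prot = protein_blues.reindex(observed.index).dropna()
            if len(prot) == len(observed):
                # observed superiority in the evaluated trait shrinks by that
                # trait's heritability, whatever criterion ranked the lines
                rankings["indirect_protein"] = (prot, h2_table.get(trait, 1.0))
            else:
                warnings.warn(f"{trait}: protein BLUEs incomplete; indirect strategy omitted")
        for name, gebv in gebv_sets.items():
            srs = gebv[trait] if isinstance(gebv, pd.DataFrame) else gebv
            srs = srs.reindex(observed.index).dropna()
            if len(srs) != len(observed):
                warnings.warn(f"{trait}: GEBVs incomplete for {name}; omitted")
                continue
            rankings[name] = (srs, 1.0)  # h2 = 1 for marker-based strategies
        for strategy, (ranking, h2) in rankings.items():
            for frac in fractions:
                out = estimate_response(
                    ranking, observed, h2=h2, fraction=frac, trait=trait,
                    strategy=strategy, higher_is_better=hib,
                )
                rows.append(vars(out))
    return pd.DataFrame(rows)
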