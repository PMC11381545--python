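"""Aggregated PCS/TCS Z-scores and consecutive-visit dynamics.

Per-species abundances are standardized over all cohort samples,

    z_ij = (A_ij - mu_i) / sigma_i,

and a class score per sample aggregates the members of a colonizer class

    Z_class(j) = (1 / sqrt(n)) * sum_i z_ij,

which is standard normal under an iid-normal null regardless of the
class size n.  Consecutive same-subject visits then yield the pair
statistics mu = (Z_t + Z_{t+1})/2 and Delta = Z_{t+1} - Z_t used to
stratify individuals (class-enriched when mu > 2, depleted when mu < -2)
and to quantify community destabilization via the Jaccard similarity of
the present-species sets at adjacent visits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AbundanceMatrix, PresenceMatrix, consecutive_pairs
from .flux import PCS, TCS

ENRICHED = "enriched"
DEPLETED = "depleted"
NEITHER = "neither"


class SpeciesZScorer(BaseEstimator, TransformerMixin):
    """Standardize each species over all samples (sd with n-1 denominator).

    Zero-variance species carry no signal and are dropped with a warning
    at transform time; the fitted attributes ``mean_``, ``std_`` and
    ``kept_species_`` record the standardization actually applied.
    """

    def fit(self, X, y=None):
        values = X.values if isinstance(X, AbundanceMatrix) else pd.DataFrame(X)
        self.mean_ = values.mean(axis=1)
        self.std_ = values.std(axis=1, ddof=1)
        self.kept_species_ = values.index[self.std_ > 0]
        n_dropped = len(values.index) - len(self.kept_species_)
        if n_dropped:
            warnings.warn(
                f"dropping {n_dropped} zero-variance species from standardization",
                stacklevel=2,
            )
        return self

    def transform(self, X) -> pd.DataFrame:
        values = X.values if isinstance(X, AbundanceMatrix) else pd.DataFrame(X)
        kept = values.loc[self.kept_species_]
        return kept.sub(self.mean_[self.kept_species_], axis=0).div(
            self.std_[self.kept_species_], axis=0
        )


def species_zscores(
    abundances: AbundanceMatrix, species_subset=None
) -> pd.DataFrame:
    """Standardized species × sample matrix, optionally on a subset."""
    values = abundances.values
    if species_subset is not None:
        species_subset = list(species_subset)
        if len(species_subset) == 0:
            raise ValueError("empty species subset")
        values = values.loc[species_subset]
    return SpeciesZScorer().fit_transform(values)


def aggregate_group_score(zmatrix: pd.DataFrame, members) -> pd.Series:
    """Per-sample class score: sum of member z-scores divided by sqrt(n)."""
    members = [m for m in members if m in zmatrix.index]
    if len(members) == 0:
        raise ValueError("class has no members with defined z-scores")
    return zmatrix.loc[members].sum(axis=0) / np.sqrt(len(members))


def compute_scores(
    abundances: AbundanceMatrix,
    labels: pd.Series,
    presence: PresenceMatrix | None = None,
) -> pd.DataFrame:
    """Per-sample score table: Z_PCS, Z_TCS and (if presence given) richness."""
    z = species_zscores(abundances)
    out = pd.DataFrame(index=abundances.samples)
    for cls, column in ((PCS, "Z_PCS"), (TCS, "Z_TCS")):
        members = labels.index[labels == cls]
        out[column] = aggregate_group_score(z, members)
    if presence is not None:
        out["richness"] = presence.richness()
    out.index.name = "sample_id"
    return out


def consecutive_dynamics(scores: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Pair table of mu and Delta per class over adjacent same-subject visits."""
    pairs = consecutive_pairs(metadata)
    out = pairs.copy()
    for column in scores.columns:
        z_t = scores.loc[pairs["sample_t"], column].to_numpy()
        z_t1 = scores.loc[pairs["sample_t1"], column].to_numpy()
        key = column.removeprefix("Z_").lower()
        out[f"mu_{key}"] = 0.5 * (z_t + z_t1)
        out[f"delta_{key}"] = z_t1 - z_t
    return out


def stratify_individuals(
    pair_table: pd.DataFrame,
    class_label: str = TCS,
    hi: float = 2.0,
    lo: float = -2.0,
) -> pd.Series:
    """Label each pair enriched (mu > hi), depleted (mu < lo) or neither."""
    mu = pair_table[f"mu_{class_label.lower()}"]
    labels = pd.Series(NEITHER, index=pair_table.index, name="stratum")
    labels[mu > hi] = ENRICHED
    labels[mu < lo] = DEPLETED
    return labels


def jaccard_consecutive(presence: PresenceMatrix) -> pd.Series:
    """Jaccard similarity of present-species sets at adjacent visits.

    A pair where both visits detect nothing has an undefined similarity
    and is returned as NaN.
    """
    pairs = consecutive_pairs(presence.metadata)
    values = presence.values
    sims = []
    for a_col, b_col in zip(pairs["sample_t"], pairs["sample_t1"]):
        a = values[a_col].to_numpy()
        b = values[b_col].to_numpy()
        union = int(np.sum(a | b))
        sims.append(np.nan if union == 0 else int(np.sum(a & b)) / union)
    return pd.Series(sims, index=pairs.index, name="jaccard")


def compare_similarity(
    jaccard: pd.Series,
    strata: pd.Series,
    test: str = "wilcoxon_one_sided",
) -> dict:
    """One-sided test that enriched pairs are *less* similar than depleted.

    ``test`` is ``wilcoxon_one_sided`` (rank-sum, default — matches the
    quoted p-value) or ``t_test`` (Welch, matching the figure legend).
    """
    enriched = jaccard[strata == ENRICHED].dropna()
    depleted = jaccard[strata == DEPLETED].dropna()
    if len(enriched) < 2 or len(depleted) < 2:
        raise ValueError(
            f"need >= 2 pairs per group, got {len(enriched)} enriched / "
            f"{len(depleted)} depleted"
        )
    if test == "wilcoxon_one_sided":
        stat, p = stats.mannwhitneyu(enriched, depleted, alternative="less")
    elif test == "t_test":
        stat, p = stats.ttest_ind(enriched, depleted, equal_var=False, alternative="less")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "n_enriched": int(len(enriched)),
        "n_depleted": int(len(depleted)),
        "median_enriched": float(enriched.median()),
        "median_depleted": float(depleted.median()),
    }


def richness_dynamics(
    richness: pd.Series, pair_table: pd.DataFrame, class_label: str = PCS
) -> dict:
    """Spearman correlation between Delta_class and richness change per pair.

    ``richness`` is per-sample (species detected, or genes detected when
    gene counts are available).
    """
    delta_r = (
        richness.loc[pair_table["sample_t1"]].to_numpy()
        - richness.loc[pair_table["sample_t"]].to_numpy()
    )
    delta_z = pair_table[f"delta_{class_label.lower()}"].to_numpy()
    rho, p = stats.spearmanr(delta_z, delta_r)
    return {"rho": float(rho), "p_value": float(p), "n_pairs": int(len(pair_table))}
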