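"""Two-state Markov-chain "microbial flux" and PCS/TCS classification.

Each species' presence/absence sequence over a subject's consecutive
visits is treated as a realization of a two-state Markov chain.  Pooling
transition pairs across all subjects gives per-species maximum-likelihood
transition probabilities:

* ``inflow``  = P(absent -> present) = n_ap / (n_aa + n_ap)
* ``outflow`` = P(present -> absent) = n_pa / (n_pp + n_pa)

Species with high inflow (> t_in) and low outflow (< t_out) are
persistent colonizers (PCS); the mirror image are transient colonizers
(TCS); everything else — including species with an undefined probability
— is left unclassified.  Species at 0% or 100% prevalence carry no
transition information and are excluded from estimation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import PresenceMatrix, consecutive_pairs

PCS = "PCS"
TCS = "TCS"
UNCLASSIFIED = "UNCLASSIFIED"

COUNT_COLUMNS = ["n_aa", "n_ap", "n_pa", "n_pp"]


class MarkovFluxEstimator(BaseEstimator):
    """Per-species inflow/outflow transition-probability estimator.

    Parameters
    ----------
    t_in, t_out : float
        Classification thresholds on inflow and outflow (defaults 0.3).
        PCS requires inflow > t_in and outflow < t_out; TCS requires
        outflow > t_out and inflow < t_in; inequalities are strict.

    Attributes
    ----------
    summary_ : pandas.DataFrame
        One row per species: transition counts, inflow, outflow,
        prevalence, ``excluded`` flag and ``label``.
    n_pairs_ : int
        Number of consecutive same-subject visit pairs in the cohort.
    """

    def __init__(self, t_in: float = 0.3, t_out: float = 0.3):
        self.t_in = t_in
        self.t_out = t_out

    def fit(self, X: PresenceMatrix, y=None):
        counts = count_transitions(X)
        flux = estimate_flux(counts)
        flux["label"] = classify_colonizers(flux, t_in=self.t_in, t_out=self.t_out)
        self.summary_ = flux
        self.n_pairs_ = int(len(consecutive_pairs(X.metadata)))
        return self

    @property
    def inflow_(self) -> pd.Series:
        return self.summary_["inflow"]

    @property
    def outflow_(self) -> pd.Series:
        return self.summary_["outflow"]

    @property
    def labels_(self) -> pd.Series:
        return self.summary_["label"]


def count_transitions(presence: PresenceMatrix) -> pd.DataFrame:
    """Pool per-species transition-pair counts over all subjects.

    Pairs are adjacent *observed* visits of the same subject (a skipped
    visit does not break adjacency).  Returns one row per species with
    columns ``n_aa, n_ap, n_pa, n_pp`` and ``prevalence`` (fraction of
    all samples in which the species is present); species at prevalence
    0 or 1 are flagged ``excluded`` for downstream estimation.
    """
    pairs = consecutive_pairs(presence.metadata)
    single = presence.metadata.groupby("subject_id").size()
    lonely = single.index[single < 2].tolist()
    if lonely:
        warnings.warn(
            f"subject(s) with a single visit contribute no pairs: {lonely}",
            stacklevel=2,
        )
    values = presence.values
    n_species = len(values.index)
    n_aa = np.zeros(n_species, dtype=np.int64)
    n_ap = np.zeros(n_species, dtype=np.int64)
    n_pa = np.zeros(n_species, dtype=np.int64)
    n_pp = np.zeros(n_species, dtype=np.int64)
    for a_col, b_col in zip(pairs["sample_t"], pairs["sample_t1"]):
        a = values[a_col].to_numpy()
        b = values[b_col].to_numpy()
        n_pp += a & b
        n_pa += a & ~b
        n_ap += ~a & b
        n_aa += ~a & ~b
    out = pd.DataFrame(
        {"n_aa": n_aa, "n_ap": n_ap, "n_pa": n_pa, "n_pp": n_pp},
        index=values.index,
    )
    out["prevalence"] = values.mean(axis=1)
    out["excluded"] = (out["prevalence"] == 0.0) | (out["prevalence"] == 1.0)
    return out


def estimate_flux(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize transition counts into inflow/outflow probabilities.

    Undefined rows (zero denominator) are left NaN, never imputed.
    Species flagged ``excluded`` (prevalence 0% or 100%) get NaN for both.
    """
    flux = counts.copy()
    absent_pairs = flux["n_aa"] + flux["n_ap"]
    present_pairs = flux["n_pp"] + flux["n_pa"]
    with np.errstate(invalid="ignore", divide="ignore"):
        flux["inflow"] = np.where(absent_pairs > 0, flux["n_ap"] / absent_pairs, np.nan)
        flux["outflow"] = np.where(present_pairs > 0, flux["n_pa"] / present_pairs, np.nan)
    excluded = flux.get("excluded")
    if excluded is not None:
        flux.loc[excluded, ["inflow", "outflow"]] = np.nan
    return flux


def classify_colonizers(
    flux: pd.DataFrame, t_in: float = 0.3, t_out: float = 0.3
) -> pd.Series:
    """Label species PCS / TCS / UNCLASSIFIED by strict threshold rules."""
    inflow = flux["inflow"]
    outflow = flux["outflow"]
    labels = pd.Series(UNCLASSIFIED, index=flux.index, name="label")
    labels[(inflow > t_in) & (outflow < t_out)] = PCS
    labels[(outflow > t_out) & (inflow < t_in)] = TCS
    labels[inflow.isna() | outflow.isna()] = UNCLASSIFIED
    return labels


def compare_flux_estimates(
    flux_a: pd.DataFrame, flux_b: pd.DataFrame, min_shared: int = 10
) -> pd.DataFrame:
    """Spearman rank agreement of two flux tables on their shared species.

    Used to ask whether inflow/outflow estimated in one cohort (or at one
    sequencing depth) ranks species the same way as in another.
    """
    report = []
    for column in ("inflow", "outflow"):
        a = flux_a[column]
        b = flux_b[column]
        shared = a.dropna().index.intersection(b.dropna().index)
        if len(shared) < min_shared:
            raise ValueError(
                f"only {len(shared)} shared species with defined {column}; "
                f"need >= {min_shared}"
            )
        rho, p = stats.spearmanr(a.loc[shared], b.loc[shared])
        report.append({"score": column, "n_shared": len(shared), "rho": rho, "p": p})
    return pd.DataFrame(report).set_index("score")
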