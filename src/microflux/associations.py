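"""Enrichment, differential abundance and host-phenotype association.

Downstream questions about the colonizer classes: which functions are
carried by persistent vs transient colonizers (regression of a species'
inflow/outflow score on binary annotations), which species shift in a
disease or perturbation cohort (two-sided rank-sum tests), whether those
shifted species over-represent a class (2x2 chi-square and exact
hypergeometric), how class species co-vary (signed Spearman co-abundance
network), and whether the aggregated class scores track host phenotypes
under a random-intercept-per-subject mixed model:

    Y = Z_PCS * beta_PCS + Z_TCS * beta_TCS + u_subject + eps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix

ENRICHMENT_P_THRESHOLD = 1e-3  # adjusted-p cutoff for function enrichment


@dataclass
class EnrichmentResult:
    """Over-representation of a class within a hit set (2x2 contingency)."""

    table: np.ndarray  # rows: hit / non-hit, cols: in-class / out-of-class
    odds_ratio: float
    chi2: float
    chi2_p: float
    hypergeom_p: float
    direction: str  # "over" or "under"

    def as_dict(self) -> dict:
        return {
            "n_hit_in_class": int(self.table[0, 0]),
            "n_hit_out": int(self.table[0, 1]),
            "n_rest_in_class": int(self.table[1, 0]),
            "n_rest_out": int(self.table[1, 1]),
            "odds_ratio": self.odds_ratio,
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
            "hypergeom_p": self.hypergeom_p,
            "direction": self.direction,
        }


@dataclass
class AssociationResult:
    """Mixed-model association of a response with class scores or a species."""

    response: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    random_intercept_var: float
    residual_var: float
    fixed_effect_variance_fraction: float
    converged: bool = True
    notes: list[str] = field(default_factory=list)


def coabundance_network(
    abundances: AbundanceMatrix,
    labels: pd.Series,
    p_adj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Signed Spearman co-abundance edges among classified species.

    All PCS-or-TCS species pairs are tested; edges kept where the BH
    adjusted p-value is below the threshold.  Constant species are
    excluded with a warning.
    """
    members = labels.index[labels.isin(["PCS", "TCS"])]
    values = abundances.values.loc[members]
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples for a co-abundance network")
    constant = values.index[values.std(axis=1, ddof=1) == 0]
    if len(constant):
        warnings.warn(f"excluding {len(constant)} constant species", stacklevel=2)
        values = values.drop(index=constant)
    species = values.index.to_list()
    ranked = np.apply_along_axis(stats.rankdata, 1, values.to_numpy())
    rho_mat = np.corrcoef(ranked)
    n = values.shape[1]
    rows = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            rho = rho_mat[i, j]
            # t approximation for the Spearman p-value, as scipy uses
            t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            rows.append((species[i], species[j], rho, p))
    edges = pd.DataFrame(rows, columns=["species_a", "species_b", "rho", "p"])
    if len(edges) == 0:
        return edges.assign(p_adj=[], sign=[])
    edges["p_adj"] = multipletests(edges["p"], method="fdr_bh")[1]
    edges["sign"] = np.where(edges["rho"] > 0, "+", "-")
    return edges[edges["p_adj"] < p_adj_threshold].reset_index(drop=True)


def function_enrichment(
    flux: pd.DataFrame,
    annotations: pd.DataFrame,
    score: str = "inflow",
    p_adj_threshold: float = ENRICHMENT_P_THRESHOLD,
) -> pd.DataFrame:
    """Regress a per-species flux score on each binary function annotation.

    For every function a simple linear regression ``score ~ annotation``
    gives the coefficient (the mean-score difference between annotated
    and unannotated species), its p-value and a BH adjusted p-value; a
    function is flagged enriched when the coefficient is positive and
    the adjusted p is below the threshold.  Functions present in no or
    all species have no contrast and are skipped.
    """
    if score not in ("inflow", "outflow"):
        raise ValueError("score must be 'inflow' or 'outflow'")
    y_all = flux[score].dropna()
    shared = y_all.index.intersection(annotations.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} species with defined {score}; need >= 10")
    y = y_all.loc[shared].to_numpy()
    rows = []
    for function in annotations.columns:
        x = annotations.loc[shared, function].astype(float).to_numpy()
        if x.min() == x.max():
            continue
        res = stats.linregress(x, y)
        rows.append((function, int(x.sum()), res.slope, res.pvalue))
    table = pd.DataFrame(rows, columns=["function", "n_annotated", "coefficient", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table["enriched"] = (table["coefficient"] > 0) & (table["p_adj"] < p_adj_threshold)
    return table.set_index("function")


def differential_abundance(
    abundances: AbundanceMatrix,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Two-group per-species Wilcoxon rank-sum differential abundance.

    Groups come from the metadata ``group`` column (exactly two levels,
    each with >= 3 samples).  Returns per-species p-values and, for
    species below the threshold, the direction of the shift in the
    second (case) group; species all-zero in both groups are skipped.
    """
    groups = abundances.metadata["group"].dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    # direction is reported for the non-reference (case) group
    reference = "control" if "control" in levels else levels[0]
    case = next(g for g in levels if g != reference)
    g0 = groups.index[groups == reference]
    g1 = groups.index[groups == case]
    if len(g0) < 3 or len(g1) < 3:
        raise ValueError("each group needs >= 3 samples")
    rows = []
    for species, row in abundances.values.iterrows():
        a = row[g0].to_numpy()
        b = row[g1].to_numpy()
        if a.max() == 0 and b.max() == 0:
            continue
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        shift = np.median(b) - np.median(a)
        if shift == 0:  # median ties: fall back to the mean direction
            shift = b.mean() - a.mean()
        direction = "enriched" if shift > 0 else "depleted"
        rows.append((species, p, direction))
    table = pd.DataFrame(rows, columns=["species_id", "p", "direction"]).set_index("species_id")
    table["significant"] = table["p"] < p_threshold
    return table


def overlap_enrichment(hit_set, class_set, universe) -> EnrichmentResult:
    """Does a hit set over-represent a colonizer class within a universe?

    Builds the 2x2 hit × class table and reports the chi-square p and
    the exact hypergeometric upper-tail P(overlap >= observed).
    """
    universe = set(universe)
    if len(universe) == 0:
        raise ValueError("empty universe")
    hits = set(hit_set) & universe
    cls = set(class_set) & universe
    k = len(hits & cls)
    table = np.array(
        [
            [k, len(hits) - k],
            [len(cls) - k, len(universe) - len(hits) - len(cls) + k],
        ]
    )
    # upper tail: P(X >= k) with X ~ Hypergeom(N=|U|, K=|class|, n=|hits|)
    hyper_p = float(stats.hypergeom.sf(k - 1, len(universe), len(cls), len(hits)))
    if table.min() >= 0 and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, chi2_p = np.nan, np.nan
    a, b, c, d = table.ravel()
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    expected = len(hits) * len(cls) / len(universe)
    return EnrichmentResult(
        table=table,
        odds_ratio=float(odds),
        chi2=float(chi2),
        chi2_p=float(chi2_p),
        hypergeom_p=hyper_p,
        direction="over" if k >= expected else "under",
    )


def _mixed_fit(data: pd.DataFrame, formula: str, groups: str):
    model = smf.mixedlm(formula, data, groups=data[groups])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=True)


def mixed_model_association(
    scores: pd.DataFrame,
    phenotype: pd.Series,
    metadata: pd.DataFrame,
    response_name: str = "phenotype",
) -> AssociationResult:
    """Random-intercept mixed model of a phenotype on Z_PCS and Z_TCS.

    Falls back to OLS (with a note) when the mixed fit is singular,
    e.g. one sample per subject.
    """
    data = scores[["Z_PCS", "Z_TCS"]].copy()
    data["y"] = phenotype.reindex(data.index)
    data["subject_id"] = metadata.loc[data.index, "subject_id"]
    data = data.dropna()
    notes: list[str] = []
    one_per_subject = data.groupby("subject_id").size().max() == 1
    if one_per_subject:
        notes.append("one sample per subject: mixed model singular, using OLS")
        ols = sm.OLS(data["y"], sm.add_constant(data[["Z_PCS", "Z_TCS"]])).fit()
        coefs = {k: float(ols.params[k]) for k in ("Z_PCS", "Z_TCS")}
        pvals = {k: float(ols.pvalues[k]) for k in ("Z_PCS", "Z_TCS")}
        fixed_var = float(np.var(ols.fittedvalues - ols.params["const"], ddof=0))
        resid_var = float(ols.scale)
        frac = fixed_var / (fixed_var + resid_var) if fixed_var + resid_var > 0 else 0.0
        return AssociationResult(
            response_name, coefs, pvals, 0.0, resid_var, frac, True, notes
        )
    res = _mixed_fit(data, "y ~ Z_PCS + Z_TCS", "subject_id")
    coefs = {k: float(res.params[k]) for k in ("Z_PCS", "Z_TCS")}
    pvals = {k: float(res.pvalues[k]) for k in ("Z_PCS", "Z_TCS")}
    fixed = res.params["Intercept"] + data[["Z_PCS", "Z_TCS"]].to_numpy() @ np.array(
        [coefs["Z_PCS"], coefs["Z_TCS"]]
    )
    fixed_var = float(np.var(fixed, ddof=0))
    re_var = float(res.cov_re.iloc[0, 0])
    resid_var = float(res.scale)
    total = fixed_var + re_var + resid_var
    return AssociationResult(
        response_name,
        coefs,
        pvals,
        re_var,
        resid_var,
        fixed_var / total if total > 0 else 0.0,
        bool(res.converged),
        notes,
    )


def per_species_association(
    abundances: AbundanceMatrix,
    phenotype: pd.Series,
    labels: pd.Series | None = None,
    variance_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-species random-intercept model, filtered by explained variance.

    For each (classified) species: Y = A_i * beta_i + u_subject + eps.
    The fixed-effect explained-variance fraction is the marginal share
    var(fixed) / (var(fixed) + var(random intercept) + var(residual));
    a species is retained when it exceeds the threshold.  Zero-variance
    species are skipped.
    """
    md = abundances.metadata
    species_ids = (
        labels.index[labels.isin(["PCS", "TCS"])] if labels is not None else abundances.species
    )
    rows = []
    for species in species_ids:
        a = abundances.values.loc[species]
        if a.std(ddof=1) == 0:
            continue
        data = pd.DataFrame(
            {
                "y": phenotype.reindex(a.index),
                "abundance": a,
                "subject_id": md["subject_id"],
            }
        ).dropna()
        res = _mixed_fit(data, "y ~ abundance", "subject_id")
        beta = float(res.params["abundance"])
        fixed = res.params["Intercept"] + beta * data["abundance"].to_numpy()
        fixed_var = float(np.var(fixed, ddof=0))
        re_var = float(res.cov_re.iloc[0, 0])
        resid_var = float(res.scale)
        total = fixed_var + re_var + resid_var
        frac = fixed_var / total if total > 0 else 0.0
        rows.append((species, beta, float(res.pvalues["abundance"]), frac))
    table = pd.DataFrame(
        rows, columns=["species_id", "beta", "p", "explained_variance"]
    ).set_index("species_id")
    table["retained"] = table["explained_variance"] > variance_threshold
    return table
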