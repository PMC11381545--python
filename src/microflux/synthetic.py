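"""Synthetic longitudinal cohorts with known colonization ground truth.

Every downstream stage is testable without access to cohort metagenomes:
the generator draws, per species, a two-state Markov presence chain over
a subject's visits (initial state from the chain's stationary
distribution, so prevalence is time-homogeneous), log-normal abundance
mass when present, optional marker-gene multinomial read noise at a
fixed sequencing depth, and phenotypes linked to the aggregated class
scores through a random-intercept model.  Defaults emulate a wellness
cohort of 86 subjects sampled 4 times with a few hundred species.

The generator is test scaffolding with known truth, not a mechanistic
claim about gut ecology: it has no species interactions, no phylogeny
and no strain structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import (
    AbundanceMatrix,
    GeneCountMatrix,
    PresenceMatrix,
    scale_per_million,
)
from .flux import classify_colonizers

# stable substream ids so each stage reproduces independently of the others
_STAGE = {"params": 0, "presence": 1, "abundance": 2, "genes": 3, "phenotype": 4, "case_control": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage random substream derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE[stage],)))


@dataclass
class PhenotypeEffects:
    """Linear link from class scores to a host phenotype."""

    beta_pcs: float = 0.5
    beta_tcs: float = -0.5
    subject_random_sd: float = 0.5
    residual_sd: float = 1.0


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    Per-species arrays (``true_inflow``, ``true_outflow``,
    ``abundance_log_mean``, ``abundance_log_sd``) may be given
    explicitly; when ``None`` they are drawn once from the ``seed``:
    inflow/outflow ~ U(0.05, 0.95) (spanning both colonizer classes),
    log-mean ~ N(0, 2) (a few orders of magnitude of abundance spread),
    log-sd = 1.  The same seed and config give bit-identical cohorts.
    """

    n_subjects: int = 86
    n_visits: int = 4
    n_species: int = 300
    true_inflow: np.ndarray | None = None
    true_outflow: np.ndarray | None = None
    abundance_log_mean: np.ndarray | None = None
    abundance_log_sd: np.ndarray | float = 1.0
    read_depth: int = 10_000_000
    n_markers_per_species: int = 100
    phenotype_effects: PhenotypeEffects = field(default_factory=PhenotypeEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_visits", "n_species", "read_depth", "n_markers_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        rng = stage_rng(self.seed, "params")
        if self.true_inflow is None:
            self.true_inflow = rng.uniform(0.05, 0.95, self.n_species)
        else:
            self.true_inflow = np.broadcast_to(
                np.asarray(self.true_inflow, float), (self.n_species,)
            ).copy()
        if self.true_outflow is None:
            self.true_outflow = rng.uniform(0.05, 0.95, self.n_species)
        else:
            self.true_outflow = np.broadcast_to(
                np.asarray(self.true_outflow, float), (self.n_species,)
            ).copy()
        for name in ("true_inflow", "true_outflow"):
            arr = getattr(self, name)
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.abundance_log_mean is None:
            self.abundance_log_mean = rng.normal(0.0, 2.0, self.n_species)
        else:
            self.abundance_log_mean = np.broadcast_to(
                np.asarray(self.abundance_log_mean, float), (self.n_species,)
            ).copy()
        self.abundance_log_sd = np.broadcast_to(
            np.asarray(self.abundance_log_sd, float), (self.n_species,)
        ).copy()
        if (self.abundance_log_sd < 0).any():
            raise ValueError("abundance_log_sd must be >= 0")
        pe = self.phenotype_effects
        if pe.subject_random_sd < 0 or pe.residual_sd < 0:
            raise ValueError("phenotype sds must be >= 0")

    @property
    def species_ids(self) -> pd.Index:
        return pd.Index(
            [f"msp_{i:04d}" for i in range(self.n_species)], name="species_id"
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phenotype_effects" in raw:
            raw["phenotype_effects"] = PhenotypeEffects(**raw["phenotype_effects"])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside each simulated table."""

    inflow: pd.Series
    outflow: pd.Series
    stationary: pd.Series
    labels: pd.Series
    presence: pd.DataFrame | None = None
    subject_intercepts: pd.Series | None = None
    phenotype_effects: PhenotypeEffects | None = None
    shifted_species: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _truth_from_config(config: SimulationConfig) -> SyntheticTruth:
    species = config.species_ids
    inflow = pd.Series(config.true_inflow, index=species, name="inflow")
    outflow = pd.Series(config.true_outflow, index=species, name="outflow")
    denom = inflow + outflow
    # stationary presence probability; 0/0 chains default to all-absent
    pi = pd.Series(
        np.where(denom > 0, inflow / denom.replace(0, np.nan), 0.0).astype(float),
        index=species,
        name="stationary",
    ).fillna(0.0)
    labels = classify_colonizers(pd.DataFrame({"inflow": inflow, "outflow": outflow}))
    notes = []
    if (denom == 0).any():
        notes.append("inflow=outflow=0 for some species: stationary set to 0 (always absent)")
    return SyntheticTruth(inflow, outflow, pi, labels, notes=notes)


def _grid_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        (f"S{s:03d}V{v}", f"S{s:03d}", v)
        for s in range(config.n_subjects)
        for v in range(1, config.n_visits + 1)
    ]
    md = pd.DataFrame(rows, columns=["sample_id", "subject_id", "visit_index"])
    return md.set_index("sample_id")


def simulate_presence_paths(
    config: SimulationConfig, seed: int | None = None
) -> tuple[PresenceMatrix, SyntheticTruth]:
    """Draw per-subject, per-species two-state Markov presence chains.

    Visit 1 is Bernoulli(pi) with the stationary occupancy
    pi = inflow / (inflow + outflow); each later visit transitions with
    P(absent -> present) = inflow and P(present -> absent) = outflow.
    """
    rng = stage_rng(config.seed if seed is None else seed, "presence")
    truth = _truth_from_config(config)
    md = _grid_metadata(config)
    n_sub, n_vis, n_sp = config.n_subjects, config.n_visits, config.n_species
    inflow = truth.inflow.to_numpy()[:, None]
    outflow = truth.outflow.to_numpy()[:, None]
    pi = truth.stationary.to_numpy()[:, None]
    states = np.empty((n_sp, n_sub, n_vis), dtype=bool)
    states[:, :, 0] = rng.random((n_sp, n_sub)) < pi
    for v in range(1, n_vis):
        prev = states[:, :, v - 1]
        u = rng.random((n_sp, n_sub))
        states[:, :, v] = np.where(prev, u >= outflow, u < inflow)
    values = pd.DataFrame(
        states.reshape(n_sp, n_sub * n_vis), index=config.species_ids, columns=md.index
    )
    truth.presence = values.copy()
    return PresenceMatrix(values, md), truth


def simulate_abundances(
    presence: PresenceMatrix,
    config: SimulationConfig,
    seed: int | None = None,
    with_gene_counts: bool = False,
) -> tuple[AbundanceMatrix, GeneCountMatrix | None]:
    """Log-normal abundance mass for present species, per-million scaled.

    With ``with_gene_counts`` the per-sample species mass is split
    uniformly over that species' marker genes and ``read_depth`` reads
    are drawn multinomially, producing a gene count table (each column
    summing exactly to the depth) plus its marker map.
    """
    base_seed = config.seed if seed is None else seed
    rng = stage_rng(base_seed, "abundance")
    mask = presence.values.to_numpy()
    n_sp, n_samp = mask.shape
    log_mean = np.asarray(config.abundance_log_mean)[:, None]
    log_sd = np.asarray(config.abundance_log_sd)[:, None]
    mass = np.where(mask, np.exp(rng.normal(log_mean, log_sd, (n_sp, n_samp))), 0.0)
    empty = mass.sum(axis=0) == 0
    if empty.any():
        import warnings

        warnings.warn(
            f"{int(empty.sum())} sample(s) have no present species (zero column)",
            stacklevel=2,
        )
    values = pd.DataFrame(mass, index=presence.values.index, columns=presence.samples)
    abundance = AbundanceMatrix(scale_per_million(values), presence.metadata)
    if not with_gene_counts:
        return abundance, None
    gene_rng = stage_rng(base_seed, "genes")
    m = config.n_markers_per_species
    marker_map = {
        sp: [f"{sp}_g{g:03d}" for g in range(m)] for sp in presence.values.index
    }
    gene_ids = [g for genes in marker_map.values() for g in genes]
    probs = np.repeat(mass / np.where(mass.sum(axis=0) > 0, mass.sum(axis=0), 1.0), m, axis=0) / m
    counts = np.zeros((n_sp * m, n_samp), dtype=np.int64)
    for j in range(n_samp):
        if probs[:, j].sum() > 0:
            counts[:, j] = gene_rng.multinomial(config.read_depth, probs[:, j] / probs[:, j].sum())
    gene_counts = GeneCountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=presence.samples),
        marker_map,
    )
    return abundance, gene_counts


def simulate_phenotype(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.Series, SyntheticTruth]:
    """Phenotype linked to the class scores through a random intercept:

    Y = Z_PCS * beta_PCS + Z_TCS * beta_TCS + u_subject + eps.
    """
    rng = stage_rng(config.seed if seed is None else seed, "phenotype")
    pe = config.phenotype_effects
    subjects = metadata.loc[scores.index, "subject_id"]
    unique_subjects = pd.Index(sorted(subjects.unique()))
    u = pd.Series(
        rng.normal(0.0, pe.subject_random_sd, len(unique_subjects)),
        index=unique_subjects,
        name="subject_intercept",
    )
    eps = rng.normal(0.0, pe.residual_sd, len(scores))
    y = (
        scores["Z_PCS"].to_numpy() * pe.beta_pcs
        + scores["Z_TCS"].to_numpy() * pe.beta_tcs
        + u.loc[subjects].to_numpy()
        + eps
    )
    truth = _truth_from_config(config)
    truth.subject_intercepts = u
    truth.phenotype_effects = pe
    return pd.Series(y, index=scores.index, name="phenotype"), truth


def simulate_case_control(
    config: SimulationConfig,
    effect_on_tcs: float,
    seed: int | None = None,
    shifted_species: list[str] | None = None,
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Cross-sectional two-group cohort with a shift in chosen species.

    Each group has ``n_subjects`` single-visit samples.  Occupancy comes
    from each species' stationary probability; in cases the shifted
    species (default: all true transient colonizers) get
    ``effect_on_tcs`` added both to the logit of their occupancy and to
    their log abundance mean, so 0 is an exact null.
    """
    base_seed = config.seed if seed is None else seed
    rng = stage_rng(base_seed, "case_control")
    truth = _truth_from_config(config)
    if shifted_species is None:
        shifted_species = truth.labels.index[truth.labels == "TCS"].tolist()
    truth.shifted_species = list(shifted_species)
    species = config.species_ids
    shifted = species.isin(shifted_species)
    pi = truth.stationary.to_numpy()
    n = config.n_subjects
    eps = 1e-9
    logit = np.log((pi + eps) / (1 - pi + eps))
    pi_case = 1 / (1 + np.exp(-(logit + np.where(shifted, effect_on_tcs, 0.0))))
    rows = []
    masks = []
    for group, p in (("control", pi), ("case", pi_case)):
        present = rng.random((len(species), n)) < p[:, None]
        log_mu = np.asarray(config.abundance_log_mean)[:, None].astype(float).copy()
        if group == "case":
            log_mu = log_mu + np.where(shifted, effect_on_tcs, 0.0)[:, None]
        mass = np.where(
            present,
            np.exp(rng.normal(log_mu, np.asarray(config.abundance_log_sd)[:, None], (len(species), n))),
            0.0,
        )
        masks.append(mass)
        rows += [(f"{group[:4].upper()}{i:03d}", f"{group[:4].upper()}{i:03d}", 1, group) for i in range(n)]
    md = pd.DataFrame(rows, columns=["sample_id", "subject_id", "visit_index", "group"]).set_index(
        "sample_id"
    )
    values = pd.DataFrame(np.hstack(masks), index=species, columns=md.index)
    return AbundanceMatrix(scale_per_million(values), md), truth


def write_config(config: SimulationConfig, path) -> None:
    """Serialize a config (arrays included) to YAML; round-trips exactly."""
    d = {
        "n_subjects": config.n_subjects,
        "n_visits": config.n_visits,
        "n_species": config.n_species,
        "true_inflow": np.asarray(config.true_inflow).tolist(),
        "true_outflow": np.asarray(config.true_outflow).tolist(),
        "abundance_log_mean": np.asarray(config.abundance_log_mean).tolist(),
        "abundance_log_sd": np.asarray(config.abundance_log_sd).tolist(),
        "read_depth": config.read_depth,
        "n_markers_per_species": config.n_markers_per_species,
        "phenotype_effects": vars(config.phenotype_effects),
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)
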