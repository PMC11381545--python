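"""In-memory containers shared by every pipeline stage.

Abundance and presence tables are species × sample :class:`pandas.DataFrame`
objects carrying longitudinal sample metadata (subject, ordered visit,
optional case/control group).  Consecutive-visit pairs — the unit of the
Markov flux model, the pair dynamics and the Jaccard turnover statistics —
are defined once here: *adjacent observed visits of the same subject*,
i.e. a skipped visit does not break adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PER_MILLION = 1_000_000.0

REQUIRED_METADATA_COLUMNS = ("subject_id", "visit_index")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a sample-metadata table.

    Accepts ``sample_id`` either as a column or as the index.  Returns a
    copy indexed by ``sample_id`` with columns ``subject_id``,
    ``visit_index`` (int) and ``group`` (may be all-NA).
    """
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    md.index = md.index.astype(str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if md.index.duplicated().any():
        dups = md.index[md.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    md["subject_id"] = md["subject_id"].astype(str)
    md["visit_index"] = md["visit_index"].astype(int)
    if "group" not in md.columns:
        md["group"] = pd.NA
    key = md[["subject_id", "visit_index"]]
    if key.duplicated().any():
        bad = key[key.duplicated()].itertuples(index=False)
        raise ValueError(
            "duplicate (subject_id, visit_index) pairs: "
            + ", ".join(map(str, bad))
        )
    return md


def consecutive_pairs(metadata: pd.DataFrame) -> pd.DataFrame:
    """Enumerate adjacent observed visit pairs per subject.

    Returns a DataFrame with columns ``subject_id``, ``sample_t``,
    ``sample_t1``, ``visit_t``, ``visit_t1``, ordered by subject then
    visit.  A subject with a single visit contributes no pairs.
    """
    md = validate_metadata(metadata)
    rows = []
    for subject, sub in md.groupby("subject_id", sort=True):
        sub = sub.sort_values("visit_index")
        samples = sub.index.to_numpy()
        visits = sub["visit_index"].to_numpy()
        for i in range(len(sub) - 1):
            rows.append((subject, samples[i], samples[i + 1], visits[i], visits[i + 1]))
    return pd.DataFrame(
        rows, columns=["subject_id", "sample_t", "sample_t1", "visit_t", "visit_t1"]
    )


def _check_alignment(values: pd.DataFrame, metadata: pd.DataFrame) -> None:
    missing = [s for s in values.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")


@dataclass
class AbundanceMatrix:
    """Species × sample abundances on the per-million scale, with metadata.

    ``values``: non-negative DataFrame, rows species, columns sample ids.
    Columns sum to at most 1e6 (equality when no mass is unassigned).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.metadata = validate_metadata(self.metadata)
        self.values = self.values.astype(float)
        self.values.columns = self.values.columns.astype(str)
        self.values.columns.name = "sample_id"
        self.values.index.name = "species_id"
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance matrix contains negative entries")
        _check_alignment(self.values, self.metadata)
        # keep metadata restricted to, and ordered as, the value columns
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def species(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def pairs(self) -> pd.DataFrame:
        return consecutive_pairs(self.metadata)


@dataclass
class PresenceMatrix:
    """Binary species × sample occupancy with the same metadata contract."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.metadata = validate_metadata(self.metadata)
        self.values = self.values.astype(bool)
        self.values.columns = self.values.columns.astype(str)
        self.values.columns.name = "sample_id"
        self.values.index.name = "species_id"
        _check_alignment(self.values, self.metadata)
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def species(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def pairs(self) -> pd.DataFrame:
        return consecutive_pairs(self.metadata)

    def richness(self) -> pd.Series:
        """Detected species per sample."""
        return self.values.sum(axis=0).rename("richness")


@dataclass
class GeneCountMatrix:
    """Gene × sample integer counts plus the species → marker-gene map."""

    counts: pd.DataFrame
    marker_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("gene counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("gene counts must be integers")
        self.counts = self.counts.astype(np.int64)
        for species, markers in self.marker_map.items():
            if len(markers) == 0:
                raise ValueError(f"species {species!r} has an empty marker list")


def scale_per_million(values: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample column so it sums to 1e6 (zero columns stay zero)."""
    totals = values.sum(axis=0)
    scale = pd.Series(np.where(totals > 0, PER_MILLION / totals, 0.0), index=totals.index)
    return values * scale
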