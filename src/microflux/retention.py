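"""Kaplan–Meier species retention.

A species' stay in a subject's gut is a survival record: the clock
starts at the first observed presence, the event is the first subsequent
absence, and a species still present at the subject's last visit is
censored.  Time is measured in visit intervals (adjacent observed
visits), the only clock the sampling design provides.  The product-limit
estimator of these records is the species retention probability.
"""

from __future__ import annotations

import pandas as pd
from lifelines import KaplanMeierFitter

from .containers import PresenceMatrix


def build_retention_events(
    presence: PresenceMatrix,
    first_episode_only: bool = True,
) -> pd.DataFrame:
    """Extract (subject, species) survival records from presence profiles.

    Returns a DataFrame with columns ``subject_id``, ``species_id``,
    ``duration`` (visit intervals, >= 1) and ``observed`` (1 = loss seen,
    0 = censored at the subject's last visit).  A subject × species pair
    never present contributes no record.  With ``first_episode_only``
    (default) only the episode starting at the first observed presence is
    used, avoiding within-subject pseudo-replication; set it to False to
    emit every colonization episode as its own record.
    """
    md = presence.metadata
    values = presence.values
    records: list[tuple[str, str, int, int]] = []
    for subject, sub in md.groupby("subject_id", sort=True):
        samples = sub.sort_values("visit_index").index.to_numpy()
        if len(samples) < 2:
            continue
        block = values[samples].to_numpy()
        for i, species in enumerate(values.index):
            states = block[i]
            start = 0
            while True:
                present_at = next((j for j in range(start, len(states)) if states[j]), None)
                if present_at is None:
                    break
                lost_at = next(
                    (j for j in range(present_at + 1, len(states)) if not states[j]), None
                )
                if lost_at is None:
                    records.append((subject, species, len(states) - 1 - present_at, 0))
                    break
                records.append((subject, species, lost_at - present_at, 1))
                if first_episode_only:
                    break
                start = lost_at + 1
    out = pd.DataFrame(records, columns=["subject_id", "species_id", "duration", "observed"])
    return out[out["duration"] >= 1].reset_index(drop=True)


def km_curve(events: pd.DataFrame) -> pd.DataFrame:
    """Product-limit retention curve S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    ``events`` needs columns ``duration`` and ``observed``.  Returns the
    curve as a DataFrame indexed by time with columns ``n_risk``,
    ``n_event``, ``n_censored`` and ``survival`` (S(0) = 1 in row 0).
    """
    if len(events) == 0:
        raise ValueError("no retention events to fit")
    kmf = KaplanMeierFitter()
    kmf.fit(events["duration"], event_observed=events["observed"])
    table = kmf.event_table
    curve = pd.DataFrame(
        {
            "n_risk": table["at_risk"].astype(int),
            "n_event": table["observed"].astype(int),
            "n_censored": table["censored"].astype(int),
            "survival": kmf.survival_function_["KM_estimate"].reindex(table.index),
        }
    )
    curve.index.name = "time"
    return curve


def retention_probability(curve: pd.DataFrame, horizon: float) -> float:
    """S at the last event time <= horizon (1.0 before any event)."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    eligible = curve.index[curve.index <= horizon]
    if len(eligible) == 0:
        return 1.0
    return float(curve.loc[eligible.max(), "survival"])


def species_retention(
    presence: PresenceMatrix,
    horizon: float,
    first_episode_only: bool = True,
) -> pd.Series:
    """Per-species retention probability at a horizon (NaN if no records)."""
    events = build_retention_events(presence, first_episode_only=first_episode_only)
    out = {}
    for species, sub in events.groupby("species_id"):
        out[species] = retention_probability(km_curve(sub), horizon)
    return pd.Series(out, name=f"retention@{horizon:g}").reindex(presence.species)
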