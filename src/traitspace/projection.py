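"""Projection of user entities into a fitted trait space.

Uploaded entities are treated as supplementary (inactive) individuals: each is
log10-transformed, centered and scaled with the *reference* statistics stored
in the space, then multiplied by the reference loadings.  The background PCA is
never refitted, so projecting data leaves the space unaltered, and a reference
row projected this way lands exactly on its active score.

Entities with a missing or nonpositive value for any trait of the space are
excluded with a per-entity reason (no imputation of any kind is performed); a
trait of the space missing as a *column* is a hard error, because the space
must be refitted without that trait instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trait_space import TraitSpace, standardize

logger = logging.getLogger(__name__)


class MissingTraitColumnError(ValueError):
    """A trait required by the space has no column in the uploaded table."""


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of checking an uploaded table against a space."""

    n_input: int
    n_valid: int
    n_excluded: int
    exclusions: dict[str, list[str]] = field(default_factory=dict)  # entity_id -> reasons
    missing_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        assert self.n_input == self.n_valid + self.n_excluded


@dataclass(frozen=True)
class ProjectionResult:
    """Coordinates of valid entities on the space's components.

    ``coordinates`` has one row per valid entity and columns PC1..PCp; extra
    (non-trait) columns of the upload are carried through for grouping.
    """

    entity_ids: tuple[str, ...]
    coordinates: pd.DataFrame
    traits: tuple[str, ...]
    n_used: int
    extra: pd.DataFrame
    report: ValidationReport


def validate_entities(table: pd.DataFrame, space: TraitSpace) -> ValidationReport:
    """Check each entity for the space's traits; report exclusions.

    An entity is valid iff every trait of the space is present, non-missing
    and strictly positive in its row.
    """
    missing_cols = [t for t in space.traits if t not in table.columns]
    if missing_cols:
        raise MissingTraitColumnError(
            f"uploaded table lacks column(s) {missing_cols} required by the space; "
            "refit the space without these traits to project this table"
        )
    if "entity_id" not in table.columns:
        raise ValueError("uploaded table must have an 'entity_id' column")

    exclusions: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        reasons = []
        for t in space.traits:
            val = pd.to_numeric(pd.Series([row[t]]), errors="coerce").iloc[0]
            if pd.isna(val):
                reasons.append(f"missing value for {t}")
            elif val <= 0:
                reasons.append(f"nonpositive value for {t} ({val!r})")
        if reasons:
            exclusions[str(row["entity_id"])] = reasons
    n_input = len(table)
    n_excluded = len(exclusions)
    return ValidationReport(
        n_input=n_input,
        n_valid=n_input - n_excluded,
        n_excluded=n_excluded,
        exclusions=exclusions,
        missing_columns=[],
    )


def project_entities(space: TraitSpace, table: pd.DataFrame) -> ProjectionResult:
    """Project entities as supplementary individuals onto the space.

    Coordinates for all p components are returned (downstream analyses may
    need more than the plotted pair).  Values whose standardized magnitude
    exceeds 4 reference SDs trigger a warning — they lie outside the
    worldwide range the space was calibrated on — but are never excluded.
    """
    report = validate_entities(table, space)
    valid = table[~table["entity_id"].astype(str).isin(report.exclusions)]

    if len(valid) == 0:
        coords = pd.DataFrame(
            np.empty((0, space.n_components)),
            columns=[f"PC{k + 1}" for k in range(space.n_components)],
        )
        extra_cols = [c for c in table.columns if c not in space.traits and c != "entity_id"]
        return ProjectionResult(
            entity_ids=(),
            coordinates=coords,
            traits=space.traits,
            n_used=space.stats.n_used,
            extra=table.loc[[], extra_cols],
            report=report,
        )

    z, _ = standardize(valid, space.traits, stats=space.stats)
    extreme = np.abs(z.to_numpy()) > 4.0
    if extreme.any():
        n_ext = int(extreme.any(axis=1).sum())
        msg = (
            f"{n_ext} {'entity falls' if n_ext == 1 else 'entities fall'} outside 4 reference SDs "
            "on at least one trait; they are projected anyway"
        )
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)

    scores = z.to_numpy() @ space.loadings
    coords = pd.DataFrame(
        scores,
        index=z.index,
        columns=[f"PC{k + 1}" for k in range(space.n_components)],
    )
    extra_cols = [c for c in valid.columns if c not in space.traits and c != "entity_id"]
    return ProjectionResult(
        entity_ids=tuple(str(e) for e in valid.loc[z.index, "entity_id"]),
        coordinates=coords,
        traits=space.traits,
        n_used=space.stats.n_used,
        extra=valid.loc[z.index, extra_cols],
        report=report,
    )


__all__ = [
    "MissingTraitColumnError",
    "ValidationReport",
    "ProjectionResult",
    "validate_entities",
    "project_entities",
]
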