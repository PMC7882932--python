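"""Fitting reference phenotypic spaces.

A trait space is a PCA fitted to log10-transformed, centered and scaled trait
values of a reference table, optionally restricted to a subset of traits and
growth forms.  Centering and scaling use the reference distribution itself, so
entities projected later (see :mod:`traitspace.projection`) are standardized
against the worldwide distribution rather than their own sample — the point of
using a global reference space.

Conventions (normative for this package):

* log base 10 — the choice of base is absorbed by the z-scoring and does not
  affect scores;
* standard deviations and covariances use the n-1 divisor, so eigenvalues of
  the standardized covariance sum exactly to the number of traits;
* component signs are fixed so that, for each component, the trait with the
  largest absolute loading has a positive loading (ties broken by canonical
  trait order), making figures reproducible across runs and BLAS libraries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference_data import CANONICAL_TRAITS, complete_case_mask, validate_trait_table


@dataclass(frozen=True)
class ReferenceStats:
    """Per-trait mean and SD of log10 values over the reference rows used."""

    traits: tuple[str, ...]
    mean: np.ndarray  # log10-scale means, aligned to traits
    sd: np.ndarray    # log10-scale SDs (n-1 divisor), aligned to traits
    n_used: int

    def __post_init__(self):
        if np.any(np.asarray(self.sd) <= 0):
            bad = self.traits[int(np.argmin(self.sd))]
            raise ValueError(f"trait {bad} has zero variance in the reference rows")
        if self.n_used < 3:
            raise ValueError(f"need at least 3 complete reference rows, got {self.n_used}")


@dataclass(frozen=True)
class TraitSpace:
    """A fitted reference PCA space.

    ``loadings`` is the p x p matrix of orthonormal eigenvectors (columns =
    components, rows aligned to ``traits``); ``scores`` holds the reference
    entities' coordinates on all p components.
    """

    traits: tuple[str, ...]
    growth_forms: tuple[str, ...] | None
    stats: ReferenceStats
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray
    scores: np.ndarray
    entity_ids: tuple[str, ...]
    entity_growth_forms: tuple[str, ...] | None

    @property
    def n_components(self) -> int:
        return len(self.traits)

    # -- plain-text archive -------------------------------------------------
    # A fitted space serializes to JSON (self-describing keys; matrices as
    # nested lists) so fitting and projecting can be separate CLI runs.

    def save(self, path) -> None:
        payload = {
            "format": "traitspace-archive-v1",
            "traits": list(self.traits),
            "growth_forms": list(self.growth_forms) if self.growth_forms else None,
            "stats": {
                "mean": self.stats.mean.tolist(),
                "sd": self.stats.sd.tolist(),
                "n_used": self.stats.n_used,
            },
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained": self.explained.tolist(),
            "scores": self.scores.tolist(),
            "entity_ids": list(self.entity_ids),
            "entity_growth_forms": (
                list(self.entity_growth_forms) if self.entity_growth_forms else None
            ),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "TraitSpace":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "traitspace-archive-v1":
            raise ValueError(f"{path}: not a trait-space archive")
        traits = tuple(payload["traits"])
        stats = ReferenceStats(
            traits=traits,
            mean=np.asarray(payload["stats"]["mean"], dtype=float),
            sd=np.asarray(payload["stats"]["sd"], dtype=float),
            n_used=int(payload["stats"]["n_used"]),
        )
        gf = payload.get("growth_forms")
        egf = payload.get("entity_growth_forms")
        return cls(
            traits=traits,
            growth_forms=tuple(gf) if gf else None,
            stats=stats,
            loadings=np.asarray(payload["loadings"], dtype=float),
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            explained=np.asarray(payload["explained"], dtype=float),
            scores=np.asarray(payload["scores"], dtype=float),
            entity_ids=tuple(payload["entity_ids"]),
            entity_growth_forms=tuple(egf) if egf else None,
        )


def standardize(
    table: pd.DataFrame,
    traits: list[str] | tuple[str, ...],
    stats: ReferenceStats | None = None,
) -> tuple[pd.DataFrame, ReferenceStats]:
    """Log10-transform, center and scale the selected traits.

    Only complete rows (all selected traits present and positive) are
    returned.  When ``stats`` is omitted it is computed from those rows
    (mean and n-1 SD of log10 values) and returned alongside the matrix;
    when given, its means/SDs are applied unchanged — this is how projected
    entities are standardized against the reference distribution.

    Returns a DataFrame of z-scores indexed like the retained rows of
    ``table``, columns in trait order.
    """
    traits = list(traits)
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise ValueError(f"trait column(s) {missing} not present in table")
    mask = complete_case_mask(table, traits)
    sub = table.loc[mask, traits].apply(pd.to_numeric)
    logged = np.log10(sub.to_numpy(dtype=float))

    if stats is None:
        if logged.shape[0] < 3:
            raise ValueError(
                f"need at least 3 complete rows to compute reference stats, got {logged.shape[0]}"
            )
        mean = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = traits[int(np.argmin(sd))]
            raise ValueError(
                f"trait {bad} has identical values in all complete rows (zero variance)"
            )
        stats = ReferenceStats(traits=tuple(traits), mean=mean, sd=sd, n_used=logged.shape[0])
    else:
        order = [stats.traits.index(t) for t in traits]
        mean = np.asarray(stats.mean)[order]
        sd = np.asarray(stats.sd)[order]

    z = (logged - mean) / sd
    return pd.DataFrame(z, index=sub.index, columns=traits), stats


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| trait loads positively.

    Ties on |loading| are broken by row order, which follows the canonical
    trait order of the space.  Ties are detected within a small relative
    tolerance: with two standardized traits the loadings are exactly
    (+-1/sqrt(2), +-1/sqrt(2)), and floating-point noise must not decide
    which trait anchors the sign.
    """
    out = loadings.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        mag = np.abs(col)
        anchor = int(np.argmax(mag >= mag.max() * (1.0 - 1e-9)))  # first near-maximal row
        if col[anchor] < 0:
            out[:, k] = -col
    return out


def fit_space(
    table: pd.DataFrame,
    traits: list[str] | tuple[str, ...] | None = None,
    growth_forms: list[str] | tuple[str, ...] | None = None,
) -> TraitSpace:
    """Fit a reference PCA space on the selected traits and growth forms.

    The standardized matrix Z (complete cases only) is decomposed by SVD;
    loadings are the right singular vectors, eigenvalues the squared singular
    values over n-1, and scores Z @ loadings.  Requires at least two traits
    and three complete rows; warns when rows do not exceed the number of
    traits.
    """
    available = validate_trait_table(table)
    if traits is None:
        traits = available
    traits = [t for t in CANONICAL_TRAITS if t in traits]  # canonical order
    if len(traits) < 2:
        raise ValueError(f"at least two traits are required to fit a space, got {list(traits)}")
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise ValueError(f"trait column(s) {missing} not present in table")

    if growth_forms is not None:
        if "growth_form" not in table.columns:
            raise ValueError("growth-form filtering requested but table has no growth_form column")
        table = table[table["growth_form"].isin(list(growth_forms))]
        if table.empty:
            raise ValueError(f"no rows remain after filtering to growth forms {list(growth_forms)}")

    z, stats = standardize(table, traits)
    n, p = z.shape
    if n <= p:
        warnings.warn(
            f"only {n} complete rows for {p} traits; the fitted space will be unstable",
            UserWarning,
            stacklevel=2,
        )

    zc = z.to_numpy() - z.to_numpy().mean(axis=0)  # guard: z-scores are mean 0 already
    _, svals, vt = np.linalg.svd(zc, full_matrices=True)
    eigenvalues = np.zeros(p)
    eigenvalues[: len(svals)] = svals**2 / (n - 1)
    loadings = _fix_signs(vt.T)
    scores = zc @ loadings
    explained = eigenvalues / eigenvalues.sum()

    sub = table.loc[z.index]
    return TraitSpace(
        traits=tuple(traits),
        growth_forms=tuple(growth_forms) if growth_forms is not None else None,
        stats=stats,
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained=explained,
        scores=scores,
        entity_ids=tuple(str(e) for e in sub["entity_id"]),
        entity_growth_forms=(
            tuple(str(g) for g in sub["growth_form"]) if "growth_form" in sub.columns else None
        ),
    )


def trait_component_correlations(space: TraitSpace) -> pd.DataFrame:
    """Correlations between each trait and each principal component.

    For a PCA of standardized variables the correlation of trait t with
    component k is loading(t, k) * sqrt(eigenvalue k); these are the arrow
    coordinates of the correlation circle, and each trait's squared entries
    sum to one over all p components.
    """
    corr = space.loadings * np.sqrt(space.eigenvalues)[np.newaxis, :]
    return pd.DataFrame(
        corr,
        index=list(space.traits),
        columns=[f"PC{k + 1}" for k in range(space.n_components)],
    )


__all__ = [
    "ReferenceStats",
    "TraitSpace",
    "standardize",
    "fit_space",
    "trait_component_correlations",
]
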