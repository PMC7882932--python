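"""Synthetic reference dataset for the global spectrum of plant form and function.

The worldwide six-trait dataset underlying the global spectrum (2,214 vascular
plant species) is not publicly deposited, so this module generates a calibrated
stand-in with the same statistical skeleton: two dominant latent axes (whole-plant
size and the leaf economics spectrum), log-scale trait marginals spanning the
published worldwide ranges, and a herb/shrub/tree/other growth-form structure
correlated with plant size.

The generative model, per entity, is

    x_t = a_t * S + b_t * E + eps_t,   eps_t ~ N(0, 1 - a_t^2 - b_t^2)

where S and E are independent standard-normal latent factors (size and leaf
economics), so every standardized log-trait x_t has unit variance. x_t is
clipped to +/- ``clip`` standard deviations and affinely mapped onto the trait's
published log10 range, making those ranges hard bounds of the output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical trait column names, in canonical order: adult plant height (m),
#: stem specific density (mg/mm^3), leaf area (mm^2), leaf mass per area
#: (g/m^2), leaf nitrogen per unit mass (mg/g), seed dry mass (mg).
CANONICAL_TRAITS: tuple[str, ...] = ("H", "SSD", "LA", "LMA", "Nmass", "SM")

GROWTH_FORMS: tuple[str, ...] = ("herb", "shrub", "tree", "other")

#: Worldwide log10 ranges of the six traits, natural units as above.
#: The seed-mass upper bound is printed in the source table with a mangled
#: exponent ("2.05 x 10" plus a footnote marker); it is taken here as
#: 2.05 x 10^6 mg, consistent with the heaviest known seeds (see docs/methods.md).
TABLE_LOG10_RANGES: dict[str, tuple[float, float]] = {
    "H": (-3.0, 1.954),
    "SSD": (-1.222, 0.143),
    "LA": (-0.102, 6.446),
    "LMA": (0.690, 3.178),
    "Nmass": (0.394, 1.839),
    "SM": (-3.523, 6.312),
}

#: Default (size, economics) factor loadings per trait.  Size traits (H, SM,
#: LA, SSD) load mainly on the first factor, leaf economics traits (LMA,
#: Nmass) on the second, with opposite signs encoding the quick-to-slow
#: return trade-off.  Chosen so that a six-trait PCA on the output captures
#: roughly three-quarters of total variance in its first two components.
DEFAULT_FACTOR_LOADINGS: dict[str, tuple[float, float]] = {
    "H": (0.95, 0.0),
    "SSD": (0.60, -0.35),
    "LA": (0.80, 0.30),
    "LMA": (0.0, 0.90),
    "Nmass": (0.0, -0.90),
    "SM": (0.90, 0.10),
}


class CalibrationError(ValueError):
    """Raised when a generator calibration violates its invariants."""


@dataclass(frozen=True)
class GeneratorCalibration:
    """Parameters of the synthetic reference generator.

    Attributes
    ----------
    n_entities:
        Number of entities (rows) to generate; default 2,214, the size of the
        original global-spectrum dataset.
    seed:
        Master seed; all internal random streams are derived from it.
    factor_loadings:
        Per-trait ``(a_t, b_t)`` loadings on the size and economics factors,
        with ``a_t**2 + b_t**2 <= 1``.
    log10_ranges:
        Per-trait ``(lo, hi)`` bounds of log10 trait values in natural units.
    clip:
        Standardized log-traits are clipped to ``+/- clip`` standard
        deviations before range mapping, so the ranges are hard bounds.
    tree_threshold, shrub_threshold:
        Growth form from the latent size factor S: ``S > tree_threshold`` is a
        tree, ``shrub_threshold < S <= tree_threshold`` a shrub, the rest herbs.
    other_prob:
        Probability of independently relabelling any entity to "other".
    """

    n_entities: int = 2214
    seed: int = 42
    factor_loadings: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_LOADINGS)
    )
    log10_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_LOG10_RANGES)
    )
    clip: float = 4.0
    tree_threshold: float = 1.0
    shrub_threshold: float = 0.3
    other_prob: float = 0.05

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(t for t in CANONICAL_TRAITS if t in self.factor_loadings)

    def validate(self) -> None:
        if self.n_entities < 1:
            raise CalibrationError(f"n_entities must be positive, got {self.n_entities}")
        if self.clip <= 0:
            raise CalibrationError(f"clip must be positive, got {self.clip}")
        if not 0.0 <= self.other_prob <= 1.0:
            raise CalibrationError(
                f"other_prob must be a probability, got {self.other_prob}"
            )
        if self.shrub_threshold > self.tree_threshold:
            raise CalibrationError(
                "growth-form thresholds must be ordered: "
                f"shrub_threshold={self.shrub_threshold} > tree_threshold={self.tree_threshold}"
            )
        if set(self.factor_loadings) != set(self.log10_ranges):
            raise CalibrationError(
                "factor_loadings and log10_ranges must cover the same traits"
            )
        for t in self.factor_loadings:
            if t not in CANONICAL_TRAITS:
                raise CalibrationError(f"unknown trait {t!r}; expected one of {CANONICAL_TRAITS}")
            a, b = self.factor_loadings[t]
            if a * a + b * b > 1.0 + 1e-12:
                raise CalibrationError(
                    f"trait {t}: a^2 + b^2 = {a * a + b * b:.4f} exceeds 1, "
                    "leaving negative residual variance"
                )
            lo, hi = self.log10_ranges[t]
            if not lo < hi:
                raise CalibrationError(f"trait {t}: empty log10 range [{lo}, {hi}]")


def assign_growth_forms(
    latent_size: np.ndarray,
    calib: GeneratorCalibration,
    rng: np.random.Generator,
) -> np.ndarray:
    """Label entities herb/shrub/tree from the latent size factor, then
    independently relabel each to "other" with ``calib.other_prob``.

    Tall plants (large S) become trees; the default thresholds (0.3, 1.0)
    put roughly 62% of a standard-normal sample in herbs, 22% in shrubs and
    16% in trees before relabelling.
    """
    s = np.asarray(latent_size, dtype=float)
    forms = np.where(s > calib.tree_threshold, "tree",
                     np.where(s > calib.shrub_threshold, "shrub", "herb"))
    other = rng.random(s.shape[0]) < calib.other_prob
    forms = np.where(other, "other", forms)
    return forms.astype(object)


def generate_reference(calib: GeneratorCalibration | None = None) -> pd.DataFrame:
    """Generate a synthetic reference trait table.

    Returns a table with columns ``entity_id``, ``growth_form`` and one column
    per calibrated trait, values in natural units.  Identical calibrations
    (including the seed) produce identical tables.
    """
    if calib is None:
        calib = GeneratorCalibration()
    calib.validate()

    # One master seed; independent child streams for factors, trait noise and
    # growth-form relabelling so adding traits never perturbs the factors.
    factors_ss, noise_ss, forms_ss = np.random.SeedSequence(calib.seed).spawn(3)
    rng_factors = np.random.default_rng(factors_ss)
    rng_noise = np.random.default_rng(noise_ss)
    rng_forms = np.random.default_rng(forms_ss)

    n = calib.n_entities
    size = rng_factors.standard_normal(n)
    econ = rng_factors.standard_normal(n)

    data: dict[str, np.ndarray] = {}
    for t in calib.traits:
        a, b = calib.factor_loadings[t]
        resid_var = max(1.0 - a * a - b * b, 0.0)
        x = a * size + b * econ + np.sqrt(resid_var) * rng_noise.standard_normal(n)
        x = np.clip(x, -calib.clip, calib.clip)
        lo, hi = calib.log10_ranges[t]
        mid, halfwidth = 0.5 * (lo + hi), 0.5 * (hi - lo)
        data[t] = 10.0 ** (mid + (halfwidth / calib.clip) * x)

    table = pd.DataFrame(
        {
            "entity_id": [f"entity_{i + 1:04d}" for i in range(n)],
            "growth_form": assign_growth_forms(size, calib, rng_forms),
            **data,
        }
    )
    return table


def validate_trait_table(table: pd.DataFrame) -> list[str]:
    """Check the trait-table contract; return the canonical trait columns present.

    Raises ``ValueError`` on a missing/duplicated ``entity_id`` column, fewer
    than two canonical trait columns, or a nonpositive trait value (missing
    values are allowed and left in place).
    """
    if "entity_id" not in table.columns:
        raise ValueError("trait table must have an 'entity_id' column")
    if table["entity_id"].duplicated().any():
        dup = table.loc[table["entity_id"].duplicated(), "entity_id"].iloc[0]
        raise ValueError(f"entity_id values must be unique (duplicate: {dup!r})")
    traits = [t for t in CANONICAL_TRAITS if t in table.columns]
    if len(traits) < 2:
        raise ValueError(
            f"at least two canonical trait columns required, found {traits}; "
            f"recognized names are {CANONICAL_TRAITS}"
        )
    for t in traits:
        vals = pd.to_numeric(table[t], errors="coerce")
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            row = table.index[bad][0]
            raise ValueError(
                f"trait {t} has nonpositive value {vals[bad].iloc[0]!r} at row {row}; "
                "trait values must be strictly positive in natural units"
            )
    return traits


def load_reference(path, dialect=None) -> pd.DataFrame:
    """Load a reference trait table from CSV, validating the table contract.

    Growth-form strings outside {herb, shrub, tree, other} are mapped to
    "other" with a logged warning.  Rows with missing trait values are kept;
    they are simply incomplete for any trait set containing that trait.
    """
    from .io import CsvDialect, read_entities_csv

    if dialect is None:
        dialect = CsvDialect()
    table = read_entities_csv(path, dialect)
    validate_trait_table(table)
    if "growth_form" in table.columns:
        known = table["growth_form"].isna() | table["growth_form"].isin(GROWTH_FORMS)
        if not known.all():
            unknown = sorted(set(table.loc[~known, "growth_form"].astype(str)))
            msg = f"unknown growth form(s) {unknown} mapped to 'other'"
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
            table = table.copy()
            table.loc[~known, "growth_form"] = "other"
    return table


def complete_case_mask(table: pd.DataFrame, traits: list[str]) -> pd.Series:
    """True where every requested trait is present, numeric and positive."""
    mask = pd.Series(True, index=table.index)
    for t in traits:
        vals = pd.to_numeric(table[t], errors="coerce")
        mask &= vals.notna() & (vals > 0)
    return mask


__all__ = [
    "CANONICAL_TRAITS",
    "GROWTH_FORMS",
    "TABLE_LOG10_RANGES",
    "DEFAULT_FACTOR_LOADINGS",
    "CalibrationError",
    "GeneratorCalibration",
    "assign_growth_forms",
    "generate_reference",
    "validate_trait_table",
    "load_reference",
    "complete_case_mask",
    "replace",
]
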