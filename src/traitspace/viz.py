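"""Static figures: score-plane biplots with correlation circle and density
layers, and paired trait boxplots; export to png/pdf/svg.

The biplot reproduces the canonical trait-space display: reference entities
scattered on a pair of principal components, a white-to-red density gradient
of occurrence probability, per-growth-form density areas at the 0.50 and 0.95
masses, trait arrows from the correlation circle (scaled into the score cloud)
and optional highlighted reference entities or projected uploads colored by a
grouping column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from .density import DEFAULT_MASSES, estimate_density, growth_form_densities, hdr_regions
from .projection import ProjectionResult
from .trait_space import TraitSpace, trait_component_correlations

ALLOWED_FORMATS = ("png", "pdf", "svg")

#: white (lowest occurrence probability) to red (highest)
DENSITY_CMAP = LinearSegmentedColormap.from_list("white_red", ["#ffffff", "#ff0000"])

FORM_COLORS = {"herb": "#2e7d32", "shrub": "#ef6c00", "tree": "#5d4037", "other": "#607d8b"}
_QUAL_PALETTE = plt.cm.tab10.colors

MM = 1 / 25.4  # matplotlib sizes figures in inches


@dataclass(frozen=True)
class FigureSpec:
    """Layout and layer choices for a trait-space figure."""

    components: tuple[int, int] = (1, 2)
    density_gradient: bool = True
    form_hdr: bool = False
    forms: tuple[str, ...] | None = None
    arrows: bool = True
    highlight_ids: tuple[str, ...] = ()
    group_column: str | None = None
    masses: tuple[float, ...] = DEFAULT_MASSES
    log_density: bool = False
    width_mm: float = 180.0
    height_mm: float = 180.0
    dpi: int = 300

    def validate(self, space: TraitSpace) -> None:
        i, j = self.components
        p = space.n_components
        if i == j:
            raise ValueError(f"component indices must be distinct, got {self.components}")
        for k in (i, j):
            if not 1 <= k <= p:
                raise ValueError(
                    f"component index {k} out of range for a {p}-component space"
                )


def _axis_label(space: TraitSpace, comp: int) -> str:
    return f"PC{comp} ({space.explained[comp - 1] * 100:.1f}%)"


def biplot(
    space: TraitSpace,
    projection: ProjectionResult | None = None,
    spec: FigureSpec | None = None,
    circle_scale: float | None = None,
) -> plt.Figure:
    """Score-plane scatter with optional density, HDR, arrow and overlay layers.

    ``circle_scale`` sets the correlation-circle radius in score units;
    by default it is 0.8 times the largest absolute reference score on the
    displayed pair, which keeps the arrows inside the point cloud.
    """
    if spec is None:
        spec = FigureSpec()
    spec.validate(space)
    ci, cj = spec.components[0] - 1, spec.components[1] - 1
    pts = space.scores[:, [ci, cj]]

    fig, ax = plt.subplots(figsize=(spec.width_mm * MM, spec.height_mm * MM), dpi=spec.dpi)

    if spec.density_gradient and pts.shape[0] >= 10:
        grid = estimate_density(pts)
        values = np.log1p(grid.density) if spec.log_density else grid.density
        ax.pcolormesh(grid.x, grid.y, values.T, cmap=DENSITY_CMAP, shading="auto",
                      rasterized=True, zorder=0)

    ax.scatter(pts[:, 0], pts[:, 1], s=4, c="0.45", linewidths=0, zorder=2,
               label="reference")

    if spec.form_hdr and space.entity_growth_forms is not None:
        hdrs = growth_form_densities(space, components=spec.components,
                                     forms=list(spec.forms) if spec.forms else None,
                                     masses=spec.masses)
        for form, hdr in hdrs.items():
            color = FORM_COLORS.get(form, "#444444")
            for q in hdr.masses:
                for poly in hdr.contours[q]:
                    ax.plot(poly[:, 0], poly[:, 1], color=color,
                            linewidth=1.8 if q == min(hdr.masses) else 1.0, zorder=3)
            ax.plot([], [], color=color, label=form)

    if spec.arrows:
        corr = trait_component_correlations(space)
        s = circle_scale
        if s is None:
            s = 0.8 * float(np.abs(pts).max())
        theta = np.linspace(0, 2 * np.pi, 200)
        ax.plot(s * np.cos(theta), s * np.sin(theta), linestyle=":", color="0.3",
                linewidth=1, zorder=4)
        for t in space.traits:
            cx = corr.loc[t, f"PC{spec.components[0]}"] * s
            cy = corr.loc[t, f"PC{spec.components[1]}"] * s
            ax.annotate("", xy=(cx, cy), xytext=(0, 0),
                        arrowprops=dict(arrowstyle="->", color="black", lw=1.2),
                        zorder=5)
            ax.annotate(t, xy=(cx * 1.08, cy * 1.08), ha="center", va="center",
                        fontsize=9, zorder=5)

    if spec.highlight_ids:
        ids = np.asarray(space.entity_ids)
        wanted = set(spec.highlight_ids)
        mask = np.isin(ids, list(wanted))
        ax.scatter(pts[mask, 0], pts[mask, 1], s=60, facecolors="yellow",
                   edgecolors="black", zorder=6)
        for k, (x, y) in enumerate(pts[mask], start=1):
            ax.annotate(str(k), xy=(x, y), xytext=(4, 4),
                        textcoords="offset points", fontsize=8, zorder=7)

    if projection is not None and len(projection.entity_ids) > 0:
        px = projection.coordinates[f"PC{spec.components[0]}"].to_numpy()
        py = projection.coordinates[f"PC{spec.components[1]}"].to_numpy()
        if spec.group_column is not None:
            if spec.group_column not in projection.extra.columns:
                raise ValueError(
                    f"group column {spec.group_column!r} not in the projected table's "
                    f"extra columns {list(projection.extra.columns)}"
                )
            groups = projection.extra[spec.group_column]
            if pd.api.types.is_numeric_dtype(groups):
                sc = ax.scatter(px, py, c=groups.to_numpy(dtype=float), cmap="Blues",
                                s=28, edgecolors="black", linewidths=0.4, zorder=8)
                fig.colorbar(sc, ax=ax, label=spec.group_column, shrink=0.7)
            else:
                for g_idx, g in enumerate(sorted(groups.astype(str).unique())):
                    m = (groups.astype(str) == g).to_numpy()
                    ax.scatter(px[m], py[m], s=28,
                               color=_QUAL_PALETTE[g_idx % len(_QUAL_PALETTE)],
                               edgecolors="black", linewidths=0.4, zorder=8, label=g)
        else:
            ax.scatter(px, py, s=28, color="#1565c0", edgecolors="black",
                       linewidths=0.4, zorder=8, label="projected")

    ax.set_xlabel(_axis_label(space, spec.components[0]))
    ax.set_ylabel(_axis_label(space, spec.components[1]))
    ax.axhline(0, color="0.8", lw=0.6, zorder=1)
    ax.axvline(0, color="0.8", lw=0.6, zorder=1)
    handles, labels = ax.get_legend_handles_labels()
    if labels:
        ax.legend(loc="best", fontsize=8, frameon=False)
    fig.tight_layout()
    return fig


def trait_boxplots(
    space: TraitSpace,
    table: pd.DataFrame | None = None,
    projection: ProjectionResult | None = None,
    group_column: str | None = None,
    spec: FigureSpec | None = None,
) -> plt.Figure:
    """Per-trait boxplots of the reference next to projected groups.

    One panel per trait on a log axis; the reference distribution (natural
    units, back-transformed from the stored standardization stats via the
    reference scores) is drawn first, then one box per projected group, or a
    single box for all projected entities.  Boxes span the quartiles and the
    whiskers run to the full range of values.

    ``table`` supplies the projected entities' raw trait values; required when
    a projection is given.
    """
    if spec is None:
        spec = FigureSpec()
    traits = space.traits
    p = len(traits)
    fig, axes = plt.subplots(1, p, figsize=(max(2.0 * p, 4) , 3.2), dpi=spec.dpi)
    if p == 1:
        axes = [axes]

    # reference trait values on log10 scale: invert standardization of scores
    ref_logged = space.scores @ space.loadings.T * space.stats.sd + space.stats.mean

    group_values: list[tuple[str, pd.DataFrame]] = []
    if projection is not None and table is not None and len(projection.entity_ids) > 0:
        valid = table[table["entity_id"].astype(str).isin(projection.entity_ids)]
        if group_column is not None:
            if group_column not in valid.columns:
                raise ValueError(f"group column {group_column!r} not in uploaded table")
            for g in sorted(valid[group_column].astype(str).unique()):
                group_values.append((g, valid[valid[group_column].astype(str) == g]))
        else:
            group_values.append(("projected", valid))

    for k, (t, ax) in enumerate(zip(traits, axes)):
        series = [10.0 ** ref_logged[:, k]]
        labels = ["reference"]
        for g, sub in group_values:
            series.append(pd.to_numeric(sub[t], errors="coerce").dropna().to_numpy())
            labels.append(g)
        ax.boxplot(series, whis=(0, 100), tick_labels=labels, showfliers=False)
        ax.set_yscale("log")
        ax.set_title(t, fontsize=10)
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    fig.tight_layout()
    return fig


def export_figure(fig: plt.Figure, path, fmt: str | None = None,
                  width_mm: float | None = None, height_mm: float | None = None,
                  dpi: int | None = None) -> str:
    """Write a figure to png, pdf or svg.

    The format defaults to the file extension; width/height (mm) and dpi
    (png only) override the figure's current size.  Returns the path written.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower() if "." in path else ""
    fmt = fmt.lower()
    if fmt not in ALLOWED_FORMATS:
        raise ValueError(
            f"unsupported format {fmt!r}; allowed formats are {', '.join(ALLOWED_FORMATS)}"
        )
    if width_mm is not None or height_mm is not None:
        w, h = fig.get_size_inches()
        fig.set_size_inches(width_mm * MM if width_mm else w,
                            height_mm * MM if height_mm else h)
    fig.savefig(path, format=fmt, dpi=dpi if dpi is not None else fig.dpi)
    return path


__all__ = [
    "ALLOWED_FORMATS",
    "FigureSpec",
    "biplot",
    "trait_boxplots",
    "export_figure",
]
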