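"""Multi-level polar chart of a fitted blockwise-component survival model.

The circle is divided into equal-angle sectors, one per selected
component, ordered clockwise by decreasing |Cox coefficient|; the sector
radius is proportional to |coefficient| (normalized so the largest is 1)
and its fill encodes the coefficient sign (shaded = positive, white =
negative).  Inside each sector, every nonzero-loading variable of the
component is a point whose distance from the origin is proportional to
its |loading| (scaled by the sector radius) with color/shape encoding the
loading sign: filled dark triangles for positive, open circles for
negative.  Angular positions are jittered (seeded) within the middle 80%
of the sector so coincident loadings stay distinguishable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .coxmodel import CoxFit
from .spca import SparseComponent

__all__ = ["ChartSector", "ChartPoint", "MPChartSpec", "build_mpchart_spec", "render_mpchart"]


@dataclass
class ChartPoint:
    variable: str
    radius: float  # |loading| * sector radius, in [0, 1]
    angle: float  # radians
    positive: bool


@dataclass
class ChartSector:
    label: str
    start_angle: float  # radians, end_angle < start_angle (clockwise)
    end_angle: float
    radius: float  # |coefficient| / max |coefficient|
    positive: bool
    points: list[ChartPoint] = field(default_factory=list)


@dataclass
class MPChartSpec:
    """Deterministic geometry of the chart; serializable for testing."""

    sectors: list[ChartSector]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MPChartSpec":
        raw = json.loads(text)
        sectors = [
            ChartSector(
                label=s["label"],
                start_angle=s["start_angle"],
                end_angle=s["end_angle"],
                radius=s["radius"],
                positive=s["positive"],
                points=[ChartPoint(**p) for p in s["points"]],
            )
            for s in raw["sectors"]
        ]
        return cls(sectors=sectors, seed=raw["seed"])


def build_mpchart_spec(
    fit: CoxFit, provenance: dict[str, SparseComponent], seed: int = 0
) -> MPChartSpec:
    """Compute sector and point geometry from a fitted model and its loadings.

    Scale-free: multiplying every coefficient by a constant leaves the
    spec unchanged.  Equal |coefficient| ties are ordered by label.
    """
    if not fit.labels:
        raise ValueError("fitted model has no selected components")
    order = sorted(
        range(len(fit.labels)), key=lambda i: (-abs(fit.coef[i]), fit.labels[i])
    )
    max_b = max(abs(float(b)) for b in fit.coef)
    if max_b == 0:
        raise ValueError("all coefficients are zero; nothing to draw")
    k_star = len(fit.labels)
    width = 2.0 * math.pi / k_star
    rng = np.random.default_rng(seed)
    sectors: list[ChartSector] = []
    for pos, i in enumerate(order):
        label = fit.labels[i]
        if label not in provenance:
            raise KeyError(f"no loadings recorded for component {label!r}")
        comp = provenance[label]
        if not comp.support:
            raise ValueError(f"component {label!r} has no nonzero loadings")
        start = math.pi / 2 - pos * width  # clockwise from 12 o'clock
        end = start - width
        radius = abs(float(fit.coef[i])) / max_b
        points = []
        for nm in comp.support:
            loading = comp.loading_of(nm)
            # angular jitter inside the middle 80% of the sector
            frac = 0.1 + 0.8 * rng.uniform()
            points.append(
                ChartPoint(
                    variable=nm,
                    radius=abs(loading) * radius,
                    angle=start - frac * width,
                    positive=loading > 0,
                )
            )
        sectors.append(
            ChartSector(label, start, end, radius, float(fit.coef[i]) > 0, points)
        )
    return MPChartSpec(sectors=sectors, seed=seed)


def render_mpchart(spec: MPChartSpec, path: str | Path, png: bool = False) -> Path:
    """Render a chart spec to SVG (optionally also PNG alongside).

    Rendering is a pure function of the spec: the same spec always
    produces byte-identical SVG.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.lines import Line2D
    from matplotlib.patches import Patch

    if not spec.sectors:
        raise ValueError("chart spec has no sectors")
    path = Path(path)

    with matplotlib.rc_context({"svg.hashsalt": "blocksurv", "svg.fonttype": "none"}):
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
        ax.set_theta_zero_location("E")
        ax.set_ylim(0, 1.05)
        ax.set_yticklabels([])
        ax.set_xticks([])
        ax.grid(alpha=0.3)
        for sector in spec.sectors:
            mid = 0.5 * (sector.start_angle + sector.end_angle)
            width = sector.start_angle - sector.end_angle
            color = "#9ecae1" if sector.positive else "white"
            ax.bar(
                mid, sector.radius, width=width, bottom=0.0, color=color,
                edgecolor="black", linewidth=0.8, zorder=2,
            )
            ax.text(mid, 1.02, sector.label, ha="center", va="bottom", fontsize=9)
            for pt in sector.points:
                if pt.positive:
                    ax.plot(pt.angle, pt.radius, marker="^", color="#08306b",
                            markersize=6, linestyle="none", zorder=3)
                else:
                    ax.plot(pt.angle, pt.radius, marker="o", markerfacecolor="white",
                            markeredgecolor="#08306b", markersize=6, linestyle="none",
                            zorder=3)
        legend_items = [
            Patch(facecolor="#9ecae1", edgecolor="black", label="coefficient > 0"),
            Patch(facecolor="white", edgecolor="black", label="coefficient < 0"),
            Line2D([], [], marker="^", color="#08306b", linestyle="none",
                   label="loading > 0"),
            Line2D([], [], marker="o", markerfacecolor="white",
                   markeredgecolor="#08306b", linestyle="none", label="loading < 0"),
        ]
        ax.legend(handles=legend_items, loc="lower left", bbox_to_anchor=(-0.12, -0.1),
                  fontsize=8, frameon=False)
        fig.savefig(path, format="svg", metadata={"Date": None})
        if png:
            fig.savefig(path.with_suffix(".png"), format="png", dpi=150)
        plt.close(fig)
    return path
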