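"""Tabular cluster report and per-region visualization.

The cluster table is TSV with one row per final cluster (singletons included,
flagged as below min-support) and 1-based inclusive breakpoint bounds; a
companion file lists member mapping ids per cluster.  The per-region plot
draws, in the (deletion start, deletion end) plane, each mapping's triangle
in its sample's color with gray shading proportional to the Gaussian height,
and for each cluster with enough support the trapezoid spanned by
``l, r, mu - 3 sigma, mu + 3 sigma`` (clipped to the diagonal and the
triangle bounds), filled yellow and labeled with the mapping count.
Mappings of smaller clusters are drawn with dotted outlines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cluster import ClusteringResult
from .io import SampleConfig
from .model import Region

TABLE_FIXED_COLUMNS = (
    "chrom", "region_id", "cluster_id", "l", "r", "mu", "sigma", "n",
)

#: number of gray shading bands per mapping triangle
_SHADE_BINS = 16


@dataclass(frozen=True)
class ClusterRecord:
    """One reported cluster; coordinates stored 0-based half-open."""

    chrom: str
    region_id: str
    cluster_id: str
    l: int
    r: int
    mu: float
    sigma: float
    n: int
    sample_counts: dict[str, int]
    members: tuple[str, ...]
    below_min_support: bool


def records_from_results(
    results: Sequence[ClusteringResult],
    min_support: int = 2,
) -> list[ClusterRecord]:
    records = []
    for res in results:
        for c in res.clusters:
            records.append(
                ClusterRecord(
                    chrom=res.chrom,
                    region_id=res.region_id,
                    cluster_id=f"{res.region_id}.{c.id}",
                    l=c.l,
                    r=c.r,
                    mu=c.mu,
                    sigma=c.sigma,
                    n=c.n,
                    sample_counts=dict(c.sample_counts),
                    members=tuple(sorted(c.members)),
                    below_min_support=c.n < min_support,
                )
            )
    records.sort(key=lambda rec: (rec.chrom, rec.region_id, rec.l, rec.cluster_id))
    return records


def write_cluster_table(
    results: Sequence[ClusteringResult],
    path: str | Path,
    sample_ids: Sequence[str],
    min_support: int = 2,
    members_path: str | Path | None = None,
) -> int:
    """Write the cluster table (and the members companion file).

    Columns: chrom, region_id, cluster_id, l, r, mu, sigma, n, one count
    column per sample (in the given order), below_min_support.  ``l``/``r``
    are written 1-based inclusive.  Returns the number of rows written.
    """
    records = records_from_results(results, min_support=min_support)
    path = Path(path)
    if members_path is None:
        members_path = path.with_suffix(".members.tsv")
    with open(path, "w") as fh:
        fh.write("# l and r are 1-based inclusive breakpoint-region bounds; "
                 "mu/sigma are the expected deletion size model (bp)\n")
        header = list(TABLE_FIXED_COLUMNS) + list(sample_ids) + ["below_min_support"]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            row = [
                rec.chrom, rec.region_id, rec.cluster_id,
                str(rec.l + 1), str(rec.r),
                repr(rec.mu), repr(rec.sigma), str(rec.n),
            ]
            row += [str(rec.sample_counts.get(s, 0)) for s in sample_ids]
            row.append("1" if rec.below_min_support else "0")
            fh.write("\t".join(row) + "\n")
    with open(members_path, "w") as fh:
        fh.write("cluster_id\tmapping_ids\n")
        for rec in records:
            fh.write(f"{rec.cluster_id}\t{','.join(rec.members)}\n")
    return len(records)


def read_cluster_table(path: str | Path) -> list[ClusterRecord]:
    """Parse a written cluster table back into records (exact round trip for
    l, r, mu, sigma, n and per-sample counts)."""
    records: list[ClusterRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                n_fixed = len(TABLE_FIXED_COLUMNS)
                sample_ids = header[n_fixed:-1]
                continue
            base = dict(zip(header, fields))
            counts = {s: int(base[s]) for s in sample_ids}
            records.append(
                ClusterRecord(
                    chrom=base["chrom"],
                    region_id=base["region_id"],
                    cluster_id=base["cluster_id"],
                    l=int(base["l"]) - 1,
                    r=int(base["r"]),
                    mu=float(base["mu"]),
                    sigma=float(base["sigma"]),
                    n=int(base["n"]),
                    sample_counts=counts,
                    members=(),
                    below_min_support=base["below_min_support"] == "1",
                )
            )
    if header is None:
        raise ValueError(f"{path}: missing header")
    return records


def _triangle_polygon(l: float, r: float):
    from shapely.geometry import Polygon

    return Polygon([(l, l), (l, r), (r, r)])


def _size_band(l: float, r: float, s_lo: float, s_hi: float):
    """Intersection of the triangle over [l, r] with the diagonal strip
    s_lo <= y - x <= s_hi."""
    from shapely.geometry import Polygon

    pad = (r - l) + (s_hi - s_lo) + 10.0
    strip = Polygon([
        (l - pad, l - pad + s_lo),
        (r + pad, r + pad + s_lo),
        (r + pad, r + pad + s_hi),
        (l - pad, l - pad + s_hi),
    ])
    return _triangle_polygon(l, r).intersection(strip)


def _draw_polygon(ax, poly, **kwargs):
    from matplotlib.patches import Polygon as MplPolygon

    geoms = getattr(poly, "geoms", [poly])
    for geom in geoms:
        if geom.is_empty or geom.area == 0:
            continue
        ax.add_patch(MplPolygon(list(geom.exterior.coords), **kwargs))


def render_region(
    region: Region,
    result: ClusteringResult,
    cfgs: Sequence[SampleConfig],
    min_support: int,
    path: str | Path,
) -> Path:
    """Render one region to an image file (format chosen by extension)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = {cfg.sample_id: cfg.color for cfg in cfgs}
    models = {cfg.sample_id: cfg.model for cfg in cfgs}
    supported = [c for c in result.clusters if c.n >= min_support]
    small_members = set()
    for c in result.clusters:
        if c.n < min_support:
            small_members |= c.members

    fig, ax = plt.subplots(figsize=(7, 7))
    for m in region.mappings:
        model = models[m.sample_id]
        l, r = m.left_inner, m.right_inner
        mu, sigma = m.span_d - model.mean, model.sd
        _shade_triangle(ax, l, r, mu, sigma)
        dotted = m.id in small_members
        tri = _triangle_polygon(l, r)
        _draw_polygon(
            ax, tri, fill=False,
            edgecolor=colors.get(m.sample_id, "black"),
            linestyle=":" if dotted else "-", linewidth=0.8,
        )
    for c in supported:
        band = _size_band(c.l, c.r, max(c.mu - 3 * c.sigma, 0.0),
                          c.mu + 3 * c.sigma)
        _draw_polygon(ax, band, facecolor="yellow", alpha=0.6,
                      edgecolor="goldenrod", linewidth=1.0)
        cx = (c.l + c.r) / 2
        cy = min(cx + c.mu, c.r)
        ax.annotate(str(c.n), (cx, cy), ha="center", va="bottom",
                    fontsize=10, fontweight="bold")
    lo, hi = region.start, region.end
    ax.plot([lo, hi], [lo, hi], color="lightgray", linewidth=0.5, zorder=0)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel(f"deletion start ({region.chrom})")
    ax.set_ylabel(f"deletion end ({region.chrom})")
    ax.set_title(f"region {result.region_id}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def _shade_triangle(ax, l: int, r: int, mu: float, sigma: float) -> None:
    """Gray bands parallel to the diagonal, <=16 levels at equal pdf
    quantiles, darkness proportional to the normal height."""
    qs = np.linspace(0.0, 1.0, _SHADE_BINS + 1)[1:-1]
    edges = np.concatenate(([0.0], norm.ppf(qs, loc=mu, scale=sigma), [r - l]))
    edges = np.clip(edges, 0.0, r - l)
    peak = norm.pdf(mu, loc=mu, scale=sigma)
    for s_lo, s_hi in zip(edges[:-1], edges[1:]):
        if s_hi <= s_lo:
            continue
        height = norm.pdf((s_lo + s_hi) / 2, loc=mu, scale=sigma)
        shade = 1.0 - 0.75 * (height / peak)  # 1 = white, darker = taller
        band = _size_band(l, r, s_lo, s_hi)
        _draw_polygon(ax, band, facecolor=str(shade), edgecolor="none",
                      zorder=0.5)
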