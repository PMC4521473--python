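"""Morphology features and the aggregated per-well feature vector.

Implements the six canonical morphology statistics of the profiling method:

* ``invasion inhibition`` — per-organoid roundness, 4·area / (π·d²) where d
  is the maximum distance between any two pixels of the mask; highest for a
  sphere, lower for irregular/invasive shapes;
* ``per-organoid size`` — the pixel count of one organoid's mask in one
  section;
* ``total proliferation`` — the accumulated mask area over the whole stack;
* ``cell polarity`` — mean (and spread) of the shortest distance between a
  nucleus mass center and the organoid boundary line; hollow, polarised
  structures score low with low spread;
* ``organoid branching`` — the organoid mask is skeletonised and translated
  into a graph of edges and vertices; a branch is an edge with exactly one
  single-connected (degree-1) vertex; the value is the mean branch length;
* ``organoid count`` — the per-well sum over sections of the per-section
  organoid mask count, Σᵢ nᵢ.

Around these, a documented battery of 70 morphological descriptors per
channel plus 7 two-channel correlative descriptors is computed per object
per section and aggregated per well by mean and standard deviation, giving
the 294-entry well feature vector.  The auxiliary (non-canonical)
descriptors are intensity, texture and spatial-context statistics; shape
information enters through the canonical features so that the battery does
not duplicate their signal in redundant boundary/convexity encodings.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.morphology import skeletonize

from .segmentation import NucleusObject, OrganoidObject, SectionMask

__all__ = [
    "invasion_inhibition",
    "per_organoid_size",
    "total_proliferation",
    "cell_polarity",
    "organoid_branching",
    "organoid_count",
    "max_pairwise_distance",
    "boundary_pixels",
    "skeleton_branch_lengths",
    "extract_feature_battery",
    "featurize_plate",
    "zscore_normalize",
    "feature_names",
    "feature_definitions",
    "CANONICAL_FEATURES",
    "N_FEATURES",
]

log = logging.getLogger(__name__)

N_FEATURES = 294


# ---------------------------------------------------------------------------
# canonical morphology statistics


def max_pairwise_distance(pixels: np.ndarray) -> float:
    """Maximum Euclidean distance between any two pixel centers.

    The maximum is attained at vertices of the convex hull; degenerate
    (collinear / tiny) point sets fall back to exhaustive search.
    """
    pts = np.asarray(pixels, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear: brute-force over all points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(math.sqrt(d2.max()))


def per_organoid_size(mask: SectionMask) -> int:
    """Geometric area of one organoid mask in one section, in pixels."""
    return mask.area


def invasion_inhibition(mask: SectionMask) -> float:
    """Per-organoid roundness: 4 · area / (π · major_axis²).

    ``major_axis`` is the maximum distance between any two pixels of the
    mask.  A continuous disk scores 1; elongated or protrusive shapes score
    lower.  Single-pixel masks are rejected (the statistic is undefined at
    zero diameter).
    """
    if mask.area < 2:
        raise ValueError("invasion inhibition is undefined for single-pixel masks")
    d = max_pairwise_distance(mask.pixels)
    return 4.0 * mask.area / (math.pi * d * d)


def total_proliferation(masks: Iterable[SectionMask]) -> int:
    """Accumulated mask area over the whole stack: Σᵢ Σⱼ Areaᵢⱼ."""
    return int(sum(m.area for m in masks))


def organoid_count(
    masks_per_section: dict[int, list[SectionMask]] | list[OrganoidObject],
    variant: str = "per_section_sum",
) -> int:
    """Per-well organoid count.

    The default ``per_section_sum`` variant implements the formula
    Σᵢ₌₁..ₛ nᵢ (sum of per-section mask counts).  The ``distinct_objects``
    variant instead counts linked 3-D objects.
    """
    if variant not in ("per_section_sum", "distinct_objects"):
        raise ValueError(f"unknown organoid_count variant {variant!r}")
    if isinstance(masks_per_section, dict):
        if variant == "distinct_objects":
            raise ValueError("distinct_objects requires linked OrganoidObjects")
        return sum(len(v) for v in masks_per_section.values())
    objects = masks_per_section
    if variant == "distinct_objects":
        return len(objects)
    return sum(len(o.sections) for o in objects)


def boundary_pixels(mask: SectionMask) -> np.ndarray:
    """Pixels of the mask 8-adjacent to a non-mask pixel (the boundary line)."""
    xs, ys = mask.pixels[:, 0], mask.pixels[:, 1]
    x0, y0 = int(xs.min()), int(ys.min())
    local = np.zeros((int(ys.max()) - y0 + 3, int(xs.max()) - x0 + 3), dtype=bool)
    local[ys - y0 + 1, xs - x0 + 1] = True
    eroded = ndimage.binary_erosion(local, structure=np.ones((3, 3)), border_value=0)
    by, bx = np.nonzero(local & ~eroded)
    return np.column_stack([bx + x0 - 1, by + y0 - 1]).astype(np.int64)


def cell_polarity(organoid: OrganoidObject, section: int) -> tuple[float, float]:
    """Mean and spread of nucleus-to-boundary shortest distances.

    For each child nucleus with a mass center in the given section, the
    minimum Euclidean distance from its mass center to any boundary pixel of
    the organoid's mask in that section; returns the mean and the population
    standard deviation over nuclei.  Undefined (raises) when the organoid
    has no nuclei in the section.
    """
    mask = organoid.mask_in_section(section)
    if mask is None:
        raise ValueError(f"organoid {organoid.object_id} has no mask in section {section}")
    centers = [n.mass_center for n in organoid.children if n.section_index == section]
    if not centers:
        raise ValueError("cell polarity is undefined without nuclei in the section")
    pb = boundary_pixels(mask)
    tree = cKDTree(pb)
    dists, _ = tree.query(np.asarray(centers, dtype=float))
    dists = np.atleast_1d(dists)
    return float(dists.mean()), float(dists.std(ddof=0))


def skeleton_branch_lengths(mask: SectionMask) -> list[int]:
    """Branch lengths of the skeleton graph of a mask.

    The mask is skeletonised; skeleton pixels form a graph under
    8-adjacency.  Topological vertices are pixels of degree ≠ 2; edges are
    the pixel paths between them.  A branch is an edge incident to exactly
    one degree-1 vertex, and its length is the number of path pixels
    excluding the non-tip terminal.
    """
    # skeletonise on a tight local canvas; branch lengths are shift-invariant
    xs, ys = mask.pixels[:, 0], mask.pixels[:, 1]
    x0, y0 = int(xs.min()) - 1, int(ys.min()) - 1
    img = np.zeros((int(ys.max()) - y0 + 2, int(xs.max()) - x0 + 2), dtype=bool)
    img[ys - y0, xs - x0] = True
    skel = skeletonize(img)
    ys, xs = np.nonzero(skel)
    nodes = list(zip(xs.tolist(), ys.tolist()))
    if len(nodes) < 2:
        return []
    nodeset = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for x, y in nodes:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if (dx or dy) and (x + dx, y + dy) in nodeset:
                    g.add_edge((x, y), (x + dx, y + dy))
    special = [n for n in g.nodes if g.degree[n] != 2]
    if not special:
        return []  # pure cycle
    lengths: list[int] = []
    visited_edges: set[frozenset] = set()
    for start in special:
        for nb in list(g.neighbors(start)):
            edge = frozenset((start, nb))
            if edge in visited_edges:
                continue
            path = [start, nb]
            visited_edges.add(edge)
            prev, cur = start, nb
            while g.degree[cur] == 2:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                visited_edges.add(frozenset((cur, nxt)))
                prev, cur = cur, nxt
                path.append(cur)
            end = path[-1]
            deg1 = (g.degree[start] == 1) + (g.degree[end] == 1)
            if deg1 == 1:
                lengths.append(len(path) - 1)
    return lengths


def organoid_branching(mask: SectionMask) -> float:
    """Mean skeleton branch length of one organoid mask; 0 with no branches."""
    lengths = skeleton_branch_lengths(mask)
    if not lengths:
        return 0.0
    return float(np.mean(lengths))


# ---------------------------------------------------------------------------
# the per-channel descriptor battery


def _entropy(values: np.ndarray, bins: int = 32) -> float:
    hist, _ = np.histogram(values, bins=bins)
    p = hist / max(hist.sum(), 1)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _gini(values: np.ndarray) -> float:
    v = np.sort(np.asarray(values, dtype=float) - values.min() + 1e-9)
    n = len(v)
    return float((2 * np.arange(1, n + 1) - n - 1).dot(v) / (n * v.sum()))


class _SectionContext:
    """Precomputed per-section image derivatives shared by all objects."""

    def __init__(self, image: np.ndarray):
        img = np.asarray(image, dtype=float)
        self.img = img
        gy, gx = np.gradient(img)
        self.grad = np.hypot(gx, gy)
        self.lap = np.abs(ndimage.laplace(img))
        mean = ndimage.uniform_filter(img, 3)
        self.locvar = np.maximum(ndimage.uniform_filter(img**2, 3) - mean**2, 0.0)
        self.blur1 = np.abs(img - ndimage.gaussian_filter(img, 1.0))
        self.blur2 = np.abs(img - ndimage.gaussian_filter(img, 2.0))
        self.diff_h = np.abs(np.diff(img, axis=1, prepend=img[:, :1]))
        self.diff_v = np.abs(np.diff(img, axis=0, prepend=img[:1, :]))
        self.diff_d = np.abs(img - np.roll(np.roll(img, 1, 0), 1, 1))
        self.gx, self.gy = gx, gy
        self.bg_median = float(np.median(img))
        mad = float(np.median(np.abs(img - self.bg_median)))
        self.bg_mad = 1.4826 * mad


def _object_descriptors(mask: SectionMask, ctx: _SectionContext,
                        n_sections: int) -> dict[str, float]:
    """The 65 auxiliary intensity / texture / context descriptors of one
    object in one section."""
    xs, ys = mask.pixels[:, 0], mask.pixels[:, 1]
    v = ctx.img[ys, xs]
    h, w = ctx.img.shape
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    vmin, vmax = float(v.min()), float(v.max())
    pcts = np.percentile(v, (5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95))
    p05, p10, p20, p25, p30, p40, med, p60, p70, p75, p80, p90, p95 = map(float, pcts)
    mad = float(np.median(np.abs(v - med))) * 1.4826
    iqr = p75 - p25
    eps = 1e-9
    z = (v - mean) / max(sd, eps)

    d: dict[str, float] = {}
    # intensity distribution (20)
    d["int_mean"] = mean
    d["int_sd"] = sd
    d["int_cv"] = sd / max(abs(mean), eps)
    d["int_min"] = vmin
    d["int_max"] = vmax
    d["int_range"] = vmax - vmin
    d["int_median"] = med
    d["int_mad"] = mad
    d["int_p05"] = p05
    d["int_p10"] = p10
    d["int_p25"] = p25
    d["int_p75"] = p75
    d["int_p90"] = p90
    d["int_p95"] = p95
    d["int_iqr"] = iqr
    d["int_skew"] = float((z**3).mean())
    d["int_kurt"] = float((z**4).mean()) - 3.0
    d["int_entropy"] = _entropy(v)
    hist, _ = np.histogram(v, bins=32)
    p_hist = hist / max(hist.sum(), 1)
    d["int_energy"] = float((p_hist**2).sum())
    d["frac_high"] = float((v > mean + 1.5 * sd).mean())
    d["frac_low"] = float((v < mean - 1.5 * sd).mean())

    # texture (13)
    g = ctx.grad[ys, xs]
    gmean = float(g.mean())
    d["grad_mean"] = gmean
    d["grad_median"] = float(np.median(g))
    d["grad_sd"] = float(g.std(ddof=0))
    d["grad_cv"] = d["grad_sd"] / max(gmean, eps)
    d["grad_max"] = float(g.max())
    d["lap_mean"] = float(ctx.lap[ys, xs].mean())
    d["lap_var"] = float(ctx.lap[ys, xs].var())
    d["tenengrad"] = float((g**2).mean())
    lv = ctx.locvar[ys, xs]
    d["locvar_mean"] = float(lv.mean())
    d["locvar_sd"] = float(lv.std(ddof=0))
    bpix = boundary_pixels(mask)
    bvals = ctx.img[bpix[:, 1], bpix[:, 0]]
    interior = mean
    d["edge_int_mean"] = float(bvals.mean())
    d["interior_int_mean"] = interior
    d["edge_interior_ratio"] = d["edge_int_mean"] / max(interior, eps)

    # z context (1); in-plane well position is deliberately not a feature —
    # where an organoid sits in the well is not morphology
    d["pos_z_rel"] = mask.section_index / max(n_sections - 1, 1)

    # additional robust distribution statistics (3)
    d["int_p20"] = p20
    d["int_p80"] = p80
    d["mad_mean_ratio"] = mad / max(abs(mean), eps)

    # scale-free dispersion of log intensity (2)
    d["int_log_sd"] = float(np.log(np.maximum(v, 1.0)).std(ddof=0))
    d["diff_v_rel"] = float(ctx.diff_v[ys, xs].mean()) / max(med, eps)

    # robust distribution statistics (7)
    d["int_p30"] = p30
    d["int_p40"] = p40
    d["int_p60"] = p60
    d["int_p70"] = p70
    d["int_geomean_rel"] = float(np.exp(np.mean(np.log(np.maximum(v, 1.0))))) / max(mean, eps)
    d["robust_cv"] = mad / max(abs(med), eps)
    d["tail_ratio"] = (p95 - med) / max(med - p05, eps)

    # quantile ratios (3)
    d["p90_p10_ratio"] = p90 / max(p10, eps)
    d["p75_p25_ratio"] = p75 / max(p25, eps)
    d["median_mean_ratio"] = med / max(mean, eps)


    # extreme-value intensity (4)
    k = max(1, int(0.05 * len(v)))
    vs = np.sort(v)
    d["top5_mean"] = float(vs[-k:].mean())
    d["bottom5_mean"] = float(vs[:k].mean())
    lo, hi = int(0.1 * len(v)), max(int(0.9 * len(v)), 1)
    d["trimmed_mean_rel"] = float(vs[lo:hi].mean()) / max(mean, eps) if hi > lo else 1.0
    wlo, whi = p05, p95
    d["winsor_sd_rel"] = float(np.clip(v, wlo, whi).std(ddof=0)) / max(sd, eps)

    # first-difference texture (4)
    d["diff_h"] = float(ctx.diff_h[ys, xs].mean())
    d["diff_v"] = float(ctx.diff_v[ys, xs].mean())
    d["diff_d"] = float(ctx.diff_d[ys, xs].mean())
    d["diff_h_rel"] = float(ctx.diff_h[ys, xs].mean()) / max(med, eps)

    # multi-scale blur residuals (3)
    b1 = float(ctx.blur1[ys, xs].mean())
    b2 = float(ctx.blur2[ys, xs].mean())
    d["blur1_resid"] = b1
    d["blur2_resid"] = b2
    d["blur_ratio"] = b1 / max(b2, eps)

    # dispersion shape (4)
    d["gini"] = _gini(v)
    d["quartile_skew"] = (p75 + p25 - 2 * med) / max(iqr, eps)
    d["fano"] = sd * sd / max(abs(mean), eps)
    d["diff_d_rel"] = float(ctx.diff_d[ys, xs].mean()) / max(med, eps)
    return d


_AUX_NAMES: list[str] = list(
    _object_descriptors(
        SectionMask(0, np.array([[2, 2], [2, 3], [3, 2], [3, 3], [4, 3]]), "actin"),
        _SectionContext(np.arange(64.0).reshape(8, 8)),
        8,
    )
)
assert len(_AUX_NAMES) == 65, f"auxiliary battery has {len(_AUX_NAMES)} descriptors"

_PER_OBJECT_CANONICAL = ["per_organoid_size", "invasion_inhibition", "organoid_branching"]
_PER_WELL_CANONICAL = ["total_proliferation", "organoid_count"]
_CORRELATIVE = [
    "cell_polarity",
    "nuclei_per_organoid_section",
    "nuclei_count_dispersion",
    "channel_correlation",
    "nuclei_intensity_in_mask",
    "channel_intensity_ratio",
    "nuclei_per_organoid_ratio",
]

#: the six canonical morphology features as named columns of the well vector
CANONICAL_FEATURES = [
    "actin_invasion_inhibition__mean",
    "actin_organoid_count__mean",
    "actin_total_proliferation__mean",
    "corr_cell_polarity__mean",
    "actin_organoid_branching__mean",
    "actin_per_organoid_size__mean",
]


def _base_names() -> list[str]:
    names = []
    for ch in ("actin", "nuclei"):
        for n in _PER_OBJECT_CANONICAL + _PER_WELL_CANONICAL + _AUX_NAMES:
            names.append(f"{ch}_{n}")
    for n in _CORRELATIVE:
        names.append(f"corr_{n}")
    return names


def feature_names() -> list[str]:
    """The 294 feature names of the well vector, in canonical order."""
    out = []
    for base in _base_names():
        out.append(f"{base}__mean")
        out.append(f"{base}__sd")
    assert len(out) == N_FEATURES
    return out


_PER_WELL_BASES = {f"{ch}_{n}" for ch in ("actin", "nuclei") for n in _PER_WELL_CANONICAL}
_PER_WELL_BASES.add("corr_nuclei_per_organoid_ratio")
_PER_WELL_BASES.add("corr_nuclei_count_dispersion")


def feature_definitions() -> dict[str, str]:
    """Human-readable definition of every base feature (JSON sidecar)."""
    defs = {
        "per_organoid_size": "pixel count of one organoid mask in one section",
        "invasion_inhibition": "4*area/(pi*d^2), d = max pairwise pixel distance; roundness",
        "organoid_branching": "mean length of skeleton-graph edges with exactly one degree-1 vertex",
        "total_proliferation": "per-well accumulated mask area over the whole stack",
        "organoid_count": "per-well sum over sections of per-section mask counts",
        "cell_polarity": "mean shortest distance from child-nucleus mass centers to the organoid boundary",
        "nuclei_per_organoid_section": "number of child nuclei in the organoid's section",
        "nuclei_count_dispersion": "per-well CV of per-section nuclei-object counts over organoid-bearing sections",
        "channel_correlation": "Pearson correlation of actin and nuclei intensities within the organoid mask",
        "nuclei_intensity_in_mask": "log mean nuclei-channel intensity inside the organoid mask",
        "channel_intensity_ratio": "mean actin / mean nuclei-channel intensity within the organoid mask",
        "nuclei_per_organoid_ratio": "per-well nuclei-object count / organoid object count",
        "int_mean": "mean intensity within the mask",
        "int_sd": "intensity standard deviation within the mask",
        "int_cv": "intensity coefficient of variation",
        "int_min": "minimum intensity", "int_max": "maximum intensity",
        "int_range": "intensity range", "int_median": "median intensity",
        "int_mad": "scaled median absolute deviation of intensity",
        "int_p05": "5th intensity percentile", "int_p10": "10th intensity percentile",
        "int_p25": "25th intensity percentile", "int_p75": "75th intensity percentile",
        "int_p90": "90th intensity percentile", "int_p95": "95th intensity percentile",
        "int_iqr": "intensity interquartile range",
        "int_p30": "30th intensity percentile", "int_p40": "40th intensity percentile",
        "int_p60": "60th intensity percentile", "int_p70": "70th intensity percentile",
        "int_geomean_rel": "geometric mean / arithmetic mean intensity",
        "robust_cv": "scaled MAD / median intensity",
        "tail_ratio": "(p95 - median) / (median - p05) intensity tail asymmetry",
        "diff_h_rel": "mean absolute horizontal first difference / median intensity",
        "int_skew": "intensity skewness", "int_kurt": "intensity excess kurtosis",
        "int_entropy": "Shannon entropy of the intensity histogram",
        "int_energy": "histogram energy (sum of squared bin probabilities)",
        "grad_median": "median gradient magnitude",
        "frac_high": "fraction of pixels brighter than mean + 1.5 sd",
        "frac_low": "fraction of pixels dimmer than mean - 1.5 sd",
        "grad_mean": "mean gradient magnitude", "grad_sd": "gradient magnitude sd",
        "grad_cv": "gradient magnitude cv", "grad_max": "max gradient magnitude",
        "lap_mean": "mean absolute Laplacian", "lap_var": "variance of absolute Laplacian",
        "tenengrad": "mean squared gradient magnitude",
        "locvar_mean": "mean 3x3 local intensity variance",
        "locvar_sd": "sd of 3x3 local intensity variance",
        "edge_int_mean": "mean intensity on boundary pixels",
        "interior_int_mean": "mean intensity within the mask",
        "edge_interior_ratio": "boundary / interior mean intensity",
        "pos_z_rel": "section index / stack depth",
        "int_p20": "20th intensity percentile",
        "int_p80": "80th intensity percentile",
        "mad_mean_ratio": "scaled MAD / mean intensity",
        "intcentroid_offset": "offset of intensity-weighted centroid, in equivalent radii",
        "radial_slope": "correlation of intensity with radial distance from centroid",
        "bg_median": "section background median intensity",
        "bg_mad": "section background scaled MAD",
        "int_log_sd": "standard deviation of log intensity",
        "p90_p10_ratio": "90th / 10th intensity percentile",
        "p75_p25_ratio": "75th / 25th intensity percentile",
        "median_mean_ratio": "median / mean intensity",
        "euler_number": "1 - number of holes", "n_holes": "number of holes",
        "hole_area_frac": "hole area / mask area",
        "top5_mean": "mean of the brightest 5% of pixels",
        "bottom5_mean": "mean of the dimmest 5% of pixels",
        "bright_dist_rel": "distance of the brightest pixel from the centroid, in equivalent radii",
        "trimmed_mean_rel": "10% trimmed mean / mean",
        "winsor_sd_rel": "5-95% winsorised sd / sd",
        "grad_dir_entropy": "entropy of the gradient direction histogram",
        "diff_h": "mean absolute horizontal first difference",
        "diff_v": "mean absolute vertical first difference",
        "diff_d": "mean absolute diagonal first difference",
        "blur1_resid": "mean residual against 1 px Gaussian blur",
        "blur2_resid": "mean residual against 2 px Gaussian blur",
        "blur_ratio": "ratio of 1 px to 2 px blur residuals",
        "gini": "Gini coefficient of intensity",
        "quartile_skew": "Bowley quartile skewness",
        "fano": "intensity variance / mean",
        "diff_v_rel": "mean absolute vertical first difference / median intensity",
        "diff_d_rel": "mean absolute diagonal first difference / median intensity",
    }
    return defs


# ---------------------------------------------------------------------------
# extraction


def _nan_mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) == 0:
        return math.nan, math.nan
    if len(arr) == 1:
        return float(arr[0]), 0.0  # sd of a single observation is 0 by convention
    return float(arr.mean()), float(arr.std(ddof=1))


def _channel_rows(objects: list[OrganoidObject], stack: np.ndarray,
                  contexts: list[_SectionContext]) -> dict[str, list[float]]:
    n_sections = stack.shape[0]
    rows: dict[str, list[float]] = {n: [] for n in _PER_OBJECT_CANONICAL + _AUX_NAMES}
    for obj in objects:
        for m in obj.sections:
            rows["per_organoid_size"].append(per_organoid_size(m))
            try:
                rows["invasion_inhibition"].append(invasion_inhibition(m))
            except ValueError:
                rows["invasion_inhibition"].append(math.nan)
            rows["organoid_branching"].append(organoid_branching(m))
            for name, val in _object_descriptors(
                    m, contexts[m.section_index], n_sections).items():
                rows[name].append(val)
    return rows


def _correlative_rows(organoids: list[OrganoidObject],
                      actin_stack: np.ndarray, nuclei_stack: np.ndarray
                      ) -> dict[str, list[float]]:
    rows: dict[str, list[float]] = {
        n: [] for n in _CORRELATIVE
        if n not in ("nuclei_per_organoid_ratio", "nuclei_actin_overlap")
    }
    eps = 1e-9
    for org in organoids:
        for m in org.sections:
            i = m.section_index
            xs, ys = m.pixels[:, 0], m.pixels[:, 1]
            av = actin_stack[i][ys, xs].astype(float)
            nv = nuclei_stack[i][ys, xs].astype(float)
            children = [n for n in org.children if n.section_index == i]
            try:
                cp, _ = cell_polarity(org, i)
            except ValueError:
                cp = math.nan
            rows["cell_polarity"].append(cp)
            rows["nuclei_per_organoid_section"].append(float(len(children)))
            if av.std() > 0 and nv.std() > 0:
                rows["channel_correlation"].append(float(np.corrcoef(av, nv)[0, 1]))
            else:
                rows["channel_correlation"].append(0.0)
            rows["nuclei_intensity_in_mask"].append(float(np.log(max(nv.mean(), 1.0))))
            rows["channel_intensity_ratio"].append(float(av.mean()) / max(nv.mean(), eps))
    return rows


def extract_feature_battery(
    organoids: list[OrganoidObject],
    nuclei_objects: list[OrganoidObject],
    actin_stack: np.ndarray,
    nuclei_stack: np.ndarray,
    count_variant: str = "per_section_sum",
) -> pd.Series:
    """Compute the raw 294-entry well feature vector.

    Object measurements are aggregated per well by mean and standard
    deviation; per-well measurements enter with their SD aggregate fixed at
    0.  Wells with zero organoids yield NaN for aggregation-undefined
    entries.
    """
    actx = [_SectionContext(actin_stack[i]) for i in range(actin_stack.shape[0])]
    nctx = [_SectionContext(nuclei_stack[i]) for i in range(nuclei_stack.shape[0])]

    values: dict[str, float] = {}

    for ch, objects, stack, ctxs in (
        ("actin", organoids, actin_stack, actx),
        ("nuclei", nuclei_objects, nuclei_stack, nctx),
    ):
        rows = _channel_rows(objects, stack, ctxs)
        for name, vals in rows.items():
            mean, sd = _nan_mean_sd(vals)
            values[f"{ch}_{name}__mean"] = mean
            values[f"{ch}_{name}__sd"] = sd
        all_masks = [m for o in objects for m in o.sections]
        per_section: dict[int, list[SectionMask]] = {}
        for m in all_masks:
            per_section.setdefault(m.section_index, []).append(m)
        values[f"{ch}_total_proliferation__mean"] = float(total_proliferation(all_masks))
        values[f"{ch}_total_proliferation__sd"] = 0.0
        values[f"{ch}_organoid_count__mean"] = float(
            organoid_count(objects, count_variant))
        values[f"{ch}_organoid_count__sd"] = 0.0

    crows = _correlative_rows(organoids, actin_stack, nuclei_stack)
    for name, vals in crows.items():
        mean, sd = _nan_mean_sd(vals)
        values[f"corr_{name}__mean"] = mean
        values[f"corr_{name}__sd"] = sd
    n_org = max(len(organoids), 1)
    values["corr_nuclei_per_organoid_ratio__mean"] = len(nuclei_objects) / n_org
    values["corr_nuclei_per_organoid_ratio__sd"] = 0.0
    # per-well dispersion of nuclei load across sections (CV of per-section
    # nuclei-object counts over the sections that contain organoids)
    sections_used = sorted({m.section_index for o in organoids for m in o.sections})
    per_sec = [sum(1 for o in nuclei_objects for m in o.sections
                   if m.section_index == i) for i in sections_used]
    if per_sec and np.mean(per_sec) > 0:
        values["corr_nuclei_count_dispersion__mean"] = float(
            np.std(per_sec) / np.mean(per_sec))
    else:
        values["corr_nuclei_count_dispersion__mean"] = math.nan
    values["corr_nuclei_count_dispersion__sd"] = 0.0

    vec = pd.Series(values).reindex(feature_names())
    assert len(vec) == N_FEATURES
    return vec


def featurize_plate(well_results: dict[str, tuple[list, list, np.ndarray, np.ndarray]],
                    count_variant: str = "per_section_sum") -> pd.DataFrame:
    """Stack per-well feature vectors into a wells × 294 table."""
    table = {
        well: extract_feature_battery(org, nuc, a, n, count_variant)
        for well, (org, nuc, a, n) in well_results.items()
    }
    df = pd.DataFrame(table).T
    df.index.name = "well"
    return df


# ---------------------------------------------------------------------------
# normalisation


def zscore_normalize(
    table: pd.DataFrame, plate_map: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score normalise every feature against the buffer-control wells.

    Per feature f: z = (x − mean_buffer(f)) / sd_buffer(f) (sample SD,
    n−1), applied to all wells.  Features whose buffer SD is 0 (or undefined)
    are excluded from the returned table and reported, with a log record,
    rather than propagating NaN.
    """
    buffer_wells = plate_map.loc[plate_map["role"] == "buffer", "well"]
    buffer_wells = [w for w in buffer_wells if w in table.index]
    if len(buffer_wells) < 2:
        raise ValueError("z-score normalisation needs at least 2 buffer wells")
    buf = table.loc[buffer_wells]
    mean = buf.mean(axis=0)
    sd = buf.std(axis=0, ddof=1)
    bad = sd.isna() | (sd == 0) | mean.isna()
    excluded = sorted(table.columns[bad])
    if excluded:
        log.info("excluding %d features with zero/undefined buffer SD: %s",
                 len(excluded), ", ".join(excluded[:8]) + ("..." if len(excluded) > 8 else ""))
    kept = table.columns[~bad]
    normalized = (table[kept] - mean[kept]) / sd[kept]
    return normalized, excluded
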