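"""The Ts-Fr triangle: edge fitting and the per-pixel Priestley-Taylor coefficient.

A scene's scatter of land-surface temperature against fractional
vegetation cover forms a triangle: its upper, decreasing boundary (the
"dry edge") marks pixels under maximal water stress, its lower, nearly
horizontal boundary (the "wet edge") marks unstressed, well-watered
pixels.  The Priestley-Taylor coefficient phi is assigned per pixel by
two-step linear interpolation between those edges:

    phi_i = (Tmax_i - Ts_i) / (Tmax_i - Tmin) * (phi_max - phi_min_i) + phi_min_i

with phi_max = 1.26, phi_min_i = 1.26 * Fr_i, Tmax_i the dry-edge
temperature at the pixel's Fr, and Tmin the (constant) wet-edge
temperature.  phi is clipped to [0, 1.26]; 1.26 is attained exactly on
the wet edge and 0 at the dry bare-soil corner.

Edge fitting is observational: per-Fr-bin extreme temperature percentiles
give dry/wet candidates, the dry edge is a trimmed least-squares line
through the dry candidates, and the wet edge is the median of the wet
candidates over the well-vegetated half of the triangle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .errors import DomainError, EdgeFitError

__all__ = [
    "EdgeFitConfig",
    "EdgeModel",
    "PhiField",
    "ndvi",
    "ndvi_bounds",
    "vegetation_fraction",
    "fit_edges",
    "phi_map",
]

#: Minimum separation (K) enforced between dry and wet edges in phi_map.
EDGE_SEPARATION_K = 0.5


@dataclass(frozen=True)
class EdgeFitConfig:
    """Tunables of the observational edge fit.

    Defaults follow common Ts-VI triangle practice: 5%-wide Fr bins,
    extreme 0.5% temperature percentiles per bin, and iterative trimming
    of low outliers from the dry-edge regression.
    """

    bin_width: float = 0.05
    min_bin_count: int = 20
    dry_percentile: float = 99.5
    wet_percentile: float = 0.5
    min_valid_pixels: int = 1000
    min_fr_span: float = 0.3
    trim_sd: float = 2.0
    max_trim_iter: int = 5
    wet_fr_threshold: float = 0.5


@dataclass
class EdgeModel:
    """Fitted dry edge (line) and wet edge (horizontal) of the triangle."""

    dry_intercept: float  # K, dry-edge temperature at Fr = 0
    dry_slope: float  # K per unit Fr, <= 0 after fallback handling
    t_min: float  # K, wet-edge temperature
    bin_width: float = 0.05
    bin_diagnostics: dict = field(default_factory=dict)

    def dry_edge_temperature(self, fr: np.ndarray | float) -> np.ndarray | float:
        return self.dry_intercept + self.dry_slope * fr

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "EdgeModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PhiField:
    """Per-pixel Priestley-Taylor coefficient and vegetation fraction."""

    phi: np.ndarray
    fr: np.ndarray


def ndvi(rho4: np.ndarray, rho5: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index (NIR - red) / (NIR + red).

    Pixels with a zero denominator become NaN.
    """
    red = np.asarray(rho4, dtype=float)
    nir = np.asarray(rho5, dtype=float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, np.nan)
    return out


def ndvi_bounds(
    ndvi_arr: np.ndarray, lo_pct: float = 2.0, hi_pct: float = 98.0
) -> tuple[float, float]:
    """Robust per-scene NDVI scaling bounds (percentiles of valid pixels)."""
    vals = ndvi_arr[np.isfinite(ndvi_arr)]
    if vals.size == 0:
        raise DomainError("no valid NDVI pixels to derive bounds from")
    lo, hi = np.percentile(vals, [lo_pct, hi_pct])
    if not hi > lo:
        raise DomainError(f"degenerate NDVI bounds ({lo}, {hi})")
    return float(lo), float(hi)


def vegetation_fraction(
    ndvi_arr: np.ndarray, ndvi_min: float, ndvi_max: float
) -> np.ndarray:
    """Fraction of vegetation Fr = ((NDVI - NDVI_min)/(NDVI_max - NDVI_min))^2.

    The rescaled NDVI is clipped to [0, 1] before squaring, so Fr is in
    [0, 1] even for pixels outside the scaling bounds.
    """
    if not ndvi_max > ndvi_min:
        raise DomainError(
            f"ndvi_max ({ndvi_max}) must exceed ndvi_min ({ndvi_min})"
        )
    scaled = (np.asarray(ndvi_arr, dtype=float) - ndvi_min) / (ndvi_max - ndvi_min)
    return np.clip(scaled, 0.0, 1.0) ** 2


def fit_edges(
    ts_K: np.ndarray,
    fr: np.ndarray,
    config: EdgeFitConfig = EdgeFitConfig(),
) -> EdgeModel:
    """Fit the dry and wet edges of the Ts-Fr triangle.

    Procedure: partition Fr in [0, 1] into bins of ``config.bin_width``;
    in each bin holding at least ``config.min_bin_count`` pixels, record
    the ``dry_percentile`` temperature as a dry-edge candidate and the
    ``wet_percentile`` temperature as a wet candidate.  The dry edge is
    the least-squares line through the dry candidates with iterative
    trimming (candidates more than ``trim_sd`` residual standard
    deviations *below* the current fit are dropped and the line refit, at
    most ``max_trim_iter`` times — low outliers are contaminated bins, a
    candidate above the fit is real dry-edge signal).  The wet-edge
    temperature is the median wet candidate over bins whose center lies at
    Fr >= ``wet_fr_threshold``, where the wet edge is actually populated.

    If the fitted dry slope comes out positive the scene has no usable
    decreasing dry edge; the fit falls back to a horizontal dry edge at
    the global ``dry_percentile`` temperature and flags the scene in the
    diagnostics.

    The fit is fully deterministic for a fixed pixel set.
    """
    ts = np.asarray(ts_K, dtype=float).ravel()
    f = np.asarray(fr, dtype=float).ravel()
    valid = np.isfinite(ts) & np.isfinite(f)
    ts, f = ts[valid], f[valid]

    if ts.size < config.min_valid_pixels:
        raise EdgeFitError(
            f"only {ts.size} valid pixels (< {config.min_valid_pixels}); "
            "use a larger area of interest"
        )
    span = float(f.max() - f.min())
    if span < config.min_fr_span:
        raise EdgeFitError(
            f"Fr span {span:.3f} < {config.min_fr_span}; the scene does not "
            "populate a triangle — use a larger or more heterogeneous AOI"
        )

    n_bins = int(round(1.0 / config.bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)

    centers, dry_cand, wet_cand, counts = [], [], [], []
    for b in range(n_bins):
        in_bin = idx == b
        n = int(in_bin.sum())
        if n < config.min_bin_count:
            continue
        tvals = ts[in_bin]
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        dry_cand.append(float(np.percentile(tvals, config.dry_percentile)))
        wet_cand.append(float(np.percentile(tvals, config.wet_percentile)))
        counts.append(n)

    if len(centers) < 3:
        raise EdgeFitError(
            f"only {len(centers)} populated Fr bins; cannot fit edges — "
            "use a larger area of interest"
        )

    c = np.array(centers)
    d = np.array(dry_cand)

    keep = np.ones(len(c), dtype=bool)
    slope = intercept = 0.0
    for _ in range(config.max_trim_iter + 1):
        slope, intercept = np.polyfit(c[keep], d[keep], 1)
        resid = d - (intercept + slope * c)
        sd = float(resid[keep].std())
        if sd == 0:
            break
        new_keep = keep & ~(resid < -config.trim_sd * sd)
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep

    fallback = False
    if slope > 0:
        # no decreasing dry edge in this scene: horizontal fallback
        fallback = True
        intercept = float(np.percentile(ts, config.dry_percentile))
        slope = 0.0

    wet_sel = c >= config.wet_fr_threshold
    if wet_sel.any():
        t_min = float(np.median(np.array(wet_cand)[wet_sel]))
    else:
        t_min = float(np.median(wet_cand))

    diagnostics = {
        "bin_centers": list(map(float, c)),
        "bin_counts": counts,
        "dry_candidates": list(map(float, dry_cand)),
        "wet_candidates": list(map(float, wet_cand)),
        "dry_candidates_kept": list(map(bool, keep)),
        "horizontal_fallback": fallback,
        "n_valid_pixels": int(ts.size),
    }
    return EdgeModel(
        dry_intercept=float(intercept),
        dry_slope=float(slope),
        t_min=t_min,
        bin_width=config.bin_width,
        bin_diagnostics=diagnostics,
    )


def phi_map(
    ts_K: np.ndarray,
    fr: np.ndarray,
    edges: EdgeModel,
    constants: PhysicalConstants = CONSTANTS,
) -> PhiField:
    """Per-pixel Priestley-Taylor coefficient by two-step interpolation.

    The dry-edge temperature is clamped to at least ``t_min + 0.5 K`` so
    the interpolation stays bounded where the fitted edges nearly touch
    at high vegetation cover; phi is clipped to [0, phi_max] for pixels
    falling outside the fitted triangle.
    """
    ts = np.asarray(ts_K, dtype=float)
    f = np.asarray(fr, dtype=float)
    phi_max = constants.phi_max

    t_max = np.maximum(
        edges.dry_intercept + edges.dry_slope * f, edges.t_min + EDGE_SEPARATION_K
    )
    phi_min = phi_max * f
    phi = (t_max - ts) / (t_max - edges.t_min) * (phi_max - phi_min) + phi_min
    phi = np.clip(phi, 0.0, phi_max)
    # propagate nodata (clip would otherwise keep NaN, which is fine; be explicit)
    phi = np.where(np.isfinite(ts) & np.isfinite(f), phi, np.nan)
    return PhiField(phi=phi, fr=f)
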