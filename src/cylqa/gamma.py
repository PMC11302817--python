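"""Gamma-index analysis on cylindrical-surface dose maps.

The per-point gamma is the minimum, over candidate positions on the reference
surface, of

    sqrt( dist^2 / dta^2  +  (D_eval - D_ref)^2 / (dose_tol * D_ref_max)^2 )

with distance measured on the cylinder surface (circumferential arc length
with wraparound, Euclidean axially).  Dose differences use the global scale
(reference-map maximum); a local mode is available via ``local=True``.  The
reference map is interpolated bilinearly on a sub-diode lattice because the
diode pitch exceeds typical distance tolerances.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .simulate import DetectorGeometry, DetectorMap

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "CLINICAL_CRITERIA",
    "gamma_point",
    "gamma_analysis",
    "gpr_classify",
]


@dataclasses.dataclass(frozen=True)
class GammaCriteria:
    """One clinical criterion: dose tolerance, DTA tolerance, thresholds."""

    dose_tol: float                  # fraction, e.g. 0.03
    dta_tol: float                   # mm
    low_dose_threshold: float = 0.10  # fraction of reference max
    pass_rate_threshold: float = 95.0  # percent

    def __post_init__(self) -> None:
        for name in ("dose_tol", "dta_tol", "low_dose_threshold",
                     "pass_rate_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.low_dose_threshold >= 1:
            raise ValueError("low_dose_threshold must be < 1")

    @property
    def label(self) -> str:
        return f"{self.dose_tol * 100:g}%/{self.dta_tol:g} mm"


#: The three clinical criteria with their plan-approval pass-rate bounds.
CLINICAL_CRITERIA: tuple[GammaCriteria, ...] = (
    GammaCriteria(0.03, 3.0, 0.10, 95.0),
    GammaCriteria(0.03, 2.0, 0.10, 90.0),
    GammaCriteria(0.02, 2.0, 0.10, 85.0),
)


@dataclasses.dataclass(frozen=True)
class GammaResult:
    """Per-point gamma map (NaN where excluded) plus the pass rate."""

    gamma_map: np.ndarray
    gpr: float
    n_analyzed: int
    passed: bool
    criteria: GammaCriteria

    def __post_init__(self) -> None:
        if not (0.0 <= self.gpr <= 100.0):
            raise ValueError(f"gpr out of range: {self.gpr}")


def _bilinear_wrap(ref: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                   valid: np.ndarray) -> np.ndarray:
    """Bilinear interpolation; columns wrap, rows outside the map are masked."""
    n_ax, n_ci = ref.shape
    r = np.clip(rows, 0.0, n_ax - 1.0)
    r0 = np.minimum(np.floor(r).astype(np.intp), n_ax - 2)
    fr = r - r0
    cmod = np.mod(cols, n_ci)
    c0 = np.floor(cmod).astype(np.intp)
    fc = cmod - c0
    c0 = np.mod(c0, n_ci)
    c1 = np.mod(c0 + 1, n_ci)
    top = ref[r0, c0] * (1 - fc) + ref[r0, c1] * fc
    bot = ref[r0 + 1, c0] * (1 - fc) + ref[r0 + 1, c1] * fc
    out = top * (1 - fr) + bot * fr
    return np.where(valid, out, np.nan)


def _offset_lattice(criteria: GammaCriteria, search_step: float | None,
                    search_radius_factor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    step = criteria.dta_tol / 10.0 if search_step is None else float(search_step)
    if step <= 0:
        raise ValueError("search_step must be > 0")
    radius = search_radius_factor * criteria.dta_tol
    n = int(np.floor(radius / step + 1e-9))
    offs = np.arange(-n, n + 1) * step
    ds, dz = np.meshgrid(offs, offs, indexing="ij")
    dist2 = (ds ** 2 + dz ** 2).ravel()
    return ds.ravel(), dz.ravel(), dist2


def _min_gamma(ref: np.ndarray, geometry: DetectorGeometry,
               eval_dose: np.ndarray, eval_rows: np.ndarray,
               eval_cols: np.ndarray, criteria: GammaCriteria,
               search_step: float | None, search_radius_factor: float,
               local: bool, chunk: int = 128) -> np.ndarray:
    """Minimum gamma for eval points at fractional (row, col) surface positions."""
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference map maximum is zero; gamma undefined")
    ds, dz, dist2 = _offset_lattice(criteria, search_step, search_radius_factor)
    d_cols = ds / geometry.circ_pitch
    d_rows = dz / geometry.axial_pitch
    dta2 = criteria.dta_tol ** 2
    denom_glob = (criteria.dose_tol * ref_max) ** 2

    n = eval_dose.size
    out = np.empty(n)
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        rows = eval_rows[a:b, None] + d_rows[None, :]
        cols = eval_cols[a:b, None] + d_cols[None, :]
        valid = (rows >= 0.0) & (rows <= geometry.n_axial - 1.0)
        dref = _bilinear_wrap(ref, rows, cols, valid)
        ddiff2 = (eval_dose[a:b, None] - dref) ** 2
        if local:
            denom = (criteria.dose_tol * np.maximum(dref, 1e-12 * ref_max)) ** 2
        else:
            denom = denom_glob
        cap = dist2[None, :] / dta2 + ddiff2 / denom
        out[a:b] = np.sqrt(np.nanmin(cap, axis=1))
    return out


def gamma_point(ref_map: DetectorMap, eval_dose: float,
                eval_pos: tuple[float, float], criteria: GammaCriteria,
                *, search_step: float | None = None,
                search_radius_factor: float = 3.0,
                local: bool = False) -> float:
    """Gamma of a single evaluated dose at surface position (axial mm, arc mm).

    The axial coordinate is measured from row 0 (increasing toward the last
    row), the arc coordinate from column 0 along increasing column index.
    """
    geom = ref_map.geometry
    z_mm, s_mm = eval_pos
    row = z_mm / geom.axial_pitch
    col = s_mm / geom.circ_pitch
    g = _min_gamma(ref_map.values, geom, np.array([float(eval_dose)]),
                   np.array([row]), np.array([col]), criteria,
                   search_step, search_radius_factor, local)
    return float(g[0])


def gamma_analysis(measured: DetectorMap, calculated: DetectorMap,
                   criteria: GammaCriteria, *,
                   search_step: float | None = None,
                   search_radius_factor: float = 3.0,
                   local: bool = False) -> GammaResult:
    """Full-map gamma with the measured map as reference.

    Diodes whose reference dose falls below ``low_dose_threshold`` times the
    reference maximum are excluded from the analysis; the pass rate is the
    percentage of analyzed diodes with gamma <= 1.
    """
    if measured.geometry != calculated.geometry:
        raise ValueError("measured and calculated maps have mismatched geometries")
    geom = measured.geometry
    ref = measured.values
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference map maximum is zero; gamma undefined")

    analyzed = ref >= criteria.low_dose_threshold * ref_max
    rows, cols = np.nonzero(analyzed)
    gamma_vals = _min_gamma(ref, geom, calculated.values[rows, cols],
                            rows.astype(float), cols.astype(float), criteria,
                            search_step, search_radius_factor, local)
    gamma_map = np.full(geom.shape, np.nan)
    gamma_map[rows, cols] = gamma_vals
    n_analyzed = int(analyzed.sum())
    gpr = 100.0 * float(np.count_nonzero(gamma_vals <= 1.0)) / n_analyzed
    return GammaResult(gamma_map=gamma_map, gpr=gpr, n_analyzed=n_analyzed,
                       passed=gpr > criteria.pass_rate_threshold,
                       criteria=criteria)


def gpr_classify(result: GammaResult) -> bool:
    """Plan approval: pass iff the pass rate strictly exceeds the bound."""
    return result.gpr > result.criteria.pass_rate_threshold
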