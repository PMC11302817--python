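"""Independent reference implementations used only to cross-check results.

These deliberately share no code with the package: gamma is an exhaustive
lattice enumeration built on scipy's RegularGridInterpolator in physical
(mm) coordinates, and AUC is the normalized Mann-Whitney U statistic with
rank-averaged ties.
"""

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import rankdata


def brute_force_gamma_map(measured, calculated, criteria, step=None,
                          radius_factor=3.0):
    """Exhaustive gamma: enumerate every lattice offset for every diode.

    Returns (gamma_map with NaN at excluded diodes, gpr).
    """
    geom = measured.geometry
    ref = measured.values
    ref_max = ref.max()
    if step is None:
        step = criteria.dta_tol / 10.0
    col_pitch = geom.circumference / geom.n_circ
    pad = int(np.ceil(radius_factor * criteria.dta_tol / col_pitch)) + 1
    ext = np.concatenate([ref[:, -pad:], ref, ref[:, :pad]], axis=1)
    rows_mm = np.arange(geom.n_axial) * geom.axial_pitch
    cols_mm = np.arange(-pad, geom.n_circ + pad) * col_pitch
    interp = RegularGridInterpolator((rows_mm, cols_mm), ext)

    n = int(np.floor(radius_factor * criteria.dta_tol / step + 1e-9))
    offs = np.arange(-n, n + 1) * step
    dzz, dss = np.meshgrid(offs, offs, indexing="ij")
    dz, ds = dzz.ravel(), dss.ravel()
    dist2 = dz ** 2 + ds ** 2

    circ = geom.circumference
    denom = (criteria.dose_tol * ref_max) ** 2
    gamma_map = np.full(geom.shape, np.nan)
    analyzed = ref >= criteria.low_dose_threshold * ref_max
    idx_r, idx_c = np.nonzero(analyzed)
    for r, c in zip(idx_r, idx_c):
        z_cand = r * geom.axial_pitch + dz
        s_cand = np.mod(c * col_pitch + ds, circ)
        ok = (z_cand >= 0) & (z_cand <= rows_mm[-1])
        pts = np.stack([z_cand[ok], s_cand[ok]], axis=1)
        dref = interp(pts)
        val = dist2[ok] / criteria.dta_tol ** 2 \
            + (calculated.values[r, c] - dref) ** 2 / denom
        gamma_map[r, c] = np.sqrt(val.min())
    vals = gamma_map[analyzed]
    gpr = 100.0 * np.count_nonzero(vals <= 1.0) / vals.size
    return gamma_map, gpr


def mann_whitney_auc(scores, labels, positive_class):
    """AUC as the Mann-Whitney U statistic normalized by n_pos * n_neg."""
    scores = np.asarray(scores, dtype=float)
    s = scores if scores.ndim == 1 else scores[:, positive_class]
    pos = np.asarray(labels) == positive_class
    ranks = rankdata(s)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def binary_metrics_by_hand(tp, fp, fn, tn):
    """Literal accuracy / recall / precision / F1 from the four counts."""
    acc = (tp + tn) / (tp + tn + fp + fn)
    rec = tp / (tp + fn) if tp + fn else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return acc, pre, rec, f1
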