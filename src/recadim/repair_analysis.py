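"""Single-cell DSB-repair analysis: SOS gating, foci detection, event timing.

Works on the frozen track-table schema emitted by :mod:`recadim.synthetic_data`
(``frames.csv``: cell_id, time_min, length_um, cfp; ``foci.csv``: cell_id,
time_min, channel, position_um, intensity, present), into which real
single-cell tracking output can equally be coerced.

Cells undergoing repair are selected by a fourfold increase in the CFP
SOS-reporter signal. Repair duration is the time between loss and
reappearance of the broken-locus ParB focus; homology-search completion is
read out as the first sustained colocalization of the MalI sister foci.
Dwell-time distributions are summarised by maximum-likelihood gamma fits.
Loss/reappearance and colocalization calls require two consecutive frames to
reject single-frame detection dropouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from skimage.feature import peak_local_max
from skimage.filters import gaussian as _gaussian_filter


# ---------------------------------------------------------------------------
# image operations

def subtract_background(image: np.ndarray, kernel_px: float = 20.0) -> np.ndarray:
    """High-pass filter: subtract a Gaussian-smoothed copy (sigma = kernel_px)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("subtract_background expects a 2D image")
    if kernel_px <= 0:
        raise ValueError("kernel_px must be positive")
    smooth = _gaussian_filter(image, sigma=kernel_px, preserve_range=True)
    return image - smooth


def _radial_symmetry_center(window: np.ndarray) -> tuple[float, float]:
    """Sub-pixel center by gradient-based radial symmetry.

    Intensity gradients of a radially symmetric spot all point through its
    center; the center is the least-squares intersection point of the lines
    through each mid-pixel along its local gradient, weighted by gradient
    magnitude and proximity to the centroid (Parthasarathy-style estimator).
    Returns (x, y) in window coordinates.
    """
    I = np.asarray(window, dtype=float)
    h, w = I.shape
    # gradients on the dual (midpoint) grid, along the two 45° diagonals
    du = I[1:, 1:] - I[:-1, :-1]
    dv = I[1:, :-1] - I[:-1, 1:]
    # 3x3 boxcar smoothing
    k = np.ones((3, 3)) / 9.0
    from scipy.signal import convolve2d
    du = convolve2d(du, k, mode="same", boundary="symm")
    dv = convolve2d(dv, k, mode="same", boundary="symm")
    gx = du - dv   # gradient in x (45° basis rotated back)
    gy = du + dv
    mag2 = gx * gx + gy * gy
    if mag2.sum() <= 0:
        return (w - 1) / 2.0, (h - 1) / 2.0
    ym, xm = np.mgrid[0.5:h - 1, 0.5:w - 1]
    # centroid of gradient magnitude, used for distance weighting
    xc = (xm * mag2).sum() / mag2.sum()
    yc = (ym * mag2).sum() / mag2.sum()
    dist = np.sqrt((xm - xc) ** 2 + (ym - yc) ** 2)
    wgt = mag2 / (dist + 0.1)
    # line through (xm, ym) with slope m = gy/gx: minimize sum of weighted
    # squared distances -> 2x2 normal equations
    m2 = gy * gy
    mm = gx * gy
    g2 = gx * gx
    norm = m2 + g2
    norm[norm == 0] = 1.0
    A11 = (wgt * m2 / norm).sum()
    A12 = -(wgt * mm / norm).sum()
    A22 = (wgt * g2 / norm).sum()
    b1 = (wgt * (m2 * xm - mm * ym) / norm).sum()
    b2 = (wgt * (g2 * ym - mm * xm) / norm).sum()
    det = A11 * A22 - A12 * A12
    if abs(det) < 1e-12:
        return (w - 1) / 2.0, (h - 1) / 2.0
    x = (A22 * b1 - A12 * b2) / det
    y = (A11 * b2 - A12 * b1) / det
    return float(x), float(y)


def detect_foci(
    image: np.ndarray,
    radius_px: int = 3,
    threshold: float | None = None,
    min_distance: int = 3,
) -> pd.DataFrame:
    """Sub-pixel spot detection: local-maximum seeding + radial-symmetry refinement.

    ``image`` should be background-subtracted. ``threshold`` is an absolute
    intensity floor for candidate maxima; by default it is a robust
    6-sigma-above-median level estimated from the image itself. Returns a
    DataFrame with columns x_px, y_px, intensity (possibly empty).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_foci expects a 2D image")
    if threshold is None:
        med = np.median(image)
        mad = np.median(np.abs(image - med))
        threshold = med + 6.0 * 1.4826 * max(mad, 1e-12)
    peaks = peak_local_max(image, min_distance=min_distance,
                           threshold_abs=threshold, exclude_border=radius_px)
    rows = []
    for yo, xo in peaks:
        y0, y1 = yo - radius_px, yo + radius_px + 1
        x0, x1 = xo - radius_px, xo + radius_px + 1
        win = image[y0:y1, x0:x1]
        dx, dy = _radial_symmetry_center(win)
        rows.append({"x_px": x0 + dx, "y_px": y0 + dy,
                     "intensity": float(image[yo, xo])})
    return pd.DataFrame(rows, columns=["x_px", "y_px", "intensity"])


def map_to_backbone(
    spots_xy: np.ndarray,
    backbone_xy: np.ndarray,
    flip: bool = False,
) -> np.ndarray:
    """Arclength positions of spots projected orthogonally onto a backbone polyline.

    ``backbone_xy`` is an (N, 2) polyline from the reference pole to the other
    pole; ``flip=True`` reverses the orientation (position becomes L − x), used
    to orient cells so the remaining ParB focus is on top. Spots that project
    beyond the polyline are clamped to its ends.
    """
    spots = np.atleast_2d(np.asarray(spots_xy, dtype=float))
    bb = np.asarray(backbone_xy, dtype=float)
    if bb.ndim != 2 or bb.shape[0] < 2:
        raise ValueError("backbone must be an (N>=2, 2) polyline")
    seg = np.diff(bb, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    out = np.empty(spots.shape[0])
    for i, p in enumerate(spots):
        rel = p[None, :] - bb[:-1]
        t = np.clip((rel * seg).sum(axis=1) / np.maximum(seg_len**2, 1e-300), 0, 1)
        proj = bb[:-1] + t[:, None] * seg
        d2 = ((p[None, :] - proj) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        out[i] = cum[j] + t[j] * seg_len[j]
    if flip:
        out = total - out
    return out


# ---------------------------------------------------------------------------
# SOS gating

@dataclass
class SosCall:
    gated: bool
    fold_change: float
    induction_time: float | None   # min; None if not gated


def gate_sos(
    times: np.ndarray,
    cfp: np.ndarray,
    fold_threshold: float = 4.0,
    baseline_frames: int = 5,
) -> SosCall:
    """Fourfold SOS gate with half-max induction timing.

    The baseline is the median of the first ``baseline_frames`` frames (the
    pre-induction signal); a cell is gated when max/baseline exceeds
    ``fold_threshold``. The induction time is the linearly interpolated first
    crossing of half of the maximum signal.
    """
    times = np.asarray(times, dtype=float)
    cfp = np.asarray(cfp, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 frames")
    baseline = float(np.median(cfp[:baseline_frames]))
    if baseline <= 0:
        raise ValueError("nonpositive baseline")
    fold = float(cfp.max() / baseline)
    gated = fold > fold_threshold
    induction = None
    if gated:
        half = cfp.max() / 2.0
        above = np.nonzero(cfp >= half)[0]
        k = int(above[0])
        if k == 0:
            induction = float(times[0])
        else:
            induction = float(np.interp(half, [cfp[k - 1], cfp[k]],
                                        [times[k - 1], times[k]]))
    return SosCall(gated, fold, induction)


# ---------------------------------------------------------------------------
# event extraction

@dataclass
class RepairEvent:
    status: str                       # "event" | "no_event" | "censored"
    parB_loss: float | None = None    # min
    reappear: float | None = None
    repair_duration: float | None = None
    coloc_time: float | None = None
    length_at_break: float | None = None


def _first_run(mask: np.ndarray, min_consecutive: int, start: int = 0) -> int | None:
    """Index of the first run of >= min_consecutive True values at or after start."""
    run = 0
    for i in range(start, mask.size):
        run = run + 1 if mask[i] else 0
        if run >= min_consecutive:
            return i - min_consecutive + 1
    return None


def extract_repair_event(
    times: np.ndarray,
    present: np.ndarray,
    min_consecutive: int = 2,
) -> RepairEvent:
    """Loss and reappearance of the broken-locus focus.

    ``present`` is the per-frame presence of the focus (for count-based input
    use ``present = n_foci >= 2``). Loss is the first of ≥ min_consecutive
    consecutive absent frames; reappearance is the first of ≥ min_consecutive
    present frames after the loss. A track that never loses the focus is a
    no-event; a loss without reappearance is censored.
    """
    times = np.asarray(times, dtype=float)
    present = np.asarray(present, dtype=bool)
    i_loss = _first_run(~present, min_consecutive)
    if i_loss is None or i_loss == 0:
        return RepairEvent("no_event")
    i_re = _first_run(present, min_consecutive, start=i_loss)
    t_loss = float(times[i_loss])
    if i_re is None:
        return RepairEvent("censored", parB_loss=t_loss)
    t_re = float(times[i_re])
    return RepairEvent("event", parB_loss=t_loss, reappear=t_re,
                       repair_duration=t_re - t_loss)


def colocalization_time(
    times: np.ndarray,
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    dist_threshold_um: float = 0.25,
    origin: float = 0.0,
    min_consecutive: int = 2,
) -> float | None:
    """First sustained sister-locus colocalization after the time origin.

    Returns minutes relative to ``origin`` (the ParB-loss-aligned DSB time),
    or None when the loci never colocalize for ``min_consecutive`` frames
    (censored).
    """
    times = np.asarray(times, dtype=float)
    close = np.abs(np.asarray(pos_a, float) - np.asarray(pos_b, float)) < dist_threshold_um
    after = times >= origin
    i = _first_run(close & after, min_consecutive)
    if i is None:
        return None
    return float(times[i] - origin)


# ---------------------------------------------------------------------------
# statistics

@dataclass
class GammaFit:
    shape: float
    scale: float
    mean: float
    sd: float
    log_likelihood: float
    mean_se: float
    mean_ci: tuple[float, float]
    n: int


def fit_gamma(durations: np.ndarray) -> GammaFit:
    """Maximum-likelihood gamma fit (loc fixed at 0) of positive dwell times.

    Initialisation is by moment matching; the standard error of the fitted
    mean comes from the inverse Fisher information via the delta method
    (mean = shape·scale).
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 durations")
    if (x <= 0).any():
        raise ValueError("durations must be positive")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    loglik = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
    n = x.size
    # per-observation Fisher information for (shape a, scale θ)
    I = np.array([[polygamma(1, shape), 1.0 / scale],
                  [1.0 / scale, shape / scale**2]])
    cov = np.linalg.inv(n * I)
    grad = np.array([scale, shape])          # ∇(aθ)
    mean_se = float(math.sqrt(grad @ cov @ grad))
    mean = shape * scale
    return GammaFit(
        shape=float(shape), scale=float(scale), mean=float(mean),
        sd=float(scale * math.sqrt(shape)), log_likelihood=loglik,
        mean_se=mean_se,
        mean_ci=(mean - 1.96 * mean_se, mean + 1.96 * mean_se), n=n)


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class LengthRegression:
    slope: float                 # min/µm
    intercept: float             # min
    slope_ci: tuple[float, float]
    p_value: float
    n: int


def regress_vs_length(durations: np.ndarray, lengths: np.ndarray) -> LengthRegression:
    """OLS regression of event durations on cell length at the time of the break."""
    import statsmodels.api as sm

    y = np.asarray(durations, dtype=float)
    x = np.asarray(lengths, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0:
        raise ValueError("degenerate length variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    return LengthRegression(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        p_value=float(fit.pvalues[1]), n=int(y.size))


# ---------------------------------------------------------------------------
# cohort pipeline

@dataclass
class AnalysisConfig:
    fold_threshold: float = 4.0
    baseline_frames: int = 5
    min_consecutive: int = 2
    dist_threshold_um: float = 0.25


@dataclass
class CohortResults:
    per_cell: pd.DataFrame
    repair_fit: GammaFit | None
    coloc_fit: GammaFit | None
    reca_fit: GammaFit | None
    length_regression: LengthRegression | None
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def g(f):
            return None if f is None else {
                "shape": f.shape, "scale": f.scale, "mean": f.mean, "sd": f.sd,
                "mean_se": f.mean_se, "mean_ci": list(f.mean_ci), "n": f.n}
        return {
            "repair_fit": g(self.repair_fit),
            "coloc_fit": g(self.coloc_fit),
            "reca_fit": g(self.reca_fit),
            "length_regression": None if self.length_regression is None else {
                "slope": self.length_regression.slope,
                "intercept": self.length_regression.intercept,
                "slope_ci": list(self.length_regression.slope_ci),
                "p_value": self.length_regression.p_value,
                "n": self.length_regression.n},
            "counts": self.counts,
        }


def analyze_cohort(
    frames: pd.DataFrame,
    foci: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> CohortResults:
    """Run the full single-cell pipeline on track tables.

    Per cell: SOS gate and induction time; loss/reappearance of the broken
    ParB locus from the per-frame count of present ParB foci; MalI sister
    colocalization aligned to ParB loss; RecA structure lifetime from its
    presence interval. Population level: gamma fits of repair,
    colocalization and RecA-lifetime distributions, and an OLS regression of
    repair duration on cell length at the break. Censored cells are counted,
    never silently dropped.
    """
    cfg = config or AnalysisConfig()
    rows = []
    counts = {"cells": 0, "gated": 0, "events": 0, "no_event": 0, "censored": 0}
    for cell_id, fr in frames.groupby("cell_id"):
        counts["cells"] += 1
        fr = fr.sort_values("time_min")
        t = fr["time_min"].to_numpy()
        sos = gate_sos(t, fr["cfp"].to_numpy(), cfg.fold_threshold,
                       cfg.baseline_frames)
        row = {"cell_id": cell_id, "gated": sos.gated,
               "fold_change": sos.fold_change, "induction_time": sos.induction_time,
               "status": None, "parB_loss": None, "reappear": None,
               "repair_duration": None, "coloc_time": None,
               "reca_lifetime": None, "length_at_break": None}
        fc = foci[foci["cell_id"] == cell_id]
        if sos.gated and not fc.empty:
            counts["gated"] += 1
            parb = fc[fc["channel"] == "ParB"]
            n_present = (parb[parb["present"]].groupby("time_min").size()
                         .reindex(np.unique(parb["time_min"]), fill_value=0))
            ev = extract_repair_event(n_present.index.to_numpy(),
                                      (n_present >= 2).to_numpy(),
                                      cfg.min_consecutive)
            row["status"] = ev.status
            counts[{"event": "events", "no_event": "no_event",
                    "censored": "censored"}[ev.status]] += 1
            row["parB_loss"] = ev.parB_loss
            row["reappear"] = ev.reappear
            row["repair_duration"] = ev.repair_duration
            if ev.parB_loss is not None:
                row["length_at_break"] = float(
                    np.interp(ev.parB_loss, t, fr["length_um"].to_numpy()))
                mali = fc[(fc["channel"] == "MalI") & fc["present"]]
                if not mali.empty:
                    piv = mali.pivot_table(index="time_min", columns="focus_id",
                                           values="position_um")
                    if piv.shape[1] >= 2:
                        row["coloc_time"] = colocalization_time(
                            piv.index.to_numpy(),
                            piv.iloc[:, 0].to_numpy(), piv.iloc[:, 1].to_numpy(),
                            cfg.dist_threshold_um, origin=ev.parB_loss,
                            min_consecutive=cfg.min_consecutive)
                reca = fc[(fc["channel"] == "RecA")]
                pres = reca[reca["present"]]
                if not pres.empty:
                    dt = np.median(np.diff(np.unique(reca["time_min"])))
                    row["reca_lifetime"] = float(
                        pres["time_min"].max() - pres["time_min"].min() + dt)
        rows.append(row)
    per_cell = pd.DataFrame(rows)

    def fit_if(series) -> GammaFit | None:
        vals = series.dropna().to_numpy(dtype=float)
        vals = vals[vals > 0]
        return fit_gamma(vals) if vals.size >= 10 else None

    repair_fit = fit_if(per_cell["repair_duration"])
    coloc_fit = fit_if(per_cell["coloc_time"])
    reca_fit = fit_if(per_cell["reca_lifetime"])
    reg = None
    ok = per_cell.dropna(subset=["repair_duration", "length_at_break"])
    if len(ok) >= 3 and ok["length_at_break"].std() > 0:
        reg = regress_vs_length(ok["repair_duration"].to_numpy(),
                                ok["length_at_break"].to_numpy())
    return CohortResults(per_cell, repair_fit, coloc_fit, reca_fit, reg, counts)
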