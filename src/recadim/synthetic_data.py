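"""Synthetic single-cell DSB-repair cohorts, spot images and STED line profiles.

The generator emulates the observables of a mother-machine DSB experiment:
per-cell time series of length and SOS-reporter (CFP) intensity, focus tracks
for the ParB break marker, MalI sister-locus markers and RecA structures, 2D
fluorescent spot images for the detector, and 1D STED line profiles for the
filament-width estimator. Every stochastic element is driven by a single
seeded generator, so a fixed seed reproduces the cohort bit-for-bit.

Event durations are drawn from gamma distributions moment-matched to the
configured mean ± sd (guaranteeing positivity). Two constructions keep the
per-cell timeline consistent:

* repair duration = colocalization time + an independent gamma increment
  whose moments are chosen so the repair marginal keeps exactly the
  configured (mean, sd) while colocalization always precedes reappearance;
* RecA structure lifetime = spot phase + filament phase (the configured phase
  means add up to the configured lifetime mean).

The RecA appearance lead relative to ParB loss has sd larger than its mean,
so it is drawn from a (shifted) normal and its sign may flip; orderings
involving it are deliberately not enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import filament_width


def gamma_from_moments(mean: float, sd: float):
    """Frozen gamma distribution with the given mean and standard deviation."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return stats.gamma(a=shape, scale=scale)


@dataclass
class CohortConfig:
    """Study conditions of a synthetic DSB-repair cohort.

    Durations are minutes unless noted; ``reca_lead`` is in seconds. The
    defaults are the measured population moments of the mother-machine
    experiments: repair 15.2 ± 5.0 min, colocalization 9.1 ± 3.3 min, RecA
    lifetime 8.8 ± 3.0 min split into a 2.6 ± 1.4 min spot phase and a
    6.2 ± 2.8 min filament phase, RecA appearing 35 ± 98 s before ParB loss,
    generation time 35 ± 10 min, and a fourfold SOS gate with an eightfold
    induced amplitude.
    """

    n_cells: int = 765
    frame_interval: float = 1.0          # min
    movie_length: float = 120.0          # min
    induction_time: float = 20.0         # min, start of the nuclease pulse
    cut_fraction: float = 0.6
    generation_mean: float = 35.0
    generation_sd: float = 10.0
    repair_mean: float = 15.2
    repair_sd: float = 5.0
    coloc_mean: float = 9.1
    coloc_sd: float = 3.3
    reca_lifetime_mean: float = 8.8
    reca_lifetime_sd: float = 3.0
    reca_spot_phase_mean: float = 2.6
    reca_spot_phase_sd: float = 1.4
    reca_filament_phase_mean: float = 6.2
    reca_filament_phase_sd: float = 2.8
    reca_lead_mean_s: float = 35.0
    reca_lead_sd_s: float = 98.0
    disassembly_lead_mean: float = 6.6   # recorded, not drawn: implied by the
    disassembly_lead_sd: float = 5.2     # lifetime and repair constructions
    sos_fold_on_dsb: float = 8.0
    sos_lifetime_coupling: float = 0.36  # Pearson coupling of SOS amplitude to lifetime
    cfp_noise_cv: float = 0.05
    cfp_baseline: float = 100.0
    dsb_delay_mean: float = 3.0          # min, nuclease pulse -> cut
    dsb_delay_sd: float = 1.5
    sos_rise_delay: float = 4.0          # min, cut -> CFP half-max
    sos_rise_tau: float = 1.5            # min, logistic rise time of CFP
    position_jitter_um: float = 0.03     # OU jitter sd of focus positions
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cut_fraction <= 1.0:
            raise ValueError("cut_fraction must be in [0, 1]")
        for name in (
            "generation_mean", "repair_mean", "coloc_mean", "reca_lifetime_mean",
            "reca_spot_phase_mean", "reca_filament_phase_mean", "frame_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "generation_sd", "repair_sd", "coloc_sd", "reca_lifetime_sd",
            "reca_spot_phase_sd", "reca_filament_phase_sd", "cfp_noise_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.repair_mean <= self.coloc_mean:
            raise ValueError("repair_mean must exceed coloc_mean")
        var_inc = self.repair_sd**2 - self.coloc_sd**2
        if var_inc <= 0:
            raise ValueError("repair_sd must exceed coloc_sd for the coupled draw")


DURATION_KINDS = ("repair", "coloc", "reca_lifetime", "generation",
                  "spot_phase", "filament_phase")


def duration_distribution(config: CohortConfig, kind: str):
    """The moment-matched gamma law for one duration kind."""
    table = {
        "repair": (config.repair_mean, config.repair_sd),
        "coloc": (config.coloc_mean, config.coloc_sd),
        "reca_lifetime": (config.reca_lifetime_mean, config.reca_lifetime_sd),
        "generation": (config.generation_mean, config.generation_sd),
        "spot_phase": (config.reca_spot_phase_mean, config.reca_spot_phase_sd),
        "filament_phase": (config.reca_filament_phase_mean, config.reca_filament_phase_sd),
    }
    if kind not in table:
        raise ValueError(f"unknown duration kind {kind!r}; choose from {DURATION_KINDS}")
    return gamma_from_moments(*table[kind])


def sample_durations(config: CohortConfig, kind: str, n: int,
                     seed: int | None = None) -> np.ndarray:
    """Draw n durations from the configured gamma law for ``kind``."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return duration_distribution(config, kind).rvs(size=n, random_state=rng)


@dataclass
class FociTrack:
    """One focus channel of one cell: per-frame backbone position and presence."""

    channel: str                  # ParB | MalI | RecA
    focus_id: int
    times: np.ndarray             # min
    positions: np.ndarray         # µm from the reference pole
    intensities: np.ndarray       # a.u.
    present: np.ndarray           # bool


@dataclass
class CellRecord:
    """One synthetic cell: time series, focus tracks, and ground-truth events."""

    cell_id: int
    times: np.ndarray             # min
    lengths: np.ndarray           # µm
    cfp: np.ndarray               # a.u.
    foci: list[FociTrack]
    events: dict                  # ground truth; NaN where not applicable


def _grow_lengths(times, birth_length, doubling_time, first_division, rng, config):
    """Exponential growth (fixed doubling time) with halving at divisions.

    The doubling time sets the growth rate; division events may come later
    than one doubling (SOS-delayed division produces transiently longer
    cells), so length and division timing are decoupled.
    """
    lengths = np.empty_like(times)
    t_div, L0, next_div = 0.0, birth_length, first_division
    for i, t in enumerate(times):
        while t >= next_div:
            L0 = L0 * 2.0 ** ((next_div - t_div) / doubling_time) / 2.0
            t_div = next_div
            next_div = t_div + max(5.0, gamma_from_moments(
                config.generation_mean, max(config.generation_sd, 1e-6)
            ).rvs(random_state=rng))
        lengths[i] = L0 * 2.0 ** ((t - t_div) / doubling_time)
    return lengths


def _ou_jitter(n, sd, rng, theta=0.5):
    """Discrete Ornstein–Uhlenbeck noise with stationary sd."""
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    a = math.exp(-theta)
    innov_sd = sd * math.sqrt(1 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + rng.normal(0, innov_sd)
    return x


def generate_cohort(config: CohortConfig) -> list[CellRecord]:
    """Generate a seeded cohort of CellRecords.

    ``cut_fraction`` of the cells receive a DSB after the nuclease pulse; in
    those cells CFP rises ``sos_fold_on_dsb``-fold (log-normally dispersed and
    correlated with the RecA lifetime), the broken-locus ParB focus is lost
    and reappears after the repair duration, the MalI sister foci converge to
    mid-cell and colocalize, and a RecA structure spans
    [ParB loss − lead, ... + lifetime]. Uncut cells show none of these.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    times = np.arange(0.0, config.movie_length + config.frame_interval / 2,
                      config.frame_interval)

    cut = rng.random(n) < config.cut_fraction
    # event-time draws (vectorised; unused entries for uncut cells stay NaN)
    coloc_rel = duration_distribution(config, "coloc").rvs(size=n, random_state=rng)
    inc_mean = config.repair_mean - config.coloc_mean
    inc_sd = math.sqrt(config.repair_sd**2 - config.coloc_sd**2)
    repair_rel = coloc_rel + gamma_from_moments(inc_mean, inc_sd).rvs(
        size=n, random_state=rng)
    spot_phase = duration_distribution(config, "spot_phase").rvs(size=n, random_state=rng)
    fil_phase = duration_distribution(config, "filament_phase").rvs(size=n, random_state=rng)
    lifetime = spot_phase + fil_phase
    lead_min = rng.normal(config.reca_lead_mean_s / 60.0,
                          config.reca_lead_sd_s / 60.0, size=n)
    dsb_delay = gamma_from_moments(config.dsb_delay_mean, config.dsb_delay_sd).rvs(
        size=n, random_state=rng)
    proc_delay = gamma_from_moments(1.0, 0.5).rvs(size=n, random_state=rng)

    # SOS amplitude log-normally dispersed, correlated with the RecA lifetime
    rho = config.sos_lifetime_coupling
    z_life = (lifetime - lifetime.mean()) / max(lifetime.std(), 1e-12)
    w = rho * z_life + math.sqrt(max(1 - rho * rho, 0.0)) * rng.standard_normal(n)
    sigma_f = 0.25
    sos_fold = config.sos_fold_on_dsb * np.exp(sigma_f * (w - sigma_f / 2))

    cells: list[CellRecord] = []
    for i in range(n):
        birth_length = max(1.0, rng.normal(2.0, 0.2))
        generation = max(5.0, duration_distribution(config, "generation").rvs(
            random_state=rng))
        events: dict[str, float] = {k: float("nan") for k in (
            "dsb_time", "parB_loss", "reca_appear", "filament_start",
            "reca_disassembly", "reca_lifetime", "coloc_time", "reappear_time",
            "repair_duration", "division_time", "sos_half_time", "sos_fold",
            "length_at_break")}
        events["cut"] = bool(cut[i])

        if cut[i]:
            dsb = config.induction_time + dsb_delay[i]
            loss = dsb + proc_delay[i]
            reappear = loss + repair_rel[i]
            coloc = loss + coloc_rel[i]
            appear = loss - lead_min[i]
            disassembly = appear + lifetime[i]
            division = max(generation, reappear + 8.0)
            events.update(
                dsb_time=dsb, parB_loss=loss, reca_appear=appear,
                filament_start=appear + spot_phase[i],
                reca_disassembly=disassembly, reca_lifetime=lifetime[i],
                coloc_time=coloc, reappear_time=reappear,
                repair_duration=repair_rel[i], division_time=division,
                sos_half_time=dsb + config.sos_rise_delay, sos_fold=sos_fold[i],
            )
            lengths = _grow_lengths(times, birth_length, generation, division,
                                    rng, config)
            events["length_at_break"] = float(np.interp(loss, times, lengths))
        else:
            division = generation
            events["division_time"] = division
            lengths = _grow_lengths(times, birth_length, generation, division,
                                    rng, config)

        # CFP trace: flat baseline, logistic rise for cut cells
        base = config.cfp_baseline * rng.normal(1.0, 0.05)
        cfp = np.full_like(times, base)
        if cut[i]:
            t_half = events["sos_half_time"]
            cfp = base * (1.0 + (sos_fold[i] - 1.0) /
                          (1.0 + np.exp(-(times - t_half) / config.sos_rise_tau)))
        cfp = cfp * (1.0 + config.cfp_noise_cv * rng.standard_normal(times.size))

        foci = _make_foci(times, lengths, events, config, rng)
        cells.append(CellRecord(i, times, lengths, cfp, foci, events))
    return cells


def _make_foci(times, lengths, ev, config, rng):
    """Piecewise-linear position programs with OU jitter for all channels."""
    nT = times.size
    jit = lambda: _ou_jitter(nT, config.position_jitter_um, rng)  # noqa: E731
    cut = ev["cut"]
    tracks: list[FociTrack] = []

    # convention: the remaining (uncut) focus is oriented toward the reference
    # pole, at fraction 0.25 of the length; the broken locus sits at 0.75.
    frac_keep = np.full(nT, 0.25)
    frac_cut = np.full(nT, 0.75)
    if cut:
        loss, reappear = ev["parB_loss"], ev["reappear_time"]
        # remaining focus translocates to mid-cell after the break, returns
        # after repair; reappeared focus splits from mid-cell.
        frac_keep = np.interp(times, [loss, loss + 5.0, reappear, reappear + 10.0],
                              [0.25, 0.45, 0.45, 0.3])
        frac_cut = np.interp(times, [loss, reappear, reappear + 10.0],
                             [0.75, 0.55, 0.7])
    parb_present_cut = np.ones(nT, dtype=bool)
    if cut:
        parb_present_cut = ~((times >= ev["parB_loss"]) & (times < ev["reappear_time"]))
    inten = lambda: np.clip(rng.normal(500, 50, nT), 100, None)  # noqa: E731
    tracks.append(FociTrack("ParB", 0, times, np.clip(frac_keep * lengths + jit(), 0, lengths),
                            inten(), np.ones(nT, dtype=bool)))
    tracks.append(FociTrack("ParB", 1, times, np.clip(frac_cut * lengths + jit(), 0, lengths),
                            inten(), parb_present_cut))

    # MalI sister loci: converge so their separation crosses the diffraction
    # threshold (0.25 µm) at the true colocalization time, hold near zero
    # until reappearance, then segregate.
    mid = 0.5 * lengths
    if cut:
        loss, coloc, reappear = ev["parB_loss"], ev["coloc_time"], ev["reappear_time"]
        # slow approach, then a sharp capture through the 0.25 µm threshold
        # exactly at the true colocalization time (capture is a discrete event)
        sep0 = 0.5 * lengths[0]
        sep = np.interp(
            times,
            [loss, coloc - 0.5, coloc, coloc + 0.5, reappear, reappear + 10.0],
            [sep0, 0.45, 0.25, 0.08, 0.08, 0.8])
        sep[times < loss] = sep0
    else:
        sep = 0.5 * lengths
    for sgn, fid in ((-1.0, 0), (1.0, 1)):
        pos = np.clip(mid + sgn * sep / 2.0 + jit() * 0.5, 0, lengths)
        tracks.append(FociTrack("MalI", fid, times, pos, inten(),
                                np.ones(nT, dtype=bool)))

    if cut:
        appear, disassembly = ev["reca_appear"], ev["reca_disassembly"]
        present = (times >= appear) & (times < disassembly)
        spot_end = ev["filament_start"]
        reca_int = np.where(times < spot_end, 300.0, 600.0) * rng.normal(1, 0.1, nT)
        pos = np.clip(frac_cut * lengths + jit(), 0, lengths)
        tracks.append(FociTrack("RecA", 0, times, pos, reca_int, present))
    return tracks


# ---------------------------------------------------------------------------
# tabular export (frozen CSV schemas; real data can be coerced into these)

def cohort_frames_df(cells: list[CellRecord]) -> pd.DataFrame:
    return pd.concat(
        [pd.DataFrame({"cell_id": c.cell_id, "time_min": c.times,
                       "length_um": c.lengths, "cfp": c.cfp}) for c in cells],
        ignore_index=True)


def cohort_foci_df(cells: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for c in cells:
        for tr in c.foci:
            rows.append(pd.DataFrame({
                "cell_id": c.cell_id, "time_min": tr.times, "channel": tr.channel,
                "focus_id": tr.focus_id, "position_um": tr.positions,
                "intensity": tr.intensities, "present": tr.present}))
    return pd.concat(rows, ignore_index=True)


def cohort_events_df(cells: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"cell_id": c.cell_id, **c.events} for c in cells])


def write_cohort_csvs(cells: list[CellRecord], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "frames": outdir / "frames.csv",
        "foci": outdir / "foci.csv",
        "events_truth": outdir / "events_truth.csv",
    }
    cohort_frames_df(cells).to_csv(paths["frames"], index=False)
    cohort_foci_df(cells).to_csv(paths["foci"], index=False)
    cohort_events_df(cells).to_csv(paths["events_truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# spot images

@dataclass
class SpotImage:
    """Synthetic 2D fluorescence frame with its ground-truth spot list."""

    image: np.ndarray             # uint16 counts
    pixel_size_nm: float
    truth: pd.DataFrame           # columns x_px, y_px, amplitude
    background: float
    noise: dict


def generate_spot_image(
    spots: list[tuple[float, float, float]],
    psf_sigma_px: float = 1.5,
    shape: tuple[int, int] = (64, 64),
    pixel_size_nm: float = 80.0,
    background: float = 100.0,
    poisson: bool = True,
    gaussian_sd: float = 2.0,
    seed: int = 0,
) -> SpotImage:
    """Sum of Gaussian kernels + background + Poisson/Gaussian noise.

    ``spots`` is a list of (x_px, y_px, amplitude); all spots must lie inside
    the frame.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    h, w = shape
    for x, y, _ in spots:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"spot ({x}, {y}) outside the {shape} frame")
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    for x, y, amp in spots:
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * psf_sigma_px**2))
    rng = np.random.default_rng(seed)
    if poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if gaussian_sd > 0:
        img = img + rng.normal(0, gaussian_sd, shape)
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(spots, columns=["x_px", "y_px", "amplitude"])
    return SpotImage(img, pixel_size_nm, truth, background,
                     {"poisson": poisson, "gaussian_sd": gaussian_sd, "seed": seed})


# ---------------------------------------------------------------------------
# STED line profiles

@dataclass
class LineProfile:
    """1D STED intensity profile sampled on a uniform 20-nm pixel grid."""

    profile_id: int
    positions_nm: np.ndarray
    intensities: np.ndarray


def generate_line_profiles(
    diameter_nm: float = 37.5,
    shell_nm: float = 3.0,
    psf_fwhm_nm: float = 35.0,
    noise_cv: float = 0.05,
    n: int = 74,
    seed: int = 0,
    pixel_nm: float = 20.0,
    extent_nm: float = 300.0,
) -> list[LineProfile]:
    """Noisy realisations of the cylinder-shell forward model.

    Each profile is the forward-model prediction sampled at the STED pixel
    size (20 nm) with multiplicative Gaussian noise of the given cv.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if diameter_nm < 0 or psf_fwhm_nm <= 0:
        raise ValueError("need diameter >= 0 and psf_fwhm > 0")
    x_fine, y_fine = filament_width.forward_profile(
        diameter_nm, shell_nm, psf_fwhm_nm, extent_nm=extent_nm + pixel_nm)
    x = np.arange(-extent_nm, extent_nm + pixel_nm / 2, pixel_nm)
    y0 = np.interp(x, x_fine, y_fine)
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        noise = 1.0 + noise_cv * rng.standard_normal(x.size)
        profiles.append(LineProfile(i, x.copy(), y0 * noise))
    return profiles


def profiles_df(profiles: list[LineProfile]) -> pd.DataFrame:
    return pd.concat(
        [pd.DataFrame({"profile_id": p.profile_id, "position_nm": p.positions_nm,
                       "intensity": p.intensities}) for p in profiles],
        ignore_index=True)
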