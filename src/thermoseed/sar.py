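"""Virtual thermometry and calorimetric SAR estimation.

The measurement protocol places optical-fibre probes in drilled holes at
named stations of the scaffold — C (centre), L/R (left/right of centre),
T (top) — plus one background station O in the surrounding agar.  Each
probe trace is a noisy temperature-vs-time record with the field switched
off at t_off.  SAR is estimated calorimetrically: the initial slope
dT/dt of the heating branch times the phantom's specific heat,

    SAR = C_p * dT/dt            (single probe, W/g with C_p in J/(g K))

and the protocol's headline figure averages the slopes of the probes
inside the scaffold:

    SAR = C_p * (1/N_T) * sum_i dT_i/dt_i

reported as mean +- sample standard deviation.  A loss-corrected
"corrected slope" estimator is also provided: it fits the saturating
exponential T(t) = T0 + dT_max (1 - exp(-t/tau)) to the heating branch
(optionally constrained jointly by the cooling branch) and returns
dT_max / tau, the t -> 0 slope with linear losses removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_INSIDE_PROBES = ("C", "R", "L", "T")

#: default probe stations, metres, relative to the scaffold centre.
#: O sits on the phantom's top face, axially ~1 cm above the scaffold
#: (a radial placement outside the scaffold is impossible through the
#: 2.5 mm annular agar gap).
DEFAULT_PROBE_POSITIONS = {
    "C": (0.0, 0.0, 0.0),
    "L": (-7e-3, 0.0, 0.0),
    "R": (7e-3, 0.0, 0.0),
    "T": (0.0, 0.0, 9e-3),
    "O": (0.0, 0.0, 20e-3),
}


class LayoutError(ValueError):
    """Probe position outside the simulated grid."""


class EstimationError(RuntimeError):
    """Slope/SAR estimation failed."""


@dataclass(frozen=True)
class ProbeLayout:
    """Named probe positions (relative to the scaffold centre) and the
    sampling characteristics of the virtual thermometer."""

    positions: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_PROBE_POSITIONS))
    sampling_rate: float = 1.0   # Hz
    noise_sd: float = 0.1        # degC

    def absolute_positions(self, scaffold_center) -> dict:
        c = np.asarray(scaffold_center, dtype=float)
        return {k: c + np.asarray(v, dtype=float) for k, v in self.positions.items()}


@dataclass(frozen=True)
class TemperatureRecord:
    """Time-stamped multi-probe temperatures with the field-off marker."""

    times: np.ndarray                    # s, strictly increasing
    temperatures: Mapping[str, np.ndarray]  # degC per probe label
    field_off_time: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if int((t < self.field_off_time).sum()) < 3:
            raise ValueError("need at least 3 samples before field-off")
        object.__setattr__(self, "temperatures",
                           {k: np.asarray(v, dtype=float)
                            for k, v in self.temperatures.items()})

    @property
    def probes(self) -> tuple:
        return tuple(self.temperatures)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(self.temperatures),
                            index=pd.Index(self.times, name="time_s"))


@dataclass(frozen=True)
class SARResult:
    """Per-probe slopes/SARs and the multi-probe mean +- SD summary."""

    slopes: Mapping[str, float]        # K/s
    slope_errs: Mapping[str, float]    # K/s, OLS standard errors
    sars: Mapping[str, float]          # W/g
    mean_sar: float
    sd_sar: float
    n_probes: int
    fit_window: float
    specific_heat: float               # J/(g K)
    window_sensitivity: Mapping[float, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"SAR = {self.mean_sar:.3f} +- {self.sd_sar:.3f} W/g "
                 f"(N_T = {self.n_probes}, window {self.fit_window:.0f} s, "
                 f"C_p {self.specific_heat:g} J/(g K))"]
        for p in self.sars:
            lines.append(f"  {p}: slope {self.slopes[p]:.4f} K/s -> "
                         f"{self.sars[p]:.3f} W/g")
        if self.window_sensitivity:
            ws = ", ".join(f"{w:.0f}s: {v:.3f}" for w, v in
                           sorted(self.window_sensitivity.items()))
            lines.append(f"  window sensitivity (mean SAR): {ws}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# virtual probes

def _trilinear(history, position):
    """Time series at an arbitrary point via trilinear interpolation of the
    stored fields.  Coordinates are clamped to the voxel-centre grid (a
    probe on a phantom face reads the outermost voxel layer); NaN (ambient)
    corner weights are renormalized over the valid corners."""
    axes = history.grid_axes
    pos = np.asarray(position, dtype=float)
    idx, frac = [], []
    for d in range(3):
        ax = axes[d]
        p = np.clip(pos[d], ax[0], ax[-1])
        i = int(np.clip(np.searchsorted(ax, p) - 1, 0, max(len(ax) - 2, 0)))
        denom = ax[i + 1] - ax[i] if len(ax) > 1 else 1.0
        f = (p - ax[i]) / denom if denom else 0.0
        idx.append(i)
        frac.append(np.clip(f, 0.0, 1.0))
    series = np.zeros(len(history.times))
    weight = np.zeros(len(history.times))
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                w = ((frac[0] if cx else 1 - frac[0])
                     * (frac[1] if cy else 1 - frac[1])
                     * (frac[2] if cz else 1 - frac[2]))
                if w == 0:
                    continue
                vals = history.fields[:,
                                      min(idx[0] + cx, history.labels.shape[0] - 1),
                                      min(idx[1] + cy, history.labels.shape[1] - 1),
                                      min(idx[2] + cz, history.labels.shape[2] - 1)]
                ok = np.isfinite(vals)
                series[ok] += w * vals[ok]
                weight[ok] += w
    if np.any(weight == 0):
        raise LayoutError(f"probe at {position} has no solid neighbourhood")
    return series / weight


def sample_probes(history, layout: ProbeLayout, seed: int = 0,
                  scaffold_center=(0.0, 0.0, 0.0),
                  noise_sd: Optional[float] = None,
                  probes: Optional[Sequence[str]] = None,
                  metadata: Optional[dict] = None) -> TemperatureRecord:
    """Read the virtual probes from a simulated temperature history.

    Trilinear interpolation in space at each station, linear interpolation
    in time onto the layout's sampling grid, plus additive Gaussian sensor
    noise (``noise_sd`` overrides the layout default; deterministic for a
    fixed seed).
    """
    rng = np.random.default_rng(seed)
    sd = layout.noise_sd if noise_sd is None else noise_sd
    positions = layout.absolute_positions(scaffold_center)
    if probes is not None:
        positions = {k: positions[k] for k in probes}
    x, y, z = history.grid_axes
    margin = 0.51 * (x[1] - x[0]) if len(x) > 1 else np.inf
    for name, p in positions.items():
        for d, ax in enumerate((x, y, z)):
            if p[d] < ax[0] - margin or p[d] > ax[-1] + margin:
                raise LayoutError(f"probe {name} at {np.round(p * 1e3, 1)} mm "
                                  "outside the simulated grid")
    t_samp = np.arange(0.0, history.times[-1] + 1e-9, 1.0 / layout.sampling_rate)
    temps = {}
    for name, p in positions.items():
        series = _trilinear(history, p)
        vals = np.interp(t_samp, history.times, series)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=vals.shape)
        temps[name] = vals
    return TemperatureRecord(t_samp, temps, history.field_off_time,
                             metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# background subtraction

def subtract_background(record: TemperatureRecord,
                        control: TemperatureRecord) -> TemperatureRecord:
    """Remove non-magnetic background heating using a control record.

    The control (agar/PLA sample without magnetic filler, same protocol)
    is resampled onto the record's time base; the per-probe corrected
    trace is record - (control - control baseline), which restores the
    record's initial baseline.  A single-probe control is broadcast to all
    record probes.
    """
    t0, t1 = record.times[0], record.times[-1]
    if control.times[-1] < t0 or control.times[0] > t1:
        raise EstimationError("control and record time ranges do not overlap")
    corrected = {}
    for probe, trace in record.temperatures.items():
        if probe in control.temperatures:
            ctrl = control.temperatures[probe]
        elif len(control.temperatures) == 1:
            ctrl = next(iter(control.temperatures.values()))
        else:
            raise EstimationError(f"control record lacks probe {probe!r}")
        ctrl_i = np.interp(record.times, control.times, ctrl)
        # the control's field-on value anchors the restored baseline
        corrected[probe] = trace - (ctrl_i - ctrl_i[0])
    meta = dict(record.metadata)
    meta["background_corrected"] = True
    return replace(record, temperatures=corrected, metadata=meta)


# ---------------------------------------------------------------------------
# slope estimators

def initial_slope(times, temps, field_off_time: float, window: float = 30.0):
    """OLS slope (K/s) of the heating branch over (0, window].

    Returns (slope, standard_error).  The window must not extend past the
    field-off time and needs at least 3 samples.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(temps, dtype=float)
    # work relative to the record start so estimates are invariant under a
    # uniform time shift
    t = t - t[0]
    field_off_time = field_off_time - times[0]
    if window > field_off_time + 1e-9:
        raise ValueError("fit window must not extend past field-off")
    mask = (t >= 0) & (t <= window + 1e-9)
    if mask.sum() < 3:
        raise EstimationError("too few samples in the fit window")
    tt, yy = t[mask], y[mask]
    A = np.vstack([tt, np.ones_like(tt)]).T
    coef, res, *_ = np.linalg.lstsq(A, yy, rcond=None)
    slope = coef[0]
    n = len(tt)
    resid = yy - A @ coef
    s2 = (resid @ resid) / max(n - 2, 1)
    sxx = ((tt - tt.mean()) ** 2).sum()
    se = np.sqrt(s2 / sxx) if sxx > 0 else np.inf
    return float(slope), float(se)


def _heating_cooling_model(t, T0, dTmax, tau, t_off):
    heat = T0 + dTmax * (1.0 - np.exp(-np.clip(t, 0, None) / tau))
    peak = T0 + dTmax * (1.0 - np.exp(-t_off / tau))
    cool = T0 + (peak - T0) * np.exp(-(t - t_off) / tau)
    return np.where(t <= t_off, heat, cool)


def corrected_slope(times, temps, field_off_time: float,
                    use_cooling: bool = True):
    """Loss-corrected initial slope from a saturating-exponential fit.

    Fits T(t) = T0 + dT_max (1 - exp(-t/tau)) on the heating branch; with
    ``use_cooling`` the post-switch-off branch (same tau, continuous at
    t_off) joins the fit, which both cross-checks tau and tightens the
    estimate.  Returns (slope = dT_max/tau, standard_error, info dict).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(temps, dtype=float)
    t = t - t[0]
    field_off_time = field_off_time - float(np.asarray(times)[0])
    heat = t <= field_off_time + 1e-9
    if use_cooling and (t.max() - field_off_time) < 30.0:
        use_cooling = False
    sel = np.ones_like(t, dtype=bool) if use_cooling else heat
    T0_guess = y[heat][:3].mean()
    dT_guess = max(y[heat].max() - T0_guess, 1e-6)
    tau_guess = max(field_off_time / 2.0, 1.0)

    def model(tt, T0, dTmax, tau):
        return _heating_cooling_model(tt, T0, dTmax, tau, field_off_time)

    try:
        popt, pcov = curve_fit(model, t[sel], y[sel],
                               p0=(T0_guess, dT_guess, tau_guess),
                               maxfev=20000)
    except RuntimeError as exc:
        raise EstimationError(f"saturating-exponential fit did not converge: {exc}")
    T0, dTmax, tau = popt
    slope = dTmax / tau
    # delta method on slope = dTmax / tau
    g = np.array([0.0, 1.0 / tau, -dTmax / tau**2])
    var = float(g @ pcov @ g)
    se = np.sqrt(var) if var >= 0 else np.inf
    info = {"T0": T0, "dT_max": dTmax, "tau": tau, "used_cooling": bool(use_cooling)}
    if use_cooling:
        cool = ~heat
        if cool.sum() >= 3:
            yc = y[cool]
            tc = t[cool]
            peak = yc[0]
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = (yc - T0) / max(peak - T0, 1e-12)
                ok = ratio > 1e-3
                if ok.sum() >= 3:
                    slope_ln = np.polyfit(tc[ok], np.log(ratio[ok]), 1)[0]
                    info["tau_cooling"] = -1.0 / slope_ln if slope_ln < 0 else np.inf
    return float(slope), float(se), info


def sar_single(slope: float, specific_heat: float = 4.2) -> float:
    """Eq.-style calorimetric SAR (W/g): C_p [J/(g K)] times slope [K/s].

    ``specific_heat`` defaults to the agar phantom's 4.2 J/(g K) — the
    calorimetric convention is that the probe reads heat delivered to the
    phantom-equivalent medium.
    """
    if specific_heat <= 0:
        raise ValueError("specific_heat must be positive")
    return specific_heat * slope


def sar_average(record: TemperatureRecord,
                probes: Optional[Sequence[str]] = None,
                specific_heat: float = 4.2, window: float = 30.0,
                method: str = "slope",
                window_sensitivity=(10.0, 30.0, 60.0)) -> SARResult:
    """Multi-probe averaged SAR: mean +- sample SD of per-probe SARs.

    The default probe subset is the stations inside the scaffold
    (C, R, L, T); with a single probe the result equals
    :func:`sar_single` on that probe exactly.
    """
    if probes is None:
        probes = [p for p in DEFAULT_INSIDE_PROBES if p in record.temperatures]
    probes = list(probes)
    if not probes:
        raise EstimationError("no probes selected for SAR averaging")
    missing = [p for p in probes if p not in record.temperatures]
    if missing:
        raise EstimationError(f"record lacks probes {missing}")

    def slopes_for(win):
        out = {}
        errs = {}
        for p in probes:
            if method == "corrected":
                s, e, _ = corrected_slope(record.times, record.temperatures[p],
                                          record.field_off_time)
            else:
                s, e = initial_slope(record.times, record.temperatures[p],
                                     record.field_off_time, win)
            out[p] = s
            errs[p] = e
        return out, errs

    slopes, errs = slopes_for(window)
    sars = {p: sar_single(s, specific_heat) for p, s in slopes.items()}
    vals = np.array(list(sars.values()))
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    sens = {}
    if method == "slope":
        for w in window_sensitivity:
            if w <= record.field_off_time:
                try:
                    s_w, _ = slopes_for(w)
                except EstimationError:
                    continue
                sens[float(w)] = float(np.mean(
                    [sar_single(s, specific_heat) for s in s_w.values()]))
    return SARResult(slopes, errs, sars, mean, sd, len(probes), window,
                     specific_heat, sens)


# ---------------------------------------------------------------------------
# temperature-log CSV (long format written; long or wide accepted)

def record_to_csv(record: TemperatureRecord, path) -> None:
    meta = record.metadata
    with open(path, "w") as fh:
        for key in ("freq_hz", "b0_mT", "cp_J_per_gK"):
            if key in meta:
                fh.write(f"# {key}={meta[key]}\n")
        fh.write(f"# t_off_s={record.field_off_time}\n")
        fh.write("time_s,probe,temp_C\n")
        # repr round-trips doubles exactly, so a written log reloads
        # bit-identically
        for probe, vals in record.temperatures.items():
            for t, v in zip(record.times, vals):
                fh.write(f"{float(t)!r},{probe},{float(v)!r}\n")


def record_from_csv(path) -> TemperatureRecord:
    meta = {}
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_rows += 1
                key, _, val = line[1:].strip().partition("=")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    meta[key.strip()] = val
            else:
                break
    df = pd.read_csv(path, skiprows=header_rows, float_precision="round_trip")
    t_off = float(meta.pop("t_off_s", np.inf))
    if {"time_s", "probe", "temp_C"}.issubset(df.columns):
        wide = df.pivot_table(index="time_s", columns="probe", values="temp_C")
    elif "time_s" in df.columns:
        wide = df.set_index("time_s")
    else:
        raise ValueError("unrecognized temperature-log format")
    wide = wide.sort_index()
    if not np.isfinite(t_off):
        t_off = float(wide.index[-1])
    return TemperatureRecord(wide.index.to_numpy(dtype=float),
                             {str(c): wide[c].to_numpy(dtype=float)
                              for c in wide.columns},
                             t_off, metadata=meta)
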