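"""Wind and flight-coefficient estimation from 1-Hz GPS tracks.

The empirical pipeline mirrors the classical ground-speed-sinusoid method
for soaring seabirds:

1. project latitude/longitude to local East/North meters;
2. cut each individual's track into 300-s segments and differentiate the
   positions into per-sample ground velocity ``(V_x, V_y)``, speed ``V_h``
   and track bearing ``theta_V`` (degrees clockwise from North);
3. within each segment fit ``V_h = V_h_bar + a sin(theta_V) + b cos(theta_V)``
   by ordinary least squares.  The sinusoid amplitude ``W_0 = sqrt(a^2+b^2)``
   is half the max-min spread of the fitted curve — the wind speed felt at
   flight height — and its peak bearing ``theta_W = atan2(a, b)`` is the
   blowing-toward wind direction (ground speed is maximal in pure tailwind);
4. correct the systematic underestimate of the 10-m reference wind with the
   published linear calibration ``W_ref = 1.80 W_0 - 1.42`` and convert to
   mean shear ``sigma_bar = W_ref / (h_ref - h_0)``;
5. recover the air-relative yaw per sample from the wind-triangle
   (law of cosines / sines)::

       U_h = sqrt(V_h^2 + W_ref^2 - 2 V_h W_ref cos(theta_V - theta_W))
       psi = asin(V_h / U_h * sin(theta_V - theta_W))

   and impute the (unobserved) pitch angle from yaw with the linear map
   ``gamma = l(theta) psi - m(theta)``, ``l = 0.00309 theta + 0.02``,
   ``m = 0.00427 theta - 0.47`` (all in degrees) calibrated on optimized
   trajectories at W_ref = 10 m/s;
6. average the per-sample coefficients into segment-level ``eta_bar`` and
   ``epsilon_bar`` (samples with relative travel direction
   ``theta = |theta_V - theta_W|`` outside the crosswind band 60-120 deg are
   excluded);
7. regress each coefficient on ``sigma_bar`` with a linear mixed model
   (per-individual random intercept) to test the trade-off trend.

Altitude is never observed at 1 Hz here, so ``gamma`` is always
model-imputed; segment outputs carry that caveat in their metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "TrackSegment",
    "WindEstimate",
    "SegmentMetrics",
    "TrendFit",
    "PipelineConfig",
    "project_track",
    "segment_track",
    "ground_velocity",
    "fit_wind_sinusoid",
    "estimate_wind",
    "air_relative_yaw",
    "estimate_gamma",
    "segment_metrics",
    "analyze_tracks",
    "fit_trend",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class PipelineConfig:
    """Quality gates and conventions of the track pipeline."""

    window_s: float = 300.0           # segment length
    min_valid_samples: int = 150      # of the nominal 300
    min_bearing_span_deg: float = 90.0
    max_residual_rms: float = 5.0     # m/s, sinusoid-fit RMS gate
    theta_range_deg: tuple = (60.0, 120.0)
    gamma_map_units: str = "deg"      # units of the psi->gamma linear map
    wind_h_ref: float = 10.0
    wind_h_0: float = 0.03

    @property
    def sigma_denominator(self) -> float:
        return self.wind_h_ref - self.wind_h_0


@dataclass
class Track:
    """A single individual's 1-Hz position time series."""

    individual: str
    t: np.ndarray                       # seconds, strictly increasing
    x: np.ndarray                       # East [m]
    y: np.ndarray                       # North [m]
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def gaps(self) -> np.ndarray:
        """Indices after which the sampling interval exceeds 1.5 s."""
        return np.where(np.diff(self.t) > 1.5)[0]


@dataclass
class TrackSegment:
    individual: str
    t0: float
    samples: pd.DataFrame  # columns t, Vx, Vy, Vh, thetaV (deg in [0,360))


@dataclass
class WindEstimate:
    V_h_bar: float
    a: float
    b: float
    W_0: float
    W_ref: float
    theta_W_deg: float
    sigma_bar: float
    residual_rms: float
    n: int
    reject_reason: Optional[str] = None

    @property
    def valid(self) -> bool:
        return self.reject_reason is None


@dataclass
class SegmentMetrics:
    individual: str
    t0: float
    eta_bar: float
    epsilon_bar: float
    mean_theta_deg: float
    retained_fraction: float
    sigma_bar: float
    n_retained: int
    n_asin_clamped: int = 0
    gamma_source: str = "model-imputed (psi->gamma linear map)"


@dataclass
class TrendFit:
    response: str
    slope: float
    slope_se: float
    intercept: float
    p_value: float
    n_individuals: int
    n_segments: int
    model: str = "mixed"           # "mixed" or "pooled-ols" fallback
    random_intercepts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def project_track(individual: str, t, lat=None, lon=None,
                  x=None, y=None) -> Track:
    """Build a :class:`Track`, projecting lat/lon if x/y are not given.

    Uses a local equirectangular projection about the track centroid:
    ``x = R cos(lat0) dlon``, ``y = R dlat`` (radians).  Pre-projected input
    passes through unchanged.
    """
    t = np.asarray(t, dtype=float)
    if x is not None and y is not None:
        return Track(individual, t, np.asarray(x, float), np.asarray(y, float))
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("latitude/longitude out of range")
    if np.ptp(lat) > 2.0 or np.ptp(lon) > 2.0:
        logger.warning("track %s spans > 2 deg; local projection distorts",
                       individual)
    lat0 = lat.mean()
    lon0 = lon.mean()
    xm = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    ym = EARTH_RADIUS_M * np.radians(lat - lat0)
    return Track(individual, t, xm, ym, lat=lat, lon=lon)


def ground_velocity(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Finite-difference ground velocity, speed and bearing per sample.

    ``theta_V`` is the four-quadrant bearing from North in [0, 360) degrees.
    Stationary samples (V_h = 0, bearing undefined) are dropped.
    """
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-positive sampling interval")
    vx = np.diff(x) / dt
    vy = np.diff(y) / dt
    vh = np.hypot(vx, vy)
    keep = vh > 0
    theta_v = np.degrees(np.arctan2(vx[keep], vy[keep])) % 360.0
    return pd.DataFrame({"t": t[:-1][keep], "Vx": vx[keep], "Vy": vy[keep],
                         "Vh": vh[keep], "thetaV": theta_v})


def segment_track(track: Track, cfg: PipelineConfig | None = None) -> List[TrackSegment]:
    """Cut a track into consecutive fixed-length windows of ground velocity."""
    cfg = cfg or PipelineConfig()
    vel = ground_velocity(track.t, track.x, track.y)
    t_start = track.t[0]
    t_end = track.t[-1]
    segments = []
    t0 = t_start
    while t0 + cfg.window_s <= t_end + 1e-9:
        s = vel[(vel.t >= t0) & (vel.t < t0 + cfg.window_s)]
        segments.append(TrackSegment(track.individual, float(t0),
                                     s.reset_index(drop=True)))
        t0 += cfg.window_s
    return segments


# ---------------------------------------------------------------------------
# wind estimation
# ---------------------------------------------------------------------------

def _bearing_span_deg(theta_v: np.ndarray) -> float:
    """Circular span: 360 minus the largest empty arc between bearings."""
    th = np.sort(np.asarray(theta_v) % 360.0)
    if len(th) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([th, [th[0] + 360.0]]))
    return 360.0 - float(gaps.max())


def fit_wind_sinusoid(vh: np.ndarray, theta_v_deg: np.ndarray):
    """OLS fit of V_h on (1, sin theta_V, cos theta_V); returns (V_h_bar, a, b, rms).

    Raises ``ValueError`` on rank deficiency (all bearings equal).
    """
    th = np.radians(np.asarray(theta_v_deg, float))
    X = np.column_stack([np.ones_like(th), np.sin(th), np.cos(th)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("bearing coverage rank-deficient: sinusoid unidentifiable")
    coef, _, _, _ = np.linalg.lstsq(X, np.asarray(vh, float), rcond=None)
    resid = vh - X @ coef
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return float(coef[0]), float(coef[1]), float(coef[2]), rms


def estimate_wind(segment: TrackSegment,
                  cfg: PipelineConfig | None = None) -> WindEstimate:
    """Per-segment wind estimate from the ground-speed sinusoid.

    ``W_0 = sqrt(a^2 + b^2)`` equals half the max-minus-min of the fitted
    sinusoid; ``theta_W`` is the bearing of its maximum (tailwind, i.e. the
    blowing-toward direction); ``W_ref = 1.80 W_0 - 1.42`` is the 10-m
    calibration.  Segments failing the quality gates (sample count, bearing
    span, fit RMS, non-positive W_ref) carry a ``reject_reason``.
    """
    cfg = cfg or PipelineConfig()
    s = segment.samples
    n = len(s)

    def rejected(reason, **kw):
        logger.info("segment %s@%.0f rejected: %s", segment.individual,
                    segment.t0, reason)
        d = dict(V_h_bar=np.nan, a=np.nan, b=np.nan, W_0=np.nan,
                 W_ref=np.nan, theta_W_deg=np.nan, sigma_bar=np.nan,
                 residual_rms=np.nan, n=n, reject_reason=reason)
        d.update(kw)
        return WindEstimate(**d)

    if n < cfg.min_valid_samples:
        return rejected(f"too few samples ({n} < {cfg.min_valid_samples})")
    span = _bearing_span_deg(s.thetaV.to_numpy())
    if span < cfg.min_bearing_span_deg:
        return rejected(f"bearing span {span:.0f} deg < "
                        f"{cfg.min_bearing_span_deg:.0f} deg")
    try:
        vbar, a, b, rms = fit_wind_sinusoid(s.Vh.to_numpy(), s.thetaV.to_numpy())
    except ValueError as err:
        return rejected(str(err))
    if rms > cfg.max_residual_rms:
        return rejected(f"fit residual RMS {rms:.2f} m/s > {cfg.max_residual_rms}")
    W0 = math.hypot(a, b)
    theta_w = math.degrees(math.atan2(a, b)) % 360.0
    W_ref = 1.80 * W0 - 1.42
    if W_ref <= 0:
        return rejected(f"corrected wind non-positive (W_ref = {W_ref:.2f})",
                        V_h_bar=vbar, a=a, b=b, W_0=W0, W_ref=W_ref,
                        theta_W_deg=theta_w, residual_rms=rms)
    return WindEstimate(V_h_bar=vbar, a=a, b=b, W_0=W0, W_ref=W_ref,
                        theta_W_deg=theta_w,
                        sigma_bar=W_ref / cfg.sigma_denominator,
                        residual_rms=rms, n=n)


# ---------------------------------------------------------------------------
# air-relative angles and per-segment coefficients
# ---------------------------------------------------------------------------

def air_relative_yaw(V_h, theta_V_deg, W_ref, theta_W_deg):
    """Air-relative yaw psi [deg] from the wind triangle (principal branch).

    Returns ``(psi_deg, U_h, clamped)`` arrays; ``clamped`` flags samples
    where the asin argument was clipped to [-1, 1] or where the true angle
    lies beyond the principal branch (airspeed pointing downwind of the
    crosswind axis).  Samples with ``U_h = 0`` yield NaN and must be dropped.
    """
    V_h = np.asarray(V_h, float)
    d = np.radians(np.asarray(theta_V_deg, float) - theta_W_deg)
    U_h = np.sqrt(np.maximum(
        V_h ** 2 + W_ref ** 2 - 2 * V_h * W_ref * np.cos(d), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(U_h > 0, V_h * np.sin(d) / np.where(U_h > 0, U_h, 1.0),
                       np.nan)
    clipped = np.abs(arg) > 1.0
    # beyond-branch geometry: airspeed has a downwind component larger than
    # the wind vector, i.e. the angle at the wind vertex exceeds 90 deg
    beyond = (W_ref - V_h * np.cos(d)) < 0.0
    psi = np.degrees(np.arcsin(np.clip(arg, -1.0, 1.0)))
    psi = np.where(U_h > 0, psi, np.nan)
    return psi, U_h, clipped | beyond


def estimate_gamma(psi_deg, theta_deg, units: str = "deg"):
    """Impute pitch from yaw: gamma = l(theta) psi - m(theta).

    ``l = 0.00309 theta + 0.02`` and ``m = 0.00427 theta - 0.47`` with theta
    in degrees.  With ``units='deg'`` (default) psi and gamma are in degrees;
    ``units='rad'`` applies the same map with psi/gamma in radians (the
    published map's units are ambiguous; degrees keep the three angles
    self-consistent).
    """
    theta_deg = np.asarray(theta_deg, float)
    ell = 0.00309 * theta_deg + 0.02
    m = 0.00427 * theta_deg - 0.47
    if units == "deg":
        return ell * np.asarray(psi_deg, float) - m
    if units == "rad":
        return ell * np.radians(np.asarray(psi_deg, float)) - np.radians(m)
    raise ValueError("units must be 'deg' or 'rad'")


def segment_metrics(segment: TrackSegment, wind: WindEstimate,
                    cfg: PipelineConfig | None = None,
                    min_retained: int = 30) -> Optional[SegmentMetrics]:
    """Per-segment eta_bar / epsilon_bar from imputed air-relative angles.

    theta = |theta_V - theta_W| folded to [0, 180] per sample; samples
    outside the crosswind band are excluded.  Returns None (with a log
    record) if the segment retains fewer than ``min_retained`` samples.
    """
    cfg = cfg or PipelineConfig()
    if not wind.valid:
        return None
    s = segment.samples
    psi, U_h, clamped = air_relative_yaw(s.Vh.to_numpy(), s.thetaV.to_numpy(),
                                         wind.W_ref, wind.theta_W_deg)
    theta = np.abs((s.thetaV.to_numpy() - wind.theta_W_deg + 180.0) % 360.0
                   - 180.0)
    lo, hi = cfg.theta_range_deg
    keep = (theta >= lo) & (theta <= hi) & np.isfinite(psi)
    n_keep = int(keep.sum())
    if n_keep < min_retained:
        logger.info("segment %s@%.0f: only %d crosswind samples retained",
                    segment.individual, segment.t0, n_keep)
        return None
    psi_k = psi[keep]
    th_k = theta[keep]
    if cfg.gamma_map_units == "deg":
        gam_k = estimate_gamma(psi_k, th_k, units="deg")
        g_r, p_r, t_r = np.radians(gam_k), np.radians(psi_k), np.radians(th_k)
    else:
        p_r = np.radians(psi_k)
        t_r = np.radians(th_k)
        g_r = estimate_gamma(psi_k, th_k, units="rad")
    eta_bar = float(np.mean(np.sin(2 * g_r) * np.sin(p_r)))
    eps_bar = float(np.mean(np.cos(g_r) * np.sin(p_r + t_r)))
    return SegmentMetrics(
        individual=segment.individual, t0=segment.t0,
        eta_bar=eta_bar, epsilon_bar=eps_bar,
        mean_theta_deg=float(th_k.mean()),
        retained_fraction=n_keep / max(len(s), 1),
        sigma_bar=wind.sigma_bar, n_retained=n_keep,
        n_asin_clamped=int(clamped[keep].sum()))


# ---------------------------------------------------------------------------
# end-to-end and trend model
# ---------------------------------------------------------------------------

def analyze_tracks(tracks: Iterable[Track],
                   cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the full pipeline; one row per segment (rejections included).

    Columns: id, t0, W0, Wref, thetaW_deg, sigma_bar, eta_bar, epsilon_bar,
    n_retained, reject_reason.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for track in tracks:
        for seg in segment_track(track, cfg):
            wind = estimate_wind(seg, cfg)
            row = {"id": seg.individual, "t0": seg.t0, "W0": wind.W_0,
                   "Wref": wind.W_ref, "thetaW_deg": wind.theta_W_deg,
                   "sigma_bar": wind.sigma_bar, "eta_bar": np.nan,
                   "epsilon_bar": np.nan, "n_retained": 0,
                   "reject_reason": wind.reject_reason}
            if wind.valid:
                m = segment_metrics(seg, wind, cfg)
                if m is None:
                    row["reject_reason"] = "too few crosswind samples"
                else:
                    row.update(eta_bar=m.eta_bar, epsilon_bar=m.epsilon_bar,
                               n_retained=m.n_retained)
            rows.append(row)
    return pd.DataFrame(rows)


def fit_trend(segments: pd.DataFrame, response: str = "eta_bar") -> TrendFit:
    """Mixed-model trend of a coefficient on sigma_bar.

    Gaussian linear mixed model ``response ~ sigma_bar`` with a
    per-individual random intercept.  Falls back to pooled OLS (flagged in
    ``model``) when only one individual is present or the random-effects fit
    is singular / fails to converge.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if response not in ("eta_bar", "epsilon_bar"):
        raise ValueError("response must be eta_bar or epsilon_bar")
    d = segments.dropna(subset=[response, "sigma_bar"])[
        ["id", "sigma_bar", response]].rename(columns={response: "y"})
    if len(d) < 10:
        raise ValueError(f"need >= 10 usable segments, have {len(d)}")
    n_ind = d["id"].nunique()
    if d["y"].nunique() == 1:
        return TrendFit(response=response, slope=0.0, slope_se=0.0,
                        intercept=float(d["y"].iloc[0]), p_value=1.0,
                        n_individuals=n_ind, n_segments=len(d),
                        model="degenerate-constant")

    def pooled():
        X = sm.add_constant(d["sigma_bar"])
        res = sm.OLS(d["y"], X).fit()
        logger.warning("trend fit for %s downgraded to pooled OLS", response)
        return TrendFit(response=response,
                        slope=float(res.params["sigma_bar"]),
                        slope_se=float(res.bse["sigma_bar"]),
                        intercept=float(res.params["const"]),
                        p_value=float(res.pvalues["sigma_bar"]),
                        n_individuals=n_ind, n_segments=len(d),
                        model="pooled-ols")

    if n_ind < 2:
        return pooled()
    try:
        md = smf.mixedlm("y ~ sigma_bar", d, groups=d["id"])
        res = md.fit(reml=True, method="lbfgs")
        if not np.isfinite(res.bse["sigma_bar"]) or res.bse["sigma_bar"] == 0:
            return pooled()
        re = {k: float(v.iloc[0]) for k, v in res.random_effects.items()}
        return TrendFit(response=response,
                        slope=float(res.params["sigma_bar"]),
                        slope_se=float(res.bse["sigma_bar"]),
                        intercept=float(res.params["Intercept"]),
                        p_value=float(res.pvalues["sigma_bar"]),
                        n_individuals=n_ind, n_segments=len(d),
                        model="mixed", random_intercepts=re)
    except (np.linalg.LinAlgError, ValueError):
        return pooled()
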