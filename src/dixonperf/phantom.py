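"""Synthetic dynamic multi-echo first-pass cardiac perfusion phantom.

Generates a seedable 2D short-axis phantom with full ground truth for
testing the motion-correction and quantification pipeline: first-pass
contrast enhancement of the right/left ventricles and myocardium, a
static epicardial fat layer, rigid plus smooth non-rigid respiratory
motion, and a three-echo saturation-recovery spoiled gradient-echo
signal with fat off-resonance and gadolinium-dependent T2* decay.

The signal model per pixel and echo ``n`` is::

    S_n = [ W e^(-TE_n R2*_w) + F e^(-TE_n R2*_f) e^(i 2π Δf_fat TE_n) ] e^(i 2π ψ TE_n)
    W   = PD_w sin(α) (1 - e^(-TD R1_w)),   R1_w = 1/T1_0 + r1 C,  R2*_w = 1/T2*_0 + r2* C
    F   = PD_f sin(α) (1 - e^(-TD R1_f))

Gadolinium enhances only the water relaxation rates; the fat
magnetisation is unaffected, which is the property the fat-guided
rigid registration relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Dict, List, Optional, Tuple

import numpy as np

from .kinetics import ConcentrationCurve, KineticParams, twocxm_forward
from .series import DynamicEchoSeries
from .transforms import rigid_matrix

__all__ = [
    "AifParams", "TissueProps", "MotionTrajectory", "PhantomSpec",
    "PhantomTruth", "gamma_variate_aif", "simulate_signal", "apply_motion",
    "make_phantom", "DEFAULT_TISSUES",
]

LABELS = {"background": 0, "body": 1, "rv": 2, "lv": 3, "myo": 4,
          "epi_fat": 5, "chest_fat": 6}


@dataclass
class AifParams:
    """Gamma-variate bolus shape, peak-normalised.

    ``c(t) = amplitude * (τ/(shape*washout))**shape * exp(shape - τ/washout)``
    with ``τ = t - delay``; the peak equals ``amplitude`` (mM) at
    ``τ = shape*washout`` seconds after arrival.
    """

    amplitude: float = 3.0   # mM, main-bolus peak (rest, 0.05 mmol/kg scale)
    delay: float = 35.0      # s, main-bolus arrival in the LV
    shape: float = 3.0
    washout: float = 1.5     # s; time-to-peak = shape*washout = 4.5 s, a
                             # realistic first-pass LV upstroke
    prebolus_delay: float = 5.0  # s, pre-bolus arrival
    rv_lead: float = 3.0     # s, RV enhancement precedes the LV

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.washout <= 0:
            raise ValueError("gamma-variate shape parameters must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class TissueProps:
    """Baseline relaxation and proton-density properties of one tissue."""

    t1: float      # ms
    t2s: float     # ms (np.inf allowed: no decay across echoes)
    pd_water: float
    pd_fat: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2s <= 0:
            raise ValueError("baseline T1 and T2* must be positive")


DEFAULT_TISSUES: Dict[str, TissueProps] = {
    "background": TissueProps(t1=1000.0, t2s=30.0, pd_water=0.0),
    "body": TissueProps(t1=1000.0, t2s=25.0, pd_water=0.5),
    "rv": TissueProps(t1=1900.0, t2s=30.0, pd_water=1.0),
    "lv": TissueProps(t1=1900.0, t2s=30.0, pd_water=1.0),
    "myo": TissueProps(t1=1500.0, t2s=30.0, pd_water=1.0),
    "epi_fat": TissueProps(t1=380.0, t2s=40.0, pd_water=0.0, pd_fat=0.9),
    "chest_fat": TissueProps(t1=380.0, t2s=40.0, pd_water=0.0, pd_fat=0.9),
}


@dataclass
class MotionTrajectory:
    """Per-frame rigid motion plus an optional smooth dense component.

    ``tx, ty`` in pixels, ``theta`` in radians.  The dense component is a
    separable low-frequency displacement mode scaled per frame by a
    sinusoid; it vanishes at the image border and its Jacobian deviation
    from identity is bounded by ``π * nonrigid_amplitude / grid``.
    """

    tx: np.ndarray
    ty: np.ndarray
    theta: np.ndarray
    nonrigid_amplitude: float = 0.0
    period: float = 5.0
    nonrigid_phase: float = 0.9

    def __post_init__(self) -> None:
        self.tx = np.asarray(self.tx, float)
        self.ty = np.asarray(self.ty, float)
        self.theta = np.asarray(self.theta, float)
        if not (self.tx.shape == self.ty.shape == self.theta.shape):
            raise ValueError("tx, ty, theta must have equal lengths")
        if not np.all(np.isfinite(self.tx)) or not np.all(np.isfinite(self.ty)) \
                or not np.all(np.isfinite(self.theta)):
            raise ValueError("trajectory contains non-finite values")

    def __len__(self) -> int:
        return self.tx.size

    @classmethod
    def static(cls, n_frames: int) -> "MotionTrajectory":
        z = np.zeros(n_frames)
        return cls(z, z.copy(), z.copy())

    @classmethod
    def sinusoidal(cls, n_frames: int, trans_amplitude: Tuple[float, float] = (1.5, 5.0),
                   rot_amplitude_deg: float = 3.0, period: float = 5.0,
                   phase: float = 0.0, nonrigid_amplitude: float = 0.0) -> "MotionTrajectory":
        """Sinusoidal free-breathing motion: head–foot dominant translation
        (``ty``), smaller in-plane ``tx``, rotation in degrees, breathing
        period in frames."""
        t = np.arange(n_frames, dtype=float)
        w = 2 * np.pi / period
        tx = trans_amplitude[0] * np.sin(w * t + phase + 0.4)
        ty = trans_amplitude[1] * np.sin(w * t + phase)
        th = np.deg2rad(rot_amplitude_deg) * np.sin(w * t + phase + 1.1)
        return cls(tx, ty, th, nonrigid_amplitude=nonrigid_amplitude, period=period)

    def dense_field(self, frame: int, shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
        """Dense (dy, dx) displacement of the given frame, in pixels."""
        ny, nx = shape
        if self.nonrigid_amplitude == 0:
            z = np.zeros(shape)
            return z, z.copy()
        a = self.nonrigid_amplitude * np.sin(
            2 * np.pi * frame / self.period + self.nonrigid_phase)
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        my = np.sin(np.pi * yy / (ny - 1)) * np.sin(np.pi * xx / (nx - 1))
        dy = a * my * np.sin(2 * np.pi * xx / (nx - 1))
        dx = 0.6 * a * my * np.cos(2 * np.pi * yy / (ny - 1))
        return dy, dx


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition."""

    grid_size: int = 128
    pixel_spacing: float = 2.5          # mm
    n_frames: int = 80
    frame_interval: float = 1.0         # s
    echo_times: Tuple[float, ...] = (1.0, 1.9, 2.8)  # ms (TE1 1.0, ΔTE 0.9)
    flip_angle: float = 14.0            # degrees
    saturation_delay: float = 75.0      # ms
    fat_offset: float = -434.0          # Hz at 3 T
    r1: float = 4.5                     # L mmol^-1 s^-1
    r2s: float = 6.0                    # L mmol^-1 s^-1
    tissues: Dict[str, TissueProps] = dfield(default_factory=lambda: dict(DEFAULT_TISSUES))
    motion: Optional[MotionTrajectory] = None
    noise_sd: float = 0.0               # fraction of myocardial baseline signal
    seed: int = 0
    aif_params: AifParams = dfield(default_factory=AifParams)
    tissue_params: Optional[List[KineticParams]] = None  # per myocardial sector
    n_sectors: int = 6
    dilution: float = 0.1
    psi: float = 0.0                    # background field map, Hz

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, float)
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if not (0 < self.dilution <= 1):
            raise ValueError("dilution must lie in (0, 1]")
        if self.tissue_params is None:
            # rest myocardium: Fb 1 mL/min/g; vp ~ plasma fraction of a ~10%
            # blood volume; PS set so the first-pass gadolinium extraction
            # 1 - exp(-PS/Fp) is ~0.6, in line with Gd-DTPA literature
            self.tissue_params = [KineticParams.from_fb(1.0, 0.06, 0.2, 0.5)
                                  for _ in range(self.n_sectors)]
        if len(self.tissue_params) != self.n_sectors:
            raise ValueError("tissue_params must have one entry per sector")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PhantomTruth:
    """Ground truth accompanying one phantom realisation."""

    labels: np.ndarray                 # uint8 label image
    sector_labels: np.ndarray          # 0 outside myo, 1..n_sectors inside
    aif_true: ConcentrationCurve       # undistorted main-bolus AIF (mM)
    aif_total: ConcentrationCurve      # pre-bolus + main bolus, as seen by tissue
    rv_curve: ConcentrationCurve
    tissue_curves: List[ConcentrationCurve]
    mbf: np.ndarray                    # true Fb per pixel (NaN outside myo)
    trajectory: MotionTrajectory
    m0_blood: np.ndarray               # true LV blood-pool M0(t), signal units
    t2s_blood: np.ndarray              # true LV blood-pool T2*(t), ms
    spec: PhantomSpec = None           # type: ignore[assignment]

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    @property
    def myo_mask(self) -> np.ndarray:
        return self.mask("myo")

    @property
    def lv_mask(self) -> np.ndarray:
        return self.mask("lv")

    @property
    def heart_mask(self) -> np.ndarray:
        return self.mask("lv") | self.mask("myo")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def gamma_variate_aif(params: AifParams, frame_times: np.ndarray,
                      delay: Optional[float] = None,
                      amplitude: Optional[float] = None) -> np.ndarray:
    """Peak-normalised gamma-variate bolus curve on the given time grid (mM)."""
    if params.shape <= 0 or params.washout <= 0:
        raise ValueError("gamma-variate shape parameters must be positive")
    t = np.asarray(frame_times, float)
    d = params.delay if delay is None else delay
    a = params.amplitude if amplitude is None else amplitude
    tau = t - d
    out = np.zeros_like(t)
    pos = tau > 0
    tp = params.shape * params.washout
    out[pos] = a * (tau[pos] / tp) ** params.shape * np.exp(params.shape - tau[pos] / params.washout)
    return out


def simulate_signal(conc: np.ndarray, spec: PhantomSpec, pd_water: np.ndarray,
                    pd_fat: np.ndarray, t1_map: np.ndarray, t2s_map: np.ndarray,
                    fat_t1: float = 380.0, fat_t2s: float = 40.0,
                    psi: Optional[np.ndarray] = None) -> DynamicEchoSeries:
    """Render complex three-echo signal from concentration maps.

    ``conc`` is (n_frames, ny, nx) in mM and must be non-negative.  The
    relaxivity maps apply to the water component only; fat magnetisation
    is independent of gadolinium.
    """
    conc = np.asarray(conc, float)
    if np.any(conc < 0):
        raise ValueError("concentration maps must be non-negative")
    te = np.asarray(spec.echo_times, float)          # ms
    td = spec.saturation_delay                       # ms
    sina = np.sin(np.deg2rad(spec.flip_angle))
    r1_ms = spec.r1 / 1000.0                         # per ms per mM
    r2s_ms = spec.r2s / 1000.0
    nt = conc.shape[0]
    ny, nx = conc.shape[1:]
    psi_map = np.zeros((ny, nx)) if psi is None else np.asarray(psi, float)

    r1_w = 1.0 / t1_map[None] + r1_ms * conc          # (t, y, x)
    r2s_w = 1.0 / t2s_map[None] + r2s_ms * conc
    w = pd_water[None] * sina * (-np.expm1(-td * r1_w))
    f = pd_fat * sina * (-np.expm1(-td / fat_t1))     # (y, x), static

    data = np.empty((nt, te.size, ny, nx), dtype=complex)
    for n, te_n in enumerate(te):
        fat_phase = np.exp(1j * 2 * np.pi * spec.fat_offset * te_n * 1e-3)
        psi_phase = np.exp(1j * 2 * np.pi * psi_map * te_n * 1e-3)
        data[:, n] = (w * np.exp(-te_n * r2s_w)
                      + f * np.exp(-te_n / fat_t2s) * fat_phase) * psi_phase
    return DynamicEchoSeries(data, te, spec.frame_times, spec.pixel_spacing)


def apply_motion(series: DynamicEchoSeries, trajectory: MotionTrajectory,
                 interpolation: str = "linear", background: float = 0.0) -> DynamicEchoSeries:
    """Move every frame of the series along the trajectory.

    Frame ``t`` content is displaced by ``(tx, ty, theta)`` (rotation
    about the image centre) and then by the dense field; all echoes of a
    frame share the same motion.  Out-of-grid samples take the
    ``background`` value.
    """
    if len(trajectory) != series.n_frames:
        raise ValueError("trajectory length must equal the number of frames")
    order = {"nearest": 0, "linear": 1}[interpolation]
    ny, nx = series.data.shape[2:]
    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    out = np.empty_like(series.data)
    from scipy import ndimage

    for tix in range(series.n_frames):
        p = (trajectory.tx[tix], trajectory.ty[tix], trajectory.theta[tix])
        m = np.linalg.inv(rigid_matrix(p, center))
        dy, dx = trajectory.dense_field(tix, (ny, nx))
        # content displaced by d: sample the source at x - d, then rigidly
        ys = yy - dy
        xs = xx - dx
        cy = m[0, 0] * ys + m[0, 1] * xs + m[0, 2]
        cx = m[1, 0] * ys + m[1, 1] * xs + m[1, 2]
        for e in range(series.n_echoes):
            img = series.data[tix, e]
            if np.iscomplexobj(img):
                re = ndimage.map_coordinates(img.real, [cy, cx], order=order,
                                             mode="constant", cval=background)
                im = ndimage.map_coordinates(img.imag, [cy, cx], order=order,
                                             mode="constant", cval=0.0)
                out[tix, e] = re + 1j * im
            else:
                out[tix, e] = ndimage.map_coordinates(img, [cy, cx], order=order,
                                                      mode="constant", cval=background)
    return DynamicEchoSeries(out, series.echo_times.copy(), series.frame_times.copy(),
                             series.pixel_spacing)


def _geometry(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Label and sector-label images for the short-axis phantom."""
    n = spec.grid_size
    s = n / 128.0
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(yy - c, xx - c)
    labels = np.zeros((n, n), dtype=np.uint8)

    body = ((yy - c) / (0.40 * n)) ** 2 + ((xx - c) / (0.46 * n)) ** 2 <= 1.0
    labels[body] = LABELS["body"]

    chest = body & (yy > c - 0.38 * n) & (yy < c - 0.33 * n)
    labels[chest] = LABELS["chest_fat"]

    lv_r, myo_r = 10 * s, 16 * s
    # epicardial fat is patchy: discrete arcs of varying thickness with real
    # gaps, as on a short-axis slice (and what makes rotation observable to
    # the fat-guided registration)
    ang0 = np.arctan2(yy - c, xx - c)
    thick = (4.0 * np.maximum(0.0, np.cos(ang0 - 0.6))
             + 2.5 * np.maximum(0.0, np.cos(2 * ang0 + 1.2)) - 0.8) * s
    labels[(r > myo_r) & (r <= myo_r + thick)] = LABELS["epi_fat"]
    # pericardial fat pad anterior to the RV
    pad = np.hypot(yy - (c + 14 * s), xx - (c - 22 * s)) <= 4 * s
    labels[pad & (labels == LABELS["body"])] = LABELS["epi_fat"]
    labels[(r > lv_r) & (r <= myo_r)] = LABELS["myo"]
    labels[r <= lv_r] = LABELS["lv"]

    # RV blood pool abuts the septum (shares a border with the myocardium)
    rv = np.hypot(yy - c, xx - (c - 24 * s)) <= 8.5 * s
    rv &= labels != LABELS["myo"]
    rv &= labels != LABELS["lv"]
    labels[rv] = LABELS["rv"]

    myo = labels == LABELS["myo"]
    ang = np.arctan2(yy - c, xx - c)  # (-pi, pi]
    sector = np.zeros((n, n), dtype=np.uint8)
    k = np.floor((ang + np.pi) / (2 * np.pi) * spec.n_sectors).astype(int)
    k = np.clip(k, 0, spec.n_sectors - 1)
    sector[myo] = k[myo] + 1
    return labels, sector


def make_phantom(spec: PhantomSpec) -> Tuple[DynamicEchoSeries, PhantomTruth]:
    """Generate one phantom realisation plus its ground truth.

    Tissue concentration curves are exact 2CXM forward solutions for the
    per-sector kinetic parameters driven by the total (pre-bolus + main)
    AIF; the pre-bolus is the main bolus scaled by ``dilution`` and
    injected earlier in the timeline.
    """
    t = spec.frame_times
    ap = spec.aif_params

    main = gamma_variate_aif(ap, t)
    pre = gamma_variate_aif(ap, t, delay=ap.prebolus_delay,
                            amplitude=ap.amplitude * spec.dilution)
    total = pre + main
    rv_total = (gamma_variate_aif(ap, t, delay=ap.delay - ap.rv_lead)
                + gamma_variate_aif(ap, t, delay=ap.prebolus_delay - ap.rv_lead,
                                    amplitude=ap.amplitude * spec.dilution))

    aif_total = ConcentrationCurve(t, total, role="aif")
    tissue_curves = [twocxm_forward(p, aif_total) for p in spec.tissue_params]

    labels, sectors = _geometry(spec)
    n = spec.grid_size
    conc = np.zeros((spec.n_frames, n, n))
    conc[:, labels == LABELS["lv"]] = total[:, None]
    conc[:, labels == LABELS["rv"]] = rv_total[:, None]
    for k, curve in enumerate(tissue_curves):
        conc[:, sectors == k + 1] = curve.value[:, None]

    t1 = np.full((n, n), 1000.0)
    t2s = np.full((n, n), 30.0)
    pdw = np.zeros((n, n))
    pdf = np.zeros((n, n))
    for name, lab in LABELS.items():
        props = spec.tissues[name]
        sel = labels == lab
        t1[sel] = props.t1
        t2s[sel] = props.t2s
        pdw[sel] = props.pd_water
        pdf[sel] = props.pd_fat
    fat_props = spec.tissues["epi_fat"]

    psi_map = np.full((n, n), float(spec.psi))
    series = simulate_signal(conc, spec, pdw, pdf, t1, t2s,
                             fat_t1=fat_props.t1, fat_t2s=fat_props.t2s,
                             psi=psi_map)

    # blood-pool ground truth for the T2* module
    blood = spec.tissues["lv"]
    sina = np.sin(np.deg2rad(spec.flip_angle))
    r1_t = 1.0 / blood.t1 + spec.r1 / 1000.0 * total
    m0_blood = blood.pd_water * sina * (-np.expm1(-spec.saturation_delay * r1_t))
    with np.errstate(divide="ignore"):
        t2s_blood = 1.0 / (1.0 / blood.t2s + spec.r2s / 1000.0 * total)

    trajectory = spec.motion if spec.motion is not None else MotionTrajectory.static(spec.n_frames)
    if spec.motion is not None:
        series = apply_motion(series, trajectory)

    if spec.noise_sd > 0:
        myo = spec.tissues["myo"]
        base = myo.pd_water * sina * (-np.expm1(-spec.saturation_delay / myo.t1)) \
            * np.exp(-spec.echo_times[0] / myo.t2s)
        sigma = spec.noise_sd * base
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0, sigma, series.data.shape) \
            + 1j * rng.normal(0, sigma, series.data.shape)
        series = DynamicEchoSeries(series.data + noise, series.echo_times,
                                   series.frame_times, series.pixel_spacing)

    mbf = np.full((n, n), np.nan)
    for k, p in enumerate(spec.tissue_params):
        mbf[sectors == k + 1] = p.fb

    truth = PhantomTruth(
        labels=labels, sector_labels=sectors,
        aif_true=ConcentrationCurve(t, main, role="aif_main"),
        aif_total=aif_total,
        rv_curve=ConcentrationCurve(t, rv_total, role="aif"),
        tissue_curves=tissue_curves, mbf=mbf, trajectory=trajectory,
        m0_blood=m0_blood, t2s_blood=t2s_blood, spec=spec,
    )
    return series, truth
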