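"""FRAP recovery fitting, DNA-curtain compaction rates, and the
nuclear-concentration estimate.

FRAP traces are double-normalized (background-subtracted, reference-
corrected, pre-bleach-scaled) and fitted with a single-exponential recovery
I(t) = Io + (Ie - Io)(1 - exp(-t/tau)).  The mobile fraction is
Mf = (Ie - Io)/(Ipre - Io), the half-time t1/2 = tau*ln2, and the apparent
diffusion coefficient uses the circular-bleach half-time approximation
D = 0.88 r^2 / (4 t1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import ValidationError


@dataclass
class FrapTrace:
    """Raw FRAP intensities; bleach at t = 0, >= 3 pre-bleach samples."""

    time_s: np.ndarray
    bleached: np.ndarray
    background: np.ndarray | None = None
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.sum(self.time_s < 0) < 3:
            raise ValidationError("need >= 3 pre-bleach samples (t < 0)")
        for name in ("background", "reference"):
            v = getattr(self, name)
            if v is not None:
                arr = np.asarray(v, dtype=float)
                if arr.shape != self.time_s.shape:
                    raise ValidationError(f"{name} length mismatch")
                setattr(self, name, arr)


@dataclass
class FrapFit:
    """Fitted single-exponential FRAP recovery parameters."""

    tau_s: float
    t_half_s: float
    mobile_fraction: float
    Io: float
    Ie: float
    apparent_D_um2_s: float | None
    bleach_radius_um: float | None
    rss: float
    degenerate: bool = False
    clipped: bool = False


def mobile_fraction(Ie: float, Io: float, Ipre: float) -> float:
    """Mf = (Ie - Io) / (Ipre - Io)."""
    if Ipre == Io:
        raise ValidationError("Ipre equals Io; mobile fraction undefined")
    if Ipre < Io:
        raise ValidationError("Ipre must exceed Io")
    return (Ie - Io) / (Ipre - Io)


def normalize_frap(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Double normalization of a FRAP trace.

    I_norm(t) = [(I_bleach - I_bg) / (I_ref - I_bg)] / mean of the same
    ratio over the pre-bleach samples.  With no background the subtraction
    is skipped; with no reference the denominator is 1 (single
    normalization).  Dividing by the reference cancels acquisition
    bleaching common to both ROIs.  Returns (time_s, normalized).
    """
    bg = trace.background if trace.background is not None else 0.0
    sig = trace.bleached - bg
    if trace.reference is not None:
        ref = trace.reference - bg
        if np.any(ref <= 0):
            raise ValidationError("reference <= background; cannot normalize")
        ratio = sig / ref
    else:
        ratio = sig
    pre = trace.time_s < 0
    pre_mean = ratio[pre].mean()
    if pre_mean <= 0:
        raise ValidationError("non-positive pre-bleach mean")
    return trace.time_s, ratio / pre_mean


def fit_frap_recovery(time_s: np.ndarray, normalized: np.ndarray,
                      bleach_radius_um: float | None = None,
                      Ipre: float = 1.0) -> FrapFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Fits I(t) = Io + (Ie - Io)(1 - exp(-t/tau)) to the t >= 0 samples of a
    normalized trace.  A plateau within 1% of the bleach floor is flagged
    degenerate; Mf outside [0, 1] is clipped and flagged.
    """
    time_s = np.asarray(time_s, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    post = time_s >= 0
    t = time_s[post]
    y = normalized[post]
    if len(t) < 8:
        raise ValidationError("need >= 8 post-bleach points")

    def model(t, Io, Ie, tau):
        return Io + (Ie - Io) * (1.0 - np.exp(-t / tau))

    Io0 = float(y[0])
    Ie0 = float(np.mean(y[-max(3, len(y) // 5):]))
    tau0 = max(float(t[len(t) // 2]), 1e-3)
    try:
        popt, _ = curve_fit(model, t, y, p0=(Io0, max(Ie0, Io0 + 1e-6), tau0),
                            bounds=([-np.inf, -np.inf, 1e-9],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise ValidationError(f"FRAP fit did not converge: {exc}") from exc
    Io, Ie, tau = map(float, popt)
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    degenerate = abs(Ie - Io) < 0.01 * max(abs(Ipre - Io), 1e-12)
    mf = mobile_fraction(Ie, Io, Ipre) if Ipre > Io else np.nan
    clipped = False
    if np.isfinite(mf) and not (0.0 <= mf <= 1.0):
        mf = float(np.clip(mf, 0.0, 1.0))
        clipped = True
    t_half = tau * np.log(2.0)
    D = None
    if bleach_radius_um is not None:
        D = 0.88 * bleach_radius_um ** 2 / (4.0 * t_half)
    return FrapFit(tau_s=tau, t_half_s=t_half, mobile_fraction=float(mf),
                   Io=Io, Ie=Ie, apparent_D_um2_s=D,
                   bleach_radius_um=bleach_radius_um, rss=rss,
                   degenerate=degenerate, clipped=clipped)


# ---------------------------------------------------------------------------
# DNA-curtain compaction
# ---------------------------------------------------------------------------

@dataclass
class Kymograph:
    """Frames x positions intensity matrix from a single DNA molecule.

    The anchored (barrier) end of the DNA sits at pixel 0; the free end is
    the farthest supra-threshold pixel in each frame.
    """

    intensity: np.ndarray
    pixel_nm: float
    dt_s: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValidationError("kymograph must be a 2D matrix")
        if self.pixel_nm <= 0 or self.dt_s <= 0:
            raise ValidationError("pixel_nm and dt_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]


def track_dna_end(kymo: Kymograph, intensity_threshold: float) -> np.ndarray:
    """Per-frame position (px) of the farthest supra-threshold pixel.

    Frames with no supra-threshold pixel give NaN.
    """
    mask = kymo.intensity >= intensity_threshold
    ends = np.full(kymo.n_frames, np.nan)
    for f in range(kymo.n_frames):
        idx = np.nonzero(mask[f])[0]
        if len(idx):
            ends[f] = idx[-1]
    return ends


def compaction_rate(kymo: Kymograph, intensity_threshold: float,
                    fit_window: tuple[int, int] | None = None
                    ) -> tuple[float, np.ndarray]:
    """|slope| of the tracked DNA-end position (nm) against time (s).

    The end position is the farthest supra-threshold pixel from the anchor
    in each frame; the rate is the absolute least-squares slope over
    ``fit_window`` (frame range, default all frames).  Returns
    ``(rate_nm_s, end_track_px)``.
    """
    ends = track_dna_end(kymo, intensity_threshold)
    lo, hi = fit_window if fit_window is not None else (0, kymo.n_frames)
    sel = ends[lo:hi]
    frames = np.arange(lo, hi)
    valid = ~np.isnan(sel)
    if valid.sum() < 3:
        raise ValidationError("need >= 3 frames with a detectable DNA end")
    if valid.mean() < 0.9:
        warnings.warn("DNA end undetected in >10% of fitted frames")
    t = frames[valid] * kymo.dt_s
    pos_nm = sel[valid] * kymo.pixel_nm
    slope = np.polyfit(t, pos_nm, 1)[0]
    return float(abs(slope)), ends


# ---------------------------------------------------------------------------
# nuclear concentration worked example
# ---------------------------------------------------------------------------

AVOGADRO = 6.02214076e23


def nuclear_concentration(total_mass_ng: float, n_cells: int, mw_kda: float,
                          nucleus_diameter_um: float) -> float:
    """Nuclear concentration (nM) of a protein from bulk mass per cell.

    Per-cell protein mass is converted to moles via the molecular weight and
    divided by the volume of a spherical nucleus of the given diameter:
    C = ((m/n)/MW) / ((4/3) pi (d/2)^3).
    """
    if n_cells <= 0 or mw_kda <= 0 or nucleus_diameter_um <= 0:
        raise ValidationError("cells, molecular weight and diameter must be "
                              "positive")
    if total_mass_ng < 0:
        raise ValidationError("mass must be non-negative")
    grams_per_cell = total_mass_ng * 1e-9 / n_cells
    mol_per_cell = grams_per_cell / (mw_kda * 1e3)
    radius_dm = nucleus_diameter_um * 1e-5 / 2.0   # um -> dm, so volume in L
    volume_l = 4.0 / 3.0 * np.pi * radius_dm ** 3
    return float(mol_per_cell / volume_l * 1e9)
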