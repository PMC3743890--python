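"""Water-fat separation of multi-echo gradient-echo images (Dixon method).

The acquisition model per voxel, for echo time ``TE_n``, is

    S_n = (rho_w + rho_f * exp(2j*pi*df_fat*TE_n)) * exp(2j*pi*psi*TE_n)

with complex water/fat amplitudes ``rho_w``, ``rho_f`` (the shared initial
phase phi0 is absorbed into them), chemical-shift frequency ``df_fat`` and
B0 off-resonance ``psi`` (Hz).  Reconstruction proceeds in two stages:

1. :func:`estimate_fieldmap` — a phase-difference estimate of ``psi`` from a
   like-phase echo pair (fat phase differing by a whole number of cycles),
   spatially unwrapped and anchored, then refined by per-voxel Gauss-Newton
   iterations on the full nonlinear model (an IDEAL-style descent).
2. :func:`separate_water_fat` — after demodulating ``exp(-2j*pi*psi*TE_n)``,
   a linear least-squares solve for ``rho_w``, ``rho_f`` at arbitrary echo
   times; :func:`two_point_separate` provides the classical in/opposed-phase
   two-echo path with a spatially smoothed field phase.

The fat fraction is the magnitude ratio ``FF = 100*F/(W+F)`` with
``W = |rho_w|``, ``F = |rho_f|``; voxels whose total signal falls below a
noise floor are marked invalid rather than reported as zero.

A :class:`DixonModel` wraps both stages in a fit/results interface::

    res = DixonModel(image, method="3pt").fit()
    res.fat_fraction.ff      # percent map
    res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase

__all__ = [
    "MultiEchoImage",
    "FieldMap",
    "FatFractionMap",
    "CollinearEchoError",
    "estimate_fieldmap",
    "separate_water_fat",
    "two_point_separate",
    "fat_fraction_map",
    "estimate_noise_sd",
    "DixonModel",
    "DixonResults",
]


class CollinearEchoError(ValueError):
    """Echo times make the water and fat model columns collinear."""


@dataclass
class MultiEchoImage:
    """Complex multi-echo image stack on a single 2D grid.

    ``data`` has shape (n_echoes, ny, nx); ``echo_times`` are in seconds,
    strictly increasing.
    """

    data: np.ndarray
    echo_times: np.ndarray
    field_strength_t: float = 3.0
    voxel_size_mm: tuple[float, float] = (1.0, 1.0)
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_echoes, ny, nx)")
        if self.echo_times.ndim != 1 or self.echo_times.size != self.data.shape[0]:
            raise ValueError("echo_times must match the number of echo images")
        if self.echo_times.size < 2:
            raise ValueError("at least 2 echoes are required")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be strictly increasing")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def fat_frequency(self) -> float:
        """Chemical-shift frequency in Hz (metadata override or 3.4 ppm)."""
        if "fat_freq_hz" in self.meta and self.meta["fat_freq_hz"] is not None:
            return float(self.meta["fat_freq_hz"])
        return 42.576e6 * self.field_strength_t * 3.4e-6

    def select_echoes(self, indices) -> "MultiEchoImage":
        idx = list(indices)
        return MultiEchoImage(
            data=self.data[idx],
            echo_times=self.echo_times[idx],
            field_strength_t=self.field_strength_t,
            voxel_size_mm=self.voxel_size_mm,
            meta=dict(self.meta),
        )


@dataclass
class FieldMap:
    """Per-voxel B0 off-resonance in Hz with a validity mask."""

    psi_hz: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.psi_hz = np.asarray(self.psi_hz, float)
        self.valid = np.asarray(self.valid, bool)
        if self.psi_hz.shape != self.valid.shape:
            raise ValueError("psi_hz and valid must share a shape")


@dataclass
class FatFractionMap:
    """Per-voxel fat fraction in percent with provenance.

    ``ff`` is in [0, 100] where ``valid``; voxels whose total water+fat
    amplitude fell below the signal floor are invalid (ff is NaN there).
    """

    ff: np.ndarray
    valid: np.ndarray
    method: str
    echo_times: np.ndarray
    signal_floor: float = 0.0

    def __post_init__(self) -> None:
        self.ff = np.asarray(self.ff, float)
        self.valid = np.asarray(self.valid, bool)
        bad = self.valid & (~np.isfinite(self.ff) | (self.ff < 0) | (self.ff > 100))
        if bad.any():
            raise ValueError("valid fat fractions must lie in [0, 100]")


def estimate_noise_sd(img: MultiEchoImage, background_quantile: float = 0.1) -> float:
    """Per-channel noise SD estimated from the lowest-magnitude voxels.

    The lowest ``background_quantile`` of mean echo magnitudes is taken as
    background; the SD of real/imaginary parts there estimates the channel
    noise.  Returns 0.0 for a noiseless image.
    """
    mag = np.abs(img.data).mean(axis=0)
    thr = np.quantile(mag, background_quantile)
    bg = mag <= thr
    if not bg.any():
        return 0.0
    # std per echo and channel so constant signal does not read as noise
    stds = [
        s
        for n in range(img.n_echoes)
        for s in (img.data[n, bg].real.std(), img.data[n, bg].imag.std())
    ]
    return float(np.mean(stds))


def _model_matrix(echo_times: np.ndarray, fat_freq: float) -> np.ndarray:
    a = np.exp(2j * np.pi * fat_freq * np.asarray(echo_times, float))
    return np.column_stack([np.ones_like(a), a])


def _check_conditioning(echo_times: np.ndarray, fat_freq: float) -> None:
    g = _model_matrix(echo_times, fat_freq)
    cond = np.linalg.cond(g)
    if not np.isfinite(cond) or cond > 1e8:
        tes = ", ".join(f"{t * 1e3:.3f} ms" for t in np.asarray(echo_times))
        raise CollinearEchoError(
            f"echo times ({tes}) give collinear water/fat model columns at "
            f"fat frequency {fat_freq:.1f} Hz (condition number {cond:.2g}); "
            "fat phase advances by a whole number of cycles between echoes"
        )


def _phase_pair(echo_times: np.ndarray, fat_freq: float) -> tuple[int, int, float]:
    """Pick the echo pair whose fat phase difference is closest to a whole
    number of cycles; returns (i, j, cycle residual)."""
    best = None
    n = len(echo_times)
    for i in range(n):
        for j in range(i + 1, n):
            c = fat_freq * (echo_times[j] - echo_times[i])
            resid = abs(c - round(c))
            if best is None or resid < best[2]:
                best = (i, j, resid)
    return best


def _candidate_score(
    img: MultiEchoImage, psi: np.ndarray, valid: np.ndarray, fat_freq: float
) -> float:
    """Mean relative model residual on the brightest valid voxels."""
    mag = np.abs(img.data).mean(axis=0)
    sel = valid & (mag >= np.quantile(mag[valid], 0.95)) if valid.any() else valid
    if not sel.any():
        return np.inf
    te = img.echo_times
    g = _model_matrix(te, fat_freq)
    s = img.data[:, sel] * np.exp(-2j * np.pi * psi[sel] * te[:, None])
    rho, *_ = np.linalg.lstsq(g, s, rcond=None)
    resid = np.abs(g @ rho - s).sum(axis=0) / np.maximum(np.abs(s).sum(axis=0), 1e-30)
    return float(resid.mean())


def _fit_smooth_surface(
    psi: np.ndarray, weights: np.ndarray, valid: np.ndarray, degree: int = 3
) -> np.ndarray:
    """Weighted 2D polynomial surface fit to the field estimate.

    Shim fields are spatially smooth; the surface extrapolates a reliable
    field into regions where the phase-difference weight vanishes (voxels
    near 50% fat fraction have no opposed-phase signal to measure).
    """
    ny, nx = psi.shape
    u = np.linspace(-1, 1, ny)[:, None] * np.ones((1, nx))
    v = np.ones((ny, 1)) * np.linspace(-1, 1, nx)[None, :]
    cols = [
        (u**i * v**j).ravel()
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
    ]
    a = np.column_stack(cols)
    w = (weights * valid).ravel()
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(a * sw[:, None], psi.ravel() * sw, rcond=None)
    return (a @ coef).reshape(ny, nx)


def _refine_fieldmap(
    img: MultiEchoImage,
    psi: np.ndarray,
    valid: np.ndarray,
    fat_freq: float,
    iterations: int,
) -> np.ndarray:
    """Per-voxel Gauss-Newton refinement of psi on the full signal model.

    Unknowns per voxel: the real field increment and the complex water/fat
    amplitudes (5 real parameters); each echo contributes 2 real equations.
    Requires >= 3 echoes to be overdetermined.
    """
    te = img.echo_times
    if img.n_echoes < 3 or iterations <= 0 or not valid.any():
        return psi
    g = _model_matrix(te, fat_freq)  # (nE, 2)
    pinv = np.linalg.pinv(g)
    s = img.data[:, valid]  # (nE, M)
    p0 = psi[valid].copy()
    p = p0.copy()
    n_e = te.size
    # the refinement polishes the unwrapped initial estimate; individual
    # low-SNR voxels must not jump to a period/swap-aliased solution
    max_shift = 0.25 / (te[-1] - te[0])
    for _ in range(iterations):
        demod = np.exp(-2j * np.pi * p[None, :] * te[:, None])
        sp = s * demod
        rho = pinv @ sp  # (2, M)
        model = g @ rho  # (nE, M)
        r = sp - model
        # column 0: d model / d psi = 2j*pi*TE_n * model ; columns 1..4: rho
        c0 = 2j * np.pi * te[:, None] * model
        a = np.empty((p.size, 2 * n_e, 5))
        a[:, :n_e, 0] = c0.real.T
        a[:, n_e:, 0] = c0.imag.T
        for k, col in enumerate(
            (np.ones(n_e), 1j * np.ones(n_e), g[:, 1], 1j * g[:, 1])
        ):
            col = np.broadcast_to(col, (p.size, n_e))
            a[:, :n_e, k + 1] = col.real
            a[:, n_e:, k + 1] = col.imag
        b = np.concatenate([r.real.T, r.imag.T], axis=1)
        ata = np.einsum("mij,mik->mjk", a, a)
        atb = np.einsum("mij,mi->mj", a, b)
        ata += 1e-12 * np.trace(ata, axis1=1, axis2=2)[:, None, None] * np.eye(5)
        try:
            delta = np.linalg.solve(ata, atb[:, :, None])[:, 0, 0]
        except np.linalg.LinAlgError:
            break
        delta = np.clip(delta, -0.25 / (te[-1] - te[0]), 0.25 / (te[-1] - te[0]))
        p = np.clip(p + delta, p0 - max_shift, p0 + max_shift)
        if np.max(np.abs(delta)) < 1e-9:
            break
    out = psi.copy()
    out[valid] = p
    return out


def estimate_fieldmap(
    img: MultiEchoImage,
    *,
    smoothing_sigma: float = 0.0,
    refine_iterations: int = 4,
    signal_floor: float | None = None,
) -> FieldMap:
    """Estimate the B0 off-resonance field psi (Hz) from phase evolution.

    The initial estimate is the spatially unwrapped phase difference of the
    echo pair whose fat phase advance is closest to a whole number of cycles
    (for such a pair the water-fat interference cancels and the phase
    difference is ``2*pi*psi*dTE`` exactly).  The unwrapped map is anchored
    by choosing the period offset that minimises the model residual on the
    brightest voxels, breaking ties toward the smallest magnitude-weighted
    |psi| (fields are assumed within half the ambiguity period, i.e. shim
    within +/- 1/(2*dTE)).  With >= 3 echoes the result is refined by
    Gauss-Newton iterations on the full model.

    An all-zero image yields an all-invalid mask rather than an error.
    """
    if img.n_echoes < 2:
        raise ValueError("field-map estimation needs at least 2 echoes")
    fat_freq = img.fat_frequency()
    mag = np.abs(img.data).mean(axis=0)
    if signal_floor is None:
        signal_floor = 5.0 * estimate_noise_sd(img)
    valid = mag > max(signal_floor, 1e-12 * max(mag.max(), 1e-300))
    if not valid.any():
        return FieldMap(psi_hz=np.zeros(img.shape), valid=valid)

    i, j, resid = _phase_pair(img.echo_times, fat_freq)
    dte = img.echo_times[j] - img.echo_times[i]
    pd = img.data[j] * np.conj(img.data[i])
    if resid <= 0.05:
        phase = np.angle(pd)
        period = 1.0 / dte
    else:
        # no like-phase pair (e.g. in/opposed two-echo data): double the
        # phase to cancel the sign of (W - F), halving the unambiguous range
        phase = 0.5 * np.angle(pd * pd)
        period = 0.5 / dte

    marr = np.ma.array(phase, mask=~valid)
    unwrapped = np.asarray(unwrap_phase(marr))
    psi = unwrapped / (2 * np.pi * dte)

    # anchor the arbitrary unwrapping offset: residual first, then |psi|
    w = mag * valid
    offsets = np.arange(-2, 3) * period
    med = np.average(psi[valid], weights=w[valid])
    offsets = offsets - period * round(med / period)
    scored = []
    for off in offsets:
        cand = psi + off
        scored.append(
            (
                round(_candidate_score(img, cand, valid, fat_freq), 6),
                float(np.average(np.abs(cand[valid]), weights=w[valid])),
                float(off),
            )
        )
    best_off = min(scored)[2]
    psi = psi + best_off

    # voxels without opposed-phase signal (fat fraction near 50%) carry no
    # usable phase difference: re-initialise them from a smooth surface fit
    w_pd = np.abs(pd)
    if valid.any():
        surface = _fit_smooth_surface(psi, w_pd, valid)
        reliable_level = np.average(w_pd[valid], weights=w[valid])
        unreliable = valid & (w_pd < 0.1 * reliable_level)
        psi = np.where(unreliable, surface, psi)
    else:
        unreliable = ~valid

    if smoothing_sigma > 0:
        wsum = ndimage.gaussian_filter(w, smoothing_sigma)
        psi_s = ndimage.gaussian_filter(psi * w, smoothing_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(wsum > 0, psi_s / wsum, psi)

    # refine only where the phase difference is identifiable; elsewhere the
    # smooth surface stands (per-voxel descent is ill-posed near FF = 50%)
    psi = _refine_fieldmap(img, psi, valid & ~unreliable, fat_freq, refine_iterations)
    psi = np.where(valid, psi, 0.0)
    return FieldMap(psi_hz=psi, valid=valid)


def separate_water_fat(
    img: MultiEchoImage, field: FieldMap, *, fat_freq: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares water/fat amplitudes given a field map (>= 2 echoes).

    Demodulates the off-resonance phase, solves the linear single-peak model
    at the image's echo times, and returns nonnegative magnitude maps
    (W, F).  Raises :class:`CollinearEchoError` when the echo configuration
    cannot distinguish water from fat.
    """
    if fat_freq is None:
        fat_freq = img.fat_frequency()
    _check_conditioning(img.echo_times, fat_freq)
    te = img.echo_times
    g = _model_matrix(te, fat_freq)
    pinv = np.linalg.pinv(g)
    ny, nx = img.shape
    s = img.data.reshape(img.n_echoes, -1) * np.exp(
        -2j * np.pi * field.psi_hz.ravel()[None, :] * te[:, None]
    )
    rho = pinv @ s
    water = np.abs(rho[0]).reshape(ny, nx)
    fat = np.abs(rho[1]).reshape(ny, nx)
    return water, fat


def two_point_separate(
    img: MultiEchoImage,
    smoothing_sigma: float = 2.0,
    *,
    fat_freq: float | None = None,
    phase_tolerance: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical two-point (in-phase / opposed-phase) separation with B0
    phase correction.

    Requires exactly two echoes, one near in-phase (fat phase a whole number
    of cycles) and one near opposed-phase (odd half-cycles), within
    ``phase_tolerance`` cycles.  The field-induced phase is estimated from
    the doubled inter-echo phase difference (cancelling the sign of W - F),
    spatially unwrapped and smoothed with a Gaussian of ``smoothing_sigma``
    voxels, then removed so the opposed-phase image recovers its sign:

        W = (IP + OP_signed) / 2,   F = (IP - OP_signed) / 2
    """
    if img.n_echoes != 2:
        raise ValueError("two_point_separate requires exactly 2 echoes")
    if fat_freq is None:
        fat_freq = img.fat_frequency()
    cycles = fat_freq * img.echo_times
    frac = np.abs(cycles - np.round(cycles))
    classes = []
    for f in frac:
        if f <= phase_tolerance:
            classes.append("in")
        elif abs(f - 0.5) <= phase_tolerance:
            classes.append("opposed")
        else:
            classes.append("other")
    if sorted(classes) != ["in", "opposed"]:
        tes = ", ".join(f"{t * 1e3:.3f} ms" for t in img.echo_times)
        raise ValueError(
            f"two-point separation needs one in-phase and one opposed-phase "
            f"echo; got phase classes {classes} for TEs ({tes})"
        )
    ip_idx = classes.index("in")
    op_idx = 1 - ip_idx
    s_ip = img.data[ip_idx]
    s_op = img.data[op_idx]
    mag_ip = np.abs(s_ip)
    valid = mag_ip > 1e-12 * max(mag_ip.max(), 1e-300)

    q = np.where(valid, s_op * np.conj(s_ip) / np.maximum(mag_ip, 1e-300), 0.0)
    # doubled phase removes the pi jumps where F > W
    phase2 = np.angle(q * q)
    marr = np.ma.array(phase2, mask=~valid)
    phi_field = 0.5 * np.asarray(unwrap_phase(marr))
    if smoothing_sigma > 0:
        w = mag_ip * valid
        wsum = ndimage.gaussian_filter(w, smoothing_sigma)
        phi_s = ndimage.gaussian_filter(phi_field * w, smoothing_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi_field = np.where(wsum > 0, phi_s / wsum, phi_field)

    d = np.real(q * np.exp(-1j * phi_field))  # signed (W - F)
    water = np.clip((mag_ip + d) / 2.0, 0.0, None)
    fat = np.clip((mag_ip - d) / 2.0, 0.0, None)
    return water, fat


def fat_fraction_map(
    water: np.ndarray,
    fat: np.ndarray,
    *,
    signal_floor: float = 0.0,
    method: str = "3pt",
    echo_times: np.ndarray | None = None,
) -> FatFractionMap:
    """Fat signal as a percentage of total signal, ``100*F/(W+F)``.

    Voxels with total amplitude below ``signal_floor`` (or exactly zero) are
    marked invalid; their ff value is NaN, never a silent zero.  Negative
    input amplitudes indicate an upstream defect and are rejected.
    """
    water = np.asarray(water, float)
    fat = np.asarray(fat, float)
    if water.shape != fat.shape:
        raise ValueError("water and fat maps must share a grid")
    if (water < 0).any() or (fat < 0).any():
        raise ValueError("negative water/fat amplitudes are not meaningful")
    total = water + fat
    valid = total >= max(signal_floor, 0.0)
    valid &= total > 0
    ff = np.full(water.shape, np.nan)
    ff[valid] = 100.0 * fat[valid] / total[valid]
    return FatFractionMap(
        ff=ff,
        valid=valid,
        method=method,
        echo_times=np.asarray(echo_times if echo_times is not None else []),
        signal_floor=signal_floor,
    )


class DixonModel:
    """Water-fat separation model for one multi-echo acquisition.

    Parameters
    ----------
    image : MultiEchoImage
    method : "3pt" (field-map estimation + least squares, >= 3 echoes) or
        "2pt" (classical in/opposed two-echo path).
    signal_floor : absolute amplitude below which voxels are invalid;
        default 5x the estimated background noise SD.
    smoothing_sigma : Gaussian smoothing (voxels) of the field phase
        estimate (two-point path and optional three-point presmoothing).
    """

    def __init__(
        self,
        image: MultiEchoImage,
        method: str = "3pt",
        *,
        signal_floor: float | None = None,
        smoothing_sigma: float | None = None,
        fat_freq: float | None = None,
    ):
        if method not in ("2pt", "3pt"):
            raise ValueError("method must be '2pt' or '3pt'")
        if method == "3pt" and image.n_echoes < 3:
            raise ValueError("3-point separation needs at least 3 echoes")
        if method == "2pt" and image.n_echoes != 2:
            raise ValueError("2-point separation needs exactly 2 echoes")
        self.image = image
        self.method = method
        self.fat_freq = fat_freq if fat_freq is not None else image.fat_frequency()
        if signal_floor is None:
            signal_floor = 5.0 * estimate_noise_sd(image)
        self.signal_floor = signal_floor
        self.smoothing_sigma = smoothing_sigma

    def fit(self) -> "DixonResults":
        img = self.image
        if self.method == "3pt":
            sigma = 0.0 if self.smoothing_sigma is None else self.smoothing_sigma
            field = estimate_fieldmap(
                img, smoothing_sigma=sigma, signal_floor=self.signal_floor
            )
            water, fat = separate_water_fat(img, field, fat_freq=self.fat_freq)
        else:
            sigma = 2.0 if self.smoothing_sigma is None else self.smoothing_sigma
            water, fat = two_point_separate(
                img, smoothing_sigma=sigma, fat_freq=self.fat_freq
            )
            i, j, _ = _phase_pair(img.echo_times, self.fat_freq)
            field = FieldMap(
                psi_hz=np.zeros(img.shape),
                valid=np.abs(img.data).mean(axis=0) > self.signal_floor,
            )
        ffmap = fat_fraction_map(
            water,
            fat,
            signal_floor=self.signal_floor,
            method=self.method,
            echo_times=img.echo_times,
        )
        resid = self._residual(water, fat, field)
        return DixonResults(
            model=self,
            water=water,
            fat=fat,
            field_map=field,
            fat_fraction=ffmap,
            residual_rms=resid,
        )

    def _residual(self, water, fat, field) -> float:
        img = self.image
        te = img.echo_times
        g = _model_matrix(te, self.fat_freq)
        pred = np.einsum(
            "ek,kij->eij", g, np.stack([water, fat])
        ) * np.exp(2j * np.pi * field.psi_hz[None] * te[:, None, None])
        sel = field.valid
        if not sel.any():
            return float("nan")
        err = np.abs(np.abs(pred[:, sel]) - np.abs(img.data[:, sel]))
        return float(np.sqrt(np.mean(err**2)))


@dataclass
class DixonResults:
    """Fitted water/fat maps, field map and fat-fraction map."""

    model: DixonModel
    water: np.ndarray
    fat: np.ndarray
    field_map: FieldMap
    fat_fraction: FatFractionMap
    residual_rms: float

    def summary(self) -> str:
        ff = self.fat_fraction
        v = ff.valid
        lines = [
            "Dixon water-fat separation",
            "==========================",
            f"method:            {self.model.method}",
            f"echo times (ms):   "
            + ", ".join(f"{t * 1e3:.3f}" for t in self.model.image.echo_times),
            f"fat frequency:     {self.model.fat_freq:.1f} Hz",
            f"signal floor:      {self.model.signal_floor:.4g}",
            f"valid voxels:      {int(v.sum())} / {v.size}",
        ]
        if v.any():
            lines += [
                f"FF median (valid): {np.median(ff.ff[v]):.2f} %",
                f"FF range (valid):  {ff.ff[v].min():.2f} - {ff.ff[v].max():.2f} %",
                f"field range:       "
                f"{self.field_map.psi_hz[v].min():.1f} to "
                f"{self.field_map.psi_hz[v].max():.1f} Hz",
                f"residual RMS:      {self.residual_rms:.4g}",
            ]
        return "\n".join(lines)

    def plot_maps(self, axes=None):
        """Quick-look panel of FF, water, fat and field maps."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 4, figsize=(14, 3.5))
        panels = [
            (np.where(self.fat_fraction.valid, self.fat_fraction.ff, np.nan),
             "fat fraction (%)", dict(vmin=0, vmax=100, cmap="inferno")),
            (self.water, "water", {}),
            (self.fat, "fat", {}),
            (np.where(self.field_map.valid, self.field_map.psi_hz, np.nan),
             "field (Hz)", dict(cmap="RdBu_r")),
        ]
        for ax, (im, title, kw) in zip(np.ravel(axes), panels):
            h = ax.imshow(im, **kw)
            ax.set_title(title)
            ax.axis("off")
            plt.colorbar(h, ax=ax, fraction=0.046)
        return axes
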