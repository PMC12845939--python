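"""Iris-code biometrics: boundary localisation, rubber-sheet normalisation,
phase-quadrant encoding, shift-tolerant Hamming matching and FAR/FRR/EER
evaluation.

The encoder follows the classical iris-recognition recipe: the annulus between
the pupil and limbus boundaries is remapped to a dilation-invariant
pseudo-polar grid, each radial row is band-pass filtered along the angular
axis with a log-Gabor kernel, and every filter response is quantised to two
bits by the quadrant of its phase.  Codes are compared by the minimum
fractional Hamming distance over a small range of circular angular shifts,
which absorbs head/eye roll between acquisitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

__all__ = [
    "EyeImage",
    "BoundaryFit",
    "NormalizedTexture",
    "IrisCode",
    "MatchResult",
    "BiometricEval",
    "DetectionError",
    "locate_boundaries",
    "rubber_sheet",
    "encode",
    "hamming",
    "identify",
    "evaluate_biometrics",
    "eer_from_curves",
    "code_to_hex",
    "code_from_hex",
    "write_gallery",
    "read_gallery",
]


class DetectionError(RuntimeError):
    """No usable circular boundary could be found in the image."""


@dataclass
class EyeImage:
    """Greyscale eye image with intensities in [0, 1]."""

    data: np.ndarray
    pixel_pitch: float = 1.0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 64:
            raise ValueError("EyeImage requires a 2-D grid of at least 64x64")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EyeImage intensities must be finite")


@dataclass
class BoundaryFit:
    """Pupil and limbus circles, each as (cx, cy, r) in pixels."""

    pupil: tuple[float, float, float]
    limbus: tuple[float, float, float]
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.pupil[2] >= self.limbus[2]:
            raise ValueError("pupil radius must be smaller than limbus radius")


@dataclass
class NormalizedTexture:
    """Pseudo-polar iris texture; rows index radius, columns index angle.

    The angular origin is the +x image axis, angles increase counter-clockwise.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("texture must be 2-D (n_radial x n_angular)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("texture values must be finite")

    @property
    def n_radial(self) -> int:
        return self.values.shape[0]

    @property
    def n_angular(self) -> int:
        return self.values.shape[1]


@dataclass
class IrisCode:
    """Fixed-length phase code.

    ``bits`` is flat with layout (radial, angular, quadrature-pair): position
    ``p = r * n_angular + a`` occupies bits ``2p`` (sign of the real part) and
    ``2p + 1`` (sign of the imaginary part).
    """

    bits: np.ndarray
    n_radial: int
    n_angular: int
    identity: str | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8).ravel()
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        if self.bits.size != 2 * self.n_radial * self.n_angular:
            raise ValueError("bit count does not match the code geometry")

    def __len__(self) -> int:
        return self.bits.size

    def as_grid(self) -> np.ndarray:
        return self.bits.reshape(self.n_radial, self.n_angular, 2)


@dataclass
class MatchResult:
    probe_id: str | None
    best_id: str | None
    distance: float
    shift: int
    accepted: bool


@dataclass
class BiometricEval:
    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float
    eer_threshold: float

    @property
    def gar(self) -> np.ndarray:
        return 1.0 - self.frr


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _radial_profile(img: np.ndarray, cx: float, cy: float,
                    radii: np.ndarray, n_theta: int = 64) -> np.ndarray:
    """Mean intensity on circles of the given radii (circular line integrals)."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    xs = cx + radii[:, None] * np.cos(theta)[None, :]
    ys = cy + radii[:, None] * np.sin(theta)[None, :]
    vals = map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    return vals.reshape(len(radii), n_theta).mean(axis=1)


def _best_circle(img: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                 blur_sigma: float = 2.0) -> tuple[float, float, float, float]:
    """Integro-differential search: maximise the blurred radial derivative of
    the circular line integral over candidate centres and radii."""
    best = (-np.inf, 0.0, 0.0, 0.0)
    for cx, cy in centers:
        prof = _radial_profile(img, cx, cy, radii)
        deriv = gaussian_filter1d(np.gradient(prof, radii), blur_sigma)
        k = int(np.argmax(deriv))
        if deriv[k] > best[0]:
            best = (float(deriv[k]), float(cx), float(cy), float(radii[k]))
    return best


def locate_boundaries(image: EyeImage, min_pupil_r: int = 6,
                      min_edge_strength: float = 5e-3) -> BoundaryFit:
    """Locate the pupil and limbus circles with the integro-differential
    operator (pupil first, then limbus constrained to a larger radius).

    Raises :class:`DetectionError` when no contrast edge exists.
    """
    img = image.data
    h, w = img.shape
    if float(img.std()) < 1e-6:
        raise DetectionError("image has no contrast; no boundary to fit")

    # coarse centre: centroid of the darkest decile (pupil is the dark disc)
    thresh = np.quantile(img, 0.08)
    dark = img <= thresh
    if not dark.any():
        raise DetectionError("no dark central disc found")
    ys, xs = np.nonzero(dark)
    cx0, cy0 = float(xs.mean()), float(ys.mean())

    r_max = 0.48 * min(h, w)
    offs = np.arange(-3, 4)
    centers = np.array([(cx0 + dx, cy0 + dy) for dx in offs for dy in offs])
    radii_p = np.arange(min_pupil_r, int(0.6 * r_max))
    sp, pcx, pcy, pr = _best_circle(img, centers, radii_p.astype(float))
    if sp < min_edge_strength:
        raise DetectionError("no pupil boundary edge found")

    radii_l = np.arange(int(pr * 1.2) + 1, int(r_max))
    if len(radii_l) < 3:
        raise DetectionError("no room for a limbus boundary")
    centers_l = np.array([(pcx + dx, pcy + dy) for dx in offs for dy in offs])
    sl, lcx, lcy, lr = _best_circle(img, centers_l, radii_l.astype(float))
    if sl < min_edge_strength:
        raise DetectionError("no limbus boundary edge found")

    return BoundaryFit(pupil=(pcx, pcy, pr), limbus=(lcx, lcy, lr),
                       score=float(min(sp, sl)))


# ---------------------------------------------------------------------------
# normalisation and encoding
# ---------------------------------------------------------------------------

def rubber_sheet(image: EyeImage, fit: BoundaryFit, n_radial: int = 16,
                 n_angular: int = 16, angular_offset: int = 0) -> NormalizedTexture:
    """Homogeneous rubber-sheet remapping of the iris annulus.

    Samples the image at ``p(theta, rho) = (1-rho) * p_pupil(theta) +
    rho * p_limbus(theta)`` on a regular (rho, theta) grid with bilinear
    interpolation, which makes the texture invariant to pupil dilation.
    ``angular_offset`` rotates the sampling grid by whole angular steps; the
    result is exactly the circular column shift of the unshifted texture.
    """
    pcx, pcy, pr = fit.pupil
    lcx, lcy, lr = fit.limbus
    rho = (np.arange(n_radial) + 0.5) / n_radial
    theta = 2 * np.pi * ((np.arange(n_angular) + angular_offset) % n_angular) / n_angular
    ct, st = np.cos(theta), np.sin(theta)
    # boundary points for every theta, blended by rho
    px = (1 - rho)[:, None] * (pcx + pr * ct)[None, :] + rho[:, None] * (lcx + lr * ct)[None, :]
    py = (1 - rho)[:, None] * (pcy + pr * st)[None, :] + rho[:, None] * (lcy + lr * st)[None, :]
    h, w = image.data.shape
    if px.min() < -0.5 or px.max() > w - 0.5 or py.min() < -0.5 or py.max() > h - 0.5:
        raise ValueError("rubber-sheet sampling falls outside the image")
    vals = map_coordinates(image.data, [py.ravel(), px.ravel()], order=1, mode="nearest")
    return NormalizedTexture(vals.reshape(n_radial, n_angular))


def _log_gabor(n: int, f0: float, sigma_ratio: float) -> np.ndarray:
    """One-sided log-Gabor transfer function on the rfft frequency grid."""
    f = np.arange(n // 2 + 1, dtype=float)
    g = np.zeros_like(f)
    pos = f > 0
    g[pos] = np.exp(-(np.log(f[pos] / f0) ** 2) / (2 * np.log(sigma_ratio) ** 2))
    return g


def encode(texture: NormalizedTexture, n_bits: int = 512,
           center_freq_frac: float = 3.0 / 16.0,
           sigma_ratio: float = 0.5) -> IrisCode:
    """Phase-quadrant coding of the normalised texture.

    Each radial row is filtered along the angular axis with a log-Gabor
    band-pass (analytic response via the one-sided spectrum); the sign of the
    real and imaginary parts of each filtered sample gives two bits.
    ``n_bits`` must equal 2 * n_radial * n_angular.
    """
    if n_bits not in (512, 1024):
        raise ValueError("n_bits must be 512 or 1024")
    t = texture.values
    if 2 * t.size != n_bits:
        raise ValueError(
            f"texture {t.shape} provides {t.size} positions; "
            f"{n_bits}-bit code needs {n_bits // 2}"
        )
    n_ang = texture.n_angular
    rows = t - t.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(rows, axis=1)
    g = _log_gabor(n_ang, f0=max(2.0, center_freq_frac * n_ang), sigma_ratio=sigma_ratio)
    # analytic signal: positive frequencies only, doubled (DC/Nyquist stay 0)
    resp = _analytic(spec * g[None, :], n_ang)
    bits = np.empty((texture.n_radial, n_ang, 2), dtype=np.uint8)
    bits[..., 0] = (resp.real >= 0)
    bits[..., 1] = (resp.imag >= 0)
    return IrisCode(bits=bits.ravel(), n_radial=texture.n_radial, n_angular=n_ang)


def _analytic(rspec: np.ndarray, n: int) -> np.ndarray:
    """Complex response from a one-sided (rfft) spectrum."""
    full = np.zeros((rspec.shape[0], n), dtype=complex)
    full[:, : rspec.shape[1]] = rspec
    full[:, 1: (n + 1) // 2] *= 2.0  # analytic: double strictly-positive freqs
    return np.fft.ifft(full, axis=1)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def hamming(code_a: IrisCode, code_b: IrisCode, max_shift: int = 4) -> float:
    """Minimum fractional Hamming distance over circular angular shifts
    ``s`` in ``[-max_shift, +max_shift]`` (one shift = one angular position =
    two bits)."""
    if len(code_a) != len(code_b):
        raise ValueError("codes must have equal length")
    if (code_a.n_radial, code_a.n_angular) != (code_b.n_radial, code_b.n_angular):
        raise ValueError("codes must share the same grid geometry")
    a = code_a.as_grid()
    b = code_b.as_grid()
    best = 1.0
    for s in range(-max_shift, max_shift + 1):
        d = float(np.mean(a != np.roll(b, s, axis=1)))
        if d < best:
            best = d
    return best


def identify(probe: IrisCode, gallery: list[IrisCode], threshold: float = 0.32,
             max_shift: int = 4) -> MatchResult:
    """Nearest-code identification with an acceptance threshold.

    Ties on distance are broken by the lowest gallery index.
    """
    if not gallery:
        raise ValueError("gallery is empty")
    best_i, best_d, best_s = 0, np.inf, 0
    for i, g in enumerate(gallery):
        a = probe.as_grid()
        b = g.as_grid()
        for s in range(-max_shift, max_shift + 1):
            d = float(np.mean(a != np.roll(b, s, axis=1)))
            if d < best_d:
                best_i, best_d, best_s = i, d, s
    accepted = best_d <= threshold
    return MatchResult(
        probe_id=probe.identity,
        best_id=gallery[best_i].identity if accepted else None,
        distance=best_d,
        shift=best_s,
        accepted=accepted,
    )


def evaluate_biometrics(genuine_scores, impostor_scores,
                        grid: np.ndarray | None = None) -> BiometricEval:
    """FAR/FRR/GAR curves over a threshold grid and the interpolated EER.

    FAR(t) is the fraction of impostor scores <= t (wrongly accepted);
    FRR(t) is the fraction of genuine scores > t (wrongly rejected).  The EER
    is read off at the FAR = FRR crossing by linear interpolation on the
    sign-change segment.
    """
    gen = np.asarray(genuine_scores, dtype=float)
    imp = np.asarray(impostor_scores, dtype=float)
    if gen.size == 0 or imp.size == 0:
        raise ValueError("both score sets must be non-empty")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 501)
    grid = np.asarray(grid, dtype=float)
    far = np.array([np.mean(imp <= t) for t in grid])
    frr = np.array([np.mean(gen > t) for t in grid])
    eer, eer_t = eer_from_curves(grid, far, frr)
    return BiometricEval(thresholds=grid, far=far, frr=frr, eer=eer, eer_threshold=eer_t)


def eer_from_curves(grid: np.ndarray, far: np.ndarray,
                     frr: np.ndarray) -> tuple[float, float]:
    d = far - frr
    if d[0] >= 0:
        return float((far[0] + frr[0]) / 2), float(grid[0])
    idx = np.nonzero(d >= 0)[0]
    if len(idx) == 0:
        return float((far[-1] + frr[-1]) / 2), float(grid[-1])
    j = int(idx[0])
    d0, d1 = d[j - 1], d[j]
    if d1 == d0:
        s = 0.0
    else:
        s = -d0 / (d1 - d0)
    eer = far[j - 1] + s * (far[j] - far[j - 1])
    t = grid[j - 1] + s * (grid[j] - grid[j - 1])
    return float(eer), float(t)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def code_to_hex(code: IrisCode) -> str:
    """Hex string, big-endian bit order, left-padded to a whole byte count."""
    return np.packbits(code.bits).tobytes().hex()


def code_from_hex(hex_str: str, n_radial: int, n_angular: int,
                  identity: str | None = None) -> IrisCode:
    n_bits = 2 * n_radial * n_angular
    raw = np.frombuffer(bytes.fromhex(hex_str), dtype=np.uint8)
    bits = np.unpackbits(raw)[:n_bits]
    return IrisCode(bits=bits, n_radial=n_radial, n_angular=n_angular, identity=identity)


def write_gallery(codes: list[IrisCode], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in codes:
            rec = {
                "identity_id": c.identity,
                "n_bits": len(c),
                "n_radial": c.n_radial,
                "n_angular": c.n_angular,
                "code_hex": code_to_hex(c),
            }
            fh.write(json.dumps(rec) + "\n")


def read_gallery(path) -> list[IrisCode]:
    codes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            codes.append(code_from_hex(
                rec["code_hex"], rec["n_radial"], rec["n_angular"],
                identity=rec.get("identity_id"),
            ))
    return codes
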