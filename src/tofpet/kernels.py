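"""Closed-form coincidence-timing kernels for ultra-fast TOF-PET.

A 511-keV annihilation photon entering a scintillation crystal of length
``L`` is absorbed at an exponentially distributed depth, truncated to the
crystal.  Expressed in time (depth / speed of light), the absorption delay of
each photon follows a truncated exponential on ``[0, T]`` with rate
``lambda = beta * c`` and ``T = L / c``.  The coincidence time difference
``d = t_A - t_B`` of two independently absorbed photons then follows the
symmetric "CTR kernel"

    f_D(d) = lambda * sinh(lambda*(T - |d|)) * csch(lambda*T/2)**2 / 4,
    |d| <= T,

which tends to the Laplace distribution as the crystal grows (``T -> inf``).
Additional per-detector timing blur (photodetection, electronics) adds a
Gaussian component; the resulting kernel is the analytic convolution of
``f_D`` with a zero-mean normal.

All kernels share one contract (:class:`TimingKernel`): a vectorised ``pdf``,
``cdf`` and a ``support`` interval, which is everything binned TOF projection
weights need.  Evaluation is arranged so that no intermediate exceeds the
double-precision range even for very long/opaque crystals (large
``lambda*T``) or very wide blur (large ``lambda*sigma``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import erf, erfcx, ndtr

__all__ = [
    "SPEED_OF_LIGHT_MM_PER_PS",
    "DEFAULT_BETA_PER_MM",
    "CrystalTimingParams",
    "GaussianTimingParams",
    "ConvolvedTimingParams",
    "TimingKernel",
    "CTRKernel",
    "LaplaceKernel",
    "GaussianKernel",
    "ConvolvedKernel",
    "truncated_exp_pdf",
    "ctr_pdf",
    "ctr_cdf",
    "laplace_pdf",
    "laplace_cdf",
    "conv_pdf",
    "conv_cdf",
    "kernel_fwhm",
    "bin_probabilities",
    "ctr_pdf_oracle",
    "conv_pdf_reference",
    "kernel_to_config",
    "kernel_from_config",
]

#: Speed of light in mm/ps.
SPEED_OF_LIGHT_MM_PER_PS = 0.2998

#: Default 511-keV absorption coefficient, mm^-1 (LYSO-like).  The effective
#: value depends on the detector stack; it is a parameter everywhere.
DEFAULT_BETA_PER_MM = 0.087

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.35482...
_SQRT2 = math.sqrt(2.0)

# Exponents beyond this are declared unrepresentable rather than silently
# saturated (double overflow is at ~709).
_MAX_EXPONENT = 700.0


def _require_finite(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrystalTimingParams:
    """Crystal length / absorption parameters of the photon-travel-spread model.

    Parameters
    ----------
    L : float
        Crystal length in mm.
    beta : float
        Linear absorption coefficient in mm^-1.
    c : float
        Speed of light in mm/ps.

    The derived quantities ``T = L / c`` (maximum travel time, ps) and
    ``lam = beta * c`` (absorption rate in time, ps^-1) are exact.
    """

    L: float
    beta: float = DEFAULT_BETA_PER_MM
    c: float = SPEED_OF_LIGHT_MM_PER_PS

    def __post_init__(self):
        if not (self.L > 0 and self.beta > 0 and self.c > 0):
            raise ValueError("L, beta and c must all be positive")

    @property
    def T(self) -> float:
        """Maximum photon travel time through the crystal, ps."""
        return self.L / self.c

    @property
    def lam(self) -> float:
        """Absorption rate in the time domain, ps^-1."""
        return self.beta * self.c


@dataclass(frozen=True)
class GaussianTimingParams:
    """Zero-centred (by default) Gaussian timing blur, parameterised by sigma."""

    sigma: float
    mu: float = 0.0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def fwhm(self) -> float:
        return _FWHM_PER_SIGMA * self.sigma


@dataclass(frozen=True)
class ConvolvedTimingParams:
    """Parameters of the CTR (x) Gaussian convolution kernel."""

    lam: float
    T: float
    sigma: float

    def __post_init__(self):
        if not (self.lam > 0 and self.T > 0 and self.sigma > 0):
            raise ValueError("lam, T and sigma must all be positive")


# ---------------------------------------------------------------------------
# Truncated exponential absorption-time density
# ---------------------------------------------------------------------------


def truncated_exp_pdf(t, p: CrystalTimingParams):
    """Density of the absorption delay of a single photon, ps^-1.

    ``lam * exp(-lam t) / (1 - exp(-lam T))`` on ``[0, T]``, zero outside.
    """
    t = _require_finite(t, "t")
    lam, T = p.lam, p.T
    # 1 - exp(-lam T) == -expm1(-lam T), exact for small lam*T
    norm = -math.expm1(-lam * T)
    with np.errstate(under="ignore"):
        out = np.where((t >= 0) & (t <= T), lam * np.exp(-lam * np.minimum(t, T)) / norm, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# CTR kernel (difference of two truncated exponentials)
# ---------------------------------------------------------------------------


def ctr_pdf(d, p: CrystalTimingParams):
    """Coincidence-timing-resolution kernel density, ps^-1.

    Stable rearrangement with only non-positive exponents::

        f_D(d) = (lam/2) * exp(-lam|d|) * (1 - exp(-2 lam (T-|d|)))
                 / (1 - exp(-lam T))**2
    """
    d = _require_finite(d, "d")
    lam, T = p.lam, p.T
    a = np.abs(d)
    den = math.expm1(-lam * T) ** 2
    with np.errstate(under="ignore"):
        num = -np.exp(-lam * a) * np.expm1(-2.0 * lam * np.maximum(T - a, 0.0))
        out = np.where(a <= T, 0.5 * lam * num / den, 0.0)
    return out if out.ndim else float(out)


def ctr_cdf(d, p: CrystalTimingParams):
    """CDF of the CTR kernel; exactly 1/2 at ``d = 0``, clamped to [0, 1].

    The upper-tail mass beyond ``|d|`` is
    ``exp(-lam|d|) * expm1(-lam(T-|d|))**2 / (2 * expm1(-lam T)**2)``.
    """
    d = _require_finite(d, "d")
    lam, T = p.lam, p.T
    a = np.minimum(np.abs(d), T)
    den = 2.0 * math.expm1(-lam * T) ** 2
    with np.errstate(under="ignore"):
        tail = np.exp(-lam * a) * np.expm1(-lam * (T - a)) ** 2 / den
    out = np.where(d >= 0, 1.0 - tail, tail)
    out = np.where(d == 0, 0.5, out)
    return out if out.ndim else float(out)


def ctr_pdf_oracle(d, p: CrystalTimingParams) -> float:
    """Reference CTR density by direct integration of the joint distribution.

    Substituting ``d = t_A - t_B``, ``s = t_A + t_B`` (Jacobian 1/2) and
    integrating the product of the two single-photon densities over
    ``s in [|d|, 2T - |d|]``.  Scalar, quadrature-based; intended as a slow
    independent check of :func:`ctr_pdf`.
    """
    d = float(d)
    T = p.T
    if abs(d) > T:
        return 0.0

    def integrand(s):
        tA = 0.5 * (s + d)
        tB = 0.5 * (s - d)
        return truncated_exp_pdf(tA, p) * truncated_exp_pdf(tB, p) * 0.5

    val, _ = integrate.quad(integrand, abs(d), 2.0 * T - abs(d), limit=200)
    return val


# ---------------------------------------------------------------------------
# Laplace limit (infinitely long crystal)
# ---------------------------------------------------------------------------


def laplace_pdf(d, lam: float):
    """Laplace density ``(lam/2) exp(-|d| lam)`` — the ``T -> inf`` CTR limit."""
    if not lam > 0:
        raise ValueError("lam must be positive")
    d = _require_finite(d, "d")
    with np.errstate(under="ignore"):
        out = 0.5 * lam * np.exp(-lam * np.abs(d))
    return out if out.ndim else float(out)


def laplace_cdf(d, lam: float):
    """Laplace CDF ``(1 + sgn(d) (1 - exp(-|d| lam))) / 2``."""
    if not lam > 0:
        raise ValueError("lam must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("d must not be NaN")
    with np.errstate(under="ignore"):
        tail = 0.5 * np.exp(-lam * np.abs(d))
    out = np.where(d >= 0, 1.0 - tail, tail)
    out = np.where(d == 0, 0.5, out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# CTR (x) Gaussian convolution
# ---------------------------------------------------------------------------
#
# Writing the CTR kernel as a two-sided difference of exponentials,
#
#   f_D(x) = C0 * (exp(-lam|x|) - exp(-2 lam T) exp(+lam|x|)),
#   C0 = lam / (2 (1 - exp(-lam T))**2),   |x| <= T,
#
# its convolution with N(0, sigma^2) reduces to four integrals of the form
#
#   J(a, b, s; off) = int_a^b exp(-s lam x + off) N(x; d, sigma^2) dx
#                   = exp(m) [Phi(-u(a)) - Phi(-u(b))],
#   u(x0) = (x0 - d + s lam sigma^2) / sigma,
#   m     = off - s lam d + lam^2 sigma^2 / 2.
#
# exp(m) overflows long before the product does, so every product
# exp(m) Phi(+-u) is evaluated through erfcx using the identity
#   exp(m) Phi(-u) = erfcx(u / sqrt 2) / 2 * exp(eps(x0)),
#   eps(x0) = off - s lam x0 - (x0 - d)^2 / (2 sigma^2),
# whose exponent is bounded by ~lam*T for every term that actually occurs.


def _exp_phi_terms(x0, d, s, lam, sigma, off):
    """Return ``u(x0)`` and the two stable half-products at endpoint ``x0``.

    ``pos`` equals ``exp(m) * Phi(-u)`` valid where ``u >= 0``;
    ``neg`` equals ``exp(m) * Phi(u)``  valid where ``u <  0``.
    """
    u = (x0 - d + s * lam * sigma * sigma) / sigma
    eps = off - s * lam * x0 - (x0 - d) ** 2 / (2.0 * sigma * sigma)
    with np.errstate(under="ignore"):
        e = np.exp(eps)
        pos = 0.5 * erfcx(np.maximum(u, 0.0) / _SQRT2) * e
        neg = 0.5 * erfcx(np.maximum(-u, 0.0) / _SQRT2) * e
    return u, pos, neg


def _J(a, b, s, lam, sigma, d, off):
    """Stable ``int_a^b exp(-s lam x + off) N(x; d, sigma^2) dx`` (vectorised in d)."""
    ua, pos_a, neg_a = _exp_phi_terms(a, d, s, lam, sigma, off)
    ub, pos_b, neg_b = _exp_phi_terms(b, d, s, lam, sigma, off)
    m = off - s * lam * d + 0.5 * lam * lam * sigma * sigma
    # mixed-sign case (ua < 0 <= ub) has m bounded; guard anyway
    mixed = (ua < 0) & (ub >= 0)
    if np.any(mixed & (m > _MAX_EXPONENT)):
        raise FloatingPointError(
            f"convolution kernel overflow at lam={lam}, T=?, sigma={sigma}"
        )
    with np.errstate(under="ignore", over="ignore"):
        exp_m = np.exp(np.where(mixed, m, 0.0))
    both_pos = ua >= 0
    both_neg = ub < 0
    out = np.where(both_pos, pos_a - pos_b, 0.0)
    out = np.where(both_neg, neg_b - neg_a, out)
    out = np.where(mixed, exp_m - neg_a - pos_b, out)
    return out


def _conv_norm(lam: float, T: float) -> float:
    return lam / (2.0 * math.expm1(-lam * T) ** 2)


def conv_pdf(d, p: ConvolvedTimingParams):
    """Density of the CTR kernel convolved with a zero-mean Gaussian, ps^-1.

    Analytically equal to the closed erf form (see
    :func:`conv_pdf_reference`) but rearranged through scaled complementary
    error functions so that every exponent stays bounded by ``~lam*T`` —
    the naive form overflows via ``exp(2 T lam)`` and
    ``exp(lam^2 sigma^2 / 2)`` at physically plausible parameters.
    """
    d = _require_finite(d, "d")
    lam, T, sigma = p.lam, p.T, p.sigma
    if lam * T > _MAX_EXPONENT:
        raise FloatingPointError(
            f"convolution kernel overflow: lam={lam}/ps, T={T} ps, sigma={sigma} ps"
        )
    a = np.abs(d)  # kernel is even in d; evaluate on |d| for exact symmetry
    off = -2.0 * lam * T
    val = (
        _J(0.0, T, +1.0, lam, sigma, a, 0.0)
        + _J(-T, 0.0, -1.0, lam, sigma, a, 0.0)
        - _J(0.0, T, -1.0, lam, sigma, a, off)
        - _J(-T, 0.0, +1.0, lam, sigma, a, off)
    )
    out = _conv_norm(lam, T) * val
    out = np.maximum(out, 0.0)  # clip tiny negative round-off in far tails
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"convolution kernel overflow: lam={lam}/ps, T={T} ps, sigma={sigma} ps"
        )
    return out if out.ndim else float(out)


def _K(a, b, s, lam, sigma, d, off):
    """Stable ``int_a^b exp(-s lam x + off) Phi((d - x)/sigma) dx``.

    By parts: ``(exp(-s lam a + off) Phi((d-a)/sigma)
    - exp(-s lam b + off) Phi((d-b)/sigma) - J(a,b,s;off)) / (s lam)``.
    All boundary exponents ``-s lam x0 + off`` are <= 0 for the four term
    combinations used by :func:`conv_cdf`.
    """
    with np.errstate(under="ignore"):
        ba = math.exp(-s * lam * a + off) * ndtr((d - a) / sigma)
        bb = math.exp(-s * lam * b + off) * ndtr((d - b) / sigma)
    return (ba - bb - _J(a, b, s, lam, sigma, d, off)) / (s * lam)


def conv_cdf(d, p: ConvolvedTimingParams):
    """CDF of the convolved kernel (analytic; monotone, 0/1 at the tails)."""
    d = _require_finite(d, "d")
    lam, T, sigma = p.lam, p.T, p.sigma
    if lam * T > _MAX_EXPONENT:
        raise FloatingPointError(
            f"convolution kernel overflow: lam={lam}/ps, T={T} ps, sigma={sigma} ps"
        )
    off = -2.0 * lam * T
    val = (
        _K(0.0, T, +1.0, lam, sigma, d, 0.0)
        + _K(-T, 0.0, -1.0, lam, sigma, d, 0.0)
        - _K(0.0, T, -1.0, lam, sigma, d, off)
        - _K(-T, 0.0, +1.0, lam, sigma, d, off)
    )
    out = np.clip(_conv_norm(lam, T) * val, 0.0, 1.0)
    # beyond the far tail the CDF is 1 to double precision; snap to keep
    # the plateau exactly monotone
    out = np.where(out > 1.0 - 1e-14, 1.0, out)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"convolution kernel overflow: lam={lam}/ps, T={T} ps, sigma={sigma} ps"
        )
    return out if out.ndim else float(out)


def conv_pdf_reference(d, p: ConvolvedTimingParams):
    """Convolved density in its raw closed erf form (un-stabilised).

    Direct transcription of the analytic convolution between the CTR kernel
    on ``[-T, T]`` and the Gaussian; overflows for large ``lam*T`` or
    ``lam*sigma`` and exists as a cross-check oracle for :func:`conv_pdf`
    at moderate parameters.
    """
    d = np.asarray(d, dtype=float)
    lam, T, s = p.lam, p.T, p.sigma
    sq = _SQRT2 * s
    ls2 = lam * s * s
    A = np.exp(0.5 * lam * (-2.0 * d + ls2)) * math.sqrt(0.5 * math.pi) * lam * math.cosh(T * lam)
    B = erf((d - ls2) / sq)
    C = erf((T + d - ls2) / sq)
    D = erf((T - d + ls2) / sq)
    E = erf((d + ls2) / sq)
    F = erf((-T + d + ls2) / sq)
    G = erf((T + d + ls2) / sq)
    e2TL = math.exp(2.0 * T * lam)
    H = np.exp(2.0 * d * lam) * (-E + F)
    Jt = np.exp(2.0 * (T + d) * lam) * (-E + G)
    num = A * ((1.0 + e2TL) * B - C + e2TL * D + H + Jt)
    den = 2.0 * (1.0 + e2TL) * (math.cosh(T * lam) - 1.0) * math.sqrt(2.0 * math.pi)
    out = num / den
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Kernel contract
# ---------------------------------------------------------------------------


class TimingKernel:
    """Common contract: vectorised ``pdf``/``cdf`` plus a ``support`` interval.

    ``pdf`` is >= 0 and integrates to 1 over the support; ``cdf`` is monotone
    with ``cdf(lo) = 0`` and ``cdf(hi) = 1``.  Densities are defined (and
    zero) outside the support rather than raising, which keeps binned use
    branch-free.
    """

    support: tuple[float, float] = (-math.inf, math.inf)

    def pdf(self, d):  # pragma: no cover - abstract
        raise NotImplementedError

    def cdf(self, d):  # pragma: no cover - abstract
        raise NotImplementedError

    def fwhm(self) -> float:
        return kernel_fwhm(self)


@dataclass(frozen=True)
class CTRKernel(TimingKernel):
    """Analytic coincidence-timing kernel of two truncated-exponential delays."""

    params: CrystalTimingParams

    @property
    def support(self):
        return (-self.params.T, self.params.T)

    def pdf(self, d):
        return ctr_pdf(d, self.params)

    def cdf(self, d):
        return ctr_cdf(d, self.params)


@dataclass(frozen=True)
class LaplaceKernel(TimingKernel):
    """Infinite-crystal limit of the CTR kernel."""

    lam: float

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("lam must be positive")

    @property
    def support(self):
        return (-math.inf, math.inf)

    def pdf(self, d):
        return laplace_pdf(d, self.lam)

    def cdf(self, d):
        return laplace_cdf(d, self.lam)


@dataclass(frozen=True)
class GaussianKernel(TimingKernel):
    """Normal timing kernel (the conventional TOF model)."""

    sigma: float
    mu: float = 0.0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_fwhm(cls, fwhm: float, mu: float = 0.0) -> "GaussianKernel":
        return cls(sigma=fwhm / _FWHM_PER_SIGMA, mu=mu)

    @property
    def support(self):
        return (-math.inf, math.inf)

    def pdf(self, d):
        d = _require_finite(d, "d")
        z = (d - self.mu) / self.sigma
        with np.errstate(under="ignore"):
            out = np.exp(-0.5 * z * z) / (self.sigma * math.sqrt(2.0 * math.pi))
        return out if out.ndim else float(out)

    def cdf(self, d):
        d = np.asarray(d, dtype=float)
        out = ndtr((d - self.mu) / self.sigma)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConvolvedKernel(TimingKernel):
    """CTR kernel convolved with zero-mean Gaussian blur of width ``sigma``."""

    params: ConvolvedTimingParams

    @classmethod
    def from_crystal(cls, crystal: CrystalTimingParams, sigma: float) -> "ConvolvedKernel":
        return cls(ConvolvedTimingParams(lam=crystal.lam, T=crystal.T, sigma=sigma))

    @property
    def support(self):
        return (-math.inf, math.inf)

    def pdf(self, d):
        return conv_pdf(d, self.params)

    def cdf(self, d):
        return conv_cdf(d, self.params)


# ---------------------------------------------------------------------------
# Kernel utilities
# ---------------------------------------------------------------------------


def _kernel_scale(k: TimingKernel) -> float:
    """A positive length scale of the kernel, for bracketing searches."""
    lo, hi = k.support
    if math.isfinite(hi) and hi > 0:
        return hi
    # width where the density falls well below the peak, by doubling
    centre = getattr(k, "mu", 0.0)
    peak = float(k.pdf(centre))
    w = 1.0
    while float(k.pdf(centre + w)) > 1e-12 * peak and w < 1e12:
        w *= 2.0
    return w


def kernel_fwhm(k: TimingKernel) -> float:
    """Full width at half maximum of a symmetric unimodal kernel, ps.

    Brackets the half-peak crossing on the right flank and bisects to a
    relative tolerance of 1e-9.  Raises if the density is not unimodal
    about its centre.
    """
    from scipy.optimize import brentq

    centre = getattr(k, "mu", 0.0)
    peak = float(k.pdf(centre))
    if not peak > 0:
        raise ValueError("kernel has no positive peak at its centre")
    scale = _kernel_scale(k)
    grid = centre + np.linspace(0.0, scale, 129)
    vals = np.asarray(k.pdf(grid), dtype=float)
    if np.any(np.diff(vals) > 1e-9 * peak):
        raise ValueError("kernel_fwhm requires a unimodal kernel")
    half = 0.5 * peak
    idx = np.nonzero(vals < half)[0]
    if idx.size == 0:
        raise ValueError("half maximum not reached inside the kernel support")
    hi = grid[idx[0]]
    lo = grid[idx[0] - 1] if idx[0] > 0 else centre
    x = brentq(lambda t: float(k.pdf(t)) - half, lo, hi, xtol=1e-15, rtol=1e-12)
    return 2.0 * (x - centre)


def bin_probabilities(k: TimingKernel, edges) -> np.ndarray:
    """Per-bin kernel masses ``cdf(edges[i+1]) - cdf(edges[i])``."""
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("edges must be a 1-D array of at least two values")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    return np.maximum(np.diff(np.asarray(k.cdf(edges), dtype=float)), 0.0)


# ---------------------------------------------------------------------------
# Config round-trip
# ---------------------------------------------------------------------------


def kernel_to_config(k: TimingKernel) -> dict:
    """Serialise a kernel to a flat mapping of plain floats/strings."""
    if isinstance(k, CTRKernel):
        p = k.params
        return {"kind": "ctr", "L_mm": p.L, "beta_per_mm": p.beta, "c_mm_per_ps": p.c}
    if isinstance(k, LaplaceKernel):
        return {
            "kind": "laplace",
            "beta_per_mm": k.lam / SPEED_OF_LIGHT_MM_PER_PS,
            "c_mm_per_ps": SPEED_OF_LIGHT_MM_PER_PS,
        }
    if isinstance(k, GaussianKernel):
        return {"kind": "gaussian", "sigma_ps": k.sigma, "mu_ps": k.mu}
    if isinstance(k, ConvolvedKernel):
        p = k.params
        return {
            "kind": "conv",
            "L_mm": p.T * SPEED_OF_LIGHT_MM_PER_PS,
            "beta_per_mm": p.lam / SPEED_OF_LIGHT_MM_PER_PS,
            "c_mm_per_ps": SPEED_OF_LIGHT_MM_PER_PS,
            "sigma_ps": p.sigma,
        }
    raise TypeError(f"cannot serialise kernel of type {type(k).__name__}")


def kernel_from_config(cfg: dict) -> TimingKernel:
    """Inverse of :func:`kernel_to_config`."""
    kind = cfg["kind"]
    c = float(cfg.get("c_mm_per_ps", SPEED_OF_LIGHT_MM_PER_PS))
    if kind == "ctr":
        return CTRKernel(CrystalTimingParams(L=float(cfg["L_mm"]), beta=float(cfg["beta_per_mm"]), c=c))
    if kind == "laplace":
        return LaplaceKernel(lam=float(cfg["beta_per_mm"]) * c)
    if kind == "gaussian":
        return GaussianKernel(sigma=float(cfg["sigma_ps"]), mu=float(cfg.get("mu_ps", 0.0)))
    if kind == "conv":
        crystal = CrystalTimingParams(L=float(cfg["L_mm"]), beta=float(cfg["beta_per_mm"]), c=c)
        return ConvolvedKernel.from_crystal(crystal, sigma=float(cfg["sigma_ps"]))
    raise ValueError(f"unknown kernel kind: {kind!r}")
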