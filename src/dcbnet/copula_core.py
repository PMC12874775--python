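"""Bivariate copula families: evaluation, conditioning, sampling, Kendall-τ maps.

Every conditional dependency in a dynamic copula Bayesian network is a
bivariate copula C(u, v) with slice-specific parameters.  This module is the
family registry: each family exposes the CDF, the density c(u, v), the
conditional CDF (h-function) h(v|u) = ∂C/∂u, a sampler, and the two-way map
between Kendall's τ and the copula parameter(s).

Families registered by default: independence, gaussian, clayton, frank,
gumbel, joe, amh, raftery, marshall_olkin, roch_alegre — the families the
study's per-edge fits select from, plus standard Archimedean families used
for testing.  Additional families can be registered behind the same contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "CopulaFamily",
    "CopulaParams",
    "get_family",
    "list_families",
    "register_family",
    "registry_descriptor",
    "registry_from_descriptor",
    "copula_cdf",
    "copula_density",
    "conditional_cdf",
    "sample_copula",
    "tau_from_theta",
    "theta_from_tau",
]

#: interior clamp used by callers that must evaluate densities at empirical
#: boundary pseudo-observations (see parameter_learning.edge_loglik)
BOUNDARY_EPS = 1e-10


@dataclass(frozen=True)
class CopulaParams:
    """A family name bound to a concrete parameter vector θ = (θ1[, θ2])."""

    family: str
    theta: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "theta", tuple(float(t) for t in self.theta))
        fam = get_family(self.family)
        fam.check_theta(self.theta)


class CopulaFamily:
    """Base class for bivariate copula families.

    Subclasses implement ``_cdf``/``_pdf``/``_hfunc`` on interior points with
    θ already validated; the public wrappers handle validation, broadcasting
    and boundary conditions.  ``param_bounds`` are numerically safe open
    intervals; evaluation outside them is rejected.
    """

    name: str = ""
    n_params: int = 1
    param_bounds: tuple[tuple[float, float], ...] = ()
    #: closed-form τ(θ) available (otherwise the 1-D Archimedean integral or
    #: quadrature fallback is used)
    supports_closed_form_tau: bool = False
    #: False for families with a singular component (the density then
    #: integrates to less than one)
    absolutely_continuous: bool = True

    # -- validation -------------------------------------------------------
    def check_theta(self, theta: Sequence[float]) -> None:
        theta = tuple(theta)
        if len(theta) != self.n_params:
            raise ValueError(
                f"{self.name}: expected {self.n_params} parameter(s), got {len(theta)}"
            )
        for j, (t, (lo, hi)) in enumerate(zip(theta, self.param_bounds)):
            if not np.isfinite(t) or not (lo <= t <= hi):
                raise ValueError(
                    f"{self.name}: theta[{j}]={t} outside domain [{lo}, {hi}]"
                )

    @staticmethod
    def _check_unit(x, name, strict=False):
        x = np.asarray(x, dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError(f"NaN in {name}")
        lo, hi = (0.0, 1.0)
        bad = (x < lo) | (x > hi) if not strict else (x <= lo) | (x >= hi)
        if np.any(bad):
            kind = "open (0,1)" if strict else "closed [0,1]"
            raise ValueError(f"{name} outside the {kind} unit interval")
        return x

    # -- public surface ---------------------------------------------------
    def cdf(self, u, v, theta):
        self.check_theta(theta)
        u = self._check_unit(u, "u")
        v = self._check_unit(v, "v")
        u, v = np.broadcast_arrays(u, v)
        out = np.empty(u.shape, dtype=float)
        # Sklar boundary conditions, exact
        zero = (u == 0) | (v == 0)
        uone = (v == 1)
        vone = (u == 1)
        interior = ~(zero | uone | vone)
        out[zero] = 0.0
        out[uone & ~zero] = u[uone & ~zero]
        out[vone & ~zero & ~uone] = v[vone & ~zero & ~uone]
        if np.any(interior):
            out[interior] = np.clip(
                self._cdf(u[interior], v[interior], tuple(theta)), 0.0, 1.0
            )
        return out if out.shape else float(out)

    def pdf(self, u, v, theta):
        self.check_theta(theta)
        u = self._check_unit(u, "u", strict=True)
        v = self._check_unit(v, "v", strict=True)
        u, v = np.broadcast_arrays(u, v)
        out = np.maximum(self._pdf(u, v, tuple(theta)), 0.0)
        return out if out.shape else float(out)

    def hfunc(self, v, u, theta):
        """Conditional CDF h(v|u) = ∂C(u,v)/∂u."""
        self.check_theta(theta)
        u = self._check_unit(u, "u", strict=True)
        v = self._check_unit(v, "v")
        u, v = np.broadcast_arrays(u, v)
        out = np.empty(u.shape, dtype=float)
        out[v == 0] = 0.0
        out[v == 1] = 1.0
        interior = (v > 0) & (v < 1)
        if np.any(interior):
            out[interior] = np.clip(
                self._hfunc(v[interior], u[interior], tuple(theta)), 0.0, 1.0
            )
        return out if out.shape else float(out)

    def hinv(self, w, u, theta):
        """Generalized inverse of the h-function in v (vectorized bisection).

        Works for families whose h has jumps (singular components): returns
        inf{v : h(v|u) ≥ w}, which is the correct conditional sampler.
        """
        self.check_theta(theta)
        w = self._check_unit(w, "w")
        u = self._check_unit(u, "u", strict=True)
        w, u = np.broadcast_arrays(w, u)
        lo = np.full(w.shape, 1e-12)
        hi = np.full(w.shape, 1.0 - 1e-12)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            ge = self.hfunc(mid, u, theta) >= w
            hi = np.where(ge, mid, hi)
            lo = np.where(ge, lo, mid)
        out = 0.5 * (lo + hi)
        return out if out.shape else float(out)

    def sample(self, n, theta, rng):
        """Draw n pairs via conditional inversion: u ~ U(0,1), v = h⁻¹(w|u)."""
        self.check_theta(theta)
        if n < 1:
            raise ValueError("n must be >= 1")
        u = rng.uniform(size=n)
        w = rng.uniform(size=n)
        v = self.hinv(w, u, theta)
        return np.column_stack([u, v])

    # -- Kendall's tau ----------------------------------------------------
    def tau(self, theta) -> float:
        self.check_theta(theta)
        return float(self._tau(tuple(theta)))

    def _tau(self, theta):
        # default: Monte-Carlo estimate of 4 E[C(U,V)] - 1 at large n
        rng = np.random.default_rng(20090201)
        uv = self.sample(200_000, theta, rng)
        c = self.cdf(uv[:, 0], uv[:, 1], theta)
        return 4.0 * float(np.mean(c)) - 1.0

    def tau_range(self) -> tuple[float, float]:
        """Attainable τ interval when varying θ1 (θ2 at its default)."""
        lo, hi = self.param_bounds[0]
        rest = self._default_extra_params()
        t_lo = self.tau((lo,) + rest)
        t_hi = self.tau((hi,) + rest)
        return (min(t_lo, t_hi), max(t_lo, t_hi))

    def _default_extra_params(self) -> tuple[float, ...]:
        """Second-parameter default for τ-inversion: the domain midpoint."""
        return tuple(0.5 * (lo + hi) for lo, hi in self.param_bounds[1:])

    def theta_from_tau(self, tau: float) -> CopulaParams:
        tau = float(tau)
        lo, hi = self.param_bounds[0]
        rest = self._default_extra_params()
        t_lo, t_hi = self.tau((lo,) + rest), self.tau((hi,) + rest)
        tmin, tmax = min(t_lo, t_hi), max(t_lo, t_hi)
        if not (tmin <= tau <= tmax):
            raise ValueError(
                f"{self.name}: tau={tau} outside attainable range "
                f"[{tmin:.4f}, {tmax:.4f}]"
            )
        theta1 = optimize.brentq(
            lambda t: self.tau((t,) + rest) - tau, lo, hi, xtol=1e-12
        )
        return CopulaParams(self.name, (theta1,) + rest)

    # -- serialization ----------------------------------------------------
    def descriptor(self) -> dict:
        return {
            "name": self.name,
            "n_params": self.n_params,
            "param_domain": [list(b) for b in self.param_bounds],
            "supports_closed_form_tau": self.supports_closed_form_tau,
            "absolutely_continuous": self.absolutely_continuous,
        }


class ArchimedeanFamily(CopulaFamily):
    """Archimedean copulas C(u,v) = φ⁻¹(φ(u) + φ(v)).

    Subclasses provide the generator φ with its first two derivatives and its
    inverse.  Density: c = −φ''(C) φ'(u) φ'(v) / φ'(C)³ ; h-function:
    h(v|u) = φ'(u)/φ'(C).  Kendall's τ by the one-dimensional generator
    integral τ = 1 + 4 ∫₀¹ φ(t)/φ'(t) dt when no closed form is declared.
    """

    def phi(self, t, theta):
        raise NotImplementedError

    def phi_prime(self, t, theta):
        raise NotImplementedError

    def phi_dprime(self, t, theta):
        raise NotImplementedError

    def phi_inv(self, s, theta):
        raise NotImplementedError

    def _cdf(self, u, v, theta):
        return self.phi_inv(self.phi(u, theta) + self.phi(v, theta), theta)

    def _pdf(self, u, v, theta):
        with np.errstate(all="ignore"):
            C = np.clip(self._cdf(u, v, theta), 1e-300, 1.0 - 1e-16)
            num = (-self.phi_dprime(C, theta) * self.phi_prime(u, theta)
                   * self.phi_prime(v, theta))
            den = self.phi_prime(C, theta) ** 3
            out = num / den
        return np.where(np.isfinite(out), out, 0.0)

    def _hfunc(self, v, u, theta):
        with np.errstate(all="ignore"):
            C = np.clip(self._cdf(u, v, theta), 1e-300, 1.0 - 1e-16)
            out = self.phi_prime(u, theta) / self.phi_prime(C, theta)
        return np.where(np.isfinite(out), out, 1.0)

    def _tau(self, theta):
        with np.errstate(all="ignore"):
            val, err = integrate.quad(
                lambda t: self.phi(t, theta) / self.phi_prime(t, theta),
                0.0,
                1.0,
                limit=200,
                points=[1e-6, 1e-3, 1 - 1e-3],
            )
        if not np.isfinite(val) or err > 1e-5:
            raise RuntimeError(
                f"{self.name}: generator integral for tau did not converge"
            )
        return 1.0 + 4.0 * val


# ---------------------------------------------------------------------------
# concrete families
# ---------------------------------------------------------------------------


class Independence(CopulaFamily):
    name = "independence"
    n_params = 0
    param_bounds = ()
    supports_closed_form_tau = True

    def _cdf(self, u, v, theta):
        return u * v

    def _pdf(self, u, v, theta):
        return np.ones_like(u)

    def _hfunc(self, v, u, theta):
        return v

    def _tau(self, theta):
        return 0.0

    def theta_from_tau(self, tau):
        if abs(tau) > 1e-12:
            raise ValueError("independence: only tau=0 is attainable")
        return CopulaParams(self.name, ())


class Gaussian(CopulaFamily):
    name = "gaussian"
    param_bounds = ((-0.999, 0.999),)
    supports_closed_form_tau = True

    def _cdf(self, u, v, theta):
        rho = theta[0]
        x = special.ndtri(np.clip(u, 1e-16, 1 - 1e-16))
        y = special.ndtri(np.clip(v, 1e-16, 1 - 1e-16))
        lower = np.full((x.size, 2), -np.inf)
        upper = np.column_stack([x.ravel(), y.ravel()])
        cov = np.array([[1.0, rho], [rho, 1.0]])
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov)
        vals = mvn.cdf(upper)
        return np.asarray(vals).reshape(x.shape)

    def _pdf(self, u, v, theta):
        rho = theta[0]
        x = special.ndtri(u)
        y = special.ndtri(v)
        r2 = 1.0 - rho * rho
        return np.exp(
            -(rho * rho * (x * x + y * y) - 2 * rho * x * y) / (2 * r2)
        ) / math.sqrt(r2)

    def _hfunc(self, v, u, theta):
        rho = theta[0]
        x = special.ndtri(u)
        y = special.ndtri(v)
        return special.ndtr((y - rho * x) / math.sqrt(1.0 - rho * rho))

    def hinv(self, w, u, theta):
        self.check_theta(theta)
        rho = theta[0]
        w = self._check_unit(w, "w")
        u = self._check_unit(u, "u", strict=True)
        w = np.clip(w, 1e-16, 1 - 1e-16)
        x = special.ndtri(u)
        out = special.ndtr(special.ndtri(w) * math.sqrt(1 - rho * rho) + rho * x)
        return out if np.ndim(out) else float(out)

    def _tau(self, theta):
        return 2.0 / math.pi * math.asin(theta[0])

    def theta_from_tau(self, tau):
        if not -1.0 < tau < 1.0:
            raise ValueError(f"gaussian: tau={tau} outside attainable range (-1, 1)")
        rho = math.sin(math.pi * tau / 2.0)
        rho = min(max(rho, self.param_bounds[0][0]), self.param_bounds[0][1])
        return CopulaParams(self.name, (rho,))


class Clayton(ArchimedeanFamily):
    name = "clayton"
    param_bounds = ((1e-4, 30.0),)
    supports_closed_form_tau = True

    def phi(self, t, theta):
        th = theta[0]
        return (np.power(t, -th) - 1.0) / th

    def phi_prime(self, t, theta):
        th = theta[0]
        return -np.power(t, -th - 1.0)

    def phi_dprime(self, t, theta):
        th = theta[0]
        return (th + 1.0) * np.power(t, -th - 2.0)

    def phi_inv(self, s, theta):
        th = theta[0]
        return np.power(1.0 + th * s, -1.0 / th)

    def _tau(self, theta):
        th = theta[0]
        return th / (th + 2.0)

    def theta_from_tau(self, tau):
        if not 0.0 < tau < 1.0:
            raise ValueError(f"clayton: tau={tau} outside attainable range (0, 1)")
        th = 2.0 * tau / (1.0 - tau)
        lo, hi = self.param_bounds[0]
        if not lo <= th <= hi:
            raise ValueError(f"clayton: tau={tau} maps outside theta domain")
        return CopulaParams(self.name, (th,))


class Frank(ArchimedeanFamily):
    name = "frank"
    param_bounds = ((-35.0, 35.0),)
    supports_closed_form_tau = True

    def _is_indep(self, theta):
        return abs(theta[0]) < 1e-8

    def phi(self, t, theta):
        th = theta[0]
        return -np.log(np.expm1(-th * t) / np.expm1(-th))

    def phi_prime(self, t, theta):
        th = theta[0]
        return th / (1.0 - np.exp(th * t))

    def phi_dprime(self, t, theta):
        th = theta[0]
        e = np.exp(th * t)
        return th * th * e / np.square(1.0 - e)

    def phi_inv(self, s, theta):
        th = theta[0]
        return -np.log1p(np.exp(-s) * np.expm1(-th)) / th

    def _cdf(self, u, v, theta):
        if self._is_indep(theta):
            return u * v
        return super()._cdf(u, v, theta)

    def _pdf(self, u, v, theta):
        if self._is_indep(theta):
            return np.ones_like(u)
        return super()._pdf(u, v, theta)

    def _hfunc(self, v, u, theta):
        if self._is_indep(theta):
            return v
        return super()._hfunc(v, u, theta)

    def _tau(self, theta):
        th = theta[0]
        if abs(th) < 1e-8:
            return 0.0
        # Debye function D1
        d1, _ = integrate.quad(lambda t: t / np.expm1(t), 0.0, th)
        return 1.0 - 4.0 / th * (1.0 - d1 / th)


class Gumbel(ArchimedeanFamily):
    name = "gumbel"
    param_bounds = ((1.0, 50.0),)
    supports_closed_form_tau = True

    def phi(self, t, theta):
        return np.power(-np.log(t), theta[0])

    def phi_prime(self, t, theta):
        th = theta[0]
        return -th * np.power(-np.log(t), th - 1.0) / t

    def phi_dprime(self, t, theta):
        th = theta[0]
        lt = -np.log(t)
        return th * np.power(lt, th - 2.0) * (th - 1.0 + lt) / (t * t)

    def phi_inv(self, s, theta):
        return np.exp(-np.power(s, 1.0 / theta[0]))

    def _tau(self, theta):
        return 1.0 - 1.0 / theta[0]

    def theta_from_tau(self, tau):
        if not 0.0 <= tau < 1.0:
            raise ValueError(f"gumbel: tau={tau} outside attainable range [0, 1)")
        th = 1.0 / (1.0 - tau)
        lo, hi = self.param_bounds[0]
        if th > hi:
            raise ValueError(f"gumbel: tau={tau} maps outside theta domain")
        return CopulaParams(self.name, (max(th, lo),))


class Joe(ArchimedeanFamily):
    name = "joe"
    param_bounds = ((1.0, 50.0),)

    def phi(self, t, theta):
        th = theta[0]
        x = th * np.log1p(-t)  # log((1-t)^θ)
        with np.errstate(divide="ignore"):
            exact = -np.log(-np.expm1(x))
        # for (1-t)^θ below double resolution, φ = -log(1-e^x) ≈ e^x
        return np.where(x < -30.0, np.exp(x), exact)

    def phi_prime(self, t, theta):
        th = theta[0]
        omt = 1.0 - t
        B = -np.expm1(th * np.log(omt))  # 1 - (1-t)^th
        return -th * np.power(omt, th - 1.0) / B

    def phi_dprime(self, t, theta):
        th = theta[0]
        omt = 1.0 - t
        B = -np.expm1(th * np.log(omt))
        return (
            th * (th - 1.0) * np.power(omt, th - 2.0) / B
            + th * th * np.power(omt, 2.0 * th - 2.0) / (B * B)
        )

    def phi_inv(self, s, theta):
        th = theta[0]
        with np.errstate(divide="ignore"):
            return -np.expm1(np.log(-np.expm1(-s)) / th)

    def _tau(self, theta):
        # τ = 1 − 4 Σ_{k≥1} 1/(k(θk+2)(θ(k−1)+2)), terms O(k⁻³)
        th = theta[0]
        k = np.arange(1.0, 20001.0)
        s = np.sum(1.0 / (k * (th * k + 2.0) * (th * (k - 1.0) + 2.0)))
        return 1.0 - 4.0 * s


class AMH(ArchimedeanFamily):
    """Ali–Mikhail–Haq copula; τ attainable in ≈ (−0.1817, 1/3)."""

    name = "amh"
    param_bounds = ((-0.9999, 0.9999),)
    supports_closed_form_tau = True

    def phi(self, t, theta):
        th = theta[0]
        return np.log((1.0 - th * (1.0 - t)) / t)

    def phi_prime(self, t, theta):
        th = theta[0]
        return th / (1.0 - th * (1.0 - t)) - 1.0 / t

    def phi_dprime(self, t, theta):
        th = theta[0]
        return 1.0 / (t * t) - th * th / np.square(1.0 - th * (1.0 - t))

    def phi_inv(self, s, theta):
        th = theta[0]
        return (1.0 - th) / (np.exp(s) - th)

    def _tau(self, theta):
        th = theta[0]
        if abs(th) < 1e-8:
            return 0.0
        return 1.0 - 2.0 * (th + (1.0 - th) ** 2 * math.log(1.0 - th)) / (3.0 * th * th)


class Raftery(CopulaFamily):
    """Raftery copula (absolutely continuous, positive dependence only).

    C(u,v) = min(u,v) + ((1−θ)/(1+θ)) (uv)^{1/(1−θ)} [1 − max(u,v)^{−(1+θ)/(1−θ)}];
    τ = 2θ/(3−θ).
    """

    name = "raftery"
    param_bounds = ((1e-6, 0.999),)
    supports_closed_form_tau = True

    def _abk(self, theta):
        th = theta[0]
        a = 1.0 / (1.0 - th)
        b = (1.0 + th) / (1.0 - th)
        k = (1.0 - th) / (1.0 + th)
        return a, b, k

    def _cdf(self, u, v, theta):
        a, b, k = self._abk(theta)
        mn = np.minimum(u, v)
        mx = np.maximum(u, v)
        return mn + k * np.power(u * v, a) * (1.0 - np.power(mx, -b))

    def _pdf(self, u, v, theta):
        a, b, k = self._abk(theta)
        th = theta[0]
        mn = np.minimum(u, v)
        mx = np.maximum(u, v)
        # for u < v (and symmetrically): c = k a² (uv)^{a-1} + k a θ/(1-θ) mn^{a-1} mx^{a-b-1}
        with np.errstate(all="ignore"):
            out = k * a * a * np.power(u * v, a - 1.0) + k * a * th / (
                1.0 - th
            ) * np.power(mn, a - 1.0) * np.power(mx, a - b - 1.0)
        return np.where(np.isfinite(out), out, 0.0)

    def _hfunc(self, v, u, theta):
        a, b, k = self._abk(theta)
        lower = u < v  # min = u
        with np.errstate(all="ignore"):
            # branch u < v: dC/du = 1 + k[a u^{a-1} v^a - a u^{a-1} v^{a-b}]
            h_low = 1.0 + k * a * np.power(u, a - 1.0) * (
                np.power(v, a) - np.power(v, a - b)
            )
            # branch u >= v: dC/du = k[a u^{a-1} v^a - (a-b) v^a u^{a-b-1}]
            h_high = k * np.power(v, a) * (
                a * np.power(u, a - 1.0) - (a - b) * np.power(u, a - b - 1.0)
            )
            out = np.where(lower, h_low, h_high)
        return np.where(np.isfinite(out), out, np.where(lower, 1.0, 0.0))

    def _tau(self, theta):
        th = theta[0]
        return 2.0 * th / (3.0 - th)

    def theta_from_tau(self, tau):
        if not 0.0 < tau < 1.0:
            raise ValueError(f"raftery: tau={tau} outside attainable range (0, 1)")
        th = 3.0 * tau / (2.0 + tau)
        lo, hi = self.param_bounds[0]
        if not lo <= th <= hi:
            raise ValueError(f"raftery: tau={tau} maps outside theta domain")
        return CopulaParams(self.name, (th,))


class MarshallOlkin(CopulaFamily):
    """Marshall–Olkin copula C(u,v) = min(v u^{1−θ1}, u v^{1−θ2}).

    Has a singular component of mass τ = θ1θ2/(θ1+θ2−θ1θ2) along the curve
    u^{θ1} = v^{θ2}; the density below is the absolutely continuous part.
    Sampled exactly by the exponential-shock construction.
    """

    name = "marshall_olkin"
    n_params = 2
    param_bounds = ((1e-4, 1.0), (1e-4, 1.0))
    supports_closed_form_tau = True
    absolutely_continuous = False

    def _cdf(self, u, v, theta):
        a, b = theta
        return np.minimum(v * np.power(u, 1.0 - a), u * np.power(v, 1.0 - b))

    def _pdf(self, u, v, theta):
        a, b = theta
        ua = np.power(u, a)
        vb = np.power(v, b)
        return np.where(ua > vb, (1.0 - a) * np.power(u, -a), (1.0 - b) * np.power(v, -b))

    def _hfunc(self, v, u, theta):
        a, b = theta
        ua = np.power(u, a)
        vb = np.power(v, b)
        return np.where(
            ua >= vb, (1.0 - a) * np.power(u, -a) * v, np.power(v, 1.0 - b)
        )

    def sample(self, n, theta, rng):
        self.check_theta(theta)
        if n < 1:
            raise ValueError("n must be >= 1")
        a, b = theta
        # shock rates chosen so the survival exponents give (alpha, beta) = (a, b)
        l1 = (1.0 - a) / a
        l2 = (1.0 - b) / b
        z1 = rng.exponential(1.0 / l1, size=n) if l1 > 0 else np.full(n, np.inf)
        z2 = rng.exponential(1.0 / l2, size=n) if l2 > 0 else np.full(n, np.inf)
        z12 = rng.exponential(1.0, size=n)
        x = np.minimum(z1, z12)
        y = np.minimum(z2, z12)
        # X has rate l1 + 1 = 1/a ; survival U' = exp(-x/a); use u = 1 - U'
        u = 1.0 - np.exp(-x / a)
        v = 1.0 - np.exp(-y / b)
        # copula of survival functions: MO copula couples (exp(-x/a), exp(-y/b));
        # flip both to keep positive dependence with uniform margins
        return np.column_stack([1.0 - u, 1.0 - v])

    def _tau(self, theta):
        a, b = theta
        return a * b / (a + b - a * b)


class RochAlegre(ArchimedeanFamily):
    """Two-parameter Archimedean family with generator
    φ(t) = ((1 − ln t)^θ1 − 1)^θ2,  θ1 > 0, θ2 ≥ 1
    (inverse φ⁻¹(s) = exp(1 − (s^{1/θ2} + 1)^{1/θ1})).
    """

    name = "roch_alegre"
    n_params = 2
    param_bounds = ((1e-3, 10.0), (1.0, 10.0))

    def _default_extra_params(self):
        # τ-inversion anchors θ2 at 1 (second transform inactive), where the
        # attainable τ range spans ≈ (0, 1); the domain midpoint would
        # restrict it to high-τ values only
        return (1.0,)

    def phi(self, t, theta):
        a, b = theta
        # g = (1 - ln t)^a − 1 via expm1 for precision near t = 1
        g = np.expm1(a * np.log1p(-np.log(t)))
        return np.power(np.maximum(g, 0.0), b)

    def _g(self, t, a):
        return np.power(1.0 - np.log(t), a) - 1.0

    def phi_prime(self, t, theta):
        a, b = theta
        L = 1.0 - np.log(t)
        g = np.power(L, a) - 1.0
        gp = -a * np.power(L, a - 1.0) / t
        return b * np.power(np.maximum(g, 1e-300), b - 1.0) * gp

    def phi_dprime(self, t, theta):
        a, b = theta
        L = 1.0 - np.log(t)
        g = np.maximum(np.power(L, a) - 1.0, 1e-300)
        gp = -a * np.power(L, a - 1.0) / t
        gpp = (a * (a - 1.0) * np.power(L, a - 2.0) + a * np.power(L, a - 1.0)) / (t * t)
        return b * (b - 1.0) * np.power(g, b - 2.0) * gp * gp + b * np.power(
            g, b - 1.0
        ) * gpp

    def phi_inv(self, s, theta):
        a, b = theta
        return np.exp(1.0 - np.power(np.power(s, 1.0 / b) + 1.0, 1.0 / a))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, CopulaFamily] = {}


def register_family(family: CopulaFamily) -> None:
    _REGISTRY[family.name] = family


for _cls in (
    Independence,
    Gaussian,
    Clayton,
    Frank,
    Gumbel,
    Joe,
    AMH,
    Raftery,
    MarshallOlkin,
    RochAlegre,
):
    register_family(_cls())


def get_family(name) -> CopulaFamily:
    if isinstance(name, CopulaFamily):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown copula family {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def list_families() -> list[str]:
    return sorted(_REGISTRY)


def registry_descriptor() -> str:
    """JSON descriptor of the registry (name, n_params, parameter domains)."""
    return json.dumps([_REGISTRY[k].descriptor() for k in sorted(_REGISTRY)], indent=2)


def registry_from_descriptor(text: str) -> list[dict]:
    """Parse and validate a registry descriptor against loaded families."""
    entries = json.loads(text)
    for e in entries:
        fam = get_family(e["name"])
        if fam.n_params != e["n_params"]:
            raise ValueError(f"descriptor mismatch for {e['name']}: n_params")
    return entries


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def copula_cdf(params: CopulaParams, u, v):
    """C(u, v) with Sklar boundary conditions enforced exactly."""
    return get_family(params.family).cdf(u, v, params.theta)


def copula_density(params: CopulaParams, u, v):
    """Copula density c(u, v) on the open unit square."""
    return get_family(params.family).pdf(u, v, params.theta)


def conditional_cdf(params: CopulaParams, v, given_u):
    """h-function h(v | u) = ∂C(u, v)/∂u — the conditional CDF of V given U=u."""
    return get_family(params.family).hfunc(v, given_u, params.theta)


def sample_copula(params: CopulaParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` dependent uniform pairs, reproducibly for a given seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return get_family(params.family).sample(n, params.theta, rng)


def tau_from_theta(params: CopulaParams) -> float:
    """Population Kendall τ implied by the parameters."""
    return get_family(params.family).tau(params.theta)


def theta_from_tau(family, tau: float) -> CopulaParams:
    """Parameters matching a target τ (θ2 at its domain-midpoint default)."""
    return get_family(family).theta_from_tau(tau)
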