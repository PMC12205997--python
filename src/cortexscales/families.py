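"""Four-parameter distribution families for normative trajectory models.

Two families are provided:

* ``gaussian`` — location/scale only (the skew and kurtosis parameters are
  carried but inert), a robust fallback;
* ``bcpe`` — Box-Cox power exponential: a Box-Cox transform
  ``z = ((y/mu)^nu - 1) / (nu sigma)`` (log form at nu=0) of a positive
  response, with the standardized residual following a power-exponential
  distribution whose shape parameter ``tau`` controls kurtosis (tau=2 is
  Gaussian).  The density is truncated to y > 0 as usual.

Each family exposes per-observation ``loglik``, ``cdf`` and ``ppf`` in
terms of (mu, sigma, nu, tau) arrays, plus link functions mapping each
parameter to an unconstrained linear-predictor scale.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import norm

_EPS = 1e-10


class Gaussian:
    """y ~ N(mu, sigma); nu, tau unused."""

    name = "gaussian"
    params = ("mu", "sigma")
    links = {"mu": "identity", "sigma": "log", "nu": "identity", "tau": "log"}

    @staticmethod
    def loglik(y, mu, sigma, nu=None, tau=None):
        return norm.logpdf(y, loc=mu, scale=sigma)

    @staticmethod
    def cdf(y, mu, sigma, nu=None, tau=None):
        return norm.cdf(y, loc=mu, scale=sigma)

    @staticmethod
    def ppf(q, mu, sigma, nu=None, tau=None):
        return norm.ppf(q, loc=mu, scale=sigma)

    @staticmethod
    def default_eta(y):
        return {"mu": float(np.mean(y)), "sigma": float(np.log(np.std(y) + _EPS))}


def _pe_const(tau):
    """log normalising pieces of the standardized power exponential."""
    log_c = 0.5 * (-2.0 / tau * np.log(2.0) + special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau))
    return log_c


def _pe_logpdf(z, tau):
    log_c = _pe_const(tau)
    c = np.exp(log_c)
    return (
        np.log(tau)
        - log_c
        - (1.0 + 1.0 / tau) * np.log(2.0)
        - special.gammaln(1.0 / tau)
        - 0.5 * np.abs(z / c) ** tau
    )


def _pe_cdf(z, tau):
    c = np.exp(_pe_const(tau))
    s = 0.5 * np.abs(z / c) ** tau
    p = special.gammainc(1.0 / tau, s)
    return 0.5 * (1.0 + np.sign(z) * p)


def _pe_ppf(q, tau):
    q = np.asarray(q, dtype=float)
    c = np.exp(_pe_const(tau))
    s = special.gammaincinv(1.0 / tau, np.abs(2.0 * q - 1.0))
    return np.sign(q - 0.5) * c * (2.0 * s) ** (1.0 / tau)


class BCPE:
    """Box-Cox power exponential on a positive response."""

    name = "bcpe"
    params = ("mu", "sigma", "nu", "tau")
    links = {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}

    @staticmethod
    def _z(y, mu, sigma, nu):
        ratio = y / mu
        small = np.abs(nu) < 1e-8
        with np.errstate(divide="ignore", invalid="ignore"):
            z_gen = (ratio**nu - 1.0) / (nu * sigma)
        z_log = np.log(ratio) / sigma
        return np.where(small, z_log, z_gen)

    @staticmethod
    def _log_trunc(sigma, nu, tau):
        # P(Z < 1/(sigma|nu|)) -- the mass kept by truncating to y > 0.
        lim = 1.0 / (sigma * np.maximum(np.abs(nu), 1e-8))
        p = _pe_cdf(lim, tau)
        p = np.where(np.abs(nu) < 1e-8, 1.0, p)
        return np.log(np.maximum(p, _EPS))

    @classmethod
    def loglik(cls, y, mu, sigma, nu, tau):
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0) or np.any(mu <= 0) or np.any(sigma <= 0) or np.any(tau <= 0):
            return np.full(np.broadcast(y, mu).shape, -np.inf)
        z = cls._z(y, mu, sigma, nu)
        ll = (
            (nu - 1.0) * np.log(y)
            - nu * np.log(mu)
            - np.log(sigma)
            + _pe_logpdf(z, tau)
            - cls._log_trunc(sigma, nu, tau)
        )
        return ll

    @classmethod
    def cdf(cls, y, mu, sigma, nu, tau):
        z = cls._z(np.asarray(y, dtype=float), mu, sigma, nu)
        nu_b = np.broadcast_to(nu, z.shape)
        sig_b = np.broadcast_to(sigma, z.shape)
        tau_b = np.broadcast_to(tau, z.shape)
        fz = _pe_cdf(z, tau_b)
        trunc = np.exp(cls._log_trunc(sig_b, nu_b, tau_b))
        lower = 1.0 - _pe_cdf(1.0 / (sig_b * np.maximum(np.abs(nu_b), 1e-8)), tau_b)
        pos = nu_b > 1e-8
        out = np.where(pos, (fz - lower) / trunc, fz / trunc)
        return np.clip(out, 0.0, 1.0)

    @classmethod
    def ppf(cls, q, mu, sigma, nu, tau):
        q = np.asarray(q, dtype=float)
        nu_b = np.broadcast_to(np.asarray(nu, float), np.broadcast(q, mu).shape).astype(float)
        sig_b = np.broadcast_to(np.asarray(sigma, float), nu_b.shape).astype(float)
        tau_b = np.broadcast_to(np.asarray(tau, float), nu_b.shape).astype(float)
        mu_b = np.broadcast_to(np.asarray(mu, float), nu_b.shape).astype(float)
        trunc = np.exp(cls._log_trunc(sig_b, nu_b, tau_b))
        lower = 1.0 - _pe_cdf(1.0 / (sig_b * np.maximum(np.abs(nu_b), 1e-8)), tau_b)
        pos = nu_b > 1e-8
        q_adj = np.where(pos, q * trunc + lower, q * trunc)
        z = _pe_ppf(np.clip(q_adj, _EPS, 1.0 - _EPS), tau_b)
        small = np.abs(nu_b) < 1e-8
        with np.errstate(invalid="ignore"):
            base = np.maximum(1.0 + sig_b * nu_b * z, _EPS)
            y_gen = mu_b * base ** (1.0 / np.where(small, 1.0, nu_b))
        y_log = mu_b * np.exp(sig_b * z)
        return np.where(small, y_log, y_gen)

    @staticmethod
    def default_eta(y):
        return {
            "mu": float(np.log(np.mean(y))),
            "sigma": float(np.log(np.std(y) / np.mean(y) + _EPS)),
            "nu": 1.0,
            "tau": float(np.log(2.0)),
        }


FAMILIES = {"gaussian": Gaussian, "bcpe": BCPE}


def apply_link(name: str, eta: np.ndarray) -> np.ndarray:
    """Map a linear predictor to the distribution-parameter scale."""
    return np.exp(eta) if name == "log" else eta


def link_of(family, param: str) -> str:
    return family.links[param]
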