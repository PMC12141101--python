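"""Wind-speed profiles for near-surface shear soaring.

Two profile families are supported:

* ``logarithmic`` — the standard neutral atmospheric-boundary-layer profile
  ``W(z) = W_ref * log(z / h_0) / log(h_ref / h_0)``, parameterized by the
  reference wind speed ``W_ref`` at reference height ``h_ref`` (10 m) and a
  surface roughness length ``h_0`` (0.03 m, open sea).
* ``sigmoid`` — ``W(z) = W_ref / (1 + exp(-z / h_ref))``, which keeps wind
  speeds low over a finite height band (wave-shadow / lee conditions).

The shear strength ``sigma(z) = dW/dz`` is the vertical gradient of the
horizontal wind and drives the energy-harvest term of the glider energetics.
For the logarithmic family the height-averaged shear over ``[h_0, h_ref]``
has the closed form ``sigma_bar = W_ref / (h_ref - h_0)``, which is used as
the scalar "environmental energy supply" axis throughout the package.

The raw operations raise on out-of-domain heights.  Trajectory-integration
code that may momentarily evaluate below ``h_0`` should use the ``clamped=``
variants of :func:`wind_speed` / :func:`shear_strength` so a constraint
violation is never hidden silently in analysis paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindProfileConfig",
    "wind_speed",
    "shear_strength",
    "mean_shear",
]


@dataclass(frozen=True)
class WindProfileConfig:
    """Wind-profile family and parameters.

    Parameters
    ----------
    family:
        ``"logarithmic"`` or ``"sigmoid"``.
    W_ref:
        Reference wind speed [m/s] (at ``h_ref`` for the logarithmic family;
        the asymptotic speed for the sigmoid family).
    h_ref:
        Reference height [m].  Default 10 m (logarithmic).  For the sigmoid
        family the conventional scale height is 1.0 m.
    h_0:
        Surface roughness length [m], logarithmic family only.
    """

    family: str = "logarithmic"
    W_ref: float = 10.0
    h_ref: float = 10.0
    h_0: float = 0.03

    def __post_init__(self) -> None:
        if self.family not in ("logarithmic", "sigmoid"):
            raise ValueError(f"unknown wind family {self.family!r}")
        if self.W_ref < 0:
            raise ValueError("W_ref must be >= 0")
        if self.family == "logarithmic":
            if not (self.h_ref > self.h_0 > 0):
                raise ValueError("logarithmic profile requires h_ref > h_0 > 0")
        else:
            if self.h_ref <= 0:
                raise ValueError("sigmoid profile requires h_ref > 0")

    @classmethod
    def sigmoid(cls, W_ref: float = 10.0, h_ref: float = 1.0) -> "WindProfileConfig":
        """Sigmoid profile with the conventional 1-m scale height."""
        return cls(family="sigmoid", W_ref=W_ref, h_ref=h_ref)

    @property
    def log_denominator(self) -> float:
        """log(h_ref / h_0) for the logarithmic family."""
        return math.log(self.h_ref / self.h_0)


def wind_speed(z, cfg: WindProfileConfig, clamped: bool = False):
    """Horizontal wind speed W(z) [m/s] at height(s) ``z`` [m].

    With ``clamped=True`` (integration utilities only) logarithmic wind below
    ``h_0`` is clamped to 0 instead of raising.
    """
    z = np.asarray(z, dtype=float)
    if cfg.family == "logarithmic":
        if clamped:
            zc = np.maximum(z, cfg.h_0)
            out = cfg.W_ref * np.log(zc / cfg.h_0) / cfg.log_denominator
        else:
            if np.any(z <= 0):
                raise ValueError("logarithmic wind profile undefined for z <= 0")
            out = cfg.W_ref * np.log(z / cfg.h_0) / cfg.log_denominator
    else:
        if not clamped and np.any(z < 0):
            raise ValueError("sigmoid wind profile defined for z >= 0")
        out = cfg.W_ref / (1.0 + np.exp(-z / cfg.h_ref))
    return out if out.ndim else float(out)


def shear_strength(z, cfg: WindProfileConfig, clamped: bool = False):
    """Wind shear sigma(z) = dW/dz [1/s] at height(s) ``z`` [m].

    Logarithmic: ``sigma = W_ref / (log(h_ref/h_0) * z)``.
    Sigmoid: analytic derivative ``W_ref * e^(-z/h_ref) / (h_ref (1+e^(-z/h_ref))^2)``.
    With ``clamped=True``, logarithmic sigma below ``h_0`` is held at sigma(h_0).
    """
    z = np.asarray(z, dtype=float)
    if cfg.family == "logarithmic":
        if clamped:
            zc = np.maximum(z, cfg.h_0)
            out = cfg.W_ref / (cfg.log_denominator * zc)
        else:
            if np.any(z <= 0):
                raise ValueError("shear strength undefined for z <= 0 (logarithmic)")
            out = cfg.W_ref / (cfg.log_denominator * z)
    else:
        if not clamped and np.any(z < 0):
            raise ValueError("sigmoid shear defined for z >= 0")
        e = np.exp(-z / cfg.h_ref)
        out = cfg.W_ref * e / (cfg.h_ref * (1.0 + e) ** 2)
    return out if out.ndim else float(out)


def mean_shear(cfg: WindProfileConfig) -> float:
    """Height-averaged shear sigma_bar = W_ref / (h_ref - h_0) [1/s].

    Defined only for the logarithmic family, where it is the exact average of
    ``shear_strength`` over ``[h_0, h_ref]``.
    """
    if cfg.family != "logarithmic":
        raise NotImplementedError("mean shear is defined for the logarithmic family only")
    return cfg.W_ref / (cfg.h_ref - cfg.h_0)
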