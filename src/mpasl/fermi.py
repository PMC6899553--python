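"""Modified Fermi signal model for multi-phase PCASL.

The signal acquired at RF phase offset ``theta`` (degrees) in a multi-phase
pseudo-continuous ASL experiment is modelled as an empirical line shape

    f(theta) = Ms - dM * [ 2 / (1 + exp((|theta - phi| - alpha) / beta)) - 1 ]

where ``Ms`` is the static tissue magnitude, ``dM`` the perfusion-weighted
modulation amplitude, ``phi`` the off-resonance phase offset of the feeding
artery, and ``alpha``/``beta`` (degrees) control the width and steepness of
the inversion notch.  At ``theta = phi`` labelling is maximal and the signal
is ``Ms - dM``; at 180 degrees away the acquisition is a pure control and the
signal approaches ``Ms + dM``.

All angles at this interface are in degrees, and the phase difference is
always the wrapped circular distance in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FermiShape",
    "FermiParams",
    "HUMAN_SHAPE",
    "RAT_SHAPE",
    "wrap_phase",
    "wrap_phase_difference",
    "fermi_bracket",
    "evaluate_fermi",
]


@dataclass(frozen=True)
class FermiShape:
    """Line-shape constants of the modified Fermi function.

    Parameters
    ----------
    alpha : float
        Half-width of the inversion notch, degrees.  54 for human 3T
        acquisitions, 70 for rat acquisitions at 9.4T.
    beta : float
        Steepness of the notch shoulder, degrees.  13 (human) / 19 (rat).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")


#: Line shape for human 3T multi-phase PCASL.
HUMAN_SHAPE = FermiShape(alpha=54.0, beta=13.0)
#: Line shape for preclinical (rat, 9.4T) multi-phase PCASL.
RAT_SHAPE = FermiShape(alpha=70.0, beta=19.0)


@dataclass(frozen=True)
class FermiParams:
    """Voxel (or region) parameters of the modified Fermi model.

    ``delta_m`` and ``m_s`` are in arbitrary signal units, ``phi`` in degrees
    wrapped to [0, 360).
    """

    delta_m: float
    m_s: float
    phi: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.delta_m, self.m_s, self.phi]).all():
            raise ValueError("FermiParams fields must be finite")
        if self.delta_m < 0:
            raise ValueError(f"delta_m must be >= 0, got {self.delta_m}")
        if self.m_s < 0:
            raise ValueError(f"m_s must be >= 0, got {self.m_s}")
        object.__setattr__(self, "phi", float(np.mod(self.phi, 360.0)))


def wrap_phase(phi):
    """Wrap angles (degrees) to the principal range [0, 360)."""
    return np.mod(phi, 360.0)


def _wrap_signed(delta):
    """Wrap a phase difference (degrees) to (-180, 180]."""
    return -(np.mod(-np.asarray(delta, dtype=float) + 180.0, 360.0) - 180.0)


def wrap_phase_difference(theta, phi):
    """Circular absolute difference ``|theta - phi|`` in degrees, in [0, 180].

    Equals ``min_k |theta - phi + 360 k|``.  Inputs may be scalars or arrays
    (broadcast); non-finite input raises ``ValueError``.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(phi))):
        raise ValueError("wrap_phase_difference requires finite inputs")
    out = np.abs(_wrap_signed(theta - phi))
    return out if out.ndim else float(out)


def fermi_bracket(abs_delta, shape: FermiShape):
    """The bracket term ``2 / (1 + exp((|d| - alpha)/beta)) - 1`` in [-1, 1].

    ``abs_delta`` is the wrapped absolute phase difference in degrees.
    Equals +1 deep inside the notch (maximal labelling), 0 at
    ``|d| = alpha`` and -1 far outside (control condition).
    """
    x = (np.asarray(abs_delta, dtype=float) - shape.alpha) / shape.beta
    return 2.0 / (1.0 + np.exp(np.clip(x, -500.0, 500.0))) - 1.0


def evaluate_fermi(params: FermiParams, shape: FermiShape, thetas):
    """Evaluate the modified Fermi model at phase offsets ``thetas`` (degrees).

    Returns an array of signals ``Ms - dM * bracket(|theta - phi|)``, each in
    ``[Ms - dM, Ms + dM]``.
    """
    if not isinstance(shape, FermiShape):
        shape = FermiShape(*shape)
    d = wrap_phase_difference(thetas, params.phi)
    return params.m_s - params.delta_m * fermi_bracket(d, shape)
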