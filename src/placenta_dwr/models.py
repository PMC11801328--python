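"""Forward signal models for combined diffusion-relaxation MRI.

Two voxel-wise models describe the measured magnitude signal S(TE, b):

* mono-exponential T2*-ADC::

      S = S0 * exp(-(TE - TE_min)/T2*) * exp(-b * ADC)

* two-compartment T2*-IVIM, separating fast pseudo-diffusion (perfusing
  blood, coefficient D*, relaxation T2*_fast) from slow true diffusion
  (coefficient ADC, relaxation T2*_slow), mixed by the perfusion
  fraction f::

      S = S0 * [ f * exp(-(TE - TE_min)/T2*_fast) * exp(-b * D*)
               + (1 - f) * exp(-(TE - TE_min)/T2*_slow) * exp(-b * ADC) ]

S0 is the signal at the shortest echo time with zero diffusion weighting.
A single-tensor model provides the direction-dependent substrate for
fractional anisotropy at the first TE: S = S0 * exp(-b * g^T D g).

Compartments are labelled so that D* > ADC (the fast compartment is the
one with the larger diffusion coefficient); f always refers to the fast
compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionScheme

__all__ = [
    "MonoExpParams",
    "IvimParams",
    "DiffusionTensor",
    "signal_monoexp",
    "signal_ivim",
    "signal_tensor",
    "fractional_anisotropy",
]


@dataclass(frozen=True)
class MonoExpParams:
    """T2*-ADC model parameters for one voxel or ROI.

    s0 in arbitrary units (> 0), t2_star in ms (> 0), adc in mm^2/s (>= 0).
    """

    s0: float
    t2_star: float
    adc: float

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError(f"s0 must be > 0, got {self.s0}")
        if self.t2_star <= 0:
            raise ValueError(f"t2_star must be > 0, got {self.t2_star}")
        if self.adc < 0:
            raise ValueError(f"adc must be >= 0, got {self.adc}")


@dataclass(frozen=True)
class IvimParams:
    """Two-compartment T2*-IVIM parameters for one voxel or ROI.

    f is the perfusion (fast-compartment) signal fraction in [0, 1];
    t2_star_fast / t2_star_slow in ms; d_star and adc in mm^2/s with
    d_star > adc by labelling convention (enforced at construction when
    both are positive and f is interior; degenerate draws may tie).
    """

    s0: float
    f: float
    t2_star_fast: float
    t2_star_slow: float
    d_star: float
    adc: float

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError(f"s0 must be > 0, got {self.s0}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"perfusion fraction must lie in [0, 1], got {self.f}")
        if self.t2_star_fast <= 0 or self.t2_star_slow <= 0:
            raise ValueError("compartment T2* values must be > 0")
        if self.d_star < 0 or self.adc < 0:
            raise ValueError("diffusion coefficients must be >= 0")

    def canonical(self) -> "IvimParams":
        """Relabel compartments so d_star > adc (f follows the fast one)."""
        if self.d_star >= self.adc:
            return self
        return IvimParams(
            s0=self.s0,
            f=1.0 - self.f,
            t2_star_fast=self.t2_star_slow,
            t2_star_slow=self.t2_star_fast,
            d_star=self.adc,
            adc=self.d_star,
        )

    @property
    def slow_monoexp(self) -> MonoExpParams:
        """The slow compartment viewed as a mono-exponential model."""
        return MonoExpParams(self.s0, self.t2_star_slow, self.adc)


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric 3x3 diffusion tensor (mm^2/s) plus non-DW signal s0."""

    dxx: float
    dyy: float
    dzz: float
    dxy: float
    dxz: float
    dyz: float
    s0: float = 1.0

    @classmethod
    def from_matrix(cls, d: np.ndarray, s0: float = 1.0) -> "DiffusionTensor":
        d = np.asarray(d, dtype=float)
        if d.shape != (3, 3):
            raise ValueError(f"tensor must be 3x3, got shape {d.shape}")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("diffusion tensor must be symmetric")
        return cls(d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2], s0)

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.dxx, self.dxy, self.dxz],
                [self.dxy, self.dyy, self.dyz],
                [self.dxz, self.dyz, self.dzz],
            ]
        )

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.as_matrix())

    @property
    def fa(self) -> float:
        return fractional_anisotropy(self.eigenvalues())


def fractional_anisotropy(eigenvalues: np.ndarray) -> float:
    """FA from tensor eigenvalues.

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2) / sqrt(l1^2+l2^2+l3^2),
    0 for isotropic tensors, 1 in the rank-1 limit.  Returns 0 for an
    all-zero tensor.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    denom = np.sqrt(np.sum(lam**2))
    if denom == 0.0:
        return 0.0
    num = np.sqrt(
        (lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[2] - lam[0]) ** 2
    )
    return float(np.sqrt(0.5) * num / denom)


def _decay(te: np.ndarray, te_min: float, t2: float) -> np.ndarray:
    return np.exp(-(te - te_min) / t2)


def signal_monoexp(params: MonoExpParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Noiseless T2*-ADC signal, one value per scheme measurement.

    Independent of gradient direction; equals s0 at (TE = TE_min, b = 0).
    """
    te = scheme.echo_times
    b = scheme.b_values
    return params.s0 * _decay(te, scheme.te_min, params.t2_star) * np.exp(-b * params.adc)


def signal_ivim(params: IvimParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Noiseless two-compartment T2*-IVIM signal per scheme measurement."""
    te = scheme.echo_times
    b = scheme.b_values
    te_min = scheme.te_min
    fast = params.f * _decay(te, te_min, params.t2_star_fast) * np.exp(-b * params.d_star)
    slow = (1.0 - params.f) * _decay(te, te_min, params.t2_star_slow) * np.exp(-b * params.adc)
    return params.s0 * (fast + slow)


def signal_tensor(tensor: DiffusionTensor, scheme: AcquisitionScheme) -> np.ndarray:
    """Single-tensor diffusion signal S = s0 * exp(-b g^T D g).

    The scheme must contain first-TE measurements only: the tensor model
    carries no relaxation term, matching its use as the FA substrate on
    the shortest-echo-time data.
    """
    te = scheme.echo_times
    if not np.allclose(te, te[0]):
        raise ValueError("tensor model expects a single-TE (first-TE) scheme")
    d = tensor.as_matrix()
    g = scheme.directions
    b = scheme.b_values
    quad = np.einsum("ij,jk,ik->i", g, d, g)
    return tensor.s0 * np.exp(-b * quad)
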