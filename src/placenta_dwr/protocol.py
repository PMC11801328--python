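"""Multi-echo multi-b diffusion acquisition schemes.

A combined diffusion-relaxation acquisition interleaves diffusion
preparations (b-value + gradient direction) with several gradient-echo
readout times, so every voxel is sampled on a (b, g, TE) grid.  The scheme
object carries one row per acquired volume and is the measurement-space
contract shared by the forward signal models and the fitters.

Sidecars use the FSL bval/bvec dialect (one space-separated row per
quantity) plus a same-length echo-time file in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Measurement",
    "AcquisitionScheme",
    "build_protocol_scheme",
    "shell_directions",
    "read_scheme",
    "write_scheme",
]

#: Shells of the placental protocol: b-value (s/mm^2) -> number of gradient
#: directions.  Ten shells carry 3 directions; b=18, 36 and 800 carry 8, 7
#: and 15.  Together: 60 diffusion preparations.
PROTOCOL_SHELLS: dict[float, int] = {
    5: 3, 10: 3, 18: 8, 25: 3, 36: 7, 50: 3, 100: 3,
    200: 3, 400: 3, 600: 3, 800: 15, 1200: 3, 1600: 3,
}

#: Echo times of the protocol, ms.
PROTOCOL_ECHO_TIMES: tuple[float, ...] = (78.0, 114.0, 150.0, 186.0)

_DIRECTION_TOL = 1e-6


@dataclass(frozen=True)
class Measurement:
    """One acquired volume: diffusion weighting, direction and echo time.

    Parameters
    ----------
    b_value : float
        Diffusion weighting in s/mm^2, >= 0.
    direction : tuple of float
        Unit gradient direction (checked to 1e-6 when b_value > 0).
    echo_time : float
        Echo time in ms, > 0.
    """

    b_value: float
    direction: tuple[float, float, float]
    echo_time: float

    def __post_init__(self) -> None:
        if self.b_value < 0:
            raise ValueError(f"b_value must be >= 0, got {self.b_value}")
        if self.echo_time <= 0:
            raise ValueError(f"echo_time must be > 0, got {self.echo_time}")
        if self.b_value > 0:
            norm = float(np.linalg.norm(self.direction))
            if abs(norm - 1.0) > _DIRECTION_TOL:
                raise ValueError(
                    f"direction must be unit length for b > 0; |g| = {norm:.8f}"
                )


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered collection of measurements defining the acquisition.

    ``te_min`` (the shortest echo time acquired) is the reference point of
    the T2* decay term in both signal models and is derived, not supplied.
    """

    measurements: tuple[Measurement, ...]

    def __post_init__(self) -> None:
        if len(self.measurements) == 0:
            raise ValueError("an acquisition scheme cannot be empty")

    @property
    def te_min(self) -> float:
        return min(m.echo_time for m in self.measurements)

    def __len__(self) -> int:
        return len(self.measurements)

    # --- array views used by the numerical code ------------------------
    @property
    def b_values(self) -> np.ndarray:
        return np.array([m.b_value for m in self.measurements], dtype=float)

    @property
    def directions(self) -> np.ndarray:
        return np.array([m.direction for m in self.measurements], dtype=float)

    @property
    def echo_times(self) -> np.ndarray:
        return np.array([m.echo_time for m in self.measurements], dtype=float)

    def subset(self, mask: np.ndarray) -> "AcquisitionScheme":
        """Scheme restricted to measurements where ``mask`` is True."""
        kept = tuple(m for m, k in zip(self.measurements, mask) if k)
        return AcquisitionScheme(kept)

    def at_first_te(self) -> "AcquisitionScheme":
        """Measurements acquired at the shortest echo time only."""
        te0 = self.te_min
        return self.subset(self.echo_times == te0)


def shell_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Evenly spread ``n`` unit directions by electrostatic repulsion.

    Directions are treated as antipodally symmetric (a diffusion gradient
    and its negation probe the same axis), so charges repel both each
    other and each other's antipodes.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    if n == 1:
        return np.array([[1.0, 0.0, 0.0]])
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            dist2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            force += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        pts = pts + step * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # canonical hemisphere + stable order so the scheme is reproducible
    flip = pts[:, 2] < 0
    pts[flip] *= -1.0
    order = np.lexsort((pts[:, 1], pts[:, 0], pts[:, 2]))
    return pts[order]


def build_protocol_scheme() -> AcquisitionScheme:
    """Build the full placental protocol scheme.

    Sixty diffusion preparations (see :data:`PROTOCOL_SHELLS`), each
    replicated at four echo times {78, 114, 150, 186} ms: 240 volumes.
    Shells ascend by b, directions in generation order, TE innermost.
    """
    measurements: list[Measurement] = []
    for shell_index, b in enumerate(sorted(PROTOCOL_SHELLS)):
        n_dir = PROTOCOL_SHELLS[b]
        dirs = shell_directions(n_dir, seed=shell_index)
        for g in dirs:
            for te in PROTOCOL_ECHO_TIMES:
                measurements.append(
                    Measurement(float(b), (float(g[0]), float(g[1]), float(g[2])), te)
                )
    return AcquisitionScheme(tuple(measurements))


class SchemeFormatError(ValueError):
    """Sidecar files are inconsistent or unparsable."""


def _read_rows(path: Path, expected_rows: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise SchemeFormatError(
                    f"{path}: non-numeric token on line {lineno}: {exc}"
                ) from None
    if len(rows) != expected_rows:
        raise SchemeFormatError(
            f"{path}: expected {expected_rows} row(s), found {len(rows)}"
        )
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise SchemeFormatError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    return np.asarray(rows, dtype=float)


def read_scheme(bval_path, bvec_path, te_path) -> AcquisitionScheme:
    """Read a scheme from FSL-style bval/bvec sidecars plus a TE file (ms).

    All three files must encode the same number of measurements; a length
    mismatch raises :class:`SchemeFormatError` naming the offending file.
    """
    bvals = _read_rows(Path(bval_path), 1)[0]
    bvecs = _read_rows(Path(bvec_path), 3)
    tes = _read_rows(Path(te_path), 1)[0]
    n = len(bvals)
    if bvecs.shape[1] != n:
        raise SchemeFormatError(
            f"{bvec_path}: {bvecs.shape[1]} columns but {bval_path} has {n}"
        )
    if len(tes) != n:
        raise SchemeFormatError(
            f"{te_path}: {len(tes)} entries but {bval_path} has {n}"
        )
    measurements = tuple(
        Measurement(float(bvals[i]), (float(bvecs[0, i]), float(bvecs[1, i]), float(bvecs[2, i])), float(tes[i]))
        for i in range(n)
    )
    return AcquisitionScheme(measurements)


def write_scheme(scheme: AcquisitionScheme, bval_path, bvec_path, te_path) -> None:
    """Write sidecar files that :func:`read_scheme` reads back identically.

    Values are written with 6 significant digits, enough to round-trip the
    unit-direction tolerance.
    """

    def fmt(values: Iterable[float]) -> str:
        return " ".join(f"{v:.6g}" for v in values)

    Path(bval_path).write_text(fmt(scheme.b_values) + "\n")
    bvecs = scheme.directions.T
    Path(bvec_path).write_text("\n".join(fmt(row) for row in bvecs) + "\n")
    Path(te_path).write_text(fmt(scheme.echo_times) + "\n")
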