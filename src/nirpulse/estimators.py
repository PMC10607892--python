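"""Pigment-component separation: matrix inverse vs Wiener estimation.

The conventional separation inverts the system matrix, r = F^-1 v, and is
blind to sensor noise; with the weak hemoglobin band contrast of the
near-infrared range, F is nearly singular and the inversion amplifies
noise strongly.  The Wiener (linear MMSE) estimator instead uses the
second-order statistics of the pigment components (Rrr) and of the noise
(Rnn) to build the estimation matrix

    G = Rrr F^T (F Rrr F^T + Rnn)^-1

which minimizes the ensemble mean squared error <(r - G v)^T (r - G v)>
and reduces to F^-1 as the noise vanishes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError, NumericalError
from .forward_model import DensitySeries, PigmentSeries, SystemMatrix

__all__ = [
    "AutocorrelationMatrix",
    "WienerEstimator",
    "conventional_separate",
    "build_pigment_autocorrelation",
    "wiener_matrix",
    "wiener_separate",
]

_SYM_TOL = 1e-9
_PSD_TOL = 1e-9
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class AutocorrelationMatrix:
    """Symmetric positive semi-definite 2x2 second-moment matrix <x x^T>.

    ``role`` records which quantity it summarizes (pigment / noise /
    observation / cross); ``provenance`` records whether it was computed
    analytically or sampled (with sample count and seed).
    """

    entries: np.ndarray
    role: str
    provenance: str = "analytic"

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        if entries.shape != (2, 2):
            raise ConfigurationError(
                f"autocorrelation matrix must be 2x2, got {entries.shape}"
            )
        if not np.all(np.isfinite(entries)):
            raise InputError("autocorrelation entries must be finite")
        scale = max(1.0, float(np.abs(entries).max()))
        if np.abs(entries - entries.T).max() > _SYM_TOL * scale:
            raise InputError("autocorrelation matrix must be symmetric")
        # cross-correlation matrices (Rrv) need not be PSD
        if self.role != "cross":
            eigvals = np.linalg.eigvalsh(0.5 * (entries + entries.T))
            if eigvals.min() < -_PSD_TOL * scale:
                raise InputError(
                    f"autocorrelation matrix must be PSD (min eigenvalue {eigvals.min():.3e})"
                )


@dataclass(frozen=True)
class WienerEstimator:
    """The Wiener estimation matrix G together with its provenance inputs."""

    G: np.ndarray
    F: SystemMatrix
    Rrr: AutocorrelationMatrix
    Rnn: AutocorrelationMatrix

    def to_json(self) -> str:
        """Serialize all matrices (and their provenance) for a run sidecar."""
        payload = {
            "G": self.G.tolist(),
            "F": self.F.entries.tolist(),
            "Rrr": {
                "entries": self.Rrr.entries.tolist(),
                "provenance": self.Rrr.provenance,
            },
            "Rnn": {
                "entries": self.Rnn.entries.tolist(),
                "provenance": self.Rnn.provenance,
            },
        }
        return json.dumps(payload, indent=2)


def conventional_separate(F: SystemMatrix, v: DensitySeries) -> PigmentSeries:
    """Noise-blind separation r = F^-1 v (one linear solve per session)."""
    F.require_invertible()
    r = np.linalg.solve(F.entries, v.vectors.T).T
    return PigmentSeries(vectors=r, frame_rate=v.frame_rate, method_tag="conventional")


def build_pigment_autocorrelation(
    hb_range: tuple[float, float],
    shade_value: float,
    n_samples: int,
    seed: int | None = None,
    hb_samples: Sequence[float] | None = None,
) -> AutocorrelationMatrix:
    """Second moment Rrr = <r r^T> of the pigment ensemble.

    The ensemble varies the hemoglobin component (uniformly over
    ``hb_range``, or over user-supplied ``hb_samples``) while the shade
    component is held fixed — blood volume fluctuates in time, the
    illumination/geometry term does not.  A degenerate range (min == max)
    yields the exact rank-one moment matrix.
    """
    lo, hi = float(hb_range[0]), float(hb_range[1])
    if lo > hi:
        raise InputError(f"hb_range min {lo} exceeds max {hi}")
    if n_samples < 1:
        raise InputError(f"n_samples must be >= 1, got {n_samples}")

    if hb_samples is not None:
        h = np.asarray(hb_samples, dtype=float)
        provenance = f"empirical({h.size})"
    elif lo == hi:
        entries = np.array(
            [
                [lo * lo, lo * shade_value],
                [lo * shade_value, shade_value * shade_value],
            ]
        )
        return AutocorrelationMatrix(
            entries=entries, role="pigment", provenance="analytic"
        )
    else:
        rng = np.random.default_rng(seed)
        h = rng.uniform(lo, hi, size=n_samples)
        provenance = f"sampled({n_samples}, seed={seed})"

    r = np.column_stack([h, np.full(h.size, shade_value)])
    entries = r.T @ r / h.size
    entries = 0.5 * (entries + entries.T)
    return AutocorrelationMatrix(entries=entries, role="pigment", provenance=provenance)


def wiener_matrix(
    Rrr: AutocorrelationMatrix, F: SystemMatrix, Rnn: AutocorrelationMatrix
) -> WienerEstimator:
    """Build G = Rrr F^T (F Rrr F^T + Rnn)^-1.

    With Rnn = 0 and invertible F this reduces exactly to F^-1.  The inner
    matrix is solved, never explicitly inverted; an ill-conditioned inner
    matrix raises with its condition number.
    """
    Fm = F.entries
    inner = Fm @ Rrr.entries @ Fm.T + Rnn.entries
    cond = float(np.linalg.cond(inner))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise NumericalError(
            f"F Rrr F^T + Rnn is numerically singular (condition number {cond:.3e})"
        )
    # inner is symmetric: G^T = inner^-1 F Rrr
    G = np.linalg.solve(inner, Fm @ Rrr.entries).T
    return WienerEstimator(G=G, F=F, Rrr=Rrr, Rnn=Rnn)


def wiener_separate(est: WienerEstimator, v: DensitySeries) -> PigmentSeries:
    """Apply the Wiener estimation matrix per frame: r~ = G v."""
    r = v.vectors @ est.G.T
    return PigmentSeries(vectors=r, frame_rate=v.frame_rate, method_tag="wiener")
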