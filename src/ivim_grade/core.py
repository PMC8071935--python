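"""IVIM forward model and core data types.

The intravoxel incoherent motion (IVIM) model describes diffusion-weighted MRI
signal decay as the sum of two exponential pools::

    S_b / S_0 = f * exp(-b * D*) + (1 - f) * exp(-b * D)

where ``D`` (mm^2/s) is the true (tissue) diffusion coefficient, ``D*``
(mm^2/s) the pseudo-diffusion coefficient attributed to capillary perfusion
(typically an order of magnitude larger than D), and ``f`` the perfusion
fraction, i.e. the fractional signal contribution of the fast pool at b = 0.

At high diffusion weighting (b >~ 200 s/mm^2) the fast pool has decayed and the
model reduces to the diffusion-only asymptote::

    S_b / S_0 = (1 - f) * exp(-b * D)

All coefficients are stored internally in mm^2/s; the reporting layer converts
to the conventional display units of 1e-3 mm^2/s (D) and 1e-2 mm^2/s (D*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PAPER_B_VALUES",
    "PAPER_NEX",
    "ValidationError",
    "BValueScheme",
    "IVIMParams",
    "SignalCurve",
    "ivim_signal",
    "ivim_signal_curve",
    "diffusion_only_signal",
    "read_curves_csv",
    "write_curves_csv",
]

#: The study's 10-b-value acquisition design (s/mm^2) ...
PAPER_B_VALUES: tuple[float, ...] = (0, 30, 50, 80, 150, 200, 400, 600, 800, 1000)
#: ... and per-b number of excitations (signal averages).
PAPER_NEX: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 2, 4, 6, 8)


class ValidationError(ValueError):
    """Raised when an input violates a model-domain invariant."""


@dataclass(frozen=True)
class BValueScheme:
    """An ordered diffusion-weighting scheme with per-b excitation counts.

    Parameters
    ----------
    b_values
        Strictly increasing b values in s/mm^2; the first must be 0 so the
        curve can be normalized to S0.
    nex
        Number of excitations (averages) per b value, all >= 1.
    """

    b_values: tuple[float, ...] = PAPER_B_VALUES
    nex: tuple[int, ...] = PAPER_NEX

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        object.__setattr__(self, "b_values", tuple(b.tolist()))
        object.__setattr__(self, "nex", tuple(int(n) for n in self.nex))
        if b.size < 2:
            raise ValidationError("scheme needs at least two b values")
        if len(self.nex) != b.size:
            raise ValidationError("b_values and nex must have equal length")
        if b[0] != 0:
            raise ValidationError("first b value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("b_values must be strictly increasing")
        if any(n < 1 for n in self.nex):
            raise ValidationError("all nex must be >= 1")

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    def __len__(self) -> int:
        return len(self.b_values)


@dataclass(frozen=True)
class IVIMParams:
    """The IVIM parameter triple.

    Attributes
    ----------
    D : float
        True diffusion coefficient, mm^2/s.
    D_star : float
        Pseudo-diffusion coefficient, mm^2/s; physically D_star > D.
    f : float
        Perfusion (pseudo-diffusion) fraction in [0, 1].
    """

    D: float
    D_star: float
    f: float

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ValidationError(f"D must be > 0, got {self.D}")
        if not (self.D_star > 0):
            raise ValidationError(f"D_star must be > 0, got {self.D_star}")
        if not (0.0 <= self.f <= 1.0):
            raise ValidationError(f"f must lie in [0, 1], got {self.f}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.D, self.D_star, self.f)


@dataclass(frozen=True)
class SignalCurve:
    """One ROI's normalized decay curve S_b/S_0 sampled on a scheme."""

    scheme: BValueScheme
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", tuple(s.tolist()))
        if s.size != len(self.scheme):
            raise ValidationError("signal length must match scheme")
        if np.any(s <= 0):
            raise ValidationError("all signal values must be > 0")

    @property
    def signal_array(self) -> np.ndarray:
        return np.asarray(self.signal, dtype=float)

    def normalized(self) -> "SignalCurve":
        """Divide by the b=0 entry so the curve starts at exactly 1."""
        s = self.signal_array
        return SignalCurve(self.scheme, tuple((s / s[0]).tolist()))


def _validate_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValidationError("b values must be non-negative")
    return b


def ivim_signal(params: IVIMParams, b) -> np.ndarray | float:
    """Evaluate the bi-exponential IVIM decay S_b/S_0 at b (scalar or array).

    Returns ``f*exp(-b*D*) + (1-f)*exp(-b*D)``; equals 1 at b = 0 and is
    strictly decreasing in b for valid parameters.
    """
    b = _validate_b(b)
    out = params.f * np.exp(-b * params.D_star) + (1.0 - params.f) * np.exp(
        -b * params.D
    )
    return float(out) if out.ndim == 0 else out


def diffusion_only_signal(D: float, f: float, b) -> np.ndarray | float:
    """Evaluate the high-b diffusion-only asymptote ``(1-f)*exp(-b*D)``."""
    if not D > 0:
        raise ValidationError(f"D must be > 0, got {D}")
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"f must lie in [0, 1], got {f}")
    b = _validate_b(b)
    out = (1.0 - f) * np.exp(-b * D)
    return float(out) if out.ndim == 0 else out


def ivim_signal_curve(params: IVIMParams, scheme: BValueScheme) -> SignalCurve:
    """Noise-free SignalCurve of the IVIM model over a scheme."""
    s = ivim_signal(params, scheme.b_array)
    return SignalCurve(scheme, tuple(np.asarray(s).tolist()))


def read_curves_csv(path) -> dict[str, SignalCurve]:
    """Read decay curves from CSV with columns ``b,signal`` (plus optional
    ``roi_id`` grouping several ROIs in one file).

    Raw intensity input is accepted: each curve is normalized by its b=0 entry.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "b" not in df.columns or "signal" not in df.columns:
        raise ValidationError("curves CSV requires columns 'b' and 'signal'")
    groups = df.groupby("roi_id") if "roi_id" in df.columns else [("roi", df)]
    curves: dict[str, SignalCurve] = {}
    for roi_id, g in groups:
        g = g.sort_values("b")
        b = g["b"].to_numpy(dtype=float)
        nex = tuple([1] * len(b))
        scheme = BValueScheme(tuple(b.tolist()), nex)
        curve = SignalCurve(scheme, tuple(g["signal"].to_numpy(dtype=float).tolist()))
        curves[str(roi_id)] = curve.normalized()
    return curves


def write_curves_csv(curves: dict[str, SignalCurve], path) -> None:
    """Write curves in the ``roi_id,b,signal`` layout read_curves_csv accepts."""
    import pandas as pd

    rows = [
        {"roi_id": roi, "b": b, "signal": s}
        for roi, c in curves.items()
        for b, s in zip(c.scheme.b_values, c.signal)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
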