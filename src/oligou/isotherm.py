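"""Equilibrium binding isotherms from fluorescence anisotropy titrations.

A fluorescein-labeled RNA at fixed total concentration :math:`R_t` is titrated
with protein (total concentration :math:`P_t` per point); the anisotropy rises
from ``r_free`` to ``r_bound`` as the RNA is bound.  Because :math:`R_t` is not
always negligible relative to :math:`K_d`, the default model is the exact
single-site solution in total concentrations (ligand depletion), which is
quadratic in the bound fraction:

.. math::

    f_b = \\frac{(R_t + P_t + K_d) - \\sqrt{(R_t + P_t + K_d)^2 - 4 R_t P_t}}
               {2 R_t}

The hyperbolic limit :math:`f_b = P_t/(K_d + P_t)` is available for the
dilute-RNA regime.  Observed anisotropy is modeled as
``r = r_free + (r_bound - r_free) * f_b`` (equal quantum yields assumed, so no
intensity weighting).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "fraction_bound",
    "predict_anisotropy",
    "fit_kd",
    "normalize_isotherm",
    "read_titration_csv",
    "write_titration_csv",
]

#: Kd search bounds in uM; a fit pinned at either end is flagged unconverged
#: (weak binders are reported as right-censored, e.g. "Kd >> 200 uM").
KD_BOUNDS_UM = (1e-4, 1e5)


@dataclass
class TitrationSeries:
    """One labeled-RNA titration.

    Parameters
    ----------
    rna_label : substrate name, e.g. ``"UUUUUUU"`` or ``"CUCUCUC"``.
    rna_total_uM : total labeled RNA concentration :math:`R_t` (uM).  Stored
        explicitly per series and required for the depletion model.
    points : sequence of ``(protein_total_uM, anisotropy)`` pairs.
    temperature_C : metadata only.
    """

    rna_label: str
    rna_total_uM: float
    points: list[tuple[float, float]] = field(default_factory=list)
    temperature_C: float = 20.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.rna_total_uM) or self.rna_total_uM <= 0:
            raise ValueError("rna_total_uM must be a positive finite number")
        pts = [(float(p), float(r)) for p, r in self.points]
        if any(not (np.isfinite(p) and np.isfinite(r)) for p, r in pts):
            raise ValueError("titration points must be finite")
        if any(p < 0 for p, _ in pts):
            raise ValueError("protein concentrations must be non-negative")
        self.points = sorted(pts, key=lambda t: t[0])

    @property
    def protein_uM(self) -> np.ndarray:
        return np.array([p for p, _ in self.points], dtype=float)

    @property
    def anisotropy(self) -> np.ndarray:
        return np.array([r for _, r in self.points], dtype=float)


@dataclass
class BindingFit:
    """Least-squares estimates for a single-site isotherm."""

    kd_uM: float
    r_free: float
    r_bound: float
    model: str
    sse: float
    stderr_kd_uM: float
    converged: bool
    message: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def fraction_bound(p_total_uM, rna_total_uM, kd_uM):
    """Exact single-site bound fraction of the labeled RNA with ligand depletion.

    Vectorized over ``p_total_uM``.  Returns values clipped to [0, 1]
    (clipping only absorbs rounding at the boundaries).
    """
    p = np.asarray(p_total_uM, dtype=float)
    if np.any(p < 0):
        raise ValueError("protein concentration must be >= 0")
    if rna_total_uM <= 0:
        raise ValueError("rna_total_uM must be > 0")
    if kd_uM < 0:
        raise ValueError("kd_uM must be >= 0")
    s = rna_total_uM + p + kd_uM
    disc = s * s - 4.0 * rna_total_uM * p
    fb = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * rna_total_uM)
    return np.clip(fb, 0.0, 1.0)


def _fb(model: str, p: np.ndarray, rna_total_uM: float, kd: float) -> np.ndarray:
    if model == "depletion":
        return fraction_bound(p, rna_total_uM, kd)
    if model == "hyperbolic":
        return p / (kd + p)
    raise ValueError(f"unknown model {model!r}; use 'depletion' or 'hyperbolic'")


def predict_anisotropy(
    protein_uM: Sequence[float],
    rna_total_uM: float,
    kd_uM: float,
    r_free: float,
    r_bound: float,
    model: str = "depletion",
) -> np.ndarray:
    """Forward model: anisotropy at each titration point."""
    p = np.asarray(protein_uM, dtype=float)
    fb = _fb(model, p, rna_total_uM, kd_uM)
    return r_free + (r_bound - r_free) * fb


def fit_kd(series: TitrationSeries, model: str = "depletion") -> BindingFit:
    """Fit (Kd, r_free, r_bound) to a titration by non-linear least squares.

    Initialization uses the endpoints of the (sorted) series for the plateau
    anisotropies and the half-amplitude protein concentration for Kd, which is
    robust for monotone isotherms.  The Kd standard error comes from the local
    curvature of the objective (Gauss-Newton covariance).  A fit that does not
    converge, pins Kd at its bounds, or has no resolvable amplitude is returned
    with ``converged=False`` and a diagnostic message, never silently.
    """
    p = series.protein_uM
    r = series.anisotropy
    if len(np.unique(p)) < 4:
        raise ValueError("need at least 4 distinct protein concentrations")

    r0, r1 = r[0], r[-1]
    amplitude = r1 - r0
    # half-amplitude crossing as Kd guess; fall back to median concentration
    if abs(amplitude) > 0:
        half = r0 + amplitude / 2.0
        above = np.nonzero((r - half) * np.sign(amplitude) >= 0)[0]
        kd0 = p[above[0]] if len(above) and p[above[0]] > 0 else np.median(p[p > 0])
    else:
        kd0 = np.median(p[p > 0])
    kd0 = float(np.clip(kd0, *KD_BOUNDS_UM))

    lo = [KD_BOUNDS_UM[0], -np.inf, -np.inf]
    hi = [KD_BOUNDS_UM[1], np.inf, np.inf]

    def resid(theta):
        kd, rf, rb = theta
        return predict_anisotropy(p, series.rna_total_uM, kd, rf, rb, model) - r

    sol = least_squares(
        resid, x0=[kd0, r0, r1], bounds=(lo, hi), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    kd, rf, rb = sol.x
    sse = float(np.sum(sol.fun**2))

    # Kd stderr from J'J curvature; guard the rank-deficient case
    stderr = float("inf")
    dof = len(p) - 3
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (sse / dof)
            if cov[0, 0] >= 0:
                stderr = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            pass

    converged = bool(sol.success)
    message = sol.message
    rel = 1.0 + 1e-6
    if kd <= KD_BOUNDS_UM[0] * rel or kd >= KD_BOUNDS_UM[1] / rel:
        converged = False
        message = f"Kd pinned at search bound ({kd:.3g} uM); likely censored"
    if abs(rb - rf) < 1e-12 or not np.isfinite(stderr):
        converged = False
        message = "amplitude unresolved; Kd unidentifiable"
    return BindingFit(
        kd_uM=float(kd), r_free=float(rf), r_bound=float(rb), model=model,
        sse=sse, stderr_kd_uM=stderr, converged=converged, message=message,
    )


def normalize_isotherm(series: TitrationSeries, fit: BindingFit) -> np.ndarray:
    """(r - r_free)/(r_bound - r_free); for display only, never for fitting."""
    if not fit.converged:
        raise ValueError("cannot normalize against an unconverged fit")
    return (series.anisotropy - fit.r_free) / (fit.r_bound - fit.r_free)


def read_titration_csv(path_or_buf) -> TitrationSeries:
    """Read a titration CSV with `# rna_label=` / `# rna_total_uM=` header lines
    followed by `protein_total_uM,anisotropy` columns."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            kv = line.lstrip("#").strip()
            if "=" in kv:
                k, v = kv.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    if "rna_total_uM" not in meta:
        raise ValueError("missing '# rna_total_uM=' metadata line")
    return TitrationSeries(
        rna_label=meta.get("rna_label", ""),
        rna_total_uM=float(meta["rna_total_uM"]),
        points=list(zip(df["protein_total_uM"], df["anisotropy"])),
        temperature_C=float(meta.get("temperature_C", 20.0)),
    )


def write_titration_csv(series: TitrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rna_label={series.rna_label}\n")
        fh.write(f"# rna_total_uM={series.rna_total_uM}\n")
        fh.write(f"# temperature_C={series.temperature_C}\n")
        fh.write("protein_total_uM,anisotropy\n")
        for p, r in series.points:
            fh.write(f"{p},{r}\n")
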