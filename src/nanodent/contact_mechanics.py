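"""Oliver-Pharr analysis of unloading curves and Hertzian references.

The unloading branch is fitted to the power law P = alpha (h - h_f)^m; the
contact stiffness S = dP/dh at maximum depth, contact depth
h_c = h_max - eps P_max / S and spherical contact area
A_c = pi (2 R h_c - h_c^2) then give the reduced modulus
E_r = sqrt(pi) / (2 beta) * S / sqrt(A_c) and, through the compliance sum
1/E_r = (1 - nu_s^2)/E + (1 - nu_i^2)/E_i, the sample Young's modulus E.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .indentation import ForceDisplacementCurve
from .units import KJ_MOL_NM3_TO_GPA

__all__ = [
    "PowerLawFit",
    "OliverPharrResult",
    "fit_unloading",
    "oliver_pharr",
    "hertz_curve",
    "analyze_curve",
]

#: GPa per (curve force unit / nm^2), by declared force unit
_FORCE_UNIT_TO_GPA = {
    "kJ/mol/nm": KJ_MOL_NM3_TO_GPA,
    "GPa*nm^2": 1.0,
}


@dataclass
class PowerLawFit:
    """P = alpha (h - h_f)^m fitted on the upper unloading branch."""

    alpha: float
    m: float
    h_f: float  # residual depth, nm
    h_max: float  # nm
    p_max: float  # force units
    stiffness: float  # S = dP/dh at h_max, force units / nm
    fit_range: tuple[float, float]
    residual_norm: float
    force_unit: str = "kJ/mol/nm"

    def __post_init__(self) -> None:
        if not (1.0 <= self.m <= 3.0):
            raise ValueError(f"unloading exponent m={self.m:.3f} outside [1, 3]")
        if self.h_f >= self.h_max:
            raise ValueError("residual depth must be below maximum depth")
        if self.stiffness <= 0:
            raise ValueError("contact stiffness must be positive")

    def predict(self, h: np.ndarray) -> np.ndarray:
        return self.alpha * np.clip(h - self.h_f, 0.0, None) ** self.m


@dataclass
class OliverPharrResult:
    """Derived contact quantities; moduli in GPa."""

    fit: PowerLawFit
    h_c: float  # nm
    a_c: float  # nm^2
    e_reduced: float  # GPa
    e_sample: float  # GPa
    radius: float
    epsilon: float
    beta: float
    nu_sample: float
    indenter: Optional[tuple[float, float]] = None  # (E_i GPa, nu_i) if elastic


def _powerlaw_ls(h, p, h_f0, h_min, h_f_bounds):
    """Polish (alpha, m, h_f) by bounded least squares from a log-linear start."""
    mask = h > h_f0 + 1e-12
    x = np.log(h[mask] - h_f0)
    y = np.log(np.clip(p[mask], 1e-300, None))
    m0, loga = np.polyfit(x, y, 1)
    m0 = float(np.clip(m0, 1.0, 3.0))
    p0 = [np.exp(loga), m0, max(h_f0, h_f_bounds[0])]

    def resid(theta):
        a, m, hf = theta
        base = np.clip(h - hf, 1e-12, None)
        return a * base**m - p

    res = least_squares(
        resid, p0,
        bounds=([1e-12, 1.0, h_f_bounds[0]],
                [np.inf, 3.0, min(h_f_bounds[1], h_min - 1e-9)]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return res.x, float(np.linalg.norm(res.fun))


def fit_unloading(
    curve: ForceDisplacementCurve,
    fit_fraction: tuple[float, float] = (0.25, 0.95),
    n_multistart: int = 8,
    h_f_bounds: tuple[float, float] = (0.0, np.inf),
) -> PowerLawFit:
    """Fit the power-law unloading model over the stated force fraction.

    ``fit_fraction`` selects samples whose force lies between the given
    fractions of the force at the start of unloading (common practice: the
    upper 25 %-95 % of the branch).  A grid of residual-depth starting values
    guards against the local-minimum trap of the three-parameter fit; the
    default bounds keep the residual depth physical (h_f >= 0), which also
    suppresses a spurious high-exponent fit basin on noisy curves.
    """
    if "unload" in curve.phase:
        branch = curve.branch("unload")
    else:  # standalone curve without phase labels: treat everything as unload
        branch = curve
    h, p = branch.depth, branch.force
    if len(h) < 10:
        raise ValueError("unloading branch needs at least 10 points")
    if not (p > 0).any():
        raise ValueError("no positive forces on the unloading branch: lost contact")
    p_top = p[np.argmax(h)]
    if p_top <= 0:
        p_top = p.max()
    lo, hi = fit_fraction
    sel = (p >= lo * p_top) & (p <= hi * p_top) & (p > 0)
    if sel.sum() < 5:
        sel = p > 0
    h_sel, p_sel = h[sel], p[sel]
    # S is evaluated at the depth where unloading starts, not at the top of
    # the (possibly clipped) fit window
    h_max = float(h.max())
    h_min = float(h_sel.min())

    best = None
    for h_f0 in np.linspace(max(0.0, h_f_bounds[0]), 0.98 * h_min, n_multistart):
        try:
            theta, rnorm = _powerlaw_ls(h_sel, p_sel, h_f0, h_min, h_f_bounds)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or rnorm < best[1]:
            best = (theta, rnorm)
    if best is None:
        raise RuntimeError("power-law fit did not converge from any start")
    (alpha, m, h_f), rnorm = best
    s = alpha * m * (h_max - h_f) ** (m - 1.0)
    return PowerLawFit(
        alpha=float(alpha), m=float(m), h_f=float(h_f), h_max=h_max,
        p_max=float(alpha * (h_max - h_f) ** m), stiffness=float(s),
        fit_range=(h_min, h_max), residual_norm=rnorm,
        force_unit=curve.metadata.get("force_unit", "kJ/mol/nm"),
    )


def oliver_pharr(
    fit: PowerLawFit,
    radius: float,
    nu_sample: float = 0.30,
    indenter_elasticity: Optional[tuple[float, float]] = None,
    epsilon: float = 0.75,
    beta: float = 1.0,
) -> OliverPharrResult:
    """Contact depth, spherical contact area, reduced and sample moduli.

    ``indenter_elasticity`` is ``(E_i GPa, nu_i)`` for an elastic tip; the
    default rigid tip drops that compliance term.  ``epsilon`` = 0.75 is the
    standard geometry factor for spherical/paraboloid tips, ``beta`` the tip
    shape correction.
    """
    if radius <= fit.h_max:
        raise ValueError("indenter radius must exceed the maximum depth")
    h_c = fit.h_max - epsilon * fit.p_max / fit.stiffness
    if h_c <= 0:
        raise ValueError(
            f"contact depth h_c={h_c:.4g} <= 0: ill-posed contact geometry"
        )
    a_c = np.pi * (2.0 * radius * h_c - h_c**2)
    unit = _FORCE_UNIT_TO_GPA.get(fit.force_unit)
    if unit is None:
        raise ValueError(f"unknown force unit {fit.force_unit!r}")
    e_r = np.sqrt(np.pi) / (2.0 * beta) * fit.stiffness / np.sqrt(a_c) * unit
    inv_e = 1.0 / e_r
    if indenter_elasticity is not None:
        e_i, nu_i = indenter_elasticity
        inv_e -= (1.0 - nu_i**2) / e_i
        if inv_e <= 0:
            raise ValueError("indenter compliance exceeds total compliance")
    e_sample = (1.0 - nu_sample**2) / inv_e
    return OliverPharrResult(
        fit=fit, h_c=float(h_c), a_c=float(a_c), e_reduced=float(e_r),
        e_sample=float(e_sample), radius=radius, epsilon=epsilon, beta=beta,
        nu_sample=nu_sample, indenter=indenter_elasticity,
    )


def hertz_curve(
    e_reduced: float, radius: float, h_max: float, n_points: int = 200
) -> ForceDisplacementCurve:
    """Ideal elastic sphere-on-flat curve P = (4/3) E_r sqrt(R) h^(3/2).

    ``e_reduced`` in GPa; forces are emitted in GPa*nm^2 so the fitted moduli
    come back in GPa without conversion.  Load and unload branches coincide
    (no hysteresis in the ideal elastic case).
    """
    if h_max >= radius:
        raise ValueError("h_max must stay below the radius")
    h_load = np.linspace(0.0, h_max, n_points)
    h_unload = h_load[::-1]
    h = np.concatenate([h_load, h_unload])
    p = (4.0 / 3.0) * e_reduced * np.sqrt(radius) * h**1.5
    phase = np.array(["load"] * n_points + ["unload"] * n_points, dtype=object)
    t = np.arange(2 * n_points, dtype=float)
    return ForceDisplacementCurve(
        t, h, p, phase,
        {"force_unit": "GPa*nm^2", "radius_nm": radius, "hertz_e_r_gpa": e_reduced},
    )


def analyze_curve(
    curve: ForceDisplacementCurve,
    radius: Optional[float] = None,
    nu_sample: float = 0.30,
    fit_fraction: tuple[float, float] = (0.25, 0.95),
    epsilon: float = 0.75,
    beta: float = 1.0,
    indenter_elasticity: Optional[tuple[float, float]] = None,
) -> OliverPharrResult:
    """One-call pipeline: fit the unloading branch, then Oliver-Pharr."""
    if radius is None:
        radius = curve.metadata.get("radius_nm")
        if radius is None:
            raise ValueError("indenter radius not given and absent from metadata")
    fit = fit_unloading(curve, fit_fraction=fit_fraction)
    return oliver_pharr(
        fit, radius, nu_sample=nu_sample,
        indenter_elasticity=indenter_elasticity, epsilon=epsilon, beta=beta,
    )


def analyze_batch(curves, radius: Optional[float] = None, **kwargs):
    """Analyze replicate curves; per-curve table plus mean +/- standard error.

    Returns ``(table, summary)`` where summary holds the across-replicate
    mean and standard error (n - 1 denominator) of E_r and E.
    """
    import pandas as pd

    rows = []
    for label, curve in curves:
        res = analyze_curve(curve, radius=radius, **kwargs)
        rows.append(
            {"curve": label, "S": res.fit.stiffness, "m": res.fit.m,
             "h_f_nm": res.fit.h_f, "h_c_nm": res.h_c, "A_c_nm2": res.a_c,
             "E_r_gpa": res.e_reduced, "E_gpa": res.e_sample}
        )
    table = pd.DataFrame(rows)
    n = len(table)
    summary = {
        "n": n,
        "E_gpa_mean": float(table["E_gpa"].mean()),
        "E_gpa_se": float(table["E_gpa"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "E_r_gpa_mean": float(table["E_r_gpa"].mean()),
        "E_r_gpa_se": float(table["E_r_gpa"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    }
    return table, summary
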