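"""Two-state ion-induced folding model for FRET titrations.

The observable is modelled as

    E(c) = E0 + dE * (KA * c**n) / (1 + KA * c**n)

where ``E0`` is the FRET efficiency with no added ion, ``dE`` the
increase at saturation, ``KA`` the apparent association constant and
``n`` a Hill coefficient.  The transition is half complete at
``c_half = (1/KA)**(1/n)``.

The functional form is the unique Hill-type two-state expression
consistent with that half-point relation; protein titrations reuse it
unchanged with the ligand declared on the curve.

Fitting is unweighted nonlinear least squares on the pooled points, with
``KA`` optimized on a log scale (positivity) and ``n`` bounded to
[0.3, 5] to avoid pathological exponents on sparse data.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FittingError, InputError

__all__ = [
    "TitrationCurve",
    "TwoStateFit",
    "model_efret",
    "half_point",
    "fit_titration",
    "bootstrap_ci",
    "read_titration_table",
    "write_titration_table",
    "fit_report_text",
]

_N_BOUNDS = (0.3, 5.0)
_MIN_POINTS = 5
_FLAT_DE = 0.05  # below this fitted amplitude the curve is flagged "no transition"


@dataclass
class TitrationCurve:
    """E_FRET versus ligand concentration.

    Concentrations are sorted ascending on construction; ties keep their
    relative order.  At least five points are required for fitting.
    """

    concentrations: np.ndarray
    efret: np.ndarray
    ligand_name: str = "Mg2+"
    unit: str = "uM"
    replicate: Optional[np.ndarray] = None

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        e = np.asarray(self.efret, dtype=float)
        if c.ndim != 1 or e.ndim != 1 or c.size != e.size:
            raise InputError("concentrations and efret must be 1-D and equal length")
        if np.any(c < 0):
            raise InputError("negative concentration")
        if np.any((e < -0.1) | (e > 1.1)):
            raise InputError("E_FRET outside [-0.1, 1.1]")
        order = np.argsort(c, kind="stable")
        self.concentrations = c[order]
        self.efret = e[order]
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)[order]

    def __len__(self) -> int:
        return self.concentrations.size

    def converted(self, unit: str) -> "TitrationCurve":
        """Copy with concentrations expressed in another unit (uM/mM/M)."""
        factors = {"uM": 1e-6, "µM": 1e-6, "mM": 1e-3, "M": 1.0}
        try:
            scale = factors[self.unit] / factors[unit]
        except KeyError as exc:
            raise InputError(f"unknown concentration unit: {exc}") from None
        return TitrationCurve(
            concentrations=self.concentrations * scale,
            efret=self.efret.copy(),
            ligand_name=self.ligand_name,
            unit=unit,
            replicate=None if self.replicate is None else self.replicate.copy(),
        )


@dataclass
class TwoStateFit:
    """Fitted two-state model parameters and derived quantities."""

    E0: float
    dE: float
    KA: float
    n: float
    half_point: float
    rss: float
    unit: str = "uM"
    ligand_name: str = "Mg2+"
    ci: Optional[dict[str, tuple[float, float]]] = None
    flags: list[str] = field(default_factory=list)

    def predict(self, conc) -> np.ndarray:
        return model_efret(self.E0, self.dE, self.KA, self.n, conc)


def model_efret(E0: float, dE: float, KA: float, n: float, conc):
    """Model E_FRET at the given concentration(s).

    Returns ``E0`` at zero concentration and approaches ``E0 + dE`` at
    saturation; exactly ``E0 + dE/2`` at ``(1/KA)**(1/n)``.
    """
    if KA <= 0:
        raise InputError("KA must be positive")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise InputError("negative concentration")
    with np.errstate(divide="ignore"):
        x = KA * np.power(c, n)
    out = E0 + dE * x / (1.0 + x)
    return out if out.ndim else float(out)


def half_point(KA: float, n: float) -> float:
    """Concentration at half-completion, (1/KA)**(1/n)."""
    if KA <= 0 or n <= 0:
        raise InputError("KA and n must be positive")
    return (1.0 / KA) ** (1.0 / n)


def _initial_guess(curve: TitrationCurve) -> tuple[float, float, float, float]:
    e = curve.efret
    c = curve.concentrations
    e0 = float(e.min())
    de = float(e.max() - e.min())
    mid = e0 + de / 2.0
    # first crossing of the midpoint, linearly interpolated
    half = c[c > 0].min() if np.any(c > 0) else 1.0
    for i in range(1, len(e)):
        lo, hi = e[i - 1], e[i]
        if (lo - mid) * (hi - mid) <= 0 and hi != lo:
            frac = (mid - lo) / (hi - lo)
            half = c[i - 1] + frac * (c[i] - c[i - 1])
            break
    half = max(half, np.finfo(float).tiny)
    return e0, de, half, 1.0


def fit_titration(
    curve: TitrationCurve,
    fix_n: Optional[float] = None,
    init: Optional[Sequence[float]] = None,
) -> TwoStateFit:
    """Least-squares fit of the two-state model to a titration curve.

    Parameters
    ----------
    curve:
        The titration data; ≥5 points spanning a ≥10-fold range of
        positive concentrations.
    fix_n:
        If given, the Hill coefficient is held at this value.
    init:
        Optional ``(E0, dE, KA, n)`` starting point overriding the
        built-in heuristic.

    Raises
    ------
    InputError
        On too few points or insufficient concentration span.
    FittingError
        On non-convergence; carries the best-so-far parameters.
    """
    if len(curve) < _MIN_POINTS:
        raise InputError(
            f"need ≥{_MIN_POINTS} points to fit, got {len(curve)}"
        )
    pos = curve.concentrations[curve.concentrations > 0]
    if pos.size == 0 or pos.max() / pos.min() < 10.0:
        raise InputError(
            "concentrations must span at least a 10-fold range"
        )

    if init is not None:
        e0_i, de_i, ka_i, n_i = (float(v) for v in init)
        half_i = half_point(ka_i, n_i) if ka_i > 0 else 1.0
    else:
        e0_i, de_i, half_i, n_i = _initial_guess(curve)
    if fix_n is not None:
        if not (_N_BOUNDS[0] <= fix_n <= _N_BOUNDS[1]):
            raise InputError(f"fix_n must lie in {_N_BOUNDS}")
        n_i = float(fix_n)
    n_i = float(np.clip(n_i, *_N_BOUNDS))
    log_ka_i = -n_i * math.log(half_i)

    c = curve.concentrations
    y = curve.efret
    free_n = fix_n is None

    def residuals(theta):
        e0, de, log_ka = theta[:3]
        n = theta[3] if free_n else fix_n
        with np.errstate(over="ignore"):
            x = np.exp(log_ka) * np.power(c, n)
        return e0 + de * x / (1.0 + x) - y

    theta0 = [e0_i, de_i, log_ka_i] + ([n_i] if free_n else [])
    lower = [-1.0, -2.0, -700.0] + ([_N_BOUNDS[0]] if free_n else [])
    upper = [2.0, 2.0, 700.0] + ([_N_BOUNDS[1]] if free_n else [])
    theta0 = np.clip(theta0, lower, upper)

    result = least_squares(
        residuals, theta0, bounds=(lower, upper), method="trf", xtol=1e-14,
        ftol=1e-14, gtol=1e-14, max_nfev=20000,
    )
    e0, de, log_ka = result.x[:3]
    n = float(result.x[3]) if free_n else float(fix_n)
    ka = float(np.exp(log_ka))
    fit = TwoStateFit(
        E0=float(e0),
        dE=float(de),
        KA=ka,
        n=n,
        half_point=half_point(ka, n),
        rss=float(np.sum(result.fun**2)),
        unit=curve.unit,
        ligand_name=curve.ligand_name,
    )
    if not result.success:
        raise FittingError(
            f"fit did not converge: {result.message}",
            best_fit=fit,
            diagnostics=result.message,
        )
    if abs(fit.dE) < _FLAT_DE:
        fit.flags.append("no transition")
    return fit


def bootstrap_ci(
    curve: TitrationCurve,
    fit: TwoStateFit,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap percentile intervals.

    Residuals of the fit are resampled with replacement onto the fitted
    curve and the model refitted; per-parameter percentile intervals at
    the requested level are returned (and attached to ``fit.ci``).
    Fitted residuals are inflated by sqrt(m/(m-p)) to undo least-squares
    shrinkage (p = 4 parameters).  Deterministic for a given seed.
    """
    if n_boot < 1:
        raise InputError("n_boot must be ≥1")
    rng = np.random.default_rng(seed)
    yhat = fit.predict(curve.concentrations)
    m, p = len(curve), 4
    inflation = math.sqrt(m / max(m - p, 1))
    residuals = (curve.efret - yhat) * inflation
    names = ("E0", "dE", "KA", "n", "half_point")
    draws: dict[str, list[float]] = {k: [] for k in names}
    for _ in range(n_boot):
        ystar = yhat + rng.choice(residuals, size=residuals.size, replace=True)
        ystar = np.clip(ystar, -0.1, 1.1)
        bcurve = TitrationCurve(
            concentrations=curve.concentrations.copy(),
            efret=ystar,
            ligand_name=curve.ligand_name,
            unit=curve.unit,
        )
        try:
            bfit = fit_titration(bcurve, init=(fit.E0, fit.dE, fit.KA, fit.n))
        except FittingError as exc:
            if exc.best_fit is None:
                continue
            bfit = exc.best_fit
        for k in names:
            draws[k].append(getattr(bfit, k))
    alpha = (1.0 - level) / 2.0
    ci = {
        k: (
            float(np.quantile(v, alpha)),
            float(np.quantile(v, 1.0 - alpha)),
        )
        for k, v in draws.items()
        if v
    }
    fit.ci = ci
    if n_boot < 50:
        fit.flags.append(f"bootstrap n_boot={n_boot} < 50: intervals unreliable")
    return ci


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_titration_table(path) -> TitrationCurve:
    """Read a delimited titration table.

    Comment lines starting with ``#`` may carry ``ligand=`` / ``unit=``
    tokens; the header row names at least ``concentration`` and
    ``efret`` columns (``replicate`` optional).  Comma, tab and
    whitespace separation are accepted.
    """
    import pandas as pd

    text = Path(path).read_text()
    meta = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            for tok in line.lstrip("#").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise InputError(f"no data rows in {path}")
    sep = "," if "," in body_lines[0] else None
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("concentration", "efret"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return TitrationCurve(
        concentrations=df["concentration"].to_numpy(float),
        efret=df["efret"].to_numpy(float),
        ligand_name=meta.get("ligand", "Mg2+"),
        unit=meta.get("unit", "uM"),
        replicate=df["replicate"].to_numpy() if "replicate" in df.columns else None,
    )


def write_titration_table(curve: TitrationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ligand={curve.ligand_name} unit={curve.unit}\n")
        fh.write("concentration\tefret\n")
        for c, e in zip(curve.concentrations, curve.efret):
            fh.write(f"{c:.10g}\t{e:.10g}\n")


def fit_report_text(fit: TwoStateFit) -> str:
    """Fit summary as key=value lines."""
    lines = [
        f"ligand={fit.ligand_name}",
        f"unit={fit.unit}",
        f"E0={fit.E0:.6g}",
        f"dE_FRET={fit.dE:.6g}",
        f"KA={fit.KA:.6g}",
        f"hill_n={fit.n:.6g}",
        f"half_point={fit.half_point:.6g}",
        f"rss={fit.rss:.6g}",
    ]
    if fit.ci:
        for k, (lo, hi) in fit.ci.items():
            lines.append(f"ci_{k}={lo:.6g},{hi:.6g}")
    for flag in fit.flags:
        lines.append(f"flag={flag}")
    return "\n".join(lines) + "\n"
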