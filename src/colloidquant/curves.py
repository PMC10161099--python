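"""Titration, viability, and dose-response models.

Four explicit models:

* apparent-pKa titration —
  ``F = Background + (Maximum - Background) / (1 + 10**(pH - pKa))``
* viability normalizations — % metabolic activity relative to the
  blank-treated control, or relative to the pre-treatment (day-0) value
* monophasic dose response —
  ``Y = Bottom + (Top - Bottom) / (1 + ([Drug]/IC50)**Hill)``
* biphasic dose response — a two-term analogue separating a
  sub-micromolar growth-suppression (static) transition from a
  micromolar toxicity transition.

All fits are nonlinear least squares with deterministic, data-driven
starting values; IC50s are parameterized on the log10 scale for
conditioning over wide concentration spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synthetic import titration_model

_MAX_ITER = 500
_RSS_TOL = 1e-10


@dataclass
class TitrationCurve:
    """pH / fluorescence pairs from one TNS titration."""

    ph: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.ph.shape != self.fluorescence.shape:
            raise ValueError("ph and fluorescence must have equal length")
        if self.ph.size and (self.ph.min() < 3.0 or self.ph.max() > 10.0):
            raise ValueError("pH values must lie within [3, 10]")


@dataclass
class PkaFitResult:
    pka: float
    background: float
    maximum: float
    rss: float
    converged: bool
    ionizable: bool

    def predict(self, ph) -> np.ndarray:
        return titration_model(np.asarray(ph, float), self.background,
                               self.maximum, self.pka)


@dataclass
class ViabilityRecord:
    """Plate-reader intensities for one well (day 6 and, for
    proliferation experiments, day 0)."""

    i_sample_6d: float
    i_background_6d: float
    i_control_6d: float = float("nan")
    i_sample_0d: float = float("nan")
    i_background_0d: float = float("nan")


@dataclass
class DoseResponseFit:
    model: str                    # "monophasic" | "biphasic"
    top: float
    bottom: float
    rss: float
    converged: bool
    ic50: float = float("nan")         # monophasic
    hill: float = float("nan")
    plateau: float = float("nan")      # biphasic
    ic50_stat: float = float("nan")
    hill_stat: float = float("nan")
    ic50_tox: float = float("nan")
    hill_tox: float = float("nan")

    def predict(self, conc_um) -> np.ndarray:
        conc_um = np.asarray(conc_um, float)
        if self.model == "monophasic":
            return monophasic_model(conc_um, self.top, self.bottom,
                                    self.ic50, self.hill)
        return biphasic_model(conc_um, self.top, self.plateau, self.bottom,
                              self.ic50_stat, self.hill_stat,
                              self.ic50_tox, self.hill_tox)


def _half_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float:
    """x at which y (sorted by x) first crosses ``level``; interpolated."""
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            t = (level - y0) / (y1 - y0)
            return x[i] + t * (x[i + 1] - x[i])
    return x[len(x) // 2]


def fit_pka(ph, fluorescence=None) -> PkaFitResult:
    """Fit the titration model to fluorescence-versus-pH data.

    A compound is flagged non-ionizable when the fitted dynamic range
    (Maximum - Background) is below 3x the residual SD — i.e. the curve
    is flat at the noise level, as for a compound that is never
    protonated over the sampled pH range — or when the fitted pKa falls
    outside that range.

    Accepts either a :class:`TitrationCurve` or ``(ph, fluorescence)``
    arrays.
    """
    if isinstance(ph, TitrationCurve):
        ph, fluorescence = ph.ph, ph.fluorescence
    ph = np.asarray(ph, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if ph.shape != f.shape:
        raise ValueError("ph and fluorescence must have equal length")
    if ph.size < 4:
        raise ValueError("need at least 4 points to fit the titration model")

    order = np.argsort(ph)
    ph, f = ph[order], f[order]
    b0, m0 = float(f.min()), float(f.max())
    pka0 = _half_crossing(ph, f, (b0 + m0) / 2.0)
    resid = lambda p: titration_model(ph, p[0], p[1], p[2]) - f
    try:
        sol = least_squares(
            resid, x0=[b0, m0, pka0], method="lm",
            xtol=_RSS_TOL, ftol=_RSS_TOL, gtol=_RSS_TOL,
            max_nfev=_MAX_ITER * 4,
        )
        converged = bool(sol.success)
        background, maximum, pka = map(float, sol.x)
        rss = float(sol.fun @ sol.fun)
    except Exception:
        return PkaFitResult(float("nan"), b0, m0, float("nan"), False, False)

    n_free = max(ph.size - 3, 1)
    resid_sd = np.sqrt(rss / n_free)
    dynamic_range = maximum - background
    scale = max(abs(maximum), abs(background), 1.0)
    if dynamic_range <= 0:
        converged = False
    ionizable = (
        converged
        and dynamic_range >= 3.0 * resid_sd
        and dynamic_range > 1e-9 * scale
        and ph.min() <= pka <= ph.max()
    )
    return PkaFitResult(pka, background, maximum, rss, converged, ionizable)


def relative_activity(rec: ViabilityRecord) -> float:
    """% metabolic activity relative to the blank-treated control:
    ``100 * (I_sample,6d - I_bg,6d) / (I_control,6d - I_bg,6d)``."""
    denom = rec.i_control_6d - rec.i_background_6d
    if denom == 0 or not np.isfinite(denom):
        raise ZeroDivisionError("control and background intensities coincide")
    return 100.0 * (rec.i_sample_6d - rec.i_background_6d) / denom


def original_activity(rec: ViabilityRecord) -> float:
    """% metabolic activity relative to the pre-treatment value:
    ``100 * (I_sample,6d - I_bg,6d) / (I_sample,0d - I_bg,0d)``."""
    denom = rec.i_sample_0d - rec.i_background_0d
    if denom == 0 or not np.isfinite(denom):
        raise ZeroDivisionError("day-0 sample and background coincide")
    return 100.0 * (rec.i_sample_6d - rec.i_background_6d) / denom


def _dose_term(conc: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    """(D/IC50)^Hill computed in log10-dose space; exactly 0 at D = 0."""
    out = np.zeros_like(conc)
    pos = conc > 0
    out[pos] = 10.0 ** (hill * (np.log10(conc[pos]) - log_ic50))
    return out


def monophasic_model(conc_um, top, bottom, ic50, hill) -> np.ndarray:
    """Four-parameter inhibition curve; activity falls from Top to Bottom
    with midpoint IC50."""
    conc_um = np.asarray(conc_um, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + _dose_term(conc_um, np.log10(ic50), hill)
    )


def biphasic_model(conc_um, top, plateau, bottom,
                   ic50_stat, hill_stat, ic50_tox, hill_tox) -> np.ndarray:
    """Two-transition inhibition curve.

    Activity falls from Top to an intermediate Plateau around the static
    (growth-suppression) IC50 and from Plateau to Bottom around the
    toxicity IC50.  With ``plateau == top`` the first term vanishes and
    the curve reduces exactly to the monophasic model.
    """
    conc_um = np.asarray(conc_um, dtype=float)
    return (
        bottom
        + (plateau - bottom)
        / (1.0 + _dose_term(conc_um, np.log10(ic50_tox), hill_tox))
        + (top - plateau)
        / (1.0 + _dose_term(conc_um, np.log10(ic50_stat), hill_stat))
    )


def _fit_monophasic(conc: np.ndarray, y: np.ndarray) -> DoseResponseFit:
    top0, bot0 = float(y.max()), float(y.min())
    pos = conc > 0
    logc = np.log10(conc[pos])
    order = np.argsort(logc)
    lx, ly = logc[order], y[pos][order]
    l50 = _half_crossing(lx, ly, (top0 + bot0) / 2.0)

    def resid(p):
        top, bottom, log_ic50, hill = p
        return bottom + (top - bottom) / (
            1.0 + _dose_term(conc, log_ic50, hill)
        ) - y

    sol = least_squares(
        resid, x0=[top0, bot0, l50, 1.0],
        bounds=([-np.inf, -np.inf, lx.min() - 4, 1e-3],
                [np.inf, np.inf, lx.max() + 4, 50.0]),
        xtol=_RSS_TOL, ftol=_RSS_TOL, gtol=_RSS_TOL, max_nfev=_MAX_ITER * 8,
    )
    top, bottom, log_ic50, hill = map(float, sol.x)
    return DoseResponseFit(
        model="monophasic", top=top, bottom=bottom,
        ic50=10.0 ** log_ic50, hill=hill,
        rss=float(sol.fun @ sol.fun), converged=bool(sol.success),
    )


def _fit_biphasic(conc: np.ndarray, y: np.ndarray) -> DoseResponseFit:
    top0, bot0 = float(y.max()), float(y.min())
    pos = conc > 0
    logc = np.log10(conc[pos])
    order = np.argsort(logc)
    lx, ly = logc[order], y[pos][order]
    plat0 = float(np.median(y))
    l_stat0 = _half_crossing(lx, ly, (top0 + plat0) / 2.0)
    l_tox0 = _half_crossing(lx, ly, (plat0 + bot0) / 2.0)
    gap0 = max(l_tox0 - l_stat0, 0.5)

    # parameterization enforces Bottom <= Plateau <= Top and
    # IC50_stat < IC50_tox (identifiability of the two transitions)
    def unpack(p):
        bottom, d_plat, d_top, l_stat, gap, h_stat, h_tox = p
        plateau = bottom + d_plat
        top = plateau + d_top
        return top, plateau, bottom, l_stat, l_stat + gap, h_stat, h_tox

    def resid(p):
        top, plateau, bottom, l_stat, l_tox, h_stat, h_tox = unpack(p)
        return (
            bottom
            + (plateau - bottom) / (1.0 + _dose_term(conc, l_tox, h_tox))
            + (top - plateau) / (1.0 + _dose_term(conc, l_stat, h_stat))
            - y
        )

    x0 = [bot0, max(plat0 - bot0, 1e-3), max(top0 - plat0, 1e-3),
          l_stat0, gap0, 1.0, 1.0]
    sol = least_squares(
        resid, x0=x0,
        bounds=([-np.inf, 0.0, 0.0, lx.min() - 4, 1e-6, 1e-3, 1e-3],
                [np.inf, np.inf, np.inf, lx.max() + 4, 12.0, 50.0, 50.0]),
        xtol=_RSS_TOL, ftol=_RSS_TOL, gtol=_RSS_TOL, max_nfev=_MAX_ITER * 8,
    )
    top, plateau, bottom, l_stat, l_tox, h_stat, h_tox = unpack(sol.x)
    return DoseResponseFit(
        model="biphasic", top=float(top), bottom=float(bottom),
        plateau=float(plateau),
        ic50_stat=float(10.0 ** l_stat), hill_stat=float(h_stat),
        ic50_tox=float(10.0 ** l_tox), hill_tox=float(h_tox),
        rss=float(sol.fun @ sol.fun), converged=bool(sol.success),
    )


def fit_dose_response(conc_um, activity_percent,
                      model: str = "monophasic") -> DoseResponseFit:
    """Fit % activity versus drug concentration (uM).

    Zero-dose points are allowed and anchor the Top asymptote.  The
    caller chooses the model; the biphasic form is appropriate when the
    data show an intermediate plateau between a sub-micromolar static
    effect and micromolar toxicity.
    """
    conc = np.asarray(conc_um, dtype=float)
    y = np.asarray(activity_percent, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("conc and activity must have equal length")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    n_par = 4 if model == "monophasic" else 7
    if np.unique(conc).size < n_par + 1:
        raise ValueError(
            f"need at least {n_par + 1} distinct concentrations for the "
            f"{model} model"
        )
    if model == "monophasic":
        return _fit_monophasic(conc, y)
    if model == "biphasic":
        return _fit_biphasic(conc, y)
    raise ValueError(f"unknown model {model!r}")
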