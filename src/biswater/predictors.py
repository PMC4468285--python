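"""Total-body-water predictors: four 50 kHz regressions and two BIS methods.

Single-frequency (SFBIA) equations use the impedance quotient H^2/R at
50 kHz (or H^2/|Z| at 100 kHz for Deurenberg) plus anthropometry:

    Deurenberg:  6.69 + 0.34573 H^2/Z100 + 0.17065 W - 0.11 age + 2.66 sex
    Heitmann:   -17.58 + 0.240 H^2/R50 - 0.172 W + 0.40 sex*W + 0.165 H
    Kushner:     men  8.399 + 0.396 H^2/R50 + 0.143 W
                 women 8.315 + 0.382 H^2/R50 + 0.105 W
    Sun:         men  1.203 + 0.499 H^2/R50 + 0.176 W
                 women 3.747 + 0.450 H^2/R50 + 0.113 W

with H in cm, W in kg, sex coded 1 = male, 0 = female, output in litres.

The BIS methods apply Hanai mixture theory to the extrapolated Cole
resistances Re = R0 and Ri = R0*Rinf/(R0-Rinf):

    ECW = (1/1000) (Kb^2 rho_e^2 / Db)^(1/3) (sqrt(W) H^2 / Re)^(2/3)

and ICW via the ratio x = ICW/ECW solving

    (1 + x)^(5/2) = ((Re + Ri)/Ri) (1 + (rho_i/rho_e) x),

a fifth-degree equation with a unique positive root; TBW = ECW + ICW.
The BMI-indexed variant replaces the fixed mixture coefficients with
Kef = 0.188/BMI + 0.2883 and Kif = 5.8758/BMI + 0.4194 applied to the
same (H^2 sqrt(W) / R)^(2/3) quotients for Re and Ri respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from scipy.optimize import brentq

from .cole import ColeParams, ImpedanceSpectrum, parallel_ri, resistance_at

if TYPE_CHECKING:
    from .cohort import Subject

__all__ = [
    "SF_METHODS",
    "BIS_METHODS",
    "METHODS",
    "MixtureConstants",
    "FluidVolumes",
    "tbw_deurenberg",
    "tbw_heitmann",
    "tbw_kushner",
    "tbw_sun",
    "ecw_delorenzo",
    "solve_icw_ratio",
    "icw_delorenzo",
    "volumes_delorenzo",
    "volumes_moissl",
    "predict_all",
]

SF_METHODS = ("deurenberg", "heitmann", "kushner", "sun")
BIS_METHODS = ("delorenzo", "moissl")
METHODS = SF_METHODS + BIS_METHODS

# Physiological plausibility bands; QC flags only, never filters.
TBW_QC_RANGE_L = (10.0, 70.0)
ICW_ECW_RATIO_QC_RANGE = (0.3, 4.0)


@dataclass(frozen=True)
class MixtureConstants:
    """Hanai mixture-theory constants (resistivities in ohm*cm, Db in kg/cm^3)."""

    kb: float = 4.3
    db: float = 1.05e-3
    rho_e: float = 40.5
    rho_i: float = 273.9

    def __post_init__(self) -> None:
        if min(self.kb, self.db, self.rho_e, self.rho_i) <= 0:
            raise ValueError("all mixture constants must be positive")
        if self.rho_i <= self.rho_e:
            raise ValueError("intracellular resistivity must exceed extracellular")

    @classmethod
    def for_sex(cls, sex: str) -> "MixtureConstants":
        if sex == "male":
            return cls(rho_e=40.5, rho_i=273.9)
        if sex == "female":
            return cls(rho_e=39.0, rho_i=264.9)
        raise ValueError(f"unknown sex {sex!r}")

    @property
    def k_ecw(self) -> float:
        """ECW prefactor (1/1000)(Kb^2 rho_e^2 / Db)^(1/3); ~0.307 men, ~0.299 women."""
        return 1e-3 * (self.kb**2 * self.rho_e**2 / self.db) ** (1.0 / 3.0)


@dataclass(frozen=True)
class FluidVolumes:
    """Predicted volumes in litres; SF methods carry TBW only (ECW/ICW NaN)."""

    method: str
    tbw_l: float
    ecw_l: float = math.nan
    icw_l: float = math.nan
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def _sex_code(subject) -> int:
    if subject.sex == "male":
        return 1
    if subject.sex == "female":
        return 0
    raise ValueError(f"unknown sex {subject.sex!r}")


def _check_resistance(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")


def tbw_deurenberg(subject, z100_ohm: float) -> float:
    """TBW (L) from |Z| at 100 kHz, weight, age and sex."""
    _check_resistance(z100_ohm, "Z100")
    h2z = subject.height_cm**2 / z100_ohm
    return (
        6.69
        + 0.34573 * h2z
        + 0.17065 * subject.weight_kg
        - 0.11 * subject.age
        + 2.66 * _sex_code(subject)
    )


def tbw_heitmann(subject, r50_ohm: float) -> float:
    """TBW (L) from R at 50 kHz with a sex-by-weight interaction term."""
    _check_resistance(r50_ohm, "R50")
    h2r = subject.height_cm**2 / r50_ohm
    return (
        -17.58
        + 0.240 * h2r
        - 0.172 * subject.weight_kg
        + 0.40 * _sex_code(subject) * subject.weight_kg
        + 0.165 * subject.height_cm
    )


def tbw_kushner(subject, r50_ohm: float) -> float:
    """TBW (L) from R at 50 kHz, sex-specific coefficients (Kushner-Schoeller)."""
    _check_resistance(r50_ohm, "R50")
    h2r = subject.height_cm**2 / r50_ohm
    if _sex_code(subject):
        return 8.399 + 0.396 * h2r + 0.143 * subject.weight_kg
    return 8.315 + 0.382 * h2r + 0.105 * subject.weight_kg


def tbw_sun(subject, r50_ohm: float) -> float:
    """TBW (L) from R at 50 kHz, sex-specific coefficients (Sun)."""
    _check_resistance(r50_ohm, "R50")
    h2r = subject.height_cm**2 / r50_ohm
    if _sex_code(subject):
        return 1.203 + 0.499 * h2r + 0.176 * subject.weight_kg
    return 3.747 + 0.450 * h2r + 0.113 * subject.weight_kg


def ecw_delorenzo(subject, re_ohm: float, constants: MixtureConstants | None = None) -> float:
    """Mixture-theory ECW (L): k_ecw * (sqrt(W) H^2 / Re)^(2/3)."""
    _check_resistance(re_ohm, "Re")
    if constants is None:
        constants = MixtureConstants.for_sex(subject.sex)
    quot = math.sqrt(subject.weight_kg) * subject.height_cm**2 / re_ohm
    return constants.k_ecw * quot ** (2.0 / 3.0)


def solve_icw_ratio(
    re_ohm: float,
    ri_ohm: float,
    rho_i: float,
    rho_e: float,
    x_max: float = 20.0,
) -> float:
    """Unique positive root x of (1+x)^(5/2) = ((Re+Ri)/Ri)(1 + (rho_i/rho_e) x).

    g(x) = (1+x)^(5/2) - k(1 + r x) with k = (Re+Ri)/Ri >= 1 and
    r = rho_i/rho_e > 1 has g(0) = 1 - k <= 0 and g -> +inf, so a bracketed
    Brent search on (0, x_max] finds the root; x = 0 is returned only in the
    exact k = 1 (Ri -> inf, ICW = 0) limit.
    """
    _check_resistance(re_ohm, "Re")
    _check_resistance(ri_ohm, "Ri")
    if not rho_i > rho_e > 0:
        raise ValueError("require rho_i > rho_e > 0")
    k = (re_ohm + ri_ohm) / ri_ohm
    r = rho_i / rho_e

    if k == 1.0:
        return 0.0

    def g(x: float) -> float:
        return (1.0 + x) ** 2.5 - k * (1.0 + r * x)

    if g(x_max) < 0:
        raise ValueError(
            f"no root in (0, {x_max}]: Re={re_ohm}, Ri={ri_ohm}, "
            f"rho_i/rho_e={r:.3f} outside model range"
        )
    return float(brentq(g, 0.0, x_max, xtol=1e-14, rtol=8.9e-16))


def icw_delorenzo(ecw_l: float, x_ratio: float) -> float:
    """ICW = x * ECW (litres)."""
    if ecw_l < 0 or x_ratio < 0:
        raise ValueError("ECW and ICW/ECW ratio must be non-negative")
    return x_ratio * ecw_l


def _qc_flags(tbw_l: float, x_ratio: float | None = None) -> tuple[str, ...]:
    flags = []
    lo, hi = TBW_QC_RANGE_L
    if not lo <= tbw_l <= hi:
        flags.append("tbw_outside_10_70_l")
    if x_ratio is not None:
        lo, hi = ICW_ECW_RATIO_QC_RANGE
        if not lo <= x_ratio <= hi:
            flags.append("icw_ecw_ratio_outside_0.3_4")
    return tuple(flags)


def volumes_delorenzo(
    subject, re_ohm: float, ri_ohm: float, constants: MixtureConstants | None = None
) -> FluidVolumes:
    """Classical mixture-theory ECW/ICW/TBW from (Re, Ri)."""
    if constants is None:
        constants = MixtureConstants.for_sex(subject.sex)
    ecw = ecw_delorenzo(subject, re_ohm, constants)
    x = solve_icw_ratio(re_ohm, ri_ohm, constants.rho_i, constants.rho_e)
    icw = icw_delorenzo(ecw, x)
    tbw = ecw + icw
    return FluidVolumes(
        method="delorenzo", tbw_l=tbw, ecw_l=ecw, icw_l=icw, qc_flags=_qc_flags(tbw, x)
    )


def volumes_moissl(subject, re_ohm: float, ri_ohm: float) -> FluidVolumes:
    """BMI-compensated ECW/ICW/TBW from (Re, Ri)."""
    _check_resistance(re_ohm, "Re")
    _check_resistance(ri_ohm, "Ri")
    bmi = subject.bmi
    kef = 0.188 / bmi + 0.2883
    kif = 5.8758 / bmi + 0.4194
    quot = subject.height_cm**2 * math.sqrt(subject.weight_kg)
    ecw = kef * (quot / re_ohm) ** (2.0 / 3.0)
    icw = kif * (quot / ri_ohm) ** (2.0 / 3.0)
    tbw = ecw + icw
    return FluidVolumes(
        method="moissl",
        tbw_l=tbw,
        ecw_l=ecw,
        icw_l=icw,
        qc_flags=_qc_flags(tbw, icw / ecw),
    )


def predict_all(
    subject,
    spectrum: ImpedanceSpectrum,
    cole: ColeParams | None,
    methods: Iterable[str] | None = None,
) -> list[FluidVolumes]:
    """All requested predictors for one subject.

    R50 and |Z|100 are read (or log-interpolated) from the measured spectrum;
    the BIS methods use Re = R0 and Ri from the fitted Cole parameters.
    ``cole=None`` marks an unusable (unconverged) fit: BIS entries are
    emitted with NaN volumes and a ``no_converged_fit`` flag rather than
    fabricated numbers.
    """
    wanted: Sequence[str] = tuple(methods) if methods is not None else METHODS
    unknown = set(wanted) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    r50, _, _ = resistance_at(spectrum, 50e3)
    _, _, z100 = resistance_at(spectrum, 100e3)

    out: list[FluidVolumes] = []
    for method in wanted:
        if method == "deurenberg":
            tbw = tbw_deurenberg(subject, z100)
            out.append(FluidVolumes(method, tbw, qc_flags=_qc_flags(tbw)))
        elif method == "heitmann":
            tbw = tbw_heitmann(subject, r50)
            out.append(FluidVolumes(method, tbw, qc_flags=_qc_flags(tbw)))
        elif method == "kushner":
            tbw = tbw_kushner(subject, r50)
            out.append(FluidVolumes(method, tbw, qc_flags=_qc_flags(tbw)))
        elif method == "sun":
            tbw = tbw_sun(subject, r50)
            out.append(FluidVolumes(method, tbw, qc_flags=_qc_flags(tbw)))
        elif cole is None:
            out.append(
                FluidVolumes(method, math.nan, qc_flags=("no_converged_fit",))
            )
        else:
            ri = parallel_ri(cole.r0_ohm, cole.rinf_ohm)
            if method == "delorenzo":
                out.append(volumes_delorenzo(subject, cole.r0_ohm, ri))
            else:
                out.append(volumes_moissl(subject, cole.r0_ohm, ri))
    return out
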