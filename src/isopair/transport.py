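"""Transwell transport, apparent permeability and PAMPA effective permeability.

Unit conventions, package-wide: volumes in uL (converted internally to cm3
where needed), time in seconds for Papp and hours for Pe, concentrations in
uM, amounts in pmol, membrane area in cm2.

Three equivalent routes to transport T (%):

* amounts:  T = Q_A(t) / Q_D(t0) x 100
* HPLC:     T = (A_A/A_D) x (V_inj_D/V_inj_A) x (V_A_well/V_D_well) x 100
* MALDI:    T = (r_A/r_D) x (1/R) x (V_A_well/V_D_well) x 100

where r_A, r_D are the measured light/heavy area ratios of acceptor and
donor aliquots spiked with the heavy standard at S_A and S_D (uM), and
R = S_D/S_A.  Since r = C_light/S, the MALDI form reduces algebraically to
the amounts form, which is the identity the test suite checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WellAssay",
    "HplcMeasurement",
    "MaldiMeasurement",
    "TransportResult",
    "PampaAssay",
    "UndefinedTransportError",
    "transport_hplc",
    "transport_maldi",
    "transport_amounts",
    "apparent_permeability",
    "pampa_pe",
    "pampa_transport",
    "classify_pe",
    "PE_POOR_THRESHOLD",
    "PE_EXCELLENT_THRESHOLD",
]


class UndefinedTransportError(ZeroDivisionError):
    """Donor signal is zero; transport is undefined."""


# Passive-diffusion classification boundaries for PAMPA Pe (cm/s).
PE_POOR_THRESHOLD = 2.0e-6
PE_EXCELLENT_THRESHOLD = 4.0e-6


@dataclass(frozen=True)
class WellAssay:
    """Transwell geometry and timing.

    The membrane area is never implicit: 1.12 cm2 corresponds to a standard
    12-well insert and must be overridden for other formats.
    """

    V_D_well: float = 200.0  # donor well volume, uL
    V_A_well: float = 800.0  # acceptor well volume, uL
    t: float = 7200.0  # assay duration, s
    area: float = 1.12  # transwell membrane area, cm2
    C_D0: float = 200.0  # initial donor concentration, uM

    def __post_init__(self) -> None:
        if min(self.V_D_well, self.V_A_well, self.t, self.area) <= 0:
            raise ValueError("volumes, time and area must be positive")


@dataclass(frozen=True)
class HplcMeasurement:
    """Integrated chromatogram areas and injected volumes (uL)."""

    area_acceptor: float
    area_donor: float
    V_inj_acceptor: float
    V_inj_donor: float

    def __post_init__(self) -> None:
        if self.area_acceptor < 0 or self.area_donor < 0:
            raise ValueError("areas must be non-negative")
        if self.V_inj_acceptor <= 0 or self.V_inj_donor <= 0:
            raise ValueError("injected volumes must be positive")


@dataclass(frozen=True)
class MaldiMeasurement:
    """Light/heavy area ratios of acceptor and donor aliquots.

    Each aliquot is mixed 1:1 with the heavy standard at a concentration
    matched to its expected range (e.g. 2 uM for the acceptor, 200 uM for
    the donor, giving R = 100).
    """

    ratio_acceptor: float
    ratio_donor: float
    C_heavy_acceptor_spike: float = 2.0  # uM
    C_heavy_donor_spike: float = 200.0  # uM

    def __post_init__(self) -> None:
        if self.ratio_acceptor < 0 or self.ratio_donor < 0:
            raise ValueError("ratios must be non-negative")
        if self.C_heavy_acceptor_spike <= 0 or self.C_heavy_donor_spike <= 0:
            raise ValueError("spike concentrations must be positive")

    @property
    def R(self) -> float:
        """Donor/acceptor heavy-spike concentration ratio (dimensionless)."""
        return self.C_heavy_donor_spike / self.C_heavy_acceptor_spike


@dataclass(frozen=True)
class TransportResult:
    T: float  # transport, %
    P_app: float  # apparent permeability, cm/s
    mode: str  # {hplc | maldi | amounts}


@dataclass(frozen=True)
class PampaAssay:
    """Acceptor/donor concentrations (uM) and run time (h) of a PAMPA well."""

    C_A_t: float
    C_D_0: float
    t: float = 4.0

    def __post_init__(self) -> None:
        if self.C_A_t < 0 or self.C_D_0 < 0:
            raise ValueError("concentrations must be non-negative")
        if self.t <= 0:
            raise ValueError("run time must be positive")


def transport_amounts(Q_A: float, Q_D0: float) -> float:
    """T (%) from acceptor amount at time t and initial donor amount (pmol)."""
    if Q_D0 <= 0:
        raise UndefinedTransportError("initial donor amount must be positive")
    if Q_A < 0:
        raise ValueError("acceptor amount must be non-negative")
    return Q_A / Q_D0 * 100.0


def transport_hplc(m: HplcMeasurement, w: WellAssay) -> float:
    """T (%) from integrated HPLC areas corrected by injected and well volumes."""
    if m.area_donor == 0:
        raise UndefinedTransportError("donor chromatogram area is zero")
    return (
        (m.area_acceptor / m.area_donor)
        * (m.V_inj_donor / m.V_inj_acceptor)
        * (w.V_A_well / w.V_D_well)
        * 100.0
    )


def transport_maldi(m: MaldiMeasurement, w: WellAssay, as_printed: bool = False) -> float:
    """T (%) from light/heavy ratios of spiked acceptor and donor aliquots.

    The default form divides the ratio of ratios by R = S_D/S_A, which makes
    it algebraically identical to the amounts definition.  ``as_printed``
    reproduces, for auditability, a literal reading in which the donor
    heavy amount is multiplied by R inside the denominator; that arrangement
    over-scales T by R^2 and is not dimensionally consistent with the
    amounts definition.
    """
    if m.ratio_donor == 0:
        raise UndefinedTransportError("donor light/heavy ratio is zero")
    volume_term = (w.V_A_well / w.V_D_well) * 100.0
    if as_printed:
        return (m.ratio_acceptor / (m.ratio_donor / m.R)) * volume_term
    return (m.ratio_acceptor / m.ratio_donor) / m.R * volume_term


def apparent_permeability(T: float, w: WellAssay) -> float:
    """Papp (cm/s) = (V_D/t) (1/A) (T/100), with V_D converted uL -> cm3."""
    if T < 0:
        raise ValueError("transport must be non-negative")
    v_d_cm3 = w.V_D_well * 1e-3
    return (v_d_cm3 / w.t) * (1.0 / w.area) * (T / 100.0)


def classify_pe(pe: float) -> str:
    """Passive-diffusion call: poor < 2.0e-6 <= uncertain <= 4.0e-6 < excellent."""
    if pe < PE_POOR_THRESHOLD:
        return "poor"
    if pe <= PE_EXCELLENT_THRESHOLD:
        return "uncertain"
    return "excellent"


def pampa_pe(p: PampaAssay) -> tuple[float, str]:
    """PAMPA effective permeability (cm/s) and its classification.

    Pe = (-218.3 / t[h]) log10(1 - 2 C_A(t)/C_D(t0)) x 1e-6 cm/s, the
    standard double-sink form; the argument of the log must stay positive
    (acceptor below the 50% equilibrium concentration).
    """
    if p.C_D_0 <= 0:
        raise UndefinedTransportError("donor concentration must be positive")
    x = 2.0 * p.C_A_t / p.C_D_0
    if x >= 1.0:
        raise ValueError("acceptor at or beyond equilibrium: 2 C_A/C_D0 must be < 1")
    pe = (-218.3 / p.t) * math.log10(1.0 - x) * 1e-6
    return pe, classify_pe(pe)


def pampa_transport(p: "PampaAssay | None" = None, Q_A: float | None = None,
                    Q_D0: float | None = None) -> float:
    """PAMPA transport (%): acceptor amount over initial donor amount x 100.

    Either pass amounts (pmol) directly, or a :class:`PampaAssay` — PAMPA
    plates have equal donor and acceptor volumes, so the amount ratio equals
    the concentration ratio.
    """
    if p is not None:
        return transport_amounts(p.C_A_t, p.C_D_0)
    if Q_A is None or Q_D0 is None:
        raise ValueError("provide either a PampaAssay or both Q_A and Q_D0")
    return transport_amounts(Q_A, Q_D0)


def transport_result_maldi(m: MaldiMeasurement, w: WellAssay) -> TransportResult:
    T = transport_maldi(m, w)
    return TransportResult(T=T, P_app=apparent_permeability(T, w), mode="maldi")


def transport_result_hplc(m: HplcMeasurement, w: WellAssay) -> TransportResult:
    T = transport_hplc(m, w)
    return TransportResult(T=T, P_app=apparent_permeability(T, w), mode="hplc")
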