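"""Serial-dilution limit-of-quantification (LOQ) analysis.

A dilution series carries one response R_i per member: the measured
light/heavy area ratio in MALDI mode, or the dilution- and
injection-corrected absorbance R_i = A x d / V in HPLC mode.  Because the
internal standard (or the correction) makes R_i nominally constant along
the series, the per-member deviation from the reference mean

    deviation_i (%) = (R_i / R_bar - 1) x 100

measures quantification error directly, and the LOQ is the lowest
concentration down to which the deviation stays within a stated bound
(8% by default).  The reference mean R_bar excludes a configurable number
of trailing (most dilute) members — 1 for MALDI, 5 for HPLC by default —
so the noisy tail does not contaminate the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DilutionSeries",
    "LoqResult",
    "response_ratio_hplc",
    "loq_deviations",
    "call_loq",
    "MALDI_N_DISCARD",
    "HPLC_N_DISCARD",
]

MALDI_N_DISCARD = 1
HPLC_N_DISCARD = 5


def response_ratio_hplc(A: float, d: float, V: float) -> float:
    """HPLC response R_i = A x d / V (area x fold-dilution / injected uL)."""
    if V <= 0:
        raise ValueError("injected volume must be positive")
    if d < 1:
        raise ValueError("fold-dilution must be at least 1")
    if A < 0:
        raise ValueError("area must be non-negative")
    return A * d / V


@dataclass(frozen=True)
class DilutionSeries:
    """Decreasing concentrations (uM) with one response per member."""

    concentrations: Tuple[float, ...]
    responses: Tuple[float, ...]
    n_discard_for_mean: int = MALDI_N_DISCARD

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        resp = tuple(float(r) for r in self.responses)
        if len(conc) != len(resp):
            raise ValueError("concentrations and responses must align")
        if len(conc) < 3:
            raise ValueError("a dilution series needs at least 3 members")
        if any(c2 >= c1 for c1, c2 in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        if not 0 <= self.n_discard_for_mean < len(conc):
            raise ValueError("n_discard_for_mean must be smaller than the member count")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)

    @classmethod
    def from_hplc(
        cls,
        concentrations: Sequence[float],
        areas: Sequence[float],
        fold_dilutions: Sequence[float],
        injected_volumes: Sequence[float],
        n_discard_for_mean: int = HPLC_N_DISCARD,
    ) -> "DilutionSeries":
        responses = [
            response_ratio_hplc(a, d, v)
            for a, d, v in zip(areas, fold_dilutions, injected_volumes, strict=True)
        ]
        return cls(tuple(concentrations), tuple(responses), n_discard_for_mean)


@dataclass(frozen=True)
class LoqResult:
    """Reference mean, per-member deviations (%), and the LOQ call."""

    r_bar: float
    deviations: Tuple[float, ...]
    concentrations: Tuple[float, ...]
    threshold: Optional[float] = None
    loq_concentration: Optional[float] = None
    below_lowest_tested: bool = False
    above_highest_tested: bool = False


def loq_deviations(s: DilutionSeries) -> LoqResult:
    """Compute R_bar over the retained members and all per-member deviations.

    R_bar is the plain mean of the responses excluding the trailing
    ``n_discard_for_mean`` members; deviation_i = (R_i/R_bar - 1) x 100 is
    computed for every member, including the discarded ones.
    """
    retained = s.responses[: len(s.responses) - s.n_discard_for_mean]
    r_bar = float(np.mean(retained))
    if r_bar == 0:
        raise ValueError("reference mean is zero; deviations undefined")
    deviations = tuple((r / r_bar - 1.0) * 100.0 for r in s.responses)
    return LoqResult(r_bar=r_bar, deviations=deviations, concentrations=s.concentrations)


def call_loq(r: LoqResult, threshold: float = 8.0, rule: str = "strict") -> LoqResult:
    """Call the LOQ concentration from the deviation profile.

    rule="strict" (default): the LOQ is the lowest concentration c such
    that EVERY member at concentration >= c has |deviation| <= threshold —
    the longest compliant run from the top of the series.  rule="per_member"
    relaxes this to the lowest concentration whose own member is compliant.

    If all members comply, the LOQ is the lowest tested concentration and
    ``below_lowest_tested`` is set; if the most concentrated member already
    fails under the strict rule, ``loq_concentration`` is None and
    ``above_highest_tested`` is set.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    ok = [abs(d) <= threshold for d in r.deviations]
    loq: Optional[float] = None
    below = above = False
    if rule == "strict":
        run = 0
        while run < len(ok) and ok[run]:
            run += 1
        if run == 0:
            above = True
        else:
            loq = r.concentrations[run - 1]
            if run == len(ok):
                below = True
    elif rule == "per_member":
        compliant = [c for c, o in zip(r.concentrations, ok) if o]
        if not compliant:
            above = True
        else:
            loq = min(compliant)
            if ok[-1]:
                below = True
    else:
        raise ValueError(f"unknown rule {rule!r}; expected 'strict' or 'per_member'")
    return LoqResult(
        r_bar=r.r_bar,
        deviations=r.deviations,
        concentrations=r.concentrations,
        threshold=threshold,
        loq_concentration=loq,
        below_lowest_tested=below,
        above_highest_tested=above,
    )
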