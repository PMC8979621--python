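"""Stimulation protocols, tone-burst timing and acoustic dosimetry.

The exposure metric used throughout is the spatial-peak temporal-average
intensity

    I_spta = P_rms^2 / (rho c) * DC

where ``P_rms`` is the root-mean-square acoustic pressure at the target,
``rho c`` the characteristic acoustic impedance of the coupling medium
(water, for a transducer immersed in a degassed tank), and ``DC`` the duty
cycle of the pulsed protocol.  The pulse-average intensity ``I_sppa`` is the
same quantity at DC = 1.  Pressures are expressed in kPa and intensities in
mW/cm^2, matching how such exposures are conventionally reported; the
conversion to and from SI happens only inside the arithmetic.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import asdict, dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    DomainError,
    InvalidMediumError,
    ProtocolError,
    UnsupportedModalityError,
)

__all__ = [
    "Modality",
    "Medium",
    "WATER",
    "StimProtocol",
    "IntensityBin",
    "INTENSITY_BIN_EDGES",
    "compute_isppa",
    "compute_ispta",
    "classify_intensity",
    "burst_timing",
    "protocol_grid",
    "dosimetry_table",
    "protocol_to_dict",
    "protocol_from_dict",
]

#: mW/cm^2 per W/m^2
_MW_CM2_PER_W_M2 = 0.1
#: Pa per kPa
_PA_PER_KPA = 1.0e3

_REL_TOL = 1e-9


class Modality(str, Enum):
    """Stimulation modality: ultrasound or intracellular electrical pulse."""

    US = "US"
    EL = "EL"


@dataclass(frozen=True)
class Medium:
    """Acoustic propagation medium.

    Parameters
    ----------
    density : float
        Mass density rho, kg/m^3.
    speed_of_sound : float
        Longitudinal sound speed c, m/s.
    """

    density: float = 1000.0
    speed_of_sound: float = 1482.0

    def __post_init__(self) -> None:
        if not (self.density > 0 and math.isfinite(self.density)):
            raise InvalidMediumError(f"density must be positive, got {self.density}")
        if not (self.speed_of_sound > 0 and math.isfinite(self.speed_of_sound)):
            raise InvalidMediumError(
                f"speed of sound must be positive, got {self.speed_of_sound}"
            )

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance rho*c, in Pa s/m."""
        return self.density * self.speed_of_sound


#: Degassed water near room temperature.
WATER = Medium(density=1000.0, speed_of_sound=1482.0)


@dataclass(frozen=True)
class StimProtocol:
    """One stimulation setting.

    Ultrasound protocols are pulsed sinusoidal tone bursts: the carrier runs
    for ``duty_cycle * prp`` ms (T-on) out of every pulse-repetition period
    ``prp``, repeated to fill ``stim_duration`` ms; a duty cycle of 1 is a
    single continuous burst.  Electrical protocols are current steps through
    the recording electrode.

    Parameters
    ----------
    modality : Modality
        ``Modality.US`` or ``Modality.EL``.
    p_rms : float
        RMS acoustic pressure at the target, kPa (US only).
    duty_cycle : float
        On-time fraction of the pulse repetition period, in (0, 1].
    prp : float
        Pulse repetition period, ms.
    stim_duration : float
        Total duration of one stimulation window, ms.  Must be an integer
        multiple of ``prp`` for pulsed protocols.
    carrier_frequency : float
        US carrier frequency, kHz.
    n_windows : int
        Number of repeated stimulation windows in a recording.
    isi : float
        Inter-stimulation interval between window onsets, s.
    el_current : float, optional
        Injected current, nA (EL only).
    el_duration : float, optional
        Current-step duration, s (EL only).
    """

    modality: Modality = Modality.US
    p_rms: float = 0.0
    duty_cycle: float = 1.0
    prp: float = 100.0
    stim_duration: float = 300.0
    carrier_frequency: float = 490.0
    n_windows: int = 3
    isi: float = 25.0
    el_current: float | None = None
    el_duration: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality(self.modality))
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ProtocolError(f"duty_cycle must be in (0, 1], got {self.duty_cycle}")
        if self.prp <= 0:
            raise ProtocolError(f"prp must be positive, got {self.prp}")
        if self.stim_duration <= 0:
            raise ProtocolError(
                f"stim_duration must be positive, got {self.stim_duration}"
            )
        if self.p_rms < 0:
            raise ProtocolError(f"p_rms must be non-negative, got {self.p_rms}")
        if self.n_windows < 1:
            raise ProtocolError(f"n_windows must be >= 1, got {self.n_windows}")
        if self.modality is Modality.US and self.duty_cycle < 1.0:
            ratio = self.stim_duration / self.prp
            if abs(ratio - round(ratio)) > 1e-6:
                raise ProtocolError(
                    "stim_duration must be an integer multiple of prp for pulsed "
                    f"protocols (got {self.stim_duration} / {self.prp})"
                )
        if self.modality is Modality.EL:
            if self.el_current is None or self.el_duration is None:
                raise ProtocolError("EL protocols require el_current and el_duration")
            if self.el_duration <= 0:
                raise ProtocolError("el_duration must be positive")

    @property
    def t_on(self) -> float:
        """Tone-burst duration per cycle, ms."""
        return self.duty_cycle * self.prp

    @property
    def t_off(self) -> float:
        """Silent interval per cycle, ms."""
        return (1.0 - self.duty_cycle) * self.prp

    @property
    def prf(self) -> float:
        """Pulse repetition frequency, Hz (prp is in ms)."""
        return 1000.0 / self.prp

    @property
    def n_cycles(self) -> int:
        """Number of tone bursts in one stimulation window."""
        if self.duty_cycle >= 1.0:
            return 1
        return int(round(self.stim_duration / self.prp))


class IntensityBin(str, Enum):
    """Qualitative exposure class for I_spta, inclusive on the upper edge."""

    very_low = "very_low"
    low = "low"
    medium = "medium"
    high = "high"
    very_high = "very_high"

    @property
    def upper_bound(self) -> float | None:
        """Upper I_spta edge of this bin in mW/cm^2 (None for the open top bin)."""
        idx = list(IntensityBin).index(self)
        if idx < len(INTENSITY_BIN_EDGES):
            return INTENSITY_BIN_EDGES[idx]
        return None


#: Upper edges (mW/cm^2) of very_low, low, medium, high; very_high is open-ended.
INTENSITY_BIN_EDGES: tuple[float, ...] = (0.5, 2.5, 5.0, 10.0)


def compute_isppa(p_rms: float, medium: Medium = WATER) -> float:
    """Spatial-peak pulse-average intensity P_rms^2 / (rho c), in mW/cm^2.

    Parameters
    ----------
    p_rms : float
        RMS pressure in kPa; must be non-negative.
    medium : Medium
        Propagation medium providing rho and c.
    """
    if not isinstance(medium, Medium):
        raise InvalidMediumError("medium must be a Medium instance")
    if p_rms < 0:
        raise DomainError(f"p_rms must be non-negative, got {p_rms}")
    p_pa = p_rms * _PA_PER_KPA
    return p_pa * p_pa / medium.impedance * _MW_CM2_PER_W_M2


def compute_ispta(protocol: StimProtocol, medium: Medium = WATER) -> float:
    """Spatial-peak temporal-average intensity I_sppa * DC, in mW/cm^2.

    Only defined for ultrasound protocols; the duty cycle of an electrical
    step carries no acoustic meaning.
    """
    if protocol.modality is not Modality.US:
        raise UnsupportedModalityError("I_spta is defined for US protocols only")
    return compute_isppa(protocol.p_rms, medium) * protocol.duty_cycle


def classify_intensity(ispta: float) -> IntensityBin:
    """Bin an I_spta value into the five-level exposure classification.

    Edges are inclusive on the upper side: 0.5 mW/cm^2 is still ``very_low``.
    """
    if ispta < 0 or not math.isfinite(ispta):
        raise DomainError(f"I_spta must be finite and non-negative, got {ispta}")
    idx = bisect.bisect_left(INTENSITY_BIN_EDGES, ispta)
    # bisect_left puts exact edge values into the lower bin (inclusive upper edge)
    return list(IntensityBin)[idx]


def burst_timing(protocol: StimProtocol) -> list[tuple[float, float]]:
    """Tone-burst on-intervals of one stimulation window.

    Returns half-open ``[start, end)`` pairs in ms relative to window onset.
    A continuous (DC = 1) protocol is a single burst spanning the whole
    stimulation duration.
    """
    if protocol.modality is not Modality.US:
        raise UnsupportedModalityError("burst timing is defined for US protocols only")
    if protocol.duty_cycle >= 1.0:
        return [(0.0, protocol.stim_duration)]
    return [
        (k * protocol.prp, k * protocol.prp + protocol.t_on)
        for k in range(protocol.n_cycles)
    ]


def protocol_grid(
    pressures: Sequence[float] = (8.0, 12.0, 16.0, 20.0),
    duty_cycles: Sequence[float] = (0.05, 0.5, 1.0),
    **kwargs,
) -> list[StimProtocol]:
    """Cartesian grid of US protocols (default: 4 pressures x 3 duty cycles)."""
    return [
        StimProtocol(modality=Modality.US, p_rms=p, duty_cycle=dc, **kwargs)
        for p in pressures
        for dc in duty_cycles
    ]


def dosimetry_table(
    protocols: Iterable[StimProtocol] | None = None, medium: Medium = WATER
) -> pd.DataFrame:
    """Per-protocol dosimetry summary, ordered by I_spta.

    Columns: p_rms_kpa, duty_cycle, isppa_mw_cm2, ispta_mw_cm2, bin.
    """
    if protocols is None:
        protocols = protocol_grid()
    rows = []
    for prot in protocols:
        ispta = compute_ispta(prot, medium)
        rows.append(
            {
                "p_rms_kpa": prot.p_rms,
                "duty_cycle": prot.duty_cycle,
                "isppa_mw_cm2": compute_isppa(prot.p_rms, medium),
                "ispta_mw_cm2": ispta,
                "bin": classify_intensity(ispta).value,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("ispta_mw_cm2", kind="stable").reset_index(drop=True)
    )


def protocol_to_dict(protocol: StimProtocol) -> dict:
    """JSON-serializable record of a protocol."""
    d = asdict(protocol)
    d["modality"] = protocol.modality.value
    return d


def protocol_from_dict(record: dict) -> StimProtocol:
    """Inverse of :func:`protocol_to_dict`; ignores unknown keys."""
    fields = {f for f in StimProtocol.__dataclass_fields__}
    return StimProtocol(**{k: v for k, v in record.items() if k in fields})
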