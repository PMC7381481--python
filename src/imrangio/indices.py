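"""Coronary physiology indices.

Pure arithmetic on per-lesion observables:

* ``IMR`` — index of microcirculatory resistance, hyperaemic distal pressure
  times hyperaemic mean transit time (units "U" = mmHg·s), from
  pressure-wire thermodilution.
* wedge-corrected ``IMR`` — the same quantity corrected for coronary wedge
  pressure (collateral supply), applicable before stenting only.
* ``IMR_angio`` — the pressure-wire-free surrogate computed from angiography:
  mean aortic pressure × QFR × (contrast frame count / frame rate), where QFR
  (quantitative flow ratio) stands in for hyperaemic Pd/Pa and the frame
  count over fps stands in for the mean transit time.
* ``CFR`` — coronary flow reserve, resting over hyperaemic mean transit time.

Records are plain frozen dataclasses validated on construction; computations
raise :class:`~imrangio.exceptions.InvalidInputError` naming the offending
field rather than propagating NaNs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Literal, Optional

import pandas as pd

from .exceptions import (
    DegenerateHaemodynamicsError,
    InvalidInputError,
    JoinError,
    MissingFieldError,
)

Timepoint = Literal["pre_pci", "post_pci"]
VesselRole = Literal["IRA", "non_IRA"]

#: acquisition rate used for QFR cine runs (frames per second)
DEFAULT_FPS = 15.0

_TIMEPOINTS = ("pre_pci", "post_pci")
_VESSEL_ROLES = ("IRA", "non_IRA")


def _require_positive(name: str, value: Optional[float]) -> float:
    if value is None:
        raise MissingFieldError(name)
    if not math.isfinite(value) or value <= 0:
        raise InvalidInputError(name, f"must be a positive finite number, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class PhysioRecord:
    """Pressure-wire observables for one lesion at one timepoint.

    Hyperaemic values are mandatory; resting values and the coronary wedge
    pressure ``Pcw`` (measured during balloon inflation, hence pre-PCI only)
    are optional and simply omitted from downstream panels when absent.
    """

    lesion_id: str
    timepoint: Timepoint
    vessel_role: VesselRole
    Pa_hyp: float
    Pd_hyp: float
    tTmean_hyp: float
    Pa_rest: Optional[float] = None
    Pd_rest: Optional[float] = None
    tTmean_rest: Optional[float] = None
    Pcw: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timepoint not in _TIMEPOINTS:
            raise InvalidInputError("timepoint", f"must be one of {_TIMEPOINTS}")
        if self.vessel_role not in _VESSEL_ROLES:
            raise InvalidInputError("vessel_role", f"must be one of {_VESSEL_ROLES}")
        _require_positive("Pa_hyp", self.Pa_hyp)
        _require_positive("Pd_hyp", self.Pd_hyp)
        _require_positive("tTmean_hyp", self.tTmean_hyp)
        if self.Pd_hyp > self.Pa_hyp:
            raise InvalidInputError("Pd_hyp", "distal pressure cannot exceed aortic pressure")
        for name in ("Pa_rest", "Pd_rest", "tTmean_rest"):
            value = getattr(self, name)
            if value is not None:
                _require_positive(name, value)
        if self.Pcw is not None:
            if self.timepoint != "pre_pci":
                raise InvalidInputError(
                    "Pcw", "wedge pressure is measured during balloon inflation; pre_pci only"
                )
            if not math.isfinite(self.Pcw) or self.Pcw < 0:
                raise InvalidInputError("Pcw", "must be a non-negative finite number")
            if self.Pcw >= self.Pd_hyp:
                raise DegenerateHaemodynamicsError(
                    f"Pcw ({self.Pcw}) must be below Pd_hyp ({self.Pd_hyp}); "
                    "no meaningful wedge correction exists"
                )


@dataclass(frozen=True)
class AngioRecord:
    """Angiography observables for one lesion at one timepoint.

    ``QFR`` is consumed as a measured scalar in (0, 1]; whether it was the
    contrast-flow or fixed-flow variant is carried as metadata only and never
    enters a formula.
    """

    lesion_id: str
    timepoint: Timepoint
    QFR: float
    Nframes: float
    fps: float = DEFAULT_FPS
    Pa_hyp: float = 0.0
    qfr_variant: Optional[str] = None

    def __post_init__(self) -> None:
        if self.timepoint not in _TIMEPOINTS:
            raise InvalidInputError("timepoint", f"must be one of {_TIMEPOINTS}")
        if not math.isfinite(self.QFR) or not (0.0 < self.QFR <= 1.0):
            raise InvalidInputError("QFR", f"must lie in (0, 1], got {self.QFR!r}")
        # real cine runs have integer frame counts >= 1; positive fractional
        # values are permitted so the simulator's rounding-disabled diagnostic
        # mode can represent an exact transit time
        if not math.isfinite(self.Nframes) or self.Nframes <= 0:
            raise InvalidInputError("Nframes", f"must be positive, got {self.Nframes!r}")
        _require_positive("fps", self.fps)
        _require_positive("Pa_hyp", self.Pa_hyp)


@dataclass(frozen=True)
class IndexPanel:
    """All indices computable for one lesion/timepoint.

    Optional indices are ``None`` when their inputs were absent — never
    defaulted or imputed.
    """

    lesion_id: str
    timepoint: Timepoint
    IMR: float
    IMR_angio: float
    PdPa_hyp: float
    IMR_wedge: Optional[float] = None
    CFR: Optional[float] = None
    vessel_role: Optional[VesselRole] = None


def compute_imr(rec: PhysioRecord) -> float:
    """IMR = Pd(hyperaemia) × tTmean(hyperaemia), in U (mmHg·s)."""
    pd_hyp = _require_positive("Pd_hyp", rec.Pd_hyp)
    tt = _require_positive("tTmean_hyp", rec.tTmean_hyp)
    return pd_hyp * tt


def compute_wedge_corrected_imr(rec: PhysioRecord) -> float:
    """IMR corrected for coronary wedge pressure (collateral flow).

    IMR_corr = Pa × tTmean × (Pd − Pcw) / (Pa − Pcw).  With Pcw = 0 this
    collapses exactly to the uncorrected IMR.
    """
    if rec.Pcw is None:
        raise MissingFieldError("Pcw", "wedge pressure required for corrected IMR")
    pa = _require_positive("Pa_hyp", rec.Pa_hyp)
    pd_hyp = _require_positive("Pd_hyp", rec.Pd_hyp)
    tt = _require_positive("tTmean_hyp", rec.tTmean_hyp)
    if rec.Pcw >= pd_hyp:
        raise DegenerateHaemodynamicsError(
            f"Pcw ({rec.Pcw}) >= Pd_hyp ({pd_hyp}): no meaningful correction"
        )
    if rec.Pcw == 0.0:  # collapses algebraically to the uncorrected IMR
        return pd_hyp * tt
    return pa * tt * (pd_hyp - rec.Pcw) / (pa - rec.Pcw)


def compute_imr_angio(rec: AngioRecord) -> float:
    """IMR_angio = Pa(hyperaemia) × QFR × Nframes(hyperaemia) / fps, in U."""
    return rec.Pa_hyp * rec.QFR * (rec.Nframes / rec.fps)


def compute_cfr(rec: PhysioRecord) -> float:
    """Coronary flow reserve: tTmean(rest) / tTmean(hyperaemia).

    The standard thermodilution definition; raises when resting data are
    absent so callers omit CFR rather than default it.
    """
    if rec.tTmean_rest is None:
        raise MissingFieldError("tTmean_rest", "resting transit time required for CFR")
    rest = _require_positive("tTmean_rest", rec.tTmean_rest)
    hyp = _require_positive("tTmean_hyp", rec.tTmean_hyp)
    return rest / hyp


def frames_from_transit_time(tTmean: float, fps: float = DEFAULT_FPS) -> int:
    """Frame count corresponding to a transit time at a given frame rate.

    Rounds half away from zero and clamps at one frame (a cine run always
    contains at least one frame).  This is the inverse of the
    ``Nframes / fps`` mapping used by :func:`compute_imr_angio` and is what
    the cohort simulator uses to discretise transit times.
    """
    tt = _require_positive("tTmean", tTmean)
    f = _require_positive("fps", fps)
    # round-half-away-from-zero for positive input: floor(x + 0.5)
    return max(1, math.floor(tt * f + 0.5))


def compute_panel(physio: PhysioRecord, angio: AngioRecord) -> IndexPanel:
    """Join one lesion's physiology and angiography into an index panel.

    Every index whose inputs are present is populated; optional inputs that
    are absent yield absent panel fields.
    """
    if physio.lesion_id != angio.lesion_id or physio.timepoint != angio.timepoint:
        raise JoinError(
            f"records do not match: physio ({physio.lesion_id}, {physio.timepoint}) "
            f"vs angio ({angio.lesion_id}, {angio.timepoint})"
        )
    imr_wedge = None
    if physio.Pcw is not None:
        imr_wedge = compute_wedge_corrected_imr(physio)
    cfr = None
    if physio.tTmean_rest is not None:
        cfr = compute_cfr(physio)
    return IndexPanel(
        lesion_id=physio.lesion_id,
        timepoint=physio.timepoint,
        IMR=compute_imr(physio),
        IMR_angio=compute_imr_angio(angio),
        PdPa_hyp=physio.Pd_hyp / physio.Pa_hyp,
        IMR_wedge=imr_wedge,
        CFR=cfr,
        vessel_role=physio.vessel_role,
    )


# ---------------------------------------------------------------------------
# CSV interfaces

_PHYSIO_COLUMNS = [
    "lesion_id", "timepoint", "vessel_role",
    "Pa_hyp", "Pd_hyp", "tTmean_hyp",
    "Pa_rest", "Pd_rest", "tTmean_rest", "Pcw",
]
_ANGIO_COLUMNS = ["lesion_id", "timepoint", "qfr", "n_frames", "fps", "Pa_hyp", "qfr_variant"]
_PANEL_COLUMNS = [
    "lesion_id", "timepoint", "vessel_role",
    "IMR", "IMR_wedge", "IMR_angio", "CFR", "PdPa_hyp",
]


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_physiology(path) -> list[PhysioRecord]:
    """Read ``physiology.csv`` (empty cell = absent optional field)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PhysioRecord(
                lesion_id=str(row.lesion_id),
                timepoint=str(row.timepoint),
                vessel_role=str(row.vessel_role),
                Pa_hyp=float(row.Pa_hyp),
                Pd_hyp=float(row.Pd_hyp),
                tTmean_hyp=float(row.tTmean_hyp),
                Pa_rest=_opt(getattr(row, "Pa_rest", None)),
                Pd_rest=_opt(getattr(row, "Pd_rest", None)),
                tTmean_rest=_opt(getattr(row, "tTmean_rest", None)),
                Pcw=_opt(getattr(row, "Pcw", None)),
            )
        )
    return records


def read_angiography(path) -> list[AngioRecord]:
    """Read ``angiography.csv``."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        variant = getattr(row, "qfr_variant", None)
        records.append(
            AngioRecord(
                lesion_id=str(row.lesion_id),
                timepoint=str(row.timepoint),
                QFR=float(row.qfr),
                Nframes=float(row.n_frames),
                fps=float(row.fps),
                Pa_hyp=float(row.Pa_hyp),
                qfr_variant=None if (variant is None or pd.isna(variant)) else str(variant),
            )
        )
    return records


def physio_to_frame(records: list[PhysioRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in fields(PhysioRecord)} for r in records]
    return pd.DataFrame(rows, columns=_PHYSIO_COLUMNS)


def angio_to_frame(records: list[AngioRecord]) -> pd.DataFrame:
    rows = [
        {
            "lesion_id": r.lesion_id,
            "timepoint": r.timepoint,
            "qfr": r.QFR,
            "n_frames": r.Nframes,
            "fps": r.fps,
            "Pa_hyp": r.Pa_hyp,
            "qfr_variant": r.qfr_variant,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_ANGIO_COLUMNS)


def panels_to_frame(panels: list[IndexPanel]) -> pd.DataFrame:
    """One row per lesion/timepoint with all panel fields."""
    rows = [
        {
            "lesion_id": p.lesion_id,
            "timepoint": p.timepoint,
            "vessel_role": p.vessel_role,
            "IMR": p.IMR,
            "IMR_wedge": p.IMR_wedge,
            "IMR_angio": p.IMR_angio,
            "CFR": p.CFR,
            "PdPa_hyp": p.PdPa_hyp,
        }
        for p in panels
    ]
    return pd.DataFrame(rows, columns=_PANEL_COLUMNS)


def compute_panels(
    physio: list[PhysioRecord], angio: list[AngioRecord]
) -> list[IndexPanel]:
    """Join physiology and angiography record lists on (lesion_id, timepoint)."""
    angio_by_key = {(a.lesion_id, a.timepoint): a for a in angio}
    if len(angio_by_key) != len(angio):
        raise JoinError("duplicate (lesion_id, timepoint) in angiography records")
    panels = []
    for p in physio:
        key = (p.lesion_id, p.timepoint)
        if key not in angio_by_key:
            raise JoinError(f"no angiography record for {key}")
        panels.append(compute_panel(p, angio_by_key[key]))
    return panels


def write_indices(panels: list[IndexPanel], path) -> None:
    """Write ``indices.csv`` with numeric fields to 4 decimal places."""
    panels_to_frame(panels).to_csv(path, index=False, float_format="%.4f")


def read_indices(path) -> pd.DataFrame:
    return pd.read_csv(path)
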