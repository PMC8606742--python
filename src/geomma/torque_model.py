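"""Isometric muscle torque from moment arms and muscle architecture.

Maximal isometric force is physiological cross-sectional area (PCSA, mm^2)
times a specific tension of 0.3 N/mm^2.  Torque about a joint axis is the
scalar moment arm times the fibre force projected onto the line of action:

    tau_theta = r_theta * F_max * [a * fl_active(l) + fl_passive(l)] * cos(pennation)

with activation a in [0, 1] and l the fibre length normalised to optimal
fibre length.  Fibre length follows the rigid-tendon assumption:
(musculotendon length - tendon slack length) / cos(pennation).

The musculotendon curves are generalised Hill-type shapes, not
species-specific: a Gaussian active force-length curve peaking at normalised
length 1, an exponential passive curve engaging above optimal length, a
linear-region tendon curve, and a standard force-velocity curve that is
stored for completeness but unused (the analysis is purely isometric).
Tabulated curves can be substituted for any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

#: specific tension of vertebrate skeletal muscle used throughout (N/mm^2)
SPECIFIC_TENSION = 0.3

#: width (normalised lengths) of the Gaussian active force-length curve
ACTIVE_FL_WIDTH = 0.45
#: passive curve: normalised force 1 at normalised length 1 + PASSIVE_RANGE
PASSIVE_EXP_RATE = 5.0
PASSIVE_RANGE = 0.7
#: tendon strain at maximal isometric force (linear-region tendon model)
TENDON_STRAIN_AT_FMAX = 0.033


def max_isometric_force(pcsa: float,
                        specific_tension: float = SPECIFIC_TENSION) -> float:
    """Maximal isometric force (N) from PCSA (mm^2)."""
    if pcsa <= 0:
        raise ValueError(f"pcsa must be positive, got {pcsa}")
    return float(pcsa) * float(specific_tension)


@dataclass(frozen=True)
class MuscleArchitecture:
    """Architectural parameters of one muscle (or muscle head)."""

    pcsa: float                    # mm^2
    optimal_fibre_length: float    # mm
    tendon_slack_length: float     # mm
    pennation: float = 0.0         # deg, inserting fibres vs line of action
    specific_tension: float = SPECIFIC_TENSION  # N/mm^2

    def __post_init__(self) -> None:
        for name in ("pcsa", "optimal_fibre_length", "tendon_slack_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.pennation < 90.0:
            raise ValueError("pennation must be in [0, 90) degrees")

    @property
    def f_max(self) -> float:
        """Maximal isometric force (N) = PCSA x specific tension."""
        return max_isometric_force(self.pcsa, self.specific_tension)

    def normalised_fibre_length(self, mt_length: float) -> float:
        """Fibre length / optimal length for a musculotendon length (mm),
        under the rigid-tendon assumption."""
        fibre = (mt_length - self.tendon_slack_length) / np.cos(
            np.radians(self.pennation))
        return float(fibre / self.optimal_fibre_length)


def _active_fl(l: np.ndarray) -> np.ndarray:
    return np.exp(-(((np.asarray(l, float) - 1.0) / ACTIVE_FL_WIDTH) ** 2))


def _passive_fl(l: np.ndarray) -> np.ndarray:
    l = np.asarray(l, float)
    scale = np.expm1(PASSIVE_EXP_RATE * PASSIVE_RANGE)
    return np.where(l > 1.0, np.expm1(PASSIVE_EXP_RATE * (l - 1.0)) / scale, 0.0)


def _tendon_fl(strain: np.ndarray) -> np.ndarray:
    strain = np.asarray(strain, float)
    return np.clip(strain / TENDON_STRAIN_AT_FMAX, 0.0, None)


def _force_velocity(v: np.ndarray, v_max: float = 10.0, k: float = 0.25
                    ) -> np.ndarray:
    """Hill hyperbola (shortening v > 0, normalised to optimal lengths/s);
    stored but unused in the isometric analysis."""
    v = np.asarray(v, float)
    conc = (1.0 - v / v_max) / (1.0 + v / (k * v_max))
    return np.clip(conc, 0.0, None)


@dataclass(frozen=True)
class MusculotendonCurves:
    """The four normalised musculotendon curves."""

    active_fl: Callable = field(default=_active_fl)
    passive_fl: Callable = field(default=_passive_fl)
    tendon_fl: Callable = field(default=_tendon_fl)
    force_velocity: Callable = field(default=_force_velocity)

    @staticmethod
    def unit() -> "MusculotendonCurves":
        """Flat curves (active = 1, passive = 0): torque proportional to
        moment arm, the null model for rank-order comparisons."""
        return MusculotendonCurves(active_fl=lambda l: np.ones_like(np.asarray(l, float)),
                                   passive_fl=lambda l: np.zeros_like(np.asarray(l, float)))

    @staticmethod
    def from_table(lengths, forces, which: str = "active_fl",
                   base: "MusculotendonCurves | None" = None
                   ) -> "MusculotendonCurves":
        """Replace one curve with a tabulated (length, force) interpolant."""
        lengths = np.asarray(lengths, float)
        forces = np.asarray(forces, float)
        if lengths.shape != forces.shape or lengths.ndim != 1:
            raise ValueError("curve table must be two equal 1D columns")

        def interp(l):
            return np.interp(np.asarray(l, float), lengths, forces)

        base = base or MusculotendonCurves()
        kwargs = {f.name: getattr(base, f.name)
                  for f in base.__dataclass_fields__.values()}
        if which not in kwargs:
            raise ValueError(f"unknown curve {which!r}")
        kwargs[which] = interp
        return MusculotendonCurves(**kwargs)


def isometric_torque(r_theta: float, arch: MuscleArchitecture,
                     curves: MusculotendonCurves,
                     normalised_fibre_length: float = 1.0,
                     activation: float = 1.0) -> float:
    """Isometric torque (N mm) about one DOF for one muscle.

    Linear in activation when the passive force is zero; zero whenever the
    moment arm is zero.
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation must be in [0, 1], got {activation}")
    l = float(normalised_fibre_length)
    force = arch.f_max * (activation * float(curves.active_fl(l))
                          + float(curves.passive_fl(l)))
    return float(r_theta) * force * float(np.cos(np.radians(arch.pennation)))


def summed_series(series: dict[str, pd.Series],
                  head_groups: dict[str, list[str]] | None = None) -> pd.Series:
    """Sum per-muscle series, averaging multi-head muscles first.

    Muscles modelled as several heads/lines of action would be
    over-represented by a plain sum, so the heads of each group are averaged
    before the groups are summed.  All series must share one abscissa
    (e.g. joint angle grid).  Applies identically to moment-arm and torque
    series.
    """
    if not series:
        raise ValueError("no series to sum")
    series = {k: pd.Series(v) for k, v in series.items()}
    first = next(iter(series.values())).index
    for name, s in series.items():
        if not s.index.equals(first):
            raise ValueError(f"series {name!r} has a misaligned abscissa")
    if head_groups is None:
        head_groups = {name: [name] for name in series}
    grouped = set()
    for members in head_groups.values():
        for m in members:
            if m not in series:
                raise KeyError(f"head group references unknown series {m!r}")
            grouped.add(m)
    missing = set(series) - grouped
    if missing:
        raise ValueError(f"series not assigned to any head group: {sorted(missing)}")
    total = pd.Series(0.0, index=first)
    for members in head_groups.values():
        total = total + pd.concat([series[m] for m in members], axis=1).mean(axis=1)
    return total


def peak_rank_order(series_per_motion: dict[str, pd.Series]
                    ) -> list[tuple[str, float]]:
    """Motions ranked by peak absolute summed value, descending.

    Ties are broken alphabetically by motion label.
    """
    if not series_per_motion:
        raise ValueError("no series to rank")
    peaks = {m: float(np.abs(np.asarray(s, float)).max())
             for m, s in series_per_motion.items()}
    return sorted(peaks.items(), key=lambda kv: (-kv[1], kv[0]))
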