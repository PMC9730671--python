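"""Dose-volume histogram containers and radiobiological DVH reduction.

The normal-liver DVH is the dosimetric substrate of the risk models.  It is
reduced in two steps: a per-bin fractionation correction to the equieffective
dose in 2-Gy fractions (EQD2, linear-quadratic model), followed by the
generalized equivalent uniform dose (gEUD), the power mean

    gEUD(a) = (sum_i v_i * D_i**a) ** (1/a)

over differential DVH bins (v_i, D_i), with volume-effect parameter ``a``.
``a = 1`` is the arithmetic mean dose (mean liver dose, MLD); ``a > 1``
up-weights hot regions, ``a < 1`` cold regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DifferentialDVH",
    "CumulativeDVH",
    "RadbioParams",
    "DVHParseError",
    "DVHValidationError",
    "read_dvh_table",
    "cumulative_to_differential",
    "eqd2_transform",
    "geud",
    "geud_profile",
    "write_geud_profile",
    "DEFAULT_A_VALUES",
]

#: Volume-effect parameters at which gEUD is evaluated by default.
DEFAULT_A_VALUES = (0.01, 0.05, 0.1, 0.5, 1.0, 2.0)

# Normalisation policy: deviations of the volume sum from 1 below this are
# silently accepted (renormalised), deviations up to REJECT_TOL renormalise
# with a warning, anything larger is treated as a unit error and rejected.
_NORM_TOL = 1e-6
_REJECT_TOL = 1e-2


class DVHParseError(ValueError):
    """A DVH file could not be parsed (malformed row, missing column)."""


class DVHValidationError(ValueError):
    """A DVH violates a structural invariant (monotonicity, volume sum)."""


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential DVH: volume fraction per dose bin, volumes summing to 1."""

    bin_doses: np.ndarray
    bin_volumes: np.ndarray

    def __post_init__(self):
        doses = np.asarray(self.bin_doses, dtype=float)
        vols = np.asarray(self.bin_volumes, dtype=float)
        object.__setattr__(self, "bin_doses", doses)
        object.__setattr__(self, "bin_volumes", vols)
        if doses.ndim != 1 or doses.shape != vols.shape:
            raise DVHValidationError("bin_doses and bin_volumes must be 1-D and equal length")
        if doses.size == 0:
            raise DVHValidationError("empty DVH")
        if doses[0] < 0:
            raise DVHValidationError("bin doses must be >= 0")
        if doses.size > 1 and not np.all(np.diff(doses) > 0):
            raise DVHValidationError("bin doses must be strictly increasing")
        if np.any(vols < 0):
            raise DVHValidationError("bin volumes must be >= 0")
        if abs(vols.sum() - 1.0) > _NORM_TOL:
            raise DVHValidationError(
                f"bin volumes must sum to 1 within {_NORM_TOL} (got {vols.sum()!r}); "
                "use DifferentialDVH.from_raw to renormalise"
            )

    @classmethod
    def from_raw(cls, bin_doses, bin_volumes) -> "DifferentialDVH":
        """Build from un-normalised volumes (absolute cm3, percent, ...).

        Renormalises to fractions; a relative deviation of the implied total
        above 1% of itself cannot be detected here, but a zero/negative total
        is rejected.
        """
        vols = np.asarray(bin_volumes, dtype=float)
        total = vols.sum()
        if total <= 0:
            raise DVHValidationError("total DVH volume must be positive")
        return cls(np.asarray(bin_doses, dtype=float), vols / total)

    @property
    def mean_dose(self) -> float:
        return float(self.bin_volumes @ self.bin_doses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.bin_doses, "volume": self.bin_volumes})


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: volume receiving at least each dose (planning export dialect)."""

    bin_doses: np.ndarray
    volume_at_or_above: np.ndarray

    def __post_init__(self):
        doses = np.asarray(self.bin_doses, dtype=float)
        vols = np.asarray(self.volume_at_or_above, dtype=float)
        object.__setattr__(self, "bin_doses", doses)
        object.__setattr__(self, "volume_at_or_above", vols)
        if doses.ndim != 1 or doses.shape != vols.shape or doses.size < 2:
            raise DVHValidationError("cumulative DVH needs >= 2 matching dose/volume points")
        if not np.all(np.diff(doses) > 0):
            raise DVHValidationError("cumulative dose grid must be strictly increasing")
        if np.any(np.diff(vols) > 0):
            raise DVHValidationError("cumulative volume column must be non-increasing")
        if vols[0] <= 0:
            raise DVHValidationError("total volume (first cumulative entry) must be positive")


@dataclass(frozen=True)
class RadbioParams:
    """Fractionation-correction and gEUD sweep parameters.

    alpha_beta is the linear-quadratic alpha/beta ratio in Gy (2.0 Gy for
    normal liver); n_fractions the number of delivered fractions; a_values
    the volume-effect parameters swept by :func:`geud_profile`.
    """

    alpha_beta: float = 2.0
    n_fractions: int = 1
    a_values: tuple = field(default=DEFAULT_A_VALUES)

    def __post_init__(self):
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError("n_fractions must be a positive integer")
        if any(a <= 0 for a in self.a_values):
            raise ValueError("all a_values must be > 0")


def cumulative_to_differential(c: CumulativeDVH) -> DifferentialDVH:
    """Convert a cumulative DVH to a normalised differential DVH.

    Each differential bin takes the volume lost between consecutive grid
    doses and is placed at the interval midpoint; volume still at or above
    the last grid dose is placed at that dose.
    """
    vols = c.volume_at_or_above / c.volume_at_or_above[0]
    drops = -np.diff(vols)
    mids = 0.5 * (c.bin_doses[:-1] + c.bin_doses[1:])
    residual = vols[-1]
    if drops.sum() <= 0:
        raise DVHValidationError(
            "cumulative volume never decreases over the grid; dose mass cannot be located"
        )
    if residual > 1e-12:
        mids = np.append(mids, c.bin_doses[-1])
        drops = np.append(drops, residual)
    keep = drops > 0
    return DifferentialDVH.from_raw(mids[keep], drops[keep])


def read_dvh_table(path, dialect: str = "differential", volume_unit: str = "fraction") -> DifferentialDVH:
    """Read a two-column delimited DVH file into a normalised DifferentialDVH.

    The file must have a header with columns ``dose_gy`` and ``volume``
    (comma or tab separated, autodetected).  ``dialect`` selects the export
    convention; ``volume_unit`` one of fraction/percent/cm3.
    """
    if dialect not in ("cumulative", "differential"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if volume_unit not in ("fraction", "percent", "cm3"):
        raise ValueError(f"unknown volume_unit {volume_unit!r}")
    raw = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.strip().lower(): c for c in raw.columns}
    if "dose_gy" not in cols or "volume" not in cols:
        raise DVHParseError(f"{path}: expected columns 'dose_gy' and 'volume', got {list(raw.columns)}")
    dose = pd.to_numeric(raw[cols["dose_gy"]], errors="coerce")
    vol = pd.to_numeric(raw[cols["volume"]], errors="coerce")
    bad = dose.isna() | vol.isna()
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise DVHParseError(f"{path}: malformed numeric row at line {line}")
    dose, vol = dose.to_numpy(), vol.to_numpy()

    scale = {"fraction": 1.0, "percent": 0.01, "cm3": None}[volume_unit]
    if dialect == "cumulative":
        c = CumulativeDVH(dose, vol)  # unit-free: converted volumes are normalised below
        return cumulative_to_differential(c)
    if scale is None:  # cm3 differential: normalise by total
        return DifferentialDVH.from_raw(dose, vol)
    vol = vol * scale
    total = vol.sum()
    if total <= 0:
        raise DVHValidationError(f"{path}: volume column sums to {total}, expected ~1")
    if abs(total - 1.0) > _REJECT_TOL:
        raise DVHValidationError(
            f"{path}: volume fractions sum to {total:.4f}; deviation > 1% suggests a unit error"
        )
    if abs(total - 1.0) > _NORM_TOL:
        warnings.warn(
            f"{path}: volume fractions sum to {total:.6f}; renormalising", stacklevel=2
        )
    return DifferentialDVH.from_raw(dose, vol)


def eqd2_transform(d: DifferentialDVH, p: RadbioParams) -> DifferentialDVH:
    """Per-bin linear-quadratic conversion to the equieffective dose in 2-Gy fractions.

    Each bin dose D becomes D * (d + alpha/beta) / (2 + alpha/beta) with
    d = D / n_fractions the bin's dose per fraction (every voxel assumed
    irradiated proportionally in every fraction).  Identity when d = 2 Gy.
    """
    d_per_fx = d.bin_doses / p.n_fractions
    new_doses = d.bin_doses * (d_per_fx + p.alpha_beta) / (2.0 + p.alpha_beta)
    return DifferentialDVH(new_doses, d.bin_volumes)


def geud(d: DifferentialDVH, a: float) -> float:
    """Generalized equivalent uniform dose (sum_i v_i D_i^a)^(1/a), a > 0.

    0^a is taken as 0, so zero-dose bins contribute nothing.
    """
    if a <= 0:
        raise ValueError("volume-effect parameter a must be > 0")
    powered = np.power(d.bin_doses, a)  # 0**a == 0 for a > 0
    return float((d.bin_volumes @ powered) ** (1.0 / a))


def geud_profile(d: DifferentialDVH, p: RadbioParams) -> dict:
    """gEUD over the parameter sweep p.a_values, keyed by a (a=1 is the MLD)."""
    return {float(a): geud(d, a) for a in p.a_values}


def write_geud_profile(profile: dict, path) -> None:
    """Write a gEUD sweep as delimited text with columns a, geud_gy."""
    pd.DataFrame(
        {"a": list(profile.keys()), "geud_gy": list(profile.values())}
    ).to_csv(path, index=False)
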