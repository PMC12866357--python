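"""Absorbed-dose computation and interspecies extrapolation.

The dose model is local deposition of electron energy: every decay in a
tissue deposits its mean electron energy (beta plus conversion/Auger) in
that tissue, and photon cross-dose is neglected — appropriate for a
medium-energy beta emitter such as Lu-177 at mouse-organ scale.  Under that
model the absorbed dose per unit injected activity follows directly from
the time-integrated activity coefficient (TIAC, h·%ID/g):

    decays per gram per MBq injected = (TIAC/100) · 3600 s/h · 1e6 Bq/MBq
    D [Gy/MBq] = Δ_local [J/decay] · decays/g · 1000 g/kg

(the factor 1000 converts J/g to J/kg = Gy).

Red marrow, which cannot be dissected cleanly in a mouse, is estimated two
ways: from the blood concentration scaled by a red-marrow-to-blood activity
concentration ratio (RMBLR, the standard blood-based method), or from the
femur/bone compartment scaled by a marrow-to-skeleton partition factor.

Human extrapolation offers two allometric routes: ``concentration_mass_scaled``
rescales a concentration by the body-mass ratio (equivalent to preserving
%ID per whole body per gram of body mass), and ``relative_organ_mass``
preserves the organ's fractional %ID and rescales by the organ-mass ratio.
The default is the mixed convention: concentration-mass scaling for the
tumor (a lesion has no phantom counterpart organ) and relative organ mass
for normal organs.  Human doses are reported per GBq.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .biodist import Nuclide
from .kinetics import TIACResult

__all__ = [
    "GY_PER_J_PER_G",
    "AbsorbedDoseTable",
    "HumanPhantom",
    "ADULT_PHANTOM",
    "absorbed_dose_local",
    "red_marrow_dose",
    "extrapolate_to_human",
    "dose_ratio_table",
]

GY_PER_J_PER_G = 1000.0  # 1 J/g = 1000 J/kg = 1000 Gy
_SECONDS_PER_HOUR = 3600.0
_BQ_PER_MBQ = 1.0e6


def absorbed_dose_local(tiac: Union[TIACResult, float], nuclide: Nuclide) -> float:
    """Absorbed dose in Gy per MBq injected, local-deposition model.

    Linear in both the TIAC and the nuclide's per-decay energy.
    """
    value = tiac.tiac_h_pctid_g if isinstance(tiac, TIACResult) else float(tiac)
    if value < 0:
        raise ValueError("TIAC must be >= 0")
    decays_per_g = (value / 100.0) * _SECONDS_PER_HOUR * _BQ_PER_MBQ
    return nuclide.delta_local_j * decays_per_g * GY_PER_J_PER_G


def red_marrow_dose(
    blood_tiac: Optional[TIACResult] = None,
    skeletal_tiac: Optional[TIACResult] = None,
    mode: str = "blood_based",
    rmblr: float = 1.0,
    nuclide: Nuclide = None,
    marrow_to_skeleton_factor: float = 0.5,
) -> float:
    """Red-marrow absorbed dose (Gy/MBq) by one of two estimators.

    blood_based
        D_RM = RMBLR × D_blood, with RMBLR the red-marrow-to-blood activity
        concentration ratio (default 1.0; antibody studies typically use
        0.3–1.0 depending on marrow access of the intact IgG).
    skeletal
        D_RM from the femur/bone compartment concentration scaled by a
        marrow-to-skeleton partition factor (config; the default 0.5 is a
        generic phantom-derived share of skeletal activity residing in
        marrow, not a measured constant).
    """
    if nuclide is None:
        raise ValueError("nuclide is required")
    if mode == "blood_based":
        if blood_tiac is None:
            raise ValueError("blood_based mode requires the blood TIAC")
        if not 0 < rmblr <= 2:
            raise ValueError(f"rmblr must be in (0, 2], got {rmblr}")
        return rmblr * absorbed_dose_local(blood_tiac, nuclide)
    if mode == "skeletal":
        if skeletal_tiac is None:
            raise ValueError("skeletal mode requires the femur/bone TIAC")
        if not 0 < marrow_to_skeleton_factor <= 1:
            raise ValueError("marrow_to_skeleton_factor must be in (0, 1]")
        return marrow_to_skeleton_factor * absorbed_dose_local(skeletal_tiac, nuclide)
    raise ValueError(f"unknown red-marrow mode {mode!r}")


@dataclass(frozen=True)
class HumanPhantom:
    """Reference human for allometric extrapolation.

    ``tumor_mass_g`` is the assumed unit-density lesion mass used when a
    tumor is extrapolated by organ-mass ratio (default 10 g).
    """

    body_mass_kg: float
    organ_masses_g: Mapping[str, float]
    marrow_mass_g: float
    tumor_mass_g: float = 10.0

    def __post_init__(self) -> None:
        if not self.body_mass_kg > 0:
            raise ValueError("body_mass_kg must be > 0")
        for k, m in self.organ_masses_g.items():
            if not m > 0:
                raise ValueError(f"organ mass {k!r} must be > 0")
        if not self.marrow_mass_g > 0 or not self.tumor_mass_g > 0:
            raise ValueError("marrow and tumor masses must be > 0")
        if sum(self.organ_masses_g.values()) >= self.body_mass_kg * 1000.0:
            raise ValueError("organ masses must sum to less than the body mass")

    @property
    def remainder_mass_g(self) -> float:
        """Body mass not assigned to a named organ (carcass-type aggregate)."""
        return self.body_mass_kg * 1000.0 - sum(self.organ_masses_g.values())


#: Adult reference phantom (≈70 kg male, organ masses from standard
#: reference-man compilations, rounded).  Used as the default target for
#: extrapolation; pass your own phantom to change it.
ADULT_PHANTOM = HumanPhantom(
    body_mass_kg=70.0,
    organ_masses_g={
        "blood": 5300.0,
        "liver": 1800.0,
        "kidney": 310.0,
        "spleen": 150.0,
        "lungs": 1000.0,
        "gi": 1200.0,
        "skin": 3300.0,
        "muscle": 28000.0,
        "femur": 1000.0,
    },
    marrow_mass_g=1170.0,
    tumor_mass_g=10.0,
)


@dataclass(frozen=True)
class AbsorbedDoseTable:
    """Per-tissue absorbed dose with tumor-to-tissue ratios.

    Doses are Gy/MBq for ``species="mouse"`` and Gy/GBq for
    ``species="human"``.  ``ratios`` is filled by :func:`dose_ratio_table`;
    tissues with zero dose get a NaN ratio and appear in
    ``undefined_ratios``.
    """

    species: str
    doses: Mapping[str, float]
    tumor_tissue: str
    ratios: Mapping[str, float] = field(default_factory=dict)
    undefined_ratios: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "human"):
            raise ValueError("species must be 'mouse' or 'human'")
        if self.tumor_tissue not in self.doses:
            raise ValueError(f"tumor tissue {self.tumor_tissue!r} missing from doses")
        for k, d in self.doses.items():
            if d < 0:
                raise ValueError(f"negative dose for {k!r}")

    @property
    def dose_unit(self) -> str:
        return "Gy/MBq" if self.species == "mouse" else "Gy/GBq"

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Tidy table; ``rounded=True`` applies the report convention
        (doses to 2 decimals, ratios to integers)."""
        rows = []
        for tissue, d in self.doses.items():
            r = self.ratios.get(tissue, np.nan)
            if rounded:
                d = round(d, 2)
                r = int(round(r)) if np.isfinite(r) else np.nan
            rows.append((tissue, d, r))
        return pd.DataFrame(rows, columns=["tissue", f"dose_{self.species}", "tumor_to_tissue_ratio"])


def dose_ratio_table(table: AbsorbedDoseTable) -> AbsorbedDoseTable:
    """Fill tumor-to-tissue dose ratios: ratio(t) = D(tumor)/D(t).

    Full precision is retained internally; rounding to integers is applied
    only in text output (``to_frame(rounded=True)``).  Tissues with zero
    dose are flagged as undefined rather than dropped.
    """
    tumor_dose = table.doses[table.tumor_tissue]
    if not tumor_dose > 0:
        raise ValueError("tumor dose must be > 0 to form ratios")
    ratios = {}
    undefined = []
    for tissue, d in table.doses.items():
        if d > 0:
            ratios[tissue] = tumor_dose / d
        else:
            ratios[tissue] = np.nan
            undefined.append(tissue)
    return replace(table, ratios=ratios, undefined_ratios=tuple(undefined))


def extrapolate_to_human(
    mouse_doses: Mapping[str, float],
    phantom: HumanPhantom,
    mouse_body_mass_g: float,
    mouse_organ_masses_g: Optional[Mapping[str, float]] = None,
    method: str = "mixed",
    tumor_tissue: str = "tumor",
    mouse_tumor_mass_g: float = 0.3,
    marrow_tissues: tuple[str, ...] = ("rm", "rm_blood_based"),
    carcass_tissues: tuple[str, ...] = ("carcass",),
) -> dict[str, float]:
    """Allometric extrapolation of mouse doses (Gy/MBq) to human (Gy/GBq).

    Methods
    -------
    concentration_mass_scaled
        C_h = C_m × BW_mouse/BW_human; every tissue scaled by the same
        body-mass ratio.
    relative_organ_mass
        The organ's fractional %ID is preserved, so the concentration (and
        dose) scales by the organ-mass ratio m_organ,mouse/m_organ,human.
        Requires organ masses for both species; a tissue missing from the
        phantom is skipped with a warning.  Carcass-type aggregates use the
        phantom's body-remainder mass; marrow rows use the marrow mass;
        the tumor uses the phantom's assumed lesion mass.
    mixed (default)
        concentration_mass_scaled for the tumor, relative_organ_mass for
        everything else — a lesion has no phantom counterpart organ, while
        organ burdens are better preserved as fractional uptake.

    The Gy/MBq → Gy/GBq unit change contributes a factor 1000.
    """
    if method not in ("concentration_mass_scaled", "relative_organ_mass", "mixed"):
        raise ValueError(f"unknown extrapolation method {method!r}")
    if not mouse_body_mass_g > 0:
        raise ValueError("mouse_body_mass_g must be > 0")
    bw_factor = mouse_body_mass_g / (phantom.body_mass_kg * 1000.0)
    mouse_organ_masses_g = mouse_organ_masses_g or {}
    mouse_remainder = mouse_body_mass_g - sum(mouse_organ_masses_g.values())

    def organ_factor(tissue: str) -> Optional[float]:
        if tissue == tumor_tissue:
            return mouse_tumor_mass_g / phantom.tumor_mass_g
        if tissue in marrow_tissues:
            # marrow rows are already marrow-equivalent concentrations;
            # scale by body mass like any concentration-based estimate
            return bw_factor
        if tissue in carcass_tissues:
            if mouse_remainder <= 0:
                return None
            return mouse_remainder / phantom.remainder_mass_g
        if tissue in phantom.organ_masses_g and tissue in mouse_organ_masses_g:
            return mouse_organ_masses_g[tissue] / phantom.organ_masses_g[tissue]
        return None

    out: dict[str, float] = {}
    for tissue, dose in mouse_doses.items():
        if method == "concentration_mass_scaled" or (method == "mixed" and tissue == tumor_tissue):
            f = bw_factor
        else:
            f = organ_factor(tissue)
            if f is None:
                warnings.warn(
                    f"no organ mass available for {tissue!r}; tissue skipped", stacklevel=2
                )
                continue
        out[tissue] = dose * f * 1000.0  # Gy/MBq -> Gy/GBq
    return out
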