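"""Biodistribution data model and derived quantities.

The raw readout of a preclinical biodistribution study is the percentage of
the injected radioactive dose found per gram of tissue (%ID/g), measured in
groups of animals terminated at a series of time points after injection.
This module holds those observations (:class:`TissueTimeCourse`,
:class:`BiodistributionStudy`), the physical constants of the radionuclide
(:class:`Nuclide`), and the quantities derived directly from the raw table:
tumor-to-organ uptake ratios, the fraction of uptake abolished by blocking
with excess unlabeled antibody, and the antigen-density estimate from a
saturation binding assay.

Conventions
-----------
* %ID/g values are stored as percentages (65 means 65 %ID/g).  They are
  converted to fraction-of-injected-activity per gram only inside the dose
  computations (:mod:`rptdose.dosimetry`).
* Times are hours after injection and must be strictly increasing.
* Group means are taken over whichever animals are present at a time point;
  missing animals are never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "Nuclide",
    "LUTETIUM_177",
    "TissueTimeCourse",
    "BiodistributionStudy",
    "BindingAssay",
    "tumor_to_organ_ratios",
    "blocking_specificity",
    "antigens_per_cell",
]

AVOGADRO = 6.02214076e23
"""Avogadro's number, molecules per mole."""


@dataclass(frozen=True)
class Nuclide:
    """Physical data of a radionuclide under the local-deposition model.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"Lu-177"``.
    t_half_phys_h : float
        Physical half-life in hours.
    delta_local_j : float
        Locally deposited energy per decay (mean beta plus conversion and
        Auger electrons), in joules.  Photon energy is excluded: at mouse
        organ scale the photon cross-dose of a medium-energy beta emitter
        is neglected.
    """

    name: str
    t_half_phys_h: float
    delta_local_j: float

    def __post_init__(self) -> None:
        if not self.t_half_phys_h > 0:
            raise ValueError(f"t_half_phys_h must be > 0, got {self.t_half_phys_h}")
        if not self.delta_local_j > 0:
            raise ValueError(f"delta_local_j must be > 0, got {self.delta_local_j}")

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant, 1/h."""
        return np.log(2.0) / self.t_half_phys_h


#: Lutetium-177: half-life 6.647 d; mean electron energy per decay
#: (beta + conversion/Auger) ~147 keV = 2.36e-14 J, from standard
#: nuclear-data compilations.  Config, not hard-wired: pass your own
#: :class:`Nuclide` anywhere one is accepted.
LUTETIUM_177 = Nuclide(name="Lu-177", t_half_phys_h=159.528, delta_local_j=2.36e-14)


@dataclass(frozen=True)
class TissueTimeCourse:
    """Per-tissue %ID/g observations over time across animals.

    ``values`` holds one array of per-animal %ID/g measurements for each
    entry of ``times_h``; group sizes may differ between time points.
    """

    tissue: str
    times_h: tuple[float, ...]
    values: tuple[tuple[float, ...], ...]
    blocked: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if t.size == 0:
            raise ValueError(f"{self.tissue}: empty time course")
        if t.size != len(self.values):
            raise ValueError(f"{self.tissue}: {t.size} times but {len(self.values)} value groups")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.tissue}: times must be strictly increasing, got {t}")
        for ti, vals in zip(t, self.values):
            v = np.asarray(vals, dtype=float)
            if v.size < 1:
                raise ValueError(f"{self.tissue} at {ti} h: at least one animal required")
            if np.any(v < 0):
                raise ValueError(f"{self.tissue} at {ti} h: negative %ID/g")

    @classmethod
    def from_observations(
        cls, tissue: str, observations: Sequence[tuple[float, Sequence[float]]], blocked: bool = False
    ) -> "TissueTimeCourse":
        obs = sorted(observations, key=lambda o: o[0])
        return cls(
            tissue=tissue,
            times_h=tuple(float(t) for t, _ in obs),
            values=tuple(tuple(float(x) for x in v) for _, v in obs),
            blocked=blocked,
        )

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.times_h, dtype=float)

    @property
    def means(self) -> np.ndarray:
        """Per-time-point group mean %ID/g."""
        return np.array([np.mean(v) for v in self.values])

    @property
    def sds(self) -> np.ndarray:
        """Per-time-point group SD (ddof=1; 0 when a single animal)."""
        return np.array([np.std(v, ddof=1) if len(v) > 1 else 0.0 for v in self.values])

    @property
    def n_animals(self) -> np.ndarray:
        return np.array([len(v) for v in self.values])

    def scaled(self, c: float) -> "TissueTimeCourse":
        """Return a copy with every %ID/g multiplied by ``c`` (c >= 0)."""
        if c < 0:
            raise ValueError("scale factor must be >= 0")
        return TissueTimeCourse(
            tissue=self.tissue,
            times_h=self.times_h,
            values=tuple(tuple(c * x for x in v) for v in self.values),
            blocked=self.blocked,
        )


@dataclass(frozen=True)
class BiodistributionStudy:
    """A full biodistribution study: one time course per tissue plus masses."""

    nuclide: Nuclide
    tissues: Mapping[str, TissueTimeCourse]
    tumor_tissue: str
    body_mass_g: float
    organ_masses_g: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError("study has no tissues")
        if self.tumor_tissue not in self.tissues:
            raise ValueError(f"tumor tissue {self.tumor_tissue!r} not among tissues")
        if not self.body_mass_g > 0:
            raise ValueError("body_mass_g must be > 0")
        for k, m in self.organ_masses_g.items():
            if not m > 0:
                raise ValueError(f"organ mass for {k!r} must be > 0, got {m}")

    @property
    def tumor(self) -> TissueTimeCourse:
        return self.tissues[self.tumor_tissue]

    def scaled(self, c: float) -> "BiodistributionStudy":
        return BiodistributionStudy(
            nuclide=self.nuclide,
            tissues={k: tc.scaled(c) for k, tc in self.tissues.items()},
            tumor_tissue=self.tumor_tissue,
            body_mass_g=self.body_mass_g,
            organ_masses_g=dict(self.organ_masses_g),
        )


def tumor_to_organ_ratios(study: BiodistributionStudy) -> pd.DataFrame:
    """Tumor-to-organ uptake ratio table with first-order error propagation.

    For every non-tumor, non-blocked tissue sampled on the tumor's time grid,
    ratio(tissue, t) = mean tumor %ID/g at t / mean tissue %ID/g at t.  The
    SD is propagated from the two group SDs by the delta method,

        SD_r = r * sqrt( (SD_tum/mean_tum)^2 + (SD_org/mean_org)^2 ),

    i.e. per-animal pairing is *not* assumed (animals contributing the tumor
    and organ means are the same mice, but the printed group statistics do
    not retain the pairing).

    Returns a tidy frame with columns ``tissue, time_h, ratio, ratio_sd,
    undefined``; a zero organ mean makes the cell undefined (NaN ratio,
    ``undefined=True``) rather than silently dropping it.

    Raises
    ------
    ValueError
        If a tissue's sampling grid differs from the tumor's.
    """
    tumor = study.tumor
    tt, tm, ts = tumor.times, tumor.means, tumor.sds
    rows = []
    for name, tc in study.tissues.items():
        if name == study.tumor_tissue or tc.blocked:
            continue
        if not np.array_equal(tc.times, tt):
            raise ValueError(
                f"tissue {name!r} sampled at {tc.times} but tumor at {tt}; grids must align"
            )
        om, os = tc.means, tc.sds
        for i, t in enumerate(tt):
            if om[i] == 0.0:
                rows.append((name, t, np.nan, np.nan, True))
                continue
            r = tm[i] / om[i]
            cv2 = (ts[i] / tm[i]) ** 2 if tm[i] > 0 else 0.0
            sd = r * np.sqrt(cv2 + (os[i] / om[i]) ** 2) if tm[i] > 0 else ts[i] / om[i]
            rows.append((name, t, r, sd, False))
    return pd.DataFrame(rows, columns=["tissue", "time_h", "ratio", "ratio_sd", "undefined"])


def blocking_specificity(unblocked: float, blocked: float) -> float:
    """Fraction of uptake abolished by blocking with excess unlabeled binder.

    Returns ``(unblocked - blocked) / unblocked``.  A value of 1 means the
    entire uptake was receptor-mediated; 0 means blocking had no effect.
    Negative values (blocked exceeds unblocked) indicate no detectable
    specific component and are returned as-is with a warning.
    """
    if unblocked <= 0:
        raise ValueError(f"unblocked uptake must be > 0, got {unblocked}")
    if blocked < 0:
        raise ValueError(f"blocked uptake must be >= 0, got {blocked}")
    frac = (unblocked - blocked) / unblocked
    if frac < 0:
        warnings.warn(
            "blocked uptake exceeds unblocked uptake: no specific component detectable",
            stacklevel=2,
        )
    return frac


@dataclass(frozen=True)
class BindingAssay:
    """Saturation binding/blocking assay readout for antigen quantification.

    ``bound_amount_mol`` is the molar amount of radiolabeled antibody bound
    at a saturating concentration; ``blocked_bound_mol`` the amount bound
    under a large molar excess of unlabeled competitor (non-specific
    component); ``n_cells`` the number of cells in the sample.
    """

    bound_amount_mol: float
    blocked_bound_mol: float
    n_cells: float

    def __post_init__(self) -> None:
        if self.bound_amount_mol < 0 or self.blocked_bound_mol < 0:
            raise ValueError("bound amounts must be >= 0")
        if not self.n_cells > 0:
            raise ValueError("n_cells must be > 0")


def antigens_per_cell(assay: BindingAssay, antigens_per_antibody: float = 1.0) -> float:
    """Antigen density from specific binding at saturation.

    specific = bound - blocked (clamped at 0 with a warning if blocked
    exceeds bound), and

        N = specific [mol] * N_A * antigens_per_antibody / n_cells.

    ``antigens_per_antibody`` exposes the binding stoichiometry: the default
    1.0 assumes one antigen per bound antibody; a bivalently engaged IgG
    would justify 2.0.
    """
    specific = assay.bound_amount_mol - assay.blocked_bound_mol
    if specific < 0:
        warnings.warn("blocked exceeds total bound; specific binding clamped to 0", stacklevel=2)
        specific = 0.0
    return specific * AVOGADRO * antigens_per_antibody / assay.n_cells
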