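"""CSV/JSON readers and writers and the run-level configuration.

Schemas (comma-separated, UTF-8, dot decimal, header mandatory; times in
hours for biodistribution, days for efficacy):

* biodistribution: ``tissue, time_h, animal_id, pct_id_per_g, blocked``
* tumor growth:    ``animal_id, group, day, volume_mm3``
* survival:        ``animal_id, group, time_d, event``

Readers validate row by row and raise :class:`CSVValidationError` carrying
line numbers; malformed rows are never silently dropped.  Output files
start with a comment header recording the config hash and seed, so reruns
with the same configuration are byte-identical and recognizably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .biodist import BiodistributionStudy, LUTETIUM_177, Nuclide, TissueTimeCourse
from .dosimetry import ADULT_PHANTOM, HumanPhantom
from .efficacy import SurvivalDataset, TumorGrowthRecord
from .kinetics import GrowthModel
from .synthetic import MOUSE_ORGAN_MASSES_G

__all__ = [
    "CSVValidationError",
    "read_biodistribution_csv",
    "write_biodistribution_csv",
    "read_growth_csv",
    "write_growth_csv",
    "read_survival_csv",
    "write_survival_csv",
    "RunConfig",
    "write_table_with_header",
]

log = logging.getLogger("rptdose")


class CSVValidationError(ValueError):
    """Schema violation in an input table, with per-row messages."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        super().__init__(f"{path}: {len(problems)} invalid rows:\n" + "\n".join(problems))


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CSVValidationError(path, [f"missing required columns: {missing}"])


def read_biodistribution_csv(
    path,
    nuclide: Nuclide = LUTETIUM_177,
    tumor_tissue: str = "tumor",
    body_mass_g: float = 27.0,
    organ_masses_g: Optional[Mapping[str, float]] = None,
) -> BiodistributionStudy:
    """Read a biodistribution table into a :class:`BiodistributionStudy`.

    Blocked rows form separate time courses keyed ``"<tissue>_blocked"``.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ("tissue", "time_h", "animal_id", "pct_id_per_g", "blocked"), path)
    problems = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            t = float(row["time_h"])
            v = float(row["pct_id_per_g"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric time_h or pct_id_per_g")
            continue
        if not np.isfinite(t) or t < 0:
            problems.append(f"line {line}: invalid time_h {row['time_h']!r}")
        if not np.isfinite(v) or v < 0:
            problems.append(f"line {line}: invalid pct_id_per_g {row['pct_id_per_g']!r}")
        if str(row["blocked"]).lower() not in ("true", "false", "0", "1"):
            problems.append(f"line {line}: blocked must be boolean, got {row['blocked']!r}")
    if problems:
        raise CSVValidationError(path, problems)
    df["blocked"] = df["blocked"].astype(str).str.lower().isin(("true", "1"))
    tissues: dict[str, TissueTimeCourse] = {}
    for (tissue, blocked), sub in df.groupby(["tissue", "blocked"], sort=True):
        obs = [
            (float(t), [float(x) for x in grp["pct_id_per_g"]])
            for t, grp in sub.groupby("time_h", sort=True)
        ]
        key = f"{tissue}_blocked" if blocked else str(tissue)
        tissues[key] = TissueTimeCourse.from_observations(str(tissue), obs, blocked=bool(blocked))
    return BiodistributionStudy(
        nuclide=nuclide,
        tissues=tissues,
        tumor_tissue=tumor_tissue,
        body_mass_g=body_mass_g,
        organ_masses_g=dict(organ_masses_g or {}),
    )


def write_biodistribution_csv(study: BiodistributionStudy, path, header: str = "") -> None:
    rows = []
    for key, tc in study.tissues.items():
        for t, vals in zip(tc.times_h, tc.values):
            for j, v in enumerate(vals):
                rows.append((tc.tissue, t, f"{key}-t{t:g}-a{j + 1}", v, tc.blocked))
    df = pd.DataFrame(rows, columns=["tissue", "time_h", "animal_id", "pct_id_per_g", "blocked"])
    write_table_with_header(df, path, header)


def read_growth_csv(path) -> list[TumorGrowthRecord]:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ("animal_id", "group", "day", "volume_mm3"), path)
    problems = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            d, v = float(row["day"]), float(row["volume_mm3"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric day or volume_mm3")
            continue
        if not np.isfinite(d) or d < 0:
            problems.append(f"line {line}: invalid day {row['day']!r}")
        if not np.isfinite(v) or v < 0:
            problems.append(f"line {line}: invalid volume_mm3 {row['volume_mm3']!r}")
    if problems:
        raise CSVValidationError(path, problems)
    records = []
    for (aid, grp), sub in df.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("day")
        records.append(
            TumorGrowthRecord(
                animal_id=str(aid),
                group=str(grp),
                times_d=tuple(float(x) for x in sub["day"]),
                volumes_mm3=tuple(float(x) for x in sub["volume_mm3"]),
                end_of_study_d=float(sub["day"].max()),
            )
        )
    return records


def write_growth_csv(records, path, header: str = "") -> None:
    rows = [
        (r.animal_id, r.group, d, v)
        for r in records
        for d, v in zip(r.times_d, r.volumes_mm3)
    ]
    df = pd.DataFrame(rows, columns=["animal_id", "group", "day", "volume_mm3"])
    write_table_with_header(df, path, header)


def read_survival_csv(path) -> SurvivalDataset:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ("animal_id", "group", "time_d", "event"), path)
    problems = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            t, e = float(row["time_d"]), int(row["event"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric time_d or event")
            continue
        if not t > 0:
            problems.append(f"line {line}: time_d must be > 0, got {row['time_d']!r}")
        if e not in (0, 1):
            problems.append(f"line {line}: event must be 0/1, got {row['event']!r}")
    if problems:
        raise CSVValidationError(path, problems)
    return SurvivalDataset.from_frame(df)


def write_survival_csv(data: SurvivalDataset, path, header: str = "") -> None:
    write_table_with_header(data.to_frame(), path, header)


def write_table_with_header(df: pd.DataFrame, path, header: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_DEFAULTS = dict(
    tiac_method="trapezoid_tail",
    extrapolation_method="mixed",
    rm_mode="blood_based",
    rmblr=1.0,
    marrow_to_skeleton_factor=0.5,
    confirm_n=2,
    limit_mm3=1000.0,
    tumor_model="uptake_washout",
    organ_model="mono_exp",
    mouse_tumor_mass_g=0.3,
    reference_group="placebo",
    seed=0,
)


@dataclass
class RunConfig:
    """Run-level configuration tying the pipeline stages together.

    Every field left at its default is logged with source "default" when
    loaded from JSON; user-supplied fields are logged with source "user".
    """

    biodistribution_csv: Optional[str] = None
    growth_csv: Optional[str] = None
    survival_csv: Optional[str] = None
    output_dir: str = "."
    nuclide: Nuclide = field(default_factory=lambda: LUTETIUM_177)
    phantom: HumanPhantom = field(default_factory=lambda: ADULT_PHANTOM)
    growth_model: Optional[GrowthModel] = None
    mouse_body_mass_g: float = 27.0
    mouse_organ_masses_g: dict = field(default_factory=lambda: dict(MOUSE_ORGAN_MASSES_G))
    tiac_method: str = _DEFAULTS["tiac_method"]
    extrapolation_method: str = _DEFAULTS["extrapolation_method"]
    rm_mode: str = _DEFAULTS["rm_mode"]
    rmblr: float = _DEFAULTS["rmblr"]
    marrow_to_skeleton_factor: float = _DEFAULTS["marrow_to_skeleton_factor"]
    confirm_n: int = _DEFAULTS["confirm_n"]
    limit_mm3: float = _DEFAULTS["limit_mm3"]
    tumor_model: str = _DEFAULTS["tumor_model"]
    organ_model: str = _DEFAULTS["organ_model"]
    mouse_tumor_mass_g: float = _DEFAULTS["mouse_tumor_mass_g"]
    reference_group: str = _DEFAULTS["reference_group"]
    seed: int = _DEFAULTS["seed"]

    def __post_init__(self) -> None:
        if self.tiac_method not in ("trapezoid_tail", "analytic_fit"):
            raise ValueError(f"invalid tiac_method {self.tiac_method!r}")
        if self.extrapolation_method not in (
            "concentration_mass_scaled", "relative_organ_mass", "mixed",
        ):
            raise ValueError(f"invalid extrapolation_method {self.extrapolation_method!r}")
        if self.rm_mode not in ("blood_based", "skeletal"):
            raise ValueError(f"invalid rm_mode {self.rm_mode!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        path = Path(path)
        raw = json.loads(path.read_text(encoding="utf-8"))
        kwargs: dict = {}
        if "nuclide" in raw:
            kwargs["nuclide"] = Nuclide(
                name=raw["nuclide"].get("name", "custom"),
                t_half_phys_h=raw["nuclide"]["t_half_phys_h"],
                delta_local_j=raw["nuclide"]["delta_local_j"],
            )
        if "phantom" in raw:
            ph = raw["phantom"]
            kwargs["phantom"] = HumanPhantom(
                body_mass_kg=ph["body_mass_kg"],
                organ_masses_g=ph["organ_masses_g"],
                marrow_mass_g=ph["marrow_mass_g"],
                tumor_mass_g=ph.get("tumor_mass_g", 10.0),
            )
        if "growth_model" in raw:
            gm = raw["growth_model"]
            kwargs["growth_model"] = GrowthModel(
                v0_mm3=gm["v0_mm3"], k_growth_per_day=gm["k_growth_per_day"]
            )
        for key in (
            "biodistribution_csv", "growth_csv", "survival_csv", "output_dir",
            "mouse_body_mass_g", "mouse_organ_masses_g", "tiac_method",
            "extrapolation_method", "rm_mode", "rmblr", "marrow_to_skeleton_factor",
            "confirm_n", "limit_mm3", "tumor_model", "organ_model",
            "mouse_tumor_mass_g", "reference_group", "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        cfg = cls(**kwargs)
        for key, default in _DEFAULTS.items():
            source = "user" if key in raw else "default"
            log.info("config %s=%r (%s)", key, getattr(cfg, key), source)
        for key in ("biodistribution_csv", "growth_csv", "survival_csv"):
            p = getattr(cfg, key)
            if p is not None and not (path.parent / p).exists() and not Path(p).exists():
                raise FileNotFoundError(f"config references missing file: {p}")
        return cfg

    def to_canonical_dict(self) -> dict:
        d = asdict(self)
        d["nuclide"] = {
            "name": self.nuclide.name,
            "t_half_phys_h": self.nuclide.t_half_phys_h,
            "delta_local_j": self.nuclide.delta_local_j,
        }
        d["phantom"] = {
            "body_mass_kg": self.phantom.body_mass_kg,
            "organ_masses_g": dict(self.phantom.organ_masses_g),
            "marrow_mass_g": self.phantom.marrow_mass_g,
            "tumor_mass_g": self.phantom.tumor_mass_g,
        }
        if self.growth_model is not None:
            d["growth_model"] = asdict(self.growth_model)
        return d

    @property
    def config_hash(self) -> str:
        """First 12 hex digits of the SHA-256 of the canonical config JSON.

        The output directory is excluded: where results are written does not
        change what they are, and reruns into different directories must be
        recognizably identical.
        """
        d = self.to_canonical_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @property
    def output_header(self) -> str:
        return f"rptdose config_hash={self.config_hash} seed={self.seed}"
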