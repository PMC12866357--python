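"""End-to-end pipeline stages: biodistribution → dose tables; efficacy reports.

`run_dosimetry` executes the full dosimetry chain on a
:class:`~rptdose.biodist.BiodistributionStudy`: per-tissue time-activity
fits, tumor growth-dilution correction, time-integrated activity, mouse
absorbed doses with both red-marrow estimators, allometric extrapolation,
and the tumor-to-tissue ratio tables for both species.  `run_efficacy`
executes the response/survival chain on growth and survival tables.  Both
are deterministic for fixed inputs; stage failures carry the stage name and
the offending tissue or group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .biodist import BiodistributionStudy
from .dosimetry import (
    AbsorbedDoseTable,
    absorbed_dose_local,
    dose_ratio_table,
    extrapolate_to_human,
    red_marrow_dose,
)
from .efficacy import (
    KMCurve,
    classify_response,
    cr_rate,
    kaplan_meier,
    logrank_test,
    survival_summary,
)
from .io import RunConfig, read_biodistribution_csv, read_growth_csv, read_survival_csv, write_table_with_header
from .kinetics import TIACResult, TimeActivityModel, growth_dilution_correction, tiac

__all__ = ["DosimetryRun", "run_dosimetry", "EfficacyRun", "run_efficacy"]

log = logging.getLogger("rptdose")


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage and the offending item."""


@dataclass(frozen=True)
class DosimetryRun:
    """Results of a full dosimetry pipeline run."""

    tiacs: Mapping[str, TIACResult]
    mouse_table: AbsorbedDoseTable
    human_table: AbsorbedDoseTable

    def combined_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Report table: tissue, dose_preclinical, ratio_preclinical,
        dose_human, ratio_human."""
        m = self.mouse_table.to_frame(rounded=rounded).rename(
            columns={"dose_mouse": "dose_preclinical", "tumor_to_tissue_ratio": "ratio_preclinical"}
        )
        h = self.human_table.to_frame(rounded=rounded).rename(
            columns={"dose_human": "dose_human", "tumor_to_tissue_ratio": "ratio_human"}
        )
        return m.merge(h, on="tissue", how="outer")


def run_dosimetry(
    config: RunConfig, study: Optional[BiodistributionStudy] = None, write: bool = False
) -> DosimetryRun:
    """Execute biodist → kinetics → dosimetry and build both dose tables.

    ``study`` may be passed directly (e.g. from the simulator); otherwise it
    is read from ``config.biodistribution_csv``.  With ``write=True`` the
    Table-2-shaped CSV and its JSON twin are written to
    ``config.output_dir``.
    """
    if study is None:
        if config.biodistribution_csv is None:
            raise StageError("input: no biodistribution study or CSV provided")
        study = read_biodistribution_csv(
            config.biodistribution_csv,
            nuclide=config.nuclide,
            body_mass_g=config.mouse_body_mass_g,
            organ_masses_g=config.mouse_organ_masses_g,
        )
    if not study.tissues:
        raise StageError("validation: empty tissue map")
    nuclide = study.nuclide
    tiacs: dict[str, TIACResult] = {}
    mouse_doses: dict[str, float] = {}
    tumor = study.tumor_tissue
    k_h = (config.growth_model.k_growth_per_day / 24.0) if config.growth_model else 0.0

    for name, tc in study.tissues.items():
        if tc.blocked:
            continue
        model_name = config.tumor_model if name == tumor else config.organ_model
        try:
            fit = TimeActivityModel.from_timecourse(tc, model=model_name).fit()
            tail_rate = None
            use_tc = tc
            if name == tumor and config.growth_model is not None:
                use_tc = growth_dilution_correction(tc, config.growth_model)
                # corrected curve washes out at lambda_eff - k; the physical
                # floor is applied inside tiac()
                tail_rate = fit.lambda_eff - k_h
            res = tiac(use_tc, fit, method=config.tiac_method, nuclide=nuclide, tail_rate=tail_rate)
        except Exception as exc:
            raise StageError(f"kinetics: tissue {name!r}: {exc}") from exc
        tiacs[name] = res
        mouse_doses[name] = absorbed_dose_local(res, nuclide)
        log.info(
            "stage=kinetics tissue=%s model=%s tiac=%.4g tail_frac=%.3f",
            name, model_name, res.tiac_h_pctid_g, res.tail_fraction,
        )

    # red-marrow rows: the default run emits both estimators when their
    # source compartments are present
    try:
        if "blood" in tiacs:
            mouse_doses["rm_blood_based"] = red_marrow_dose(
                blood_tiac=tiacs["blood"], mode="blood_based",
                rmblr=config.rmblr, nuclide=nuclide,
            )
        if "femur" in tiacs:
            mouse_doses["rm"] = red_marrow_dose(
                skeletal_tiac=tiacs["femur"], mode="skeletal",
                marrow_to_skeleton_factor=config.marrow_to_skeleton_factor,
                nuclide=nuclide,
            )
    except Exception as exc:
        raise StageError(f"dosimetry: red marrow: {exc}") from exc

    mouse_table = dose_ratio_table(
        AbsorbedDoseTable(species="mouse", doses=mouse_doses, tumor_tissue=tumor)
    )
    human_doses = extrapolate_to_human(
        mouse_doses,
        phantom=config.phantom,
        mouse_body_mass_g=study.body_mass_g,
        mouse_organ_masses_g=dict(study.organ_masses_g),
        method=config.extrapolation_method,
        tumor_tissue=tumor,
        mouse_tumor_mass_g=config.mouse_tumor_mass_g,
    )
    human_table = dose_ratio_table(
        AbsorbedDoseTable(species="human", doses=human_doses, tumor_tissue=tumor)
    )
    run = DosimetryRun(tiacs=tiacs, mouse_table=mouse_table, human_table=human_table)
    if write:
        from pathlib import Path

        out = Path(config.output_dir)
        df = run.combined_frame(rounded=True)
        write_table_with_header(df, out / "dose_table.csv", config.output_header)
        (out / "dose_table.json").write_text(
            df.to_json(orient="records", indent=2), encoding="utf-8"
        )
    return run


@dataclass(frozen=True)
class EfficacyRun:
    """Results of the efficacy pipeline: per-group response and survival."""

    response_table: pd.DataFrame
    km_curves: Mapping[str, KMCurve]
    summary: Optional[pd.DataFrame]
    pairwise_logrank: Optional[pd.DataFrame]


def run_efficacy(
    config: RunConfig,
    growth_records=None,
    survival=None,
    write: bool = False,
) -> EfficacyRun:
    """Execute response classification, KM estimation and pairwise log-rank.

    Growth records and/or survival data may be passed directly or read from
    the configured CSVs.  With a single group the report contains no tests.
    """
    if growth_records is None and config.growth_csv is not None:
        growth_records = read_growth_csv(config.growth_csv)
    if survival is None and config.survival_csv is not None:
        survival = read_survival_csv(config.survival_csv)
    if growth_records is None and survival is None:
        raise StageError("input: neither growth nor survival data provided")

    response_rows = []
    if growth_records:
        by_group: dict[str, list] = {}
        for rec in growth_records:
            try:
                call = classify_response(rec, limit_mm3=config.limit_mm3, confirm_n=config.confirm_n)
            except Exception as exc:
                raise StageError(f"efficacy: animal {rec.animal_id!r}: {exc}") from exc
            by_group.setdefault(rec.group, []).append(call)
        for group in sorted(by_group):
            calls = by_group[group]
            rate = cr_rate(calls)
            states = {s: sum(c.state == s for c in calls) for s in
                      ("complete_response", "regrowth_after_cr", "progression", "stable")}
            response_rows.append({"group": group, "n": rate.n, "n_cr": rate.n_cr,
                                  "cr_percent": rate.percent, **states})
        log.info("stage=response groups=%d animals=%d", len(by_group), len(growth_records))
    response_table = pd.DataFrame(response_rows)

    km_curves: dict[str, KMCurve] = {}
    summary = None
    pairwise = None
    if survival is not None:
        for group in survival.groups:
            km_curves[group] = kaplan_meier(survival, group)
        groups = list(km_curves)
        if config.reference_group in km_curves and km_curves[config.reference_group].median_defined:
            summary = survival_summary(km_curves, config.reference_group)
        rows = []
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                res = logrank_test(survival, a, b)
                rows.append((a, b, res.chi2, res.p_value))
        if rows:
            pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "chi2", "p_value"])
        log.info("stage=survival groups=%d comparisons=%d", len(groups), len(rows))

    run = EfficacyRun(
        response_table=response_table, km_curves=km_curves,
        summary=summary, pairwise_logrank=pairwise,
    )
    if write:
        from pathlib import Path

        out = Path(config.output_dir)
        if not response_table.empty:
            write_table_with_header(response_table, out / "response.csv", config.output_header)
        if summary is not None:
            write_table_with_header(summary, out / "survival_summary.csv", config.output_header)
        if pairwise is not None:
            write_table_with_header(pairwise, out / "logrank.csv", config.output_header)
        blob = {
            "response": response_table.to_dict(orient="records"),
            "summary": None if summary is None else summary.to_dict(orient="records"),
            "pairwise_logrank": None if pairwise is None else pairwise.to_dict(orient="records"),
        }
        import json

        (out / "efficacy.json").write_text(json.dumps(blob, indent=2, default=float), encoding="utf-8")
    return run
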