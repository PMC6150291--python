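"""End-to-end orchestration: correction -> quenching -> binding -> thermo ->
conformation -> competition, driven by a YAML study manifest.

Study manifest schema (paths relative to the manifest file)::

    series:                    # one titration manifest per temperature
      - t288.yaml
      - t298.yaml
      - t309.yaml
    skip_inner_filter: false   # optional: treat absorbances as negligible
    eem:                       # optional conformational section
      reference: hsa_eem.csv
      treated:
        ACV-HSA: acv_eem.csv
    competition:               # optional site-marker section
      - marker: WAR
        free: t298.yaml
        with_marker: war298.yaml

Stages lacking inputs (a single temperature, no EEM...) are skipped and the
reason is logged and recorded in the report — never silently fabricated.
Identical manifest and inputs produce byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from typing import Optional

import pandas as pd
import yaml

from . import io as qio
from .binding_thermo import (
    BindingFitResult,
    ForceCall,
    ThermoResult,
    classify_forces,
    fit_double_log,
    fit_vant_hoff,
    gibbs_from_K,
)
from .competition import CompetitionResult, compare_with_marker
from .conformation import EEMPeakSummary, eem_find_peaks, percent_quench
from .correction import apply_correction
from .datatypes import TitrationSeries
from .errors import PipelineError, QuenchBindError
from .quenching import MechanismCall, QuenchFitResult, classify_mechanism, fit_quenching

log = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("quenchbind")
    except PackageNotFoundError:  # pragma: no cover - editable-install edge
        return "unknown"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineReport:
    """All derived quantities of one study run, plus provenance."""

    quench: list[QuenchFitResult] = field(default_factory=list)
    binding: list[BindingFitResult] = field(default_factory=list)
    mechanism: Optional[MechanismCall] = None
    thermo: Optional[ThermoResult] = None
    forces: Optional[ForceCall] = None
    eem_reference: Optional[EEMPeakSummary] = None
    eem_quench: dict[str, EEMPeakSummary] = field(default_factory=dict)
    competition: list[CompetitionResult] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    # ---- presentation -----------------------------------------------------
    def quench_table(self) -> pd.DataFrame:
        """Per-temperature quenching constants, display-rounded as in the
        literature (K_SV/K_LB in 1e4 M^-1, K_q in 1e13 M^-1 s^-1)."""
        rows = []
        for q, b in zip(self.quench, self.binding):
            rows.append(
                {
                    "T_K": q.temperature_K,
                    "K_SV_1e4": round(q.K_sv / 1e4, 2),
                    "K_SV_se_1e4": round((q.K_sv_stderr or 0.0) / 1e4, 2),
                    "K_q_1e13": round(q.K_q / 1e13, 2),
                    "R2_SV": round(q.r2_sv, 4),
                    "K_LB_1e4": round(q.K_lb / 1e4, 2) if q.K_lb is not None else float("nan"),
                    "R2_LB": round(q.r2_lb, 4) if q.r2_lb is not None else float("nan"),
                    "K_1e4": round(b.K / 1e4, 2),
                    "n": round(b.n, 2),
                    "R2_bind": round(b.r2, 4),
                }
            )
        return pd.DataFrame(rows)

    def thermo_table(self) -> pd.DataFrame:
        if self.thermo is None:
            return pd.DataFrame()
        rows = []
        for T, dG in sorted(self.thermo.dG0_by_T_kJ.items()):
            rows.append(
                {
                    "T_K": T,
                    "dG0_kJ": round(dG, 2),
                    "dH0_kJ": round(self.thermo.dH0_kJ, 2),
                    "dS0_J": round(self.thermo.dS0_J, 2),
                    "R2": round(self.thermo.r2, 4),
                }
            )
        return pd.DataFrame(rows)

    def competition_table(self) -> pd.DataFrame:
        rows = []
        for c in self.competition:
            rows.append(
                {
                    "marker": c.marker_name,
                    "K_SV_free_1e4": round(c.K_sv_free / 1e4, 2),
                    "K_SV_marker_1e4": round(c.K_sv_marker / 1e4, 2),
                    "K_free_1e4": round(c.K_free / 1e4, 2),
                    "K_marker_1e4": round(c.K_marker / 1e4, 2),
                    "ratio_K": round(c.ratio_K, 3),
                    "displaced": c.displaced,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def enc(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return asdict(obj)
            if isinstance(obj, (set, tuple)):
                return list(obj)
            return str(obj)

        payload = {
            "quench": [asdict(q) for q in self.quench],
            "binding": [asdict(b) for b in self.binding],
            "mechanism": asdict(self.mechanism) if self.mechanism else None,
            "thermo": asdict(self.thermo) if self.thermo else None,
            "forces": asdict(self.forces) if self.forces else None,
            "eem_reference": asdict(self.eem_reference) if self.eem_reference else None,
            "eem_quench": {k: asdict(v) for k, v in self.eem_quench.items()},
            "competition": [asdict(c) for c in self.competition],
            "skipped": self.skipped,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=enc)


def _load_and_correct(path: str, *, skip_inner_filter: bool) -> TitrationSeries:
    try:
        series = qio.read_manifest(path)
    except QuenchBindError as exc:
        raise PipelineError(f"stage 'read': failed on {path}: {exc}") from exc
    try:
        return apply_correction(series, skip=skip_inner_filter)
    except QuenchBindError as exc:
        raise PipelineError(f"stage 'correction': failed on {path}: {exc}") from exc


def run_pipeline(
    manifest_path: str,
    *,
    fit_intercept: bool = False,
    skip_inner_filter: Optional[bool] = None,
) -> PipelineReport:
    """Execute the full analysis described by a study manifest."""
    manifest_path = os.fspath(manifest_path)
    with open(manifest_path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "series" not in doc:
        raise PipelineError(f"stage 'read': {manifest_path} is not a study manifest (missing 'series')")
    base = os.path.dirname(manifest_path)
    if skip_inner_filter is None:
        skip_inner_filter = bool(doc.get("skip_inner_filter", False))

    report = PipelineReport()
    report.provenance = {
        "manifest": os.path.abspath(manifest_path),
        "manifest_sha256": _sha256(manifest_path),
        "software": f"quenchbind {_package_version()}",
        "fit_intercept": fit_intercept,
        "skip_inner_filter": skip_inner_filter,
    }

    series_paths = [os.path.join(base, p) for p in doc["series"]]
    series_list = [_load_and_correct(p, skip_inner_filter=skip_inner_filter) for p in series_paths]
    series_list.sort(key=lambda s: s.temperature_K)
    report.provenance["series_sha256"] = {p: _sha256(p) for p in series_paths}

    # quenching + binding fits, per temperature
    for s in series_list:
        try:
            report.quench.append(fit_quenching(s, fit_intercept=fit_intercept))
            report.binding.append(fit_double_log(s))
        except QuenchBindError as exc:
            raise PipelineError(f"stage 'quench/bind': failed on series at {s.temperature_K} K: {exc}") from exc

    # mechanism
    if len(report.quench) >= 2:
        report.mechanism = classify_mechanism(report.quench)
    else:
        msg = "mechanism: skipped (needs >= 2 temperatures)"
        log.info(msg)
        report.skipped.append(msg)

    # van't Hoff thermodynamics from the double-log K(T)
    if len(report.binding) >= 2:
        try:
            report.thermo = fit_vant_hoff({b.temperature_K: b.K for b in report.binding})
        except QuenchBindError as exc:
            raise PipelineError(f"stage 'thermo': {exc}") from exc
        report.forces = classify_forces(report.thermo.dH0_kJ, report.thermo.dS0_J)
    else:
        msg = "thermo: skipped (needs K at >= 2 temperatures)"
        log.info(msg)
        report.skipped.append(msg)

    # conformational (EEM) section
    eem_doc = doc.get("eem")
    if eem_doc:
        try:
            ref = qio.read_eem(os.path.join(base, eem_doc["reference"]))
            report.eem_reference = eem_find_peaks(ref)
            for name, path in (eem_doc.get("treated") or {}).items():
                treated = qio.read_eem(os.path.join(base, path))
                report.eem_quench[name] = percent_quench(report.eem_reference, treated)
        except QuenchBindError as exc:
            raise PipelineError(f"stage 'conformation': {exc}") from exc
    else:
        msg = "conformation: skipped (no EEM inputs)"
        log.info(msg)
        report.skipped.append(msg)

    # competition section
    for entry in doc.get("competition") or []:
        try:
            free = _load_and_correct(os.path.join(base, entry["free"]), skip_inner_filter=skip_inner_filter)
            marked = _load_and_correct(os.path.join(base, entry["with_marker"]), skip_inner_filter=skip_inner_filter)
            report.competition.append(
                compare_with_marker(
                    free,
                    marked,
                    entry.get("marker", "marker"),
                    fit_intercept=fit_intercept,
                )
            )
        except QuenchBindError as exc:
            raise PipelineError(f"stage 'competition': failed on marker {entry.get('marker')}: {exc}") from exc
    if not doc.get("competition"):
        msg = "competition: skipped (no marker series)"
        log.info(msg)
        report.skipped.append(msg)

    return report
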