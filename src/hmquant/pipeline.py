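"""End-to-end study orchestration.

``run_study`` generates a phantom cohort, simulates every configured rater
with both ROI-placement methods, computes early/late H/M ratios, classifies
them against the pathological cut-offs and assembles the full agreement
panel (ICC, Fleiss kappa, pairwise Cohen kappa, per-rater Spearman between
methods, chi-square on pathological proportions).  ``analyze_external`` runs
the identical analysis on user-supplied images and ROI files.

Seeding is hierarchical off the single master seed: the cohort, each
(subject, rater, method) placement, and the Fleiss bootstrap all draw from
disjoint spawn keys, so runs are deterministic and byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import agreement
from .errors import (
    CompletenessError,
    DegenerateInputError,
    DivisionError,
    HMQuantError,
    ValidationError,
)
from .hm import DEFAULT_CUTOFFS, classify, hm_ratio
from .io import read_planar, read_roiset, write_roiset
from .phantom import (
    CohortRecord,
    PhantomParams,
    RaterProfile,
    default_profiles,
    generate_cohort,
    save_cohort,
    simulate_rater_rois,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "analyze_external", "quantify_cohort"]

logger = logging.getLogger("hmquant.pipeline")

METHODS = ("manual", "semiautomatic")
PHASES = ("early", "late")


@dataclass
class StudyConfig:
    """One complete replication-run description."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    n_subjects: int = 35
    profiles: List[RaterProfile] = field(default_factory=default_profiles)
    cutoffs: Tuple[float, float] = DEFAULT_CUTOFFS
    methods: Tuple[str, ...] = METHODS
    hm_spec: Optional[tuple] = None
    seed: int = 0
    fleiss_bootstrap: int = 2000
    image_format: str = "text"

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValidationError("need >= 2 rater profiles")
        if self.cutoffs[0] <= 0 or self.cutoffs[1] <= 0:
            raise ValidationError("cut-offs must be > 0")
        for m in self.methods:
            if m not in METHODS:
                raise ValidationError(f"unknown method {m!r}")
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise ValidationError("rater labels must be unique")

    @property
    def raters(self) -> List[str]:
        return [p.label for p in self.profiles]

    @classmethod
    def from_dict(cls, doc: dict) -> "StudyConfig":
        doc = dict(doc)
        if "phantom" in doc and isinstance(doc["phantom"], dict):
            doc["phantom"] = PhantomParams(**doc["phantom"])
        if "profiles" in doc:
            doc["profiles"] = [
                p if isinstance(p, RaterProfile) else RaterProfile(**p) for p in doc["profiles"]
            ]
        for key in ("cutoffs", "methods", "hm_spec"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def from_file(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) if not path.endswith(".json") else json.load(fh)
        return cls.from_dict(doc or {})


@dataclass(frozen=True)
class StudyReport:
    """Full panel of per-rater summaries and agreement statistics."""

    n_subjects: int
    raters: Tuple[str, ...]
    methods: Tuple[str, ...]
    panel: dict
    results: pd.DataFrame  # subject, rater, method, early_hm, late_hm, *_path

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "raters": list(self.raters),
            "methods": list(self.methods),
            **self.panel,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"

    def to_text(self) -> str:
        return _format_text(self)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.results.to_csv(os.path.join(outdir, "hm_results.csv"), index=False)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            fh.write(self.to_json())
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(self.to_text())


# ---------------------------------------------------------------------------
# Core runs
# ---------------------------------------------------------------------------

def _placement_seed(master: int, subject_idx: int, rater_idx: int, method: str):
    return np.random.SeedSequence(
        entropy=master, spawn_key=(2, subject_idx, rater_idx, METHODS.index(method))
    )


def quantify_cohort(
    records: Sequence[CohortRecord],
    config: StudyConfig,
    roisets_out: Optional[dict] = None,
) -> pd.DataFrame:
    """Simulate raters and compute per-subject H/M ratios and labels."""
    rows = []
    for si, rec in enumerate(records):
        for ri, profile in enumerate(config.profiles):
            for method in config.methods:
                try:
                    rois = simulate_rater_rois(
                        rec, profile, method, seed=_placement_seed(config.seed, si, ri, method)
                    )
                    early = hm_ratio(rec.early, rois.cardiac, rois.mediastinal)
                    late = hm_ratio(rec.late, rois.cardiac, rois.mediastinal)
                    cls = classify(early, late, config.cutoffs)
                except HMQuantError as exc:
                    logger.error(
                        "stage failure subject=%s rater=%s method=%s: %s",
                        rec.subject_id, profile.label, method, exc,
                    )
                    raise
                logger.debug(
                    "quantified subject=%s rater=%s method=%s early=%.4f late=%.4f",
                    rec.subject_id, profile.label, method, early, late,
                )
                if roisets_out is not None:
                    roisets_out[(rec.subject_id, profile.label, method)] = rois
                rows.append(
                    {
                        "subject": rec.subject_id,
                        "rater": profile.label,
                        "method": method,
                        "early_hm": early,
                        "late_hm": late,
                        "early_path": cls.early_pathological,
                        "late_path": cls.late_pathological,
                    }
                )
    return pd.DataFrame(rows)


def build_report(
    results: pd.DataFrame,
    raters: Sequence[str],
    methods: Sequence[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> StudyReport:
    """Assemble the agreement panel from a per-subject results table."""
    subjects = sorted(results["subject"].unique())
    n = len(subjects)
    panel: dict = {"summary": {}, "icc": {}, "fleiss": {}, "cohen": {}, "chi_square": {},
                   "spearman": {}}

    for method in methods:
        panel["summary"][method] = {}
        panel["icc"][method] = {}
        panel["fleiss"][method] = {}
        panel["cohen"][method] = {}
        panel["chi_square"][method] = {}
        sub = results[results["method"] == method]
        for phase in PHASES:
            ratio_col, path_col = f"{phase}_hm", f"{phase}_path"
            cont = sub.pivot(index="subject", columns="rater", values=ratio_col)
            cont = cont.loc[subjects, list(raters)].to_numpy()
            cat = sub.pivot(index="subject", columns="rater", values=path_col)
            cat = cat.loc[subjects, list(raters)].to_numpy().astype(int)

            panel["summary"][method][phase] = {
                r: {
                    "mean": float(cont[:, i].mean()),
                    "sd": float(cont[:, i].std(ddof=1)),
                    "n_pathological": int(cat[:, i].sum()),
                }
                for i, r in enumerate(raters)
            }
            try:
                res = agreement.icc(cont, form="icc2")
                panel["icc"][method][phase] = {
                    "estimate": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "label": agreement.interpret("icc", res.estimate),
                }
            except DegenerateInputError as exc:
                panel["icc"][method][phase] = {"degenerate": True, "reason": str(exc)}

            fl = agreement.fleiss_kappa(
                cat, n_boot=n_boot,
                seed=int(np.random.SeedSequence(entropy=seed, spawn_key=(3,)).entropy % (2**32)),
            )
            if fl.degenerate:
                panel["fleiss"][method][phase] = {"degenerate": True}
            else:
                panel["fleiss"][method][phase] = {
                    "estimate": fl.estimate,
                    "ci_low": fl.ci_low,
                    "ci_high": fl.ci_high,
                    "label": agreement.interpret("fleiss", fl.estimate),
                }

            pairs_k, pairs_c = {}, {}
            for i in range(len(raters)):
                for j in range(i + 1, len(raters)):
                    key = f"{raters[i]}|{raters[j]}"
                    ck = agreement.cohens_kappa(cat[:, i], cat[:, j])
                    if ck.degenerate and not np.isfinite(ck.estimate):
                        pairs_k[key] = {"degenerate": True}
                    else:
                        pairs_k[key] = {
                            "estimate": ck.estimate,
                            "label": agreement.interpret("cohen", ck.estimate),
                            "degenerate": ck.degenerate,
                        }
                    a, b = int(cat[:, i].sum()), int(cat[:, j].sum())
                    try:
                        chi = agreement.chi_square_2x2([[a, n - a], [b, n - b]])
                        pairs_c[key] = {"statistic": chi.statistic, "p": chi.p}
                    except DegenerateInputError:
                        pairs_c[key] = {"degenerate": True}
            panel["cohen"][method][phase] = pairs_k
            panel["chi_square"][method][phase] = pairs_c

    if set(METHODS) <= set(methods):
        for phase in PHASES:
            panel["spearman"][phase] = {}
            for r in raters:
                x = results[(results["rater"] == r) & (results["method"] == "manual")]
                y = results[(results["rater"] == r) & (results["method"] == "semiautomatic")]
                x = x.set_index("subject").loc[subjects, f"{phase}_hm"].to_numpy()
                y = y.set_index("subject").loc[subjects, f"{phase}_hm"].to_numpy()
                sp = agreement.spearman_rho(x, y)
                panel["spearman"][phase][r] = (
                    {"undefined": True} if sp.undefined else {"rho": sp.rho, "p": sp.p}
                )

    return StudyReport(
        n_subjects=n,
        raters=tuple(raters),
        methods=tuple(methods),
        panel=panel,
        results=results,
    )


def run_study(config: Optional[StudyConfig] = None, outdir: Optional[str] = None) -> StudyReport:
    """Run the full simulated study; optionally persist all artifacts."""
    config = config or StudyConfig()
    logger.info("generating cohort n=%d seed=%d", config.n_subjects, config.seed)
    records = generate_cohort(
        n=config.n_subjects,
        hm_spec=config.hm_spec,
        params=config.phantom,
        seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)),
    )
    roisets: dict = {}
    results = quantify_cohort(records, config, roisets_out=roisets)
    report = build_report(
        results, config.raters, config.methods, n_boot=config.fleiss_bootstrap, seed=config.seed
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        save_cohort(records, os.path.join(outdir, "images"), config.image_format)
        roi_dir = os.path.join(outdir, "rois")
        os.makedirs(roi_dir, exist_ok=True)
        for (sid, rater, method), rois in roisets.items():
            write_roiset(rois, os.path.join(roi_dir, f"{sid}_{rater}_{method}.json"))
        report.write(outdir)
    return report


def analyze_external(
    image_dir: str,
    roi_dir: str,
    raters: Optional[Sequence[str]] = None,
    methods: Optional[Sequence[str]] = None,
    cutoffs: Tuple[float, float] = DEFAULT_CUTOFFS,
    image_format: str = "text",
    n_boot: int = 2000,
    seed: int = 0,
) -> StudyReport:
    """Run the identical analysis on external images and ROI-set files.

    Layout: ``<image_dir>/<subject>_{early,late}.<ext>`` and
    ``<roi_dir>/<subject>_<rater>_<method>.json``.  Raters/methods default to
    everything discovered in *roi_dir*; any missing subject/rater/method
    combination raises :class:`CompletenessError` naming the gaps.
    """
    ext = "txt" if image_format == "text" else "dcm"
    pat = re.compile(r"^(.+)_early\." + ext + "$")
    subjects = sorted(m.group(1) for f in os.listdir(image_dir) if (m := pat.match(f)))
    if not subjects:
        raise CompletenessError([("<no subjects found>", "", "")])

    roi_pat = re.compile(r"^(.+)_([^_]+)_(manual|semiautomatic)\.json$")
    found = {}
    for f in os.listdir(roi_dir):
        m = roi_pat.match(f)
        if m:
            found[(m.group(1), m.group(2), m.group(3))] = os.path.join(roi_dir, f)
    if raters is None:
        raters = sorted({k[1] for k in found}, key=str)
    if methods is None:
        methods = [m for m in METHODS if any(k[2] == m for k in found)]

    gaps = [
        (sid, r, meth)
        for sid in subjects
        for r in raters
        for meth in methods
        if (sid, r, meth) not in found
    ]
    if gaps:
        raise CompletenessError(gaps)

    rows = []
    for sid in subjects:
        early = read_planar(os.path.join(image_dir, f"{sid}_early.{ext}"), image_format,
                            phase="early", subject_id=sid)
        late = read_planar(os.path.join(image_dir, f"{sid}_late.{ext}"), image_format,
                           phase="late", subject_id=sid)
        for r in raters:
            for meth in methods:
                rois = read_roiset(found[(sid, r, meth)])
                try:
                    e = hm_ratio(early, rois.cardiac, rois.mediastinal)
                    l = hm_ratio(late, rois.cardiac, rois.mediastinal)
                except DivisionError as exc:
                    raise DivisionError(
                        f"subject {sid} rater {r} method {meth}: {exc}"
                    ) from exc
                cls = classify(e, l, cutoffs)
                rows.append(
                    {
                        "subject": sid, "rater": r, "method": meth,
                        "early_hm": e, "late_hm": l,
                        "early_path": cls.early_pathological,
                        "late_path": cls.late_pathological,
                    }
                )
    results = pd.DataFrame(rows)
    return build_report(results, raters, methods, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Text rendering
# ---------------------------------------------------------------------------

def _fmt_stat(d: dict, with_ci: bool = True) -> str:
    if d.get("degenerate"):
        return "degenerate"
    if with_ci and "ci_low" in d:
        return f"{d['estimate']:.2f} ({d['ci_low']:.2f}-{d['ci_high']:.2f}) [{d['label']}]"
    if "estimate" in d:
        return f"{d['estimate']:.2f} [{d['label']}]"
    return "n/a"


def _format_text(report: StudyReport) -> str:
    p = report.panel
    lines = [f"Inter- and intra-rater indices (n = {report.n_subjects} subjects)", ""]
    for phase in PHASES:
        lines.append(f"== {phase.capitalize()} H/M ratio ==")
        for method in report.methods:
            lines.append(f"  -- {method} method --")
            summ = p["summary"][method][phase]
            for r in report.raters:
                s = summ[r]
                lines.append(
                    f"    {r:<10s} {s['mean']:.2f} +/- {s['sd']:.2f}   "
                    f"pathological {s['n_pathological']}/{report.n_subjects}"
                )
            lines.append(f"    ICC          {_fmt_stat(p['icc'][method][phase])}")
            lines.append(f"    Fleiss kappa {_fmt_stat(p['fleiss'][method][phase])}")
            for pair, d in p["cohen"][method][phase].items():
                lines.append(f"    Cohen kappa {pair:<22s} {_fmt_stat(d, with_ci=False)}")
            for pair, d in p["chi_square"][method][phase].items():
                txt = "degenerate" if d.get("degenerate") else (
                    f"chi2={d['statistic']:.2f} p={d['p']:.3g}"
                )
                lines.append(f"    Chi-square  {pair:<22s} {txt}")
        lines.append("")
    if p.get("spearman"):
        lines.append("== Intra-rater (manual vs semi-automatic, Spearman) ==")
        for phase in PHASES:
            for r, d in p["spearman"].get(phase, {}).items():
                txt = "undefined" if d.get("undefined") else f"rho={d['rho']:.2f} p={d['p']:.3g}"
                lines.append(f"  {phase:<6s} {r:<10s} {txt}")
    return "\n".join(lines) + "\n"
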