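"""End-to-end stepwise classification workflow over a cohort table.

The workflow mirrors the recommended diagnostic escalation: strict
classification from the primary markers first (MYCN amplification,
TERT rearrangement, TERT expression, then the ALT assays), and only
samples that remain ambiguous are escalated to the evidence-weighted
resolution using whichever auxiliary metrics (telomere content/length,
TERRA, TVR singletons, insertions, ATRX) are present. Non-ambiguous
samples never consult auxiliary markers.
"""
from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from typing import Optional

import pandas as pd

from .classify import ClassifierConfig, TMMCall, resolve_ambiguous, strict_classify
from .errors import InputError
from .simulate import features_from_row

try:
    __version__ = version("telotype")
except PackageNotFoundError:  # not installed (e.g. source tree)
    __version__ = "unknown"


@dataclass
class WorkflowReport:
    calls: list[TMMCall]
    provenance: dict[str, list[str]]  # sample -> markers consulted
    config: ClassifierConfig
    counts: dict[str, int] = field(default_factory=dict)
    tool_version: str = __version__

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "label": c.label,
                    "stage": c.stage,
                    "evidence": ";".join(f"{m}={d}" for m, d in c.evidence),
                }
                for c in self.calls
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "tool_version": self.tool_version,
                "config": dataclasses.asdict(self.config),
                "counts": self.counts,
                "samples": [
                    {
                        "sample_id": c.sample_id,
                        "label": c.label,
                        "stage": c.stage,
                        "evidence": [list(e) for e in c.evidence],
                        "markers_used": self.provenance[c.sample_id],
                    }
                    for c in self.calls
                ],
            },
            indent=2,
            sort_keys=True,
        )


def load_cohort_table(path: str) -> pd.DataFrame:
    """Read a cohort marker TSV (one row per sample, NA for missing)."""
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise InputError(f"cannot read cohort table {path}: {exc}") from exc
    if "sample_id" not in frame.columns:
        raise InputError(f"{path}: missing required column 'sample_id'")
    for col in ("mna", "tert_ra", "atrx_mut", "tert_expr_high",
                "telomerase_activity_high", "apb", "cca"):
        if col in frame.columns and frame[col].dtype == object:
            frame[col] = frame[col].map(
                {"True": True, "False": False, "true": True, "false": False,
                 True: True, False: False}
            )
    return frame.set_index("sample_id", drop=False)


def run_workflow(
    cohort: pd.DataFrame,
    config: Optional[ClassifierConfig] = None,
) -> WorkflowReport:
    """Classify every sample of a cohort table, escalating only the
    strictly-ambiguous ones, and assemble the audit report."""
    cfg = config or ClassifierConfig()
    calls: list[TMMCall] = []
    provenance: dict[str, list[str]] = {}
    for _, row in cohort.iterrows():
        features = features_from_row(row)
        call = strict_classify(features)
        used = [m for m, _ in call.evidence]
        if call.label == "ambiguous":
            call = resolve_ambiguous(features, cfg)
            used += [m for m, _ in call.evidence]
        calls.append(call)
        provenance[features.sample_id] = used
    counts = Counter(c.label for c in calls)
    counts["n_samples"] = len(calls)
    counts["n_resolved"] = sum(c.stage == "resolved" for c in calls)
    return WorkflowReport(
        calls=calls,
        provenance=provenance,
        config=cfg,
        counts=dict(counts),
    )


def reproduce_cohort_statistics(
    cohort: pd.DataFrame, config: Optional[ClassifierConfig] = None
) -> dict:
    """Cohort-level summary used to reproduce published cohort numbers
    from a user-supplied per-sample marker table: strict-classification
    rate, subgroup metric means and ROC threshold proposals.

    The study's own marker table is controlled-access and not shipped;
    this function runs on any table in the cohort TSV dialect.
    """
    from .classify import empirical_roc, propose_threshold

    report = run_workflow(cohort, config)
    strict_labels = {
        c.sample_id: c.label for c in report.calls if c.stage == "strict"
    }
    n = len(report.calls)
    out: dict = {
        "n_samples": n,
        "strict_unambiguous": len(strict_labels),
        "strict_unambiguous_percent": 100.0 * len(strict_labels) / n,
        "labels": dict(Counter(c.label for c in report.calls)),
    }
    final = {c.sample_id: c.label for c in report.calls}
    unamb = cohort.loc[list(strict_labels)]
    is_alt = pd.Series(
        [strict_labels[s] == "ALT_pos" for s in unamb["sample_id"]],
        index=unamb.index,
    )
    for metric, key in (("tc_ratio", "tc"), ("trf_kb", "trf"), ("terra_total", "terra")):
        if metric not in unamb.columns:
            continue
        mask = unamb[metric].notna()
        if is_alt[mask].nunique() < 2:
            continue
        curve = empirical_roc(
            unamb.loc[mask, metric].to_numpy(), is_alt[mask].to_numpy()
        )
        thr, sens, spec = propose_threshold(curve)
        out[f"{key}_auc"] = curve.auc
        out[f"{key}_youden_threshold"] = thr
        out[f"{key}_sensitivity"] = sens
        out[f"{key}_specificity"] = spec
        for label in ("TMM_neg", "ALT_pos", "TEL_pos"):
            members = [s for s, lab in final.items() if lab == label]
            vals = cohort.loc[members, metric].dropna()
            if len(vals):
                out[f"{key}_mean_{label}"] = float(vals.mean())
    return out
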