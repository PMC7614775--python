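"""Selectivity ranking and end-to-end pipeline orchestration.

A selectivity report ranks every quantified cysteine site under one
treatment condition by its (capped) competition ratio, mirroring the
rank-plots used to read off the most potently engaged site and any
off-targets. ``run_pipeline`` wires the stages together — synthetic-data
generation (or ingestion of user tables), QC, site aggregation,
engagement calls, optional dose-response fits, and report emission —
writing a reproducible artifact bundle with a provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dose import DoseResponseSeries, FourPLFit, InsufficientDataError, fit_4pl
from .simulate import duplicate_design, generate_psm_table, generate_truths
from .tmt import ChannelLayout, QcReport, QcThresholds, quantify

__all__ = ["SelectivityReport", "rank_sites", "engagement_series",
           "run_pipeline", "config_digest"]


@dataclass
class SelectivityReport:
    """Ranked engagement table for one condition."""

    condition: str
    table: pd.DataFrame                      # ranked: site_id, ratio, engagement_pct, engaged
    engaged_site_count: int
    top_site: str | None
    declared_targets: tuple[str, ...] = ()
    off_targets: tuple[str, ...] = ()        # engaged sites not declared as targets
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "engaged_site_count": self.engaged_site_count,
            "top_site": self.top_site,
            "declared_targets": list(self.declared_targets),
            "off_targets": list(self.off_targets),
            "ranking": self.table[["site_id", "ratio", "engagement_pct", "engaged"]]
                .to_dict(orient="records"),
            "provenance": self.provenance,
        }


def rank_sites(
    sites: pd.DataFrame,
    condition: str,
    declared_targets: Sequence[str] = (),
    *,
    provenance: Mapping | None = None,
) -> SelectivityReport:
    """Rank called sites of one condition by capped competition ratio.

    Ordering is deterministic: descending ratio, ties broken by
    lexicographic ``site_id``. Engaged sites not listed in
    ``declared_targets`` are reported as off-targets. An empty table is a
    valid (empty) report.
    """
    if "engaged" not in sites.columns:
        raise ValueError("rank_sites expects a called site table (run call_engagement)")
    sub = sites[sites["condition"] == condition].copy()
    sub = sub.sort_values(["ratio", "site_id"],
                          ascending=[False, True], kind="mergesort",
                          ignore_index=True)
    engaged = sub[sub["engaged"]]
    off = tuple(s for s in engaged["site_id"] if s not in set(declared_targets))
    return SelectivityReport(
        condition=condition,
        table=sub,
        engaged_site_count=int(sub["engaged"].sum()),
        top_site=sub["site_id"].iloc[0] if len(sub) else None,
        declared_targets=tuple(declared_targets),
        off_targets=off,
        provenance=dict(provenance or {}),
    )


def engagement_series(
    sites: pd.DataFrame,
    layout: ChannelLayout,
    site_id: str,
    *,
    compound: str | None = None,
) -> DoseResponseSeries:
    """Concentration series of one site's engagement across conditions.

    Concentrations come from the layout's ``condition_meta``; conditions
    without metadata (or belonging to a different compound) are skipped.
    """
    sub = sites[sites["site_id"] == site_id]
    concs, resps, time = [], [], None
    for _, row in sub.iterrows():
        meta = layout.condition_meta.get(row["condition"])
        if meta is None:
            continue
        if compound is not None and meta.get("compound") != compound:
            continue
        concs.append(float(meta["conc_uM"]))
        resps.append(float(row["engagement_pct"]))
        time = meta.get("time_min", time)
    order = np.argsort(concs)
    return DoseResponseSeries.from_arrays(
        compound or "compound", "engagement_pct",
        np.asarray(concs)[order], np.asarray(resps)[order],
        preincubation_time=time)


def config_digest(config: Mapping) -> str:
    """Stable SHA-256 of a canonicalized configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_sites": 200,
        "planted": {"JAK1_C817": 0.1, "TYK2_C838": 1.0},
        "concentrations": [0.01, 0.1, 1.0, 10.0],
        "compound": "compound",
        "preincubation_time": 60.0,
        "noise_cv": 0.10,
        "psm_lambda": 2.0,
        "k_inact": 0.08,
        "qc_violation_rates": {},
    },
    "quantify": {
        "agg": "median",
        "ratio_threshold": 4.0,
        "ratio_cap": 20.0,
    },
    "report": {
        "declared_targets": ["JAK1_C817"],
    },
    "dose": {"fit_planted": True},
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def run_pipeline(config: Mapping | None, out_dir) -> dict:
    """Execute the full synthetic pipeline and write an artifact bundle.

    Stages: generate truths and PSM table -> per-channel fractions -> QC
    filtering -> site aggregation -> engagement calls -> selectivity
    report per condition -> optional 4PL fits for the planted sites.
    Identical config and seed produce identical bundles.

    Writes into ``out_dir``: ``psms.tsv``, ``truth_ledger.tsv``,
    ``sites.tsv``, ``qc_report.json``, ``report.json``, ``fits.json``
    and ``provenance.json``. Returns the in-memory bundle.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sim = cfg["simulate"]

    truths = generate_truths(
        int(sim["n_sites"]),
        liganded=sim["planted"],
        k_inact=float(sim["k_inact"]),
        preincubation_time=float(sim["preincubation_time"]),
        psm_lambda=float(sim["psm_lambda"]),
        seed=seed,
    )
    design = duplicate_design(
        sim["concentrations"],
        compound=sim["compound"],
        preincubation_time=float(sim["preincubation_time"]),
        noise_cv=float(sim["noise_cv"]),
        seed=seed + 1,
        qc_violation_rates=sim["qc_violation_rates"],
    )
    psms, ledger = generate_psm_table(truths, design)
    layout = ChannelLayout.from_design(design)

    q = cfg["quantify"]
    sites, qc_report = quantify(
        psms, layout,
        agg=q["agg"],
        ratio_threshold=float(q["ratio_threshold"]),
        ratio_cap=float(q["ratio_cap"]),
    )

    provenance = {
        "package": "cysengage",
        "version": __version__,
        "config_sha256": config_digest(cfg),
        "seed": seed,
        "n_psms": int(len(psms)),
        "n_sites_quantified": int(sites["site_id"].nunique()) if len(sites) else 0,
    }
    declared = list(cfg["report"].get("declared_targets", []))
    reports = {
        condition: rank_sites(sites, condition, declared, provenance=provenance)
        for condition in sorted(sites["condition"].unique())
    } if len(sites) else {}

    fits: dict[str, FourPLFit] = {}
    if cfg["dose"].get("fit_planted"):
        for site_id in sim["planted"]:
            try:
                series = engagement_series(sites, layout, site_id,
                                           compound=sim["compound"])
                fits[site_id] = fit_4pl(series)
            except (InsufficientDataError, ValueError):
                continue

    psms.to_csv(out / "psms.tsv", sep="\t", index=False)
    ledger.to_csv(out / "truth_ledger.tsv", sep="\t", index=True)
    sites.to_csv(out / "sites.tsv", sep="\t", index=False)
    qc_report.to_json(out / "qc_report.json")
    with open(out / "report.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in reports.items()}, fh, indent=2)
    with open(out / "fits.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in fits.items()}, fh, indent=2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return {
        "config": cfg,
        "truths": truths,
        "design": design,
        "layout": layout,
        "psms": psms,
        "ledger": ledger,
        "sites": sites,
        "qc_report": qc_report,
        "reports": reports,
        "fits": fits,
        "provenance": provenance,
    }
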