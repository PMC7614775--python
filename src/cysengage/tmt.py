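"""PSM-level TMT competition quantification and per-cysteine engagement.

Implements the MS-ABPP competition arithmetic: each PSM's reporter-ion
intensities are divided by the mean of the DMSO (vehicle) channels, PSMs
failing quality filters are removed, the surviving per-channel fractions
are averaged over a condition's replicate channels and aggregated to
protein-cysteine sites, and sites are called engaged when their
competition ratio (DMSO / compound signal) meets a threshold. A ratio of
4 corresponds to a 75% loss of probe-labeled peptide signal versus DMSO.

Quality filters (defaults): summed DMSO reporter intensity >= 10,000;
DMSO coefficient of variation <= 0.5 (sample standard deviation, ddof=1);
fully tryptic, non-reverse sequences; peptide length >= 6. Boundary
values are retained (the exclusions are strict ``< 10,000`` and
``> 0.5``). Each excluded PSM is tallied once, under the first failing
rule in the fixed order reverse -> non-tryptic -> length -> DMSO sum ->
DMSO CV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import ExperimentDesign

__all__ = [
    "ChannelLayout",
    "QcThresholds",
    "QcReport",
    "compute_psm_fractions",
    "apply_qc_filters",
    "aggregate_sites",
    "call_engagement",
    "quantify",
]

#: Fixed attribution order for QC exclusions.
QC_RULE_ORDER = ("reverse", "nontryptic", "short_peptide", "low_dmso_sum", "high_dmso_cv")


@dataclass(frozen=True)
class ChannelLayout:
    """Maps reporter channels to vehicle and treatment conditions.

    ``treatment_channels`` maps a condition identifier to the replicate
    channels measured under that condition; ``condition_meta`` carries the
    compound, concentration (μM) and preincubation time for each
    condition.
    """

    dmso_channels: tuple[str, ...]
    treatment_channels: Mapping[str, tuple[str, ...]]
    condition_meta: Mapping[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.dmso_channels) < 2:
            raise ValueError("at least two DMSO channels are required")
        treat = [ch for chs in self.treatment_channels.values() for ch in chs]
        if len(set(treat)) != len(treat):
            raise ValueError("a channel may belong to only one treatment condition")
        if set(treat) & set(self.dmso_channels):
            raise ValueError("DMSO and treatment channels must be disjoint")

    @property
    def all_channels(self) -> tuple[str, ...]:
        return self.dmso_channels + tuple(
            ch for chs in self.treatment_channels.values() for ch in chs)

    @classmethod
    def from_design(cls, design: ExperimentDesign) -> "ChannelLayout":
        """Derive the layout from a synthetic experiment design."""
        dmso = design.dmso_channels
        treatment: dict[str, list[str]] = {}
        meta: dict[str, dict] = {}
        for ch in design.channels:
            cond = design.condition_map[ch]
            if cond.is_vehicle:
                continue
            cid = f"{cond.treatment}@{cond.concentration:g}uM"
            treatment.setdefault(cid, []).append(ch)
            meta[cid] = {
                "compound": cond.treatment,
                "conc_uM": cond.concentration,
                "time_min": design.preincubation_time,
            }
        return cls(
            dmso_channels=dmso,
            treatment_channels={k: tuple(v) for k, v in treatment.items()},
            condition_meta=meta,
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelLayout":
        return cls(
            dmso_channels=tuple(d["dmso_channels"]),
            treatment_channels={k: tuple(v) for k, v in d["treatment_channels"].items()},
            condition_meta=dict(d.get("condition_meta", {})),
        )

    def to_dict(self) -> dict:
        return {
            "dmso_channels": list(self.dmso_channels),
            "treatment_channels": {k: list(v) for k, v in self.treatment_channels.items()},
            "condition_meta": {k: dict(v) for k, v in self.condition_meta.items()},
        }


@dataclass(frozen=True)
class QcThresholds:
    """Retention thresholds for PSM quality filtering."""

    min_dmso_sum: float = 10_000.0
    max_dmso_cv: float = 0.5
    min_peptide_length: int = 6
    require_tryptic: bool = True
    exclude_reverse: bool = True


@dataclass
class QcReport:
    """Per-rule exclusion tallies; excluded + retained = input rows."""

    excluded: dict[str, int]
    retained: int

    @property
    def total_excluded(self) -> int:
        return sum(self.excluded.values())

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _intensity_columns(layout: ChannelLayout) -> dict[str, str]:
    return {ch: f"intensity_{ch}" for ch in layout.all_channels}


def compute_psm_fractions(psms: pd.DataFrame, layout: ChannelLayout) -> pd.DataFrame:
    """Per-channel fraction-of-DMSO for every PSM.

    Divides each reporter intensity by the mean of that PSM's DMSO-channel
    intensities, adding one ``frac_<channel>`` column per channel plus a
    ``quantifiable`` flag. PSMs whose DMSO mean is zero, negative or
    missing are flagged unquantifiable (their fractions are NaN) rather
    than raising.
    """
    cols = _intensity_columns(layout)
    missing = [c for c in cols.values() if c not in psms.columns]
    if missing:
        raise KeyError(f"PSM table lacks intensity columns: {missing}")
    out = psms.copy()
    dmso_mat = out[[cols[ch] for ch in layout.dmso_channels]].to_numpy(float)
    dmso_mean = np.nanmean(dmso_mat, axis=1)
    quantifiable = np.isfinite(dmso_mean) & (dmso_mean > 0)
    denom = np.where(quantifiable, dmso_mean, np.nan)
    for ch in layout.all_channels:
        out[f"frac_{ch}"] = out[cols[ch]].to_numpy(float) / denom
    out["quantifiable"] = quantifiable
    return out


def apply_qc_filters(
    psms: pd.DataFrame,
    layout: ChannelLayout,
    thresholds: QcThresholds | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Filter PSMs on sequence and DMSO-channel quality rules.

    Retains rows that are non-reverse, fully tryptic, at least
    ``min_peptide_length`` residues, with summed DMSO intensity
    ``>= min_dmso_sum`` and DMSO CV ``<= max_dmso_cv`` (sample standard
    deviation over DMSO channels divided by their mean). Idempotent:
    re-filtering the retained table removes nothing.
    """
    t = thresholds or QcThresholds()
    cols = [f"intensity_{ch}" for ch in layout.dmso_channels]
    dmso = psms[cols].to_numpy(float)
    dmso_sum = np.nansum(dmso, axis=1)
    dmso_mean = np.nanmean(dmso, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dmso_cv = np.nanstd(dmso, axis=1, ddof=1) / dmso_mean

    fails = {
        "reverse": psms["is_reverse"].to_numpy(bool) if t.exclude_reverse
        else np.zeros(len(psms), bool),
        "nontryptic": ~psms["is_tryptic"].to_numpy(bool) if t.require_tryptic
        else np.zeros(len(psms), bool),
        "short_peptide": psms["peptide"].str.len().to_numpy() < t.min_peptide_length,
        "low_dmso_sum": dmso_sum < t.min_dmso_sum,
        "high_dmso_cv": dmso_cv > t.max_dmso_cv,  # NaN CV never exceeds
    }
    attributed = np.full(len(psms), "", dtype=object)
    for rule in QC_RULE_ORDER:
        mask = fails[rule] & (attributed == "")
        attributed[mask] = rule
    keep = attributed == ""
    report = QcReport(
        excluded={rule: int((attributed == rule).sum()) for rule in QC_RULE_ORDER},
        retained=int(keep.sum()),
    )
    return psms.loc[keep].copy(), report


def _parse_residues(value) -> list[int]:
    if isinstance(value, (int, np.integer)):
        return [int(value)]
    return [int(tok) for tok in str(value).replace(",", ";").split(";") if tok.strip()]


def aggregate_sites(
    psms: pd.DataFrame,
    layout: ChannelLayout,
    agg: str = "median",
) -> pd.DataFrame:
    """Aggregate per-PSM fractions to protein-cysteine sites per condition.

    For each PSM and condition the per-channel fractions are first averaged
    over the condition's replicate channels; the site-level fraction is
    then the ``agg`` statistic (median by default, mean optionally) over
    the PSMs grouped by protein ID and residue number. Peptides carrying
    several labeled cysteines contribute a row to every residue, with an
    ``ambiguous`` flag set. Sites with no retained PSMs are simply absent.

    Output columns: ``site_id, protein, residue, condition, fraction,
    ratio, engagement_pct, n_psms, ambiguous``.
    """
    if agg not in ("median", "mean"):
        raise ValueError("agg must be 'median' or 'mean'")
    frac_cols = {ch: f"frac_{ch}" for ch in layout.all_channels}
    if any(c not in psms.columns for c in frac_cols.values()):
        psms = compute_psm_fractions(psms, layout)
    psms = psms[psms["quantifiable"]]

    frames = []
    if len(psms):
        residues = psms["modified_residues"].map(_parse_residues)
        base = pd.DataFrame({
            "protein": psms["protein"].to_numpy(),
            "residue": residues.to_numpy(),
            "ambiguous": (residues.str.len() > 1).to_numpy(),
        })
        for cid, channels in layout.treatment_channels.items():
            mat = psms[[frac_cols[ch] for ch in channels]].to_numpy(float)
            cond = base.copy()
            cond["condition"] = cid
            cond["psm_fraction"] = np.nanmean(mat, axis=1)
            frames.append(cond.explode("residue", ignore_index=True))
    if not frames:
        return pd.DataFrame(columns=[
            "site_id", "protein", "residue", "condition", "fraction",
            "ratio", "engagement_pct", "n_psms", "ambiguous"])
    long = pd.concat(frames, ignore_index=True)
    long["residue"] = long["residue"].astype(int)
    grouped = long.groupby(["protein", "residue", "condition"], sort=True).agg(
        fraction=("psm_fraction", agg),
        n_psms=("psm_fraction", "size"),
        ambiguous=("ambiguous", "any"),
    ).reset_index()
    with np.errstate(divide="ignore"):
        grouped["ratio"] = np.where(
            grouped["fraction"] > 0, 1.0 / grouped["fraction"], np.inf)
    grouped["engagement_pct"] = 100.0 * (1.0 - grouped["fraction"])
    grouped.insert(0, "site_id",
                   grouped["protein"] + "_C" + grouped["residue"].astype(str))
    return grouped[["site_id", "protein", "residue", "condition", "fraction",
                    "ratio", "engagement_pct", "n_psms", "ambiguous"]]


def call_engagement(
    sites: pd.DataFrame,
    ratio_threshold: float = 4.0,
    ratio_cap: float = 20.0,
) -> pd.DataFrame:
    """Cap competition ratios and flag significantly engaged sites.

    Ratios above ``ratio_cap`` (including infinite ratios from zero
    compound signal) are reported at the cap; ``fraction`` and
    ``engagement_pct`` are recomputed from the capped ratio so the
    identity ``engagement_pct = 100 * (1 - 1/ratio)`` holds on every
    output row. The cap is applied before thresholding, so ``engaged``
    is ``capped ratio >= ratio_threshold``.
    """
    if ratio_cap < ratio_threshold:
        raise ValueError("ratio_cap must be >= ratio_threshold")
    out = sites.copy()
    out["ratio"] = np.minimum(out["ratio"].to_numpy(float), ratio_cap)
    out["fraction"] = 1.0 / out["ratio"]
    out["engagement_pct"] = 100.0 * (1.0 - out["fraction"])
    out["engaged"] = out["ratio"] >= ratio_threshold
    return out


def quantify(
    psms: pd.DataFrame,
    layout: ChannelLayout,
    *,
    thresholds: QcThresholds | None = None,
    agg: str = "median",
    ratio_threshold: float = 4.0,
    ratio_cap: float = 20.0,
) -> tuple[pd.DataFrame, QcReport]:
    """Full PSM-to-site pipeline: fractions -> QC -> aggregation -> calls."""
    fractions = compute_psm_fractions(psms, layout)
    retained, report = apply_qc_filters(fractions, layout, thresholds)
    sites = aggregate_sites(retained, layout, agg=agg)
    called = call_engagement(sites, ratio_threshold, ratio_cap)
    return called, report
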