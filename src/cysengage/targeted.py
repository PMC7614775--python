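"""Targeted site quantification: PRM and targeted-TMT.

Parallel reaction monitoring (PRM) quantifies a cysteine-containing
peptide by summing the chromatographic peak areas of six pre-selected
fragment ions; engagement is the fractional loss of that summed signal in
a treated sample relative to the mean of the vehicle (DMSO) samples.

Targeted TMT re-uses the multiplexed competition arithmetic of
:mod:`cysengage.tmt` on per-channel signal-to-noise values, after a gate
requiring at least ten summed signal-to-noise across the control (DMSO)
channels; records below the gate are rejected, not imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tmt import ChannelLayout, aggregate_sites, call_engagement

__all__ = ["N_FRAGMENTS", "FRAGMENT_COLUMNS", "prm_site_quant", "targeted_tmt_quant"]

#: Number of fragment ions summed per peptide.
N_FRAGMENTS = 6
FRAGMENT_COLUMNS = tuple(f"frag{i + 1}" for i in range(N_FRAGMENTS))


def prm_site_quant(
    records: pd.DataFrame,
    *,
    vehicle_label: str = "DMSO",
) -> pd.DataFrame:
    """Per-sample engagement from six-fragment PRM peak areas.

    ``records`` needs columns ``site_id, sample, condition, conc_uM`` and
    ``frag1..frag6`` (non-negative peak areas). Per record the site signal
    is the sum of the six areas; per site, treated signals are divided by
    the mean vehicle signal:

        fraction = signal_treated / mean(signal_vehicle)
        engagement_pct = 100 * (1 - fraction)

    Sites without any vehicle sample are unquantifiable and omitted.
    Returns one row per treated record with ``fraction, ratio,
    engagement_pct`` alongside the sample annotations.
    """
    missing = [c for c in ("site_id", "condition", *FRAGMENT_COLUMNS)
               if c not in records.columns]
    if missing:
        raise KeyError(f"PRM table lacks columns: {missing}")
    areas = records[list(FRAGMENT_COLUMNS)].to_numpy(float)
    if np.any(areas < 0) or not np.all(np.isfinite(areas)):
        raise ValueError("fragment areas must be finite and >= 0")
    df = records.copy()
    df["signal"] = areas.sum(axis=1)

    out_frames = []
    for site_id, grp in df.groupby("site_id", sort=True):
        vehicle = grp[grp["condition"] == vehicle_label]
        if vehicle.empty:
            continue  # no vehicle baseline -> unquantifiable
        vmean = float(vehicle["signal"].mean())
        if vmean <= 0:
            continue
        treated = grp[grp["condition"] != vehicle_label].copy()
        treated["fraction"] = treated["signal"] / vmean
        with np.errstate(divide="ignore"):
            treated["ratio"] = np.where(
                treated["fraction"] > 0, 1.0 / treated["fraction"], np.inf)
        treated["engagement_pct"] = 100.0 * (1.0 - treated["fraction"])
        out_frames.append(treated)
    if not out_frames:
        return pd.DataFrame(columns=[*records.columns, "signal", "fraction",
                                     "ratio", "engagement_pct"])
    return pd.concat(out_frames, ignore_index=True)


def targeted_tmt_quant(
    records: pd.DataFrame,
    layout: ChannelLayout,
    sn_threshold: float = 10.0,
    *,
    ratio_threshold: float = 4.0,
    ratio_cap: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site quantification from targeted-TMT signal-to-noise values.

    ``records`` needs ``site_id, protein, modified_residues`` plus one
    ``sn_<channel>`` column per layout channel. Records whose summed
    control-channel (DMSO) S/N is below ``sn_threshold`` are rejected
    (the gate is inclusive: a sum of exactly ``sn_threshold`` is
    retained). Retained records flow through the standard fraction /
    ratio / call machinery with S/N standing in for reporter intensity.

    Returns ``(site_table, rejected_records)``.
    """
    sn_cols = {ch: f"sn_{ch}" for ch in layout.all_channels}
    missing = [c for c in sn_cols.values() if c not in records.columns]
    if missing:
        raise KeyError(f"targeted-TMT table lacks S/N columns: {missing}")
    sn = records[[sn_cols[ch] for ch in layout.all_channels]].to_numpy(float)
    if np.any(sn < 0):
        raise ValueError("signal-to-noise values must be >= 0")
    control_sum = records[[sn_cols[ch] for ch in layout.dmso_channels]] \
        .to_numpy(float).sum(axis=1)
    keep = control_sum >= sn_threshold
    rejected = records.loc[~keep].copy()

    retained = records.loc[keep].copy()
    # present S/N under the intensity schema expected by the tmt machinery
    retained = retained.rename(columns={
        sn_cols[ch]: f"intensity_{ch}" for ch in layout.all_channels})
    if "is_tryptic" not in retained.columns:
        retained["is_tryptic"] = True
    if "is_reverse" not in retained.columns:
        retained["is_reverse"] = False
    sites = aggregate_sites(retained, layout) if len(retained) else pd.DataFrame(
        columns=["site_id", "protein", "residue", "condition", "fraction",
                 "ratio", "engagement_pct", "n_psms", "ambiguous"])
    if len(sites):
        sites = call_engagement(sites, ratio_threshold, ratio_cap)
    return sites, rejected
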