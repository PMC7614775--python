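"""Functional-assay arithmetic: HTRF plates, densitometry, qPCR, trans-phos.

Four small, exact normalizations shared by the cell-based readouts:

* HTRF ratio — ``(signal 665 nm / signal 620 nm) x 10^4`` per well, then
  basal subtraction (mean of the unstimulated DMSO controls) and scaling
  to percent of the mean cytokine-stimulated DMSO control ratio;
* western densitometry — background-corrected band intensity as a percent
  of the mean background-corrected control lanes;
* relative qPCR expression — the 2^-ΔΔCt fold change versus a reference
  gene and a control sample;
* trans-phosphorylation efficiency — phospho-signal of a kinase-dead
  recipient normalized to the native-cysteine reference construct pair
  (DMSO efficiency) and to each pair's own DMSO baseline (compound
  effect).

Percent-of-control values are reported as-is (no clipping); a sample
below basal is legitimately negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateRejectedError",
    "htrf_ratio",
    "htrf_normalize_plate",
    "densitometry_normalize",
    "ddct_fold_change",
    "ddct_table",
    "transphos_efficiency",
]


class PlateRejectedError(ValueError):
    """Raised when a plate or membrane fails its assay-level sanity check."""


def htrf_ratio(signal_665, signal_620):
    """HTRF ratio ``(signal 665 / signal 620) x 10^4``; scalar or array."""
    s665 = np.asarray(signal_665, dtype=float)
    s620 = np.asarray(signal_620, dtype=float)
    if np.any(s620 <= 0):
        raise ValueError("signal_620 must be > 0 for every well")
    out = s665 / s620 * 1.0e4
    return float(out) if out.ndim == 0 else out


def htrf_normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Basal-subtracted percent-of-control for every stimulated well.

    ``wells`` needs columns ``condition`` (``unstim_dmso`` / ``stim_dmso``
    / ``stim_compound``), ``signal_665`` and ``signal_620``. The basal
    ratio (mean of the unstimulated DMSO wells) is subtracted uniformly
    and each stimulated well is expressed as a percentage of the
    basal-subtracted mean of the stimulated DMSO controls:

        pct = 100 * (ratio - basal) / (mean(stim_dmso ratios) - basal)

    Raises :class:`PlateRejectedError` when the stimulation window (mean
    stimulated control minus basal) is not positive — an assay failure.
    Returns the stimulated wells with ``ratio`` and ``pct_of_control``
    columns added.
    """
    required = {"condition", "signal_665", "signal_620"}
    if not required <= set(wells.columns):
        raise KeyError(f"plate table lacks columns: {sorted(required - set(wells.columns))}")
    df = wells.copy()
    df["ratio"] = htrf_ratio(df["signal_665"], df["signal_620"])
    unstim = df.loc[df["condition"] == "unstim_dmso", "ratio"]
    stim_ctrl = df.loc[df["condition"] == "stim_dmso", "ratio"]
    if unstim.empty or stim_ctrl.empty:
        raise ValueError("plate must contain unstim_dmso and stim_dmso wells")
    basal = float(unstim.mean())
    window = float(stim_ctrl.mean()) - basal
    if window <= 0:
        raise PlateRejectedError(
            f"stimulation window {window:.3g} <= 0; plate rejected")
    out = df[df["condition"].isin(["stim_dmso", "stim_compound"])].copy()
    out["pct_of_control"] = 100.0 * (out["ratio"] - basal) / window
    return out


def densitometry_normalize(
    records: pd.DataFrame,
    control_label: str,
    *,
    group_col: str = "group",
    by: str = "target",
) -> pd.DataFrame:
    """Background-corrected band intensity as percent of control lanes.

    ``records`` needs columns ``raw``, ``background``, ``group_col`` and
    the ``by`` column (typically the blotted target); normalization is
    performed within each ``by`` level against the mean corrected
    intensity of lanes whose group equals ``control_label``.

    Raises :class:`PlateRejectedError` when a control group's corrected
    mean is not positive.
    """
    df = records.copy()
    background = df["background"].to_numpy(float)
    corrected = df["raw"].to_numpy(float) - background
    if np.any(background < 0) or np.any(corrected < 0):
        raise ValueError("raw must be >= background >= 0 for every lane")
    df["corrected"] = corrected
    out_frames = []
    for target, grp in df.groupby(by, sort=False):
        ctrl = grp.loc[grp[group_col] == control_label, "corrected"]
        if ctrl.empty:
            raise ValueError(f"no control lanes (group={control_label!r}) for {target!r}")
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean <= 0:
            raise PlateRejectedError(
                f"control mean {ctrl_mean:.3g} <= 0 for {target!r}; experiment rejected")
        grp = grp.copy()
        grp["pct_of_control"] = 100.0 * grp["corrected"] / ctrl_mean
        out_frames.append(grp)
    return pd.concat(out_frames, ignore_index=True)


def ddct_fold_change(
    sample_ct: float,
    sample_ref_ct: float,
    control_ct: float,
    control_ref_ct: float,
) -> float:
    """2^-ΔΔCt fold change of a gene versus a control sample.

    ΔCt = Ct(gene) - Ct(reference gene) per sample; ΔΔCt is the sample's
    ΔCt minus the control's; the fold change is ``2 ** (-ΔΔCt)``. One
    extra cycle of relative ΔCt halves the reported expression.
    """
    cts = (sample_ct, sample_ref_ct, control_ct, control_ref_ct)
    if any(not np.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    if any(not 0.0 < c < 45.0 for c in cts):
        raise ValueError("Ct values must lie in (0, 45) cycles")
    ddct = (sample_ct - sample_ref_ct) - (control_ct - control_ref_ct)
    return float(2.0 ** (-ddct))


def ddct_table(
    records: pd.DataFrame,
    control_sample: str,
    *,
    sample_col: str = "sample",
    gene_col: str = "gene",
    ct_col: str = "ct",
    ref_ct_col: str = "ref_ct",
) -> pd.DataFrame:
    """Fold changes for every (sample, gene) against the control sample."""
    ctrl = records[records[sample_col] == control_sample]
    if ctrl.empty:
        raise ValueError(f"control sample {control_sample!r} not found")
    ctrl_dct = {
        row[gene_col]: float(row[ct_col]) - float(row[ref_ct_col])
        for _, row in ctrl.iterrows()
    }
    rows = []
    for _, row in records.iterrows():
        gene = row[gene_col]
        if gene not in ctrl_dct:
            continue
        dct = float(row[ct_col]) - float(row[ref_ct_col])
        rows.append({sample_col: row[sample_col], gene_col: gene,
                     "fold_change": float(2.0 ** (-(dct - ctrl_dct[gene])))})
    return pd.DataFrame(rows)


@dataclass
class TransPhosResult:
    """Normalized trans-phosphorylation efficiencies and compound effects."""

    dmso_efficiency: pd.DataFrame    # pair vs reference-pair DMSO signal, %
    compound_effect: pd.DataFrame    # compound vs same-pair DMSO signal, %
    skipped_pairs: list[tuple[str, str]]


def transphos_efficiency(
    records: pd.DataFrame,
    *,
    reference_pair: tuple[str, str] = ("WT", "K908E"),
    dmso_label: str = "DMSO",
) -> TransPhosResult:
    """Normalize trans-phosphorylation signals across construct pairs.

    ``records`` needs columns ``donor`` (catalytically active construct:
    WT or C817A), ``recipient`` (kinase-dead construct: K908E or
    K908E/C817A), ``treatment`` (DMSO or a compound id) and ``intensity``
    (phospho-signal of the recipient immunoprecipitate, >= 0). Replicate
    rows for a (pair, treatment) cell are averaged first.

    * DMSO efficiency of a pair = 100 x its DMSO signal / the DMSO signal
      of the reference pair (both constructs carrying the native
      cysteine).
    * Compound effect of a pair = 100 x its compound-treated signal /
      its own DMSO signal.

    Pairs lacking a DMSO baseline are skipped and reported in
    ``skipped_pairs``.
    """
    required = {"donor", "recipient", "treatment", "intensity"}
    if not required <= set(records.columns):
        raise KeyError(f"missing columns: {sorted(required - set(records.columns))}")
    if np.any(records["intensity"].to_numpy(float) < 0):
        raise ValueError("intensities must be >= 0")
    mean = records.groupby(["donor", "recipient", "treatment"], sort=False)[
        "intensity"].mean()

    ref_key = (*reference_pair, dmso_label)
    if ref_key not in mean.index:
        raise ValueError(
            f"reference pair {reference_pair} lacks a {dmso_label} record")
    ref_signal = float(mean.loc[ref_key])
    if ref_signal <= 0:
        raise ValueError("reference-pair DMSO signal must be > 0")

    pairs = sorted({(d, r) for d, r, _ in mean.index})
    eff_rows, effect_rows, skipped = [], [], []
    for donor, recipient in pairs:
        if (donor, recipient, dmso_label) not in mean.index:
            skipped.append((donor, recipient))
            continue
        dmso_signal = float(mean.loc[(donor, recipient, dmso_label)])
        eff_rows.append({
            "donor": donor, "recipient": recipient,
            "dmso_efficiency_pct": 100.0 * dmso_signal / ref_signal,
        })
        treatments = {t for d, r, t in mean.index
                      if (d, r) == (donor, recipient) and t != dmso_label}
        for treatment in sorted(treatments):
            if dmso_signal <= 0:
                skipped.append((donor, recipient))
                continue
            effect_rows.append({
                "donor": donor, "recipient": recipient, "treatment": treatment,
                "compound_effect_pct":
                    100.0 * float(mean.loc[(donor, recipient, treatment)]) / dmso_signal,
            })
    return TransPhosResult(
        dmso_efficiency=pd.DataFrame(eff_rows),
        compound_effect=pd.DataFrame(effect_rows),
        skipped_pairs=skipped,
    )
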