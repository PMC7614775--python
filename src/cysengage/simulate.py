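"""Synthetic TMT-ABPP and HTRF data with planted covalent engagement.

The generator emulates the two input surfaces of the pipeline:

* multiplexed cysteine-competition experiments — PSM tables with duplicate
  DMSO and duplicate compound reporter channels, log-normal reporter noise,
  a variable number of PSMs per cysteine site, and optional QC-violating
  records injected at configurable rates, together with a ground-truth
  ledger of which sites are liganded and which records violate QC;

* HTRF phospho-STAT plates — raw two-wavelength (665/620 nm) well signals
  laid out with unstimulated and stimulated DMSO controls plus a serial
  dilution of compound, following a planted four-parameter-logistic
  inhibition curve.

Site occupancy follows the standard two-step irreversible covalent model

    occupancy(C, t) = occ_max * (1 - exp(-k_inact * t * C / (K_I + C)))

so that time-dependent shifts in the 50%-engagement concentration (TE50)
emerge mechanistically and have a closed form usable as an oracle
(:func:`cysengage.dose.te50_kinetic`).

All randomness flows from a single integer seed through one
``numpy.random.Generator``. Stream order: sites are processed in list
order; per site the peptide sequence is drawn first, then per PSM the
violation label, then the per-channel noise factors in channel order.
Identical seeds therefore give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TMT10_CHANNELS",
    "SiteTruth",
    "ChannelCondition",
    "ExperimentDesign",
    "PlateDesign",
    "occupancy",
    "ki_for_te50",
    "duplicate_design",
    "generate_truths",
    "generate_psm_table",
    "generate_htrf_plate",
]

#: Reporter-channel labels of a TMT 10-plex, in mass order.
TMT10_CHANNELS = ("126", "127N", "127C", "128N", "128C",
                  "129N", "129C", "130N", "130C", "131")

#: Residues used to build synthetic tryptic peptides (no C/K/R in the body).
_BODY_RESIDUES = "ADEFGHILMNPQSTVWY"

#: QC-violation labels understood by the generator, in draw order.
QC_VIOLATIONS = ("low_intensity", "high_cv", "reverse", "nontryptic")


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one protein cysteine.

    Parameters
    ----------
    site_id:
        Identifier, conventionally ``"<PROTEIN>_C<residue>"``.
    protein, residue:
        Protein accession and cysteine residue number.
    liganded:
        Whether the site is engaged by the compound at all. Unliganded
        sites have zero occupancy at every concentration.
    k_inact:
        Maximal inactivation rate of the covalent step, per minute.
    K_I:
        Reversible binding constant of the recognition step, in μM.
    occ_max:
        Maximal attainable occupancy, fraction in [0, 1].
    n_psms:
        Number of peptide-spectrum matches generated for the site.
    base_intensity:
        Expected DMSO-channel reporter intensity (arbitrary units).
    """

    site_id: str
    protein: str
    residue: int
    liganded: bool = False
    k_inact: float = 0.08
    K_I: float = 10.0
    occ_max: float = 1.0
    n_psms: int = 1
    base_intensity: float = 5.0e5

    def __post_init__(self) -> None:
        if self.residue <= 0:
            raise ValueError("residue must be a positive integer")
        if not 0.0 <= self.occ_max <= 1.0:
            raise ValueError("occ_max must lie in [0, 1]")
        if self.k_inact < 0.0:
            raise ValueError("k_inact must be >= 0")
        if self.K_I <= 0.0:
            raise ValueError("K_I must be > 0")
        if self.n_psms < 1:
            raise ValueError("n_psms must be >= 1")
        if self.base_intensity <= 0.0:
            raise ValueError("base_intensity must be > 0")


def occupancy(truth: SiteTruth, conc: float, time: float) -> float:
    """Fractional covalent occupancy of a site after preincubation.

    Implements ``occ_max * (1 - exp(-k_inact * time * conc / (K_I + conc)))``
    for liganded sites; unliganded sites return 0 everywhere.

    Parameters
    ----------
    conc:
        Compound concentration in μM, ``>= 0``.
    time:
        Preincubation time in minutes, ``>= 0``.
    """
    if conc < 0.0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if time < 0.0:
        raise ValueError(f"time must be >= 0, got {time}")
    if not truth.liganded or conc == 0.0 or time == 0.0:
        return 0.0
    rate = truth.k_inact * time * conc / (truth.K_I + conc)
    return truth.occ_max * (-math.expm1(-rate))


def ki_for_te50(te50: float, k_inact: float, time: float) -> float:
    """K_I (μM) that plants a given TE50 under the covalent model.

    Inverts the closed form ``TE50 = K_I * ln2 / (k_inact * time - ln2)``
    (valid for ``occ_max = 1`` and ``k_inact * time > ln 2``), so a
    generator truth can be parameterized directly by the concentration at
    which occupancy reaches 50% after ``time`` minutes.
    """
    if te50 <= 0.0:
        raise ValueError("te50 must be > 0")
    kt = k_inact * time
    if kt <= math.log(2.0):
        raise ValueError("k_inact * time must exceed ln 2 for a finite TE50")
    return te50 * (kt - math.log(2.0)) / math.log(2.0)


@dataclass(frozen=True)
class ChannelCondition:
    """Treatment assigned to one reporter channel."""

    treatment: str          # "DMSO" or a compound identifier
    concentration: float    # μM; 0 for DMSO
    replicate: int

    @property
    def is_vehicle(self) -> bool:
        return self.treatment == "DMSO"


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout and noise model of one multiplexed competition experiment."""

    channels: tuple[str, ...]
    condition_map: Mapping[str, ChannelCondition]
    preincubation_time: float = 60.0
    noise_cv: float = 0.10
    seed: int = 0
    qc_violation_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.condition_map) != set(self.channels):
            raise ValueError("condition_map must assign every channel exactly once")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if len(self.dmso_channels) < 2:
            raise ValueError("at least two DMSO channels are required")
        if self.noise_cv < 0.0:
            raise ValueError("noise_cv must be >= 0")
        bad = set(self.qc_violation_rates) - set(QC_VIOLATIONS)
        if bad:
            raise ValueError(f"unknown QC violation types: {sorted(bad)}")
        if sum(self.qc_violation_rates.values()) > 1.0:
            raise ValueError("QC violation rates must sum to <= 1")

    @property
    def dmso_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if self.condition_map[c].is_vehicle)

    @property
    def concentrations(self) -> tuple[float, ...]:
        """Distinct non-vehicle concentrations in ascending order."""
        return tuple(sorted({
            cond.concentration for cond in self.condition_map.values()
            if not cond.is_vehicle
        }))


def duplicate_design(
    concentrations: Sequence[float],
    *,
    compound: str = "compound",
    preincubation_time: float = 60.0,
    noise_cv: float = 0.10,
    seed: int = 0,
    qc_violation_rates: Mapping[str, float] | None = None,
) -> ExperimentDesign:
    """Duplicate-DMSO / duplicate-compound design over the given doses.

    Four concentrations fill a TMT 10-plex (2 DMSO + 2x4 compound channels,
    labeled 126..131); other dose counts use generic channel labels, since
    the competition arithmetic is independent of the multiplexing width.
    """
    concs = [float(c) for c in concentrations]
    if any(c <= 0 for c in concs):
        raise ValueError("compound concentrations must be > 0")
    n_channels = 2 + 2 * len(concs)
    if n_channels == len(TMT10_CHANNELS):
        labels = TMT10_CHANNELS
    else:
        labels = tuple(f"ch{i + 1:02d}" for i in range(n_channels))
    cmap: dict[str, ChannelCondition] = {
        labels[0]: ChannelCondition("DMSO", 0.0, 1),
        labels[1]: ChannelCondition("DMSO", 0.0, 2),
    }
    for i, conc in enumerate(concs):
        cmap[labels[2 + 2 * i]] = ChannelCondition(compound, conc, 1)
        cmap[labels[3 + 2 * i]] = ChannelCondition(compound, conc, 2)
    return ExperimentDesign(
        channels=labels,
        condition_map=cmap,
        preincubation_time=preincubation_time,
        noise_cv=noise_cv,
        seed=seed,
        qc_violation_rates=dict(qc_violation_rates or {}),
    )


def generate_truths(
    n_sites: int,
    *,
    liganded: Mapping[str, float] | None = None,
    k_inact: float = 0.08,
    preincubation_time: float = 60.0,
    psm_lambda: float = 2.0,
    base_intensity: float = 5.0e5,
    seed: int = 0,
) -> list[SiteTruth]:
    """Build a synthetic site panel: mostly decoys plus planted targets.

    Parameters
    ----------
    n_sites:
        Total sites. The first ``len(liganded)`` are the planted targets,
        the remainder unliganded decoys.
    liganded:
        Mapping ``site_id -> TE50 (μM)`` for planted sites; K_I is derived
        from the TE50 via the closed-form inverse at ``k_inact`` and
        ``preincubation_time``.
    psm_lambda:
        PSMs per site are drawn as ``1 + Poisson(psm_lambda)``.
    """
    rng = np.random.default_rng(seed)
    liganded = dict(liganded or {})
    if len(liganded) > n_sites:
        raise ValueError("more planted sites than n_sites")
    truths: list[SiteTruth] = []
    for site_id, te50 in liganded.items():
        protein, _, tail = site_id.rpartition("_C")
        residue = int(tail) if protein and tail.isdigit() else 100
        protein = protein or site_id
        truths.append(SiteTruth(
            site_id=site_id, protein=protein, residue=residue, liganded=True,
            k_inact=k_inact,
            K_I=ki_for_te50(te50, k_inact, preincubation_time),
            n_psms=1 + int(rng.poisson(psm_lambda)),
            base_intensity=base_intensity,
        ))
    for i in range(n_sites - len(liganded)):
        residue = int(rng.integers(10, 900))
        truths.append(SiteTruth(
            site_id=f"DECOY{i + 1:04d}_C{residue}",
            protein=f"DECOY{i + 1:04d}", residue=residue, liganded=False,
            k_inact=k_inact,
            n_psms=1 + int(rng.poisson(psm_lambda)),
            base_intensity=base_intensity,
        ))
    return truths


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0.0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _draw_peptide(rng: np.random.Generator, residue: int) -> tuple[str, int]:
    """Random fully tryptic peptide with one internal cysteine.

    Returns the sequence and the position (1-based, within the protein) of
    the cysteine; the peptide is drawn 8-16 residues long ending in K or R.
    """
    length = int(rng.integers(8, 17))
    body = rng.choice(list(_BODY_RESIDUES), size=length - 1)
    cys_pos = int(rng.integers(1, length - 1))  # never first or last
    body[cys_pos] = "C"
    terminus = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + terminus, cys_pos


def generate_psm_table(
    truths: Sequence[SiteTruth],
    design: ExperimentDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a PSM-level reporter-intensity table plus its truth ledger.

    Each site contributes ``n_psms`` rows. DMSO channels carry
    ``base_intensity`` times unit-mean log-normal noise; a compound channel
    at concentration C carries ``base_intensity * (1 - occupancy(C, t))``
    times noise, with t the design's preincubation time. QC-violating rows
    are injected at ``design.qc_violation_rates`` (mutually exclusive per
    row) and labeled in the ledger:

    * ``low_intensity`` — DMSO channels rescaled so their sum is 5,000
      (below the 10,000 retention threshold);
    * ``high_cv`` — DMSO channels set to a 2x / 0.05x alternating pattern
      (CV ~ 1.3, above the 0.5 retention threshold);
    * ``reverse`` — sequence reversed and flagged ``is_reverse``;
    * ``nontryptic`` — C-terminal K/R replaced, flagged not ``is_tryptic``.

    Returns
    -------
    (psms, ledger):
        ``psms`` has one row per PSM with columns ``protein, peptide,
        modified_residues, charge, is_tryptic, is_reverse`` and one
        ``intensity_<channel>`` column per reporter channel. ``ledger``
        maps each row to its site and violation label ("clean" or one of
        the labels above).
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    rng = np.random.default_rng(design.seed)
    channels = design.channels
    dmso = set(design.dmso_channels)
    n_dmso = len(dmso)
    rates = [design.qc_violation_rates.get(v, 0.0) for v in QC_VIOLATIONS]
    cum = np.cumsum(rates)

    rows: list[dict] = []
    ledger_rows: list[dict] = []
    for truth in truths:
        peptide, cys_pos = _draw_peptide(rng, truth.residue)
        occ_by_channel = {
            ch: occupancy(truth, design.condition_map[ch].concentration,
                          design.preincubation_time)
            if not design.condition_map[ch].is_vehicle else 0.0
            for ch in channels
        }
        for _ in range(truth.n_psms):
            u = rng.random()
            violation = "clean"
            for label, edge in zip(QC_VIOLATIONS, cum):
                if u < edge:
                    violation = label
                    break
            noise = _lognormal_factors(rng, design.noise_cv, len(channels))
            intensities = {
                ch: truth.base_intensity * (1.0 - occ_by_channel[ch]) * noise[i]
                for i, ch in enumerate(channels)
            }
            pep = peptide
            is_tryptic, is_reverse = True, False
            if violation == "low_intensity":
                scale = 5_000.0 / (truth.base_intensity * n_dmso)
                for ch in dmso:
                    intensities[ch] *= scale
            elif violation == "high_cv":
                for i, ch in enumerate(sorted(dmso)):
                    intensities[ch] = truth.base_intensity * (2.0 if i % 2 == 0 else 0.05) \
                        * noise[channels.index(ch)]
            elif violation == "reverse":
                pep = peptide[::-1]
                is_reverse = True
            elif violation == "nontryptic":
                pep = peptide[:-1] + "G"
                is_tryptic = False
            rows.append({
                "protein": truth.protein,
                "peptide": pep,
                "modified_residues": str(truth.residue),
                "charge": int(rng.integers(2, 4)),
                "is_tryptic": is_tryptic,
                "is_reverse": is_reverse,
                **{f"intensity_{ch}": intensities[ch] for ch in channels},
            })
            ledger_rows.append({
                "site_id": truth.site_id,
                "protein": truth.protein,
                "residue": truth.residue,
                "liganded": truth.liganded,
                "violation": violation,
            })
    psms = pd.DataFrame(rows)
    ledger = pd.DataFrame(ledger_rows)
    ledger.index.name = "row"
    return psms, ledger


@dataclass(frozen=True)
class PlateDesign:
    """Layout and noise model of one HTRF phospho-STAT assay plate.

    Defaults mirror the bench protocol: a seven-point serial dilution in
    duplicate, two unstimulated and five stimulated DMSO control wells.
    ``basal_ratio`` and ``window`` are in HTRF-ratio units
    ((665 nm / 620 nm) x 10^4); the stimulated control level is
    ``basal_ratio + window``.
    """

    n_doses: int = 7
    dilution: float = 10.0 ** 0.5
    top_dose: float = 10.0
    replicates_per_dose: int = 2
    basal_ratio: float = 2_000.0
    window: float = 8_000.0
    n_unstim_controls: int = 2
    n_stim_controls: int = 5
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_doses < 1 or self.replicates_per_dose < 1:
            raise ValueError("n_doses and replicates_per_dose must be >= 1")
        if self.dilution <= 1.0 or self.top_dose <= 0.0:
            raise ValueError("dilution must be > 1 and top_dose > 0")
        if self.n_unstim_controls < 2:
            raise ValueError("at least two unstimulated control wells required")
        if self.n_stim_controls < 5:
            raise ValueError("at least five stimulated control wells required")
        if self.window <= 0.0 or self.basal_ratio < 0.0:
            raise ValueError("window must be > 0 and basal_ratio >= 0")
        if self.noise_cv < 0.0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def doses(self) -> tuple[float, ...]:
        """Dose series, top down."""
        return tuple(self.top_dose / self.dilution ** i for i in range(self.n_doses))


#: Reference-channel (620 nm) count emitted for every synthetic well.
_REF_SIGNAL = 10_000.0


def generate_htrf_plate(
    design: PlateDesign,
    ic50: float,
    hill: float = 1.0,
    *,
    compound: str = "compound",
) -> pd.DataFrame:
    """Generate raw two-wavelength HTRF well signals for one plate.

    Compound wells follow a planted four-parameter logistic: the intended
    HTRF ratio at dose C is ``basal_ratio + window / (1 + (C/ic50)^hill)``
    (full signal at C -> 0, full inhibition to basal at C -> inf).
    Multiplicative log-normal noise is applied to the stimulation window
    via the 665 nm channel; the 620 nm reference channel is constant, so
    the ratio formula reconstructs the intended value exactly at zero
    noise.

    Returns a table with columns
    ``well, row, col, condition, conc_uM, signal_665, signal_620``.
    """
    if ic50 <= 0.0:
        raise ValueError("ic50 must be > 0")
    rng = np.random.default_rng(design.seed)

    wells: list[tuple[str, float, float]] = []  # (condition, conc, target ratio)
    for _ in range(design.n_unstim_controls):
        wells.append(("unstim_dmso", 0.0, design.basal_ratio))
    for _ in range(design.n_stim_controls):
        wells.append(("stim_dmso", 0.0, design.basal_ratio + design.window))
    for conc in design.doses:
        resp = 1.0 / (1.0 + (conc / ic50) ** hill)
        target = design.basal_ratio + design.window * resp
        for _ in range(design.replicates_per_dose):
            wells.append(("stim_compound", conc, target))

    noise = _lognormal_factors(rng, design.noise_cv, len(wells))
    records = []
    n_cols = 12
    for i, ((condition, conc, target), nf) in enumerate(zip(wells, noise)):
        # noise acts on the cytokine-driven window, not the basal floor
        ratio = design.basal_ratio + (target - design.basal_ratio) * nf
        row, col = divmod(i, n_cols)
        records.append({
            "well": f"{chr(ord('A') + row)}{col + 1}",
            "row": chr(ord("A") + row),
            "col": col + 1,
            "condition": condition,
            "compound": compound if condition == "stim_compound" else "DMSO",
            "conc_uM": conc,
            "signal_665": ratio * _REF_SIGNAL / 1.0e4,
            "signal_620": _REF_SIGNAL,
        })
    return pd.DataFrame(records)
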