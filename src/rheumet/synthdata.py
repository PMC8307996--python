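"""Synthetic serum-like CPMG spectra and longitudinal cohort designs.

The generator emulates a three-disease anti-TNF treatment-monitoring study:
78 subjects (RA n=26, AS n=29, PsA n=23) sampled before treatment (BT) and
3/6 months after (3M, 6M), with per-subject dropout at follow-up.  Each
sample is a sum of Lorentzian multiplets at literature-style chemical shifts
(referenced to a TSP singlet at 0.000 ppm on a 600 MHz field), plus a smooth
baseline, Gaussian noise and per-sample/per-metabolite chemical-shift
jitter.  Planted disease- and time-effects are recorded in a
:class:`GroundTruth` object so downstream recovery is testable.

Concentration model (per subject *s*, metabolite *m*, disease *d*,
timepoint *t*)::

    c[s, m, t] = B[s, m] * E[m, d, t] * eps,     eps ~ LogNormal(0, sigma_w)

where ``B`` is a per-subject baseline level (LogNormal around the panel's
relative amplitude) and ``E`` the planted effect multiplier (1 for null
metabolites).  Lognormal variation keeps concentrations strictly positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable, SpectraSet, Spectrum1D, window_mask

SPECTROMETER_MHZ = 600.0
DISEASES = ("RA", "AS", "PsA")
TIMEPOINTS = ("BT", "3M", "6M")

#: number of lines per multiplicity code (binomial intensity ratios)
_PATTERN_LINES = {"singlet": 1, "doublet": 2, "triplet": 3,
                  "quartet": 4, "multiplet": 5}

__all__ = [
    "SPECTROMETER_MHZ", "DISEASES", "TIMEPOINTS",
    "MultipletSpec", "SyntheticConfig", "GroundTruth",
    "build_default_panel", "simulate_spectrum", "simulate_cohort",
    "simulate_feature_cohort", "simulate_clinical_scores",
    "effect_multiplier", "load_config", "save_config",
]


@dataclass(frozen=True)
class MultipletSpec:
    """One resonance: a Lorentzian multiplet with binomial line intensities."""

    name: str
    center_ppm: float
    pattern: str = "singlet"
    j_hz: float = 7.0
    linewidth_hz: float = 2.0
    relative_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERN_LINES:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.j_hz < 0:
            raise ValueError("j_hz must be >= 0")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be > 0")
        if self.relative_amplitude < 0:
            raise ValueError("relative_amplitude must be >= 0")


def build_default_panel() -> list[MultipletSpec]:
    """Default serum panel: ~30 resonances plus the TSP reference singlet.

    Unknown signals sit at their reported ppm positions; named metabolites
    use literature-style shifts, a few nudged slightly so that default
    integration regions remain disjoint in the crowded aliphatic region.
    Relative amplitudes are of the order of typical serum relative
    integrals.
    """
    P = MultipletSpec
    return [
        P("TSP", 0.000, "singlet", 0.0, 2.0, 1.0),
        P("isoleucine", 0.900, "triplet", 7.3, 2.0, 0.25),
        P("Unk_3", 0.967, "singlet", 0.0, 2.0, 0.12),
        P("valine", 1.025, "doublet", 7.0, 2.0, 0.90),
        P("Unk_4", 1.074, "singlet", 0.0, 2.0, 0.15),
        P("propylene_glycol", 1.135, "doublet", 6.3, 2.0, 0.15),
        P("ethanol", 1.190, "triplet", 7.1, 2.0, 0.28),
        P("isobutyrate", 1.258, "doublet", 6.8, 2.0, 0.12),
        P("lactate", 1.330, "doublet", 6.9, 2.0, 1.50),
        P("Unk_7", 1.444, "doublet", 6.7, 2.0, 0.25),
        P("alanine", 1.520, "doublet", 7.2, 2.0, 2.50),
        P("leucine", 1.705, "multiplet", 6.8, 2.0, 0.80),
        P("acetate", 1.920, "singlet", 0.0, 2.0, 0.60),
        P("Unk_8", 2.050, "multiplet", 7.0, 2.0, 1.30),
        P("glutamine", 2.130, "multiplet", 7.5, 2.0, 0.70),
        P("acetone", 2.230, "singlet", 0.0, 2.0, 0.12),
        P("glutamate", 2.350, "multiplet", 7.5, 2.0, 0.90),
        P("citrate", 2.540, "doublet", 15.0, 2.0, 0.40),
        P("2-oxoisocaproate", 2.610, "singlet", 0.0, 2.0, 0.15),
        P("3-methyl-2-oxovalerate", 2.930, "multiplet", 7.0, 2.0, 0.12),
        P("creatine", 3.030, "singlet", 0.0, 2.0, 0.75),
        P("lysine", 3.130, "triplet", 6.8, 2.0, 1.00),
        P("Unk_14", 3.246, "singlet", 0.0, 2.0, 0.30),
        P("sn_g3pc", 3.350, "singlet", 0.0, 2.0, 1.40),
        P("proline", 4.120, "multiplet", 7.2, 2.0, 0.20),
        P("tyrosine", 6.890, "doublet", 8.5, 2.0, 0.12),
        P("histidine", 7.080, "singlet", 0.0, 2.0, 0.20),
        P("Unk_16", 7.334, "triplet", 7.5, 2.0, 0.85),
        P("phenylalanine", 7.420, "multiplet", 7.5, 2.0, 0.15),
        P("tryptophan", 7.540, "doublet", 8.0, 2.0, 0.15),
        P("formate", 8.460, "singlet", 0.0, 2.0, 0.12),
    ]


@dataclass
class SyntheticConfig:
    """Full description of a synthetic study; identical configs (incl. seed)
    yield identical cohorts."""

    cohort_sizes: dict = field(
        default_factory=lambda: {"RA": 26, "AS": 29, "PsA": 23})
    timepoints: tuple = TIMEPOINTS
    n_points: int = 8192
    spectral_width_ppm: float = 20.0
    ppm_max: float = 14.8
    panel: list[MultipletSpec] | None = None
    #: nested mapping metabolite -> disease -> timepoint -> multiplier
    effect_matrix: dict = field(default_factory=dict)
    jitter_sd_ppm: float = 0.003
    noise_sd: float = 0.3
    baseline_amplitude: float = 0.05
    #: scalar or nested {disease: {timepoint: prob}}; BT is never dropped
    dropout_prob: float | dict = 0.15
    sigma_log_subject: float = 0.2
    sigma_log_within: float = 0.2
    tsp_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.cohort_sizes.values()):
            raise ValueError("cohort sizes must be > 0")
        if self.n_points < 512:
            raise ValueError("n_points must be >= 512")
        for d in self.cohort_sizes:
            for t in self.timepoints:
                p = self.dropout(d, t)
                if not 0 <= p < 1:
                    raise ValueError("dropout_prob must be in [0, 1)")
        if self.panel is None:
            self.panel = build_default_panel()

    def dropout(self, disease: str, timepoint: str) -> float:
        if timepoint == self.timepoints[0]:
            return 0.0  # baseline is never dropped
        if isinstance(self.dropout_prob, Mapping):
            return float(self.dropout_prob.get(disease, {}).get(timepoint, 0.0))
        return float(self.dropout_prob)

    def ppm_axis(self) -> np.ndarray:
        return _ppm_axis(self.n_points, self.spectral_width_ppm, self.ppm_max)


def full_resolution_config(**overrides) -> SyntheticConfig:
    """Config in full-resolution mode: exactly 60,474 points per spectrum."""
    overrides.setdefault("n_points", 60474)
    return SyntheticConfig(**overrides)


@dataclass
class GroundTruth:
    """Planted truth: effect multipliers per (metabolite, disease, timepoint),
    per-sample jitter offsets, per-sample true concentrations, and the list
    of null metabolites (multiplier 1 everywhere)."""

    multipliers: pd.DataFrame        # index (metabolite), cols (disease, tp)
    shift_offsets: pd.DataFrame      # sample x metabolite ppm offsets
    concentrations: pd.DataFrame     # sample x metabolite true multipliers
    null_metabolites: list[str]

    def to_json(self, path) -> None:
        obj = {
            "multipliers": {
                f"{m}|{d}|{t}": float(self.multipliers.loc[m, (d, t)])
                for m in self.multipliers.index
                for d, t in self.multipliers.columns},
            "shift_offsets": self.shift_offsets.to_dict(),
            "concentrations": self.concentrations.to_dict(),
            "null_metabolites": self.null_metabolites,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def effect_multiplier(effect_matrix: Mapping, metabolite: str,
                      disease: str, timepoint: str) -> float:
    """Look up a planted multiplier, defaulting to 1 (null)."""
    return float(effect_matrix.get(metabolite, {})
                 .get(disease, {}).get(timepoint, 1.0))


# --------------------------------------------------------------------------
# spectrum synthesis
# --------------------------------------------------------------------------

def _ppm_axis(n_points: int, width: float = 20.0,
              ppm_max: float = 14.8) -> np.ndarray:
    # descending axis (display convention)
    return np.linspace(ppm_max, ppm_max - width, n_points)


def _multiplet_profile(ppm: np.ndarray, spec: MultipletSpec,
                       center: float) -> np.ndarray:
    """Area-normalized Lorentzian multiplet evaluated on ``ppm``.

    Line positions are spaced by J (converted Hz -> ppm at the configured
    field); line intensities follow the binomial ratios of the multiplicity.
    Total analytic area is 1, so integrals are linear in concentration.
    """
    n = _PATTERN_LINES[spec.pattern]
    weights = np.array([float(comb(n - 1, k)) for k in range(n)])
    weights /= weights.sum()
    j_ppm = spec.j_hz / SPECTROMETER_MHZ
    offsets = (np.arange(n) - (n - 1) / 2.0) * j_ppm
    hw = spec.linewidth_hz / SPECTROMETER_MHZ / 2.0  # half width at half max
    out = np.zeros_like(ppm)
    for w, off in zip(weights, offsets):
        out += w * (hw / np.pi) / ((ppm - center - off) ** 2 + hw ** 2)
    return out


def _smooth_baseline(ppm: np.ndarray, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.zeros_like(ppm)
    span = ppm.max() - ppm.min()
    x = (ppm - ppm.min()) / span
    out = np.zeros_like(ppm)
    for k in range(1, 4):
        a = rng.normal(0.0, 1.0) / k
        phi = rng.uniform(0, 2 * np.pi)
        out += a * np.sin(2 * np.pi * k * x + phi)
    return amplitude * out


def simulate_spectrum(panel: list[MultipletSpec],
                      concentrations: Mapping[str, float] | None = None,
                      jitter_sd_ppm: float = 0.0,
                      noise_sd: float = 0.0,
                      baseline_amplitude: float = 0.0,
                      n_points: int = 8192,
                      seed: int = 0,
                      tsp_amplitude: float = 1.0,
                      spectral_width_ppm: float = 20.0,
                      ppm_max: float = 14.8,
                      sample_id: str = "sim",
                      _return_offsets: bool = False):
    """Simulate one CPMG-like spectrum from the panel.

    ``concentrations`` maps panel names to multipliers (missing names
    default to 1).  The TSP reference peak is jitter- and effect-free with
    fixed amplitude ``tsp_amplitude``.  Deterministic given ``seed``.
    """
    concentrations = dict(concentrations or {})
    names = {m.name for m in panel}
    unknown = set(concentrations) - names
    if unknown:
        raise KeyError(
            f"concentrations name metabolites not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    ppm = _ppm_axis(n_points, spectral_width_ppm, ppm_max)
    intensity = np.zeros_like(ppm)
    offsets: dict[str, float] = {}
    for spec in panel:
        if spec.name == "TSP":
            offsets[spec.name] = 0.0
            intensity += tsp_amplitude * _multiplet_profile(ppm, spec, 0.0)
            continue
        off = rng.normal(0.0, jitter_sd_ppm) if jitter_sd_ppm > 0 else 0.0
        offsets[spec.name] = off
        c = concentrations.get(spec.name, 1.0)
        amp = c * spec.relative_amplitude
        if amp != 0:
            intensity += amp * _multiplet_profile(
                ppm, spec, spec.center_ppm + off)
    intensity += _smooth_baseline(ppm, baseline_amplitude, rng)
    if noise_sd > 0:
        intensity += rng.normal(0.0, noise_sd, size=ppm.size)
    s = Spectrum1D(ppm, intensity, sample_id)
    if _return_offsets:
        return s, offsets
    return s


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def _cohort_design(config: SyntheticConfig, rng: np.random.Generator):
    """Subject roster and retained (subject, timepoint) pairs."""
    rows = []
    for disease in config.cohort_sizes:
        for i in range(config.cohort_sizes[disease]):
            subject = f"{disease}{i + 1:02d}"
            for tp in config.timepoints:
                if rng.uniform() < config.dropout(disease, tp):
                    continue
                rows.append((f"{subject}_{tp}", subject, disease, tp))
    return rows


def _draw_concentrations(config: SyntheticConfig, rng: np.random.Generator,
                         design):
    """Per-sample true concentration multipliers (TSP excluded)."""
    metabs = [m.name for m in config.panel if m.name != "TSP"]
    subjects = sorted({r[1] for r in design})
    dis = {r[1]: r[2] for r in design}
    base = pd.DataFrame(
        np.exp(rng.normal(0.0, config.sigma_log_subject,
                          size=(len(subjects), len(metabs)))),
        index=subjects, columns=metabs)
    conc = {}
    for sample_id, subject, disease, tp in design:
        eps = np.exp(rng.normal(0.0, config.sigma_log_within,
                                size=len(metabs)))
        eff = np.array([effect_multiplier(config.effect_matrix, m, disease, tp)
                        for m in metabs])
        conc[sample_id] = base.loc[subject].to_numpy() * eff * eps
    return pd.DataFrame(conc, index=metabs).T, dis


def _truth_tables(config: SyntheticConfig) -> tuple[pd.DataFrame, list[str]]:
    metabs = [m.name for m in config.panel if m.name != "TSP"]
    cols = pd.MultiIndex.from_product(
        [list(config.cohort_sizes), list(config.timepoints)],
        names=["disease", "timepoint"])
    mult = pd.DataFrame(1.0, index=metabs, columns=cols)
    for m in metabs:
        for d in config.cohort_sizes:
            for t in config.timepoints:
                mult.loc[m, (d, t)] = effect_multiplier(
                    config.effect_matrix, m, d, t)
    null = [m for m in metabs if np.allclose(mult.loc[m].to_numpy(), 1.0)]
    return mult, null


def simulate_cohort(config: SyntheticConfig) -> tuple[SpectraSet, GroundTruth]:
    """Simulate the full longitudinal cohort as spectra.

    One spectrum per retained (subject, timepoint); per-subject multipliers
    combine baseline individual levels, planted effects and lognormal
    biological noise; dropout is applied independently per follow-up
    timepoint.  Deterministic given ``config.seed``.
    """
    if not config.panel:
        raise ValueError("panel must not be empty")
    rng = np.random.default_rng(config.seed)
    design = _cohort_design(config, rng)
    conc, _ = _draw_concentrations(config, rng, design)
    spectra = np.empty((len(design), config.n_points))
    all_offsets = {}
    meta_rows = []
    for i, (sample_id, subject, disease, tp) in enumerate(design):
        s, offs = simulate_spectrum(
            config.panel, conc.loc[sample_id].to_dict(),
            jitter_sd_ppm=config.jitter_sd_ppm, noise_sd=config.noise_sd,
            baseline_amplitude=config.baseline_amplitude,
            n_points=config.n_points,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            tsp_amplitude=config.tsp_amplitude,
            spectral_width_ppm=config.spectral_width_ppm,
            ppm_max=config.ppm_max, sample_id=sample_id,
            _return_offsets=True)
        spectra[i] = s.intensity
        all_offsets[sample_id] = offs
        meta_rows.append((sample_id, subject, disease, tp, ""))
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "subject_id", "disease", "timepoint",
                 "response"]).set_index("sample_id")
    sset = SpectraSet(config.ppm_axis(), spectra, meta)
    mult, null = _truth_tables(config)
    truth = GroundTruth(mult, pd.DataFrame(all_offsets).T, conc, null)
    return sset, truth


def simulate_feature_cohort(config: SyntheticConfig
                            ) -> tuple[FeatureTable, GroundTruth]:
    """Cohort at the feature level: true concentrations straight into a
    :class:`FeatureTable`, bypassing spectral synthesis.

    Shares the concentration/dropout model of :func:`simulate_cohort`; used
    for statistical power/calibration studies where the spectral stage is
    not under test.
    """
    if not config.panel:
        raise ValueError("panel must not be empty")
    rng = np.random.default_rng(config.seed)
    design = _cohort_design(config, rng)
    conc, _ = _draw_concentrations(config, rng, design)
    amps = pd.Series({m.name: m.relative_amplitude
                      for m in config.panel if m.name != "TSP"})
    values = conc * amps
    meta = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], "") for r in design],
        columns=["sample_id", "subject_id", "disease", "timepoint",
                 "response"]).set_index("sample_id")
    mult, null = _truth_tables(config)
    truth = GroundTruth(mult, pd.DataFrame(index=meta.index), conc, null)
    return FeatureTable(values, meta), truth


def simulate_clinical_scores(meta: pd.DataFrame, seed: int = 0,
                             improvement_mean: float = 2.5,
                             improvement_sd: float = 1.2) -> pd.DataFrame:
    """Synthetic disease-activity scores for the cohort's subjects.

    RA and PsA subjects get DAS28 scores (baseline high activity, > 5.1 per
    the inclusion criteria), AS subjects BASDAI (baseline >= 4); endpoint
    scores improve by a noisy positive amount.  Returns one row per subject
    and follow-up timepoint with columns (subject_id, disease, score_type,
    baseline_score, endpoint_score, timepoint).
    """
    rng = np.random.default_rng(seed)
    rows = []
    subjects = meta[["subject_id", "disease"]].drop_duplicates("subject_id")
    followups = [t for t in meta["timepoint"].unique() if t != "BT"]
    for _, r in subjects.iterrows():
        if r.disease == "AS":
            score_type, baseline = "BASDAI", rng.uniform(4.0, 8.0)
        else:
            score_type, baseline = "DAS28", rng.uniform(5.2, 7.5)
        for k, tp in enumerate(sorted(followups), start=1):
            present = ((meta.subject_id == r.subject_id)
                       & (meta.timepoint == tp)).any()
            if not present:
                continue
            drop = rng.normal(improvement_mean * k / len(followups),
                              improvement_sd)
            rows.append((r.subject_id, r.disease, score_type,
                         round(baseline, 2),
                         round(max(0.0, baseline - drop), 2), tp))
    return pd.DataFrame(rows, columns=[
        "subject_id", "disease", "score_type", "baseline_score",
        "endpoint_score", "timepoint"])


# --------------------------------------------------------------------------
# config file round trip
# --------------------------------------------------------------------------

def save_config(config: SyntheticConfig, path) -> None:
    obj = asdict(config)
    obj["panel"] = [asdict(m) for m in config.panel]
    obj["timepoints"] = list(config.timepoints)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if obj.get("panel"):
        obj["panel"] = [MultipletSpec(**m) for m in obj["panel"]]
    if "timepoints" in obj:
        obj["timepoints"] = tuple(obj["timepoints"])
    return SyntheticConfig(**obj)
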