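"""Synthetic study cohort: spectra with known ground-truth concentrations.

Emulates the study design — two groups (control vs DSS-treated) x 3
subjects x days 0-5, i.e. 36 samples per field — at 60 and/or 800 MHz.
Per-sample metabolite concentrations are lognormal draws (guaranteeing
positivity) around baseline x fold(group, day); the treated-group fold
ramps linearly from 1 at the onset day to its day-5 value, with acetate,
succinate, glucose and taurine increased and butyrate, propionate, the
branched-chain amino acids, alanine, aspartate, glycerol and threonine
decreased. Effect magnitudes are free parameters of the design file, not
measured values. Internal standards (TSP 0.5 mM, formate 1 mM) are held
fixed.

The generator returns frequency-domain spectra plus a ground-truth table,
so downstream quantification can be scored against known concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .library import load_library
from .spin import LineshapeParams, PeakList, SpinSystem, peaks_auto, \
    first_order_peaks, default_axis, render_spectrum
from .spectrum import Spectrum

GROUPS = ("control", "dss")

# default rendered linewidths: broader at low field (poorer shimming of
# permanent magnets); values chosen to reproduce low-field congestion
FWHM_HZ = {60.0: 1.4, 800.0: 1.0}


def _default_fwhm(field_MHz: float) -> float:
    return FWHM_HZ.get(field_MHz, 1.0 if field_MHz >= 400 else 1.4)


@dataclass
class CohortDesign:
    n_per_group: int = 3
    days: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    baseline_mM: dict[str, float] = dc_field(default_factory=dict)
    cv_biological: float = 0.20
    effect_fold_day5: dict[str, float] = dc_field(default_factory=dict)
    effect_onset_day: int = 2
    internal_standards_mM: dict[str, float] = dc_field(
        default_factory=lambda: {"tsp": 0.5, "formate": 1.0})
    snr: float = 500.0
    shift_jitter_ppm: float = 0.003
    eta: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name, c in self.baseline_mM.items():
            if c <= 0:
                raise ValueError(f"baseline concentration of {name} must be > 0")
        for name, f in self.effect_fold_day5.items():
            if f <= 0:
                raise ValueError(f"fold change of {name} must be > 0")

    @staticmethod
    def default(seed: int = 0, **overrides) -> "CohortDesign":
        text = (resources.files("benchnmr") / "data"
                / "cohort_defaults.yaml").read_text()
        return CohortDesign.from_dict(yaml.safe_load(text), seed=seed,
                                      **overrides)

    @staticmethod
    def from_dict(cfg: dict, seed: int = 0, **overrides) -> "CohortDesign":
        cfg = dict(cfg)
        cfg["days"] = tuple(cfg.get("days", (0, 1, 2, 3, 4, 5)))
        cfg.update(overrides)
        cfg.setdefault("seed", seed)
        known = set(CohortDesign.__dataclass_fields__)
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown design key(s): {sorted(unknown)}")
        return CohortDesign(**cfg)

    @staticmethod
    def from_yaml(path: str | Path, seed: int = 0, **overrides) -> "CohortDesign":
        return CohortDesign.from_dict(yaml.safe_load(Path(path).read_text()),
                                      seed=seed, **overrides)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["days"] = list(d["days"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def fold(self, metabolite: str, group: str, day: int) -> float:
        """Multiplicative fold change relative to baseline at (group, day)."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        if group == "control":
            return 1.0
        target = self.effect_fold_day5.get(metabolite, 1.0)
        last = max(self.days)
        onset = self.effect_onset_day
        if day < onset or target == 1.0:
            return 1.0
        frac = (day - onset + 1) / (last - onset + 1)
        return 1.0 + (target - 1.0) * frac


def sample_concentrations(design: CohortDesign, subject: int, group: str,
                          day: int, rng: np.random.Generator | None = None
                          ) -> dict[str, float]:
    """One subject-day concentration profile (mM per metabolite).

    Lognormal draw with the design CV around baseline x fold; internal
    standards are fixed. cv = 0 returns the means exactly. With no rng, a
    deterministic per-(seed, subject, group, day) stream is used.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if day not in design.days:
        raise ValueError(f"day {day} not in design days {design.days}")
    if not (0 <= subject < design.n_per_group):
        raise ValueError(f"subject {subject} outside design")
    if rng is None:
        gi = GROUPS.index(group)
        rng = np.random.default_rng(
            (design.seed, 1000 + gi, subject, day))
    cv = design.cv_biological
    out: dict[str, float] = {}
    for name, base in design.baseline_mM.items():
        mean = base * design.fold(name, group, day)
        if cv == 0:
            out[name] = mean
        else:
            sigma2 = np.log1p(cv**2)
            mu = np.log(mean) - sigma2 / 2.0
            out[name] = float(rng.lognormal(mu, np.sqrt(sigma2)))
    out.update(design.internal_standards_mM)
    return out


class _PeakCache:
    """Per-(metabolite, field) stick spectra; concentration only rescales."""

    def __init__(self, library: dict[str, SpinSystem], mode: str = "auto"):
        self.library = library
        self.mode = mode
        self._cache: dict[tuple[str, float], PeakList] = {}

    def get(self, name: str, field_MHz: float) -> PeakList:
        if name not in self.library:
            raise KeyError(f"metabolite {name!r} not in library")
        key = (name, field_MHz)
        if key not in self._cache:
            system = self.library[name]
            if self.mode == "first_order":
                self._cache[key] = first_order_peaks(system, field_MHz)
            else:
                self._cache[key] = peaks_auto(system, field_MHz)
        return self._cache[key]


def synthesize_sample(concentrations: dict[str, float], field_MHz: float,
                      cache: _PeakCache, axis: np.ndarray,
                      fwhm_hz: float, eta: float, snr: float,
                      noise_seed: int | None,
                      shift_ppm: float = 0.0) -> Spectrum:
    """Render one spectrum from a concentration profile."""
    parts = []
    for name, conc in concentrations.items():
        parts.append(cache.get(name, field_MHz).scaled(conc))
    peaks = PeakList.concatenate(parts)
    if shift_ppm:
        lines = peaks.lines.copy()
        lines[:, 0] += shift_ppm
        peaks = PeakList(lines, field_MHz)
    shape = LineshapeParams(width_hz=fwhm_hz, eta=eta, noise_sd=0.0)
    clean = render_spectrum(peaks, axis, shape)
    noise_sd = float(np.max(clean.real)) / snr if snr and snr > 0 else 0.0
    y = clean.intensity
    if noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        y = y + rng.normal(0.0, noise_sd, y.size)
    meta = dict(clean.metadata)
    meta.update(noise_sd=noise_sd, applied_shift_ppm=shift_ppm,
                acquisition="presat-1d")
    return Spectrum(axis, y, field_MHz, meta)


def synthesize_cohort(design: CohortDesign,
                      library: dict[str, SpinSystem] | None = None,
                      fields: tuple[float, ...] = (60.0, 800.0),
                      mode: str = "first_order",
                      n_points: dict[float, int] | int | None = None
                      ) -> tuple[list[Spectrum], pd.DataFrame]:
    """Full cohort: spectra for every subject x day x field + ground truth.

    Returns (spectra, truth); each spectrum's metadata carries subject,
    group, day and a sample id. Default design: 2 groups x 3 subjects x
    6 days = 36 samples per field. ``mode`` selects the simulation route
    ('first_order' or 'auto' = exact Hamiltonian where tractable).
    """
    if not fields:
        raise ValueError("fields list must not be empty")
    library = library or load_library()
    missing = (set(design.baseline_mM) | set(design.internal_standards_mM)) \
        - set(library)
    if missing:
        raise KeyError(f"library missing metabolites: {sorted(missing)}")
    cache = _PeakCache(library, mode=mode)
    rng = np.random.default_rng(design.seed)
    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []
    for gi, group in enumerate(GROUPS):
        for subject in range(design.n_per_group):
            for day in design.days:
                conc = sample_concentrations(design, subject, group, day)
                sample_id = f"{group}{subject}_d{day}"
                for name, c in conc.items():
                    truth_rows.append(dict(
                        sample=sample_id, subject=subject, group=group,
                        day=day, metabolite=name, true_mM=c))
                jitter = (rng.normal(0.0, design.shift_jitter_ppm)
                          if design.shift_jitter_ppm else 0.0)
                noise_seeds = rng.integers(0, 2**31 - 1, size=len(fields))
                for field, nseed in zip(fields, noise_seeds):
                    if isinstance(n_points, dict):
                        npts = n_points.get(field)
                    else:
                        npts = n_points
                    axis = default_axis(field, n_points=npts)
                    spec = synthesize_sample(
                        conc, field, cache, axis,
                        fwhm_hz=_default_fwhm(field), eta=design.eta,
                        snr=design.snr, noise_seed=int(nseed),
                        shift_ppm=jitter)
                    spec.metadata.update(sample=sample_id, subject=subject,
                                         group=group, day=day)
                    spectra.append(spec)
    truth = pd.DataFrame(truth_rows)
    return spectra, truth


def single_metabolite_design(name: str, conc_mM: float, seed: int = 0,
                             **overrides) -> CohortDesign:
    """Minimal panel-of-one design (plus TSP), handy for tests/calibration."""
    return CohortDesign(
        n_per_group=2, days=(0,), baseline_mM={name: conc_mM},
        cv_biological=0.0, effect_fold_day5={},
        internal_standards_mM={"tsp": 0.5}, seed=seed, **overrides)
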