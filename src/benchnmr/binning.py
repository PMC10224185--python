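"""Uniform spectral binning into the samples x bins feature matrix.

Processed spectra are integrated over fixed 0.04-ppm bins tiled across
0-10 ppm, with the residual-water window (4.5-5.0 ppm) excluded. Bin
values are areas (trapezoidal integrals), which is what TSP normalization
refers to, not mean intensities. Because 4.5 and 5.0 are not multiples of
0.04, exclusion is decided by bin-center membership by default (a bin is
dropped when its center lies inside an exclusion window), which removes
exactly the bins [4.48, 4.52) ... [4.96, 5.00); an "any-overlap" rule is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .processing import integrate
from .spectrum import Spectrum

LABEL_COLUMNS = ["sample", "subject", "group", "day", "field_MHz"]


class NormalizationContractError(ValueError):
    """Spectrum was not TSP-normalized before binning."""


class SchemeMismatchError(ValueError):
    """Bin vectors produced under different binning schemes."""


@dataclass(frozen=True)
class BinningScheme:
    width_ppm: float = 0.04
    range_ppm: tuple[float, float] = (0.0, 10.0)
    exclusions: tuple[tuple[float, float], ...] = ((4.5, 5.0),)
    exclusion_rule: str = "center"  # or "any-overlap"

    def __post_init__(self):
        if self.width_ppm <= 0:
            raise ValueError("bin width must be positive")
        lo, hi = self.range_ppm
        for a, b in self.exclusions:
            if a >= b or a < lo or b > hi:
                raise ValueError(f"exclusion ({a}, {b}) invalid for range")
        if self.exclusion_rule not in ("center", "any-overlap"):
            raise ValueError("exclusion_rule must be 'center' or 'any-overlap'")

    def edges(self) -> np.ndarray:
        """Left edges plus final right edge; bins are [left, left+width)."""
        lo, hi = self.range_ppm
        n = int(np.floor((hi - lo) / self.width_ppm + 1e-9))
        return lo + self.width_ppm * np.arange(n + 1)

    def retained(self) -> np.ndarray:
        """Boolean mask of bins kept after exclusion."""
        e = self.edges()
        lefts, rights = e[:-1], e[1:]
        centers = 0.5 * (lefts + rights)
        keep = np.ones(centers.size, dtype=bool)
        for a, b in self.exclusions:
            if self.exclusion_rule == "center":
                keep &= ~((centers >= a) & (centers < b))
            else:
                keep &= ~((rights > a) & (lefts < b))
        return keep

    def centers(self) -> np.ndarray:
        e = self.edges()
        return (0.5 * (e[:-1] + e[1:]))[self.retained()]


def bin_spectrum(spectrum: Spectrum, scheme: BinningScheme | None = None,
                 allow_unnormalized: bool = False) -> np.ndarray:
    """Integrate a normalized spectrum into the retained bins.

    Each bin's value is the trapezoidal integral of intensity over
    [left, left + width); the sum over all (unexcluded) bins equals the
    integral over the full range by construction.
    """
    scheme = scheme or BinningScheme()
    if not spectrum.is_normalized and not allow_unnormalized:
        raise NormalizationContractError(
            "spectrum is not TSP-normalized; pass allow_unnormalized=True "
            "to bin anyway")
    e = scheme.edges()
    lo = max(e[0], spectrum.ppm[0])
    hi = min(e[-1], spectrum.ppm[-1])
    from scipy.integrate import cumulative_trapezoid
    F = cumulative_trapezoid(spectrum.real, spectrum.ppm, initial=0.0)
    Fe = np.interp(np.clip(e, lo, hi), spectrum.ppm, F)
    values = np.diff(Fe)
    return values[scheme.retained()]


def assemble_matrix(vectors: list[np.ndarray], labels: list[dict],
                    scheme: BinningScheme | None = None) -> "BinMatrix":
    scheme = scheme or BinningScheme()
    n_bins = scheme.centers().size
    for v in vectors:
        if v.shape != (n_bins,):
            raise SchemeMismatchError(
                f"bin vector of length {v.shape} does not match the "
                f"scheme's {n_bins} retained bins")
    values = np.vstack(vectors) if vectors else np.empty((0, n_bins))
    lab = pd.DataFrame(labels)
    return BinMatrix(values=values, labels=lab, scheme=scheme)


@dataclass
class BinMatrix:
    """Samples x retained-bins area matrix with sample labels."""

    values: np.ndarray
    labels: pd.DataFrame
    scheme: BinningScheme = dc_field(default_factory=BinningScheme)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (samples x bins)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels/values row mismatch")

    @property
    def centers(self) -> np.ndarray:
        return self.scheme.centers()

    def subset(self, mask) -> "BinMatrix":
        mask = np.asarray(mask)
        return BinMatrix(self.values[mask],
                         self.labels.iloc[mask].reset_index(drop=True),
                         self.scheme)

    def columns_near(self, lo: float, hi: float) -> np.ndarray:
        """Indices of retained bins whose centers lie in [lo, hi]."""
        c = self.centers
        return np.flatnonzero((c >= lo - 1e-9) & (c <= hi + 1e-9))

    def to_csv(self, path: str | Path, seed=None) -> None:
        path = Path(path)
        bins_df = pd.DataFrame(self.values,
                               columns=[f"{c:.3f}" for c in self.centers])
        df = pd.concat([self.labels.reset_index(drop=True), bins_df], axis=1)
        with open(path, "w") as fh:
            fh.write(f"# benchnmr v{__version__}"
                     + (f" seed={seed}" if seed is not None else "") + "\n")
            fh.write(f"# width_ppm={self.scheme.width_ppm} "
                     f"range={self.scheme.range_ppm} "
                     f"exclusions={self.scheme.exclusions}\n")
            df.to_csv(fh, index=False, float_format="%.10g")

    @staticmethod
    def from_csv(path: str | Path,
                 scheme: BinningScheme | None = None) -> "BinMatrix":
        scheme = scheme or BinningScheme()
        df = pd.read_csv(path, comment="#")
        label_cols = [c for c in df.columns if c in LABEL_COLUMNS]
        bin_cols = [c for c in df.columns if c not in LABEL_COLUMNS]
        values = df[bin_cols].to_numpy(dtype=float)
        if values.shape[1] != scheme.centers().size:
            raise SchemeMismatchError("CSV bin count does not match scheme")
        return BinMatrix(values, df[label_cols].copy(), scheme)
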