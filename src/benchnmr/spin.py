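"""Liquid-state 1H spin-system simulation at arbitrary spectrometer field.

Chemical shifts (delta, ppm) are field-independent while scalar couplings
(J, Hz) are fixed in Hz, so a multiplet's footprint in ppm shrinks as
1/field: the n-line envelope occupies ``n * J / field_MHz`` ppm. At 60 MHz
the shift separations (in Hz) of many metabolite protons become comparable
to J, so the weak-coupling (first-order) multiplet rules break down and the
full isotropic spin Hamiltonian

    H = sum_i nu_i Iz_i + sum_{i<j} J_ij (I_i . I_j)      [Hz]

must be diagonalized to obtain line positions and transition intensities.
Both routes are provided: :func:`first_order_peaks` (binomial multiplets,
composite-particle treatment of equivalent groups) and
:func:`full_hamiltonian_peaks` (exact diagonalization, each equivalent
proton an explicit spin-1/2, capped at 8 spins).

Peak intensities are expressed in proton equivalents: a PeakList's total
intensity equals the proton count of its spin system at every field, which
encodes the field invariance of integrated intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from math import comb, sqrt, log, pi

import numpy as np

from .spectrum import Spectrum

_HAMILTONIAN_SPIN_CAP = 8


class SpinCountError(ValueError):
    """Spin system too large for exact diagonalization; use first-order mode."""


@dataclass(frozen=True)
class SpinGroup:
    """A set of magnetically equivalent protons at one chemical shift."""

    shift_ppm: float
    n_equivalent: int = 1

    def __post_init__(self):
        if not (-0.5 <= self.shift_ppm <= 12.0):
            raise ValueError(f"shift {self.shift_ppm} ppm outside [-0.5, 12]")
        if int(self.n_equivalent) != self.n_equivalent or self.n_equivalent < 1:
            raise ValueError("n_equivalent must be a positive integer")


@dataclass
class SpinSystem:
    """One metabolite's proton network: shifts (ppm) and J couplings (Hz)."""

    name: str
    groups: list[SpinGroup]
    couplings: np.ndarray | None = None  # symmetric (g, g) in Hz

    def __post_init__(self):
        self.groups = [g if isinstance(g, SpinGroup) else SpinGroup(*g)
                       for g in self.groups]
        g = len(self.groups)
        if self.couplings is None:
            self.couplings = np.zeros((g, g))
        self.couplings = np.asarray(self.couplings, dtype=float)
        if self.couplings.shape != (g, g):
            raise ValueError("couplings must be a (groups, groups) matrix")
        if not np.allclose(self.couplings, self.couplings.T):
            raise ValueError("J matrix must be symmetric")
        if np.any(np.diag(self.couplings) != 0):
            raise ValueError("J matrix diagonal must be zero")

    @property
    def n_protons(self) -> int:
        return sum(g.n_equivalent for g in self.groups)

    @property
    def n_spins(self) -> int:
        return self.n_protons


@dataclass
class PeakList:
    """Stick spectrum: (ppm, intensity) transitions at a given field."""

    lines: np.ndarray  # (n, 2): frequency_ppm, intensity
    field_MHz: float

    def __post_init__(self):
        self.lines = np.atleast_2d(np.asarray(self.lines, dtype=float))
        if self.lines.shape[1] != 2:
            raise ValueError("lines must be (n, 2): ppm, intensity")
        if np.any(self.lines[:, 1] < -1e-12):
            raise ValueError("intensities must be non-negative")
        if self.field_MHz <= 0:
            raise ValueError("field_MHz must be positive")

    @property
    def ppm(self) -> np.ndarray:
        return self.lines[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.lines[:, 1]

    @property
    def total_intensity(self) -> float:
        return float(self.lines[:, 1].sum())

    def scaled(self, factor: float) -> "PeakList":
        out = self.lines.copy()
        out[:, 1] *= factor
        return PeakList(out, self.field_MHz)

    @staticmethod
    def concatenate(peaklists: list["PeakList"]) -> "PeakList":
        fields = {p.field_MHz for p in peaklists}
        if len(fields) != 1:
            raise ValueError("cannot concatenate PeakLists at different fields")
        return PeakList(np.vstack([p.lines for p in peaklists]),
                        peaklists[0].field_MHz)


@dataclass
class LineshapeParams:
    """Rendering parameters: pseudo-Voigt width/mixing, noise, baseline.

    width_hz : full width at half maximum, Hz (converted to ppm by field)
    eta      : Gaussian fraction of the pseudo-Voigt in [0, 1]
    noise_sd : additive frequency-domain Gaussian noise scale (0 = none)
    baseline_coeffs : np.polyval coefficients evaluated on the ppm axis
    """

    width_hz: float = 1.0
    eta: float = 0.1
    noise_sd: float = 0.0
    baseline_coeffs: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        if self.width_hz <= 0:
            raise ValueError("width_hz must be positive")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")


def multiplet_envelope_ppm(J_hz: float, n_lines: int, field_MHz: float) -> float:
    """Width in ppm occupied by an n-line multiplet of spacing J at a field.

    Convention: multiplicity x J / field (e.g. a triplet with J = 7.70 Hz
    occupies 3 x 7.70 / 60 = 0.385 ppm at 60 MHz). Note this counts one
    spacing per line, not the peak-to-peak span (n - 1) x J / field; the
    extra J on each side approximates the linewidth skirt of the outer
    lines, and it is the convention used throughout this package.
    """
    if field_MHz <= 0:
        raise ValueError("field_MHz must be positive")
    if J_hz < 0:
        raise ValueError("J must be non-negative")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    return n_lines * J_hz / field_MHz


def _merge_lines(freqs: np.ndarray, amps: np.ndarray, tol: float) -> np.ndarray:
    """Coalesce lines closer than tol (ppm); drop negligible intensities."""
    order = np.argsort(freqs)
    freqs, amps = freqs[order], amps[order]
    out_f: list[float] = []
    out_a: list[float] = []
    for f, a in zip(freqs, amps):
        if out_f and abs(f - out_f[-1]) < tol:
            # intensity-weighted position keeps degenerate merges exact
            tot = out_a[-1] + a
            out_f[-1] = (out_f[-1] * out_a[-1] + f * a) / tot
            out_a[-1] = tot
        else:
            out_f.append(f)
            out_a.append(a)
    lines = np.column_stack([out_f, out_a])
    return lines[lines[:, 1] > 1e-12]


def first_order_peaks(system: SpinSystem, field_MHz: float) -> PeakList:
    """Weak-coupling multiplets: binomial splitting by each coupled partner.

    Each group resonates at its shift, split by every coupled partner group
    of n equivalent spins into n+1 lines with binomial intensities spaced
    J/field ppm; splittings from distinct partners convolve. The group's
    lines sum to its proton count. Validity (min |delta nu| >> J) is the
    caller's responsibility.
    """
    if field_MHz <= 0:
        raise ValueError("field_MHz must be positive")
    all_lines = []
    for i, g in enumerate(system.groups):
        offsets = np.array([0.0])  # Hz
        weights = np.array([1.0])
        for j, partner in enumerate(system.groups):
            J = system.couplings[i, j]
            if j == i or J == 0:
                continue
            n = partner.n_equivalent
            split = (np.arange(n + 1) - n / 2.0) * J
            w = np.array([comb(n, k) for k in range(n + 1)], dtype=float) / 2**n
            offsets = (offsets[:, None] + split[None, :]).ravel()
            weights = (weights[:, None] * w[None, :]).ravel()
        freqs = g.shift_ppm + offsets / field_MHz
        amps = weights * g.n_equivalent
        all_lines.append(np.column_stack([freqs, amps]))
    stacked = np.vstack(all_lines)
    merged = _merge_lines(stacked[:, 0], stacked[:, 1], tol=1e-10)
    return PeakList(merged, field_MHz)


def _spin_operators(n: int):
    """Sparse-free Pauli construction of total/single-spin operators."""
    sz = np.array([[0.5, 0.0], [0.0, -0.5]])
    sp = np.array([[0.0, 1.0], [0.0, 0.0]])
    sm = sp.T
    eye = np.eye(2)

    def embed(op, k):
        mats = [op if i == k else eye for i in range(n)]
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    Iz = [embed(sz, k) for k in range(n)]
    Ip = [embed(sp, k) for k in range(n)]
    Im = [embed(sm, k) for k in range(n)]
    return Iz, Ip, Im


def full_hamiltonian_peaks(system: SpinSystem, field_MHz: float,
                           intensity_floor: float = 1e-9) -> PeakList:
    """Exact spectrum from diagonalizing the isotropic spin Hamiltonian.

    Equivalent groups are expanded into explicit spins sharing one shift
    (intra-group J is unobservable for magnetically equivalent nuclei and
    set to zero). Transition intensities are |<f| I-_total |i>|^2 under
    equal high-temperature populations, normalized so the total intensity
    equals the proton count. State space is 2^n; n is capped at 8.
    """
    if field_MHz <= 0:
        raise ValueError("field_MHz must be positive")
    n = system.n_spins
    if n > _HAMILTONIAN_SPIN_CAP:
        raise SpinCountError(
            f"{system.name}: {n} spins exceeds the cap of "
            f"{_HAMILTONIAN_SPIN_CAP}; use first_order_peaks")
    # expand groups -> per-spin shift (Hz) and J matrix
    shifts_hz = []
    group_of = []
    for gi, g in enumerate(system.groups):
        shifts_hz.extend([g.shift_ppm * field_MHz] * g.n_equivalent)
        group_of.extend([gi] * g.n_equivalent)
    Jmat = np.zeros((n, n))
    for a, b in product(range(n), range(n)):
        if a < b and group_of[a] != group_of[b]:
            Jmat[a, b] = Jmat[b, a] = system.couplings[group_of[a], group_of[b]]

    Iz, Ip, Im = _spin_operators(n)
    dim = 2**n
    H = np.zeros((dim, dim))
    for k in range(n):
        H += shifts_hz[k] * Iz[k]
    for a in range(n):
        for b in range(a + 1, n):
            if Jmat[a, b] == 0:
                continue
            # Ix.Ix + Iy.Iy = (I+I- + I-I+)/2
            H += Jmat[a, b] * (Iz[a] @ Iz[b]
                               + 0.5 * (Ip[a] @ Im[b] + Im[a] @ Ip[b]))
    energies, vecs = np.linalg.eigh(H)
    Im_tot = sum(Im)
    A = vecs.T @ Im_tot @ vecs  # <i| I- |j> in the eigenbasis
    inten = A**2 / 2**(n - 1)
    fi, fj = np.nonzero(inten > intensity_floor)
    freqs_hz = energies[fj] - energies[fi]  # |j> is the higher-M state
    amps = inten[fi, fj]
    # in strong coupling a few vanishingly weak combination transitions
    # have the higher-M eigenstate below the lower-M one; the observable
    # line sits at |dE|, and folding keeps total intensity exactly N
    freqs_hz = np.abs(freqs_hz)
    lines = _merge_lines(freqs_hz / field_MHz, amps,
                         tol=1e-9 / field_MHz)
    return PeakList(lines, field_MHz)


def peaks_auto(system: SpinSystem, field_MHz: float) -> PeakList:
    """Hamiltonian mode where tractable (<= 8 spins), else first-order."""
    if system.n_spins <= _HAMILTONIAN_SPIN_CAP:
        return full_hamiltonian_peaks(system, field_MHz)
    return first_order_peaks(system, field_MHz)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_G_NORM = 2.0 * sqrt(log(2.0) / pi)


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Area-normalized pseudo-Voigt: eta Gaussian + (1 - eta) Lorentzian."""
    u = (x - center) / fwhm
    lor = (2.0 / (pi * fwhm)) / (1.0 + 4.0 * u**2)
    if eta == 0.0:
        return lor
    gau = (_G_NORM / fwhm) * np.exp(-4.0 * log(2.0) * u**2)
    return eta * gau + (1.0 - eta) * lor


def default_axis(field_MHz: float, lo: float = -0.5, hi: float = 10.0,
                 n_points: int | None = None) -> np.ndarray:
    """Default ppm grid: 32768 points at 60 MHz, 65536 at >= 400 MHz.

    The grid starts at -0.5 ppm so the TSP reference singlet at 0.0 ppm
    is fully covered; analysis windows (binning 0-10 ppm) are narrower.
    """
    if n_points is None:
        n_points = 65536 if field_MHz >= 400 else 32768
    return np.linspace(lo, hi, n_points)


def render_spectrum(peaks: PeakList, axis: np.ndarray,
                    shape: LineshapeParams) -> Spectrum:
    """Sum of area-normalized pseudo-Voigt lines + baseline + seeded noise.

    Line areas (in ppm x intensity units) equal PeakList intensities, so a
    noiseless multiplet integrates to its proton-equivalent intensity
    within discretization error. If the axis fails to cover every line by
    at least 10 linewidths, a truncation warning is recorded in metadata.
    """
    axis = np.asarray(axis, dtype=float)
    fwhm_ppm = shape.width_hz / peaks.field_MHz
    meta: dict = {"width_hz": shape.width_hz, "eta": shape.eta}
    if peaks.lines.size:
        lo_need = peaks.ppm.min() - 10 * fwhm_ppm
        hi_need = peaks.ppm.max() + 10 * fwhm_ppm
        if axis[0] > lo_need or axis[-1] < hi_need:
            meta["truncated"] = True
            warnings.warn("axis does not cover all lines +- 10 linewidths; "
                          "integrals will be truncated", stacklevel=2)
    y = np.zeros_like(axis)
    # chunk the line loop to bound the (lines x grid) temporary
    lines = peaks.lines
    chunk = max(1, int(4e6 // max(axis.size, 1)))
    for start in range(0, len(lines), chunk):
        block = lines[start:start + chunk]
        u = (axis[None, :] - block[:, 0:1]) / fwhm_ppm
        lor = (2.0 / (pi * fwhm_ppm)) / (1.0 + 4.0 * u**2)
        if shape.eta > 0:
            gau = (_G_NORM / fwhm_ppm) * np.exp(-4.0 * log(2.0) * u**2)
            prof = shape.eta * gau + (1.0 - shape.eta) * lor
        else:
            prof = lor
        y += block[:, 1] @ prof
    if shape.baseline_coeffs:
        y = y + np.polyval(shape.baseline_coeffs, axis)
    if shape.noise_sd > 0:
        rng = np.random.default_rng(shape.seed)
        y = y + rng.normal(0.0, shape.noise_sd, axis.size)
    return Spectrum(axis, y, peaks.field_MHz, meta)
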