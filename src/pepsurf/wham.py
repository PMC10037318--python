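"""Weighted Histogram Analysis Method for umbrella-sampling windows.

Each umbrella window *j* restrains the reaction coordinate xi (nm) with a
harmonic bias w_j(xi) = k/2 (xi - z0_j)^2 and contributes N_j samples.  WHAM
recovers the unbiased distribution on a histogram grid by iterating the
self-consistency pair

    p(xi_b) = sum_j n_j(b) / sum_j N_j exp[(F_j - w_j(xi_b)) / kT]
    F_j     = -kT ln sum_b p(xi_b) exp[-w_j(xi_b) / kT]

to convergence of the window free energies F_j, then reports the potential of
mean force F(xi) = -kT ln p(xi), gauge-fixed so its minimum over supported
bins is zero.  Bins with no counts are reported as NaN (undefined), never 0.

Convergence: iteration stops when max_j |Delta F_j| < tolerance * kT
(``tolerance_mode="relative"``, the default, mirroring the dimensionless
tolerance convention of the reference gmx-wham tool) or below an absolute
kJ/mol threshold (``tolerance_mode="absolute"``).

Error bars come from a trajectory-style bootstrap: each window's sample
series is resampled with replacement in contiguous circular blocks whose
length tracks the series' integrated autocorrelation time, WHAM is re-run per
replicate (warm-started from the point estimate), replicates are gauge-aligned
to the point estimate, and the per-bin standard deviation across replicates is
the error.
"""

from __future__ import annotations

import builtins
import itertools
import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigurationError, ConvergenceError, InputError, NumericError

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "wham_pmf",
    "bootstrap_pmf_errors",
    "wham_with_errors",
    "gauge_align",
    "read_window_series",
    "load_windows",
    "KB_KJ_PER_MOL_K",
    "DEFAULT_TEMPERATURE",
]

#: Boltzmann constant in kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.0083145
DEFAULT_TEMPERATURE = 300.0  # K
DEFAULT_BINS = 200
DEFAULT_TOLERANCE = 1e-6
DEFAULT_MAX_ITER = 200_000


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias centre (nm), force constant
    (kJ mol^-1 nm^-2) and the sampled reaction-coordinate series (nm)."""

    center: float
    force_constant: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant <= 0:
            raise InputError(
                f"force constant must be > 0, got {self.force_constant}"
            )
        if self.samples.size == 0:
            raise InputError(f"window at {self.center} nm has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise InputError(f"window at {self.center} nm has non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def bias(self, xi: np.ndarray) -> np.ndarray:
        """Harmonic bias energy (kJ/mol) at reaction-coordinate values xi (nm)."""
        return 0.5 * self.force_constant * (np.asarray(xi) - self.center) ** 2


@dataclass
class PMFProfile:
    """PMF on a histogram grid, plus the converged per-window free energies."""

    grid: np.ndarray  # bin centres, nm
    free_energy: np.ndarray  # kJ/mol, NaN on unsupported bins
    errors: np.ndarray | None  # kJ/mol, NaN where undefined
    window_free_energies: np.ndarray  # kJ/mol, same gauge as free_energy
    temperature: float
    tolerance: float
    n_iterations: int = 0
    residual_history: list[float] = field(default_factory=list, repr=False)

    @property
    def supported(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_tsv(self, path: str | os.PathLike, header_lines: list[str] | None = None):
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# temperature_K = {self.temperature}\n")
            fh.write(f"# tolerance = {self.tolerance}\n")
            fh.write(f"# n_iterations = {self.n_iterations}\n")
            fh.write("xi_nm\tpmf_kJ_per_mol\terror_kJ_per_mol\n")
            err = (
                self.errors
                if self.errors is not None
                else np.full_like(self.free_energy, np.nan)
            )
            for x, f, e in zip(self.grid, self.free_energy, err):
                fh.write(f"{x:.6f}\t{f:.6f}\t{e:.6f}\n")


def _kt(temperature: float) -> float:
    if temperature <= 0:
        raise InputError(f"temperature must be > 0 K, got {temperature}")
    return KB_KJ_PER_MOL_K * temperature


def _histogram(
    windows: Sequence[UmbrellaWindow], bins: int, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros((bins, len(windows)))
    for j, w in enumerate(windows):
        inside = (w.samples >= lo) & (w.samples <= hi)
        if not inside.any():
            raise InputError(
                f"window at {w.center} nm has no samples inside [{lo}, {hi}] nm"
            )
        counts[:, j], _ = np.histogram(w.samples[inside], bins=edges)
    return centers, counts, edges


def wham_pmf(
    windows: Sequence[UmbrellaWindow],
    bins: int = DEFAULT_BINS,
    range: tuple[float, float] | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    tolerance: float = DEFAULT_TOLERANCE,
    tolerance_mode: str = "relative",
    max_iter: int = DEFAULT_MAX_ITER,
    initial_window_free_energies: np.ndarray | None = None,
) -> PMFProfile:
    """Self-consistent WHAM estimate of the PMF from umbrella windows.

    Parameters
    ----------
    windows:
        Umbrella windows (harmonic bias centre, force constant, samples).
    bins, range:
        Histogram grid; ``range`` defaults to the span of all samples.
    temperature:
        Kelvin; sets kT for the Boltzmann reweighting.
    tolerance, tolerance_mode:
        Iteration stops when max_j |Delta F_j| drops below ``tolerance * kT``
        ("relative", default) or ``tolerance`` kJ/mol ("absolute").
    initial_window_free_energies:
        Optional starting F_j (kJ/mol) — used to warm-start bootstrap
        replicates; the converged result is invariant to a constant shift of
        this guess.
    """
    windows = list(windows)
    if not windows:
        raise InputError("need at least one umbrella window")
    if bins < 2:
        raise InputError(f"need at least 2 bins, got {bins}")
    if tolerance_mode not in ("relative", "absolute"):
        raise ConfigurationError(f"unknown tolerance mode {tolerance_mode!r}")
    kt = _kt(temperature)

    if range is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
    else:
        lo, hi = range
    if not (hi > lo):
        raise InputError(f"empty reaction-coordinate range [{lo}, {hi}]")

    centers, counts, _ = _histogram(windows, bins, lo, hi)
    n_b = counts.sum(axis=1)  # total counts per bin
    N_j = np.array([w.n_samples for w in windows], dtype=float)
    bias = np.stack([w.bias(centers) for w in windows], axis=1)  # (bins, J)
    neg_bias_kt = -bias / kt
    if not np.all(np.isfinite(neg_bias_kt)):
        raise NumericError("bias energies overflow at this temperature")

    supported = n_b > 0
    log_nb = np.full(bins, -np.inf)
    log_nb[supported] = np.log(n_b[supported])
    log_Nj = np.log(N_j)

    if initial_window_free_energies is not None:
        f = np.asarray(initial_window_free_energies, dtype=float) / kt
        if f.shape != (len(windows),):
            raise InputError("initial window free energies must match window count")
    else:
        f = np.zeros(len(windows))

    threshold = tolerance if tolerance_mode == "absolute" else tolerance * kt
    residuals: list[float] = []
    for iteration in itertools.count(1):
        # log p_b = log n_b - logsumexp_j [log N_j + f_j + (-w_jb/kT)]
        log_p = log_nb - logsumexp(log_Nj[None, :] + f[None, :] + neg_bias_kt, axis=1)
        # f_j = -log sum_b p_b exp(-w_jb/kT)
        f_new = -logsumexp(log_p[supported, None] + neg_bias_kt[supported, :], axis=0)
        f_new -= f_new[0]  # pin the gauge during iteration
        residual = float(np.max(np.abs(f_new - f))) * kt  # kJ/mol
        residuals.append(residual)
        f = f_new
        if residual < threshold:
            break
        if iteration >= max_iter:
            raise ConvergenceError(
                f"WHAM did not converge in {max_iter} iterations "
                f"(residual {residual:.3e} kJ/mol, threshold {threshold:.3e})",
                residual=residual,
            )

    log_p = log_nb - logsumexp(log_Nj[None, :] + f[None, :] + neg_bias_kt, axis=1)
    pmf = np.full(bins, np.nan)
    pmf[supported] = -kt * log_p[supported]
    shift = np.nanmin(pmf)
    pmf -= shift
    window_F = kt * f - shift

    return PMFProfile(
        grid=centers,
        free_energy=pmf,
        errors=None,
        window_free_energies=window_F,
        temperature=temperature,
        tolerance=tolerance,
        n_iterations=len(residuals),
        residual_history=residuals,
    )


def gauge_align(
    estimate: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Shift ``estimate`` by a constant so it best matches ``reference``.

    PMFs are defined up to an additive constant; the least-squares offset over
    the jointly finite (optionally masked) bins removes the gauge before any
    pointwise comparison.
    """
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    ok = np.isfinite(est) & np.isfinite(ref)
    if mask is not None:
        ok &= mask
    if not ok.any():
        raise InputError("no overlapping finite bins to gauge-align on")
    return est - float(np.mean(est[ok] - ref[ok]))


def _integrated_autocorrelation(x: np.ndarray, max_lag: int | None = None) -> float:
    """Initial-positive-sequence estimate of the integrated autocorrelation time."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return 1.0
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return 1.0
    if max_lag is None:
        max_lag = min(n // 4, 1000)
    tau = 1.0
    for lag in np.arange(1, max_lag + 1):
        rho = float(np.dot(x[:-lag], x[lag:])) / (n * var)
        if rho <= 0:
            break
        tau += 2.0 * rho
    return max(tau, 1.0)


def _block_resample(rng: np.random.Generator, samples: np.ndarray) -> np.ndarray:
    """Circular block bootstrap; block length ~ integrated autocorrelation time."""
    n = samples.size
    block = int(max(1, round(_integrated_autocorrelation(samples))))
    n_blocks = -(-n // block)  # ceil
    starts = rng.integers(0, n, size=n_blocks)
    idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n] % n
    return samples[idx]


def bootstrap_pmf_errors(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 200,
    seed: int | None = None,
    resampler: Callable[[np.random.Generator, np.ndarray], np.ndarray] | None = None,
    **wham_kwargs,
) -> np.ndarray:
    """Per-bin PMF standard errors from a trajectory-style bootstrap.

    Each replicate resamples every window's series (contiguous circular
    blocks sized by the series' integrated autocorrelation time, or a custom
    ``resampler``), re-runs WHAM warm-started from the point estimate, and is
    gauge-aligned to it; the error is the per-bin standard deviation across
    replicates.  Deterministic for a given ``seed``.  Extra keyword arguments
    are forwarded to :func:`wham_pmf` and must pin ``range``/``bins`` if the
    sample span varies under resampling.
    """
    if n_boot < 2:
        raise InputError(f"need n_boot >= 2, got {n_boot}")
    windows = list(windows)
    if resampler is None:
        resampler = _block_resample

    base = wham_pmf(windows, **wham_kwargs)
    wham_kwargs = dict(wham_kwargs)
    if "range" not in wham_kwargs or wham_kwargs["range"] is None:
        wham_kwargs["range"] = (float(base.grid[0] - (base.grid[1] - base.grid[0]) / 2),
                                float(base.grid[-1] + (base.grid[1] - base.grid[0]) / 2))
    wham_kwargs.setdefault("bins", base.grid.size)
    wham_kwargs["initial_window_free_energies"] = base.window_free_energies

    rng = np.random.default_rng(seed)
    replicates = np.full((n_boot, base.grid.size), np.nan)
    for r in builtins.range(n_boot):
        resampled = [
            UmbrellaWindow(
                center=w.center,
                force_constant=w.force_constant,
                samples=resampler(rng, w.samples),
            )
            for w in windows
        ]
        prof = wham_pmf(resampled, **wham_kwargs)
        replicates[r] = gauge_align(prof.free_energy, base.free_energy)
    return np.nanstd(replicates, axis=0, ddof=1)


def wham_with_errors(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 200,
    seed: int | None = None,
    **wham_kwargs,
) -> PMFProfile:
    """Point-estimate PMF with bootstrap error bars attached."""
    profile = wham_pmf(windows, **wham_kwargs)
    dx = profile.grid[1] - profile.grid[0]
    wham_kwargs = dict(wham_kwargs)
    wham_kwargs["range"] = (
        float(profile.grid[0] - dx / 2),
        float(profile.grid[-1] + dx / 2),
    )
    wham_kwargs["bins"] = profile.grid.size
    profile.errors = bootstrap_pmf_errors(
        windows, n_boot=n_boot, seed=seed, **wham_kwargs
    )
    return profile


# ---------------------------------------------------------------------------
# window file I/O (the layout emitted by common MD engines' pull modules)
# ---------------------------------------------------------------------------


def read_window_series(path: str | os.PathLike) -> np.ndarray:
    """Reaction-coordinate column of a two-column whitespace time/xi file (nm)."""
    data = np.loadtxt(path, comments=("#", "@"), ndmin=2)
    if data.shape[1] < 2:
        raise InputError(f"{path}: expected two whitespace-delimited columns")
    return data[:, 1]


def load_windows(metadata_path: str | os.PathLike) -> list[UmbrellaWindow]:
    """Load umbrella windows from a metadata TSV.

    Columns: ``series_path`` (relative to the metadata file), ``center_nm``,
    ``force_constant_kJ_per_mol_nm2``.  Each series file is two whitespace
    columns: time, xi (nm).
    """
    meta = pd.read_csv(metadata_path, sep="\t", comment="#",
                       float_precision="round_trip")
    required = {"series_path", "center_nm", "force_constant_kJ_per_mol_nm2"}
    if not required.issubset(meta.columns):
        raise ConfigurationError(
            f"{metadata_path}: window metadata needs columns {sorted(required)}"
        )
    root = os.path.dirname(os.path.abspath(metadata_path))
    return [
        UmbrellaWindow(
            center=float(row.center_nm),
            force_constant=float(row.force_constant_kJ_per_mol_nm2),
            samples=read_window_series(os.path.join(root, str(row.series_path))),
        )
        for row in meta.itertuples()
    ]
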