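"""Free-energy profiles on the energy-gap coordinate.

The pipeline is the classic EVB/FEP/umbrella-sampling combination:

1. ``fep_accumulate`` — Zwanzig exponential averaging between adjacent
   mapping-potential windows gives ΔG(λm).  Only energy *differences*
   enter the exponent, so the huge state-independent environment term
   cancels identically; this module exploits that by computing the energy
   gap directly from the solute components.
2. ``umbrella_bin`` — each window's samples are reweighted from the
   mapping potential onto the ground-state surface and histogrammed on
   the energy gap X, giving the ground-state profile ΔGg(Xk); windows
   contributing to a bin are combined with normalized statistical weights
   pm (bin-wise sample-count fractions).
3. ``aggregate_replicates`` — profiles from independent replicate
   simulations are averaged; the replicate is the unit of error, so the
   per-bin s.e.m. comes from the scatter of replicate-level profiles.
4. ``locate_stationary_points`` — reactant, transition and product bins
   from the aggregated profile; ΔG‡ and ΔG0 read between them.
5. ``coverage_filter`` — replicates that never traverse the region
   between the reactant and product bins ("trapped" replicas) are dropped
   before any averaging.

All free energies are kcal/mol and referenced to the profile's global
minimum bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .evb_core import EVBModel, coupling_value
from .thermo import R_KCAL

__all__ = [
    "LambdaSchedule",
    "WindowSamples",
    "FreeEnergyProfile",
    "ActivationFreeEnergy",
    "CoverageReport",
    "NoBarrierError",
    "windows_from_replicate",
    "windows_from_records",
    "default_bin_edges",
    "fep_accumulate",
    "umbrella_bin",
    "aggregate_replicates",
    "locate_stationary_points",
    "coverage_filter",
    "replicate_x_samples",
]


class NoBarrierError(RuntimeError):
    """Raised when a free-energy profile has no interior maximum."""


def nan_mean_sem(stack: np.ndarray):
    """Column-wise mean and s.e.m. ignoring NaNs, without degenerate-slice
    warnings.  Returns (mean, sem, n) with NaN where undefined."""
    finite = np.isfinite(stack)
    n = finite.sum(axis=0)
    filled = np.where(finite, stack, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
        ss = np.where(finite, (stack - mean) ** 2, 0.0).sum(axis=0)
        sd = np.where(n > 1, np.sqrt(ss / np.maximum(n - 1, 1)), np.nan)
        sem = np.where(n > 1, sd / np.sqrt(n), np.nan)
    return mean, sem, n


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered mapping-parameter values; endpoints 0 and 1 mandatory."""

    values: tuple
    launch: float = 0.5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) < 2 or np.any(np.diff(v) <= 0):
            raise ValueError("lambda schedule must be strictly increasing with >= 2 windows")
        if v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("lambda schedule must contain both endpoints 0 and 1")
        if not 0.0 <= self.launch <= 1.0:
            raise ValueError("launch point must lie in [0, 1]")

    @classmethod
    def linear(cls, n_windows: int, launch: float = 0.5) -> "LambdaSchedule":
        return cls(values=tuple(np.linspace(0.0, 1.0, n_windows)), launch=launch)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class WindowSamples:
    """Samples of one (replicate, λ, T) window.

    Stores the raw component energies plus the EVB model; h11/h22/Eg/Umap/X
    are derived on demand.  X and the umbrella log-weight are computed from
    solute components only, so the state-independent u_ss cancels exactly
    (bitwise) rather than by floating-point subtraction of ~1e4-scale terms.
    """

    lam: float
    u1_rr: np.ndarray
    u1_rs: np.ndarray
    u2_rr: np.ndarray
    u2_rs: np.ndarray
    u_ss: np.ndarray
    model: EVBModel
    temperature: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.u1_rr)
        if not all(len(getattr(self, f)) == n for f in ("u1_rs", "u2_rr", "u2_rs", "u_ss")):
            raise ValueError("window sample arrays must have equal lengths")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")

    @property
    def n(self) -> int:
        return len(self.u1_rr)

    def x(self) -> np.ndarray:
        """Energy gap X = U1 − U2 (Δα included), free of u_ss by construction."""
        return (self.u1_rr + self.u1_rs) - (self.u2_rr + self.u2_rs) - self.model.delta_alpha

    def h12(self, x: Optional[np.ndarray] = None) -> np.ndarray:
        x = self.x() if x is None else x
        gap = x if self.model.coupling_gap_includes_shift else x + self.model.delta_alpha
        return np.asarray(coupling_value(gap, self.model.coupling))

    def h11(self) -> np.ndarray:
        return self.u1_rr + self.u1_rs + self.u_ss

    def h22(self) -> np.ndarray:
        return self.u2_rr + self.u2_rs + self.u_ss + self.model.delta_alpha

    def umap(self) -> np.ndarray:
        return (1.0 - self.lam) * self.h11() + self.lam * self.h22()

    def eg(self) -> np.ndarray:
        """Absolute ground-state energy (contains the full u_ss term)."""
        return self.eg_solute() + self.u_ss

    def eg_solute(self) -> np.ndarray:
        """Eg − u_ss, the exactly separable solute-mixed part of Eg."""
        x = self.x()
        return 0.5 * (
            self.u1_rr + self.u1_rs + self.u2_rr + self.u2_rs + self.model.delta_alpha
        ) - 0.5 * np.hypot(x, 2.0 * self.h12(x))

    def eg_minus_umap(self) -> np.ndarray:
        """Eg − Umap via the u_ss-free identity (λ−½)·X − ½·sqrt(X²+4·H12²)."""
        x = self.x()
        return (self.lam - 0.5) * x - 0.5 * np.hypot(x, 2.0 * self.h12(x))


def windows_from_replicate(data, model: EVBModel, equil_fraction: float = 0.1) -> List[WindowSamples]:
    """WindowSamples from a toy-system ReplicateData, dropping the first
    ``equil_fraction`` of each window's samples as analysis equilibration."""
    if not 0.0 <= equil_fraction < 1.0:
        raise ValueError("equil_fraction must lie in [0, 1)")
    out = []
    for wc in data.windows:
        k = int(equil_fraction * wc.n)
        out.append(
            WindowSamples(
                lam=wc.lam,
                u1_rr=wc.u1_rr[k:],
                u1_rs=wc.u1_rs[k:],
                u2_rr=wc.u2_rr[k:],
                u2_rs=wc.u2_rs[k:],
                u_ss=wc.u_ss[k:],
                model=model,
                temperature=data.temperature,
            )
        )
    return out


def windows_from_records(df, model: EVBModel, equil_fraction: float = 0.1) -> Dict[int, List[WindowSamples]]:
    """Group an energy-record table into per-replicate, λ-ordered windows.

    ``df`` is the EnergyRecordFile table (see io_cli); samples are ordered
    by step within each window before the equilibration fraction is cut.
    """
    out: Dict[int, List[WindowSamples]] = {}
    for rep, rep_df in df.groupby("replicate", sort=True):
        wins = []
        for lam, w in rep_df.groupby("lambda", sort=True):
            w = w.sort_values("step")
            k = int(equil_fraction * len(w))
            w = w.iloc[k:]
            wins.append(
                WindowSamples(
                    lam=float(lam),
                    u1_rr=w["u1_rr"].to_numpy(),
                    u1_rs=w["u1_rs"].to_numpy(),
                    u2_rr=w["u2_rr"].to_numpy(),
                    u2_rs=w["u2_rs"].to_numpy(),
                    u_ss=w["u_ss"].to_numpy(),
                    model=model,
                    temperature=float(w["temperature_K"].iloc[0]),
                )
            )
        out[int(rep)] = wins
    return out


def default_bin_edges(windows_by_replicate: Mapping[int, Sequence[WindowSamples]], n_bins: int = 50) -> np.ndarray:
    """Uniform bins covering the sampled X range ((X range)/n_bins width)."""
    lo, hi = math.inf, -math.inf
    for wins in windows_by_replicate.values():
        for w in wins:
            x = w.x()
            lo = min(lo, float(x.min()))
            hi = max(hi, float(x.max()))
    return np.linspace(lo, hi, n_bins + 1)


def fep_accumulate(windows: Sequence[WindowSamples], T: float) -> np.ndarray:
    """Forward FEP accumulation: ΔG(λm) relative to the first window.

    ΔG(λm) = −β⁻¹ Σ_{n<m} ln⟨exp(−β·ΔUmap)⟩ₙ with ΔUmap evaluated per
    sample of window n; since ΔUmap = −Δλ·X the environment term never
    enters.  Exponentials are stabilized by log-sum-exp, never clipped.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows for FEP accumulation")
    lams = np.array([w.lam for w in windows])
    if np.any(np.diff(lams) <= 0):
        raise ValueError("windows must be ordered strictly increasing in lambda")
    for w in windows:
        if w.n == 0:
            raise ValueError(f"window lam={w.lam} has no samples")
    beta = 1.0 / (R_KCAL * T)
    dg = np.zeros(len(windows))
    acc = 0.0
    for m in range(len(windows) - 1):
        dlam = lams[m + 1] - lams[m]
        expo = beta * dlam * windows[m].x()  # −β·ΔUmap = −β·(−Δλ·X)
        acc += -(logsumexp(expo) - math.log(len(expo))) / beta
        dg[m + 1] = acc
    return dg


@dataclass
class FreeEnergyProfile:
    """Binned ground-state free-energy profile ΔGg(Xk).

    ``dg`` is NaN in unpopulated bins and referenced so the minimum
    populated bin is zero; ``low_count`` flags populated bins with fewer
    samples than the reporting threshold (they are never interpolated).
    ``sem`` is present only after replicate aggregation.
    """

    bin_edges: np.ndarray
    dg: np.ndarray
    counts: np.ndarray
    low_count: np.ndarray
    sem: Optional[np.ndarray] = None
    n_replicates: int = 1
    replicate_support: Optional[np.ndarray] = None  # bins' populating-replicate counts

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def populated(self) -> np.ndarray:
        return np.isfinite(self.dg)


def umbrella_bin(
    windows: Sequence[WindowSamples],
    dg_lam: np.ndarray,
    T: float,
    bin_edges: np.ndarray,
    estimator: str = "delta",
    min_count: int = 10,
) -> FreeEnergyProfile:
    """Umbrella correction onto the ground-state surface for one replicate.

    Per bin k and window m the estimator is
    ΔG(λm) − β⁻¹·ln⟨1[X∈k]·exp(−β(Eg−Umap))⟩ₘ, the average running over
    ALL samples of window m ("delta" form, which carries the bin
    probability); ``estimator="within_bin"`` restricts the average to the
    in-bin samples (diagnostic alternative, losing the −β⁻¹·ln pₘ(k)
    term).  Window contributions are combined with weights pm equal to the
    window's share of the bin's samples, and the profile is referenced to
    its global minimum bin.
    """
    if estimator not in ("delta", "within_bin"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if len(dg_lam) != len(windows):
        raise ValueError("dg_lam length must match number of windows")
    beta = 1.0 / (R_KCAL * T)
    nbins = len(bin_edges) - 1
    counts = np.zeros(nbins, dtype=np.int64)
    num = np.zeros(nbins)  # Σ_m n_mk · term_mk
    for m, w in enumerate(windows):
        x = w.x()
        logw = -beta * w.eg_minus_umap()
        idx = np.digitize(x, bin_edges) - 1
        inside = (idx >= 0) & (idx < nbins)
        idx, logw = idx[inside], logw[inside]
        if idx.size == 0:
            continue
        n_mk = np.bincount(idx, minlength=nbins)
        # per-bin log-sum-exp: shift by each bin's max before exponentiating
        bin_max = np.full(nbins, -np.inf)
        np.maximum.at(bin_max, idx, logw)
        sums = np.bincount(idx, weights=np.exp(logw - bin_max[idx]), minlength=nbins)
        occ = n_mk > 0
        lse = np.zeros(nbins)
        lse[occ] = bin_max[occ] + np.log(sums[occ])
        if estimator == "delta":
            log_avg = lse[occ] - math.log(w.n)
        else:
            log_avg = lse[occ] - np.log(n_mk[occ])
        term = dg_lam[m] - log_avg / beta
        num[occ] += n_mk[occ] * term
        counts += n_mk
    populated = counts > 0
    if populated.sum() < 3:
        raise ValueError(f"free-energy profile has only {int(populated.sum())} populated bins")
    dg = np.full(nbins, np.nan)
    dg[populated] = num[populated] / counts[populated]  # Σ pm·term
    dg -= np.nanmin(dg)
    return FreeEnergyProfile(
        bin_edges=np.asarray(bin_edges, dtype=float),
        dg=dg,
        counts=counts,
        low_count=populated & (counts < min_count),
    )


def aggregate_replicates(profiles: Sequence[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Per-bin mean and s.e.m. over replicate profiles.

    Replicates are the unit of error: the s.e.m. is the standard deviation
    of the replicate-level bin values divided by √(number of replicates
    populating the bin).  All profiles must share identical bin edges.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to aggregate")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if not np.array_equal(p.bin_edges, edges):
            raise ValueError("profiles have mismatched bin edges")
    stack = np.vstack([p.dg for p in profiles])
    counts = np.vstack([p.counts for p in profiles]).sum(axis=0)
    mean, sem, n_pop = nan_mean_sem(stack)
    mean -= np.nanmin(mean)
    low = np.vstack([p.low_count for p in profiles]).any(axis=0)
    return FreeEnergyProfile(
        bin_edges=edges,
        dg=mean,
        counts=counts,
        low_count=low,
        sem=sem,
        n_replicates=len(profiles),
        replicate_support=n_pop,
    )


@dataclass(frozen=True)
class ActivationFreeEnergy:
    """ΔG‡ and ΔG0 read off a profile between its stationary bins."""

    bin_edges: np.ndarray
    rs_idx: int
    ts_idx: int
    ps_idx: int
    x_rs: float
    x_ts: float
    x_ps: float
    dg_act: float
    dg0: float
    dg_act_sem: Optional[float] = None
    dg0_sem: Optional[float] = None


def _extreme_index(values: np.ndarray, candidates: np.ndarray, centers: np.ndarray, mode: str, tie_ref: float) -> int:
    vals = values[candidates]
    target = np.nanmin(vals) if mode == "min" else np.nanmax(vals)
    ties = candidates[vals == target]
    # deterministic tie-break: bin whose center lies closest to tie_ref
    return int(ties[np.argmin(np.abs(centers[ties] - tie_ref))])


def locate_stationary_points(
    profile: FreeEnergyProfile,
    smooth_window: Optional[int] = None,
    tie_ref: float = 0.0,
) -> ActivationFreeEnergy:
    """Reactant, transition and product bins of a free-energy profile.

    The reactant (product) state is the lowest-ΔG populated bin at
    negative (positive) X; the transition state is the highest bin
    strictly between them.  ΔG‡ = ΔG(TS)−ΔG(RS), ΔG0 = ΔG(PS)−ΔG(RS);
    reported values are always taken from the raw profile.  An optional
    centered moving average of ``smooth_window`` bins is used for
    *locating* only.  Exact ties break toward the bin center nearest
    ``tie_ref`` (the energy gap of the launch region, 0 by convention).
    """
    centers = profile.centers
    pop = profile.populated
    if pop.sum() < 3:
        raise ValueError("need at least 3 populated bins")
    values = profile.dg.copy()
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        filled = np.where(pop, profile.dg, np.nan)
        # NaN-aware moving average for locating
        v = np.where(np.isfinite(filled), filled, 0.0)
        wgt = np.convolve(np.isfinite(filled).astype(float), kernel, mode="same")
        sm = np.convolve(v, kernel, mode="same")
        with np.errstate(invalid="ignore"):
            values = np.where(wgt > 0, sm / np.maximum(wgt, 1e-300), np.nan)
        values[~pop] = np.nan

    rs_side = np.flatnonzero(pop & (centers < 0))
    ps_side = np.flatnonzero(pop & (centers > 0))
    if rs_side.size == 0 or ps_side.size == 0:
        raise NoBarrierError("profile does not span both signs of the energy gap")
    rs = _extreme_index(values, rs_side, centers, "min", tie_ref)
    ps = _extreme_index(values, ps_side, centers, "min", tie_ref)
    interior = np.flatnonzero(pop)
    interior = interior[(interior > rs) & (interior < ps)]
    if interior.size == 0:
        raise NoBarrierError("no populated bins between reactant and product minima")
    ts = _extreme_index(values, interior, centers, "max", tie_ref)
    raw = profile.dg
    if not (raw[ts] > raw[rs] and raw[ts] > raw[ps]):
        raise NoBarrierError("profile is monotone between its end minima (no interior maximum)")
    sem_act = sem0 = None
    if profile.sem is not None:
        if np.isfinite(profile.sem[ts]) and np.isfinite(profile.sem[rs]):
            sem_act = float(np.hypot(profile.sem[ts], profile.sem[rs]))
        if np.isfinite(profile.sem[ps]) and np.isfinite(profile.sem[rs]):
            sem0 = float(np.hypot(profile.sem[ps], profile.sem[rs]))
    return ActivationFreeEnergy(
        bin_edges=profile.bin_edges,
        rs_idx=rs,
        ts_idx=ts,
        ps_idx=ps,
        x_rs=float(centers[rs]),
        x_ts=float(centers[ts]),
        x_ps=float(centers[ps]),
        dg_act=float(raw[ts] - raw[rs]),
        dg0=float(raw[ps] - raw[rs]),
        dg_act_sem=sem_act,
        dg0_sem=sem0,
    )


def replicate_x_samples(windows: Sequence[WindowSamples]) -> np.ndarray:
    """All energy-gap samples of one replicate, concatenated over windows."""
    return np.concatenate([w.x() for w in windows])


@dataclass
class CoverageReport:
    """Outcome of trapped-replicate filtering."""

    kept: List[int]
    dropped: List[int]
    coverage: Dict[int, float]
    required_span: float

    @property
    def fraction_dropped(self) -> float:
        total = len(self.kept) + len(self.dropped)
        return len(self.dropped) / total if total else 0.0


def coverage_filter(
    x_by_replicate: Mapping[int, np.ndarray],
    gact: ActivationFreeEnergy,
    required_span: float = 0.9,
) -> CoverageReport:
    """Drop replicates that fail to sample the reaction-coordinate span.

    A replicate is kept iff its X samples populate at least
    ``required_span`` of the bins between the aggregate profile's reactant
    and product bins (inclusive); replicas confined to a metastable
    conformation off the reaction path fail this and are excluded from all
    averages.
    """
    if not 0.0 < required_span <= 1.0:
        raise ValueError("required_span must lie in (0, 1]")
    edges = gact.bin_edges
    span_bins = np.arange(gact.rs_idx, gact.ps_idx + 1)
    kept, dropped, cov = [], [], {}
    for rep, x in x_by_replicate.items():
        idx = np.digitize(x, edges) - 1
        hit = np.intersect1d(idx, span_bins).size
        frac = hit / len(span_bins)
        cov[rep] = frac
        (kept if frac >= required_span else dropped).append(rep)
    if not kept:
        raise RuntimeError(
            "coverage filter dropped every replicate; revise the lambda schedule or sampling length"
        )
    return CoverageReport(kept=kept, dropped=dropped, coverage=cov, required_span=required_span)
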