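"""Two-state empirical valence bond (EVB) energetics.

The reacting system is described by two diabatic (valence-bond) states,
each a classical force field.  Every diagonal energy splits into three
additive parts: the internal energy of the reacting fragments (``u_rr``),
their interaction with the surroundings (``u_rs``) and the interactions
within the surroundings themselves (``u_ss``).  ``u_ss`` is identical for
both states — the environment does not change bonding topology — and is by
far the largest term for condensed-phase systems (order −4·10⁴ kcal/mol for
a solvated enzyme).  A constant gas-phase shift Δα is added to the second
(product-like) diagonal to set the absolute offset between the two states.

The adiabatic ground state is the lowest eigenvalue of the 2×2 Hamiltonian

    H = [[H11, H12], [H12, H22]],
    Eg = ½(H11+H22) − ½·sqrt((H11−H22)² + 4·H12²),

with coupling H12 either a constant A or a Gaussian in the energy gap,
A·exp(−b·ΔU²).  The energy-gap reaction coordinate is X = ΔU = U1 − U2
(after the Δα shift; ``u_ss`` cancels exactly in it).

All energies are kcal/mol; temperatures are Kelvin.  Functions accept
scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "EnergyComponents",
    "CouplingModel",
    "EVBModel",
    "MixingCoefficients",
    "diagonal_energies",
    "energy_gap",
    "coupling_value",
    "ground_state_energy",
    "mixing_coefficients",
    "mapping_potential",
    "ground_state_from_components",
]


def _require_finite(name: str, value: ArrayLike) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class EnergyComponents:
    """Per-configuration diabatic component energies (kcal/mol).

    ``u_ss`` is a single, state-independent value: it enters both diagonal
    energies once and therefore cancels in the energy gap.  Fields may be
    scalars or equally shaped arrays (one entry per sampled configuration).
    """

    u1_rr: ArrayLike
    u1_rs: ArrayLike
    u2_rr: ArrayLike
    u2_rs: ArrayLike
    u_ss: ArrayLike

    def __post_init__(self) -> None:
        for name in ("u1_rr", "u1_rs", "u2_rr", "u2_rs", "u_ss"):
            _require_finite(name, getattr(self, name))


@dataclass(frozen=True)
class CouplingModel:
    """Off-diagonal EVB element H12.

    form="constant": H12 = A.
    form="gaussian": H12 = A·exp(−b·ΔU²), with b in (kcal/mol)⁻²; reduces
    to the constant form at b = 0.
    """

    form: str = "constant"
    A: float = 0.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("constant", "gaussian"):
            raise ValueError(f"unknown coupling form {self.form!r}")
        if self.A < 0 or not np.isfinite(self.A):
            raise ValueError(f"coupling amplitude A must be finite and >= 0, got {self.A}")
        if self.b < 0 or not np.isfinite(self.b):
            raise ValueError(f"gaussian width parameter b must be finite and >= 0, got {self.b}")


@dataclass(frozen=True)
class EVBModel:
    """EVB parameters mapping component energies to the ground state.

    ``coupling_gap_includes_shift`` controls whether the ΔU fed into a
    Gaussian H12 includes the Δα shift (default) or is the raw diabatic
    difference; irrelevant for constant coupling.
    """

    delta_alpha: float = 0.0
    coupling: CouplingModel = field(default_factory=CouplingModel)
    coupling_gap_includes_shift: bool = True

    def __post_init__(self) -> None:
        _require_finite("delta_alpha", self.delta_alpha)


@dataclass(frozen=True)
class MixingCoefficients:
    """Normalized ground-state eigenvector (c1, c2); c1² + c2² = 1."""

    c1: ArrayLike
    c2: ArrayLike


def diagonal_energies(comp: EnergyComponents, model: EVBModel):
    """Diagonal EVB energies (H11, H22) from component energies.

    H11 = u1_rr + u1_rs + u_ss and H22 = u2_rr + u2_rs + u_ss + Δα.  The
    Δα shift is applied here (state 2 only) so that stored records remain
    raw force-field terms re-analyzable under any EVB parameter set.
    """
    h11 = np.asarray(comp.u1_rr) + comp.u1_rs + comp.u_ss
    h22 = np.asarray(comp.u2_rr) + comp.u2_rs + comp.u_ss + model.delta_alpha
    if h11.ndim == 0:
        return float(h11), float(h22)
    return h11, h22


def energy_gap(h11: ArrayLike, h22: ArrayLike) -> ArrayLike:
    """Energy-gap reaction coordinate X = ΔU = U1 − U2 = H11 − H22.

    The state-independent u_ss cancels; with ``diagonal_energies`` this
    includes the Δα shift, matching the ΔU fed to the Gaussian coupling.
    """
    _require_finite("h11", h11)
    _require_finite("h22", h22)
    return np.asarray(h11) - h22 if np.ndim(h11) or np.ndim(h22) else h11 - h22


def coupling_value(delta_u: ArrayLike, c: CouplingModel) -> ArrayLike:
    """Evaluate H12 at energy gap ΔU; always in [0, A]."""
    if c.form == "constant":
        return np.full_like(np.asarray(delta_u, dtype=float), c.A) if np.ndim(delta_u) else c.A
    out = c.A * np.exp(-c.b * np.square(delta_u))
    return out if np.ndim(delta_u) else float(out)


def ground_state_energy(h11: ArrayLike, h22: ArrayLike, h12: ArrayLike) -> ArrayLike:
    """Lowest eigenvalue of the 2×2 EVB Hamiltonian.

    Eg = ½(H11+H22) − ½·sqrt((H11−H22)² + 4·H12²) ≤ min(H11, H22), with
    equality exactly when H12 = 0.
    """
    _require_finite("h11", h11)
    _require_finite("h22", h22)
    _require_finite("h12", h12)
    h11 = np.asarray(h11, dtype=float)
    gap = h11 - h22
    eg = 0.5 * (h11 + h22) - 0.5 * np.hypot(gap, 2.0 * np.asarray(h12))
    return eg if eg.ndim else float(eg)


def mixing_coefficients(h11: float, h22: float, h12: float) -> MixingCoefficients:
    """Normalized ground-state eigenvector of the 2×2 Hamiltonian.

    Solves (H − Eg)·c = 0 using the numerically stable branch; undefined
    (raises) in the fully degenerate case H11 = H22 with H12 = 0.
    """
    _require_finite("h11", h11)
    _require_finite("h22", h22)
    _require_finite("h12", h12)
    if h11 == h22 and h12 == 0.0:
        raise ValueError("degenerate Hamiltonian (h11 == h22, h12 == 0): eigenvector undefined")
    eg = ground_state_energy(h11, h22, h12)
    # Pick the component guaranteed away from zero: the ground state leans
    # toward the lower diabat.
    if h11 <= h22:
        c1 = h12
        c2 = eg - h11
        if c1 == 0.0 and c2 == 0.0:  # h12 == 0, pure state 1
            c1, c2 = 1.0, 0.0
    else:
        c2 = h12
        c1 = eg - h22
        if c1 == 0.0 and c2 == 0.0:
            c1, c2 = 0.0, 1.0
    norm = float(np.hypot(c1, c2))
    return MixingCoefficients(c1=c1 / norm, c2=c2 / norm)


def ground_state_from_components(comp: EnergyComponents, model: EVBModel):
    """Convenience: (h11, h22, x, h12, eg) from raw component energies.

    ``x`` is the energy-gap coordinate h11 − h22 (Δα included).  The H12
    argument follows ``model.coupling_gap_includes_shift``.
    """
    h11, h22 = diagonal_energies(comp, model)
    x = energy_gap(h11, h22)
    gap_for_coupling = x if model.coupling_gap_includes_shift else np.asarray(x) + model.delta_alpha
    h12 = coupling_value(gap_for_coupling, model.coupling)
    eg = ground_state_energy(h11, h22, h12)
    return h11, h22, x, h12, eg


def mapping_potential(h11: ArrayLike, h22: ArrayLike, lam: float) -> ArrayLike:
    """Linear mapping ("umbrella") potential Umap = (1−λ)·H11 + λ·H22.

    λ ∈ [0, 1] drags sampling from the reactant diabat (λ=0) to the
    product diabat (λ=1).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = (1.0 - lam) * np.asarray(h11, dtype=float) + lam * np.asarray(h22)
    return out if out.ndim else float(out)
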