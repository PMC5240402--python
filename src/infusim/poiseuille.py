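"""Poiseuille mixing operators: kernel weights, stretch, tip convolution.

Laminar tube flow has a parabolic velocity profile whose centerline moves
at twice the average velocity.  A pattern of voxels entering at M is
therefore stretched axially (factor two along the centerline) and smeared
by the time it reaches the tip P.  In the discrete (Z-domain) picture the
tip composition is the convolution of the two-fold stretched entry
sequence b (b_{2j} = a_j^diff) with the geometric weight kernel

    w_i = gamma * L / (gamma*i + L)^2 ,

plus a slowly decaying *remnant* term L/(L + gamma*k) carrying the old
mixture retained near the wall.  In the Z-domain the convolution is the
product  Psi(z) = A_diff(z^2) * W(z), whose moments follow from z-derivatives
at z -> 1 without an inverse transform.

Index-to-time convention: one stretched index corresponds to *half* an
entry-voxel duration, dt_pois = gamma V_cath / (2 L u_final).  This is the
centerline mapping under which the remnant's 1/(L+gamma k) decay equals the
exact parabolic-shell kinematics L/(2 lambda) and the first arrival falls
at t_delay/2; see docs/methods.md for the relation to the closed-form
width expressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .catheter import EntrySequence
from .config import CatheterSpec

__all__ = [
    "PoiseuilleKernel",
    "TipBolus",
    "kernel",
    "stretch",
    "tip_convolution",
    "z_product_moments",
    "sequence_moments",
]


@dataclass(frozen=True)
class PoiseuilleKernel:
    """Truncated geometric weight kernel w_i = gamma L / (gamma i + L)^2."""

    weights: np.ndarray
    gamma: float
    length: float
    k_max: int

    def total(self) -> float:
        return float(self.weights.sum())

    def analytic_total(self) -> float:
        """Closed-form partial sum bound: 1 - L/(gamma k_max + L)."""
        return 1.0 - self.length / (self.gamma * self.k_max + self.length)


def kernel(catheter: CatheterSpec, k_max: int) -> PoiseuilleKernel:
    if k_max < catheter.n_voxels:
        raise ValueError("kernel truncation k_max must cover at least N voxels")
    i = np.arange(k_max + 1, dtype=float)
    g, L = catheter.gamma, catheter.length
    w = g * L / (g * i + L) ** 2
    return PoiseuilleKernel(weights=w, gamma=g, length=L, k_max=k_max)


def stretch(entry: EntrySequence | np.ndarray, mode: str = "half") -> np.ndarray:
    """Two-fold stretched sequence b from the entry deviations a_diff.

    ``mode="half"`` (default): zero-order hold with mass preserved,
    b_{2j} = b_{2j+1} = a_j / 2 (zeroth sum of b equals that of a).
    ``mode="copy"``: plain value hold b_{2j} = b_{2j+1} = a_j, appropriate
    when the sequence is a *fraction* profile resampled onto the half-step
    grid (as in :func:`tip_convolution`).
    ``mode="strict"``: b_{2j} = a_j, zeros at odd indices — the literal
    B(z) = A(z^2) substitution used by :func:`z_product_moments`.
    """
    a = entry.a_diff if isinstance(entry, EntrySequence) else np.asarray(entry, float)
    b = np.zeros(2 * len(a), dtype=float)
    if mode == "half":
        b[0::2] = 0.5 * a
        b[1::2] = 0.5 * a
    elif mode == "copy":
        b[0::2] = a
        b[1::2] = a
    elif mode == "strict":
        b[0::2] = a
    else:
        raise ValueError(f"unknown stretch mode {mode!r}")
    return b


@dataclass
class TipBolus:
    """Discrete tip composition of the dosing-error bolus.

    ``psi_pois[k]`` is the convolution (compliance) part and
    ``psi_remnant[k]`` the old-mixture remnant part of the deviation
    fraction in the tip voxel at stretched index k; the full patient-side
    fraction is their sum.  ``dt_per_index`` converts index to seconds
    after the first arrival t_delay_pois; ``u_final`` converts fraction to
    flow.
    """

    psi_pois: np.ndarray
    psi_remnant: np.ndarray
    dt_per_index: float
    u_final: float
    truncation_index: int

    @property
    def psi_patient(self) -> np.ndarray:
        return self.psi_pois + self.psi_remnant

    def times(self) -> np.ndarray:
        return np.arange(len(self.psi_pois)) * self.dt_per_index

    def to_dataframe(self) -> pd.DataFrame:
        k = np.arange(len(self.psi_pois))
        return pd.DataFrame(
            {
                "k": k,
                "tau_s": k * self.dt_per_index,
                "psi_pois": self.psi_pois,
                "psi_remnant": self.psi_remnant,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def remnant_profile(
    k: np.ndarray,
    gamma: float,
    length: float,
    u_unchanged: float,
    u_old_other: float,
    u_final_other: float,
) -> np.ndarray:
    """Old-mixture remnant fraction at stretched index k.

    L/(L + gamma k) times the mixing-ratio change of the monitored fluid
    between the old and the new steady mixture.  Independent of compliances
    and resistances.
    """
    amp = (
        u_unchanged
        * (u_final_other - u_old_other)
        / ((u_final_other + u_unchanged) * (u_old_other + u_unchanged))
    )
    return length / (length + gamma * np.asarray(k, float)) * amp


def tip_convolution(
    entry: EntrySequence,
    kern: PoiseuilleKernel,
    u_unchanged: float,
    u_old_other: float,
    u_final_other: float,
) -> TipBolus:
    """Convolve the stretched entry deviations with the Poiseuille kernel.

    The entry fractions are value-held onto the half-step grid
    (``stretch(..., "copy")``) and convolved with w; the remnant profile is
    added alongside.  Mass bookkeeping: with the half-step measure
    dt_pois = dt/2, the convolution part integrates to the same
    dosing-error volume Q as the plug-flow sequence.
    """
    if abs(kern.gamma - entry.gamma) > 1e-12 * entry.gamma:
        raise ValueError("kernel and entry sequence use different voxel sizes")
    b = stretch(entry, mode="copy")
    k_out = kern.k_max + 1
    psi = fftconvolve(b, kern.weights)[:k_out]
    if np.all(b >= 0):
        # FFT round-off can leave tiny negative values on a non-negative input
        np.clip(psi, 0.0, None, out=psi)
    k = np.arange(k_out)
    rem = remnant_profile(
        k, entry.gamma, entry.length, u_unchanged, u_old_other, u_final_other
    )
    return TipBolus(
        psi_pois=psi,
        psi_remnant=rem,
        dt_per_index=0.5 * entry.dt_per_index,
        u_final=entry.u_final,
        truncation_index=kern.k_max,
    )


def sequence_moments(seq: np.ndarray) -> dict[str, float]:
    """Index-weighted sums m0, m1, m2 of a sequence (z-derivatives at z=1)."""
    seq = np.asarray(seq, dtype=float)
    k = np.arange(len(seq), dtype=float)
    return {
        "m0": float(seq.sum()),
        "m1": float((k * seq).sum()),
        "m2": float((k * k * seq).sum()),
    }


def z_product_moments(entry: EntrySequence, kern: PoiseuilleKernel) -> dict[str, float]:
    """Moments of Psi(z) = A_diff(z^2) W(z) by the product rule at z -> 1.

    With the literal stretch (zeros at odd indices) the moments of the
    convolution follow from those of the factors:

        m0 = m0(A) m0(W)
        m1 = 2 m1(A) m0(W) + m0(A) m1(W)        (factor 2 from z^2)
        m2 = 4 m2(A) m0(W) + 4 m1(A) m1(W) + m0(A) m2(W)

    equivalent to evaluating z d/dz derivatives at z = 1 as finite
    index-weighted sums.
    """
    ma = sequence_moments(entry.a_diff)
    mw = sequence_moments(kern.weights)
    return {
        "m0": ma["m0"] * mw["m0"],
        "m1": 2.0 * ma["m1"] * mw["m0"] + ma["m0"] * mw["m1"],
        "m2": 4.0 * ma["m2"] * mw["m0"] + 4.0 * ma["m1"] * mw["m1"] + ma["m0"] * mw["m2"],
    }
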