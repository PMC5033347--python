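"""Equilibrium model of sexually-antagonistic viability selection.

A biallelic autosomal locus has genotype viabilities 1 : 1 + h·S : 1 + S
(aa : Aa : AA) in each sex, with sex-specific S and h.  The additive
fitness effect of allele A at zygote frequency p is

    s = [p + (q - p)·h] · S,        q = 1 - p

and, to first order in s, viability selection shifts the adult frequency
to p + p·q·s.  The between-sex divergence this produces within one
generation is F_ST ≈ (1/4)·p·q·(s_m - s_f)².

Selection is tied to expression by assuming fitness effects grow linearly
with log-scaled expression, s_m = a_m·M and s_f = a_f·F with
M = ln(m + 1), F = ln(f + 1).  At a sexually-antagonistic equilibrium
(s_m = -s_f) the model collapses to the prediction

    F_ST ≈ 4·p·q·A·Δ²,     A = (a_m·a_f / (a_m + a_f))²

for small bias, where Δ = (m - f)/(m + f).  The same equilibrium yields a
true mortality load: L_SA per locus, combining multiplicatively across
independent loci.

All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: tolerance below which a_m + a_f is treated as singular
_SINGULAR_TOL = 1e-12


class SingularSensitivityError(ZeroDivisionError):
    """a_m ≈ -a_f: the SA potential A diverges while F_ST stays finite.

    Compute divergence through the additive effects directly
    (``fst_from_effects``) instead of through ``sa_potential``.
    """


@dataclass
class SelectionParams:
    """Sex-specific viability-selection and dominance coefficients."""

    S_m: float
    S_f: float
    h_m: float = 0.5
    h_f: float = 0.5

    def additive_effects(self, p: float):
        return (additive_effect(p, self.S_m, self.h_m),
                additive_effect(p, self.S_f, self.h_f))


@dataclass
class LoadResult:
    """Mortality excesses per sex and the resulting selection load."""

    mu_m: float
    mu_f: float
    L_SA: float


def additive_effect(p, S, h):
    """Additive fitness effect s = [p + (q - p)·h]·S of allele A."""
    p = np.asarray(p, dtype=float)
    out = (p + (1.0 - 2.0 * p) * np.asarray(h, dtype=float)) * np.asarray(S, dtype=float)
    return out[()] if out.ndim == 0 else out


def adult_frequency(p, s):
    """First-order adult frequency p + p·q·s after viability selection.

    Neglects terms of order s²; results falling outside [0, 1] are clipped
    with a warning (supports stress tests at large s).
    """
    p = np.asarray(p, dtype=float)
    out = p + p * (1.0 - p) * np.asarray(s, dtype=float)
    if np.any(out < 0) or np.any(out > 1):
        warnings.warn("first-order adult frequency clipped to [0, 1]", RuntimeWarning)
        out = np.clip(out, 0.0, 1.0)
    return out[()] if out.ndim == 0 else out


def exact_adult_frequency(p, S, h):
    """Exact adult frequency under viabilities 1 : 1+hS : 1+S.

    Hardy-Weinberg zygote genotype frequencies are weighted by viability
    and renormalised; serves as the brute-force oracle for the first-order
    approximation ``adult_frequency``.
    """
    p = np.asarray(p, dtype=float)
    S = np.asarray(S, dtype=float)
    h = np.asarray(h, dtype=float)
    q = 1.0 - p
    num = p**2 * (1.0 + S) + p * q * (1.0 + h * S)
    den = 1.0 + S * (p**2 + 2.0 * p * q * h)
    out = num / den
    return out[()] if out.ndim == 0 else out


def fst_from_effects(p, s_m, s_f):
    """Between-sex F_ST ≈ (1/4)·p·q·(s_m - s_f)² from additive effects."""
    p = np.asarray(p, dtype=float)
    out = 0.25 * p * (1.0 - p) * (np.asarray(s_m, dtype=float) - np.asarray(s_f, dtype=float)) ** 2
    return out[()] if out.ndim == 0 else out


def expression_to_effects(m, f, a_m, a_f):
    """(s_m, s_f) = (a_m·ln(m+1), a_f·ln(f+1)): selection from expression."""
    m = np.asarray(m, dtype=float)
    f = np.asarray(f, dtype=float)
    s_m = np.asarray(a_m, dtype=float) * np.log1p(m)
    s_f = np.asarray(a_f, dtype=float) * np.log1p(f)
    return (s_m[()] if s_m.ndim == 0 else s_m, s_f[()] if s_f.ndim == 0 else s_f)


def _check_singular(a_m, a_f):
    if np.any(np.abs(np.asarray(a_m, dtype=float) + np.asarray(a_f, dtype=float)) < _SINGULAR_TOL):
        raise SingularSensitivityError(
            "a_m + a_f ~ 0: SA potential undefined; use fst_from_effects with the "
            "additive effects directly (the limit forces Δ -> 0 with finite s_m)"
        )


def sa_potential(a_m, a_f):
    """SA potential A = (a_m·a_f / (a_m + a_f))²."""
    _check_singular(a_m, a_f)
    a_m = np.asarray(a_m, dtype=float)
    a_f = np.asarray(a_f, dtype=float)
    out = (a_m * a_f / (a_m + a_f)) ** 2
    return out[()] if out.ndim == 0 else out


def equilibrium_ratio(a_m, a_f):
    """T/D ratio (a_f - a_m)/(a_f + a_m) implied by s_m = -s_f."""
    _check_singular(a_m, a_f)
    a_m = np.asarray(a_m, dtype=float)
    a_f = np.asarray(a_f, dtype=float)
    out = (a_f - a_m) / (a_f + a_m)
    return out[()] if out.ndim == 0 else out


def predicted_fst(p, A, delta):
    """Small-bias model prediction F_ST = 4·p·q·A·Δ².

    Zero at Δ = 0 and quadratic in Δ near it; the model separately forces
    divergence to zero at complete bias (no expression in one sex means no
    selection in that sex and, at equilibrium, none in the other either).
    """
    p = np.asarray(p, dtype=float)
    out = 4.0 * p * (1.0 - p) * np.asarray(A, dtype=float) * np.asarray(delta, dtype=float) ** 2
    return out[()] if out.ndim == 0 else out


def delta_from_D(D):
    """Small-bias approximation Δ ≈ D/2 with D = M - F the log-expression
    difference (Taylor expansion of Δ ≈ ½·ln(m/f) for weak bias)."""
    out = np.asarray(D, dtype=float) / 2.0
    return out[()] if out.ndim == 0 else out


def sa_load(p, S_m, h_m=0.5, h_f=0.5) -> LoadResult:
    """Per-locus mortality load at a sexually-antagonistic equilibrium.

    S_f is pinned by the equilibrium condition
    [p + (q-p)h_m]·S_m = [p + (q-p)h_f]·S_f; the load is the average of
    the sex-specific mortality excesses

        μ_m = 2pq(1-h_m)·S_m + q²·S_m
        μ_f = 2pq·h_f·S_f + p²·S_f

    and equals the closed form (p + q²h_f - p²h_m) / (2[p + (q-p)h_f])·S_m.
    """
    p = float(p)
    q = 1.0 - p
    denom = p + (q - p) * h_f
    if abs(denom) < _SINGULAR_TOL:
        raise ZeroDivisionError("p + (q - p)·h_f = 0: equilibrium S_f undefined")
    S_f = (p + (q - p) * h_m) / denom * S_m
    mu_m = 2.0 * p * q * (1.0 - h_m) * S_m + q**2 * S_m
    mu_f = 2.0 * p * q * h_f * S_f + p**2 * S_f
    return LoadResult(mu_m=mu_m, mu_f=mu_f, L_SA=0.5 * (mu_m + mu_f))


def sa_load_closed_form(p, S_m, h_m=0.5, h_f=0.5) -> float:
    """Closed-form L_SA = (p + q²·h_f - p²·h_m) / (2[p + (q-p)·h_f]) · S_m."""
    p = float(p)
    q = 1.0 - p
    denom = p + (q - p) * h_f
    if abs(denom) < _SINGULAR_TOL:
        raise ZeroDivisionError("p + (q - p)·h_f = 0: load undefined")
    return (p + q**2 * h_f - p**2 * h_m) / (2.0 * denom) * S_m


def multi_locus_load(per_locus_loads) -> float:
    """Combined load 1 - Π(1 - L_i) over loci with independent effects."""
    loads = np.asarray(list(per_locus_loads), dtype=float)
    if np.any(loads >= 1.0) or np.any(loads < 0.0):
        raise ValueError("per-locus loads must lie in [0, 1)")
    return float(1.0 - np.prod(1.0 - loads))
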