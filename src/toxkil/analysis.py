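"""Outcome classification, invasion-speed estimation and sweep statistics.

The evolutionary outcome of a run is classified from the mean genotype and
phenotype abundances near the end of the run with a decision tree:
fixation of a phenotype class (> 98% abundance), coexistence of killer,
resistant and sensitive phenotypes (each > 2%, "KRS"), and — within KRS —
whether a regulating genotype is both appreciably abundant (>= 2%) and
genuinely switching (>= 10% of its cells in each of its active and
inactive phenotypes).

Front speeds in strip-invasion experiments are estimated from the linear
regression slope beta of a strain count on time:

    v_inv(S) = -beta_S / (K_S * N),      v_inv(R) = +beta_R / (K_R * N),

with K the carrying-capacity density of the invaded/invading strain and N
the number of lattice rows.

The radial cue profile of a circular colony of radius ``a`` with interior
density rho has the closed-form rim concentration
``rho * x * I1(x) * K0(x)`` with ``x = a / lambda`` and
``lambda = L_cue / sqrt(2)`` — the continuum steady state of a uniform
disk of producers under production--degradation--diffusion.  It increases
from 0 (point colony) to rho/2 (straight half-space edge).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .dynamics import Allele, GENOTYPE_LABELS, Lattice, MOORE_OFFSETS
from .regimes import REG_LABELS, RunRecord

__all__ = [
    "OutcomeLabel",
    "AbundanceSummary",
    "Classification",
    "InvasionResult",
    "summarise_record",
    "classify_outcome",
    "classify_record",
    "invasion_speed_sensitive",
    "invasion_speed_resistant",
    "edge_cue_analytic",
    "empty_neighbour_toxin_stats",
    "compare_sweep_conditions",
]

FIXATION_THRESHOLD = 0.98
KRS_THRESHOLD = 0.02
REG_ABUNDANCE_THRESHOLD = 0.02
REG_ACTIVITY_THRESHOLD = 0.10


class OutcomeLabel(str, enum.Enum):
    SENSITIVE_FIXED = "SENSITIVE_FIXED"
    KRS_NO_REG = "KRS_NO_REG"
    KRS_REG = "KRS_REG"
    OTHER = "OTHER"


@dataclass(frozen=True)
class AbundanceSummary:
    """Mean abundance fractions over the tail window of a run.

    ``phenotype_fractions`` has keys "K", "R", "S" (killer: phi_T = 1;
    resistant: phi_R = 1 and phi_T = 0; sensitive: the rest) and sums to
    1.  ``reg_activity`` maps each regulating genotype label to its
    ``(active, inactive)`` fractions (of that genotype's cells).
    """

    phenotype_fractions: dict
    genotype_fractions: dict
    reg_activity: dict

    def __post_init__(self) -> None:
        for d in (self.phenotype_fractions, self.genotype_fractions):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0 + 1e-9:
                    raise ValueError(f"fraction out of [0,1]: {k}={v}")
        tot = sum(self.phenotype_fractions.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"phenotype fractions sum to {tot}, expected 1")


@dataclass(frozen=True)
class Classification:
    label: OutcomeLabel
    fixation: bool
    krs: bool
    potential_regulation: bool
    true_regulation: bool


def summarise_record(
    record: RunRecord, window_steps: int = 50_000
) -> AbundanceSummary:
    """Mean abundances over the last ``window_steps`` of recorded rows.

    For serial-transfer runs the end-of-cycle rows are used when present
    (population size varies hugely within a cycle); otherwise all recorded
    rows in the window are averaged.
    """
    ts = record.cycle_ends if record.cycle_ends is not None else record.timeseries
    ts = ts[ts["pop"] > 0]
    if ts.empty:
        # extinct: nothing alive in the window; call everything sensitive
        return AbundanceSummary(
            {"K": 0.0, "R": 0.0, "S": 1.0},
            {label: 0.0 for label in GENOTYPE_LABELS.values()},
            {},
        )
    last = ts["step"].iloc[-1]
    tail = ts[ts["step"] > last - window_steps]
    pop = tail["pop"].to_numpy(dtype=float)
    pheno = {
        cls: float((tail[f"n_{cls}"].to_numpy() / pop).mean())
        for cls in ("K", "R", "S")
    }
    geno = {
        label: float((tail[f"n{label}"].to_numpy() / pop).mean())
        for label in GENOTYPE_LABELS.values()
    }
    reg_activity = {}
    for label in REG_LABELS:
        n = tail[f"n{label}"].to_numpy(dtype=float)
        if n.sum() == 0:
            continue
        active = tail[f"active{label}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_active = np.where(n > 0, active / n, np.nan)
        mean_active = float(np.nanmean(frac_active))
        reg_activity[label] = (mean_active, 1.0 - mean_active)
    return AbundanceSummary(pheno, geno, reg_activity)


def classify_outcome(summary: AbundanceSummary) -> Classification:
    """Walk the outcome decision tree over an abundance summary."""
    ph = summary.phenotype_fractions
    fixed_class = next(
        (cls for cls in ("S", "K", "R") if ph[cls] > FIXATION_THRESHOLD), None
    )
    if fixed_class is not None:
        label = (
            OutcomeLabel.SENSITIVE_FIXED
            if fixed_class == "S"
            else OutcomeLabel.OTHER  # K/R fixation: outside the named outcomes
        )
        return Classification(label, True, False, False, False)
    krs = all(ph[cls] > KRS_THRESHOLD for cls in ("K", "R", "S"))
    if not krs:
        return Classification(OutcomeLabel.OTHER, False, False, False, False)
    potential = False
    true_reg = False
    for label_g, frac in summary.genotype_fractions.items():
        if label_g not in summary.reg_activity:
            continue
        if frac < REG_ABUNDANCE_THRESHOLD:
            continue
        potential = True
        active, inactive = summary.reg_activity[label_g]
        if active >= REG_ACTIVITY_THRESHOLD and inactive >= REG_ACTIVITY_THRESHOLD:
            true_reg = True
    label = OutcomeLabel.KRS_REG if true_reg else OutcomeLabel.KRS_NO_REG
    return Classification(label, False, True, potential, true_reg)


def classify_record(
    record: RunRecord, window_steps: int = 50_000
) -> Classification:
    if record.extinct:
        return Classification(OutcomeLabel.OTHER, False, False, False, False)
    return classify_outcome(summarise_record(record, window_steps))


# --------------------------------------------------------------------------
# Invasion speeds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InvasionResult:
    beta: float  # regression slope, cells / step
    v_inv: float  # front speed, lattice sites / step
    K: float  # carrying-capacity density used in the conversion
    window: tuple[int, int]  # (first, last) series index of the fit window


class EstimationError(RuntimeError):
    pass


def _select_window(
    counts: np.ndarray, declining: bool
) -> tuple[int, int]:
    """Regression window: from front establishment to 50% of initial.

    The window opens when the invaded strain's count has moved by 2% of
    its initial value (front established) and closes when it passes 50% of
    the initial value (saturation), or at the end of the series.
    """
    c0 = counts[0]
    moved = np.abs(counts.astype(float) - c0) >= 0.02 * c0
    start_idx = int(np.argmax(moved)) if moved.any() else 0
    if declining:
        crossed = counts <= 0.5 * c0
    else:
        crossed = counts >= 1.5 * c0
    end_idx = int(np.argmax(crossed)) if crossed.any() else len(counts) - 1
    if end_idx <= start_idx:
        end_idx = len(counts) - 1
    return start_idx, end_idx


def _speed(
    t: np.ndarray,
    counts: np.ndarray,
    N: int,
    K: float,
    window: tuple[int, int] | None,
    sign: float,
    declining: bool,
) -> InvasionResult:
    t = np.asarray(t, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if window is None:
        window = _select_window(counts, declining)
    lo, hi = window
    if hi - lo + 1 < 10:
        raise EstimationError(
            f"regression window has {hi - lo + 1} points; need >= 10"
        )
    res = stats.linregress(t[lo : hi + 1], counts[lo : hi + 1])
    beta = float(res.slope)
    return InvasionResult(beta, sign * beta / (K * N), K, (lo, hi))


def invasion_speed_sensitive(
    t: np.ndarray,
    sensitive_counts: np.ndarray,
    N: int,
    K_S: float,
    window: tuple[int, int] | None = None,
) -> InvasionResult:
    """Killer front speed from the decline of the sensitive count.

    ``v = -beta / (K_S * N)`` with ``K_S = 1 - delta/gamma``.
    """
    if not 0 < K_S <= 1:
        raise ValueError(f"K_S must be in (0, 1], got {K_S}")
    return _speed(t, sensitive_counts, N, K_S, window, -1.0, declining=True)


def invasion_speed_resistant(
    t: np.ndarray,
    resistant_counts: np.ndarray,
    N: int,
    K_R: float,
    window: tuple[int, int] | None = None,
) -> InvasionResult:
    """Resistant front speed from the rise of the resistant count.

    ``v = +beta / (K_R * N)`` with ``K_R = 1 - delta/(gamma (1 - C_R))``.
    """
    if not 0 < K_R <= 1:
        raise ValueError(f"K_R must be in (0, 1], got {K_R}")
    return _speed(t, resistant_counts, N, K_R, window, +1.0, declining=False)


# --------------------------------------------------------------------------
# Analytic colony edge concentration
# --------------------------------------------------------------------------

def edge_cue_analytic(
    a: float | np.ndarray, L_cue: float, rho: float
) -> float | np.ndarray:
    """Cue concentration at the rim of a uniform disk colony.

    Continuum steady state of production rho (per unit area, in the units
    where a fully occupied plane gives concentration rho), degradation and
    diffusion: at the rim of a disk of radius ``a``,

        c(a) = rho * x * I1(x) * K0(x),    x = a / lambda,

    with decay length ``lambda = L_cue / sqrt(2)`` and modified Bessel
    functions I1, K0.  Strictly increasing in ``a`` and bounded above by
    rho/2.  Evaluated with exponentially scaled Bessel functions so large
    radii do not overflow.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("colony radius must be > 0")
    if L_cue <= 0:
        raise ValueError("L_cue must be > 0")
    if not 0 < rho <= 1:
        raise ValueError("interior density rho must be in (0, 1]")
    lam = L_cue / np.sqrt(2.0)
    x = a / lam
    # I1(x) K0(x) = ive(1, x) kve(0, x): the exp(x) and exp(-x) factors cancel
    val = rho * x * special.ive(1, x) * special.kve(0, x)
    return float(val) if val.ndim == 0 else val


# --------------------------------------------------------------------------
# Empty-neighbour toxin statistics
# --------------------------------------------------------------------------

def empty_neighbour_toxin_stats(
    lattice: Lattice,
    cue: np.ndarray,
    genotype: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per number of empty Moore neighbours k = 0..8: cell count, mean
    sensed cue, and the fraction currently producing toxin.

    ``genotype`` restricts the tabulation to one gene pair (e.g.
    ``(Allele.REG, Allele.ON)``); by default all cells are counted.
    """
    empty = ~lattice.occupied
    k_empty = np.zeros(empty.shape, dtype=np.int8)
    for di, dj in MOORE_OFFSETS:
        k_empty += np.roll(empty, (-di, -dj), axis=(0, 1))
    members = lattice.occupied.copy()
    if genotype is not None:
        t, r = genotype
        members &= (lattice.toxin_gene == int(t)) & (
            lattice.resist_gene == int(r)
        )
    rows = []
    for k in range(9):
        sel = members & (k_empty == k)
        n = int(sel.sum())
        rows.append(
            {
                "k_empty": k,
                "n_cells": n,
                "mean_cue": float(cue[sel].mean()) if n else np.nan,
                "frac_producing": float(lattice.phi_t[sel].mean())
                if n
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Sweep-level statistics
# --------------------------------------------------------------------------

SWEEP_PARAM_COLUMNS = ("L_cue", "L_tox", "R0_inv", "bT_hat", "C_R", "C_C")


def compare_sweep_conditions(
    sweep: pd.DataFrame,
    group_a: str,
    group_b: str,
    label_column: str = "label",
    params: tuple[str, ...] = SWEEP_PARAM_COLUMNS,
    thresholds: tuple[float, float] = (1e-6, 1e-3),
) -> pd.DataFrame:
    """Welch two-sided t-tests per lumped parameter between outcome groups.

    ``sweep`` is a one-row-per-run table with the lumped parameters and an
    outcome-label column.  P-values are Bonferroni-adjusted by the number
    of parameters tested; stars mark adjusted significance at the two
    ``thresholds`` ("**" below the first, "*" below the second).
    """
    import warnings

    a = sweep[sweep[label_column] == group_a]
    b = sweep[sweep[label_column] == group_b]
    m = len(params)
    rows = []
    for p in params:
        xa, xb = a[p].to_numpy(float), b[p].to_numpy(float)
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(
                f"group with < 2 members for {p}; excluded from comparison"
            )
            continue
        t_stat, p_val = stats.ttest_ind(xa, xb, equal_var=False)
        p_adj = min(1.0, float(p_val) * m)
        stars = (
            "**"
            if p_adj < thresholds[0]
            else "*"
            if p_adj < thresholds[1]
            else "n.s."
        )
        rows.append(
            {
                "parameter": p,
                f"mean_{group_a}": float(xa.mean()),
                f"mean_{group_b}": float(xb.mean()),
                "t": float(t_stat),
                "p": float(p_val),
                "p_bonferroni": p_adj,
                "significance": stars,
            }
        )
    return pd.DataFrame(rows)
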