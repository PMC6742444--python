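"""Per-time-step evolutionary update of the bacterial lattice.

Cells live on an N x N periodic lattice, at most one per site.  Each cell
carries a heritable genotype: a toxin gene and a resistance gene (alleles
Off / On / Reg), a toxin production rate ``pi_T`` and — when at least one
gene is regulated — a cue response threshold ``theta``.  Each step the
cell's realised phenotype ``(phi_T, phi_R, phi_C)`` is derived from the
genotype and the local cue concentration, after which death, competition
for reproduction into empty sites, and mutation of offspring are applied.

One time step executes, in order:

1. optional position shuffle (well-mixed control),
2. cue field solve (+ optional Gaussian sensing noise),
3. phenotype update (thresholds, toxin delay in (Reg,Reg) cells,
   optional expression lag),
4. toxin field solve from the updated phenotypes,
5. death sweep: each cell dies with probability
   ``min(1, delta + (1 - phi_R) * delta_tox * c_tox)``,
6. reproductive fitness of the survivors:
   ``R = max(0, 1 - phi_T*(C_T0 + b_T*pi_T) - phi_R*C_R - phi_C*C_C)``,
7. synchronous reproduction sweep: every currently empty site (including
   sites emptied this step) fills with probability
   ``1 - exp(-(gamma/8) * sum(R_i))`` over its 8 Moore neighbours, the
   parent drawn with probability ``R_j / sum(R_i)``,
8. offspring mutation and placement (children that would express toxin
   without resistance are nonviable; their birth is cancelled).

All randomness is drawn from one seeded ``numpy.random.Generator`` in the
fixed order above, so a run is bit-reproducible at fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from . import fields
from .params import RawParams

__all__ = [
    "Allele",
    "Genotype",
    "Lattice",
    "StepOptions",
    "VIABLE_PAIRS",
    "GENOTYPE_LABELS",
    "is_viable",
    "update_phenotypes",
    "reproductive_fitness",
    "death_sweep",
    "reproduction_sweep",
    "mutate_offspring",
    "step",
    "initialise_lattice",
    "shuffle_positions",
]


class Allele(IntEnum):
    OFF = 0
    ON = 1
    REG = 2


#: Gene pairs (toxin_gene, resistance_gene) under which toxin can never be
#: expressed without resistance.  Any other combination is nonviable.
VIABLE_PAIRS: tuple[tuple[Allele, Allele], ...] = (
    (Allele.OFF, Allele.OFF),
    (Allele.OFF, Allele.ON),
    (Allele.OFF, Allele.REG),
    (Allele.ON, Allele.ON),
    (Allele.REG, Allele.ON),
    (Allele.REG, Allele.REG),
)

_NAMES = {Allele.OFF: "Off", Allele.ON: "On", Allele.REG: "Reg"}

#: Human-readable labels of the six viable gene pairs, e.g. "(Reg,On)".
GENOTYPE_LABELS: dict[tuple[int, int], str] = {
    (int(t), int(r)): f"({_NAMES[t]},{_NAMES[r]})" for t, r in VIABLE_PAIRS
}


class CorruptedStateError(RuntimeError):
    pass


def is_viable(toxin_gene: Allele, resistance_gene: Allele) -> bool:
    """True iff no cue regime can express toxin without resistance.

    Toxin Off is always safe.  Constitutive toxin requires constitutive
    resistance.  Regulated toxin requires resistance that is On, or
    regulated by the same threshold (resistance then always precedes toxin
    expression, because the toxin additionally waits out the delay).
    """
    t, r = Allele(toxin_gene), Allele(resistance_gene)
    if t == Allele.OFF:
        return True
    if t == Allele.ON:
        return r == Allele.ON
    # t == REG: fine unless resistance can be off while cue >= theta
    return r in (Allele.ON, Allele.REG)


@dataclass(frozen=True)
class Genotype:
    """Scalar genotype used to construct strains and founders."""

    toxin_gene: Allele
    resistance_gene: Allele
    pi_t: float = 0.0
    theta: float | None = None

    def __post_init__(self) -> None:
        if not is_viable(self.toxin_gene, self.resistance_gene):
            raise ValueError(
                f"nonviable gene pair ({self.toxin_gene!s}, "
                f"{self.resistance_gene!s})"
            )
        has_reg = Allele.REG in (self.toxin_gene, self.resistance_gene)
        if has_reg and self.theta is None:
            raise ValueError("regulating genotype requires a theta")
        if self.pi_t < 0:
            raise ValueError("pi_t must be >= 0")

    @property
    def label(self) -> str:
        return GENOTYPE_LABELS[(int(self.toxin_gene), int(self.resistance_gene))]


# --------------------------------------------------------------------------
# Lattice state (structure of arrays)
# --------------------------------------------------------------------------

_PER_SITE_ARRAYS = (
    "occupied",
    "toxin_gene",
    "resist_gene",
    "pi_t",
    "theta",
    "phi_t",
    "phi_r",
    "phi_c",
    "delay",
    "pend_t",
    "pend_r",
    "lag_count",
    "fresh",
    "strain",
)


class Lattice:
    """N x N grid of cell states, at most one cell per site.

    Stored as a structure of per-site arrays.  ``theta`` is NaN at sites
    whose cell carries no Reg allele (and at empty sites); ``strain`` is an
    arbitrary integer label inherited by offspring, used to track
    constructed strains in phenotypic experiments.
    """

    def __init__(self, N: int):
        if N < 3:
            raise ValueError("lattice side must be >= 3")
        self.N = N
        shape = (N, N)
        self.occupied = np.zeros(shape, dtype=bool)
        self.toxin_gene = np.zeros(shape, dtype=np.int8)
        self.resist_gene = np.zeros(shape, dtype=np.int8)
        self.pi_t = np.zeros(shape, dtype=float)
        self.theta = np.full(shape, np.nan)
        self.phi_t = np.zeros(shape, dtype=bool)
        self.phi_r = np.zeros(shape, dtype=bool)
        self.phi_c = np.zeros(shape, dtype=bool)
        self.delay = np.zeros(shape, dtype=np.int32)
        # expression-lag bookkeeping: pending target phenotype + counter
        self.pend_t = np.zeros(shape, dtype=bool)
        self.pend_r = np.zeros(shape, dtype=bool)
        self.lag_count = np.zeros(shape, dtype=np.int32)
        self.fresh = np.zeros(shape, dtype=bool)
        self.strain = np.zeros(shape, dtype=np.int16)
        self.step_count = 0

    # -- construction helpers ------------------------------------------------

    def place(
        self,
        sites: np.ndarray,
        genotype: Genotype,
        strain: int = 0,
    ) -> None:
        """Place cells of one genotype at flat site indices ``sites``."""
        i, j = np.unravel_index(np.asarray(sites, dtype=np.intp), (self.N, self.N))
        if np.any(self.occupied[i, j]):
            raise ValueError("placement collides with occupied sites")
        self.occupied[i, j] = True
        self.toxin_gene[i, j] = int(genotype.toxin_gene)
        self.resist_gene[i, j] = int(genotype.resistance_gene)
        self.pi_t[i, j] = genotype.pi_t
        self.theta[i, j] = np.nan if genotype.theta is None else genotype.theta
        self.fresh[i, j] = True
        self.strain[i, j] = strain

    def copy(self) -> "Lattice":
        out = Lattice.__new__(Lattice)
        out.N = self.N
        for name in _PER_SITE_ARRAYS:
            setattr(out, name, getattr(self, name).copy())
        out.step_count = self.step_count
        return out

    # -- queries -------------------------------------------------------------

    @property
    def popsize(self) -> int:
        return int(self.occupied.sum())

    def has_reg(self) -> np.ndarray:
        return self.occupied & (
            (self.toxin_gene == Allele.REG) | (self.resist_gene == Allele.REG)
        )

    def genotype_key(self) -> np.ndarray:
        """Integer gene-pair key ``3*toxin_gene + resist_gene`` per site."""
        return 3 * self.toxin_gene.astype(np.int16) + self.resist_gene

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lattice):
            return NotImplemented
        if self.N != other.N or self.step_count != other.step_count:
            return False
        for name in _PER_SITE_ARRAYS:
            a, b = getattr(self, name), getattr(other, name)
            if name == "theta":
                if not np.array_equal(a, b, equal_nan=True):
                    return False
            elif not np.array_equal(a, b):
                return False
        return True


@dataclass(frozen=True)
class StepOptions:
    """Per-run switches of the update rule."""

    sigma_noise: float = 0.0
    lag_steps: int = 0
    well_mixed: bool = False
    mutations: bool = True


# --------------------------------------------------------------------------
# Phenotype determination
# --------------------------------------------------------------------------

def update_phenotypes(
    lattice: Lattice,
    cue_field: np.ndarray,
    raw: RawParams,
    lag_steps: int = 0,
) -> None:
    """Set each cell's realised phenotype from the current cue field.

    On genes express unconditionally, Off genes never, Reg genes iff the
    local cue is at or above the cell's threshold.  In (Reg,Reg) cells
    toxin expression additionally requires ``tau_delay`` consecutive
    above-threshold steps (the delay counter resets whenever the cue drops
    below theta).  With ``lag_steps > 0`` the realised phenotype follows
    the instantaneous target only after the target has persistently
    differed from it for ``lag_steps`` consecutive steps; newborn cells
    adopt their target immediately at their first update.
    """
    occ = lattice.occupied
    tg = lattice.toxin_gene
    rg = lattice.resist_gene
    reg_any = occ & ((tg == Allele.REG) | (rg == Allele.REG))
    if np.any(reg_any & np.isnan(lattice.theta)):
        raise CorruptedStateError("cell with a Reg allele but no theta")

    # NaN thetas (no Reg allele) compare False, as intended
    above = reg_any & (cue_field >= lattice.theta)

    # consecutive-steps-above-threshold counter (used by the RegReg delay)
    lattice.delay = np.where(above, lattice.delay + 1, 0).astype(np.int32)

    target_r = occ & ((rg == Allele.ON) | ((rg == Allele.REG) & above))
    target_t = occ & ((tg == Allele.ON) | ((tg == Allele.REG) & above))
    regreg = (tg == Allele.REG) & (rg == Allele.REG)
    # toxin waits out the delay: expressed from the (tau_delay+1)-th
    # consecutive above-threshold step
    target_t &= ~regreg | (lattice.delay > raw.tau_delay)

    lattice.phi_c = reg_any
    if lag_steps <= 0:
        lattice.phi_t = target_t
        lattice.phi_r = target_r
        lattice.fresh &= ~occ
        return

    # expression lag: persistence filter on the (phi_T, phi_R) pair
    newborn = occ & lattice.fresh
    lattice.phi_t[newborn] = target_t[newborn]
    lattice.phi_r[newborn] = target_r[newborn]
    lattice.lag_count[newborn] = 0
    lattice.fresh &= ~occ

    settled = ~newborn & occ
    differs = settled & (
        (target_t != lattice.phi_t) | (target_r != lattice.phi_r)
    )
    same_pending = (target_t == lattice.pend_t) & (target_r == lattice.pend_r)
    # target equals realised -> reset; new pending target -> restart count
    lattice.lag_count[settled & ~differs] = 0
    lattice.lag_count[differs & same_pending] += 1
    lattice.lag_count[differs & ~same_pending] = 1
    lattice.pend_t[differs] = target_t[differs]
    lattice.pend_r[differs] = target_r[differs]

    switch = differs & (lattice.lag_count >= lag_steps)
    lattice.phi_t[switch] = target_t[switch]
    lattice.phi_r[switch] = target_r[switch]
    lattice.lag_count[switch] = 0


# --------------------------------------------------------------------------
# Fitness, death, reproduction
# --------------------------------------------------------------------------

def reproductive_fitness(
    phi_t: np.ndarray | bool,
    phi_r: np.ndarray | bool,
    phi_c: np.ndarray | bool,
    pi_t: np.ndarray | float,
    raw: RawParams,
) -> np.ndarray:
    """R = max(0, 1 - phi_T*(C_T0 + b_T*pi_T) - phi_R*C_R - phi_C*C_C)."""
    cost = (
        np.multiply(phi_t, raw.C_T0 + raw.b_T * np.asarray(pi_t))
        + np.multiply(phi_r, raw.C_R)
        + np.multiply(phi_c, raw.C_C)
    )
    return np.maximum(0.0, 1.0 - cost)


_death_prob_clamped_logged = False


def death_sweep(
    lattice: Lattice,
    toxin_field: np.ndarray,
    raw: RawParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Kill each cell independently per the basal + toxin death law.

    Death probability is ``delta + (1 - phi_R) * delta_tox * c_tox``,
    clamped at 1 (a clamp event is logged once per process).  Returns the
    boolean mask of sites emptied this sweep.
    """
    global _death_prob_clamped_logged
    if toxin_field is None or not np.any(toxin_field):
        p = raw.delta
    else:
        p = raw.delta + (~lattice.phi_r) * raw.delta_tox * toxin_field
    if np.any(p > 1.0):
        if not _death_prob_clamped_logged:
            import logging

            logging.getLogger(__name__).warning(
                "death probability exceeded 1 and was clamped"
            )
            _death_prob_clamped_logged = True
        p = np.minimum(p, 1.0)
    u = rng.random(size=(lattice.N, lattice.N))
    died = lattice.occupied & (u < p)
    _clear_sites(lattice, *np.nonzero(died))
    return died


def _clear_sites(lattice: Lattice, i: np.ndarray, j: np.ndarray) -> None:
    lattice.occupied[i, j] = False
    lattice.toxin_gene[i, j] = 0
    lattice.resist_gene[i, j] = 0
    lattice.pi_t[i, j] = 0.0
    lattice.theta[i, j] = np.nan
    lattice.phi_t[i, j] = False
    lattice.phi_r[i, j] = False
    lattice.phi_c[i, j] = False
    lattice.delay[i, j] = 0
    lattice.pend_t[i, j] = False
    lattice.pend_r[i, j] = False
    lattice.lag_count[i, j] = 0
    lattice.fresh[i, j] = False
    lattice.strain[i, j] = 0


#: Moore neighbourhood offsets, in the fixed order used for parent choice.
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def reproduction_sweep(
    lattice: Lattice,
    fitness: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Synchronous birth resolution into all currently empty sites.

    Every empty site fills with probability
    ``1 - exp(-(gamma/8) * sum R_i)`` over its 8 Moore neighbours and the
    parent is drawn with probability ``R_j / sum R_i``.  One parent may
    seed several adjacent empty sites in the same sweep.  Returns the
    birth-site coordinate arrays and the matching parent coordinates
    (births are not yet placed on the lattice).
    """
    R = np.where(lattice.occupied, fitness, 0.0)
    # Moore-neighbourhood fitness sum via separable 3x3 block sum
    rowsum = np.roll(R, 1, axis=0) + R + np.roll(R, -1, axis=0)
    S = np.roll(rowsum, 1, axis=1) + rowsum + np.roll(rowsum, -1, axis=1) - R
    empty = ~lattice.occupied
    p_fill = -np.expm1(-(gamma / 8.0) * S)
    u_fill = rng.random(size=S.shape)
    births = empty & (u_fill < p_fill)
    bi, bj = np.nonzero(births)
    nb = bi.shape[0]
    if nb == 0:
        return bi, bj, bi, bj

    # parent choice: inverse-CDF over the 8 neighbours, in MOORE order
    offs = np.array(MOORE_OFFSETS, dtype=np.intp)
    ni = (bi[:, None] + offs[:, 0]) % lattice.N
    nj = (bj[:, None] + offs[:, 1]) % lattice.N
    cum = np.cumsum(R[ni, nj], axis=1)
    # a birth implies S > 0, so the total neighbour fitness is positive
    u_parent = rng.random(nb) * cum[:, -1]
    k = (u_parent[:, None] < cum).argmax(axis=1)
    rows = np.arange(nb)
    return bi, bj, ni[rows, k], nj[rows, k]


# --------------------------------------------------------------------------
# Mutation
# --------------------------------------------------------------------------

def _mutate_gene(
    gene: np.ndarray, u: np.ndarray, mu_gain: float, mu_loss: float
) -> np.ndarray:
    """Apply at most one allele transition per gene per birth.

    Each of the three gain transitions (Off->On, Off->Reg, On->Reg) fires
    with probability ``mu_gain`` and each of the three loss transitions
    (On->Off, Reg->Off, Reg->On) with probability ``mu_loss``; from any
    allele the two possible transitions are drawn as disjoint slices of
    one uniform variate (their combined probability is << 1).
    """
    out = gene.copy()
    off = gene == Allele.OFF
    on = gene == Allele.ON
    reg = gene == Allele.REG
    out[off & (u < mu_gain)] = Allele.ON
    out[off & (u >= mu_gain) & (u < 2 * mu_gain)] = Allele.REG
    out[on & (u < mu_loss)] = Allele.OFF
    out[on & (u >= mu_loss) & (u < mu_loss + mu_gain)] = Allele.REG
    out[reg & (u < mu_loss)] = Allele.OFF
    out[reg & (u >= mu_loss) & (u < 2 * mu_loss)] = Allele.ON
    return out


def _mutate_trait(
    value: np.ndarray,
    raw: RawParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Small-step / rare-jump mutation of a quantitative trait array.

    With probability ``mu`` the trait mutates; the mutant value is uniform
    on ``[v - sigma_mu, v + sigma_mu]`` clamped below at 0, except with
    probability ``p_largemut`` it is resampled uniform on [0, 1].
    """
    n = value.shape[0]
    out = value.copy()
    fires = rng.random(n) < raw.mu
    jumps = rng.random(n) < raw.p_largemut
    steps = value + (2.0 * rng.random(n) - 1.0) * raw.sigma_mu
    resample = rng.random(n)
    out[fires] = np.maximum(0.0, steps[fires])
    big = fires & jumps
    out[big] = resample[big]
    return out


def mutate_offspring(
    toxin_gene: np.ndarray,
    resist_gene: np.ndarray,
    pi_t: np.ndarray,
    theta: np.ndarray,
    raw: RawParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mutate a batch of offspring genotypes (vectorised over births).

    Returns ``(toxin_gene, resist_gene, pi_t, theta, viable)``; children
    whose mutated gene pair could express toxin without resistance are
    flagged nonviable (their birth is cancelled by the caller).  Children
    gaining a Reg allele from a Reg-free parent draw theta ~ U[0,1];
    children gaining a toxin gene from a toxin-Off parent draw
    pi_T ~ U[0,1].  Trait values are otherwise inherited, subject to the
    small-step / rare-jump mutation at rate ``mu``.
    """
    n = toxin_gene.shape[0]
    new_tg = _mutate_gene(toxin_gene, rng.random(n), raw.mu_gain, raw.mu_loss)
    new_rg = _mutate_gene(resist_gene, rng.random(n), raw.mu_gain, raw.mu_loss)

    viable = np.ones(n, dtype=bool)
    viable &= ~((new_tg == Allele.ON) & (new_rg != Allele.ON))
    viable &= ~((new_tg == Allele.REG) & (new_rg == Allele.OFF))

    new_theta = _mutate_trait(np.where(np.isnan(theta), 0.0, theta), raw, rng)
    parent_reg = (toxin_gene == Allele.REG) | (resist_gene == Allele.REG)
    child_reg = (new_tg == Allele.REG) | (new_rg == Allele.REG)
    gained_reg = child_reg & ~parent_reg
    new_theta[gained_reg] = rng.random(int(gained_reg.sum()))
    new_theta[~child_reg] = np.nan

    new_pi = _mutate_trait(pi_t, raw, rng)
    gained_tox = (new_tg != Allele.OFF) & (toxin_gene == Allele.OFF)
    new_pi[gained_tox] = rng.random(int(gained_tox.sum()))

    return new_tg, new_rg, new_pi, new_theta, viable


# --------------------------------------------------------------------------
# Whole-step orchestration
# --------------------------------------------------------------------------

def step(
    lattice: Lattice,
    raw: RawParams,
    rng: np.random.Generator,
    options: StepOptions = StepOptions(),
) -> dict:
    """Advance the lattice by one time step in place.

    Returns per-step event counts: deaths, births, nonviable offspring,
    and the solved cue field (for recording sensed concentrations).
    """
    if options.well_mixed:
        shuffle_positions(lattice, rng)

    # the cue field matters only if someone can respond to it; in
    # constitutive-strain experiments (mutations off, no Reg alleles,
    # no sensing noise) the solve is skipped without changing anything
    need_cue = (
        options.mutations
        or options.sigma_noise > 0
        or bool(
            (lattice.toxin_gene == Allele.REG).any()
            or (lattice.resist_gene == Allele.REG).any()
        )
    )
    if need_cue:
        cue_prod, _ = fields.production_grids(lattice, raw)
        cue = fields.solve_steady_state(cue_prod, raw.d_cue, raw.D_cue)
        if options.sigma_noise > 0:
            cue = fields.add_cue_noise(cue, options.sigma_noise, rng)
    else:
        cue = np.zeros((lattice.N, lattice.N))

    update_phenotypes(lattice, cue, raw, lag_steps=options.lag_steps)

    _, tox_prod = fields.production_grids(lattice, raw)
    if np.any(tox_prod):
        tox = fields.solve_steady_state(tox_prod, raw.d_tox, raw.D_tox)
        np.clip(tox, 0.0, None, out=tox)  # rounding guard
    else:
        tox = np.zeros_like(tox_prod)

    died = death_sweep(lattice, tox, raw, rng)
    n_deaths = int(died.sum())

    fitness = reproductive_fitness(
        lattice.phi_t, lattice.phi_r, lattice.phi_c, lattice.pi_t, raw
    )
    bi, bj, pi, pj = reproduction_sweep(lattice, fitness, raw.gamma, rng)

    tg = lattice.toxin_gene[pi, pj]
    rg = lattice.resist_gene[pi, pj]
    pit = lattice.pi_t[pi, pj]
    th = lattice.theta[pi, pj]
    strain = lattice.strain[pi, pj]
    if options.mutations:
        tg, rg, pit, th, viable = mutate_offspring(tg, rg, pit, th, raw, rng)
    else:
        viable = np.ones(tg.shape, dtype=bool)
    n_nonviable = int((~viable).sum())

    bi, bj = bi[viable], bj[viable]
    lattice.occupied[bi, bj] = True
    lattice.toxin_gene[bi, bj] = tg[viable]
    lattice.resist_gene[bi, bj] = rg[viable]
    lattice.pi_t[bi, bj] = pit[viable]
    lattice.theta[bi, bj] = th[viable]
    lattice.fresh[bi, bj] = True
    lattice.strain[bi, bj] = strain[viable]

    lattice.step_count += 1
    return {
        "deaths": n_deaths,
        "births": int(bi.shape[0]),
        "nonviable": n_nonviable,
        "cue": cue,
        "toxin": tox,
    }


def initialise_lattice(
    N: int, fraction: float, rng: np.random.Generator
) -> Lattice:
    """Random start: ``floor(fraction * N^2)`` cells with random genotypes.

    Gene pairs are uniform over the six viable combinations; ``pi_T`` is
    uniform on [0,1] for every cell and ``theta`` uniform on [0,1] for
    cells carrying at least one Reg allele.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"occupancy fraction must be in (0, 1], got {fraction}")
    lattice = Lattice(N)
    k = int(fraction * N * N)
    flat = rng.choice(N * N, size=k, replace=False)
    i, j = np.unravel_index(flat, (N, N))
    pair_idx = rng.integers(0, len(VIABLE_PAIRS), size=k)
    pairs = np.array([(int(t), int(r)) for t, r in VIABLE_PAIRS], dtype=np.int8)
    lattice.occupied[i, j] = True
    lattice.toxin_gene[i, j] = pairs[pair_idx, 0]
    lattice.resist_gene[i, j] = pairs[pair_idx, 1]
    lattice.pi_t[i, j] = rng.random(k)
    theta = rng.random(k)
    has_reg = (pairs[pair_idx, 0] == Allele.REG) | (pairs[pair_idx, 1] == Allele.REG)
    lattice.theta[i, j] = np.where(has_reg, theta, np.nan)
    lattice.fresh[i, j] = True
    return lattice


def shuffle_positions(lattice: Lattice, rng: np.random.Generator) -> None:
    """Uniformly permute all site contents (well-mixed control).

    The multiset of cell states is preserved exactly; only positions (and
    hence all spatial structure) are randomised.
    """
    perm = rng.permutation(lattice.N * lattice.N)
    for name in _PER_SITE_ARRAYS:
        arr = getattr(lattice, name)
        arr.ravel()[:] = arr.ravel()[perm]
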